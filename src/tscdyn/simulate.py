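"""Synthetic TSC-derivation datasets with known planted structure.

The generator emulates the study design the pipeline assumes: five
derivation stages (TE3.5 .. TSC_Pn) under NF, NT and SNT conditions with
2-5 replicates each, plus donor cumulus cell (CC) and MII oocyte methylome
references. It produces

* a negative-binomial gene x sample count matrix with six planted
  expression-trend clusters — clusters 1-3 continuously upregulated (the
  75 driver TFs live here), cluster 4 downregulated from outgrowth,
  clusters 5/6 transiently down-/upregulated — an NT-specific
  downregulation of cluster-2/3 driver TFs at outgrowth, and an SNT rescue
  of a configured fraction of them;
* binomially sampled per-CpG methylation calls over a CGI catalogue with
  planted stage-jump (PHIM) groups, donor-inherited and de novo aberrations
  in NT (partially rescued in SNT), and FGF4-driven TSC-stage
  hypermethylation;
* truth tables recording every planted label, so each downstream stage has
  a parameter-recovery test with no external download.

Replicate noise is i.i.d. given (stage, condition); batch structure is not
modeled. Coverage is drawn per CpG per replicate independently with a
configurable dropout probability that makes CpGs "not detected".
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .core import STAGE_ORDER, ExpressionMatrix, GenomicInterval, MethylationCallSet, SampleMeta, TSSRecord

N_CHROMS = 19
GENE_SPACING = 50_000


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults are the study conditions the pipeline's recovery tests assume:
    3 replicates per stage per condition, 75 driver TFs, NB dispersion 0.1,
    replicate noise 0.2 log2 units, CpG coverage mean 30 and planted
    methylation levels 0.05 (background) vs 0.60 (high).
    """

    seed: int = 0
    # expression
    n_genes: int = 6000
    n_tf: int = 1500
    n_driver_tf: int = 75
    replicates: int = 3
    library_size: int = 2_000_000
    nb_dispersion: float = 0.1
    noise_sd: float = 0.2
    background_stage_sd: float = 0.5
    tf_stage_sd_scale: float = 1.5
    tf_stage_sd_cap: float = 4.0
    pro_clusters: float = 0.02
    down_cluster: float = 0.0075
    transient_clusters: float = 0.0125
    nt_down_factor: float = 0.05
    # methylome
    n_cgis: int = 2500
    cpgs_per_cgi: tuple[int, int] = (8, 20)
    coverage_mean: float = 30.0
    dropout: float = 0.05
    meth_background: float = 0.05
    meth_high: float = 0.60
    phim_groups: tuple[float, float, float, float, float] = (0.04, 0.04, 0.04, 0.04, 0.04)
    donor_ahm: float = 0.20
    donor_fraction: float = 0.6
    fgf4_ahm: float = 0.04
    donor_alm: float = 0.02
    cc_only: float = 0.02
    rescue_fraction: float = 0.8
    # shared
    conditions: tuple[str, ...] = ("NF", "NT", "SNT")
    deterministic: bool = False

    def __post_init__(self) -> None:
        if not (self.n_driver_tf <= self.n_tf <= self.n_genes):
            raise ValueError("need n_driver_tf <= n_tf <= n_genes")
        if not (2 <= self.replicates <= 5):
            raise ValueError("replicates per stage per condition must be in [2, 5]")
        fracs = {
            "pro_clusters": self.pro_clusters,
            "down_cluster": self.down_cluster,
            "transient_clusters": self.transient_clusters,
            "donor_ahm": self.donor_ahm,
            "donor_fraction": self.donor_fraction,
            "fgf4_ahm": self.fgf4_ahm,
            "donor_alm": self.donor_alm,
            "cc_only": self.cc_only,
            "rescue_fraction": self.rescue_fraction,
            **{f"phim_group_{i+1}": f for i, f in enumerate(self.phim_groups)},
        }
        for name, f in fracs.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"planted fraction {name} must be in [0, 1], got {f}")
        if self.nb_dispersion <= 0 or self.coverage_mean <= 0:
            raise ValueError("nb_dispersion and coverage_mean must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("cpgs_per_cgi", "phim_groups", "conditions"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        for key in ("cpgs_per_cgi", "phim_groups", "conditions"):
            data[key] = list(data[key])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class TruthTables:
    """Planted labels the recovery tests compare against."""

    expression: pd.DataFrame          # gene: cluster, trend, is_tf, is_driver, ...
    profiles: pd.DataFrame | None = None   # gene x stage target normalized means (NF)
    methylation: pd.DataFrame | None = None  # cgi: category, phim_group, origin, rescued


# target log2(RPM+1) stage profiles per cluster; clusters 1-3 strictly
# increasing (1 rising mainly from TE4.5, 2 sharply and 3 gradually from
# outgrowth), shapes chosen to be separable after per-gene z-scoring
_CLUSTER_PROFILES = {
    1: np.array([2.0, 3.5, 5.0, 6.5, 8.0]),
    2: np.array([2.0, 2.3, 6.0, 7.2, 8.0]),
    3: np.array([2.0, 2.2, 2.9, 5.6, 8.0]),
    4: np.array([8.0, 7.7, 6.0, 4.0, 2.0]),
    5: np.array([7.0, 4.5, 2.0, 4.5, 7.0]),
    6: np.array([2.0, 4.5, 7.0, 4.5, 2.0]),
}

_CLUSTER_TREND = {1: "Pro", 2: "Pro", 3: "Pro", 4: "Down", 5: "Transient", 6: "Transient"}


def gene_ids(config: SimulationConfig) -> list[str]:
    return [f"G{i:05d}" for i in range(config.n_genes)]


def gene_annotation(config: SimulationConfig) -> tuple[list[TSSRecord], list[GenomicInterval], dict[int, np.ndarray]]:
    """Deterministic genome layout: TSSs, CGI intervals and CpG positions.

    Genes are laid out round-robin over 19 chromosomes at 50 kb spacing;
    CGI i is centered on the TSS of gene i (so CGI-gene association is
    exact by construction). Returns (tss records, cgis, cgi -> CpG
    positions).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    ids = gene_ids(config)
    tss_records = []
    for i, gid in enumerate(ids):
        chrom = f"chr{(i % N_CHROMS) + 1}"
        tss = 100_000 + (i // N_CHROMS) * GENE_SPACING
        tss_records.append(TSSRecord(gid, chrom, tss, "+"))
    lo, hi = config.cpgs_per_cgi
    n_cpgs = rng.integers(lo, hi + 1, size=config.n_cgis)
    cgis = []
    cgi_cpgs: dict[int, np.ndarray] = {}
    for i in range(config.n_cgis):
        rec = tss_records[i]
        gaps = rng.integers(6, 31, size=n_cpgs[i])
        span = int(gaps.sum())
        first = rec.tss - span // 2
        pos = first + np.cumsum(gaps) - gaps[0]
        cgi_cpgs[i] = pos.astype(int)
        cgis.append(GenomicInterval(rec.chrom, int(pos[0]) - 10, int(pos[-1]) + 12, f"CGI_{i:05d}"))
    return tss_records, cgis, cgi_cpgs


# ---------------------------------------------------------------------------
# Expression


def _gene_roles(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic gene role table: TF status, cluster, driver flag."""
    n = config.n_genes
    ids = gene_ids(config)
    cluster = np.zeros(n, dtype=int)
    is_tf = np.zeros(n, dtype=bool)
    is_driver = np.zeros(n, dtype=bool)
    is_tf[: config.n_tf] = True
    nd = config.n_driver_tf
    is_driver[:nd] = True
    cluster[:nd] = 1 + (np.arange(nd) % 3)
    n_pro = max(nd, int(round(config.pro_clusters * n)))
    n_down = int(round(config.down_cluster * n))
    n_trans = int(round(config.transient_clusters * n))
    extra_pro = n_pro - nd
    start = config.n_tf                      # planted non-driver genes are non-TF
    if start + extra_pro + n_down + n_trans > n:
        raise ValueError("planted expression fractions exceed available genes")
    cluster[start : start + extra_pro] = 1 + (np.arange(extra_pro) % 3)
    start += extra_pro
    cluster[start : start + n_down] = 4
    start += n_down
    cluster[start : start + n_trans] = 5 + (np.arange(n_trans) % 2)
    trend = np.array([_CLUSTER_TREND.get(c, "none") for c in cluster], dtype=object)
    return pd.DataFrame(
        {"cluster": cluster, "trend": trend, "is_tf": is_tf, "is_driver": is_driver},
        index=pd.Index(ids, name="gene_id"),
    )


def _nt_adjust(v: np.ndarray, factor: float) -> np.ndarray:
    """Scale the RPM-scale mean by ``factor`` on the log2(RPM+1) scale."""
    return np.log2((2.0 ** v - 1.0) * factor + 1.0)


def simulate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, TruthTables]:
    """Negative-binomial count matrix with the planted cluster structure."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    roles = _gene_roles(config)
    n = config.n_genes
    n_stages = len(STAGE_ORDER)

    # per-gene target normalized profiles (NF)
    profiles = np.zeros((n, n_stages))
    clusters = roles["cluster"].to_numpy()
    drivers = roles["is_driver"].to_numpy()
    shift = rng.normal(0.0, 0.4, size=n)
    scale = np.where(drivers, rng.uniform(0.75, 0.95, size=n), rng.uniform(0.55, 0.85, size=n))
    for c, base in _CLUSTER_PROFILES.items():
        sel = clusters == c
        center = base.mean()
        profiles[sel] = center + shift[sel, None] + scale[sel, None] * (base - center)
    # Background genes fluctuate across stages without a monotone trend.
    # Non-driver TFs get heavier-tailed stage variability than the bulk
    # transcriptome: the TF compendium responds to development with diverse
    # non-ordered patterns, which is why a random TF panel carries no
    # consistent derivation signal.
    bg = clusters == 0
    n_bg = int(bg.sum())
    level = rng.uniform(0.0, 10.0, size=n_bg)
    sd = np.full(n_bg, config.background_stage_sd)
    tf_bg = roles["is_tf"].to_numpy()[bg]
    # variable TFs sit in the low-to-mid expression range; the top of the
    # abundance distribution is stable housekeeping output, so their
    # fluctuations never dominate library composition
    level[tf_bg] = rng.uniform(0.0, 6.0, size=int(tf_bg.sum()))
    sd[tf_bg] = np.minimum(
        rng.exponential(config.tf_stage_sd_scale, size=int(tf_bg.sum())),
        config.tf_stage_sd_cap,
    )
    offsets = rng.normal(0.0, 1.0, size=(n_bg, n_stages)) * sd[:, None]
    profiles[bg] = level[:, None] + offsets
    profiles = np.clip(profiles, 0.0, None)

    # NT downregulation of cluster-2/3 drivers at outgrowth; SNT rescue
    nt_down = drivers & np.isin(clusters, (2, 3))
    idx_down = np.where(nt_down)[0]
    n_rescued = int(round(config.rescue_fraction * len(idx_down)))
    rescued_idx = rng.choice(idx_down, size=n_rescued, replace=False) if len(idx_down) else np.array([], int)
    snt_rescued = np.zeros(n, dtype=bool)
    snt_rescued[rescued_idx] = True
    og = STAGE_ORDER.index("outgrowth")

    samples: list[SampleMeta] = []
    cols: dict[str, np.ndarray] = {}
    disp = config.nb_dispersion
    for cond in config.conditions:
        for si, stage in enumerate(STAGE_ORDER):
            v = profiles[:, si].copy()
            if si == og and cond in ("NT", "SNT"):
                affected = nt_down if cond == "NT" else (nt_down & ~snt_rescued)
                v[affected] = _nt_adjust(v[affected], config.nt_down_factor)
            rpm = 2.0 ** v - 1.0
            rpm = rpm / rpm.sum() * 1e6
            mu = rpm / 1e6 * config.library_size
            for rep in range(1, config.replicates + 1):
                sid = f"{cond}_{stage}_{rep}"
                samples.append(SampleMeta(sid, cond, stage, rep))
                if config.deterministic:
                    counts = np.rint(mu).astype(int)
                else:
                    mu_rep = mu * 2.0 ** rng.normal(0.0, config.noise_sd, size=n)
                    lam = rng.gamma(shape=1.0 / disp, scale=mu_rep * disp)
                    counts = rng.poisson(lam)
                cols[sid] = counts
    counts_df = pd.DataFrame(cols, index=roles.index)

    truth = roles.copy()
    truth["nt_down"] = nt_down
    truth["snt_rescued"] = snt_rescued
    prof_df = pd.DataFrame(profiles, index=roles.index, columns=list(STAGE_ORDER))
    return ExpressionMatrix(counts_df, samples), TruthTables(truth, profiles=prof_df)


def tf_universe(config: SimulationConfig) -> list[str]:
    ids = gene_ids(config)
    return ids[: config.n_tf]


def driver_panel(config: SimulationConfig) -> list[str]:
    ids = gene_ids(config)
    return ids[: config.n_driver_tf]


# ---------------------------------------------------------------------------
# Methylome

_CATEGORIES = (
    "background",
    "phim",
    "donor_ahm",
    "denovo_ahm",
    "fgf4_ahm",
    "donor_alm",
    "cc_only",
)


def _methylation_roles(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_cgis
    names = [f"CGI_{i:05d}" for i in range(n)]
    cat = np.full(n, "background", dtype=object)
    phim_group = np.zeros(n, dtype=int)
    counts = {
        f"phim{g+1}": int(round(f * n)) for g, f in enumerate(config.phim_groups)
    }
    n_donor = int(round(config.donor_ahm * n))
    n_denovo = (
        int(round(n_donor * (1.0 - config.donor_fraction) / config.donor_fraction))
        if config.donor_fraction > 0
        else 0
    )
    counts.update(
        donor_ahm=n_donor,
        denovo_ahm=n_denovo,
        fgf4_ahm=int(round(config.fgf4_ahm * n)),
        donor_alm=int(round(config.donor_alm * n)),
        cc_only=int(round(config.cc_only * n)),
    )
    total = sum(counts.values())
    if total > n:
        raise ValueError("planted methylation fractions exceed the CGI count")
    order = rng.permutation(n)
    pos = 0
    for key, cnt in counts.items():
        sel = order[pos : pos + cnt]
        pos += cnt
        if key.startswith("phim"):
            cat[sel] = "phim"
            phim_group[sel] = int(key[4:])
        else:
            cat[sel] = key
    rescued = np.zeros(n, dtype=bool)
    for key in ("donor_ahm", "denovo_ahm", "donor_alm"):
        idx = np.where(cat == key)[0]
        k = int(round(config.rescue_fraction * len(idx)))
        if k:
            rescued[rng.choice(idx, size=k, replace=False)] = True
    origin = np.where(
        np.isin(cat, ("donor_ahm", "donor_alm")), "donor",
        np.where(np.isin(cat, ("denovo_ahm", "fgf4_ahm")), "de_novo", "none"),
    )
    return pd.DataFrame(
        {"category": cat, "phim_group": phim_group, "origin": origin, "rescued": rescued},
        index=pd.Index(names, name="cgi"),
    )


def _cgi_level_profiles(config: SimulationConfig, roles: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-profile CGI methylation levels, one array of shape (n_cgis, 5|1)."""
    bg, hi = config.meth_background, config.meth_high
    n = config.n_cgis
    jump_stage = {1: 1, 2: 1, 3: 2, 4: 3, 5: 4}  # stage index where group jumps
    base = np.full((n, 5), bg)
    cat = roles["category"].to_numpy()
    grp = roles["phim_group"].to_numpy()
    rescued = roles["rescued"].to_numpy()

    prof = {c: base.copy() for c in ("NF", "NT", "SNT")}
    cc = np.full(n, bg)
    mii = np.full(n, bg)

    for g, js in jump_stage.items():
        sel = (cat == "phim") & (grp == g)
        for cond in ("NF", "NT", "SNT"):
            prof[cond][sel, js:] = hi
        if g == 1:     # transient group: back down at outgrowth, high again in TSCs
            for cond in ("NF", "NT", "SNT"):
                prof[cond][sel, 2] = bg
                prof[cond][sel, 3:] = hi

    early = [0, 1, 2]
    tsc = [3, 4]
    for key, donor_high in (("donor_ahm", True), ("denovo_ahm", False)):
        sel = cat == key
        prof["NT"][np.ix_(sel, early)] = hi
        keep = sel & ~rescued
        prof["SNT"][np.ix_(keep, early)] = hi
        if donor_high:
            cc[sel] = hi
    sel = cat == "fgf4_ahm"
    prof["NT"][np.ix_(sel, tsc)] = hi
    prof["SNT"][np.ix_(sel, tsc)] = hi
    sel = cat == "donor_alm"
    prof["NF"][sel, :] = hi
    prof["NT"][np.ix_(sel, tsc)] = hi          # remodeled back high upon TSC formation
    snt_alm = sel & ~rescued
    prof["SNT"][sel, :] = hi                   # rescued: match NF everywhere
    prof["SNT"][np.ix_(snt_alm, early)] = bg   # unrescued keep the NT deficit
    mii[sel] = hi
    cc[cat == "cc_only"] = hi
    prof["CC"] = cc[:, None]
    prof["MII"] = mii[:, None]
    return prof


@dataclass
class MethylomeSim:
    """Simulated methylome: per-sample replicate call sets plus annotation."""

    replicate_calls: dict[str, list[MethylationCallSet]]   # sample -> replicates
    cgis: list[GenomicInterval]
    tss: list[TSSRecord]
    truth: pd.DataFrame
    samples: list[SampleMeta]
    cpg_positions: dict[str, np.ndarray]                   # chrom -> positions


def simulate_methylome(config: SimulationConfig) -> MethylomeSim:
    """Binomially sampled CpG calls over the planted CGI methylation program."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    tss, cgis, cgi_cpgs = gene_annotation(config)
    roles = _methylation_roles(config, rng)
    prof = _cgi_level_profiles(config, roles)

    cgi_idx = np.concatenate([np.full(len(p), i) for i, p in cgi_cpgs.items()])
    pos = np.concatenate([cgi_cpgs[i] for i in range(config.n_cgis)])
    chroms = np.array([cgis[i].chrom for i in cgi_idx], dtype=object)

    design: list[tuple[str, str, str, int]] = []    # (sample, cond, stage, n_reps)
    for cond in config.conditions:
        for stage in STAGE_ORDER:
            design.append((f"{cond}_{stage}", cond, stage, config.replicates))
    design.append(("CC", "CC", "none", 2))
    design.append(("MII", "MII", "none", 2))

    replicate_calls: dict[str, list[MethylationCallSet]] = {}
    samples = []
    for sid, cond, stage, n_reps in design:
        if stage == "none":
            p_cgi = prof[cond][:, 0]
        else:
            p_cgi = prof[cond][:, STAGE_ORDER.index(stage)]
        p = p_cgi[cgi_idx]
        reps = []
        for rep in range(1, n_reps + 1):
            cov = 1 + rng.poisson(config.coverage_mean - 1.0, size=len(pos))
            detected = rng.random(len(pos)) >= config.dropout
            meth = rng.binomial(cov, p)
            calls = pd.DataFrame(
                {
                    "chrom": chroms[detected],
                    "pos": pos[detected],
                    "meth": meth[detected],
                    "total": cov[detected],
                }
            )
            reps.append(MethylationCallSet(f"{sid}_rep{rep}", calls))
        replicate_calls[sid] = reps
        samples.append(SampleMeta(sid, cond, stage, 1))
    cpg_positions: dict[str, np.ndarray] = {}
    for chrom in sorted(set(chroms)):
        cpg_positions[chrom] = np.sort(pos[chroms == chrom])
    return MethylomeSim(replicate_calls, cgis, tss, roles, samples, cpg_positions)


# ---------------------------------------------------------------------------
# Dataset writer (CLI `tscdyn simulate`)


def write_dataset(config: SimulationConfig, outdir: str | Path) -> None:
    """Write the full synthetic dataset as flat files for CLI consumption."""
    from . import io_formats as io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr, truth = simulate_expression(config)
    io.write_counts(expr.counts, outdir / "counts.tsv")
    io.write_sample_table(expr.samples, outdir / "samples.tsv")
    io.write_gene_list(tf_universe(config), outdir / "tf_list.txt")
    io.write_gene_list(driver_panel(config), outdir / "panel.txt")

    meth = simulate_methylome(config)
    reports = outdir / "cpg_reports"
    reports.mkdir(exist_ok=True)
    for sid, reps in meth.replicate_calls.items():
        for cs in reps:
            io.write_cpg_report(cs, reports / f"{cs.sample_id}.tsv")
    io.write_bed(meth.cgis, outdir / "cgis.bed")
    io.write_tss_table(meth.tss, outdir / "tss.tsv")
    io.write_sample_table(meth.samples, outdir / "meth_samples.tsv")

    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    truth.expression.to_csv(truth_dir / "expression.tsv", sep="\t")
    if truth.profiles is not None:
        truth.profiles.to_csv(truth_dir / "profiles.tsv", sep="\t", float_format="%.6g")
    meth.truth.to_csv(truth_dir / "methylation.tsv", sep="\t")
    config.to_yaml(outdir / "config_resolved.yaml")
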