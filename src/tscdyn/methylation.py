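"""CpG-island methylation dynamics over the derivation time course.

CpG calls are filtered by coverage per replicate, pooled per sample, and
aggregated to CpG-island (CGI) methylation as the unweighted mean of the
contained CpGs' methylation ratios (not the pooled-count ratio). On top of
the CGI x sample matrix the module calls:

* differential CGIs — |ratio difference| > 0.25 and two-sided Fisher exact
  p < 0.05 on the pooled methylated/unmethylated counts;
* highly methylated CGIs — ratio strictly above 0.25;
* PHIM-CGIs (progressively highly increased methylation) — CGIs whose
  methylation jumps by more than 0.25 between stages of one condition's
  course, grouped by K-means on the adjacent-stage difference profile;
* AHM/ALM-CGIs — aberrantly highly/lowly methylated versus the NF
  counterpart stage (difference > 0.25 either way);
* rescue accounting — which NT aberrations are no longer aberrant in SNT;
* donor origin — whether an aberration is inherited from the donor cumulus
  cell (aberrant in CC versus MII oocyte too) or arose de novo.

Promoters are classified into high/intermediate/low CpG-density classes
(HCP/ICP/LCP) from a linear-weighted CpG density around the TSS, and CGIs
are associated to the closest gene whose TSS lies within 5 kb.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .core import STAGE_ORDER, GenomicInterval, MethylationCallSet, TSSRecord
from .enrichment import hypergeom_test

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# CpG retention and CGI aggregation


def retain_cpgs(
    replicates: Sequence[MethylationCallSet],
    sample_id: str,
    min_cov: int = 5,
    mode: str = "all",
) -> MethylationCallSet:
    """Coverage-filter replicate call sets and pool them into one sample.

    ``mode="all"`` (strict, default): a CpG is retained iff its coverage is
    >= ``min_cov`` in every replicate; counts of all replicates are then
    summed. ``mode="any"``: retained iff >= ``min_cov`` in at least one
    replicate; only qualifying replicates contribute counts.
    """
    if mode not in ("all", "any"):
        raise ValueError(f"mode must be 'all' or 'any', got {mode!r}")
    frames = [r.calls for r in replicates]
    empty = pd.DataFrame(columns=list(MethylationCallSet.COLUMNS)).astype(
        {"pos": int, "meth": int, "total": int}
    )
    if not frames:
        return MethylationCallSet(sample_id, empty)
    tagged = pd.concat(
        [f.assign(_rep=i) for i, f in enumerate(frames)], ignore_index=True
    )
    if tagged.empty:
        return MethylationCallSet(sample_id, empty)
    ok = tagged["total"] >= min_cov
    if mode == "all":
        n_reps = len(frames)
        per_cpg = tagged.groupby(["chrom", "pos"])
        counts_ok = ok.groupby([tagged["chrom"], tagged["pos"]]).sum()
        present = per_cpg.size()
        keep_idx = counts_ok[(counts_ok == n_reps) & (present == n_reps)].index
        pooled = (
            tagged.set_index(["chrom", "pos"]).loc[keep_idx]
            if len(keep_idx)
            else tagged.iloc[0:0].set_index(["chrom", "pos"])
        )
        merged = pooled.groupby(level=["chrom", "pos"])[["meth", "total"]].sum()
    else:
        qualifying = tagged[ok]
        merged = qualifying.groupby(["chrom", "pos"])[["meth", "total"]].sum()
    merged = merged.reset_index()
    if merged.empty:
        return MethylationCallSet(sample_id, empty)
    return MethylationCallSet(sample_id, merged)


@dataclass
class CGIMethylationMatrix:
    """CGI x sample methylation summary.

    ``ratio`` is the unweighted mean of contained CpGs' meth/total ratios
    (NaN where undetected); ``pooled_meth``/``pooled_total`` are count sums
    over the contained detected CpGs (the 2x2 substrate for Fisher tests);
    ``detected`` is the number of detected CpGs. Rows are restricted to
    retained CGIs.
    """

    cgis: list[GenomicInterval]
    ratio: pd.DataFrame
    pooled_meth: pd.DataFrame
    pooled_total: pd.DataFrame
    detected: pd.DataFrame
    overlapping_cgis: list[str] = field(default_factory=list)

    @property
    def cgi_names(self) -> list[str]:
        return list(self.ratio.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ratio.columns)

    def interval(self, name: str) -> GenomicInterval:
        for iv in self.cgis:
            if iv.name == name:
                return iv
        raise KeyError(name)


def _find_overlaps(cgis: Sequence[GenomicInterval]) -> list[str]:
    names = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in cgis:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for ivs in by_chrom.values():
        ivs = sorted(ivs, key=lambda x: x.start)
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.end:
                names += [a.name, b.name]
    return sorted(set(names))


def _assign_cpgs(
    calls: pd.DataFrame, cgis: Sequence[GenomicInterval], overlapping: bool
) -> pd.Series:
    """Map each CpG row to a CGI name ('' if outside all CGIs)."""
    out = pd.Series("", index=calls.index, dtype=object)
    if overlapping:
        from intervaltree import IntervalTree

        trees: dict[str, IntervalTree] = {}
        for iv in cgis:
            trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv.name)
        for i, (chrom, pos) in enumerate(zip(calls["chrom"], calls["pos"])):
            hits = trees.get(chrom, None)
            if hits is None:
                continue
            found = sorted(h.data for h in hits[pos])
            if found:
                out.iloc[i] = found[0]     # first by name when CGIs overlap
        return out
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    for chrom in {iv.chrom for iv in cgis}:
        ivs = sorted((iv for iv in cgis if iv.chrom == chrom), key=lambda x: x.start)
        by_chrom[chrom] = (
            np.array([iv.start for iv in ivs]),
            np.array([iv.end for iv in ivs]),
            [iv.name for iv in ivs],
        )
    for chrom, grp in calls.groupby("chrom"):
        if chrom not in by_chrom:
            continue
        starts, ends, names = by_chrom[chrom]
        pos = grp["pos"].to_numpy()
        j = np.searchsorted(starts, pos, side="right") - 1
        inside = (j >= 0) & (pos < ends[np.clip(j, 0, None)])
        hit_names = np.array([""] + names, dtype=object)[np.where(inside, j + 1, 0)]
        out.loc[grp.index] = hit_names
    return out


def cgi_methylation(
    sample_calls: Mapping[str, MethylationCallSet],
    cgis: Sequence[GenomicInterval],
    min_detected: int = 5,
    mode: str = "all",
) -> CGIMethylationMatrix:
    """Aggregate per-sample CpG calls to CGI methylation ratios.

    CGI ratio = unweighted mean over contained detected CpGs of meth/total.
    A CGI is retained iff its detected-CpG count is >= ``min_detected`` in
    every sample (``mode="all"``, strict default) or in at least one sample
    (``mode="any"``). Overlapping CGIs are allowed but flagged.
    """
    if mode not in ("all", "any"):
        raise ValueError(f"mode must be 'all' or 'any', got {mode!r}")
    overlapping = _find_overlaps(cgis)
    if overlapping:
        logger.warning("overlapping CGIs flagged: %s", overlapping[:10])
    names = [iv.name for iv in cgis]
    sample_ids = list(sample_calls)
    ratio = pd.DataFrame(np.nan, index=names, columns=sample_ids)
    meth = pd.DataFrame(0, index=names, columns=sample_ids, dtype=int)
    total = pd.DataFrame(0, index=names, columns=sample_ids, dtype=int)
    det = pd.DataFrame(0, index=names, columns=sample_ids, dtype=int)
    for sid, cs in sample_calls.items():
        calls = cs.calls
        if calls.empty:
            continue
        assigned = _assign_cpgs(calls, cgis, bool(overlapping))
        inside = assigned != ""
        sub = calls[inside].copy()
        sub["cgi"] = assigned[inside]
        sub["r"] = sub["meth"] / sub["total"]
        agg = sub.groupby("cgi").agg(
            ratio=("r", "mean"), meth=("meth", "sum"),
            total=("total", "sum"), detected=("r", "size"),
        )
        ratio.loc[agg.index, sid] = agg["ratio"]
        meth.loc[agg.index, sid] = agg["meth"]
        total.loc[agg.index, sid] = agg["total"]
        det.loc[agg.index, sid] = agg["detected"]
    if mode == "all":
        keep = (det >= min_detected).all(axis=1)
    else:
        keep = (det >= min_detected).any(axis=1)
    kept = list(ratio.index[keep])
    return CGIMethylationMatrix(
        [iv for iv in cgis if iv.name in set(kept)],
        ratio.loc[kept],
        meth.loc[kept],
        total.loc[kept],
        det.loc[kept],
        overlapping,
    )


# ---------------------------------------------------------------------------
# Differential / highly methylated / PHIM calls


def differential_cgis(
    matrix: CGIMethylationMatrix,
    sample_a: str,
    sample_b: str,
    delta: float = 0.25,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Differential CGIs between two samples.

    Called iff |ratio_a - ratio_b| > delta AND two-sided Fisher exact
    p < alpha on the pooled (meth, unmeth) 2x2 table. CGIs with a missing
    ratio in either sample are skipped (logged).
    """
    out = []
    for cgi in matrix.cgi_names:
        ra = matrix.ratio.at[cgi, sample_a]
        rb = matrix.ratio.at[cgi, sample_b]
        if np.isnan(ra) or np.isnan(rb):
            logger.info("skipping CGI %s: missing ratio", cgi)
            continue
        ma, ta = int(matrix.pooled_meth.at[cgi, sample_a]), int(matrix.pooled_total.at[cgi, sample_a])
        mb, tb = int(matrix.pooled_meth.at[cgi, sample_b]), int(matrix.pooled_total.at[cgi, sample_b])
        d = ra - rb
        p = fisher_exact_pooled(ma, ta, mb, tb)
        out.append((cgi, ra, rb, d, p, abs(d) > delta and p < alpha))
    return pd.DataFrame(
        out, columns=["cgi", "ratio_a", "ratio_b", "delta", "p", "called"]
    ).set_index("cgi")


def fisher_exact_pooled(meth_a: int, total_a: int, meth_b: int, total_b: int) -> float:
    """Two-sided Fisher exact p on the pooled-count 2x2 table."""
    table = [[meth_a, total_a - meth_a], [meth_b, total_b - meth_b]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def classify_high(matrix: CGIMethylationMatrix, threshold: float = 0.25) -> dict[str, set[str]]:
    """Per-sample sets of highly methylated CGIs (ratio strictly > threshold)."""
    return {
        sid: set(matrix.ratio.index[matrix.ratio[sid] > threshold])
        for sid in matrix.sample_ids
    }


@dataclass
class PHIMReport:
    table: pd.DataFrame          # index cgi: is_phim, group, d1..d4 deltas
    k: int
    mode: str
    group_profiles: pd.DataFrame | None = None

    @property
    def phim_cgis(self) -> list[str]:
        return list(self.table.index[self.table["is_phim"]])

    def group_members(self, group: int) -> list[str]:
        sel = self.table["group"] == group
        return list(self.table.index[sel])


def detect_phim(
    matrix: CGIMethylationMatrix,
    stage_samples: Sequence[str],
    delta: float = 0.25,
    k: int = 5,
    seed: int = 0,
    mode: str = "adjacent",
) -> PHIMReport:
    """Progressively highly increased methylation CGIs in one condition.

    ``stage_samples`` names the condition's five stage columns in canonical
    order. ``mode="adjacent"`` (default) calls a CGI PHIM iff the largest
    absolute adjacent-stage ratio difference exceeds ``delta``;
    ``mode="global"`` uses max-over-stages minus min-over-stages. PHIM CGIs
    are grouped by K-means (fixed seed, 10 restarts, best inertia) on their
    adjacent-stage difference profile; groups are relabeled 1..k by the
    stage at which the group's mean jump occurs.
    """
    if mode not in ("adjacent", "global"):
        raise ValueError(f"mode must be 'adjacent' or 'global', got {mode!r}")
    R = matrix.ratio.loc[:, list(stage_samples)]
    complete = R.notna().all(axis=1)
    R = R.loc[complete]
    diffs = R.to_numpy()[:, 1:] - R.to_numpy()[:, :-1]
    if mode == "adjacent":
        is_phim = np.abs(diffs).max(axis=1) > delta
    else:
        vals = R.to_numpy()
        is_phim = (vals.max(axis=1) - vals.min(axis=1)) > delta
    dcols = [f"d{i + 1}" for i in range(diffs.shape[1])]
    table = pd.DataFrame(diffs, index=R.index, columns=dcols)
    table.insert(0, "is_phim", is_phim)
    table["group"] = 0
    phim_idx = table.index[table["is_phim"]]
    profiles = None
    if len(phim_idx) > 0:
        if k > len(phim_idx):
            raise ValueError(f"k={k} exceeds number of PHIM CGIs ({len(phim_idx)})")
        X = table.loc[phim_idx, dcols].to_numpy()
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        raw = km.fit_predict(X)
        centers = km.cluster_centers_
        order = sorted(
            range(k), key=lambda c: (int(np.argmax(np.abs(centers[c]))), -np.ptp(centers[c]))
        )
        remap = {c: i + 1 for i, c in enumerate(order)}
        table.loc[phim_idx, "group"] = [remap[c] for c in raw]
        profiles = pd.DataFrame(
            [centers[c] for c in order], index=range(1, k + 1), columns=dcols
        )
    return PHIMReport(table, k, mode, profiles)


# ---------------------------------------------------------------------------
# Aberrant methylation, rescue, donor origin


def detect_aberrant(
    matrix: CGIMethylationMatrix,
    test_samples: Mapping[str, str],
    ref_samples: Mapping[str, str],
    delta: float = 0.25,
) -> pd.DataFrame:
    """AHM/ALM status per (CGI, stage) of a test condition versus reference.

    ``test_samples``/``ref_samples`` map stage name -> sample column. AHM
    iff ratio_test - ratio_ref > delta; ALM iff ratio_ref - ratio_test >
    delta; else normal (NaN ratios give status 'missing').
    """
    stages = [s for s in STAGE_ORDER if s in test_samples] or list(test_samples)
    out = pd.DataFrame("normal", index=matrix.cgi_names, columns=stages, dtype=object)
    for stage in stages:
        if stage not in ref_samples:
            raise ValueError(f"stage {stage!r} missing from reference samples")
        rt = matrix.ratio[test_samples[stage]]
        rr = matrix.ratio[ref_samples[stage]]
        d = rt - rr
        col = np.where(
            d.isna(), "missing", np.where(d > delta, "AHM", np.where(-d > delta, "ALM", "normal"))
        )
        out[stage] = col
    return out


def aberrant_sets(report: pd.DataFrame, stage: str, status: str = "AHM") -> set[str]:
    """CGIs with a given aberrant status at a stage."""
    return set(report.index[report[stage] == status])


def rescue_accounting(
    nt_report: pd.DataFrame, snt_report: pd.DataFrame, stage: str, status: str = "AHM"
) -> dict[str, int]:
    """Account for which NT aberrations are corrected under Scriptaid.

    corrected = NT aberrant CGIs no longer aberrant in SNT at the same
    stage; uncorrected = still aberrant. The partition identity
    n_corrected + n_uncorrected == n_NT always holds.
    """
    if set(nt_report.index) != set(snt_report.index):
        raise ValueError("NT and SNT reports must cover the same CGI universe")
    nt = aberrant_sets(nt_report, stage, status)
    snt = aberrant_sets(snt_report, stage, status)
    uncorrected = nt & snt
    return {
        "n_NT": len(nt),
        "n_corrected": len(nt - snt),
        "n_uncorrected": len(uncorrected),
        "n_SNT": len(snt),
        "n_shared": len(uncorrected),
    }


def donor_origin(
    report: pd.DataFrame,
    stage: str,
    donor_set: set[str],
    universe: Sequence[str],
    status: str = "AHM",
) -> dict:
    """Attribute a stage's aberrant CGIs to donor inheritance or de novo.

    An aberrant CGI is donor-inherited iff it is also aberrant in the donor
    cumulus cell versus the MII oocyte (``donor_set``); otherwise de novo.
    Returns per-CGI labels, the inherited fraction and a hypergeometric
    enrichment p of the overlap within ``universe``.
    """
    ab = aberrant_sets(report, stage, status)
    labels = pd.Series(
        {c: ("donor_inherited" if c in donor_set else "de_novo") for c in sorted(ab)},
        dtype=object,
    )
    n = len(ab)
    inherited = int((labels == "donor_inherited").sum()) if n else 0
    N = len(set(universe))
    p = (
        hypergeom_test(inherited, n, len(donor_set & set(universe)), N)
        if n and donor_set
        else 1.0
    )
    return {
        "labels": labels,
        "n_aberrant": n,
        "n_inherited": inherited,
        "inherited_fraction": inherited / n if n else float("nan"),
        "enrichment_p": p,
    }


def donor_aberrant(
    matrix: CGIMethylationMatrix, cc_sample: str, mii_sample: str, delta: float = 0.25
) -> pd.DataFrame:
    """CC-versus-MII aberrant status (single comparison, stage label 'donor')."""
    return detect_aberrant(
        matrix, {"donor": cc_sample}, {"donor": mii_sample}, delta=delta
    )


# ---------------------------------------------------------------------------
# Promoter CpG density and CGI-gene association


def cpg_density(
    positions: Sequence[int], center: int, window: int = 300, weighting: str = "linear"
) -> float:
    """CpG density around a center position.

    With ``weighting="linear"`` each CpG at distance d <= window/2
    contributes w(d) = 1 - d / (window / 2) (the center CpG contributes 1);
    ``weighting="uniform"`` counts CpGs in the window.
    """
    if window <= 0 or window % 2:
        raise ValueError("window must be a positive even integer")
    half = window / 2
    pos = np.asarray(positions, dtype=float)
    d = np.abs(pos - center)
    inside = d <= half
    if weighting == "linear":
        return float(np.sum(1.0 - d[inside] / half))
    if weighting == "uniform":
        return float(np.sum(inside))
    raise ValueError(f"weighting must be 'linear' or 'uniform', got {weighting!r}")


def classify_promoters(
    tss_records: Sequence[TSSRecord],
    cpg_positions: Mapping[str, Sequence[int]],
    lo: float,
    hi: float,
    window: int = 300,
) -> pd.DataFrame:
    """HCP/ICP/LCP promoter classes from linear-weighted CpG density at the TSS.

    The lo/hi density thresholds are analysis parameters (their scale
    depends on the CpG catalogue used); HCP iff density >= hi, LCP iff
    density < lo, else ICP.
    """
    if lo > hi:
        raise ValueError("lo threshold must not exceed hi")
    rows = []
    for rec in tss_records:
        pos = cpg_positions.get(rec.chrom, ())
        dens = cpg_density(pos, rec.tss, window=window)
        cls = "HCP" if dens >= hi else ("LCP" if dens < lo else "ICP")
        rows.append((rec.gene_id, dens, cls))
    return pd.DataFrame(rows, columns=["gene_id", "density", "class"]).set_index("gene_id")


def associate_cgi_gene(
    cgis: Sequence[GenomicInterval],
    tss_records: Sequence[TSSRecord],
    max_dist: int = 5000,
) -> pd.DataFrame:
    """Associate each CGI with the closest gene whose TSS lies within 5 kb.

    Distance is measured from the interval boundary (0 if the TSS lies
    inside the CGI); ties are broken by lexicographic gene_id (logged).
    """
    by_chrom: dict[str, list[TSSRecord]] = {}
    for rec in sorted(tss_records, key=lambda r: (r.chrom, r.tss, r.gene_id)):
        by_chrom.setdefault(rec.chrom, []).append(rec)
    rows = []
    for iv in cgis:
        recs = by_chrom.get(iv.chrom, [])
        best: tuple[int, str] | None = None
        tied = False
        for rec in recs:
            d = iv.distance_to(rec.tss)
            if d > max_dist:
                continue
            key = (d, rec.gene_id)
            if best is None or key < best:
                tied = best is not None and d == best[0]
                best = key
        if best is not None:
            if tied:
                logger.info("CGI %s: distance tie broken by gene_id -> %s", iv.name, best[1])
            rows.append((iv.name, best[1], best[0]))
    return pd.DataFrame(rows, columns=["cgi", "gene_id", "distance"]).set_index("cgi")
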