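"""End-to-end recovery benchmarks on the synthetic study conditions.

Each function regenerates its inputs from a seed, runs the relevant
pipeline stage and measures how well the planted structure is recovered.
They are used by the acceptance script and the acceptance test suite.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from sklearn.metrics import adjusted_rand_score

from . import expression as ex
from . import methylation as me
from . import pseudotime as pt
from .core import STAGE_ORDER
from .simulate import (
    SimulationConfig,
    driver_panel,
    simulate_expression,
    simulate_methylome,
    tf_universe,
)


def pseudotime_recovery(seed: int, n_seeds: int = 20, iterations: int = 500) -> dict:
    """Driver-panel pseudotime vs the random-panel null over a seed sweep.

    For each derived seed: the 75-driver panel must order the five NF
    stages perfectly (stage-mean Spearman), while the random-TF null's
    per-replicate mean should leave at least one adjacent stage pair
    overlapping.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_seeds)
    n_perfect = 0
    n_separated = 0
    n_null_overlap = 0
    for s in seeds:
        cfg = SimulationConfig(seed=int(s))
        m, _ = simulate_expression(cfg)
        nf = m.subset_samples(x.sample_id for x in m.samples_where(condition="NF"))
        panel = driver_panel(cfg)
        lam = pt.compute_lambda(nf.norm, nf.samples, panel)
        T = pt.infer_pseudotime(nf.norm, panel, lam)
        diag = pt.stage_ordering_diagnostics(T, nf.samples)
        n_perfect += diag.stage_mean_spearman == 1.0
        n_separated += diag.fully_separated
        null = pt.null_pseudotime(
            m.norm, m.samples, tf_universe(cfg), n=len(panel),
            iterations=iterations, seed=int(s),
        )
        null_nf = null.loc[[x.sample_id for x in nf.samples]]
        null_diag = pt.stage_ordering_diagnostics(null_nf, nf.samples)
        n_null_overlap += any(null_diag.adjacent_overlaps)
    return {
        "n_seeds": n_seeds,
        "n_perfect_order": int(n_perfect),
        "n_fully_separated": int(n_separated),
        "n_null_overlap": int(n_null_overlap),
        "iterations": iterations,
    }


def _cgi_matrix(cfg: SimulationConfig):
    sim = simulate_methylome(cfg)
    pooled = {sid: me.retain_cpgs(reps, sid) for sid, reps in sim.replicate_calls.items()}
    return sim, me.cgi_methylation(pooled, sim.cgis)


def phim_recovery(seed: int, n_cgis_per_class: int = 200, delta: float = 0.25) -> dict:
    """PHIM sensitivity/specificity at planted jumps of 0.30 vs 0.20,
    plus K-means group recovery on the well-separated default jumps."""
    jump_kw = dict(
        n_genes=400, n_tf=100, n_driver_tf=10, pro_clusters=0.025,
        down_cluster=0.0, transient_clusters=0.0,
        n_cgis=2 * n_cgis_per_class,
        phim_groups=(0.1, 0.1, 0.1, 0.1, 0.1),     # half the CGIs are PHIM
        donor_ahm=0.0, fgf4_ahm=0.0, donor_alm=0.0, cc_only=0.0,
        coverage_mean=30.0, conditions=("NF",),
    )
    stage_cols = [f"NF_{s}" for s in STAGE_ORDER]

    # jump 0.30: planted CGIs must be called at delta 0.25
    cfg_hi = SimulationConfig(seed=seed, meth_high=0.35, **jump_kw)
    sim_hi, mat_hi = _cgi_matrix(cfg_hi)
    truth_hi = sim_hi.truth.loc[mat_hi.cgi_names]
    rep_hi = me.detect_phim(mat_hi, stage_cols, delta=delta, k=5, seed=seed)
    planted = truth_hi["category"] == "phim"
    called = rep_hi.table["is_phim"]
    sensitivity = float(called[planted].mean())

    # jump 0.20: planted CGIs must not be called
    cfg_lo = SimulationConfig(seed=seed + 1, meth_high=0.25, **jump_kw)
    sim_lo, mat_lo = _cgi_matrix(cfg_lo)
    truth_lo = sim_lo.truth.loc[mat_lo.cgi_names]
    rep_lo = me.detect_phim(mat_lo, stage_cols, delta=delta, k=1, seed=seed)
    planted_lo = truth_lo["category"] == "phim"
    fpr = float(rep_lo.table["is_phim"][planted_lo].mean())

    # K-means group recovery on the default, well-separated jump profiles
    cfg = SimulationConfig(seed=seed)
    sim, mat = _cgi_matrix(cfg)
    rep = me.detect_phim(mat, stage_cols, delta=delta, k=5, seed=0)
    truth = sim.truth.loc[mat.cgi_names]
    both = truth.index[(truth["category"] == "phim") & rep.table["is_phim"]]
    ari = float(
        adjusted_rand_score(truth.loc[both, "phim_group"], rep.table.loc[both, "group"])
    )
    return {
        "sensitivity": sensitivity,
        "false_positive_rate": fpr,
        "kmeans_ari": ari,
        "n_per_class": n_cgis_per_class,
    }


def rescue_origin_recovery(seed: int) -> dict:
    """Scriptaid rescue accounting and donor-origin attribution.

    Default study conditions plant 500 donor-inherited AHM CGIs, a rescue
    fraction of 0.8 and a donor fraction of 0.6 among early NT AHM CGIs.
    """
    cfg = SimulationConfig(seed=seed)
    sim, mat = _cgi_matrix(cfg)
    stage_map = lambda cond: {s: f"{cond}_{s}" for s in STAGE_ORDER}
    nt = me.detect_aberrant(mat, stage_map("NT"), stage_map("NF"))
    snt = me.detect_aberrant(mat, stage_map("SNT"), stage_map("NF"))
    acct = me.rescue_accounting(nt, snt, "TE3.5")
    donor = me.donor_aberrant(mat, "CC", "MII")
    donor_set = me.aberrant_sets(donor, "donor", "AHM")
    org = me.donor_origin(nt, "TE3.5", donor_set, mat.cgi_names)
    return {
        "n_NT_AHM": acct["n_NT"],
        "n_corrected": acct["n_corrected"],
        "n_uncorrected": acct["n_uncorrected"],
        "corrected_fraction": acct["n_corrected"] / acct["n_NT"] if acct["n_NT"] else float("nan"),
        "inherited_fraction": org["inherited_fraction"],
        "partition_holds": acct["n_corrected"] + acct["n_uncorrected"] == acct["n_NT"],
        "planted_rescue_fraction": cfg.rescue_fraction,
        "planted_donor_fraction": cfg.donor_fraction,
        "n_retained_cgis": len(mat.cgi_names),
    }


def deg_threshold_semantics() -> dict:
    """Threshold semantics on a constructed six-gene statistic table."""
    import pandas as pd

    stat = pd.DataFrame(
        {
            "p": [1e-6, 1e-6, 0.5, 1e-6, 0.02, 1e-6],
            "lfc": [3.0, -4.0, 3.0, 1.0, 2.5, 2.01],
        },
        index=[f"g{i}" for i in range(6)],
    )
    counts = pd.DataFrame(index=stat.index)
    tab = ex.call_degs(counts, [], [], p_thresh=0.01, lfc_thresh=2.0, stat_table=stat)
    swapped = ex.call_degs(
        counts, [], [], p_thresh=0.01, lfc_thresh=2.0,
        stat_table=stat.assign(lfc=-stat["lfc"]),
    )
    antisym = bool(
        (tab["direction"].map({"up": "down", "down": "up"}) == swapped["direction"]).all()
    )
    return {
        "n_significant": int(tab["significant"].sum()),
        "significant_genes": sorted(tab.index[tab["significant"]]),
        "direction_antisymmetric": antisym,
    }
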