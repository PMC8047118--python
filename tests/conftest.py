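import numpy as np
import pandas as pd
import pytest

from tscdyn.core import STAGE_ORDER, SampleMeta
from tscdyn.simulate import SimulationConfig, simulate_expression, simulate_methylome


TINY_KW = dict(
    n_genes=300,
    n_tf=80,
    n_driver_tf=12,
    replicates=2,
    library_size=200_000,
    n_cgis=60,
    cpgs_per_cgi=(6, 10),
    coverage_mean=20.0,
    phim_groups=(0.05,) * 5,
    donor_ahm=0.1,
    fgf4_ahm=0.05,
    donor_alm=0.03,
    cc_only=0.03,
    pro_clusters=0.05,
    down_cluster=0.02,
    transient_clusters=0.02,
)


@pytest.fixture(scope="session")
def tiny_cfg() -> SimulationConfig:
    return SimulationConfig(seed=7, **TINY_KW)


@pytest.fixture(scope="session")
def default_sim():
    """Default-condition expression dataset plus truth (seed fixed)."""
    cfg = SimulationConfig(seed=11)
    matrix, truth = simulate_expression(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def meth_pipeline():
    """Default-condition methylome, pooled per sample and aggregated to CGIs."""
    from tscdyn import methylation as me

    cfg = SimulationConfig(seed=11)
    sim = simulate_methylome(cfg)
    pooled = {sid: me.retain_cpgs(reps, sid) for sid, reps in sim.replicate_calls.items()}
    matrix = me.cgi_methylation(pooled, sim.cgis)
    return cfg, sim, matrix


def make_matrix(ratios: dict[str, list[float]], samples: list[str], n_cpgs: int = 10,
                coverage: int = 100):
    """Construct a CGIMethylationMatrix directly from exact ratios."""
    from tscdyn.core import GenomicInterval
    from tscdyn.methylation import CGIMethylationMatrix

    names = list(ratios)
    cgis = [GenomicInterval("chr1", 1000 * (i + 1), 1000 * (i + 1) + 500, n)
            for i, n in enumerate(names)]
    ratio = pd.DataFrame({s: [ratios[n][j] for n in names] for j, s in enumerate(samples)},
                         index=names)
    total = pd.DataFrame(n_cpgs * coverage, index=names, columns=samples)
    meth = (ratio * total).round().astype(int)
    det = pd.DataFrame(n_cpgs, index=names, columns=samples)
    return CGIMethylationMatrix(cgis, ratio, meth, total, det)
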