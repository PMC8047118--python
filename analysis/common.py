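"""Shared setup for the analysis drivers.

Every driver regenerates the same synthetic study from one seed (cheap,
seconds) rather than passing large intermediates on disk; small result
tables go to results/.
"""

from pathlib import Path

from tscdyn.simulate import SimulationConfig

ANALYSIS_SEED = 11

RESULTS = Path(__file__).resolve().parent.parent / "results"


def study_config(**overrides) -> SimulationConfig:
    return SimulationConfig(seed=ANALYSIS_SEED, **overrides)


def results_dir() -> Path:
    RESULTS.mkdir(exist_ok=True)
    return RESULTS
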