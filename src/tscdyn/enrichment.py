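"""Set-overlap and comparison statistics used throughout the pipeline.

Given two gene/CGI sets of sizes nA and nB drawn from a universe of N
items with observed overlap k:

* hypergeometric over-representation p-value, P(X >= k);
* representation factor RF = k / (nA * nB / N), the observed overlap
  divided by the overlap expected under independence;
* over-representation score, log2(RF) * (-log10(p)), combining effect size
  and significance in one signed quantity (positive for enrichment).

Paired comparisons between matched sample vectors use a two-sided paired t
test with Holm step-down adjustment across the comparison family;
Benjamini-Hochberg adjustment backs the differential-expression caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class EnrichmentResult:
    k: int
    nA: int
    nB: int
    N: int
    p: float
    rf: float
    ors: float

    def as_dict(self) -> dict:
        return {
            "k": self.k,
            "nA": self.nA,
            "nB": self.nB,
            "N": self.N,
            "p": self.p,
            "rf": self.rf,
            "ors": self.ors,
        }


def _validate(k: int, nA: int, nB: int, N: int) -> None:
    if N <= 0:
        raise ValueError("universe size N must be positive")
    if nA < 0 or nB < 0 or nA > N or nB > N:
        raise ValueError(f"set sizes must lie in [0, N]; got nA={nA}, nB={nB}, N={N}")
    if k < 0 or k > min(nA, nB):
        raise ValueError(f"overlap k={k} outside [0, min(nA, nB)={min(nA, nB)}]")


def hypergeom_test(k: int, nA: int, nB: int, N: int, tail: str = "over") -> float:
    """Hypergeometric tail probability of an overlap of k between two sets.

    ``tail="over"`` (default) returns P(X >= k), the over-representation
    p-value; ``tail="under"`` returns P(X <= k).
    """
    _validate(k, nA, nB, N)
    rv = stats.hypergeom(N, nA, nB)
    if tail == "over":
        return float(min(1.0, rv.sf(k - 1)))
    if tail == "under":
        return float(min(1.0, rv.cdf(k)))
    raise ValueError(f"tail must be 'over' or 'under', got {tail!r}")


def representation_factor(k: int, nA: int, nB: int, N: int) -> float:
    """Observed overlap divided by the overlap expected under independence."""
    _validate(k, nA, nB, N)
    if nA == 0 or nB == 0:
        raise ValueError("representation factor undefined for empty sets")
    return k / (nA * nB / N)


def overrepresentation_score(rf: float, p: float, literal_sign: bool = False) -> float:
    """Combine representation factor and p-value into one score.

    Default is log2(RF) * (-log10(p)), so enrichment (RF > 1, small p) gives
    a positive score. ``literal_sign=True`` uses log2(RF) * log10(p), which
    is negative for enrichment.
    """
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p must be in (0, 1], got {p}")
    if rf == 0:
        return -math.inf
    if rf < 0:
        raise ValueError("representation factor must be non-negative")
    score = math.log2(rf) * math.log10(p)
    return score if literal_sign else -score


def enrich(hits: Sequence[str], gene_set: Sequence[str], universe: Sequence[str]) -> EnrichmentResult:
    """Full overlap statistics for two item sets within a universe."""
    uni = set(universe)
    a = set(hits) & uni
    b = set(gene_set) & uni
    k, nA, nB, N = len(a & b), len(a), len(b), len(uni)
    p = hypergeom_test(k, nA, nB, N)
    rf = representation_factor(k, nA, nB, N) if nA and nB else float("nan")
    ors = overrepresentation_score(rf, p) if rf and rf > 0 else -math.inf
    return EnrichmentResult(k, nA, nB, N, p, rf, ors)


def paired_t_holm(pairs: Sequence[tuple[Sequence[float], Sequence[float]]]) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided paired t tests with Holm adjustment across the family.

    ``pairs`` is a sequence of (x, y) matched-observation vectors; returns
    (raw p, Holm-adjusted p) arrays. When all paired differences are exactly
    zero the comparison is degenerate and p is defined as 1.
    """
    raw = []
    for x, y in pairs:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.size < 2:
            raise ValueError("paired t requires matched vectors with n >= 2")
        d = x - y
        if np.all(d == 0):
            raw.append(1.0)
        else:
            raw.append(float(stats.ttest_rel(x, y).pvalue))
    raw_arr = np.asarray(raw)
    adj = holm_adjust(raw_arr)
    return raw_arr, adj


def holm_adjust(p: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with monotonicity enforcement."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
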