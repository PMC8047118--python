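"""Independent brute-force oracles used by the test suite.

Everything here is computed by exact rational enumeration with
``math.comb`` — deliberately sharing no code path with the package.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def hypergeom_upper_tail(k: int, nA: int, nB: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, nA, nB), by exact enumeration."""
    denom = comb(N, nB)
    total = Fraction(0)
    for j in range(k, min(nA, nB) + 1):
        if nB - j > N - nA:
            continue
        total += Fraction(comb(nA, j) * comb(N - nA, nB - j), denom)
    return float(min(total, Fraction(1)))


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Enumerates all tables with the observed margins and sums the exact
    probabilities of those no more likely than the observed table.
    """
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2
    denom = comb(n, col1)

    def prob(j: int) -> Fraction:
        return Fraction(comb(row1, j) * comb(row2, col1 - j), denom)

    p_obs = prob(a)
    lo = max(0, col1 - row2)
    hi = min(row1, col1)
    total = sum((prob(j) for j in range(lo, hi + 1) if prob(j) <= p_obs), Fraction(0))
    return float(min(total, Fraction(1)))


def pca_loadings_eig(X):
    """PC loadings via explicit eigendecomposition of the gene covariance.

    ``X`` is samples x genes; returns (eigenvalues desc, loading columns).
    """
    import numpy as np

    Xc = X - X.mean(axis=0, keepdims=True)
    C = Xc.T @ Xc
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    return w[order], V[:, order]
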