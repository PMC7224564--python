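"""Exact permutation moments of quadratic forms.

For a residual vector ``r`` and a symmetric matrix ``A``, the permutation
null of ``Q = x' A x`` (``x`` a uniformly random permutation of ``r``) is
the exact conditional null of a score statistic when the residuals are
exchangeable — e.g. a binary trait under an intercept-only null model,
where it conditions on the observed case count, or a case-control sample,
where the fixed case quota makes the unconditional binomial reference
inappropriate.  This module computes the first three moments of that
permutation distribution in closed form.

Derivation sketch: split ``Q = sum_i d_i x_i^2 + sum_{edges} w_e x_i x_j``
(diagonal and off-diagonal parts).  Powers of Q expand into monomials whose
permutation expectation depends only on the multiset of exponents carried
by the distinct indices involved: ``E[prod_t x_{i_t}^{k_t}] =
N(k_1..k_g) / (n)_g`` with ``N`` the sum of ``r``-power products over
distinct index tuples (computable from power sums by inclusion-exclusion)
and ``(n)_g`` the falling factorial.  The coefficient attached to each
exponent pattern is a graph invariant of ``A`` — edge, triangle, path,
star, cherry and matching sums — each computable with O(n^3) dense matrix
algebra.  Every formula is verified against exhaustive permutation
enumeration at small n in the test suite.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = ["permutation_quadform_moments"]


def _distinct_power_sums(r: np.ndarray) -> dict[tuple[int, ...], float]:
    """N(k1..kg) = sum over pairwise-distinct index tuples of prod r^{k_t},
    for every exponent multiset needed by the third-moment expansion."""
    p = {k: float(np.sum(r**k)) for k in range(1, 13)}

    def N(seq: tuple[int, ...]) -> float:
        if len(seq) == 1:
            return p[seq[0]]
        head, tail = seq[:-1], seq[-1]
        total = N(head) * p[tail]
        for t in range(len(head)):
            merged = tuple(sorted(head[:t] + (head[t] + tail,) + head[t + 1 :]))
            total -= N(merged)
        return total

    from functools import lru_cache

    N = lru_cache(maxsize=None)(N)
    needed = [
        (2,), (1, 1),
        (4,), (2, 2), (3, 1), (2, 1, 1), (1, 1, 1, 1),
        (6,), (4, 2), (2, 2, 2), (5, 1), (4, 1, 1), (3, 3), (3, 2, 1),
        (2, 2, 1, 1), (3, 1, 1, 1), (2, 1, 1, 1, 1), (1, 1, 1, 1, 1, 1),
    ]
    return {seq: N(tuple(sorted(seq, reverse=True))) for seq in needed}


def permutation_quadform_moments(
    A: np.ndarray, r: np.ndarray
) -> tuple[float, float, float]:
    """Exact (mean, variance, third central moment) of ``Q = x'Ax`` with x a
    uniform random permutation of r.  Requires n >= 7."""
    A = np.asarray(A, dtype=float)
    A = (A + A.T) / 2.0
    r = np.asarray(r, dtype=float)
    n = r.shape[0]
    if n < 7:
        raise ValueError("moment formulas need n >= 7")

    Nv = _distinct_power_sums(r)
    fall = [1.0] * 7
    for g in range(1, 7):
        fall[g] = fall[g - 1] * (n - g + 1)

    def m(*seq: int) -> float:
        return Nv[tuple(sorted(seq, reverse=True))] / fall[len(seq)]

    d = np.diag(A).copy()
    W = 2.0 * (A - np.diag(d))  # symmetric, zero diagonal; w_e = 2 A_ij

    # scalar invariants of the diagonal part
    t1 = float(d.sum())
    P2d = float(np.sum(d * d))
    P3d = float(np.sum(d**3))

    # edge invariants
    rho = W.sum(axis=1)
    sig2 = np.sum(W * W, axis=1)
    sig3 = np.sum(W**3, axis=1)
    T_w = W.sum() / 2.0
    E2 = float(np.sum(W * W)) / 2.0
    E3f = float(np.sum(W**3))
    M2 = E3f / 2.0
    W2m = W @ W
    ones = np.ones(n)
    W3sum = float(ones @ (W2m @ W) @ ones)
    trW3 = float(np.trace(W2m @ W))

    def upper(M: np.ndarray) -> float:
        return float(np.sum(np.triu(M, 1)))

    d_edge = d[:, None] + d[None, :]          # d_a + d_b per edge
    d2_edge = (d * d)[:, None] + (d * d)[None, :]
    Swd = upper(W * d_edge)                   # sum_e w_e (d_a + d_b)
    Swd2 = upper(W * d2_edge)                 # sum_e w_e (d_a^2 + d_b^2)
    Swdd = upper(W * (2.0 * np.outer(d, d)))  # sum_e w_e * 2 d_a d_b
    Sw2d = upper(W * W * d_edge)              # sum_e w_e^2 (d_a + d_b)

    # ---- moment 1 ---------------------------------------------------------
    EQ1 = t1 * m(2) + T_w * m(1, 1)

    # ---- moment 2 ---------------------------------------------------------
    ED2 = P2d * m(4) + (t1 * t1 - P2d) * m(2, 2)
    EDO = Swd * m(3, 1) + (t1 * T_w - Swd) * m(2, 1, 1)
    N_b1 = float(np.sum(rho * rho - sig2))    # ordered share-one edge pairs
    N_c1 = T_w * T_w - E2 - N_b1              # ordered disjoint edge pairs
    EO2 = E2 * m(2, 2) + N_b1 * m(2, 1, 1) + N_c1 * m(1, 1, 1, 1)
    EQ2 = ED2 + 2.0 * EDO + EO2

    # ---- moment 3 ---------------------------------------------------------
    ED3 = (
        P3d * m(6)
        + 3.0 * (P2d * t1 - P3d) * m(4, 2)
        + (t1**3 - 3.0 * t1 * P2d + 2.0 * P3d) * m(2, 2, 2)
    )

    # D^2 O: two diagonal slots (i, j) against one edge {a, b}
    same_in = Swd2                                       # i=j on the edge
    same_out = P2d * T_w - Swd2
    pair_both = Swdd                                     # i,j the two edge ends
    # ordered (i on edge, j outside): 2 * sum_e w_e (d_a+d_b)(t1-d_a-d_b)
    pair_onein = 2.0 * upper(W * (d_edge * (t1 - d_edge)))
    pair_bothout = upper(
        W * ((t1 - d_edge) ** 2 - (P2d - d2_edge))
    )
    ED2O = (
        same_in * m(5, 1)
        + same_out * m(4, 1, 1)
        + pair_both * m(3, 3)
        + pair_onein * m(3, 2, 1)
        + pair_bothout * m(2, 2, 1, 1)
    )

    # D O^2: one diagonal slot against an ordered pair of edges
    S_centre = float(np.sum(d * (rho * rho - sig2)))     # d on the shared vertex
    Wd = W @ d
    S_leaf = 2.0 * float(np.sum(Wd * rho - np.sum(W * W * d[None, :], axis=1)))
    share_d = S_centre + S_leaf                          # d anywhere on the union
    # complement count: over sharing pairs, s_e + s_f counts the shared
    # vertex twice, hence the extra S_centre
    N_cS = 2.0 * T_w * Swd - 2.0 * Sw2d - (share_d + S_centre)
    DO2 = (
        Sw2d * m(4, 2)
        + (E2 * t1 - Sw2d) * m(2, 2, 2)
        + S_centre * m(4, 1, 1)
        + S_leaf * m(3, 2, 1)
        + (t1 * N_b1 - share_d) * m(2, 2, 1, 1)
        + N_cS * m(3, 1, 1, 1)
        + (t1 * N_c1 - N_cS) * m(2, 1, 1, 1, 1)
    )

    # O^3: ordered triples of edges classified by their multigraph
    P_share = float(np.sum(sig2 * rho)) - E3f            # (e, e, f) sharing a vertex
    P_disj = E2 * T_w - M2 - P_share
    TRI = trW3 / 6.0
    STAR = float(np.sum(rho**3 - 3.0 * rho * sig2 + 2.0 * sig3)) / 6.0
    PATH = (W3sum - 2.0 * float(np.sum(sig2 * rho)) - trW3 + E3f) / 2.0
    ALLDIST = (T_w**3 - 3.0 * T_w * E2 + 2.0 * M2) / 6.0
    Cs = rho[:, None] + rho[None, :] - 2.0 * W
    Cs2 = sig2[:, None] + sig2[None, :] - 2.0 * W * W
    S_cc = upper(W * (Cs * Cs - Cs2))
    N6 = (
        6.0 * ALLDIST
        - 3.0 * (N_b1 * T_w - 2.0 * P_share)
        + 3.0 * S_cc
        - 6.0 * (TRI + STAR)
    )
    MATCH3 = N6 / 6.0
    CHERRY5 = ALLDIST - TRI - STAR - PATH - MATCH3
    EO3 = (
        M2 * m(3, 3)
        + 3.0 * (P_share * m(3, 2, 1) + P_disj * m(2, 2, 1, 1))
        + 6.0 * (
            TRI * m(2, 2, 2)
            + STAR * m(3, 1, 1, 1)
            + PATH * m(2, 2, 1, 1)
            + CHERRY5 * m(2, 1, 1, 1, 1)
            + MATCH3 * m(1, 1, 1, 1, 1, 1)
        )
    )

    EQ3 = ED3 + 3.0 * ED2O + 3.0 * DO2 + EO3

    var = EQ2 - EQ1 * EQ1
    mu3 = EQ3 - 3.0 * EQ1 * EQ2 + 2.0 * EQ1**3
    return float(EQ1), float(var), float(mu3)
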