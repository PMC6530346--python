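"""Independently coded reference implementations used only as test oracles.

Each oracle is written against the published description of its
algorithm in a deliberately different style from the package code
(explicit loops, sorting instead of ranking, exact rational
arithmetic) so that agreement is evidence of correctness rather than
shared structure.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def tmm_reference(mat: np.ndarray, trim_m: float = 0.30, trim_a: float = 0.05):
    """Trimmed mean of M-values on a feature x column matrix.

    Published algorithm: reference column by 75th percentile of y/N
    closest to the mean percentile; per column, log-ratios M and mean
    abundances A against the reference; drop the trim_m tails of M and
    trim_a tails of A (rank windows); precision-weighted mean of the
    surviving M; factors rescaled to geometric mean one.
    """
    mat = np.asarray(mat, dtype=float)
    n_feat, n_col = mat.shape
    lib = [sum(mat[:, j]) for j in range(n_col)]
    f75 = [np.quantile(mat[:, j], 0.75) / lib[j] for j in range(n_col)]
    mean75 = sum(f75) / n_col
    ref = min(range(n_col), key=lambda j: (abs(f75[j] - mean75), j))
    factors = []
    for k in range(n_col):
        ms, as_, ws = [], [], []
        for s in range(n_feat):
            pk = mat[s, k] / lib[k]
            pr = mat[s, ref] / lib[ref]
            if pk <= 0 or pr <= 0:
                continue
            ms.append(math.log2(pk / pr))
            as_.append(0.5 * (math.log2(pk) + math.log2(pr)))
            ws.append(
                (lib[k] - mat[s, k]) / (lib[k] * mat[s, k])
                + (lib[ref] - mat[s, ref]) / (lib[ref] * mat[s, ref])
            )
        if not ms or max(abs(m) for m in ms) < 1e-6:
            factors.append(1.0)
            continue
        n = len(ms)
        lo_m = math.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        m_order = sorted(range(n), key=lambda i: ms[i])
        a_order = sorted(range(n), key=lambda i: as_[i])
        m_rank = {idx: r + 1 for r, idx in enumerate(m_order)}
        a_rank = {idx: r + 1 for r, idx in enumerate(a_order)}
        num = den = 0.0
        for i in range(n):
            if lo_m <= m_rank[i] <= hi_m and lo_a <= a_rank[i] <= hi_a:
                num += ms[i] / ws[i]
                den += 1.0 / ws[i]
        factors.append(2.0 ** (num / den))
    log_gm = sum(math.log(f) for f in factors) / n_col
    return np.array([f / math.exp(log_gm) for f in factors]), ref


def bh_stepup_reference(pvalues) -> np.ndarray:
    """BH step-up by the textbook definition q_(i) = min_{j>=i} m p_(j)/j."""
    p = list(map(float, pvalues))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for pos, idx in enumerate(order):
        candidates = [m * p[order[j]] / (j + 1) for j in range(pos, m)]
        q[idx] = min(1.0, min(candidates))
    return np.array(q)


def hypergeom_upper_tail_exact(k: int, population: int, successes: int, draws: int) -> float:
    """P(X >= k) by exhaustive summation in exact rational arithmetic."""
    total = Fraction(0)
    denom = math.comb(population, draws)
    for i in range(k, min(successes, draws) + 1):
        total += Fraction(
            math.comb(successes, i) * math.comb(population - successes, draws - i), denom
        )
    return float(total)


def diff_ols_reference(sample_log2, ips_log2, design_x):
    """OLS of per-gel sample-IPS differences on [1 | treatment design]."""
    d = np.asarray(sample_log2) - np.asarray(ips_log2)
    xd = np.column_stack([np.ones(design_x.shape[0]), design_x])
    beta, *_ = np.linalg.lstsq(xd, d.T, rcond=None)
    return beta[1:].T  # (spots, 4)
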