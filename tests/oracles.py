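"""Independent reference implementations used only to cross-check the library.

These deliberately use different code paths from the package: exact integer
enumeration for the hypergeometric tail, scipy's t-test for Welch, and a
straightforward loop transcription of the q-value procedure.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import interpolate, stats


def welch_oracle(x, y) -> tuple[float, float, float]:
    """Welch test via scipy.stats.ttest_ind (equal_var=False)."""
    res = stats.ttest_ind(np.asarray(x, float), np.asarray(y, float), equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def hypergeom_tail_oracle(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by exact enumeration: X = pathway genes among n drawn of N."""
    denom = math.comb(N, n)
    num = 0
    for i in range(k, min(K, n) + 1):
        num += math.comb(K, i) * math.comb(N - K, n - i)
    return num / denom


def storey_oracle(p_values, pi0: float | None = None) -> np.ndarray:
    """Loop transcription of the q-value procedure.

    pi0 by the smoother method (cubic smoothing spline of
    #{p > lambda} / (m (1 - lambda)) on lambda = 0.05..0.95, evaluated at
    0.95), then q(i) = min over j >= i of pi0 * m * p_(j) / j.
    """
    p = [float(v) for v in p_values]
    m = len(p)
    if m == 0:
        return np.array([])
    if pi0 is None:
        if m < 100:
            pi0 = 1.0
        else:
            lams, vals = [], []
            lam = 0.05
            while lam < 0.9501:
                count = sum(1 for v in p if v > lam)
                lams.append(lam)
                vals.append(count / (m * (1.0 - lam)))
                lam += 0.05
            spline = interpolate.UnivariateSpline(lams, vals, k=3)
            pi0 = float(spline(lams[-1]))
            pi0 = min(max(pi0, 1e-8), 1.0)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    best = float("inf")
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        best = min(best, pi0 * m * p[i] / rank)
        q[i] = min(best, 1.0)
    return np.array(q)


def brute_force_promoter_map(annot, models, up: int = 2500, down: int = 500):
    """All-pairs promoter containment scan (no interval index)."""
    out: dict[str, set[str]] = {}
    for locus, chrom, pos in annot[["locus_id", "chromosome", "position"]].itertuples(
        index=False
    ):
        for m in models:
            if m.chromosome != chrom:
                continue
            if m.strand == "+":
                lo, hi = m.tss - up, m.tss + down
            else:
                lo, hi = m.tss - down, m.tss + up
            lo = max(lo, 1)
            if lo <= pos <= hi:
                out.setdefault(locus, set()).add(m.gene_symbol)
    return out
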