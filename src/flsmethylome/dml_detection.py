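"""Differentially methylated locus (DML) calling between two sample groups.

The caller follows the published analysis recipe for 450K beta values:

* dataset QC first drops any CpG with a detection p-value above 0.001 in
  any sample;
* within a comparison, individual values that are missing or have detection
  p > 0.01 are excluded;
* a locus is skipped entirely when either group retains fewer than three
  usable values;
* Welch's unequal-variance t-test gives a two-sided p-value per locus;
* p-values are converted to Storey q-values over the tested loci of the
  comparison;
* a locus is a DML when q < 0.05 and the group mean difference exceeds 0.1
  in magnitude (both strict).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import interpolate, stats

from .io_formats import BetaMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "qc_filter_loci",
    "group_values",
    "welch_test",
    "storey_qvalues",
    "call_dml",
    "LOCUS_TABLE_COLUMNS",
]

LOCUS_TABLE_COLUMNS = [
    "mean_A",
    "mean_B",
    "delta",
    "n_A",
    "n_B",
    "t_stat",
    "df",
    "p_value",
    "q_value",
    "is_dml",
    "direction",
    "skipped_reason",
]


def qc_filter_loci(
    matrix: BetaMatrix, threshold: float = 0.001
) -> tuple[BetaMatrix, int]:
    """Drop every locus with >= 1 sample whose detection p exceeds ``threshold``.

    Values never assayed (NaN detection p alongside a MISSING beta) do not
    count as failures. Returns the filtered matrix and the number of loci
    removed.
    """
    det = matrix.detection_p.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        fails = np.nansum(det > threshold, axis=1) > 0
    n_removed = int(fails.sum())
    if n_removed == matrix.shape[0]:
        logger.warning("QC filter removed all %d loci", n_removed)
    keep = matrix.beta.index[~fails]
    return matrix.subset_loci(list(keep)), n_removed


def _usable_mask(matrix: BetaMatrix, mask_detect: float) -> np.ndarray:
    beta = matrix.beta.to_numpy(dtype=float)
    det = matrix.detection_p.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        det_ok = np.isnan(det) | (det <= mask_detect)
    return ~np.isnan(beta) & det_ok


def group_values(
    matrix: BetaMatrix, locus: str, samples: list[str], mask_detect: float = 0.01
) -> np.ndarray:
    """Usable beta values at ``locus`` for ``samples``.

    A value is usable when it is non-missing and its detection p <= 0.01
    (the per-value masking threshold of the comparison analysis).
    """
    unknown = [s for s in samples if s not in matrix.beta.columns]
    if unknown:
        raise KeyError(f"unknown sample ids: {unknown}")
    if not samples:
        return np.array([], dtype=float)
    beta = matrix.beta.loc[locus, samples].to_numpy(dtype=float)
    det = matrix.detection_p.loc[locus, samples].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        ok = ~np.isnan(beta) & (np.isnan(det) | (det <= mask_detect))
    return beta[ok]


def welch_test(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test, two-sided.

    Returns ``(t_stat, df, p_value)`` with the Welch-Satterthwaite degrees
    of freedom. Degenerate zero-variance inputs follow the conventions:
    equal means give t=0, p=1; unequal means give an infinite t and p=0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_test requires >= 2 values per group")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / x.size + vy / y.size
    if se2 == 0.0:
        if mx == my:
            return 0.0, float(x.size + y.size - 2), 1.0
        t = np.inf if mx > my else -np.inf
        return float(t), float(x.size + y.size - 2), 0.0
    t = (mx - my) / np.sqrt(se2)
    df = se2**2 / (
        (vx / x.size) ** 2 / (x.size - 1) + (vy / y.size) ** 2 / (y.size - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def estimate_pi0(p_values: np.ndarray) -> float:
    """Estimate the null proportion pi0 by the smoother method.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is computed on the grid
    lambda = 0.05, 0.10, ..., 0.95, a cubic smoothing spline is fitted, and
    its value at the largest lambda is taken, clamped to (0, 1]. With fewer
    than 100 p-values the estimate is unstable and pi0 = 1 is used.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m < 100:
        return 1.0
    lam = np.arange(0.05, 0.96, 0.05)
    pi0_lam = np.array([(p > lv).sum() / (m * (1.0 - lv)) for lv in lam])
    spline = interpolate.UnivariateSpline(lam, pi0_lam, k=3)
    pi0 = float(spline(lam[-1]))
    return min(max(pi0, 1e-8), 1.0)


def storey_qvalues(p_values, pi0: float | None = None) -> np.ndarray:
    """Convert p-values to Storey q-values.

    q(i) = min_{j >= i} pi0 * m * p(j) / j over the ascending ordering,
    capped at 1, returned in the input order. ``pi0`` defaults to the
    smoother estimate (see :func:`estimate_pi0`).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def call_dml(
    matrix: BetaMatrix,
    group_A: list[str],
    group_B: list[str],
    q_thresh: float = 0.05,
    delta_thresh: float = 0.1,
    min_per_group: int = 3,
    mask_detect: float = 0.01,
    pi0: float | None = None,
) -> pd.DataFrame:
    """Call DMLs between ``group_A`` and ``group_B``.

    Returns the per-locus test table (index = locus id) with group means,
    delta = mean_A - mean_B, Welch statistics, Storey q-values computed over
    the tested loci of this comparison, the DML flag and its direction
    (``hyper`` = higher methylation in group A). Loci with fewer than
    ``min_per_group`` usable values in either group are skipped and carry no
    p/q.
    """
    if set(group_A) & set(group_B):
        raise ValueError("comparison groups must be disjoint")
    sub_a = matrix.subset_samples(list(group_A))
    sub_b = matrix.subset_samples(list(group_B))
    a = sub_a.beta.to_numpy(dtype=float)
    b = sub_b.beta.to_numpy(dtype=float)
    ok_a = _usable_mask(sub_a, mask_detect)
    ok_b = _usable_mask(sub_b, mask_detect)
    a = np.where(ok_a, a, np.nan)
    b = np.where(ok_b, b, np.nan)

    n_a = ok_a.sum(axis=1)
    n_b = ok_b.sum(axis=1)
    tested = (n_a >= min_per_group) & (n_b >= min_per_group)

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_a = np.nansum(a, axis=1) / n_a
        mean_b = np.nansum(b, axis=1) / n_b
        var_a = np.nansum((a - mean_a[:, None]) ** 2, axis=1) / (n_a - 1)
        var_b = np.nansum((b - mean_b[:, None]) ** 2, axis=1) / (n_b - 1)
        se2 = var_a / n_a + var_b / n_b
        t_stat = (mean_a - mean_b) / np.sqrt(se2)
        df = se2**2 / (
            (var_a / n_a) ** 2 / (n_a - 1) + (var_b / n_b) ** 2 / (n_b - 1)
        )
        p = 2.0 * stats.t.sf(np.abs(t_stat), df)
    # zero-variance conventions (see welch_test)
    degenerate = tested & (se2 == 0)
    eq = degenerate & (mean_a == mean_b)
    ne = degenerate & (mean_a != mean_b)
    t_stat[eq], df[eq], p[eq] = 0.0, (n_a + n_b - 2)[eq], 1.0
    t_stat[ne] = np.where(mean_a[ne] > mean_b[ne], np.inf, -np.inf)
    df[ne], p[ne] = (n_a + n_b - 2)[ne], 0.0

    delta = mean_a - mean_b
    q = np.full(matrix.shape[0], np.nan)
    if tested.any():
        q[tested] = storey_qvalues(p[tested], pi0=pi0)
    else:
        logger.warning("no testable loci in comparison")

    is_dml = tested & (q < q_thresh) & (np.abs(delta) > delta_thresh)
    direction = np.where(
        is_dml, np.where(delta > 0, "hyper", "hypo"), "none"
    )

    table = pd.DataFrame(
        {
            "mean_A": mean_a,
            "mean_B": mean_b,
            "delta": delta,
            "n_A": n_a,
            "n_B": n_b,
            "t_stat": np.where(tested, t_stat, np.nan),
            "df": np.where(tested, df, np.nan),
            "p_value": np.where(tested, p, np.nan),
            "q_value": q,
            "is_dml": is_dml,
            "direction": direction,
            "skipped_reason": np.where(tested, "none", "too_few_values"),
        },
        index=matrix.beta.index,
    )
    n_dml = int(is_dml.sum())
    logger.info(
        "tested=%d skipped=%d DML=%d hyper=%d hypo=%d",
        int(tested.sum()),
        int((~tested).sum()),
        n_dml,
        int((direction == "hyper").sum()),
        int((direction == "hypo").sum()),
    )
    return table


def write_locus_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", na_rep="NA", index_label="locus_id")


def read_locus_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="locus_id", na_values=["NA"])
    df["is_dml"] = df["is_dml"].astype(bool)
    return df
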