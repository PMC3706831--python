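"""Stability of a CpG signature across cell-culture passages.

Per cell line, beta values at the signature CpGs are compared between
passages with Spearman rank correlation on pairwise-complete observations,
then averaged across lines per passage pair. Passage-to-passage beta
differences are summarized as area-normalized histograms with 0.01-wide
bins. For heat maps, beta values are scaled to percentages (x100) and both
samples and CpGs are hierarchically clustered with complete linkage on
Euclidean distances.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .io_formats import BetaMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "StabilityReport",
    "subset_to_signature",
    "spearman_pairwise",
    "passage_stability",
    "delta_histogram",
    "cluster_heatmap",
    "linkage_to_newick",
]


def subset_to_signature(
    matrix: BetaMatrix, signature: list[str]
) -> tuple[BetaMatrix, list[str]]:
    """Restrict rows to the signature CpGs, preserving signature order.

    Returns the restricted matrix and the list of signature ids absent from
    the matrix. Zero overlap is an error.
    """
    index = set(matrix.beta.index)
    present = [s for s in signature if s in index]
    absent = [s for s in signature if s not in index]
    if not present:
        raise ValueError("signature shares no loci with the matrix")
    if absent:
        logger.warning("%d signature loci absent from matrix", len(absent))
    return matrix.subset_loci(present), absent


def spearman_pairwise(x, y, min_pairs: int = 3) -> float:
    """Spearman rho on pairwise-complete observations (average ranks).

    Pairs with a missing value on either side are omitted; fewer than
    ``min_pairs`` complete pairs gives NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < min_pairs:
        return float("nan")
    rho = stats.spearmanr(x[ok], y[ok]).statistic
    return float(rho)


def delta_histogram(
    a, b, binwidth: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of beta differences ``b - a`` over complete pairs.

    Bin edges sit at multiples of ``binwidth`` spanning [-1, 1]; densities
    are normalized so that sum(density * binwidth) = 1. Returns
    ``(edges, density)``.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    ok = ~np.isnan(a) & ~np.isnan(b)
    if not ok.any():
        raise ValueError("no complete pairs for delta histogram")
    deltas = b[ok] - a[ok]
    nbins = int(round(2.0 / binwidth))
    edges = -1.0 + binwidth * np.arange(nbins + 1)
    counts, _ = np.histogram(deltas, bins=edges)
    density = counts / (counts.sum() * binwidth)
    return edges, density


@dataclass
class StabilityReport:
    """Per-line and averaged inter-passage correlations plus histograms."""

    # (cell_line, passage_a, passage_b) -> rho; replicate pairs use equal passages
    per_line_rho: pd.DataFrame = None  # type: ignore[assignment]
    average_rho: pd.DataFrame = None  # type: ignore[assignment]
    histograms: dict[tuple[str, int, int], tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )


def passage_stability(
    matrices: dict[int, BetaMatrix],
    sheet: pd.DataFrame,
    signature: list[str] | None = None,
    binwidth: float = 0.01,
) -> StabilityReport:
    """Inter-passage Spearman correlations of signature CpGs per cell line.

    ``matrices`` maps passage number to the beta matrix of that passage's
    samples. For every cell line present in >= 2 passages, rho is computed
    for each passage pair on pairwise-complete signature values; replicate
    samples of the same (line, passage) contribute a replicate rho recorded
    under an equal passage pair. Averages are taken across lines per pair.
    """
    per_passage_cols: dict[int, dict[str, list[str]]] = {}
    for passage, matrix in matrices.items():
        at_p = sheet[(sheet["passage"] == passage)]
        by_line: dict[str, list[str]] = {}
        for sid, line in at_p[["sample_id", "cell_line_id"]].itertuples(index=False):
            if sid in matrix.beta.columns:
                by_line.setdefault(line, []).append(sid)
        per_passage_cols[passage] = by_line

    shared_lines = set.union(
        *(set(d) for d in per_passage_cols.values())
    ) if per_passage_cols else set()
    rows = []
    histograms: dict[tuple[str, int, int], tuple[np.ndarray, np.ndarray]] = {}

    # align every passage on one locus index (a locus QC-dropped from a
    # single passage simply becomes missing there and is pair-omitted)
    if signature is not None:
        index = pd.Index(signature)
        n_absent = sum(
            0 == sum(s in m.beta.index for m in matrices.values())
            for s in signature
        )
        if n_absent == len(signature):
            raise ValueError("signature shares no loci with the matrices")
        if n_absent:
            logger.warning("%d signature loci absent from all passages", n_absent)
    else:
        index = pd.Index(
            sorted(set().union(*(m.beta.index for m in matrices.values())))
        )
    aligned = {p: m.beta.reindex(index) for p, m in matrices.items()}

    def signature_values(passage: int, sid: str) -> np.ndarray:
        return aligned[passage][sid].to_numpy(dtype=float)

    n_pairs = 0
    for line in sorted(shared_lines):
        # inter-passage pairs
        for pa, pb in itertools.combinations(sorted(matrices), 2):
            for sa in per_passage_cols[pa].get(line, []):
                for sb in per_passage_cols[pb].get(line, []):
                    va, vb = signature_values(pa, sa), signature_values(pb, sb)
                    rho = spearman_pairwise(va, vb)
                    rows.append((line, pa, pb, sa, sb, rho, False))
                    histograms[(line, pa, pb)] = delta_histogram(va, vb, binwidth)
                    n_pairs += 1
        # replicate pairs within one passage of the same line
        for passage in matrices:
            sids = per_passage_cols[passage].get(line, [])
            for sa, sb in itertools.combinations(sids, 2):
                va, vb = signature_values(passage, sa), signature_values(passage, sb)
                rows.append(
                    (line, passage, passage, sa, sb, spearman_pairwise(va, vb), True)
                )
                histograms[(line, passage, passage)] = delta_histogram(va, vb, binwidth)
    if n_pairs == 0:
        raise ValueError("no cell line shared between >= 2 passages")

    per_line = pd.DataFrame(
        rows,
        columns=[
            "cell_line_id",
            "passage_a",
            "passage_b",
            "sample_a",
            "sample_b",
            "rho",
            "is_replicate_pair",
        ],
    )
    average = (
        per_line.groupby(["passage_a", "passage_b", "is_replicate_pair"])["rho"]
        .mean()
        .reset_index()
        .rename(columns={"rho": "mean_rho"})
    )
    return StabilityReport(per_line, average, histograms)


def _pairwise_complete_distances(values: np.ndarray) -> np.ndarray:
    """Condensed Euclidean distances over columns with missing data.

    For each column pair, squared differences are summed over dimensions
    observed in both and rescaled by (total dims / observed dims), so sparse
    pairs are not biased toward small distances. A pair sharing no observed
    dimension is an error.
    """
    n_dim, n_col = values.shape
    observed = ~np.isnan(values)
    filled = np.where(observed, values, 0.0)
    obs = observed.astype(float)
    # pairwise sums via matrix products
    shared = obs.T @ obs
    sq = filled**2
    cross = filled.T @ filled
    sum_sq_a = sq.T @ obs  # sum over shared dims of a^2 needs masking by both
    # sum over dims observed in both of (a-b)^2 =
    #   sum(a^2 * obs_b) + sum(b^2 * obs_a) - 2 sum(a*b)   restricted to shared
    d2 = sum_sq_a + sum_sq_a.T - 2.0 * cross
    bad = shared == 0
    if bad.any():
        i, j = np.argwhere(bad & ~np.eye(n_col, dtype=bool))[0]
        raise ValueError(f"columns {i} and {j} share no observed loci")
    with np.errstate(invalid="ignore"):
        d2 = d2 * (n_dim / shared)
    d2 = np.maximum(d2, 0.0)
    iu = np.triu_indices(n_col, 1)
    return np.sqrt(d2[iu])


def cluster_heatmap(
    matrix: BetaMatrix,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Complete-linkage clustering of samples and CpGs for heat-map export.

    Beta values are scaled to percentages (x100). Euclidean distances use
    pairwise-complete dimensions rescaled to full dimensionality. Returns
    ``(sample_linkage, locus_linkage, ordered_matrix)`` where the ordered
    matrix keeps MISSING entries (to be rendered white downstream).
    """
    if matrix.shape[1] < 2:
        raise ValueError("clustering requires >= 2 samples")
    pct = matrix.beta.to_numpy(dtype=float) * 100.0

    def link_axis(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if values.shape[1] < 2:  # single item: nothing to agglomerate
            return np.zeros((0, 4)), np.array([0])
        link = hierarchy.linkage(
            _pairwise_complete_distances(values), method="complete"
        )
        return link, hierarchy.leaves_list(link)

    sample_link, sample_order = link_axis(pct)
    locus_link, locus_order = link_axis(pct.T)
    ordered = (matrix.beta * 100.0).iloc[locus_order, sample_order]
    return sample_link, locus_link, ordered


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with merge heights."""
    tree = hierarchy.to_tree(linkage)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return render(tree, tree.dist) + ";"
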