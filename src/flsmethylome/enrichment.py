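"""Over-representation analysis of DMG sets in KEGG/GO-style gene sets.

The background is chip-restricted: only genes that appear in the database
AND whose promoters are covered by the array count, both for the background
size N and for each pathway's covered size K. For a pathway containing k of
the n background DMGs, the enrichment factor is

    EF = (k / K) / (n / N)

and the p-value is the inclusive upper tail P(X >= k) of the
hypergeometric distribution of drawing n genes from N of which K are in the
pathway. P-values convert to Storey q-values within each database;
q < 0.05 marks significance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .dml_detection import storey_qvalues
from .io_formats import PathwayDB
from .promoter_dmg import DMGSet

__all__ = [
    "covered_background",
    "enrichment_factor",
    "fold_enrichment",
    "calibrate_background_ratio",
    "hypergeom_pvalue",
    "enrich",
    "ENRICHMENT_COLUMNS",
]

ENRICHMENT_COLUMNS = [
    "pathway_id",
    "pathway_name",
    "k",
    "K",
    "n",
    "N",
    "percentage",
    "EF",
    "p_value",
    "q_value",
    "significant",
]


def covered_background(
    db: PathwayDB, genes_on_chip: set[str]
) -> tuple[frozenset[str], dict[str, frozenset[str]]]:
    """Chip-restricted background and per-pathway covered gene sets.

    Returns ``(N_set, covered)`` where ``N_set`` is the union of database
    genes intersected with the chip-covered genes and ``covered`` maps each
    pathway id to its chip-covered member set. Pathways with no covered
    genes are dropped from ``covered``.
    """
    chip = frozenset(genes_on_chip)
    background = db.gene_universe() & chip
    if not background:
        raise ValueError("chip covers no gene of the pathway database")
    covered = {
        pid: genes & chip
        for pid, (_, genes) in db.entries.items()
        if genes & chip
    }
    return frozenset(background), covered


def enrichment_factor(k: int, K: int, n: int, N: int) -> float:
    """EF = (k/K) / (n/N); requires K > 0, n > 0, N > 0."""
    if K <= 0 or n <= 0 or N <= 0:
        raise ValueError("enrichment factor undefined for K=0 or n=0")
    return (k / K) / (n / N)


def calibrate_background_ratio(k: int, K: int, ef: float) -> float:
    """Background DMG fraction n/N implied by one pathway's (k, K, EF)."""
    return (k / K) / ef


def fold_enrichment(k: int, K: int, background_ratio: float) -> float:
    """EF of a pathway given the background DMG fraction n/N directly."""
    return (k / K) / background_ratio


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Inclusive upper-tail P(X >= k), X ~ Hypergeometric(N, K, n).

    X counts pathway genes among n background DMGs drawn from a background
    of N genes of which K lie in the pathway.
    """
    if not (0 <= k <= K <= N and k <= n <= N):
        raise ValueError(f"inconsistent hypergeometric parameters {(k, K, n, N)}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    dmg: DMGSet,
    db: PathwayDB,
    chip_genes: set[str],
    q_thresh: float = 0.05,
    restrict_n_to_background: bool = True,
    pi0: float | None = None,
) -> pd.DataFrame:
    """Test every covered pathway of ``db`` for DMG over-representation.

    ``n`` counts DMGs inside the chip-restricted database background by
    default (``restrict_n_to_background=False`` counts the whole DMG set
    instead). The returned table is sorted by q-value then descending EF.
    """
    background, covered = covered_background(db, chip_genes)
    dmg_genes = set(dmg.genes)
    n = len(dmg_genes & background) if restrict_n_to_background else len(dmg_genes)
    N = len(background)
    rows = []
    for pid, cov in covered.items():
        K = len(cov)
        k = len(dmg_genes & cov)
        rows.append(
            {
                "pathway_id": pid,
                "pathway_name": db.entries[pid][0],
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                # half-even rounding matches the printed one-decimal percentages
                "percentage": round(100.0 * k / K, 1),
                "EF": enrichment_factor(k, K, n, N) if n > 0 else 0.0,
                "p_value": hypergeom_pvalue(k, K, min(n, N), N) if n > 0 else 1.0,
            }
        )
    table = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS[:-2])
    if len(table):
        table["q_value"] = storey_qvalues(table["p_value"].to_numpy(), pi0=pi0)
        table["significant"] = table["q_value"] < q_thresh
        table = table.sort_values(
            ["q_value", "EF"], ascending=[True, False], kind="stable"
        ).reset_index(drop=True)
    else:
        table["q_value"] = np.array([], dtype=float)
        table["significant"] = np.array([], dtype=bool)
    return table


def write_enrichment(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA")
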