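"""The five phenotype comparisons and gene-level union of their DMG sets.

Three primitive comparisons contrast the RA samples with OA, NL, and the
pooled OA+NL group. Two derived comparisons take gene-level unions:
``RA_vs_OA_or_NL`` collects genes significant in either primitive RA-vs-OA
or RA-vs-NL, and ``combined`` further unions in RA-vs-OA+NL. Unions act on
already-called DMG sets; q-values are not recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .promoter_dmg import DMGSet

__all__ = ["ComparisonPlan", "build_plans", "combine_dmg_sets", "COMPARISON_NAMES"]

COMPARISON_NAMES = [
    "RA_vs_OA",
    "RA_vs_NL",
    "RA_vs_OA+NL",
    "RA_vs_OA_or_NL",
    "combined",
]


@dataclass
class ComparisonPlan:
    name: str
    group_A: list[str] = field(default_factory=list)
    group_B: list[str] = field(default_factory=list)
    derivation: list[str] = field(default_factory=list)  # union of these names
    usable: bool = True

    @property
    def is_primitive(self) -> bool:
        return not self.derivation


def build_plans(
    sheet: pd.DataFrame, passage: int, min_per_group: int = 3
) -> list[ComparisonPlan]:
    """Build the five comparison plans from a sample sheet at one passage.

    A primitive plan is flagged unusable when a phenotype has fewer than
    ``min_per_group`` samples at the passage; a phenotype absent from the
    sheet altogether is an error.
    """
    for pheno in ("RA", "OA", "NL"):
        if not (sheet["phenotype"] == pheno).any():
            raise ValueError(f"sample sheet lacks phenotype {pheno}")
    at_p = sheet[sheet["passage"] == passage]
    groups = {
        pheno: sorted(at_p.loc[at_p["phenotype"] == pheno, "sample_id"])
        for pheno in ("RA", "OA", "NL")
    }
    ra = groups["RA"]

    def prim(name: str, group_b: list[str]) -> ComparisonPlan:
        usable = len(ra) >= min_per_group and len(group_b) >= min_per_group
        return ComparisonPlan(name, group_A=list(ra), group_B=group_b, usable=usable)

    plans = [
        prim("RA_vs_OA", groups["OA"]),
        prim("RA_vs_NL", groups["NL"]),
        prim("RA_vs_OA+NL", sorted(groups["OA"] + groups["NL"])),
        ComparisonPlan("RA_vs_OA_or_NL", derivation=["RA_vs_OA", "RA_vs_NL"]),
        ComparisonPlan("combined", derivation=["RA_vs_OA_or_NL", "RA_vs_OA+NL"]),
    ]
    return plans


_MERGE = {
    frozenset({"hyper"}): "hyper",
    frozenset({"hypo"}): "hypo",
}


def combine_dmg_sets(
    named_sets: dict[str, DMGSet], expression: list[str], name: str = "union"
) -> DMGSet:
    """Gene-level union of the DMG sets named in ``expression``.

    Statuses merge by direction: a gene hyper in one parent and hypo in
    another becomes ``mixed``. Supporting loci are concatenated
    (deduplicated) and provenance of parent sets is preserved implicitly
    through them.
    """
    missing = [n for n in expression if n not in named_sets]
    if missing:
        raise KeyError(f"undefined DMG set name(s): {missing}")
    out = DMGSet(name)
    for parent_name in expression:
        parent = named_sets[parent_name]
        for gene, loci in parent.supporting.items():
            bucket = out.supporting.setdefault(gene, [])
            for entry in loci:
                if entry not in bucket:
                    bucket.append(entry)
    for gene, loci in out.supporting.items():
        directions = frozenset(d for _, d in loci)
        out.genes[gene] = _MERGE.get(directions, "mixed")
    return out
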