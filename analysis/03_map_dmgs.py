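"""Map DMLs into promoter windows, label DMGs and build the union sets.

Reads the locus test tables from 02_call_dml.py plus the cohort annotation
and gene models, labels differentially methylated genes per comparison
(-2500..+500 around the TSS, strand-oriented), then derives the two union
sets (RA_vs_OA_or_NL and combined). Prints the DMG count per set — the
synthetic analogue of the study's comparison summary table — and checks
union monotonicity.
"""

import argparse
from pathlib import Path

from flsmethylome import comparison_sets, dml_detection, io_formats
from flsmethylome import promoter_dmg as pdmg


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", default="results/cohort")
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()
    cohort, outdir = Path(args.cohort), Path(args.outdir)

    annot = io_formats.read_cpg_annotation(cohort / "cpg_annotation.tsv")
    models = io_formats.read_gene_models(cohort / "gene_models.refflat.tsv")
    multimap = pdmg.map_loci_to_genes(annot, models)
    print(f"{len(multimap)} of {len(annot)} CpGs fall in a promoter window")

    sets: dict[str, pdmg.DMGSet] = {}
    for name in ["RA_vs_OA", "RA_vs_NL", "RA_vs_OA+NL"]:
        table = dml_detection.read_locus_table(outdir / f"dml_{name}.tsv")
        sets[name] = pdmg.call_dmgs(table, multimap, name)
    for name, expr in [
        ("RA_vs_OA_or_NL", ["RA_vs_OA", "RA_vs_NL"]),
        ("combined", ["RA_vs_OA_or_NL", "RA_vs_OA+NL"]),
    ]:
        sets[name] = comparison_sets.combine_dmg_sets(sets, expr, name)

    print(f"{'comparison':<16} {'DMGs':>5} {'hyper':>6} {'hypo':>5} {'mixed':>6}")
    for name in comparison_sets.COMPARISON_NAMES:
        s = sets[name]
        by = {st: sum(v == st for v in s.genes.values())
              for st in ("hyper", "hypo", "mixed")}
        print(f"{name:<16} {len(s):>5} {by['hyper']:>6} {by['hypo']:>5} {by['mixed']:>6}")
        pdmg.write_dmg_set(s, outdir / f"dmg_{name}.tsv")

    assert len(sets["combined"]) >= len(sets["RA_vs_OA_or_NL"])
    assert len(sets["combined"]) >= len(sets["RA_vs_OA+NL"])
    print("union monotonicity holds: |combined| >= |RA_vs_OA_or_NL|, |RA_vs_OA+NL|")


if __name__ == "__main__":
    main()
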