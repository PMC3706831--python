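"""Pathway over-representation of each DMG set with EF and hypergeometric q.

Reads the DMG sets from 03_map_dmgs.py and the cohort GMT, restricts the
background to promoter-covered genes present in the database, and tests
every pathway. Prints, per DMG set, the significant pathways in the study's
reporting style: EF (q-value) and k (percentage). Also verifies that the
planted pathways are recovered.
"""

import argparse
from pathlib import Path

from flsmethylome import enrichment, io_formats
from flsmethylome import promoter_dmg as pdmg
from flsmethylome.promoter_dmg import DMGSet


def read_dmg_tsv(path: Path) -> DMGSet:
    dmg = DMGSet(path.stem.removeprefix("dmg_"))
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("gene\t"):
                continue
            gene, status, _n, loci = line.rstrip("\n").split("\t")
            dmg.genes[gene] = status
            dmg.supporting[gene] = [
                tuple(entry.split(":")) for entry in loci.split(",") if entry
            ]
    return dmg


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", default="results/cohort")
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()
    cohort, outdir = Path(args.cohort), Path(args.outdir)

    db = io_formats.read_gmt(cohort / "pathways.gmt")
    annot = io_formats.read_cpg_annotation(cohort / "cpg_annotation.tsv")
    models = io_formats.read_gene_models(cohort / "gene_models.refflat.tsv")
    multimap = pdmg.map_loci_to_genes(annot, models)
    chip_genes = set().union(*multimap.values())

    truth = {}
    truth_path = cohort / "truth_pathways.tsv"
    if truth_path.exists():
        import pandas as pd

        t = pd.read_csv(truth_path, sep="\t")
        truth = set(t.loc[t["is_planted_enriched"], "pathway_id"])

    for set_name in ["combined", "RA_vs_OA+NL", "RA_vs_OA_or_NL"]:
        dmg = read_dmg_tsv(outdir / f"dmg_{set_name}.tsv")
        table = enrichment.enrich(dmg, db, chip_genes)
        enrichment.write_enrichment(table, outdir / f"enrichment_{set_name}_KEGG.tsv")
        sig = table[table["significant"]]
        print(f"\n{set_name}: n={table['n'].iloc[0]} background DMGs of "
              f"N={table['N'].iloc[0]}; {len(sig)} significant pathways")
        for _, r in sig.iterrows():
            mark = " *planted*" if r["pathway_id"] in truth else ""
            print(f"  {r['pathway_name']:<24} {r['EF']:.2f} ({r['q_value']:.3g})  "
                  f"{r['k']} ({r['percentage']}){mark}")
        if truth:
            top3 = set(table.head(3)["pathway_id"])
            recovered = truth <= top3
            print(f"  planted pathways in top 3 by q: {recovered}")


if __name__ == "__main__":
    main()
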