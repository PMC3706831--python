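"""QC-filter the passage-5 matrix and call DMLs for the primitive comparisons.

Reads the cohort written by 01_simulate_cohort.py, applies the detection-p
QC filter (> 0.001 in any sample drops the locus), then runs the Welch /
q-value / |delta| caller for RA vs OA, RA vs NL and RA vs OA+NL.
Writes one locus test table per comparison under results/ and prints the
tested/DML/hyper/hypo counts.
"""

import argparse
from pathlib import Path

from flsmethylome import comparison_sets, dml_detection, io_formats


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", default="results/cohort")
    ap.add_argument("--outdir", default="results")
    ap.add_argument("--passage", type=int, default=5)
    args = ap.parse_args()
    cohort = Path(args.cohort)
    outdir = Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    matrix = io_formats.read_beta_matrix(
        cohort / f"beta_P{args.passage}.tsv",
        cohort / f"detection_P{args.passage}.tsv",
    )
    sheet = io_formats.read_sample_sheet(cohort / "sample_sheet.csv")

    filtered, n_removed = dml_detection.qc_filter_loci(matrix)
    print(f"QC: removed {n_removed} of {matrix.shape[0]} loci "
          f"(detection p > 0.001 in >= 1 sample)")

    for plan in comparison_sets.build_plans(sheet, args.passage):
        if not plan.is_primitive:
            continue
        table = dml_detection.call_dml(filtered, plan.group_A, plan.group_B)
        out = outdir / f"dml_{plan.name}.tsv"
        dml_detection.write_locus_table(table, out)
        n_dml = int(table["is_dml"].sum())
        print(f"{plan.name}: tested {(table['skipped_reason'] == 'none').sum()}, "
              f"DML {n_dml} "
              f"(hyper {(table['direction'] == 'hyper').sum()}, "
              f"hypo {(table['direction'] == 'hypo').sum()}) -> {out}")


if __name__ == "__main__":
    main()
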