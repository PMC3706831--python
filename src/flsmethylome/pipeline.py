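"""End-to-end orchestration: simulate -> QC -> DML -> DMG -> sets -> enrichment -> stability.

Every stage is a plain function over the library modules so it can run (and
be tested) standalone; :func:`run` chains them under one config and writes a
run manifest recording the seed, package version, per-stage counts and a
SHA-256 of every output file, making determinism checkable by manifest
equality.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__, comparison_sets, dml_detection, enrichment, io_formats
from . import promoter_dmg as pdmg
from . import signature_stability as stab
from . import synthetic_data

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run"]


@dataclass
class PipelineConfig:
    """Paths, thresholds and run options for one pipeline invocation."""

    outdir: str = "run_output"
    seed: int = 0
    simulate: bool = True  # generate the cohort under <outdir>/inputs first
    # input paths; filled automatically when simulate=True
    beta_paths: dict[int, str] = field(default_factory=dict)  # passage -> TSV
    detection_paths: dict[int, str] = field(default_factory=dict)
    sheet_path: str = ""
    annotation_path: str = ""
    gene_models_path: str = ""
    gmt_paths: dict[str, str] = field(default_factory=dict)  # db name -> GMT
    signature_path: str = ""
    # analysis parameters
    dml_passage: int = 5
    qc_detect: float = 0.001
    mask_detect: float = 0.01
    q_thresh: float = 0.05
    delta_thresh: float = 0.1
    min_per_group: int = 3
    window_up: int = 2500
    window_down: int = 500
    comparisons: list[str] = field(
        default_factory=lambda: list(comparison_sets.COMPARISON_NAMES)
    )
    sim: dict = field(default_factory=dict)  # overrides for SimConfig fields

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.beta_paths = {int(k): v for k, v in cfg.beta_paths.items()}
        cfg.detection_paths = {int(k): v for k, v in cfg.detection_paths.items()}
        return cfg

    def validate(self) -> None:
        if not (0 <= self.qc_detect <= 1 and 0 <= self.mask_detect <= 1):
            raise ValueError("detection thresholds must lie in [0, 1]")
        if not (0 <= self.q_thresh <= 1):
            raise ValueError("q threshold must lie in [0, 1]")
        if self.delta_thresh < 0 or self.min_per_group < 1:
            raise ValueError("invalid delta threshold or min_per_group")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run(config: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Execute the pipeline; returns the manifest (also written to disk).

    ``stages`` may restrict execution to a subset of
    ``["simulate", "qc", "dml", "dmg", "sets", "enrich", "stability"]``;
    later stages consume in-memory results of earlier ones, so a restricted
    run must start from "simulate" or provide all input paths.
    """
    config.validate()
    all_stages = ["simulate", "qc", "dml", "dmg", "sets", "enrich", "stability"]
    stages = stages or all_stages
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "version": __version__,
        "stages": {},
        "outputs": {},
        "inputs": {},
    }

    # ------------------------------------------------------------------ inputs
    if config.simulate and "simulate" in stages:
        sim_cfg = synthetic_data.SimConfig(**{"seed": config.seed, **config.sim})
        cohort = synthetic_data.simulate_cohort(sim_cfg, outdir / "inputs")
        config.beta_paths = {
            p: str(cohort.paths[f"beta_P{p}"]) for p in sim_cfg.passages
        }
        config.detection_paths = {
            p: str(cohort.paths[f"detection_P{p}"]) for p in sim_cfg.passages
        }
        config.sheet_path = str(cohort.paths["sample_sheet"])
        config.annotation_path = str(cohort.paths["annotation"])
        config.gene_models_path = str(cohort.paths["gene_models"])
        config.gmt_paths = {"KEGG": str(cohort.paths["gmt"])}
        config.signature_path = str(cohort.paths["signature"])
        manifest["stages"]["simulate"] = {
            "n_loci": sim_cfg.n_loci,
            "n_samples": len(cohort.sheet),
            "n_planted_dml": int(cohort.truth.loci["is_planted_dml"].sum()),
        }

    matrices = {
        p: io_formats.read_beta_matrix(
            config.beta_paths[p], config.detection_paths.get(p)
        )
        for p in sorted(config.beta_paths)
    }
    sheet = io_formats.read_sample_sheet(config.sheet_path)
    annot = io_formats.read_cpg_annotation(config.annotation_path)
    models = io_formats.read_gene_models(config.gene_models_path)
    dbs = {
        name: io_formats.read_gmt(path, source=name)
        for name, path in config.gmt_paths.items()
    }
    signature = (
        io_formats.read_signature(config.signature_path)
        if config.signature_path
        else None
    )
    for key in ("sheet_path", "annotation_path", "gene_models_path"):
        manifest["inputs"][key] = _sha256(Path(getattr(config, key)))
    for p, path in config.beta_paths.items():
        manifest["inputs"][f"beta_P{p}"] = _sha256(Path(path))

    # ---------------------------------------------------------------------- qc
    if "qc" in stages:
        filtered = {}
        removed = {}
        for p, m in matrices.items():
            filtered[p], removed[p] = dml_detection.qc_filter_loci(
                m, config.qc_detect
            )
        matrices = filtered
        manifest["stages"]["qc"] = {f"removed_P{p}": r for p, r in removed.items()}

    # --------------------------------------------------------------------- dml
    dmg_sets: dict[str, pdmg.DMGSet] = {}
    if "dml" in stages:
        matrix = matrices[config.dml_passage]
        plans = comparison_sets.build_plans(
            sheet, config.dml_passage, config.min_per_group
        )
        plans = [p for p in plans if p.name in config.comparisons]
        multimap = pdmg.map_loci_to_genes(
            annot, models, up=config.window_up, down=config.window_down
        )
        counts: dict[str, dict] = {}
        for plan in plans:
            if not plan.is_primitive:
                continue
            if not plan.usable:
                logger.warning("comparison %s unusable (too few samples)", plan.name)
                continue
            table = dml_detection.call_dml(
                matrix,
                plan.group_A,
                plan.group_B,
                q_thresh=config.q_thresh,
                delta_thresh=config.delta_thresh,
                min_per_group=config.min_per_group,
                mask_detect=config.mask_detect,
            )
            dml_detection.write_locus_table(table, outdir / f"dml_{plan.name}.tsv")
            if "dmg" in stages:
                dmg_sets[plan.name] = pdmg.call_dmgs(table, multimap, plan.name)
                pdmg.write_dmg_set(
                    dmg_sets[plan.name], outdir / f"dmg_{plan.name}.tsv"
                )
            counts[plan.name] = {
                "n_dml": int(table["is_dml"].sum()),
                "n_hyper": int((table["direction"] == "hyper").sum()),
                "n_hypo": int((table["direction"] == "hypo").sum()),
                "n_dmg": len(dmg_sets.get(plan.name, ())),
            }
        manifest["stages"]["dml"] = counts

        if "sets" in stages:
            for plan in plans:
                if plan.is_primitive or not set(plan.derivation) <= set(
                    dmg_sets
                ):
                    continue
                dmg_sets[plan.name] = comparison_sets.combine_dmg_sets(
                    dmg_sets, plan.derivation, name=plan.name
                )
                pdmg.write_dmg_set(
                    dmg_sets[plan.name], outdir / f"dmg_{plan.name}.tsv"
                )
            manifest["stages"]["sets"] = {
                name: len(s) for name, s in dmg_sets.items()
            }

    # ------------------------------------------------------------------ enrich
    if "enrich" in stages and dmg_sets:
        multimap = pdmg.map_loci_to_genes(
            annot, models, up=config.window_up, down=config.window_down
        )
        chip_genes = set().union(*multimap.values()) if multimap else set()
        counts = {}
        for set_name, dmg in dmg_sets.items():
            for db_name, db in dbs.items():
                table = enrichment.enrich(dmg, db, chip_genes, config.q_thresh)
                enrichment.write_enrichment(
                    table, outdir / f"enrichment_{set_name}_{db_name}.tsv"
                )
                counts[f"{set_name}_{db_name}"] = int(table["significant"].sum())
        manifest["stages"]["enrich"] = counts

    # --------------------------------------------------------------- stability
    if "stability" in stages and len(matrices) >= 2:
        report = stab.passage_stability(matrices, sheet, signature)
        report.per_line_rho.to_csv(
            outdir / "stability_per_line.tsv", sep="\t", index=False, na_rep="NA"
        )
        report.average_rho.to_csv(
            outdir / "stability_average.tsv", sep="\t", index=False, na_rep="NA"
        )
        sig_matrix, _ = (
            stab.subset_to_signature(matrices[config.dml_passage], signature)
            if signature
            else (matrices[config.dml_passage], [])
        )
        slink, llink, ordered = stab.cluster_heatmap(sig_matrix)
        with open(outdir / "sample_tree.nwk", "w") as fh:
            fh.write(stab.linkage_to_newick(slink, list(sig_matrix.beta.columns)))
        with open(outdir / "locus_tree.nwk", "w") as fh:
            fh.write(stab.linkage_to_newick(llink, list(sig_matrix.beta.index)))
        ordered.to_csv(
            outdir / "heatmap_matrix.tsv", sep="\t", na_rep="NA",
            index_label="locus_id",
        )
        manifest["stages"]["stability"] = {
            "n_pairs": len(report.per_line_rho),
            "mean_rho": report.average_rho["mean_rho"].mean(),
        }

    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][str(path.relative_to(outdir))] = _sha256(path)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
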