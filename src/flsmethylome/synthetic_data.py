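"""Synthetic methylation-array cohorts with known planted truth.

The generator emulates the structure of a cultured-synoviocyte 450K study:
three phenotype groups of cell lines (RA/OA/NL, default 11/11/6), each line
assayed at passages 3, 5 and 7; per-CpG baseline methylation drawn from a
bimodal low/high beta mixture; between-line and within-line (assay) noise,
with extra noise at passage 7 as lines approach senescence; planted
group-level RA effects at a configurable fraction of promoter CpGs; missing
values and detection-p failures at configurable rates.

Gene models sit on one synthetic chromosome with 10 kb TSS spacing so that
promoter windows never overlap and the planted-truth tables are
unambiguous. A KEGG-style GMT is built so that designated pathways draw
most of their members from planted DMG genes while the rest sample genes
uniformly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import io_formats
from .io_formats import BetaMatrix, GeneModel, PathwayDB

__all__ = ["SimConfig", "TruthTable", "Cohort", "simulate_cohort", "passage_correlation_of"]

TSS_SPACING = 10_000
WINDOW_UP, WINDOW_DOWN = 2500, 500


@dataclass(frozen=True)
class SimConfig:
    """Study-shaped simulation parameters.

    Defaults mirror the cohort the pipeline is designed for: 20 000 CpGs,
    11/11/6 RA/OA/NL cell lines at passages 3/5/7, planted group effects of
    0.3 beta at 2% of promoter CpGs, assay noise of 0.05 beta.
    """

    n_loci: int = 20_000
    n_genes: int = 1000
    genes_per_pathway: int = 25
    n_pathways: int = 40
    group_sizes: tuple[int, int, int] = (11, 11, 6)  # RA, OA, NL cell lines
    passages: tuple[int, ...] = (3, 5, 7)
    promoter_frac: float = 0.5
    frac_dml: float = 0.02
    frac_nl_divergent: float = 0.02
    effect_size: float = 0.3
    line_sd: float = 0.05
    assay_sd: float = 0.05
    p7_extra_sd: float = 0.03
    miss_rate: float = 0.005
    det_fail_rate: float = 5e-4
    planted_pathways: tuple[str, ...] = ("pw0001", "pw0002")
    planted_gene_frac: float = 0.6
    p5_replicate_lines: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "promoter_frac",
            "frac_dml",
            "frac_nl_divergent",
            "miss_rate",
            "det_fail_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if any(g < 1 for g in self.group_sizes):
            raise ValueError("group sizes must be >= 1")
        if self.frac_dml > 0 and self.frac_dml * self.n_loci < 1:
            raise ValueError("frac_dml * n_loci < 1: no locus can be planted")


@dataclass
class TruthTable:
    """Planted ground truth: per-locus, per-gene and per-pathway labels.

    ``is_planted_dml``/``planted_delta`` describe the RA group effect at
    promoter CpGs (the DML/DMG/pathway truth). ``nl_delta`` records the
    NL-group divergence planted at intergenic CpGs so that all three
    phenotype groups are mutually separable; it never touches a promoter,
    so the gene- and pathway-level truth stays a pure RA effect.
    """

    loci: pd.DataFrame  # locus_id, is_planted_dml, planted_delta, nl_delta
    genes: pd.DataFrame  # gene_symbol, is_planted_dmg
    pathways: pd.DataFrame  # pathway_id, is_planted_enriched

    @property
    def planted_loci(self) -> list[str]:
        return list(self.loci.loc[self.loci["is_planted_dml"], "locus_id"])

    @property
    def planted_genes(self) -> set[str]:
        return set(self.genes.loc[self.genes["is_planted_dmg"], "gene_symbol"])


@dataclass
class Cohort:
    """Everything one simulated study produces, in memory plus on disk."""

    config: SimConfig
    matrices: dict[int, BetaMatrix]  # passage -> beta matrix
    sheet: pd.DataFrame
    annotation: pd.DataFrame
    gene_models: list[GeneModel]
    pathway_db: PathwayDB
    signature: list[str]
    truth: TruthTable
    paths: dict[str, Path] = field(default_factory=dict)


def _gene_layout(config: SimConfig) -> list[GeneModel]:
    models = []
    for i in range(config.n_genes):
        strand = "+" if i % 2 == 0 else "-"
        tss = TSS_SPACING * (i + 1)
        models.append(GeneModel(f"G{i + 1:04d}", f"T{i + 1:04d}", "chrS", strand, tss))
    return models


def _place_loci(
    config: SimConfig, models: list[GeneModel], rng: np.random.Generator
) -> tuple[pd.DataFrame, np.ndarray]:
    """CpG annotation plus the owning-gene index (-1 for intergenic loci)."""
    n_prom = int(round(config.promoter_frac * config.n_loci))
    owner = np.full(config.n_loci, -1, dtype=int)
    positions = np.empty(config.n_loci, dtype=int)
    for i in range(n_prom):
        g = i % config.n_genes
        owner[i] = g
        m = models[g]
        lo = m.tss - WINDOW_UP if m.strand == "+" else m.tss - WINDOW_DOWN
        hi = m.tss + WINDOW_DOWN if m.strand == "+" else m.tss + WINDOW_UP
        positions[i] = rng.integers(lo, hi + 1)
    for i in range(n_prom, config.n_loci):
        g = (i - n_prom) % config.n_genes
        # between-gene gap: windows reach tss+/-2500, so tss+4000..+6000 is free
        positions[i] = models[g].tss + rng.integers(4000, 6001)
    annot = pd.DataFrame(
        {
            "locus_id": [f"cg{i + 1:07d}" for i in range(config.n_loci)],
            "chromosome": "chrS",
            "position": positions,
        }
    )
    return annot, owner


def _baselines(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    low = rng.beta(2.0, 18.0, size=config.n_loci)  # mode near 0.1
    high = rng.beta(17.0, 3.0, size=config.n_loci)  # mode near 0.85
    pick_high = rng.random(config.n_loci) < 0.5
    return np.clip(np.where(pick_high, high, low), 0.05, 0.95)


def _signed_shifts(
    idx: np.ndarray,
    baseline: np.ndarray,
    effect: float,
    rng: np.random.Generator,
    n_loci: int,
) -> np.ndarray:
    """Balanced +/- shifts of magnitude ``effect``, kept inside (0.02, 0.98)."""
    delta = np.zeros(n_loci)
    signs = np.where(rng.random(idx.size) < 0.5, 1.0, -1.0)
    for i, s in zip(idx, signs):
        d = s * effect
        if not 0.02 <= baseline[i] + d <= 0.98:
            d = -d
        if not 0.02 <= baseline[i] + d <= 0.98:
            d = np.clip(baseline[i] + d, 0.02, 0.98) - baseline[i]
        delta[i] = d
    return delta


def _plant_effects(
    config: SimConfig, owner: np.ndarray, baseline: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Plant RA shifts at promoter loci and NL divergence at intergenic loci."""
    is_planted = np.zeros(config.n_loci, dtype=bool)
    delta = np.zeros(config.n_loci)
    nl_delta = np.zeros(config.n_loci)
    if config.effect_size == 0:
        return is_planted, delta, nl_delta  # null cohort: nothing to plant
    prom_idx = np.flatnonzero(owner >= 0)
    inter_idx = np.flatnonzero(owner < 0)
    n_planted = int(round(config.frac_dml * prom_idx.size))
    if n_planted:
        chosen = np.sort(rng.choice(prom_idx, size=n_planted, replace=False))
        delta = _signed_shifts(chosen, baseline, config.effect_size, rng, config.n_loci)
        is_planted[chosen] = True
    n_nl = int(round(config.frac_nl_divergent * inter_idx.size))
    if n_nl:
        chosen_nl = np.sort(rng.choice(inter_idx, size=n_nl, replace=False))
        nl_delta = _signed_shifts(
            chosen_nl, baseline, config.effect_size, rng, config.n_loci
        )
    return is_planted, delta, nl_delta


def _noisy_values(
    group_mean: np.ndarray, sd_total: float, rng: np.random.Generator
) -> np.ndarray:
    """One sample's betas: noise on the logit scale, locally rescaled.

    The logit-scale SD is sd_total / max(m (1 - m), 0.15) so that after the
    inverse transform the beta-scale SD is approximately ``sd_total`` for
    intermediate methylation and shrinks toward the boundaries — matching
    the heteroscedastic behavior of array beta values — while values stay
    strictly inside (0, 1). Without the cap, the 1/(m(1-m)) factor blows up
    near 0/1 and produces unrealistic heavy-tailed outliers.
    """
    m = np.clip(group_mean, 0.02, 0.98)
    scale = sd_total / np.maximum(m * (1.0 - m), 0.15)
    return expit(logit(m) + rng.normal(0.0, 1.0, size=m.size) * scale)


def _build_gmt(
    config: SimConfig, planted_genes: list[str], rng: np.random.Generator
) -> tuple[PathwayDB, pd.DataFrame]:
    all_genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    other_genes = [g for g in all_genes if g not in set(planted_genes)]
    entries: dict[str, tuple[str, frozenset[str]]] = {}
    planted_flag = []
    for j in range(config.n_pathways):
        pid = f"pw{j + 1:04d}"
        if pid in config.planted_pathways and planted_genes:
            n_from_planted = min(
                int(np.ceil(config.planted_gene_frac * config.genes_per_pathway)),
                len(planted_genes),
            )
            members = list(
                rng.choice(planted_genes, size=n_from_planted, replace=False)
            )
            n_rest = config.genes_per_pathway - len(members)
            members += list(rng.choice(other_genes, size=n_rest, replace=False))
            planted_flag.append(True)
        else:
            members = list(
                rng.choice(all_genes, size=config.genes_per_pathway, replace=False)
            )
            planted_flag.append(False)
        entries[pid] = (f"synthetic pathway {j + 1}", frozenset(members))
    db = PathwayDB(source="KEGG", entries=entries)
    truth = pd.DataFrame(
        {"pathway_id": list(entries), "is_planted_enriched": planted_flag}
    )
    return db, truth


def simulate_cohort(config: SimConfig, outdir: str | Path | None = None) -> Cohort:
    """Simulate one complete cohort; optionally write every artifact to disk.

    With ``outdir`` set, the files emitted are exactly the formats the
    readers in :mod:`flsmethylome.io_formats` consume, plus truth tables as
    TSV; output is byte-identical across runs with the same config.
    """
    rng = np.random.default_rng(config.seed)
    models = _gene_layout(config)
    annot, owner = _place_loci(config, models, rng)
    baseline = _baselines(config, rng)
    is_planted, planted_delta, nl_delta = _plant_effects(config, owner, baseline, rng)

    lines: list[tuple[str, str]] = []  # (cell_line_id, phenotype)
    for pheno, size in zip(("RA", "OA", "NL"), config.group_sizes):
        lines += [(f"{pheno}{i + 1:02d}", pheno) for i in range(size)]

    # per-line, per-locus offsets shared across passages
    line_eff = rng.normal(0.0, config.line_sd, size=(len(lines), config.n_loci))

    locus_ids = list(annot["locus_id"])
    sheet_rows = []
    matrices: dict[int, BetaMatrix] = {}
    for passage in config.passages:
        extra = config.p7_extra_sd if passage == 7 else 0.0
        cols: dict[str, np.ndarray] = {}
        det_cols: dict[str, np.ndarray] = {}

        def one_sample(li: int, pheno: str, sid: str) -> None:
            m = baseline.copy()
            if pheno == "RA":
                m = m + planted_delta
            elif pheno == "NL":
                m = m + nl_delta
            # line offset folded into the group mean before assay noise
            m = np.clip(m + line_eff[li], 0.02, 0.98)
            sd = float(np.hypot(config.assay_sd, extra))
            vals = _noisy_values(m, sd, rng) if sd > 0 else m.copy()
            miss = rng.random(config.n_loci) < config.miss_rate
            fail = rng.random(config.n_loci) < config.det_fail_rate
            det = rng.uniform(0.0, 0.0009, size=config.n_loci)
            det[fail] = rng.uniform(0.02, 0.2, size=int(fail.sum()))
            vals[miss] = np.nan
            det[miss] = np.nan
            cols[sid] = vals
            det_cols[sid] = det

        for li, (line, pheno) in enumerate(lines):
            sid = f"{line}_P{passage}"
            one_sample(li, pheno, sid)
            sheet_rows.append((sid, pheno, line, passage, ""))
            if passage == 5 and li < config.p5_replicate_lines:
                rep_sid = f"{line}_P5rep"
                one_sample(li, pheno, rep_sid)
                sheet_rows.append((rep_sid, pheno, line, passage, "rep"))

        beta = pd.DataFrame(cols, index=pd.Index(locus_ids, name="locus_id"))
        det = pd.DataFrame(det_cols, index=pd.Index(locus_ids, name="locus_id"))
        matrices[passage] = BetaMatrix(beta, det)

    sheet = pd.DataFrame(sheet_rows, columns=io_formats.SHEET_COLUMNS)

    planted_genes = sorted(
        {models[owner[i]].gene_symbol for i in np.flatnonzero(is_planted)}
    )
    db, pathway_truth = _build_gmt(config, planted_genes, rng)
    truth = TruthTable(
        loci=pd.DataFrame(
            {
                "locus_id": locus_ids,
                "is_planted_dml": is_planted,
                "planted_delta": planted_delta,
                "nl_delta": nl_delta,
            }
        ),
        genes=pd.DataFrame(
            {
                "gene_symbol": [m.gene_symbol for m in models],
                "is_planted_dmg": [m.gene_symbol in set(planted_genes) for m in models],
            }
        ),
        pathways=pathway_truth,
    )
    # the phenotype-predictive signature: RA-planted plus NL-divergent CpGs
    signature = [locus_ids[i] for i in np.flatnonzero(is_planted | (nl_delta != 0))]

    cohort = Cohort(
        config=config,
        matrices=matrices,
        sheet=sheet,
        annotation=annot,
        gene_models=models,
        pathway_db=db,
        signature=signature,
        truth=truth,
    )
    if outdir is not None:
        cohort.paths = _write_cohort(cohort, Path(outdir))
    return cohort


def _write_cohort(cohort: Cohort, outdir: Path) -> dict[str, Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for passage, matrix in cohort.matrices.items():
        bpath = outdir / f"beta_P{passage}.tsv"
        dpath = outdir / f"detection_P{passage}.tsv"
        io_formats.write_beta_matrix(matrix, bpath, dpath)
        paths[f"beta_P{passage}"] = bpath
        paths[f"detection_P{passage}"] = dpath
    paths["sample_sheet"] = outdir / "sample_sheet.csv"
    io_formats.write_sample_sheet(cohort.sheet, paths["sample_sheet"])
    paths["annotation"] = outdir / "cpg_annotation.tsv"
    io_formats.write_cpg_annotation(cohort.annotation, paths["annotation"])
    paths["gene_models"] = outdir / "gene_models.refflat.tsv"
    io_formats.write_gene_models(cohort.gene_models, paths["gene_models"])
    paths["gmt"] = outdir / "pathways.gmt"
    io_formats.write_gmt(cohort.pathway_db, paths["gmt"])
    paths["signature"] = outdir / "signature.txt"
    io_formats.write_signature(cohort.signature, paths["signature"])
    paths["truth_loci"] = outdir / "truth_loci.tsv"
    cohort.truth.loci.to_csv(paths["truth_loci"], sep="\t", index=False)
    paths["truth_genes"] = outdir / "truth_genes.tsv"
    cohort.truth.genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    paths["truth_pathways"] = outdir / "truth_pathways.tsv"
    cohort.truth.pathways.to_csv(paths["truth_pathways"], sep="\t", index=False)
    with open(outdir / "sim_config.txt", "w") as fh:
        for f in dataclasses.fields(cohort.config):
            fh.write(f"{f.name}\t{getattr(cohort.config, f.name)}\n")
    return paths


def passage_correlation_of(config: SimConfig) -> pd.DataFrame:
    """Expected ordering of inter-passage correlations under the noise ladder.

    Returns one row per passage pair with the per-passage assay SDs and the
    expected Spearman ordering rank (1 = highest correlation). With
    ``p7_extra_sd == 0`` all pairs share rank 1 (equal in expectation).
    """
    if len(config.passages) < 2:
        raise ValueError("need >= 2 passages")
    sd = {
        p: float(np.hypot(config.assay_sd, config.p7_extra_sd if p == 7 else 0.0))
        for p in config.passages
    }
    rows = []
    import itertools

    for pa, pb in itertools.combinations(sorted(config.passages), 2):
        noise = np.hypot(sd[pa], sd[pb])
        rows.append({"passage_a": pa, "passage_b": pb, "pair_noise_sd": noise})
    df = pd.DataFrame(rows)
    df["expected_rank"] = df["pair_noise_sd"].rank(method="min").astype(int)
    return df
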