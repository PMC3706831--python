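"""Readers and writers for every on-disk artifact the pipeline touches.

All tabular formats are plain TSV/CSV so that fixtures stay diffable.
Conventions pinned here and relied on everywhere else:

* Missing values are accepted on read as empty string, ``NA`` or ``NaN`` and
  always written back as ``NA``.
* Genomic coordinates are held internally as 1-based inclusive positions.
  UCSC refFlat / BED 0-based half-open intervals are converted at this
  boundary and nowhere else.
* Detection p-values may live in a parallel TSV of identical shape; when
  absent every value is treated as perfectly detected (p = 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING_MARKERS = ["", "NA", "NaN", "nan"]

__all__ = [
    "FormatError",
    "BetaMatrix",
    "GeneModel",
    "PathwayDB",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_cpg_annotation",
    "write_cpg_annotation",
    "read_gene_models",
    "write_gene_models",
    "read_gmt",
    "write_gmt",
    "read_signature",
    "write_signature",
]


class FormatError(ValueError):
    """A file violates the dialect or an invariant of its format."""


# ---------------------------------------------------------------------------
# beta matrices


@dataclass
class BetaMatrix:
    """Loci x samples methylation fractions with per-value detection p-values.

    ``beta`` holds methylation fractions in [0, 1]; NaN marks MISSING.
    ``detection_p`` has the same shape and axes; NaN there means the value was
    never assayed (mirrors a MISSING beta).
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.detection_p is None:
            self.detection_p = pd.DataFrame(
                0.0, index=self.beta.index, columns=self.beta.columns
            )
        if not self.beta.index.is_unique:
            raise FormatError("duplicate locus ids in beta matrix")
        if not self.beta.columns.is_unique:
            raise FormatError("duplicate sample ids in beta matrix")
        vals = self.beta.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any((vals < 0) | (vals > 1)):
                raise ValueError("beta values outside [0, 1]")
        if self.beta.shape != self.detection_p.shape:
            raise FormatError("beta and detection_p shapes differ")
        self.detection_p.index = self.beta.index
        self.detection_p.columns = self.beta.columns

    @property
    def locus_ids(self) -> list[str]:
        return list(self.beta.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.beta.shape

    def subset_samples(self, sample_ids: list[str]) -> "BetaMatrix":
        missing = [s for s in sample_ids if s not in self.beta.columns]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return BetaMatrix(
            self.beta[sample_ids].copy(), self.detection_p[sample_ids].copy()
        )

    def subset_loci(self, locus_ids: list[str]) -> "BetaMatrix":
        return BetaMatrix(
            self.beta.loc[locus_ids].copy(), self.detection_p.loc[locus_ids].copy()
        )


def _read_matrix_tsv(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        raise FormatError(f"{path}: duplicate sample id in header")
    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        na_values=MISSING_MARKERS,
        keep_default_na=False,
    )
    df.index = df.index.astype(str)
    df = df.astype(float)
    if not df.index.is_unique:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate locus id {dup!r}")
    return df


def read_beta_matrix(path, detection_path=None) -> BetaMatrix:
    """Read a beta-value TSV (first column locus id, header of sample ids).

    ``detection_path`` optionally points at a detection-p TSV of identical
    shape; without it all values are treated as detected (p = 0).
    """
    beta = _read_matrix_tsv(path)
    det = None
    if detection_path is not None:
        det = _read_matrix_tsv(detection_path)
        if list(det.index) != list(beta.index) or list(det.columns) != list(
            beta.columns
        ):
            raise FormatError("detection matrix axes do not match beta matrix")
    return BetaMatrix(beta, det)


def write_beta_matrix(matrix: BetaMatrix, path, detection_path=None) -> None:
    matrix.beta.to_csv(path, sep="\t", na_rep="NA", index_label="locus_id")
    if detection_path is not None:
        matrix.detection_p.to_csv(
            detection_path, sep="\t", na_rep="NA", index_label="locus_id"
        )


# ---------------------------------------------------------------------------
# sample sheets

PHENOTYPES = ("RA", "OA", "NL")
SHEET_COLUMNS = ["sample_id", "phenotype", "cell_line_id", "passage", "replicate_label"]


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a sample sheet (CSV or TSV, sniffed from the header line)."""
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if first.count("\t") >= first.count(",") else ","
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "cell_line_id": str})
    required = set(SHEET_COLUMNS[:4])
    if not required.issubset(df.columns):
        raise FormatError(f"sample sheet missing columns {required - set(df.columns)}")
    if "replicate_label" not in df.columns:
        df["replicate_label"] = ""
    df["replicate_label"] = df["replicate_label"].fillna("").astype(str)
    if df["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in sample sheet")
    bad = set(df["phenotype"]) - set(PHENOTYPES)
    if bad:
        raise FormatError(f"unknown phenotype labels: {sorted(bad)}")
    df["passage"] = df["passage"].astype(int)
    return df[SHEET_COLUMNS].copy()


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet[SHEET_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# CpG annotation


def read_cpg_annotation(path) -> pd.DataFrame:
    """Read a minimal CpG annotation TSV: locus_id, chromosome, position."""
    df = pd.read_csv(path, sep="\t", dtype={"locus_id": str, "chromosome": str})
    required = {"locus_id", "chromosome", "position"}
    if not required.issubset(df.columns):
        raise FormatError(f"annotation missing columns {required - set(df.columns)}")
    if df["locus_id"].duplicated().any():
        raise FormatError("duplicate locus_id in annotation")
    df["position"] = df["position"].astype(int)
    if (df["position"] < 1).any():
        raise ValueError("annotation positions must be >= 1")
    return df[["locus_id", "chromosome", "position"]].copy()


def write_cpg_annotation(annot: pd.DataFrame, path) -> None:
    annot[["locus_id", "chromosome", "position"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene models


@dataclass(frozen=True)
class GeneModel:
    """One transcript with its 1-based transcription start site."""

    gene_symbol: str
    transcript_id: str
    chromosome: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"unknown strand {self.strand!r}")


def read_gene_models(path) -> list[GeneModel]:
    """Read transcripts from a refFlat-style TSV or a BED6 file.

    refFlat: gene, transcript, chrom, strand, txStart, txEnd with UCSC
    0-based half-open coordinates. BED6: chrom, start, end, name, score,
    strand; the BED name serves as both transcript id and gene symbol.
    The TSS is converted to 1-based: txStart+1 on ``+``, txEnd on ``-``.
    """
    models: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected >= 6 fields")
            if fields[3] in ("+", "-"):  # refFlat layout
                gene, tx, chrom, strand = fields[0], fields[1], fields[2], fields[3]
                start, end = int(fields[4]), int(fields[5])
            elif fields[5] in ("+", "-"):  # BED6 layout (score ignored)
                chrom, tx, strand = fields[0], fields[3], fields[5]
                gene = tx
                start, end = int(fields[1]), int(fields[2])
            else:
                raise FormatError(f"{path}:{lineno}: unknown strand symbol")
            tss = start + 1 if strand == "+" else end
            if tx in seen:
                raise FormatError(f"{path}:{lineno}: duplicate transcript id {tx!r}")
            seen.add(tx)
            models.append(GeneModel(gene, tx, chrom, strand, tss))
    return models


def write_gene_models(models: list[GeneModel], path) -> None:
    """Write transcripts in the refFlat dialect (0-based half-open).

    A 1 kb dummy transcript body downstream of the TSS is emitted; only the
    TSS-bearing end is meaningful to this pipeline.
    """
    with open(path, "w") as fh:
        for m in models:
            if m.strand == "+":
                tx_start, tx_end = m.tss - 1, m.tss - 1 + 1000
            else:
                tx_start, tx_end = max(m.tss - 1000, 0), m.tss
            fh.write(
                f"{m.gene_symbol}\t{m.transcript_id}\t{m.chromosome}\t"
                f"{m.strand}\t{tx_start}\t{tx_end}\n"
            )


# ---------------------------------------------------------------------------
# pathway databases (GMT)


@dataclass
class PathwayDB:
    """Named gene sets from KEGG- or GO-style databases."""

    source: str = "KEGG"
    namespace: str = ""
    # pathway_id -> (pathway_name, gene set)
    entries: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def gene_universe(self) -> frozenset[str]:
        out: set[str] = set()
        for _, genes in self.entries.values():
            out |= genes
        return frozenset(out)


def read_gmt(path, source: str = "KEGG", namespace: str = "") -> PathwayDB:
    """Read a standard GMT file: name, description, then member genes."""
    entries: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line with < 3 fields")
            pid, name = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if pid in entries:
                raise FormatError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
            if not genes:
                raise FormatError(f"{path}:{lineno}: empty gene set")
            entries[pid] = (name, genes)
    return PathwayDB(source=source, namespace=namespace, entries=entries)


def write_gmt(db: PathwayDB, path) -> None:
    with open(path, "w") as fh:
        for pid, (name, genes) in db.entries.items():
            fh.write("\t".join([pid, name, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# signature lists


def read_signature(path) -> list[str]:
    """Read a plain-text CpG signature, one locus id per line, order kept."""
    ids: list[str] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            locus = line.strip()
            if not locus or locus.startswith("#"):
                continue
            if locus in seen:
                raise FormatError(f"duplicate id {locus!r} in signature list")
            seen.add(locus)
            ids.append(locus)
    return ids


def write_signature(ids: list[str], path) -> None:
    with open(path, "w") as fh:
        for locus in ids:
            fh.write(locus + "\n")
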