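"""Domain types and readers/writers for gene models, peaks, matrices and clinical tables.

All genomic coordinates are stored 0-based half-open internally.  GTF input
(1-based, inclusive) is converted at the boundary.  Every downstream module
consumes only the types defined here.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

BIOTYPES = ("protein_coding", "lincRNA", "pseudogene", "other_noncoding")
STRANDS = ("+", "-")

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "biotype"]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class GeneModel:
    """One gene: coordinates, strand, biotype, and a single canonical TSS.

    Coordinates are 0-based half-open.  The TSS follows the single-TSS
    convention: ``start`` for '+' strand genes, ``end`` for '-' strand genes.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} >= end {self.end}")
        if self.strand not in STRANDS:
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"{self.gene_id}: bad biotype {self.biotype!r}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def is_coding(self) -> bool:
        return self.biotype == "protein_coding"


class GeneSet:
    """Ordered collection of :class:`GeneModel` with unique gene_ids."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: list[GeneModel] = list(genes)
        self._by_id: dict[str, GeneModel] = {}
        for g in self.genes:
            if g.gene_id in self._by_id:
                raise ParseError(f"duplicate gene_id {g.gene_id!r}")
            self._by_id[g.gene_id] = g

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def biotypes(self) -> pd.Series:
        """gene_id -> biotype, in gene order."""
        return pd.Series({g.gene_id: g.biotype for g in self.genes}, name="biotype")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (g.gene_id, g.chrom, g.start, g.end, g.strand, g.biotype)
                for g in self.genes
            ],
            columns=GENE_COLUMNS,
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneSet":
        return cls(
            GeneModel(
                str(r.gene_id), str(r.chrom), int(r.start), int(r.end),
                str(r.strand), str(r.biotype),
            )
            for r in df.itertuples(index=False)
        )


@dataclass(frozen=True)
class Peak:
    """One ChIP interval with summit position and enrichment signal."""

    chrom: str
    start: int
    end: int
    summit: int
    signal: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak {self.chrom}:{self.start}-{self.end}: start >= end")
        if not (self.start <= self.summit < self.end):
            raise ValueError(
                f"peak {self.chrom}:{self.start}-{self.end}: summit {self.summit} outside"
            )
        if self.signal < 0:
            raise ValueError(f"peak {self.chrom}:{self.start}: negative signal")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class PeakSet:
    """Collection of peaks, indexable by chromosome."""

    def __init__(self, peaks: Iterable[Peak]):
        self.peaks: list[Peak] = list(peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def chromosomes(self) -> list[str]:
        return sorted({p.chrom for p in self.peaks})

    def by_chrom(self) -> dict[str, list[Peak]]:
        out: dict[str, list[Peak]] = {}
        for p in self.peaks:
            out.setdefault(p.chrom, []).append(p)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.chrom, p.start, p.end, p.summit, p.signal) for p in self.peaks],
            columns=["chrom", "start", "end", "summit", "signal"],
        )


@dataclass
class CountMatrix:
    """Genes x samples numeric matrix with optional per-sample condition labels."""

    values: pd.DataFrame  # genes as rows, samples as columns
    sample_groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            bad = self.values[(self.values < 0).any(axis=1)].index[0]
            raise ParseError(f"negative value in row {bad!r}")
        unknown = set(self.sample_groups) - set(self.values.columns)
        if unknown:
            raise ParseError(f"sample_groups refers to unknown samples {sorted(unknown)}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ClinicalTable:
    """Per-sample class (tumor/normal), optional stage and survival follow-up."""

    data: pd.DataFrame  # index sample_id; columns: class, stage, time, event

    def __post_init__(self) -> None:
        d = self.data
        bad = set(d["class"].unique()) - {"tumor", "normal"}
        if bad:
            raise ParseError(f"unknown class labels {sorted(bad)}")
        has_time = d["time"].notna()
        has_event = d["event"].notna()
        if (has_time != has_event).any():
            sid = d.index[(has_time != has_event)][0]
            raise ParseError(f"sample {sid!r}: time present iff event present")
        if (d["time"].dropna() < 0).any():
            raise ParseError("negative follow-up time")
        staged_normals = d[(d["class"] == "normal") & d["stage"].notna()]
        if len(staged_normals):
            raise ParseError(
                f"stage set for normal sample {staged_normals.index[0]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _map_gtf_biotype(raw: str | None) -> str:
    if raw is None:
        return "other_noncoding"
    if raw == "protein_coding":
        return "protein_coding"
    if raw in ("lincRNA", "lncRNA"):
        return "lincRNA"
    if "pseudogene" in raw:
        return "pseudogene"
    return "other_noncoding"


def read_gene_models(path: str | Path, format: str | None = None) -> GeneSet:
    """Read a gene table (TSV) or a GTF into a :class:`GeneSet`.

    TSV columns: gene_id, chrom, start, end, strand, biotype (0-based
    half-open).  GTF transcripts are collapsed to one gene with the most
    upstream TSS; 1-based inclusive coordinates are converted on read.
    Missing biotype defaults to ``other_noncoding`` with a warning.
    """
    path = Path(path)
    if format is None:
        format = "gtf" if path.suffix.lower() in (".gtf", ".gff") else "tsv"
    if format == "tsv":
        return _read_gene_tsv(path)
    if format == "gtf":
        return _read_gene_gtf(path)
    raise ValueError(f"unknown gene-model format {format!r}")


def _read_gene_tsv(path: Path) -> GeneSet:
    genes = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = set(GENE_COLUMNS) - set(header)
        if missing:
            raise ParseError(f"{path}: missing columns {sorted(missing)}")
        idx = {c: header.index(c) for c in GENE_COLUMNS}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                biotype = fields[idx["biotype"]]
                if biotype == "" or biotype == ".":
                    log.warning("%s line %d: missing biotype, defaulting", path, lineno)
                    biotype = "other_noncoding"
                genes.append(
                    GeneModel(
                        gene_id=fields[idx["gene_id"]],
                        chrom=fields[idx["chrom"]],
                        start=int(fields[idx["start"]]),
                        end=int(fields[idx["end"]]),
                        strand=fields[idx["strand"]],
                        biotype=biotype,
                    )
                )
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path} line {lineno}: {exc}") from exc
    return GeneSet(genes)


def _read_gene_gtf(path: Path) -> GeneSet:
    # per gene: chrom, strand, biotype, and the extremes over all its rows
    acc: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path} line {lineno}: expected 9 GTF columns")
            chrom, _src, feature, start1, end1, _score, strand, _frame, attrs = fields[:9]
            if feature not in ("gene", "transcript", "exon"):
                continue
            try:
                start = int(start1) - 1  # GTF is 1-based inclusive
                end = int(end1)
            except ValueError as exc:
                raise ParseError(f"{path} line {lineno}: {exc}") from exc
            a = dict(_GTF_ATTR.findall(attrs))
            gene_id = a.get("gene_id")
            if gene_id is None:
                raise ParseError(f"{path} line {lineno}: no gene_id attribute")
            raw_bt = a.get("gene_biotype", a.get("gene_type"))
            rec = acc.setdefault(
                gene_id,
                {"chrom": chrom, "strand": strand, "start": start, "end": end,
                 "biotype": raw_bt, "warned": False},
            )
            rec["start"] = min(rec["start"], start)
            rec["end"] = max(rec["end"], end)
            if rec["biotype"] is None:
                rec["biotype"] = raw_bt
    genes = []
    for gid, rec in acc.items():
        if rec["biotype"] is None:
            log.warning("gene %s: missing biotype in GTF, defaulting", gid)
        genes.append(
            GeneModel(gid, rec["chrom"], rec["start"], rec["end"], rec["strand"],
                      _map_gtf_biotype(rec["biotype"]))
        )
    return GeneSet(genes)


def write_gene_models(genes: GeneSet, path: str | Path) -> None:
    """Write a canonical gene TSV: sorted by (chrom, start, gene_id)."""
    df = genes.to_frame().sort_values(["chrom", "start", "gene_id"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

def read_peaks(path: str | Path, format: str | None = None) -> PeakSet:
    """Read a BED6 or ENCODE narrowPeak file.

    narrowPeak: summit = start + column-10 offset, or the interval midpoint
    (floor) when the offset is -1; signal from signalValue (column 7).
    BED6: summit = floor midpoint; signal from the score column.
    """
    path = Path(path)
    if format is None:
        format = "narrowPeak" if "narrowpeak" in path.suffix.lower() else "bed6"
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                if start >= end:
                    raise ParseError(f"{path} line {lineno}: start >= end")
                if format == "narrowPeak":
                    if len(f) < 10:
                        raise ParseError(f"{path} line {lineno}: narrowPeak needs 10 columns")
                    signal = float(f[6])
                    offset = int(f[9])
                    if offset >= end - start:
                        raise ParseError(
                            f"{path} line {lineno}: summit offset {offset} >= peak length"
                        )
                    summit = (start + end) // 2 if offset < 0 else start + offset
                else:
                    signal = float(f[4]) if len(f) > 4 and f[4] not in (".", "") else 0.0
                    summit = (start + end) // 2
                peaks.append(Peak(chrom, start, end, summit, signal))
            except ParseError:
                raise
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path} line {lineno}: {exc}") from exc
    return PeakSet(peaks)


def write_peaks(peaks: PeakSet, path: str | Path, format: str = "narrowPeak") -> None:
    """Write peaks as narrowPeak (canonical order: chrom, start, end)."""
    rows = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))
    with open(path, "w") as fh:
        for i, p in enumerate(rows):
            if format == "narrowPeak":
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i}\t0\t.\t"
                    f"{p.signal:g}\t-1\t-1\t{p.summit - p.start}\n"
                )
            else:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i}\t{p.signal:g}\t.\n")


# ---------------------------------------------------------------------------
# matrices and clinical tables
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path) -> CountMatrix:
    """Read a genes-x-samples TSV; every cell must parse as a nonnegative number."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        gi, sj = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric cell at gene {df.index[gi]!r}, sample {df.columns[sj]!r}"
        )
    if numeric.isna().to_numpy().any():
        gi, sj = np.argwhere(numeric.isna().to_numpy())[0]
        raise ParseError(
            f"{path}: missing value at gene {df.index[gi]!r}, sample {df.columns[sj]!r}"
        )
    return CountMatrix(values=numeric)


def write_matrix(matrix: CountMatrix | pd.DataFrame, path: str | Path) -> None:
    df = matrix.values if isinstance(matrix, CountMatrix) else matrix
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_sample_groups(path: str | Path) -> dict[str, str]:
    """Two-column TSV (sample_id, group) -> mapping."""
    df = pd.read_csv(path, sep="\t", header=0)
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV with columns sample_id, class, stage, time, event."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns or "class" not in df.columns:
        raise ParseError(f"{path}: clinical table needs sample_id and class columns")
    for col in ("stage", "time", "event"):
        if col not in df.columns:
            df[col] = np.nan
    df = df.set_index("sample_id")
    df["stage"] = pd.to_numeric(df["stage"], errors="coerce")
    df["time"] = pd.to_numeric(df["time"], errors="coerce")
    df["event"] = pd.to_numeric(df["event"], errors="coerce")
    return ClinicalTable(df[["class", "stage", "time", "event"]])


def write_clinical(table: ClinicalTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample_id", float_format="%.6g")


def align_clinical(matrix: CountMatrix | pd.DataFrame, clinical: ClinicalTable) -> ClinicalTable:
    """Drop clinical samples absent from the matrix, logging each drop."""
    cols = set((matrix.values if isinstance(matrix, CountMatrix) else matrix).columns)
    missing = [s for s in clinical.sample_ids if s not in cols]
    for s in missing:
        log.warning("clinical sample %r absent from expression matrix; dropped", s)
    return ClinicalTable(clinical.data.drop(index=missing))
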