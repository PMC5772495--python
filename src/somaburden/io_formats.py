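"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions
----------------------
Mutation positions are **1-based inclusive** (MAF convention).  All interval
work — differential-enrichment regions and gene bodies — is **0-based
half-open** (BED convention).  Conversions happen only at module boundaries;
nothing in this package silently re-bases a coordinate.

Chromosome names are compared as opaque strings.  No ``chr`` prefix
normalization is applied, to avoid silently mixing genome builds; callers
that need it can rename upstream.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "VariantClass",
    "SiftPred",
    "MutationRecord",
    "GenomicInterval",
    "GeneModel",
    "MAF_COLUMNS",
    "read_mutation_table",
    "write_mutation_table",
    "read_bed",
    "write_bed",
    "read_gene_models",
    "write_gene_models",
    "write_results",
    "read_results_json",
]


class FormatError(ValueError):
    """A file does not have the structure the format requires (e.g. a missing column)."""


class ValidationError(ValueError):
    """A structurally well-formed row violates a domain invariant."""


class VariantClass(str, Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    SPLICE = "splice"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    OTHER = "other"


#: Classes that truncate or disrupt the protein product irrespective of a
#: substitution-effect score.
TRUNCATING_CLASSES = frozenset(
    {VariantClass.NONSENSE, VariantClass.FRAMESHIFT, VariantClass.SPLICE}
)


class SiftPred(str, Enum):
    DELETERIOUS = "D"
    TOLERATED = "T"
    MISSING = "missing"


_NUCS = frozenset("ACGT")

# MAF-style variant classification spellings accepted on input.
_VARIANT_CLASS_ALIASES = {
    "silent": VariantClass.SYNONYMOUS,
    "synonymous_variant": VariantClass.SYNONYMOUS,
    "missense_mutation": VariantClass.MISSENSE,
    "missense_variant": VariantClass.MISSENSE,
    "nonsense_mutation": VariantClass.NONSENSE,
    "stop_gained": VariantClass.NONSENSE,
    "splice_site": VariantClass.SPLICE,
    "frame_shift_del": VariantClass.FRAMESHIFT,
    "frame_shift_ins": VariantClass.FRAMESHIFT,
    "in_frame_del": VariantClass.INFRAME_INDEL,
    "in_frame_ins": VariantClass.INFRAME_INDEL,
}


def _coerce_variant_class(value: str) -> VariantClass:
    token = str(value).strip()
    try:
        return VariantClass(token.lower())
    except ValueError:
        pass
    alias = _VARIANT_CLASS_ALIASES.get(token.lower())
    if alias is None:
        return VariantClass.OTHER
    return alias


def _coerce_sift(value) -> SiftPred:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return SiftPred.MISSING
    token = str(value).strip()
    if token in ("", ".", "NA", "nan", "missing"):
        return SiftPred.MISSING
    if token.upper().startswith("D"):
        return SiftPred.DELETERIOUS
    if token.upper().startswith("T"):
        return SiftPred.TOLERATED
    raise ValidationError(f"unrecognized SIFT prediction {value!r}")


@dataclass(frozen=True)
class MutationRecord:
    """One annotated somatic variant call (1-based inclusive position)."""

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: VariantClass
    sift_pred: SiftPred = SiftPred.MISSING
    gerp: float | None = None
    pop_freq: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or set(self.ref) - _NUCS:
            raise ValidationError(f"ref allele must be a non-empty ACGT string, got {self.ref!r}")
        if not self.alt:
            raise ValidationError("alt allele must be non-empty")
        if self.ref == self.alt:
            raise ValidationError(f"ref and alt are identical ({self.ref!r})")
        if not isinstance(self.variant_class, VariantClass):
            raise ValidationError(f"unknown variant class {self.variant_class!r}")
        if not isinstance(self.sift_pred, SiftPred):
            raise ValidationError(f"unknown SIFT prediction {self.sift_pred!r}")
        if self.pop_freq is not None and not (0.0 <= self.pop_freq <= 1.0):
            raise ValidationError(f"pop_freq must be in [0, 1], got {self.pop_freq}")

    @property
    def is_substitution(self) -> bool:
        return len(self.ref) == len(self.alt)


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic region."""

    chrom: str
    start: int
    end: int
    score: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A gene body: the annotated start-to-end interval of a gene (0-based half-open)."""

    gene: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValidationError("gene id must be non-empty")
        if self.start < 0 or self.end <= self.start:
            raise ValidationError(
                f"invalid gene body [{self.start}, {self.end}) for {self.gene}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"strand must be '+', '-' or '.', got {self.strand!r}")


#: Default column mapping: MAF-style headers -> record fields.
MAF_COLUMNS: Mapping[str, str] = {
    "sample_id": "Tumor_Sample_Barcode",
    "gene": "Hugo_Symbol",
    "chrom": "Chromosome",
    "pos": "Start_Position",
    "ref": "Reference_Allele",
    "alt": "Tumor_Seq_Allele2",
    "variant_class": "Variant_Classification",
    "sift_pred": "SIFT_Pred",
    "gerp": "GERP_RS",
    "pop_freq": "Pop_Freq",
}

_REQUIRED_FIELDS = ("sample_id", "gene", "chrom", "pos", "ref", "alt", "variant_class")
_OPTIONAL_FIELDS = ("sift_pred", "gerp", "pop_freq")


def _optional_float(value) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    token = str(value).strip()
    if token in ("", ".", "NA", "nan"):
        return None
    return float(token)


def read_mutation_table(
    path: str | Path, columns: Mapping[str, str] | None = None
) -> list[MutationRecord]:
    """Read a MAF-like TSV of annotated somatic calls.

    Parameters
    ----------
    path
        Tab-separated file with a header row.
    columns
        Field -> header-name mapping; defaults to MAF names (:data:`MAF_COLUMNS`).
        Sources differ in their headers, so the mapping is configurable.

    Returns
    -------
    Records in file order.  Malformed rows raise :class:`ValidationError`
    naming the 1-based file line.
    """
    colmap = dict(MAF_COLUMNS)
    if columns:
        colmap.update(columns)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, comment="#", skip_blank_lines=True)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty mutation table") from exc
    missing = [colmap[f] for f in _REQUIRED_FIELDS if colmap[f] not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")

    records: list[MutationRecord] = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        line_no = idx + 2  # header is line 1
        values = dict(zip(frame.columns, row))
        try:
            kwargs = {
                "sample_id": str(values[colmap["sample_id"]]).strip(),
                "gene": str(values[colmap["gene"]]).strip(),
                "chrom": str(values[colmap["chrom"]]).strip(),
                "pos": int(str(values[colmap["pos"]]).strip()),
                "ref": str(values[colmap["ref"]]).strip().upper(),
                "alt": str(values[colmap["alt"]]).strip().upper(),
                "variant_class": _coerce_variant_class(values[colmap["variant_class"]]),
            }
            if colmap["sift_pred"] in frame.columns:
                kwargs["sift_pred"] = _coerce_sift(values[colmap["sift_pred"]])
            if colmap["gerp"] in frame.columns:
                kwargs["gerp"] = _optional_float(values[colmap["gerp"]])
            if colmap["pop_freq"] in frame.columns:
                kwargs["pop_freq"] = _optional_float(values[colmap["pop_freq"]])
            records.append(MutationRecord(**kwargs))
        except (ValueError, KeyError) as exc:
            raise ValidationError(f"{path}, line {line_no}: {exc}") from exc
    return records


def write_mutation_table(
    records: Iterable[MutationRecord], path: str | Path, columns: Mapping[str, str] | None = None
) -> None:
    """Write records as a MAF-like TSV (inverse of :func:`read_mutation_table`)."""
    colmap = dict(MAF_COLUMNS)
    if columns:
        colmap.update(columns)
    field_order = _REQUIRED_FIELDS + _OPTIONAL_FIELDS
    rows = []
    for rec in records:
        row = {}
        for field in field_order:
            value = getattr(rec, field)
            if isinstance(value, Enum):
                value = value.value
            if value is None:
                value = ""
            row[colmap[field]] = value
        rows.append(row)
    frame = pd.DataFrame(rows, columns=[colmap[f] for f in field_order])
    frame.to_csv(path, sep="\t", index=False)


def _parse_bed_line(line: str, line_no: int, path) -> tuple[str, int, int, str | None, float | None, str | None]:
    fields = line.split("\t") if "\t" in line else line.split()
    if len(fields) < 3:
        raise FormatError(f"{path}, line {line_no}: BED needs >= 3 fields, got {len(fields)}")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ValidationError(f"{path}, line {line_no}: non-integer coordinates") from exc
    name = fields[3] if len(fields) > 3 and fields[3] != "." else None
    score = None
    if len(fields) > 4 and fields[4] not in (".", ""):
        score = float(fields[4])
    strand = fields[5] if len(fields) > 5 else None
    return chrom, start, end, name, score, strand


def _iter_bed_lines(path: str | Path):
    with open(path, "r", encoding="utf-8", newline=None) as handle:
        for line_no, raw in enumerate(handle, start=1):
            line = raw.rstrip("\r\n").rstrip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield line_no, line


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ file of 0-based half-open intervals.

    ``track``/``browser``/comment lines are skipped, which lets MACS2
    ``bdgdiff`` output be consumed as-is.
    """
    intervals: list[GenomicInterval] = []
    for line_no, line in _iter_bed_lines(path):
        chrom, start, end, name, score, _ = _parse_bed_line(line, line_no, path)
        try:
            intervals.append(GenomicInterval(chrom, start, end, score=score, name=name))
        except ValidationError as exc:
            raise ValidationError(f"{path}, line {line_no}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None:
                fields.append(repr(iv.score) if iv.score is not None else ".")
            handle.write("\t".join(fields) + "\n")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene bodies from a BED4/BED6 file (name column = gene id)."""
    genes: list[GeneModel] = []
    for line_no, line in _iter_bed_lines(path):
        chrom, start, end, name, _score, strand = _parse_bed_line(line, line_no, path)
        if name is None:
            raise FormatError(f"{path}, line {line_no}: gene model needs a name column")
        if strand not in ("+", "-"):
            strand = "."
        try:
            genes.append(GeneModel(gene=name, chrom=chrom, start=start, end=end, strand=strand))
        except ValidationError as exc:
            raise ValidationError(f"{path}, line {line_no}: {exc}") from exc
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for g in genes:
            handle.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene}\t0\t{g.strand}\n")


def _as_plain_rows(results: Sequence) -> list[dict]:
    rows = []
    for item in results:
        if dataclasses.is_dataclass(item) and not isinstance(item, type):
            row = dataclasses.asdict(item)
        elif isinstance(item, Mapping):
            row = dict(item)
        else:
            raise TypeError(f"cannot serialize result of type {type(item).__name__}")
        rows.append(
            {k: (v.value if isinstance(v, Enum) else v) for k, v in row.items()}
        )
    return rows


def write_results(results: Sequence, path: str | Path, format: str = "tsv") -> None:
    """Write per-gene/per-record results as TSV or JSON with a stable column order.

    Column order is the field order of the result dataclass (or insertion
    order of mappings), identical across rows.
    """
    rows = _as_plain_rows(results)
    if format == "tsv":
        if rows:
            columns = list(rows[0].keys())
            frame = pd.DataFrame(rows, columns=columns)
        else:
            frame = pd.DataFrame()
        frame.to_csv(path, sep="\t", index=False)
    elif format == "json":
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(rows, handle, indent=2)
            handle.write("\n")
    else:
        raise ValueError(f"unknown results format {format!r} (expected 'tsv' or 'json')")


def read_results_json(path: str | Path) -> list[dict]:
    with open(path, "r", encoding="utf-8") as handle:
        return json.load(handle)
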