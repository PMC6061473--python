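"""Readers and writers: variant tables, FASTA sequence sets, screen reports.

Variant tables are delimited text (CSV or TSV, sniffed) with header
``gene,position,ref,alt[,disease][,status]``; positions are rCRS m.-numbering.
Sequence sets are FASTA, optionally gapped (aligned); the human rCRS row is
recognised by a configurable identifier pattern.  Reports round-trip through
TSV (complex cells JSON-encoded) and JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reference_model import GeneRegion, MitoscreenError, genes_for_position

__all__ = [
    "VariantTableError",
    "LabellingError",
    "FormatError",
    "VariantRecord",
    "SequenceEntry",
    "SpeciesSequenceSet",
    "SpeciesRule",
    "ScreenRow",
    "ScreenReport",
    "load_variant_table",
    "load_sequence_set",
    "write_sequence_set",
    "write_report",
    "read_report",
    "TIERS",
]

TIERS = (
    "Neutral/polymorphic",
    "Possibly pathogenic",
    "Probably pathogenic",
    "Definitely pathogenic",
)

_BASES = frozenset("ACGT")

DEFAULT_REFERENCE_PATTERN = "NC_012920"


class VariantTableError(MitoscreenError):
    """One or more variant-table rows failed validation."""

    def __init__(self, row_errors: list[tuple[int, str]]):
        self.row_errors = row_errors
        lines = "; ".join(f"line {n}: {msg}" for n, msg in row_errors)
        super().__init__(f"{len(row_errors)} invalid variant row(s): {lines}")


class LabellingError(MitoscreenError):
    """A FASTA record's species label could not be resolved."""


class FormatError(MitoscreenError):
    """A sequence file violates the expected format."""


# ---------------------------------------------------------------------------
# Variant table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantRecord:
    """One disease-associated substitution at an rCRS position.

    ``ref``/``alt`` are heavy-strand alleles as in m.-notation (the coding
    strand for all complex I genes except ND6).
    """

    gene: str
    position: int
    ref: str
    alt: str
    disease: str = ""
    prior_status: Optional[str] = None

    @property
    def label(self) -> str:
        return f"m.{self.position}{self.ref}>{self.alt}"


def _validate_variant_row(
    row: dict, gene_map: Optional[Sequence[GeneRegion]]
) -> VariantRecord:
    gene = str(row["gene"]).strip()
    try:
        position = int(row["position"])
    except (TypeError, ValueError):
        raise MitoscreenError(f"position {row['position']!r} is not an integer")
    ref = str(row["ref"]).strip().upper()
    alt = str(row["alt"]).strip().upper()
    if ref not in _BASES:
        raise MitoscreenError(f"reference allele {ref!r} is not one of A,C,G,T")
    if alt not in _BASES:
        raise MitoscreenError(f"alternate allele {alt!r} is not one of A,C,G,T")
    if ref == alt:
        raise MitoscreenError(f"ref and alt are both {ref!r}")
    if position < 1:
        raise MitoscreenError(f"position {position} is not a valid rCRS coordinate")
    if gene_map is not None:
        hits = [g.name for g in genes_for_position(position, gene_map)]
        if gene not in hits:
            raise MitoscreenError(
                f"position {position} does not fall in gene {gene} "
                f"(maps to {hits or 'no gene'})"
            )
    disease = "" if pd.isna(row.get("disease", "")) else str(row.get("disease", ""))
    status = row.get("status", row.get("prior_status"))
    if status is not None and pd.isna(status):
        status = None
    return VariantRecord(gene, position, ref, alt, disease,
                         None if status is None else str(status))


def load_variant_table(
    path: str | Path,
    gene_map: Optional[Sequence[GeneRegion]] = None,
    strict: bool = True,
) -> list[VariantRecord] | tuple[list[VariantRecord], list[tuple[int, str]]]:
    """Load and validate a variant table.

    With ``strict=True`` (default) any invalid row raises
    :class:`VariantTableError` carrying every offending line number; with
    ``strict=False`` returns ``(records, row_errors)`` so callers can report
    rejects while proceeding.  Row order is preserved.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                     skip_blank_lines=True)
    required = {"gene", "position", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"variant table missing columns: {sorted(missing)}")
    records: list[VariantRecord] = []
    errors: list[tuple[int, str]] = []
    for i, row in enumerate(df.to_dict("records")):
        line_no = i + 2  # header is line 1
        try:
            records.append(_validate_variant_row(row, gene_map))
        except MitoscreenError as exc:
            errors.append((line_no, str(exc)))
    if errors and strict:
        raise VariantTableError(errors)
    if strict:
        return records
    return records, errors


# ---------------------------------------------------------------------------
# Sequence sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequenceEntry:
    sequence_id: str
    species_label: str
    residues: str


@dataclass
class SpeciesSequenceSet:
    """All sequences for one gene: non-human species plus an embedded rCRS row.

    ``aligned`` means the residue strings are rows of a multiple alignment
    (equal length, '-' gaps); otherwise they are plain gene sequences to be
    anchored to the reference by pairwise alignment.
    """

    gene: str
    entries: list[SequenceEntry]
    aligned: bool
    reference_row_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.aligned:
            lengths = {len(e.residues) for e in self.entries}
            if len(lengths) > 1:
                raise FormatError(
                    f"{self.gene}: aligned set has mixed row lengths {sorted(lengths)}"
                )
        if self.reference_row_id is not None and self.reference_row_id not in {
            e.sequence_id for e in self.entries
        }:
            raise FormatError(
                f"{self.gene}: reference_row_id {self.reference_row_id!r} "
                "names no entry"
            )
        for e in self.entries:
            if not e.species_label:
                raise LabellingError(f"{e.sequence_id}: empty species label")

    @property
    def reference_entry(self) -> Optional[SequenceEntry]:
        if self.reference_row_id is None:
            return None
        return next(e for e in self.entries
                    if e.sequence_id == self.reference_row_id)

    def non_reference_entries(self) -> list[SequenceEntry]:
        return [e for e in self.entries if e.sequence_id != self.reference_row_id]

    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.non_reference_entries():
            seen.setdefault(e.species_label, None)
        return list(seen)


@dataclass(frozen=True)
class SpeciesRule:
    """How to parse a species label from a FASTA header.

    Default: join the ``fields`` whitespace-separated tokens of the record
    description after the accession (token 0), i.e. a Linnaean binomial.
    ``fallback_to_id`` uses the record id when the description has no further
    tokens; disable it to make unresolvable headers a hard error.
    """

    delimiter: Optional[str] = None
    fields: tuple[int, int] = (1, 2)
    fallback_to_id: bool = True

    def species_of(self, record_id: str, description: str) -> str:
        tokens = description.split(self.delimiter)
        lo, hi = self.fields
        label = " ".join(tokens[lo : hi + 1]).strip()
        if label:
            return label
        if self.fallback_to_id and record_id:
            return record_id
        raise LabellingError(
            f"{record_id!r}: could not resolve a species label from "
            f"header {description!r}"
        )


def _normalise_residues(seq: str) -> str:
    return seq.upper().replace("U", "T")


def load_sequence_set(
    path: str | Path,
    gene: str,
    species_rule: SpeciesRule | Callable[[str, str], str] = SpeciesRule(),
    reference_pattern: str = DEFAULT_REFERENCE_PATTERN,
    aligned: Optional[bool] = None,
) -> SpeciesSequenceSet:
    """Read a per-gene FASTA into a :class:`SpeciesSequenceSet`.

    Residues are upper-cased with U→T.  The aligned flag, when not forced, is
    set automatically: all records equal length AND at least one gap character.
    The rCRS row is the first record whose header contains
    ``reference_pattern``.
    """
    resolve = (species_rule.species_of
               if isinstance(species_rule, SpeciesRule) else species_rule)
    entries: list[SequenceEntry] = []
    reference_row_id = None
    for rec in SeqIO.parse(str(path), "fasta"):
        species = resolve(rec.id, rec.description)
        entries.append(SequenceEntry(rec.id, species, _normalise_residues(str(rec.seq))))
        if reference_row_id is None and reference_pattern in rec.description:
            reference_row_id = rec.id
    if not entries:
        raise FormatError(f"{path}: no FASTA records")
    if aligned is None:
        lengths = {len(e.residues) for e in entries}
        has_gap = any("-" in e.residues for e in entries)
        aligned = len(lengths) == 1 and has_gap
    return SpeciesSequenceSet(gene, entries, aligned, reference_row_id)


def write_sequence_set(sset: SpeciesSequenceSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(e.residues), id=e.sequence_id,
                  description=f"{e.sequence_id} {e.species_label}")
        for e in sset.entries
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Screen reports
# ---------------------------------------------------------------------------

_ROW_COLUMNS = [
    "gene", "position", "ref", "alt", "disease",
    "human_ref_aa", "human_alt_aa", "synonymous",
    "n_carriers", "n_analysable", "n_missing",
    "species_carrier_fractions", "carrier_sequence_ids",
    "nucleotide_ci", "aa_ci",
    "resolutions", "masking_candidates",
    "total_score", "tier",
]
_JSON_CELLS = {"species_carrier_fractions", "carrier_sequence_ids",
               "resolutions", "masking_candidates"}


@dataclass
class ScreenRow:
    """Per-variant aggregate row of a screen report.

    ``species_carrier_fractions`` maps species label → fraction (0–1) of that
    species' analysable sequences carrying the alternate allele; conservation
    indices are percentages in [0, 100]; ``resolutions`` and
    ``masking_candidates`` are lists of plain dicts (JSON-serialisable).
    """

    gene: str
    position: int
    ref: str
    alt: str
    disease: str = ""
    human_ref_aa: str = ""
    human_alt_aa: str = ""
    synonymous: bool = False
    n_carriers: int = 0
    n_analysable: int = 0
    n_missing: int = 0
    species_carrier_fractions: dict = field(default_factory=dict)
    carrier_sequence_ids: list = field(default_factory=list)
    nucleotide_ci: Optional[float] = None
    aa_ci: Optional[float] = None
    resolutions: list = field(default_factory=list)
    masking_candidates: list = field(default_factory=list)
    total_score: Optional[float] = None
    tier: Optional[str] = None

    def validate(self) -> None:
        for name in ("nucleotide_ci", "aa_ci"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 100.0:
                raise MitoscreenError(f"{name}={v} outside [0, 100]")
        if self.n_carriers > self.n_analysable:
            raise MitoscreenError("carrier count exceeds analysable sequences")
        if self.tier is not None and self.tier not in TIERS:
            raise MitoscreenError(f"unknown tier {self.tier!r}")


@dataclass
class ScreenReport:
    rows: list[ScreenRow] = field(default_factory=list)

    def validate(self) -> None:
        for row in self.rows:
            row.validate()

    def to_records(self) -> list[dict]:
        return [
            {col: getattr(row, col) for col in _ROW_COLUMNS} for row in self.rows
        ]

    @classmethod
    def from_records(cls, records: list[dict]) -> "ScreenReport":
        return cls([ScreenRow(**{k: rec[k] for k in _ROW_COLUMNS})
                    for rec in records])


def write_report(report: ScreenReport, path: str | Path, format: str = "tsv") -> None:
    """Serialise a validated report; column order is fixed, numeric values are
    written with full precision so tsv and json agree exactly."""
    report.validate()
    path = Path(path)
    records = report.to_records()
    if format == "json":
        path.write_text(json.dumps({"rows": records}, sort_keys=True, indent=1)
                        + "\n")
    elif format == "tsv":
        lines = ["\t".join(_ROW_COLUMNS)]
        for rec in records:
            cells = []
            for col in _ROW_COLUMNS:
                v = rec[col]
                if col in _JSON_CELLS:
                    cells.append(json.dumps(v, sort_keys=True))
                elif v is None:
                    cells.append("")
                else:
                    cells.append(json.dumps(v))  # exact repr for numbers/bools/str
            lines.append("\t".join(cells))
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path, format: Optional[str] = None) -> ScreenReport:
    path = Path(path)
    if format is None:
        format = "json" if path.suffix == ".json" else "tsv"
    if format == "json":
        return ScreenReport.from_records(json.loads(path.read_text())["rows"])
    lines = path.read_text().splitlines()
    header = lines[0].split("\t")
    records = []
    for line in lines[1:]:
        cells = line.split("\t")
        rec = {}
        for col, cell in zip(header, cells):
            rec[col] = None if cell == "" else json.loads(cell)
        records.append(rec)
    return ScreenReport.from_records(records)
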