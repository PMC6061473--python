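"""End-to-end screen: load → align/map → call → resolve → mask → score → report.

A run is fully described by a :class:`RunConfig`; given fixed inputs and
config the report is byte-identical between runs (timestamps are isolated in
the run manifest).  Stage failures surface with the variant and file context;
partial reports are never written silently.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .alignment import ScoringScheme, build_homology_map
from .codon_context import resolve_codon, screen_masking_candidates
from .cross_species_screen import (
    call_variant,
    conservation_summary,
    filter_synonymous,
)
from .pathogenicity_rubric import (
    EvidenceBundle,
    default_rubric,
    load_rubric,
    score_variant,
    validate_rubric,
)
from .reference_model import (
    DATA_DIR,
    MitoscreenError,
    VERTEBRATE_MITO_CODE,
    default_gene_map,
    human_aa_change,
    load_gene_map,
)
from .sequence_io import (
    ScreenReport,
    ScreenRow,
    SpeciesRule,
    load_sequence_set,
    load_variant_table,
    write_report,
)

logger = logging.getLogger("mitoscreen")

__all__ = ["RunConfig", "StageError", "run_screen", "screen_variant_row",
           "load_evidence_table", "DEFAULT_REFERENCE_FASTA"]

DEFAULT_REFERENCE_FASTA = DATA_DIR / "rcrs_like_genes.synthetic.fasta"

_FLAG_KEYS = ("independent_reports", "heteroplasmy", "segregation", "biochemistry")
_PREDICTOR_KEYS = ("polyphen2", "mutpred")


class StageError(MitoscreenError):
    """A pipeline stage failed; carries the variant/file context."""


@dataclass
class RunConfig:
    """Everything needed to reproduce a screen run."""

    variants: Path
    sequences: dict[str, Path]  # gene symbol -> FASTA path
    gene_map: Optional[Path] = None  # default: packaged rCRS annotation
    reference: Optional[Path] = None  # default: packaged synthetic rCRS-like genes
    rubric: Optional[Path] = None  # default: packaged reconstruction
    evidence: Optional[Path] = None  # optional external-evidence table
    out_dir: Optional[Path] = None
    aligned: Optional[bool] = None  # force the aligned flag; None = auto
    masking_scope: str = "gene_wide"
    min_carrier_overlap: float = 1.0
    max_non_carrier_presence: float = 0.0
    aggregate: str = "sequence"  # "sequence" | "species"
    match: int = 1
    mismatch: int = -1
    gap: int = -2
    reference_pattern: str = "NC_012920"
    seed: Optional[int] = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["variants"] = Path(raw["variants"])
        raw["sequences"] = {g: Path(p) for g, p in raw["sequences"].items()}
        for key in ("gene_map", "reference", "rubric", "evidence", "out_dir"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        return cls(**raw)

    def validate(self) -> list[str]:
        problems = []
        for label, path in [("variants", self.variants),
                            ("gene_map", self.gene_map),
                            ("reference", self.reference),
                            ("rubric", self.rubric),
                            ("evidence", self.evidence),
                            *[(f"sequences[{g}]", p)
                              for g, p in self.sequences.items()]]:
            if path is not None and not Path(path).exists():
                problems.append(f"{label}: path {path} does not exist")
        if self.masking_scope not in ("gene_wide", "within_codon"):
            problems.append(f"unknown masking_scope {self.masking_scope!r}")
        if self.aggregate not in ("sequence", "species"):
            problems.append(f"unknown aggregate level {self.aggregate!r}")
        return problems

    def to_manifest_dict(self) -> dict:
        d = {k: (str(v) if isinstance(v, Path) else v)
             for k, v in self.__dict__.items() if k != "sequences"}
        d["sequences"] = {g: str(p) for g, p in self.sequences.items()}
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _load_reference_genes(path: Path) -> dict[str, str]:
    from Bio import SeqIO

    genes = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        genes[rec.id] = str(rec.seq).upper().replace("U", "T")
    return genes


def load_evidence_table(path: Path) -> dict[tuple, dict]:
    """External evidence keyed by (gene, position, ref, alt).

    Recognised columns: external_frequency, polyphen2, mutpred, and the four
    disease-report flags; all optional per row.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    out: dict[tuple, dict] = {}
    for row in df.to_dict("records"):
        key = (str(row["gene"]), int(row["position"]),
               str(row["ref"]).upper(), str(row["alt"]).upper())
        entry: dict = {"predictor_scores": {}, "disease_report_flags": {}}
        if not pd.isna(row.get("external_frequency", float("nan"))):
            entry["external_frequency"] = float(row["external_frequency"])
        for k in _PREDICTOR_KEYS:
            if k in row and not pd.isna(row[k]):
                entry["predictor_scores"][k] = float(row[k])
        for k in _FLAG_KEYS:
            if k in row and not pd.isna(row[k]):
                entry["disease_report_flags"][k] = bool(row[k])
        out[key] = entry
    return out


def screen_variant_row(
    sset,
    hmap,
    variant,
    gene,
    ref_gene_seq: str,
    rubric,
    external_evidence: Optional[dict] = None,
    masking_scope: str = "gene_wide",
    min_carrier_overlap: float = 1.0,
    max_non_carrier_presence: float = 0.0,
    aggregate: str = "sequence",
) -> ScreenRow:
    """Screen one (non-synonymous) variant against one sequence set."""
    ref_aa, alt_aa, _ = human_aa_change(variant, ref_gene_seq, gene)
    calls = call_variant(sset, hmap, variant)
    cons = conservation_summary(sset, hmap, variant, gene, ref_gene_seq)
    carrier_species = sorted(
        sp for sp, f in calls.species_fractions.items() if f > 0
    )
    resolutions = [
        resolve_codon(sset, hmap, variant, gene, ref_gene_seq,
                      species=sp).to_record()
        for sp in carrier_species
    ]
    candidates = screen_masking_candidates(
        sset, hmap, variant, gene, ref_gene_seq, masking_scope, calls,
        min_carrier_overlap, max_non_carrier_presence,
    )
    ext = external_evidence or {}
    bundle = EvidenceBundle(
        nucleotide_ci=cons.nucleotide_ci,
        aa_ci=cons.aa_ci,
        external_frequency=ext.get("external_frequency"),
        predictor_scores=ext.get("predictor_scores", {}),
        disease_report_flags=ext.get("disease_report_flags", {}),
    )
    score = score_variant(bundle, rubric)
    fractions = calls.species_fractions
    if aggregate == "species":
        fractions = {sp: (1.0 if f > 0 else 0.0) for sp, f in fractions.items()}
    return ScreenRow(
        gene=variant.gene, position=variant.position,
        ref=variant.ref, alt=variant.alt, disease=variant.disease,
        human_ref_aa=ref_aa, human_alt_aa=alt_aa, synonymous=False,
        n_carriers=calls.n_carriers,
        n_analysable=calls.n_analysable,
        n_missing=calls.n_missing,
        species_carrier_fractions=dict(sorted(fractions.items())),
        carrier_sequence_ids=sorted(calls.carrier_sequence_ids),
        nucleotide_ci=cons.nucleotide_ci,
        aa_ci=cons.aa_ci,
        resolutions=resolutions,
        masking_candidates=[c.to_record() for c in candidates],
        total_score=score.total,
        tier=score.tier,
    )


def run_screen(cfg: RunConfig) -> ScreenReport:
    """Run the full cross-species screen described by ``cfg``.

    Returns the report; when ``cfg.out_dir`` is set, also writes
    ``report.tsv``, ``report.json`` and ``manifest.json`` there.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    problems = cfg.validate()
    if problems:
        raise StageError("invalid run config: " + "; ".join(problems))

    gene_map = (load_gene_map(cfg.gene_map) if cfg.gene_map
                else default_gene_map())
    by_name = {g.name: g for g in gene_map}
    ref_path = Path(cfg.reference) if cfg.reference else DEFAULT_REFERENCE_FASTA
    ref_genes = _load_reference_genes(ref_path)
    rubric = load_rubric(cfg.rubric) if cfg.rubric else default_rubric()
    rubric_report = validate_rubric(rubric)
    if not rubric_report.valid:
        raise StageError("invalid rubric: " + "; ".join(rubric_report.violations))
    evidence_table = (load_evidence_table(cfg.evidence)
                      if cfg.evidence else {})
    scheme = ScoringScheme(cfg.match, cfg.mismatch, cfg.gap)

    variants = load_variant_table(cfg.variants, gene_map)
    retained, excluded = filter_synonymous(
        variants, ref_genes, gene_map, VERTEBRATE_MITO_CODE
    )
    logger.info("loaded %d variants (%d synonymous, excluded)",
                len(variants), len(excluded))

    sets = {}
    maps = {}
    skipped = []
    rows: list[ScreenRow] = []
    for v in sorted(retained, key=lambda v: (v.gene, v.position)):
        gene = by_name[v.gene]
        if v.gene not in cfg.sequences:
            skipped.append(v.label)
            logger.warning("%s: no sequence set supplied for %s, skipping",
                           v.label, v.gene)
            continue
        try:
            if v.gene not in sets:
                sets[v.gene] = load_sequence_set(
                    cfg.sequences[v.gene], v.gene, SpeciesRule(),
                    cfg.reference_pattern, cfg.aligned,
                )
                maps[v.gene] = build_homology_map(
                    sets[v.gene], gene, ref_genes[v.gene], scheme
                )
            rows.append(screen_variant_row(
                sets[v.gene], maps[v.gene], v, gene, ref_genes[v.gene],
                rubric,
                evidence_table.get((v.gene, v.position, v.ref, v.alt)),
                cfg.masking_scope, cfg.min_carrier_overlap,
                cfg.max_non_carrier_presence, cfg.aggregate,
            ))
        except MitoscreenError as exc:
            raise StageError(
                f"{v.label} ({v.gene}, file {cfg.sequences.get(v.gene)}): {exc}"
            ) from exc

    report = ScreenReport(rows)
    report.validate()

    if cfg.out_dir is not None:
        out_dir = Path(cfg.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_report(report, out_dir / "report.tsv", "tsv")
        write_report(report, out_dir / "report.json", "json")
        manifest = {
            "package": "mitoscreen",
            "version": __version__,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
            "config": cfg.to_manifest_dict(),
            "input_sha256": {
                "variants": _sha256(cfg.variants),
                "reference": _sha256(ref_path),
                **{f"sequences[{g}]": _sha256(p)
                   for g, p in cfg.sequences.items()},
            },
            "n_variants": len(variants),
            "synonymous_excluded": sorted(v.label for v in excluded),
            "skipped_no_sequences": skipped,
        }
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True) + "\n"
        )
    return report
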