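"""Somatic variant processing: chunked MAF/VCF parsing, coding filter,
four-tier actionability classification, and patient routing.

The tier system harmonizes OncoKB, CIViC and COSMIC evidence into one
ordered hierarchy:

* Tier 1 (known actionable): OncoKB Level 1/2/R1 or CIViC Level A evidence
  with a cancer type matching the patient's histology or one of its
  ontology ancestors.
* Tier 2 (likely actionable): OncoKB Level 3A/3B, CIViC Level B, or a
  COSMIC hotspot (recurrence >= 5).
* Tier 3 (uncertain significance): predicted deleterious in silico
  (SIFT < 0.05 or PolyPhen-2 > 0.85) without actionable clinical evidence.
* Tier 4 (likely passenger): everything else.

Rules fire in strict Tier 1 -> 4 order, so adding evidence can only keep a
variant's tier equal or make it stronger.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Iterator
from enum import IntEnum
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from . import config

logger = logging.getLogger(__name__)

__all__ = [
    "SomaticVariant",
    "EvidenceTier",
    "TierLevel",
    "ClinicalEvidenceRecord",
    "PatientProfile",
    "RoutingDecision",
    "MafFormatError",
    "parse_maf",
    "parse_vcf",
    "filter_coding",
    "classify_tier",
    "route_patient",
    "subtype_gene_panel",
]


class MafFormatError(ValueError):
    """Raised when a MAF header does not carry the required columns."""


class SomaticVariant(BaseModel):
    """One coding somatic variant in MAF convention (1-based inclusive)."""

    gene_symbol: str
    chromosome: str
    position: int = Field(ge=1)
    ref_allele: str
    alt_allele: str
    variant_classification: str
    protein_change: Optional[str] = None
    vaf: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    sift_score: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    polyphen_score: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    cosmic_recurrence: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _ref_ne_alt(self) -> "SomaticVariant":
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref_allele must differ from alt_allele")
        return self


class TierLevel(IntEnum):
    KNOWN_ACTIONABLE = 1
    LIKELY_ACTIONABLE = 2
    UNCERTAIN_SIGNIFICANCE = 3
    LIKELY_PASSENGER = 4


class EvidenceTier(BaseModel):
    level: TierLevel
    rationale: str = Field(min_length=1)


class ClinicalEvidenceRecord(BaseModel):
    """A curated evidence snapshot row for one gene (optionally one variant)."""

    gene_symbol: str
    variant_spec: str = "any"  # HGVS-p string or "any"
    source: Literal["OncoKB_snapshot", "CIViC_snapshot"]
    source_level: str
    cancer_type: str


class PatientProfile(BaseModel):
    patient_id: str
    mode: Literal["A", "B"]
    histology: str
    stage: Optional[str] = None
    metastatic_sites: list[str] = Field(default_factory=list)
    prior_treatments: list[tuple[str, str]] = Field(default_factory=list)
    biomarkers: list[str] = Field(default_factory=list)
    demographics: dict[str, str] = Field(default_factory=dict)
    geography: str = "US"

    @field_validator("prior_treatments")
    @classmethod
    def _known_outcomes(cls, v: list[tuple[str, str]]) -> list[tuple[str, str]]:
        allowed = {"response", "partial response", "stable", "progression", "failed"}
        for _, outcome in v:
            if outcome not in allowed:
                raise ValueError(f"unknown prior-treatment outcome {outcome!r}")
        return v


class RoutingDecision(BaseModel):
    mode: Literal["genomic_mode", "clinical_only_mode"]
    fusion_assay_recommended: bool = False
    modules_1_2_bypassed: bool = False
    gene_panel: list[str] = Field(default_factory=list)
    panel_provenance: Optional[str] = None


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_REQUIRED_MAF_COLUMNS = (
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
)

# Optional columns accepted under either VEP-annotated or plain MAF dialects.
_OPTIONAL_MAF_COLUMNS = {
    "protein_change": ("HGVSp_Short", "Protein_Change"),
    "sift": ("SIFT_score", "SIFT"),
    "polyphen": ("PolyPhen_score", "PolyPhen"),
    "cosmic": ("COSMIC_count", "COSMIC"),
}


def _first_present(columns: Iterable[str], names: tuple[str, ...]) -> Optional[str]:
    cols = set(columns)
    for name in names:
        if name in cols:
            return name
    return None


def _to_str(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    return s or None


def _to_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        return None


class MalformedRowCounter:
    """Skip-and-count bookkeeping for rows that violate the variant model."""

    def __init__(self) -> None:
        self.count = 0

    def record(self, row_index: int, reason: str) -> None:
        self.count += 1
        logger.warning("malformed MAF row %d skipped: %s", row_index, reason)


def parse_maf(
    path: str | Path,
    chunk_rows: int = config.MAF_CHUNK_ROWS,
    malformed: Optional[MalformedRowCounter] = None,
    _chunk_counter: Optional[list[int]] = None,
) -> Iterator[SomaticVariant]:
    """Stream variants from a (possibly multi-gigabyte) MAF file.

    Reads in ``chunk_rows`` segments so peak memory is bounded by one chunk.
    Malformed rows are counted on ``malformed`` and skipped, never fatal.
    ``_chunk_counter`` is a test seam: each chunk read appends one element.
    """
    if chunk_rows < 1:
        raise ValueError("chunk_rows must be a positive integer")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    reader = pd.read_csv(
        path, sep="\t", comment="#", chunksize=chunk_rows, dtype=str,
        keep_default_na=True, low_memory=True,
    )
    malformed = malformed if malformed is not None else MalformedRowCounter()
    first = True
    row_index = 0
    for chunk in reader:
        if first:
            missing = [c for c in _REQUIRED_MAF_COLUMNS if c not in chunk.columns]
            if missing:
                raise MafFormatError(
                    f"unrecognized MAF header: missing columns {missing}"
                )
            col_protein = _first_present(chunk.columns, _OPTIONAL_MAF_COLUMNS["protein_change"])
            col_sift = _first_present(chunk.columns, _OPTIONAL_MAF_COLUMNS["sift"])
            col_poly = _first_present(chunk.columns, _OPTIONAL_MAF_COLUMNS["polyphen"])
            col_cosmic = _first_present(chunk.columns, _OPTIONAL_MAF_COLUMNS["cosmic"])
            col_vaf = _first_present(chunk.columns, ("i_TumorVAF", "VAF", "tumor_vaf"))
            has_counts = {"t_alt_count", "t_depth"} <= set(chunk.columns)
            first = False
        if _chunk_counter is not None:
            _chunk_counter.append(len(chunk))
        for row in chunk.itertuples(index=False):
            row_index += 1
            record = dict(zip(chunk.columns, row))
            vaf = _to_float(record.get(col_vaf)) if col_vaf else None
            if vaf is None and has_counts:
                alt = _to_float(record.get("t_alt_count"))
                depth = _to_float(record.get("t_depth"))
                if alt is not None and depth:
                    vaf = alt / depth
            try:
                yield SomaticVariant(
                    gene_symbol=record["Hugo_Symbol"],
                    chromosome=str(record["Chromosome"]),
                    position=int(record["Start_Position"]),
                    ref_allele=record["Reference_Allele"],
                    alt_allele=record["Tumor_Seq_Allele2"],
                    variant_classification=record["Variant_Classification"],
                    protein_change=(_to_str(record.get(col_protein)) if col_protein else None),
                    vaf=vaf,
                    sift_score=_to_float(record.get(col_sift)) if col_sift else None,
                    polyphen_score=_to_float(record.get(col_poly)) if col_poly else None,
                    cosmic_recurrence=int(_to_float(record.get(col_cosmic)) or 0) if col_cosmic else 0,
                )
            except (ValueError, TypeError, KeyError) as exc:
                malformed.record(row_index, str(exc))


def parse_vcf(path: str | Path) -> Iterator[SomaticVariant]:
    """Read a VCF 4.x file into the MAF-convention variant model.

    Coordinates stay 1-based (VCF POS is already 1-based). Gene symbol and
    variant classification are taken from the ``GENE`` / ``VC`` INFO keys
    when present; VAF from ``AF``.
    """
    from cyvcf2 import VCF  # deferred: only Mode A VCF inputs need it

    for rec in VCF(str(path)):
        alt = rec.ALT[0] if rec.ALT else None
        if alt is None or alt == rec.REF:
            continue
        info = dict(rec.INFO)
        af = info.get("AF")
        if isinstance(af, tuple):
            af = af[0]
        yield SomaticVariant(
            gene_symbol=str(info.get("GENE", "")) or "unknown",
            chromosome=rec.CHROM,
            position=rec.POS,
            ref_allele=rec.REF,
            alt_allele=alt,
            variant_classification=str(info.get("VC", "Missense_Mutation")),
            protein_change=info.get("HGVSP"),
            vaf=float(af) if af is not None else None,
        )


# ---------------------------------------------------------------------------
# Filtering and tiering
# ---------------------------------------------------------------------------

def filter_coding(
    variants: Iterable[SomaticVariant],
    coding_set: frozenset[str] = config.CODING_CLASSIFICATIONS,
) -> list[SomaticVariant]:
    """Retain coding variants in input order; unknown labels are dropped
    conservatively (logged, never raised)."""
    retained: list[SomaticVariant] = []
    for v in variants:
        if v.variant_classification in coding_set:
            retained.append(v)
        elif v.variant_classification not in _KNOWN_NONCODING:
            logger.info(
                "unknown variant classification %r on %s: dropped (conservative)",
                v.variant_classification, v.gene_symbol,
            )
    return retained


_KNOWN_NONCODING = frozenset({
    "Silent", "Intron", "3'UTR", "5'UTR", "3'Flank", "5'Flank", "IGR", "RNA",
})


def _cancer_type_matches(record_type: str, patient_type: str, ancestors: Iterable[str]) -> bool:
    rt = record_type.strip().casefold()
    if rt == patient_type.strip().casefold():
        return True
    return any(rt == a.strip().casefold() for a in ancestors)


def _variant_matches(record: ClinicalEvidenceRecord, v: SomaticVariant) -> bool:
    if record.gene_symbol != v.gene_symbol:
        return False
    if record.variant_spec == "any":
        return True
    return v.protein_change is not None and record.variant_spec == v.protein_change


def classify_tier(
    v: SomaticVariant,
    evidence: list[ClinicalEvidenceRecord],
    patient_cancer_type: str,
    cancer_type_ancestors: Iterable[str] = (),
) -> EvidenceTier:
    """Assign the strongest tier whose rule fires; total on valid inputs.

    ``cancer_type_ancestors`` is the patient histology's ontology ancestor
    chain; a Tier 1 record's cancer type matches if it equals the histology
    or any ancestor.
    """
    matching = [r for r in evidence if _variant_matches(r, v)]

    for r in matching:  # Tier 1: strong clinical evidence + cancer-type match
        level_ok = (
            (r.source == "OncoKB_snapshot" and r.source_level in config.ONCOKB_TIER1_LEVELS)
            or (r.source == "CIViC_snapshot" and r.source_level in config.CIVIC_TIER1_LEVELS)
        )
        if level_ok and _cancer_type_matches(r.cancer_type, patient_cancer_type, cancer_type_ancestors):
            return EvidenceTier(
                level=TierLevel.KNOWN_ACTIONABLE,
                rationale=f"{r.source} {r.source_level} with matching cancer type ({r.cancer_type})",
            )

    for r in matching:  # Tier 2: emerging clinical evidence (no type match required)
        if (r.source == "OncoKB_snapshot" and r.source_level in config.ONCOKB_TIER2_LEVELS) or (
            r.source == "CIViC_snapshot" and r.source_level in config.CIVIC_TIER2_LEVELS
        ):
            return EvidenceTier(
                level=TierLevel.LIKELY_ACTIONABLE,
                rationale=f"{r.source} {r.source_level}",
            )
    if v.cosmic_recurrence >= config.COSMIC_HOTSPOT_MIN:
        return EvidenceTier(
            level=TierLevel.LIKELY_ACTIONABLE,
            rationale=f"COSMIC hotspot (recurrence {v.cosmic_recurrence} >= {config.COSMIC_HOTSPOT_MIN})",
        )

    # Tier 3: predicted deleterious without actionable clinical evidence.
    # Missing scores are treated as non-deleterious (rule cannot fire).
    if (v.sift_score is not None and v.sift_score < config.SIFT_DELETERIOUS_MAX) or (
        v.polyphen_score is not None and v.polyphen_score > config.POLYPHEN_DELETERIOUS_MIN
    ):
        return EvidenceTier(
            level=TierLevel.UNCERTAIN_SIGNIFICANCE,
            rationale=f"predicted deleterious (SIFT={v.sift_score}, PolyPhen={v.polyphen_score})",
        )

    return EvidenceTier(
        level=TierLevel.LIKELY_PASSENGER,
        rationale="no actionable evidence and benign/tolerated predictions",
    )


# ---------------------------------------------------------------------------
# Routing
# ---------------------------------------------------------------------------

def subtype_gene_panel(
    histology: str,
    ancestors: Iterable[str] = (),
    panels: dict[str, tuple[str, ...]] = config.SUBTYPE_GENE_PANELS,
    default_panel: tuple[str, ...] = config.DEFAULT_GENE_PANEL,
) -> tuple[list[str], str]:
    """Curated gene panel for a histological subtype.

    Falls back to the nearest ontology ancestor's panel, then the default
    pan-sarcoma panel. Returns ``(panel, provenance)``.
    """
    if not panels and not default_panel:
        raise ValueError("no gene panels configured")
    lookup = {k.casefold(): v for k, v in panels.items()}
    key = histology.strip().casefold()
    if key in lookup:
        return list(lookup[key]), histology
    for ancestor in ancestors:
        if ancestor.strip().casefold() in lookup:
            return list(lookup[ancestor.strip().casefold()]), f"ancestor:{ancestor}"
    return list(default_panel), "default"


def route_patient(
    profile: PatientProfile,
    coding_variants: list[SomaticVariant],
    histology_ancestors: Iterable[str] = (),
) -> RoutingDecision:
    """Route to genomic mode or clinical-only mode (totality: exactly one
    decision per profile).

    Clinical-only fires for Mode B profiles and for Mode A patients with
    zero retained coding variants; the latter also get a fusion-detection
    assay recommendation, since gene fusions are invisible to a point-
    mutation MAF.
    """
    if profile.mode == "A" and coding_variants:
        return RoutingDecision(mode="genomic_mode")
    panel, provenance = subtype_gene_panel(profile.histology, histology_ancestors)
    return RoutingDecision(
        mode="clinical_only_mode",
        fusion_assay_recommended=(profile.mode == "A"),
        modules_1_2_bypassed=True,
        gene_panel=panel,
        panel_provenance=provenance,
    )
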