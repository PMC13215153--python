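"""Neoantigen candidate screening with dual HLA resolution.

Mode A uses the patient's own HLA-A/B/C class I alleles; Mode B (or a
missing typing) substitutes a seven-allele high-frequency supertype panel
and sets a mandatory warning flag that propagates to every candidate.

Binding prediction goes through a pluggable predictor contract so that
NetMHCpan-class or MHCflurry-class backends can be wired in; the bundled
deterministic mock predictor lets the whole screen run offline.

Candidates pass the screen iff:
  mutant IC50 < 500 nM  AND  DAI > 1.0  AND  VAF >= 0.05
where DAI (differential agretopicity index) = wildtype IC50 / mutant IC50,
so DAI > 1 means the mutant peptide binds more strongly than its wildtype
counterpart.
"""

from __future__ import annotations

import hashlib
import logging
import re
from typing import Iterable, Optional, Protocol

from pydantic import BaseModel, Field, model_validator

from . import config
from .variant_tiering import PatientProfile, SomaticVariant

logger = logging.getLogger(__name__)

__all__ = [
    "HlaContext",
    "PeptideCandidate",
    "BindingPredictor",
    "MockBindingPredictor",
    "resolve_hla",
    "compute_dai",
    "filter_candidates",
    "predict_binding",
    "enumerate_peptides",
    "write_candidate_fasta",
    "write_candidate_report",
]

_ALLELE_RE = re.compile(r"^(HLA-)?[ABC]\*\d{2}:\d{2,3}$")


class HlaContext(BaseModel):
    alleles: list[str] = Field(min_length=1)
    resolution: str  # "personalized" | "supertype_panel"
    warning_flag: bool

    @model_validator(mode="after")
    def _panel_shape(self) -> "HlaContext":
        if self.resolution == "supertype_panel":
            assert tuple(self.alleles) == config.SUPERTYPE_PANEL and self.warning_flag
        elif self.resolution == "personalized":
            assert not self.warning_flag
        return self


class PeptideCandidate(BaseModel):
    peptide: str = Field(min_length=8, max_length=11)
    allele: str
    mutant_affinity: float = Field(gt=0)   # IC50 nM
    wildtype_affinity: float = Field(gt=0)  # IC50 nM
    dai: float = Field(gt=0)
    vaf: float = Field(ge=0.0, le=1.0)
    source_variant: Optional[SomaticVariant] = None
    warning_flag: bool = False


class BindingPredictor(Protocol):
    """Predictor contract: (peptide, allele) -> IC50 in nM.

    Real backends (NetMHCpan-class, MHCflurry-class) implement this same
    call signature; failures for a single pair may raise and the pair is
    skipped.
    """

    def ic50(self, peptide: str, allele: str) -> float: ...


class MockBindingPredictor:
    """Deterministic stand-in predictor.

    IC50 is derived from a stable SHA-256 hash of ``peptide|allele`` scaled
    into [10, 5000] nM, so runs are bit-reproducible with no model download.
    """

    LOW_NM = 10.0
    HIGH_NM = 5000.0

    def ic50(self, peptide: str, allele: str) -> float:
        digest = hashlib.sha256(f"{peptide}|{allele}".encode()).hexdigest()
        frac = int(digest[:12], 16) / float(16**12)
        return self.LOW_NM + frac * (self.HIGH_NM - self.LOW_NM)


def resolve_hla(profile: PatientProfile, typing: Optional[list[str]] = None) -> HlaContext:
    """Personalized context when typing is supplied in Mode A; otherwise the
    seven-allele supertype panel with the mandatory warning flag."""
    if typing and profile.mode == "A":
        for allele in typing:
            if not _ALLELE_RE.match(allele):
                raise ValueError(f"malformed HLA class I allele name: {allele!r}")
        return HlaContext(alleles=list(typing), resolution="personalized", warning_flag=False)
    return HlaContext(
        alleles=list(config.SUPERTYPE_PANEL),
        resolution="supertype_panel",
        warning_flag=True,
    )


def compute_dai(mutant_affinity: float, wildtype_affinity: float) -> float:
    """DAI = wildtype IC50 / mutant IC50 (plain ratio; >1 favors mutant)."""
    if mutant_affinity <= 0 or wildtype_affinity <= 0:
        raise ValueError("binding affinities must be positive IC50 values (nM)")
    return wildtype_affinity / mutant_affinity


def filter_candidates(
    cands: Iterable[PeptideCandidate],
    affinity_max: float = config.AFFINITY_MAX_NM,
    dai_min: float = config.DAI_MIN,
    vaf_min: float = config.VAF_MIN,
) -> list[PeptideCandidate]:
    """Order-preserving threshold filter.

    Boundary sides follow the screen definition exactly: affinity strictly
    below 500 nM, DAI strictly above 1.0, VAF at or above 0.05.
    """
    return [
        c for c in cands
        if c.mutant_affinity < affinity_max and c.dai > dai_min and c.vaf >= vaf_min
    ]


def enumerate_peptides(
    mutant_seq: str,
    wildtype_seq: str,
    mutation_pos: int,
    lengths: tuple[int, ...] = config.PEPTIDE_LENGTHS,
) -> list[tuple[str, str]]:
    """Tile 8-11-mer windows across the substituted residue.

    ``mutation_pos`` is 0-based into ``mutant_seq``. The wildtype peptide is
    the same window on ``wildtype_seq`` (single-substitution reversion);
    indels have no wildtype counterpart and are excluded upstream.
    Returns (mutant_peptide, wildtype_peptide) pairs, deduplicated in order.
    """
    if len(mutant_seq) != len(wildtype_seq):
        raise ValueError("enumerate_peptides requires substitution (equal-length) sequences")
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for k in lengths:
        for start in range(max(0, mutation_pos - k + 1), min(mutation_pos + 1, len(mutant_seq) - k + 1)):
            pair = (mutant_seq[start:start + k], wildtype_seq[start:start + k])
            if pair[0] != pair[1] and pair not in seen:
                seen.add(pair)
                pairs.append(pair)
    return pairs


def predict_binding(
    peptides: list[tuple[str, str]],
    context: HlaContext,
    predictor: BindingPredictor,
    source_variant: Optional[SomaticVariant] = None,
    vaf: float = 0.0,
) -> list[PeptideCandidate]:
    """One candidate per (mutant peptide, allele) pair; predictor failures
    skip the pair and are logged, never fatal."""
    out: list[PeptideCandidate] = []
    for mutant, wildtype in peptides:
        for allele in context.alleles:
            try:
                mut_aff = predictor.ic50(mutant, allele)
                wt_aff = predictor.ic50(wildtype, allele)
            except Exception as exc:  # contract: per-pair failure is non-fatal
                logger.warning("predictor failed on (%s, %s): %s", mutant, allele, exc)
                continue
            out.append(PeptideCandidate(
                peptide=mutant,
                allele=allele,
                mutant_affinity=mut_aff,
                wildtype_affinity=wt_aff,
                dai=compute_dai(mut_aff, wt_aff),
                vaf=vaf,
                source_variant=source_variant,
                warning_flag=context.warning_flag,
            ))
    return out


def write_candidate_fasta(cands: Iterable[PeptideCandidate], path) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(cands):
            fh.write(f">cand{i}|{c.allele}|dai={c.dai:.3f}\n{c.peptide}\n")


def write_candidate_report(cands: Iterable[PeptideCandidate], path) -> None:
    """Tab-separated report with all filter columns and pass/fail flags."""
    header = "peptide\tallele\tmutant_ic50_nm\twildtype_ic50_nm\tdai\tvaf\tpass_affinity\tpass_dai\tpass_vaf\tretained\twarning_flag\n"
    with open(path, "w") as fh:
        fh.write(header)
        for c in cands:
            pa = c.mutant_affinity < config.AFFINITY_MAX_NM
            pd_ = c.dai > config.DAI_MIN
            pv = c.vaf >= config.VAF_MIN
            fh.write(
                f"{c.peptide}\t{c.allele}\t{c.mutant_affinity:.2f}\t{c.wildtype_affinity:.2f}"
                f"\t{c.dai:.4f}\t{c.vaf:.4f}\t{pa}\t{pd_}\t{pv}\t{pa and pd_ and pv}\t{c.warning_flag}\n"
            )
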