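"""Ontology-expanded clinical-trial matching and relevance ranking.

Direct registry queries for a rare subtype return few or zero trials
because most trials recruit under broader labels. Each subtype query is
therefore expanded through a four-level cancer-type hierarchy
(direct -> parent histology -> category -> basket/tumor-agnostic), e.g.
myxofibrosarcoma -> soft tissue sarcoma -> sarcoma -> solid tumor, which
surfaces basket trials invisible to direct keyword matching.

Ranking uses a four-component relevance score:
    total = 0.35*genomic + 0.30*phase + 0.20*histology + 0.15*geography
The functional form of each component scorer is a package default and is
config-replaceable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Callable, Iterable, Optional, Protocol

from pydantic import BaseModel, Field

from . import config
from .variant_tiering import PatientProfile

logger = logging.getLogger(__name__)

__all__ = [
    "OntologyHierarchy",
    "TrialRecord",
    "RelevanceScore",
    "TrialRegistry",
    "SnapshotRegistry",
    "expand_query",
    "fetch_trials",
    "score_relevance",
    "rank_trials",
]


class OntologyHierarchy(BaseModel):
    """Subtype -> ordered four-level chain ending in "solid tumor"."""

    nodes: dict[str, tuple[str, str, str, str]]
    default_fallback: tuple[str, str, str] = ("Soft tissue sarcoma", "Sarcoma", "Solid tumor")

    def chain(self, subtype: str) -> tuple[str, str, str, str]:
        key = subtype.strip().casefold()
        for name, levels in self.nodes.items():
            if name.strip().casefold() == key:
                return levels
        return (subtype, *self.default_fallback)

    def ancestors(self, subtype: str) -> list[str]:
        """Levels 2-4 of the subtype's chain (used for cancer-type matching
        and panel fallback)."""
        return list(self.chain(subtype)[1:])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OntologyHierarchy":
        """Load from a 4-column TSV (level1..level4 per row; a row whose
        level1 is ``__default__`` supplies the fallback chain)."""
        nodes: dict[str, tuple[str, str, str, str]] = {}
        fallback = ("Soft tissue sarcoma", "Sarcoma", "Solid tumor")
        with open(path) as fh:
            header = fh.readline()
            if not header.lower().startswith("level1"):
                raise ValueError("ontology file must start with a level1..level4 header")
            for line in fh:
                parts = [p.strip() for p in line.rstrip("\n").split("\t")]
                if len(parts) != 4:
                    raise ValueError(f"ontology row must have 4 levels: {line!r}")
                if parts[0] == "__default__":
                    fallback = (parts[1], parts[2], parts[3])
                else:
                    nodes[parts[0]] = tuple(parts)  # type: ignore[arg-type]
        return cls(nodes=nodes, default_fallback=fallback)


class TrialRecord(BaseModel):
    registry_id: str
    title: str = ""
    conditions: list[str] = Field(default_factory=list)
    phase: str = "NA"  # "1".."4" or "NA"
    status: str = "Recruiting"
    locations: list[str] = Field(default_factory=list)
    genomic_keywords: list[str] = Field(default_factory=list)
    match_level: Optional[int] = None  # narrowest expansion level that hit


class RelevanceScore(BaseModel):
    genomic: float = Field(ge=0, le=1)
    phase: float = Field(ge=0, le=1)
    histology: float = Field(ge=0, le=1)
    geography: float = Field(ge=0, le=1)
    total: float = Field(ge=0, le=1)


class TrialRegistry(Protocol):
    """Registry contract: condition term -> matching trial records."""

    def search(self, condition: str) -> list[TrialRecord]: ...


class SnapshotRegistry:
    """Offline registry over a line-delimited JSON trial snapshot.

    Matching is case-insensitive exact on the trial's condition terms,
    mirroring per-condition registry queries.
    """

    def __init__(self, records: Iterable[TrialRecord]) -> None:
        self.records = list(records)
        ids = [r.registry_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("registry_id must be unique within a snapshot")

    @classmethod
    def from_jsonl(cls, path: str | Path) -> "SnapshotRegistry":
        records = []
        with open(path) as fh:
            for line in fh:
                if line.strip():
                    records.append(TrialRecord(**json.loads(line)))
        return cls(records)

    def search(self, condition: str) -> list[TrialRecord]:
        term = condition.strip().casefold()
        return [
            r for r in self.records
            if any(c.strip().casefold() == term for c in r.conditions)
        ]


def expand_query(subtype: str, hierarchy: OntologyHierarchy) -> list[str]:
    """Exactly four query terms, narrowest first; unknown subtypes use the
    default fallback chain with the input term at level 1."""
    if not subtype or not subtype.strip():
        raise ValueError("subtype must be a non-empty term")
    return list(hierarchy.chain(subtype))


def fetch_trials(
    queries: list[str],
    registry: TrialRegistry,
) -> list[TrialRecord]:
    """Run all expansion-level queries and merge, deduplicated by
    registry_id; each trial is tagged with its narrowest matching level.

    A registry failure at one level empties that level (logged, non-fatal).
    Output order is deterministic: (match_level, registry_id).
    """
    seen: dict[str, TrialRecord] = {}
    for level, term in enumerate(queries, start=1):
        try:
            hits = registry.search(term)
        except Exception as exc:
            logger.warning("registry query %r (level %d) failed: %s", term, level, exc)
            hits = []
        for trial in hits:
            if trial.registry_id not in seen:
                seen[trial.registry_id] = trial.model_copy(update={"match_level": level})
    return sorted(seen.values(), key=lambda t: (t.match_level, t.registry_id))


# --- default component scorers (config-replaceable) ------------------------

def genomic_component(trial: TrialRecord, matched_genes: list[str], clinical_only: bool = False) -> float:
    """Fraction of the patient's actionable genes named by the trial; in
    clinical-only mode any panel-gene hit counts fully."""
    if not matched_genes:
        return 0.0
    keywords = {k.strip().casefold() for k in trial.genomic_keywords}
    hits = sum(1 for g in matched_genes if g.strip().casefold() in keywords)
    if clinical_only:
        return 1.0 if hits else 0.0
    return hits / len(matched_genes)


def phase_component(trial: TrialRecord) -> float:
    return config.PHASE_SCORES.get(str(trial.phase), 0.0)


def histology_component(match_level: int) -> float:
    """Level discount: direct match 1.0, basket match 0.25."""
    return 1.0 / match_level


def geography_component(trial: TrialRecord, patient_region: str) -> float:
    local = {t.casefold() for t in config.REGION_TABLE.get(patient_region, (patient_region,))}
    return 1.0 if any(loc.strip().casefold() in local for loc in trial.locations) else 0.0


def score_relevance(
    trial: TrialRecord,
    profile: PatientProfile,
    matched_genes: list[str],
    match_level: int,
    clinical_only: bool = False,
    weights: dict[str, float] = config.RELEVANCE_WEIGHTS,
    components: Optional[dict[str, float]] = None,
) -> RelevanceScore:
    """Weighted four-component relevance score in [0, 1].

    ``components`` overrides the default scorers outright (used by tests
    and by institutions wiring custom scorers through config).
    """
    total_w = sum(weights.values())
    if abs(total_w - 1.0) > 1e-9:
        raise ValueError(f"relevance weights must sum to 1, got {total_w}")
    if components is None:
        components = {
            "genomic": genomic_component(trial, matched_genes, clinical_only),
            "phase": phase_component(trial),
            "histology": histology_component(match_level),
            "geography": geography_component(trial, profile.geography),
        }
    total = sum(weights[k] * components[k] for k in weights)
    return RelevanceScore(total=total, **components)


def rank_trials(
    trials: list[TrialRecord],
    profile: PatientProfile,
    matched_genes: list[str],
    clinical_only: bool = False,
    status_whitelist: frozenset[str] = config.RECRUITING_STATUSES,
) -> list[tuple[TrialRecord, RelevanceScore]]:
    """Score and rank recruiting trials, descending total; ties broken by
    registry_id so ranking is invariant to snapshot record order."""
    scored = [
        (t, score_relevance(t, profile, matched_genes, t.match_level or 4, clinical_only))
        for t in trials
        if t.status in status_whitelist
    ]
    return sorted(scored, key=lambda ts: (-ts[1].total, ts[0].registry_id))
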