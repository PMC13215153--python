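"""End-to-end cohort driver and reporting with exact binomial intervals.

`run_pipeline` wires all six modules over a cohort directory and a
snapshot directory (both producible by the fixtures module or replaceable
with real inputs in the same formats), emitting one dossier per patient
plus a cohort-level report: Tier 1/2 match rate and biomarker-driven
match rate with Clopper-Pearson 95% confidence intervals, the clamp
trigger rate, and per-agent match counts (each patient counted once, at
its highest-tier agent).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field
from scipy.stats import beta as beta_dist

from . import config, drug_match, evidence_rag, trial_match, variant_tiering
from .fixtures import DRUG_SYNONYMS, ConstantWeightProvider
from .orchestrator import (
    ClampResult,
    Dossier,
    ElicitationError,
    LLMProvider,
    ReasoningTrace,
    TraceStep,
    TreatmentOption,
    build_dossier,
    clamp_and_renormalize,
    composite_score,
    default_fallback_weights,
    dossier_markdown,
    exclude_failed,
    generate_weights,
    is_novel_mechanism,
)

logger = logging.getLogger(__name__)

__all__ = ["CohortReport", "clopper_pearson", "run_pipeline"]


def clopper_pearson(successes: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial 95% CI as percentages, via the beta-quantile
    characterization; lower = 0 at zero successes, upper = 100 at n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError(f"successes={successes} outside [0, {n}]")
    lower = 0.0 if successes == 0 else float(beta_dist.ppf(alpha / 2, successes, n - successes + 1))
    upper = 1.0 if successes == n else float(beta_dist.ppf(1 - alpha / 2, successes + 1, n - successes))
    return lower * 100.0, upper * 100.0


class CohortReport(BaseModel):
    n: int
    tier12_count: int
    tier12_rate_pct: float
    tier12_ci_pct: tuple[float, float]
    biomarker_matched_count: int
    biomarker_matched_rate_pct: float
    biomarker_matched_ci_pct: tuple[float, float]
    clamp_trigger_count: int
    clamp_trigger_rate_pct: float
    per_agent_counts: dict[str, int] = Field(default_factory=dict)
    per_patient_failures: int = 0

    def table(self) -> str:
        lines = [
            f"patients                 {self.n}",
            f"Tier 1/2 matched         {self.tier12_count} "
            f"({self.tier12_rate_pct:.1f}%; 95% CI {self.tier12_ci_pct[0]:.1f}-{self.tier12_ci_pct[1]:.1f}%)",
            f"biomarker-driven match   {self.biomarker_matched_count} "
            f"({self.biomarker_matched_rate_pct:.1f}%; 95% CI "
            f"{self.biomarker_matched_ci_pct[0]:.1f}-{self.biomarker_matched_ci_pct[1]:.1f}%)",
            f"clamp trigger rate       {self.clamp_trigger_rate_pct:.1f}%",
        ]
        for agent, count in sorted(self.per_agent_counts.items(), key=lambda kv: (-kv[1], kv[0])):
            lines.append(f"  {agent:<22} {count}")
        return "\n".join(lines)


_ACCESS_BY_TIER = {
    1: "standard prescription",
    2: "off-label with compendium support",
    3: "clinical trial",
    4: "compassionate use",
}


def _load_evidence(path: Path) -> list[variant_tiering.ClinicalEvidenceRecord]:
    table = pd.read_csv(path, sep="\t", dtype=str)
    return [variant_tiering.ClinicalEvidenceRecord(**row) for row in table.to_dict("records")]


def _options_from_interactions(
    interactions: list[drug_match.DrugGeneInteraction],
    allowed_genes: set[str],
) -> list[TreatmentOption]:
    best: dict[str, TreatmentOption] = {}
    for rec in interactions:
        if rec.gene_symbol not in allowed_genes:
            continue
        pathway = _ACCESS_BY_TIER[rec.harmonized_tier]
        option = TreatmentOption(
            agent=rec.drug_name,
            mechanism=rec.mechanism,
            evidence_tier=rec.harmonized_tier,
            novel_mechanism=is_novel_mechanism(rec.mechanism),
            access_pathway=pathway,
            component_scores={
                "evidence_strength": config.TIER_EVIDENCE_SCORES[rec.harmonized_tier],
                "access_feasibility": config.ACCESS_PATHWAY_SCORES[pathway],
                "expected_response": config.NEUTRAL_COMPONENT_SCORE,
                "safety_profile": config.NEUTRAL_COMPONENT_SCORE,
                "cost": config.NEUTRAL_COMPONENT_SCORE,
            },
            next_step=f"review {rec.drug_name} evidence for {rec.gene_symbol} match",
        )
        held = best.get(rec.drug_name)
        if held is None or option.evidence_tier < held.evidence_tier:
            best[rec.drug_name] = option
    return list(best.values())


def run_pipeline(
    cohort_dir: str | Path,
    snapshot_dir: str | Path,
    out_dir: Optional[str | Path] = None,
    provider: Optional[LLMProvider] = None,
) -> tuple[list[Dossier], CohortReport]:
    """Run the full six-module pipeline for every patient in the cohort.

    Per-patient failures are logged and counted, never abort the cohort.
    """
    cohort_dir, snapshot_dir = Path(cohort_dir), Path(snapshot_dir)
    provider = provider or ConstantWeightProvider()

    hierarchy = trial_match.OntologyHierarchy.from_tsv(snapshot_dir / "ontology.tsv")
    evidence = _load_evidence(snapshot_dir / "evidence.tsv")
    adapters = [
        drug_match.load_snapshot(source, snapshot_dir / f"{source.lower()}.tsv")
        for source in drug_match.SOURCES
    ]
    cache = drug_match.TtlCache()
    registry = trial_match.SnapshotRegistry.from_jsonl(snapshot_dir / "trials.jsonl")
    embedder = evidence_rag.HashedBagOfWordsEmbedder()
    corpus = evidence_rag.read_corpus_tsv(snapshot_dir / "corpus.tsv")
    index = evidence_rag.VectorIndex(evidence_rag.chunk_corpus(corpus, embedder))

    profiles: list[variant_tiering.PatientProfile] = []
    with open(cohort_dir / "profiles.jsonl") as fh:
        for line in fh:
            if line.strip():
                profiles.append(variant_tiering.PatientProfile(**json.loads(line)))

    dossiers: list[Dossier] = []
    tier12 = 0
    biomarker_matched = 0
    clamp_triggers = 0
    failures = 0
    per_agent: dict[str, int] = {}

    for profile in profiles:
        try:
            dossier, best_tier, genomic = _run_patient(
                profile, cohort_dir, hierarchy, evidence, adapters, cache,
                registry, embedder, index, provider,
            )
        except Exception:
            failures += 1
            logger.exception("patient %s failed; cohort run continues", profile.patient_id)
            continue
        dossiers.append(dossier)
        if genomic:
            biomarker_matched += 1
        if dossier.clamp_result and dossier.clamp_result.clamped:
            clamp_triggers += 1
        if best_tier is not None and best_tier <= 2:
            tier12 += 1
            top = min(
                (o for o in dossier.options if o.evidence_tier <= 2),
                key=lambda o: (o.evidence_tier, o.agent),
            )
            per_agent[top.agent] = per_agent.get(top.agent, 0) + 1
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            (out / f"{profile.patient_id}.dossier.json").write_text(dossier.model_dump_json(indent=1))
            (out / f"{profile.patient_id}.dossier.md").write_text(dossier_markdown(dossier))

    n = len(profiles)
    report = CohortReport(
        n=n,
        tier12_count=tier12,
        tier12_rate_pct=round(100.0 * tier12 / n, 1) if n else 0.0,
        tier12_ci_pct=tuple(round(x, 1) for x in clopper_pearson(tier12, n)) if n else (0.0, 0.0),
        biomarker_matched_count=biomarker_matched,
        biomarker_matched_rate_pct=round(100.0 * biomarker_matched / n, 1) if n else 0.0,
        biomarker_matched_ci_pct=(
            tuple(round(x, 1) for x in clopper_pearson(biomarker_matched, n)) if n else (0.0, 0.0)
        ),
        clamp_trigger_count=clamp_triggers,
        clamp_trigger_rate_pct=round(100.0 * clamp_triggers / len(dossiers), 1) if dossiers else 0.0,
        per_agent_counts=per_agent,
        per_patient_failures=failures,
    )
    if out_dir is not None:
        (Path(out_dir) / "cohort_report.json").write_text(report.model_dump_json(indent=1))
    return dossiers, report


def _run_patient(profile, cohort_dir, hierarchy, evidence, adapters, cache,
                 registry, embedder, index, provider):
    ancestors = hierarchy.ancestors(profile.histology)
    trace = ReasoningTrace()
    step = 0

    def note(tool: str, observation) -> None:
        nonlocal step
        step += 1
        trace.steps.append(TraceStep(
            step=step, thought=f"ran {tool}", tool=tool,
            args_digest="-", observation_digest=str(observation)[:40],
        ))

    coding: list[variant_tiering.SomaticVariant] = []
    best_variant_tier: Optional[int] = None
    maf_path = cohort_dir / f"{profile.patient_id}.maf"
    if profile.mode == "A" and maf_path.exists():
        coding = variant_tiering.filter_coding(variant_tiering.parse_maf(maf_path))
    routing = variant_tiering.route_patient(profile, coding, ancestors)
    genomic = routing.mode == "genomic_mode"

    if genomic:
        tiers = []
        for v in coding:
            gene_evidence = [r for r in evidence if r.gene_symbol == v.gene_symbol]
            tiers.append(variant_tiering.classify_tier(v, gene_evidence, profile.histology, ancestors))
        best_variant_tier = min((t.level for t in tiers), default=None)
        matched_genes = sorted({
            v.gene_symbol for v, t in zip(coding, tiers) if t.level <= 3
        })
        note("variant_tiering", {"coding": len(coding), "best_tier": best_variant_tier})
    else:
        matched_genes = list(routing.gene_panel)
        note("routing", routing.mode)

    interactions = drug_match.query_sources(matched_genes, adapters, cache=cache)
    deduped, conflicts = drug_match.deduplicate_and_harmonize(interactions, DRUG_SYNONYMS)
    note("drug_match", {"pairs": len(deduped), "conflicts": len(conflicts)})

    queries = trial_match.expand_query(profile.histology, hierarchy)
    trials = trial_match.fetch_trials(queries, registry)
    ranked_trials = trial_match.rank_trials(
        trials, profile, matched_genes, clinical_only=not genomic,
    )
    note("trial_match", {"trials": len(ranked_trials)})

    query_text = f"{profile.histology} {' '.join(matched_genes[:3])} treatment"
    retrieved = evidence_rag.retrieve(query_text, index, embedder)
    retrieval_set = {c.pmid for c in retrieved}
    claims = [
        evidence_rag.EvidenceClaim(
            statement=c.text.split(".")[0][:120], cited_pmids=[c.pmid],
        )
        for c in retrieved
    ]
    retained_claims, _ = evidence_rag.ground_citations(claims, retrieval_set)
    note("evidence_rag", {"retrieved": len(retrieved)})

    context_prompt = (
        f"patient {profile.patient_id}: {profile.histology}, stage {profile.stage}, "
        f"{len(profile.prior_treatments)} prior treatments"
    )
    try:
        raw = generate_weights(context_prompt, provider)
        clamp: ClampResult = clamp_and_renormalize(raw)
    except ElicitationError:
        logger.warning("weight elicitation failed for %s; using default weights",
                       profile.patient_id)
        clamp = default_fallback_weights()
    note("weights", {"clamped": clamp.clamped})

    options = _options_from_interactions(deduped, set(matched_genes))
    for o in options:
        o.composite = composite_score(o.component_scores, clamp.weights, o.novel_mechanism)
    options = exclude_failed(options, profile, DRUG_SYNONYMS)

    best_tier = min((o.evidence_tier for o in options), default=None)
    if genomic and best_variant_tier is not None and best_tier is not None:
        best_tier = min(best_tier, 4)

    dossier = build_dossier(
        profile.patient_id, options, ranked_trials, retained_claims, trace, clamp,
    )
    return dossier, best_tier, genomic
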