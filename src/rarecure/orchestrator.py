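"""Context-adaptive orchestration with deterministic weight clamping.

The central design tension: patient context should influence option
ranking (an LLM can weigh disease acuity, prior failures, access), but
unconstrained model output introduces unacceptable variability for a
clinical audit trail. The resolution is adaptive weight *generation* with
deterministic weight *finalization*:

1. The provider is asked for a five-dimension weight vector five times at
   temperature 0.3; the element-wise median damps outlier samples.
2. The median vector is projected onto the intersection of the probability
   simplex and the per-dimension clamp box
   {w : sum(w) = 1, l_i <= w_i <= u_i} — the Euclidean projection computed
   by bisection on the simplex Lagrange multiplier with per-coordinate box
   clipping. This is the canonical "clamp then redistribute within bounds"
   operator: the result is the closest admissible vector to the proposal.
3. A `clamped` audit flag is set iff some bound actually clipped a
   coordinate; pure redistribution of an in-bounds proposal never sets it.

Composite option score: min(1, (sum_i w_i * c_i) * (1 + 0.15 * novel)).
"""

from __future__ import annotations

import hashlib
import json
import logging
from typing import Callable, Iterable, Optional, Protocol

import numpy as np
from pydantic import BaseModel, Field
from scipy.optimize import brentq

from . import config
from .evidence_rag import EvidenceClaim
from .trial_match import TrialRecord
from .variant_tiering import PatientProfile

logger = logging.getLogger(__name__)

__all__ = [
    "ScoringWeights",
    "WeightBounds",
    "ClampResult",
    "TreatmentOption",
    "ReasoningTrace",
    "TraceStep",
    "Dossier",
    "LLMProvider",
    "ElicitationError",
    "generate_weights",
    "clamp_and_renormalize",
    "composite_score",
    "exclude_failed",
    "run_react",
    "build_dossier",
    "default_fallback_weights",
]

DIMS = config.WEIGHT_DIMENSIONS


class ScoringWeights(BaseModel):
    evidence_strength: float = Field(ge=0, le=1)
    access_feasibility: float = Field(ge=0, le=1)
    expected_response: float = Field(ge=0, le=1)
    safety_profile: float = Field(ge=0, le=1)
    cost: float = Field(ge=0, le=1)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, d) for d in DIMS])

    @classmethod
    def from_array(cls, arr: Iterable[float]) -> "ScoringWeights":
        return cls(**dict(zip(DIMS, (float(x) for x in arr))))


class WeightBounds(BaseModel):
    bounds: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: dict(config.DEFAULT_WEIGHT_BOUNDS)
    )

    def validate_feasible(self) -> "WeightBounds":
        lo, hi = self.arrays()
        if not (np.all(lo > 0) and np.all(lo < hi) and np.all(hi <= 1)):
            raise ValueError("each dimension needs 0 < lower < upper <= 1")
        if not (lo.sum() <= 1.0 <= hi.sum()):
            raise ValueError(
                f"infeasible bounds: sum(lower)={lo.sum():.3f}, sum(upper)={hi.sum():.3f}"
            )
        return self

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.bounds[d][0] for d in DIMS])
        hi = np.array([self.bounds[d][1] for d in DIMS])
        return lo, hi


class ClampResult(BaseModel):
    weights: ScoringWeights
    clamped: bool
    pre_clamp: list[float]  # raw proposal retained for audit


class TreatmentOption(BaseModel):
    agent: str
    mechanism: str = ""
    evidence_tier: int = Field(ge=1, le=4)
    component_scores: dict[str, float] = Field(default_factory=dict)
    novel_mechanism: bool = False
    access_pathway: str = "clinical trial"
    composite: float = Field(default=0.0, ge=0, le=1)
    next_step: str = ""


class TraceStep(BaseModel):
    step: int
    thought: str
    tool: str
    args_digest: str
    observation_digest: str


class ReasoningTrace(BaseModel):
    steps: list[TraceStep] = Field(default_factory=list)
    truncated: bool = False
    notes: list[str] = Field(default_factory=list)

    def to_jsonl(self) -> str:
        return "\n".join(s.model_dump_json() for s in self.steps)


class Dossier(BaseModel):
    patient_id: str
    options: list[TreatmentOption]
    trials: list[dict] = Field(default_factory=list)
    evidence_claims: list[EvidenceClaim] = Field(default_factory=list)
    clamp_result: Optional[ClampResult] = None
    trace_reference: Optional[str] = None
    empty_options_banner: Optional[str] = None
    disclaimer: str = (
        "Investigational option dossier for review by a qualified clinician; "
        "not a prescriptive recommendation."
    )


class LLMProvider(Protocol):
    """Single text-in / text-out provider contract.

    Both cloud-hosted and locally hosted model backends, and the scripted
    mock, implement this one method; pipeline logic never depends on which
    is wired in (only the endpoint differs).
    """

    def complete(self, prompt: str, temperature: float = 0.0) -> str: ...


class ElicitationError(RuntimeError):
    """Fewer than the minimum number of parseable weight samples."""


# ---------------------------------------------------------------------------
# Weight elicitation
# ---------------------------------------------------------------------------

def _parse_weight_doc(text: str) -> Optional[np.ndarray]:
    try:
        doc = json.loads(text)
        vec = np.array([float(doc[d]) for d in DIMS])
    except (ValueError, KeyError, TypeError):
        return None
    if np.any(~np.isfinite(vec)) or np.any(vec < 0):
        return None
    return vec


def generate_weights(
    context_prompt: str,
    provider: LLMProvider,
    n_samples: int = config.WEIGHT_SAMPLES,
    temperature: float = config.WEIGHT_TEMPERATURE,
    retry_cap: int = config.WEIGHT_RETRY_CAP,
    min_valid: int = config.WEIGHT_MIN_VALID,
) -> np.ndarray:
    """Element-wise median of ``n_samples`` provider weight documents.

    Malformed responses are re-requested up to ``retry_cap`` times, then
    that sample is dropped; fewer than ``min_valid`` parseable samples is
    an elicitation error (callers fall back to the default weights).
    """
    samples: list[np.ndarray] = []
    for _ in range(n_samples):
        vec = _parse_weight_doc(provider.complete(context_prompt, temperature=temperature))
        retries = 0
        while vec is None and retries < retry_cap:
            retries += 1
            vec = _parse_weight_doc(provider.complete(context_prompt, temperature=temperature))
        if vec is None:
            logger.warning("weight sample dropped after %d retries", retry_cap)
        else:
            samples.append(vec)
    if len(samples) < min_valid:
        raise ElicitationError(
            f"only {len(samples)} of {n_samples} weight samples parsed (need >= {min_valid})"
        )
    return np.median(np.stack(samples), axis=0)


def default_fallback_weights(bounds: Optional[WeightBounds] = None) -> ClampResult:
    """Midpoint of each bound range, finalized through the clamp."""
    bounds = bounds or WeightBounds()
    lo, hi = bounds.arrays()
    return clamp_and_renormalize((lo + hi) / 2.0, bounds)


# ---------------------------------------------------------------------------
# Deterministic clamping
# ---------------------------------------------------------------------------

def clamp_and_renormalize(
    raw: Iterable[float],
    bounds: Optional[WeightBounds] = None,
) -> ClampResult:
    """Project a raw weight proposal onto the box-intersected simplex.

    Solves w_i = clip(raw_i - tau, l_i, u_i) with tau chosen so sum(w) = 1
    (bisection on the monotone sum; this is the exact Euclidean projection).
    A raw vector already in bounds and summing to 1 is returned unchanged.
    ``clamped`` is true iff a box bound clipped some coordinate; the shift
    that redistributes mass for an in-bounds proposal does not set it.
    """
    bounds = (bounds or WeightBounds()).validate_feasible()
    lo, hi = bounds.arrays()
    r = np.asarray(list(raw), dtype=float)
    if r.shape != lo.shape:
        raise ValueError(f"expected {len(DIMS)} weight components, got {r.shape}")

    def excess(tau: float) -> float:
        return float(np.clip(r - tau, lo, hi).sum() - 1.0)

    t_lo = float(r.min() - hi.max() - 1.0)   # excess >= 0 here
    t_hi = float(r.max() - lo.min() + 1.0)   # excess <= 0 here
    tau = brentq(excess, t_lo, t_hi, xtol=1e-13)
    shifted = r - tau
    projected = np.clip(shifted, lo, hi)
    # absorb residual bisection error into unclipped coordinates so the
    # bounds hold exactly and the sum is 1 to machine precision
    free = (projected > lo + 1e-12) & (projected < hi - 1e-12)
    if free.any():
        projected[free] += (1.0 - projected.sum()) / free.sum()
    projected = np.clip(projected, lo, hi)
    clamped = bool(np.any(shifted < lo - 1e-12) or np.any(shifted > hi + 1e-12))
    return ClampResult(
        weights=ScoringWeights.from_array(projected),
        clamped=clamped,
        pre_clamp=[float(x) for x in r],
    )


# ---------------------------------------------------------------------------
# Option scoring
# ---------------------------------------------------------------------------

def composite_score(
    components: dict[str, float],
    weights: ScoringWeights,
    novel: bool,
    bonus: float = config.NOVELTY_BONUS,
    cap: float = config.COMPOSITE_CAP,
) -> float:
    """min(cap, weighted component sum x novelty factor)."""
    for d, c in components.items():
        if not 0.0 <= c <= 1.0:
            raise ValueError(f"component score {d}={c} outside [0, 1]")
    weighted = sum(getattr(weights, d) * components.get(d, 0.0) for d in DIMS)
    return min(cap, weighted * (1.0 + (bonus if novel else 0.0)))


def is_novel_mechanism(mechanism: str,
                       classes: tuple[str, ...] = config.NOVEL_MECHANISM_CLASSES) -> bool:
    m = mechanism.casefold()
    return any(c in m for c in classes)


def exclude_failed(
    options: list[TreatmentOption],
    profile: PatientProfile,
    synonyms: Optional[dict[str, str]] = None,
) -> list[TreatmentOption]:
    """Drop options matching a prior therapy whose outcome was progression
    or outright failure; response/stable prior agents stay eligible."""
    from .drug_match import normalize_drug_name

    failed = {
        normalize_drug_name(agent, synonyms)
        for agent, outcome in profile.prior_treatments
        if outcome in config.FAILED_OUTCOMES
    }
    return [o for o in options if normalize_drug_name(o.agent, synonyms) not in failed]


# ---------------------------------------------------------------------------
# ReAct loop
# ---------------------------------------------------------------------------

_MODE_B_BLOCKED_TOOLS = {"variant_tiering", "neoantigen_screen"}


def _digest(obj) -> str:
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:16]


def run_react(
    profile: PatientProfile,
    tools: dict[str, Callable[[dict], object]],
    provider: LLMProvider,
    iteration_cap: int = config.REACT_ITERATION_CAP,
) -> tuple[dict[str, object], ReasoningTrace]:
    """Alternate provider-proposed reasoning/action documents with tool
    invocations until the provider issues a final synthesis step.

    Provider documents are JSON: {"thought": ..., "action": <tool name>,
    "args": {...}} for tool steps, action "synthesize" to finish. Unknown
    tools get one re-prompt, then are skipped with a trace note. Mode B
    profiles never execute the genomic-input tools. The loop is bounded by
    ``iteration_cap``; with a scripted provider the run is bit-reproducible
    (the trace uses a monotonic step counter, no wall clock).
    """
    trace = ReasoningTrace()
    bundle: dict[str, object] = {}
    step_no = 0
    reprompted = False
    for _ in range(iteration_cap):
        doc = json.loads(provider.complete(f"plan step for {profile.patient_id}"))
        thought = doc.get("thought", "")
        action = doc.get("action", "")
        args = doc.get("args", {})
        if action == "synthesize":
            step_no += 1
            synthesis = provider.complete(f"synthesis for {profile.patient_id}")
            bundle["synthesis"] = synthesis
            trace.steps.append(TraceStep(
                step=step_no, thought=thought, tool="synthesize",
                args_digest=_digest(args), observation_digest=_digest(synthesis),
            ))
            return bundle, trace
        if action not in tools or (profile.mode == "B" and action in _MODE_B_BLOCKED_TOOLS):
            reason = "unknown tool" if action not in tools else "tool unavailable in Mode B"
            if not reprompted:
                reprompted = True
                trace.notes.append(f"step rejected ({reason}: {action!r}); re-prompting")
                continue
            trace.notes.append(f"step skipped ({reason}: {action!r})")
            reprompted = False
            continue
        reprompted = False
        observation = tools[action](args)
        bundle[action] = observation
        step_no += 1
        trace.steps.append(TraceStep(
            step=step_no, thought=thought, tool=action,
            args_digest=_digest(args), observation_digest=_digest(observation),
        ))
    trace.truncated = True
    trace.notes.append(f"iteration cap {iteration_cap} reached before synthesis")
    return bundle, trace


# ---------------------------------------------------------------------------
# Dossier assembly
# ---------------------------------------------------------------------------

def build_dossier(
    patient_id: str,
    options: list[TreatmentOption],
    trials: list[tuple[TrialRecord, object]] = (),
    evidence_claims: list[EvidenceClaim] = (),
    trace: Optional[ReasoningTrace] = None,
    clamp_result: Optional[ClampResult] = None,
) -> Dossier:
    """Rank options by composite (desc), breaking ties by stronger tier then
    agent name; a zero-option dossier keeps its trial section and carries an
    explicit banner."""
    ranked = sorted(options, key=lambda o: (-o.composite, o.evidence_tier, o.agent))
    return Dossier(
        patient_id=patient_id,
        options=ranked,
        trials=[
            {"registry_id": t.registry_id, "title": t.title,
             "match_level": t.match_level,
             "relevance": getattr(s, "total", None)}
            for t, s in trials
        ],
        evidence_claims=list(evidence_claims),
        clamp_result=clamp_result,
        trace_reference=_digest(trace.to_jsonl()) if trace else None,
        empty_options_banner=(
            None if ranked else
            "No ranked treatment options; see trial eligibility section."
        ),
    )


def dossier_markdown(d: Dossier) -> str:
    lines = [f"# Investigational option dossier — patient {d.patient_id}", ""]
    if d.empty_options_banner:
        lines += [f"**{d.empty_options_banner}**", ""]
    for i, o in enumerate(d.options, 1):
        lines += [
            f"## {i}. {o.agent} (composite {o.composite:.3f})",
            f"- Tier {o.evidence_tier}; mechanism: {o.mechanism or 'n/a'}"
            f"{' (novel mechanism, +15% bonus applied)' if o.novel_mechanism else ''}",
            f"- Access pathway: {o.access_pathway}",
            f"- Next step: {o.next_step or 'clinician review'}",
            "",
        ]
    if d.trials:
        lines.append("## Trial eligibility")
        for t in d.trials:
            lines.append(
                f"- {t['registry_id']} (match level {t['match_level']}, "
                f"relevance {t['relevance']:.2f}): {t['title']}"
            )
        lines.append("")
    lines.append(f"> {d.disclaimer}")
    return "\n".join(lines)
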