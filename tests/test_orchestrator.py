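"""Weight elicitation, deterministic clamping, composite scoring, the
ReAct loop, and dossier assembly."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from rarecure import config
from rarecure.fixtures import ScriptedProvider, weight_document
from rarecure.orchestrator import (
    ElicitationError,
    ScoringWeights,
    TreatmentOption,
    WeightBounds,
    build_dossier,
    clamp_and_renormalize,
    composite_score,
    default_fallback_weights,
    exclude_failed,
    generate_weights,
    run_react,
)
from rarecure.variant_tiering import PatientProfile

LO = np.array([b[0] for b in config.DEFAULT_WEIGHT_BOUNDS.values()])
HI = np.array([b[1] for b in config.DEFAULT_WEIGHT_BOUNDS.values()])


def oracle_projection(raw: np.ndarray) -> np.ndarray:
    """Independent Euclidean projection via constrained optimization."""
    res = minimize(
        lambda w: ((w - raw) ** 2).sum(), x0=(LO + HI) / 2,
        jac=lambda w: 2 * (w - raw),
        bounds=list(zip(LO, HI)),
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1,
                      "jac": lambda w: np.ones(5)}],
        method="SLSQP", tol=1e-12,
    )
    assert res.success
    return res.x


def uniform_weights() -> ScoringWeights:
    return ScoringWeights.from_array([0.2] * 5)


class TestGenerateWeights:
    def test_median_of_identical_vectors(self):
        doc = weight_document(0.4, 0.15, 0.25, 0.15, 0.05)
        provider = ScriptedProvider([doc] * 5)
        raw = generate_weights("ctx", provider)
        assert np.allclose(raw, [0.4, 0.15, 0.25, 0.15, 0.05])
        assert provider.calls == 5

    def test_median_suppresses_per_dimension_outliers(self):
        docs = [
            weight_document(0.4, 0.15, 0.25, 0.15, 0.05),
            weight_document(0.4, 0.15, 0.25, 0.15, 0.05),
            weight_document(0.9, 0.15, 0.25, 0.15, 0.05),  # evidence outlier
            weight_document(0.4, 0.15, 0.25, 0.15, 0.05),
            weight_document(0.4, 0.15, 0.90, 0.15, 0.05),  # response outlier
        ]
        raw = generate_weights("ctx", ScriptedProvider(docs))
        # independent oracle: per-dimension sort over the 5 samples
        stacked = np.array([json.loads(d) and [json.loads(d)[k] for k in config.WEIGHT_DIMENSIONS]
                            for d in docs])
        expected = np.sort(stacked, axis=0)[2]
        assert np.allclose(raw, expected)

    def test_malformed_sample_retried_then_dropped(self):
        good = weight_document(0.4, 0.15, 0.25, 0.15, 0.05)
        script = ["not json", "still not json", "nope"] + [good] * 4
        provider = ScriptedProvider(script)
        raw = generate_weights("ctx", provider)
        assert np.allclose(raw, [0.4, 0.15, 0.25, 0.15, 0.05])

    def test_too_few_valid_samples_is_elicitation_error(self):
        provider = ScriptedProvider(["junk"] * 15)
        with pytest.raises(ElicitationError):
            generate_weights("ctx", provider)

    def test_fallback_weights_are_in_bounds_unit_sum(self):
        result = default_fallback_weights()
        w = result.weights.as_array()
        assert np.all(w >= LO) and np.all(w <= HI)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)


class TestClamp:
    def test_degenerate_safety_vector_pinned_at_upper_bound(self):
        result = clamp_and_renormalize([0.0, 0.0, 0.0, 1.0, 0.0])
        assert result.weights.safety_profile == pytest.approx(0.40, abs=1e-12)
        assert result.clamped
        w = result.weights.as_array()
        assert np.all(w >= LO) and np.all(w <= HI)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_in_bounds_unit_sum_vector_is_fixed_point(self):
        raw = [0.40, 0.15, 0.25, 0.15, 0.05]
        result = clamp_and_renormalize(raw)
        assert np.allclose(result.weights.as_array(), raw, atol=1e-12)
        assert not result.clamped
        assert result.pre_clamp == raw

    def test_idempotent(self):
        first = clamp_and_renormalize([0.9, 0.0, 0.05, 0.03, 0.02])
        second = clamp_and_renormalize(first.weights.as_array())
        assert np.allclose(second.weights.as_array(), first.weights.as_array(),
                           atol=1e-9)
        assert not second.clamped

    @given(st.lists(st.floats(-0.5, 1.5), min_size=5, max_size=5))
    @settings(max_examples=200)
    def test_equals_euclidean_projection(self, raw):
        mine = clamp_and_renormalize(raw).weights.as_array()
        assert np.abs(mine - oracle_projection(np.array(raw))).max() < 1e-6

    def test_bounds_soundness_fuzz(self):
        rng = np.random.default_rng(2024)
        for _ in range(10_000):
            raw = rng.uniform(-1, 2, 5)
            w = clamp_and_renormalize(raw).weights.as_array()
            assert np.all(w >= LO - 1e-12) and np.all(w <= HI + 1e-12)
            assert abs(w.sum() - 1.0) < 1e-9

    def test_clamp_flag_honesty(self):
        # shift-only redistribution of an in-bounds proposal: no flag
        result = clamp_and_renormalize([0.35, 0.15, 0.20, 0.15, 0.05])  # sum 0.9
        assert not result.clamped
        w = result.weights.as_array()
        assert np.all(w > LO) and np.all(w < HI)

    def test_infeasible_bounds_rejected_at_load(self):
        bad = WeightBounds(bounds={d: (0.5, 0.9) for d in config.WEIGHT_DIMENSIONS})
        with pytest.raises(ValueError, match="infeasible"):
            clamp_and_renormalize([0.2] * 5, bad)


class TestCompositeScore:
    def test_novelty_bonus_multiplies(self):
        components = {d: 0.5 for d in config.WEIGHT_DIMENSIONS}  # weighted sum 0.5
        plain = composite_score(components, uniform_weights(), novel=False)
        novel = composite_score(components, uniform_weights(), novel=True)
        assert plain == pytest.approx(0.5)
        assert novel == pytest.approx(0.575)

    def test_cap_at_one(self):
        components = {d: 0.95 for d in config.WEIGHT_DIMENSIONS}
        assert composite_score(components, uniform_weights(), novel=True) == 1.0

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_monotone_and_bounded(self, c_low, c_high):
        lo_c, hi_c = sorted([c_low, c_high])
        base = {d: lo_c for d in config.WEIGHT_DIMENSIONS}
        bumped = dict(base, evidence_strength=hi_c)
        s1 = composite_score(base, uniform_weights(), novel=True)
        s2 = composite_score(bumped, uniform_weights(), novel=True)
        assert 0.0 <= s1 <= s2 <= 1.0

    def test_component_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            composite_score({"evidence_strength": 1.2}, uniform_weights(), False)


class TestExcludeFailed:
    def option(self, agent):
        return TreatmentOption(agent=agent, evidence_tier=2)

    def test_progressed_prior_therapy_removed(self):
        profile = PatientProfile(patient_id="P", mode="B", histology="Sarcoma",
                                 prior_treatments=[("pazopanib", "progression")])
        kept = exclude_failed([self.option("pazopanib"), self.option("imatinib")],
                              profile)
        assert [o.agent for o in kept] == ["imatinib"]

    def test_partial_response_prior_retained(self):
        profile = PatientProfile(patient_id="P", mode="B", histology="Sarcoma",
                                 prior_treatments=[("pazopanib", "partial response")])
        kept = exclude_failed([self.option("pazopanib")], profile)
        assert [o.agent for o in kept] == ["pazopanib"]

    def test_empty_prior_list_unchanged(self):
        profile = PatientProfile(patient_id="P", mode="B", histology="Sarcoma")
        options = [self.option("a"), self.option("b")]
        assert exclude_failed(options, profile) == options

    def test_brand_name_synonym_matches(self):
        profile = PatientProfile(patient_id="P", mode="B", histology="Sarcoma",
                                 prior_treatments=[("Votrient", "failed")])
        kept = exclude_failed([self.option("pazopanib")], profile,
                              {"votrient": "pazopanib"})
        assert kept == []


def plan_doc(action, thought="step"):
    return json.dumps({"thought": thought, "action": action, "args": {}})


ALL_TOOLS = ["variant_tiering", "neoantigen_screen", "drug_match",
             "trial_match", "evidence_rag"]


def tool_registry(calls):
    def make(name):
        def tool(args):
            calls.append(name)
            return {"tool": name}
        return tool
    return {name: make(name) for name in ALL_TOOLS}


class TestRunReact:
    def profile(self, mode="A"):
        return PatientProfile(patient_id="P1", mode=mode, histology="Sarcoma")

    def test_full_plan_trace_has_five_tool_steps_plus_synthesis(self):
        script = [plan_doc(t) for t in ALL_TOOLS] + [plan_doc("synthesize"), "final text"]
        calls = []
        bundle, trace = run_react(self.profile(), tool_registry(calls),
                                  ScriptedProvider(script))
        assert calls == ALL_TOOLS
        assert len(trace.steps) == 6
        assert trace.steps[-1].tool == "synthesize"
        assert bundle["synthesis"] == "final text"
        assert not trace.truncated

    def test_mode_b_never_invokes_genomic_tools(self):
        script = [plan_doc("variant_tiering"), plan_doc("drug_match"),
                  plan_doc("trial_match"), plan_doc("synthesize"), "done"]
        calls = []
        _, trace = run_react(self.profile(mode="B"), tool_registry(calls),
                             ScriptedProvider(script))
        assert "variant_tiering" not in calls
        assert all(s.tool not in ("variant_tiering", "neoantigen_screen")
                   for s in trace.steps)

    def test_unknown_tool_reprompted_once_then_skipped(self):
        script = [plan_doc("bogus"), plan_doc("bogus"), plan_doc("drug_match"),
                  plan_doc("synthesize"), "done"]
        calls = []
        _, trace = run_react(self.profile(), tool_registry(calls),
                             ScriptedProvider(script))
        assert calls == ["drug_match"]
        assert any("re-prompting" in n for n in trace.notes)
        assert any("skipped" in n for n in trace.notes)

    def test_iteration_cap_records_truncation(self):
        script = [plan_doc(t) for t in ALL_TOOLS] + [plan_doc("synthesize"), "x"]
        _, trace = run_react(self.profile(), tool_registry([]),
                             ScriptedProvider(script), iteration_cap=1)
        assert trace.truncated
        assert any("iteration cap" in n for n in trace.notes)

    def test_bit_reproducible_with_scripted_provider(self):
        script = [plan_doc(t) for t in ALL_TOOLS] + [plan_doc("synthesize"), "final"]
        runs = []
        for _ in range(2):
            _, trace = run_react(self.profile(), tool_registry([]),
                                 ScriptedProvider(script))
            runs.append(trace.model_dump_json())
        assert runs[0] == runs[1]


class TestBuildDossier:
    def option(self, agent="a", composite=0.5, tier=2):
        return TreatmentOption(agent=agent, evidence_tier=tier, composite=composite)

    def test_sorted_by_composite_descending(self):
        d = build_dossier("P", [self.option("a", 0.6), self.option("b", 0.8)])
        assert [o.composite for o in d.options] == [0.8, 0.6]

    def test_equal_composites_stronger_tier_first(self):
        d = build_dossier("P", [self.option("a", 0.5, tier=3),
                                self.option("b", 0.5, tier=1)])
        assert [o.evidence_tier for o in d.options] == [1, 3]

    def test_zero_options_keeps_trial_section_with_banner(self, registry):
        from rarecure.trial_match import RelevanceScore
        trials = [(registry.records[0],
                   RelevanceScore(genomic=0, phase=0, histology=0, geography=0, total=0))]
        d = build_dossier("P", [], trials=trials)
        assert d.empty_options_banner
        assert d.trials
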