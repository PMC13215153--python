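"""Variant parsing, coding filter, tier rules, and routing."""

import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from rarecure import config
from rarecure.variant_tiering import (
    ClinicalEvidenceRecord,
    MafFormatError,
    MalformedRowCounter,
    PatientProfile,
    SomaticVariant,
    TierLevel,
    classify_tier,
    filter_coding,
    parse_maf,
    route_patient,
    subtype_gene_panel,
)

HEADER = (
    "Hugo_Symbol\tChromosome\tStart_Position\tReference_Allele\tTumor_Seq_Allele2"
    "\tVariant_Classification\tHGVSp_Short\tSIFT_score\tPolyPhen_score\tCOSMIC_count\n"
)


def maf_row(gene="TP53", pos=100, cls="Missense_Mutation", ref="A", alt="G",
            protein="p.R1W", sift="0.5", poly="0.1", cosmic="0"):
    return f"{gene}\t17\t{pos}\t{ref}\t{alt}\t{cls}\t{protein}\t{sift}\t{poly}\t{cosmic}\n"


def write_maf(path, rows):
    path.write_text(HEADER + "".join(rows))
    return path


def make_variant(**overrides) -> SomaticVariant:
    base = dict(gene_symbol="TP53", chromosome="17", position=100, ref_allele="A",
                alt_allele="G", variant_classification="Missense_Mutation")
    base.update(overrides)
    return SomaticVariant(**base)


class TestParseMaf:
    def test_chunking_does_not_change_content(self, tmp_path):
        path = write_maf(tmp_path / "a.maf", [maf_row(pos=i + 1) for i in range(7)])
        chunks = []
        variants = list(parse_maf(path, chunk_rows=3, _chunk_counter=chunks))
        assert len(variants) == 7
        assert len(chunks) == 3  # 3 + 3 + 1

    def test_zero_position_row_rejected_and_counted(self, tmp_path):
        path = write_maf(tmp_path / "a.maf", [maf_row(pos=0), maf_row(pos=5)])
        counter = MalformedRowCounter()
        variants = list(parse_maf(path, malformed=counter))
        assert [v.position for v in variants] == [5]
        assert counter.count == 1

    def test_large_file_chunk_count_matches_line_oracle(self, tmp_path):
        n_rows = 250_001
        path = tmp_path / "big.maf"
        with open(path, "w") as fh:
            fh.write(HEADER)
            for i in range(n_rows):
                fh.write(maf_row(pos=i + 1))
        # independent oracle: plain text line count
        with open(path) as fh:
            assert sum(1 for _ in fh) - 1 == n_rows
        chunks = []
        variants = sum(1 for _ in parse_maf(path, chunk_rows=100_000, _chunk_counter=chunks))
        assert variants == n_rows
        assert len(chunks) == 3

    def test_streaming_invariance(self, tmp_path):
        rows = [maf_row(pos=i + 1, gene=f"G{i}") for i in range(11)]
        path = write_maf(tmp_path / "a.maf", rows)
        whole = list(parse_maf(path, chunk_rows=10_000))
        unit = list(parse_maf(path, chunk_rows=1))
        assert whole == unit

    def test_missing_file_and_bad_header(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            list(parse_maf(tmp_path / "absent.maf"))
        bad = tmp_path / "bad.maf"
        bad.write_text("foo\tbar\n1\t2\n")
        with pytest.raises(MafFormatError, match="Hugo_Symbol"):
            list(parse_maf(bad))


class TestFilterCoding:
    def test_membership_against_configured_coding_set(self):
        variants = [
            make_variant(variant_classification=c)
            for c in ["Missense_Mutation", "Silent", "Intron", "Nonsense_Mutation"]
        ]
        kept = filter_coding(variants)
        assert [v.variant_classification for v in kept] == [
            "Missense_Mutation", "Nonsense_Mutation",
        ]

    def test_empty_and_identity_cases(self):
        assert filter_coding([]) == []
        all_coding = [make_variant(variant_classification=c)
                      for c in sorted(config.CODING_CLASSIFICATIONS)]
        assert filter_coding(all_coding) == all_coding

    def test_unknown_label_dropped_not_raised(self):
        out = filter_coding([make_variant(variant_classification="Weird_Label")])
        assert out == []


ONCOKB_L1 = ClinicalEvidenceRecord(
    gene_symbol="TP53", source="OncoKB_snapshot", source_level="Level 1",
    cancer_type="Sarcoma",
)
CIVIC_B = ClinicalEvidenceRecord(
    gene_symbol="TP53", source="CIViC_snapshot", source_level="B",
    cancer_type="Lung cancer",
)
ANCESTORS = ["Soft tissue sarcoma", "Sarcoma", "Solid tumor"]


class TestClassifyTier:
    @pytest.mark.parametrize("evidence,variant_kwargs,expected", [
        ([ONCOKB_L1], {}, TierLevel.KNOWN_ACTIONABLE),
        ([], {"cosmic_recurrence": 5}, TierLevel.LIKELY_ACTIONABLE),
        ([], {"sift_score": 0.04}, TierLevel.UNCERTAIN_SIGNIFICANCE),
        ([], {"sift_score": 0.50, "polyphen_score": 0.10}, TierLevel.LIKELY_PASSENGER),
        ([CIVIC_B], {}, TierLevel.LIKELY_ACTIONABLE),
        ([], {"polyphen_score": 0.86}, TierLevel.UNCERTAIN_SIGNIFICANCE),
        ([], {"cosmic_recurrence": 4}, TierLevel.LIKELY_PASSENGER),
    ])
    def test_rule_table(self, evidence, variant_kwargs, expected):
        tier = classify_tier(make_variant(**variant_kwargs), evidence,
                             "Leiomyosarcoma", ANCESTORS)
        assert tier.level == expected
        assert tier.rationale

    def test_tier1_requires_cancer_type_match(self):
        record = ONCOKB_L1.model_copy(update={"cancer_type": "Breast cancer"})
        tier = classify_tier(make_variant(), [record], "Leiomyosarcoma", ANCESTORS)
        assert tier.level != TierLevel.KNOWN_ACTIONABLE

    def test_permutation_invariance(self):
        evidence = [ONCOKB_L1, CIVIC_B,
                    ClinicalEvidenceRecord(gene_symbol="TP53", source="CIViC_snapshot",
                                           source_level="C", cancer_type="Sarcoma")]
        v = make_variant(sift_score=0.01)
        rng = random.Random(3)
        baseline = classify_tier(v, evidence, "Leiomyosarcoma", ANCESTORS).level
        for _ in range(10):
            rng.shuffle(evidence)
            assert classify_tier(v, evidence, "Leiomyosarcoma", ANCESTORS).level == baseline

    @given(
        sift=st.one_of(st.none(), st.floats(0, 1)),
        poly=st.one_of(st.none(), st.floats(0, 1)),
        cosmic=st.integers(0, 10),
        extra_level=st.sampled_from(["Level 1", "Level 3A", "R1"]),
    )
    def test_monotone_in_evidence(self, sift, poly, cosmic, extra_level):
        """Adding an evidence record can only keep the tier or strengthen it."""
        v = make_variant(sift_score=sift, polyphen_score=poly, cosmic_recurrence=cosmic)
        base = classify_tier(v, [CIVIC_B], "Leiomyosarcoma", ANCESTORS).level
        extra = ClinicalEvidenceRecord(
            gene_symbol="TP53", source="OncoKB_snapshot",
            source_level=extra_level, cancer_type="Sarcoma",
        )
        augmented = classify_tier(v, [CIVIC_B, extra], "Leiomyosarcoma", ANCESTORS).level
        assert augmented <= base


class TestRouting:
    def profile(self, mode="A", histology="Leiomyosarcoma"):
        return PatientProfile(patient_id="P1", mode=mode, histology=histology)

    def test_genomic_mode_with_variants(self):
        decision = route_patient(self.profile(), [make_variant()] * 12)
        assert decision.mode == "genomic_mode"
        assert not decision.fusion_assay_recommended

    def test_zero_variants_routes_clinical_only_with_fusion_note(self):
        decision = route_patient(self.profile(), [])
        assert decision.mode == "clinical_only_mode"
        assert decision.fusion_assay_recommended
        assert decision.gene_panel

    def test_mode_b_bypasses_modules_1_2(self):
        decision = route_patient(self.profile(mode="B"), [])
        assert decision.mode == "clinical_only_mode"
        assert decision.modules_1_2_bypassed
        assert not decision.fusion_assay_recommended

    def test_routing_totality(self):
        for mode in ("A", "B"):
            for variants in ([], [make_variant()]):
                decision = route_patient(self.profile(mode=mode), variants)
                assert decision.mode in ("genomic_mode", "clinical_only_mode")


class TestSubtypePanel:
    def test_own_entry_verbatim(self):
        panel, provenance = subtype_gene_panel("Leiomyosarcoma")
        assert panel == list(config.SUBTYPE_GENE_PANELS["Leiomyosarcoma"])
        assert provenance == "Leiomyosarcoma"

    def test_ancestor_walk(self, hierarchy):
        # Well-differentiated liposarcoma has no own panel; parent Liposarcoma does
        ancestors = hierarchy.ancestors("Well-differentiated liposarcoma")
        panel, provenance = subtype_gene_panel("Well-differentiated liposarcoma", ancestors)
        assert panel == list(config.SUBTYPE_GENE_PANELS["Liposarcoma"])
        assert provenance == "ancestor:Liposarcoma"

    def test_unknown_histology_default_panel(self):
        panel, provenance = subtype_gene_panel("angiosarcoma of the scalp")
        assert panel == list(config.DEFAULT_GENE_PANEL)
        assert provenance == "default"

    def test_empty_panel_config_is_error(self):
        with pytest.raises(ValueError):
            subtype_gene_panel("x", panels={}, default_panel=())
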