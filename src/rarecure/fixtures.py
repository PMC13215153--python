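"""Offline fixture generators.

Everything the pipeline reads over the network in a live deployment —
variant files, evidence/drug/trial/abstract snapshots, the subtype
ontology — can be produced here deterministically from a seed, in the same
plain-text formats the real readers consume. The synthetic cohort plants
known-actionable variants and records them in a truth file so tier
recovery is checkable end-to-end; it makes no attempt to replicate real
mutation spectra.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .variant_tiering import PatientProfile

__all__ = [
    "CohortSpec",
    "make_cohort",
    "make_snapshots",
    "ScriptedProvider",
    "ConstantWeightProvider",
    "ScriptExhaustedError",
    "weight_document",
    "DRUG_SYNONYMS",
    "DEFAULT_SUBTYPE_MIX",
]

#: Desk-scale cohort subtype mix, proportional to the validation cohort's
#: published subtype percentages (liposarcoma share assigned to its
#: dedifferentiated subtype; remainder to myxofibrosarcoma).
DEFAULT_SUBTYPE_MIX: dict[str, float] = {
    "Leiomyosarcoma": 0.365,
    "Dedifferentiated liposarcoma": 0.227,
    "Undifferentiated pleomorphic sarcoma": 0.115,
    "Fibromyxosarcoma": 0.081,
    "Malignant fibrous histiocytoma": 0.050,
    "Synovial sarcoma": 0.038,
    "Malignant peripheral nerve sheath tumor": 0.031,
    "Myxofibrosarcoma": 0.093,
}

#: Brand -> generic synonym table used by drug-name normalization.
DRUG_SYNONYMS: dict[str, str] = {
    "gleevec": "imatinib",
    "ibrance": "palbociclib",
    "votrient": "pazopanib",
    "vitrakvi": "larotrectinib",
}

_MAF_HEADER = (
    "Hugo_Symbol\tChromosome\tStart_Position\tReference_Allele\tTumor_Seq_Allele2"
    "\tVariant_Classification\tHGVSp_Short\tt_alt_count\tt_depth"
    "\tSIFT_score\tPolyPhen_score\tCOSMIC_count\n"
)

_BACKGROUND_GENES = (
    "TTN", "MUC16", "OBSCN", "SYNE1", "FLG", "PCLO", "DNAH5", "RYR2",
)
_NONCODING_CLASSES = ("Silent", "Intron", "3'UTR", "5'Flank")
_BASES = ("A", "C", "G", "T")


class CohortSpec(BaseModel):
    n_patients: int = Field(default=20, ge=1)
    subtype_mix: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_SUBTYPE_MIX))
    mean_variants: float = Field(default=8.0, gt=0)
    zero_variant_fraction: float = Field(default=0.20, ge=0.0, le=1.0)
    tier1_plant_rate: float = Field(default=0.25, ge=0, le=1)
    tier2_plant_rate: float = Field(default=0.35, ge=0, le=1)
    seed: int = 0

    @model_validator(mode="after")
    def _mix_sums_to_one(self) -> "CohortSpec":
        total = sum(self.subtype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subtype proportions must sum to 1, got {total}")
        return self


def _random_variant_row(rng: np.random.Generator, gene: str, coding: bool = True,
                        sift: float = 0.5, polyphen: float = 0.1,
                        cosmic: int = 0, protein: str = "") -> str:
    pos = int(rng.integers(1_000, 5_000_000))
    ref = _BASES[rng.integers(0, 4)]
    alt = _BASES[(int(_BASES.index(ref)) + 1 + int(rng.integers(0, 3))) % 4]
    cls = "Missense_Mutation" if coding else _NONCODING_CLASSES[rng.integers(0, len(_NONCODING_CLASSES))]
    depth = int(rng.integers(80, 300))
    alt_count = int(rng.integers(8, depth // 2))
    return (
        f"{gene}\t{int(rng.integers(1, 23))}\t{pos}\t{ref}\t{alt}\t{cls}"
        f"\t{protein}\t{alt_count}\t{depth}\t{sift:.3f}\t{polyphen:.3f}\t{cosmic}\n"
    )


def make_cohort(spec: CohortSpec, out_dir: str | Path) -> tuple[list[Path], list[PatientProfile]]:
    """Write one MAF per patient plus ``truth.json`` recording every planted
    actionable variant and the zero-variant patients.

    Deterministic under ``spec.seed``: same spec twice yields identical
    bytes. Exactly ``round(n * zero_variant_fraction)`` patients get no
    coding variants (their MAF carries only non-coding rows).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    subtypes = list(spec.subtype_mix)
    probs = np.array([spec.subtype_mix[s] for s in subtypes])
    n_zero = int(round(spec.n_patients * spec.zero_variant_fraction))
    zero_ids = set(rng.permutation(spec.n_patients)[:n_zero].tolist())

    maf_paths: list[Path] = []
    profiles: list[PatientProfile] = []
    truth: dict[str, dict] = {}
    for i in range(spec.n_patients):
        pid = f"SYN-{i:03d}"
        subtype = subtypes[rng.choice(len(subtypes), p=probs)]
        profiles.append(PatientProfile(
            patient_id=pid, mode="A", histology=subtype, stage="IV",
            geography="US",
        ))
        planted: list[dict] = []
        rows: list[str] = []
        if i in zero_ids:
            for _ in range(int(rng.integers(1, 4))):
                rows.append(_random_variant_row(rng, _BACKGROUND_GENES[rng.integers(0, len(_BACKGROUND_GENES))], coding=False))
        else:
            if rng.random() < spec.tier1_plant_rate:
                rows.append(_random_variant_row(rng, "KIT", protein="p.V559D",
                                                sift=0.01, polyphen=0.95))
                planted.append({"gene": "KIT", "expected_tier": 1})
            if rng.random() < spec.tier2_plant_rate:
                rows.append(_random_variant_row(rng, "CDK4", protein="p.R24C",
                                                sift=0.02, polyphen=0.90, cosmic=12))
                planted.append({"gene": "CDK4", "expected_tier": 2})
            n_bg = max(1, int(rng.poisson(spec.mean_variants)))
            for _ in range(n_bg):
                rows.append(_random_variant_row(rng, _BACKGROUND_GENES[rng.integers(0, len(_BACKGROUND_GENES))]))
            for _ in range(int(rng.integers(0, 3))):
                rows.append(_random_variant_row(rng, _BACKGROUND_GENES[rng.integers(0, len(_BACKGROUND_GENES))], coding=False))
        path = out_dir / f"{pid}.maf"
        path.write_text(_MAF_HEADER + "".join(rows))
        maf_paths.append(path)
        truth[pid] = {
            "subtype": subtype,
            "zero_coding": i in zero_ids,
            "planted": planted,
        }
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    with open(out_dir / "profiles.jsonl", "w") as fh:
        for prof in profiles:
            fh.write(prof.model_dump_json() + "\n")
    return maf_paths, profiles


# ---------------------------------------------------------------------------
# Knowledge snapshots
# ---------------------------------------------------------------------------

_ONTOLOGY_ROWS = [
    # Level 1 (direct), Level 2 (parent), Level 3 (category), Level 4 (basket)
    ("Myxofibrosarcoma", "Soft tissue sarcoma", "Sarcoma", "Solid tumor"),
    ("Spindle cell sarcoma", "Soft tissue sarcoma", "Sarcoma", "Solid tumor"),
    ("Synovial sarcoma", "Soft tissue sarcoma", "Sarcoma", "Solid tumor"),
    ("Dedifferentiated liposarcoma", "Liposarcoma", "Sarcoma", "Solid tumor"),
    ("Leiomyosarcoma", "Soft tissue sarcoma", "Sarcoma", "Solid tumor"),
    ("Malignant peripheral nerve sheath tumor", "Soft tissue sarcoma", "Sarcoma", "Solid tumor"),
    ("Undifferentiated pleomorphic sarcoma", "Soft tissue sarcoma", "Sarcoma", "Solid tumor"),
    ("Fibromyxosarcoma", "Soft tissue sarcoma", "Sarcoma", "Solid tumor"),
    ("Malignant fibrous histiocytoma", "Soft tissue sarcoma", "Sarcoma", "Solid tumor"),
    ("Well-differentiated liposarcoma", "Liposarcoma", "Sarcoma", "Solid tumor"),
    ("Pleomorphic liposarcoma", "Liposarcoma", "Sarcoma", "Solid tumor"),
]

_EVIDENCE_ROWS = [
    # gene, variant_spec, source, source_level, cancer_type
    ("KIT", "any", "OncoKB_snapshot", "Level 1", "Sarcoma"),
    ("NTRK1", "any", "CIViC_snapshot", "A", "Sarcoma"),
    ("CDK4", "any", "OncoKB_snapshot", "Level 3A", "Solid tumor"),
    ("TP53", "any", "CIViC_snapshot", "B", "Sarcoma"),
]

_DRUG_ROWS: dict[str, list[tuple[str, str, str, str]]] = {
    "OncoKB": [
        ("imatinib", "KIT", "Level 1", "KIT tyrosine kinase inhibitor"),
        ("palbociclib", "CDK4", "Level 3A", "CDK4/CDK6 inhibitor"),
        ("selumetinib", "NF1", "Level 3B", "MEK1/MEK2 inhibitor"),
    ],
    "CIViC": [
        ("larotrectinib", "NTRK1", "B", "NTRK fusion kinase inhibitor"),
        ("olaparib", "TP53", "C", "PARP1/PARP2 inhibitor"),
    ],
    "DGIdb": [
        ("imatinib", "KIT", "interaction", "KIT tyrosine kinase inhibitor"),
        ("pazopanib", "KIT", "interaction", "VEGFR/PDGFR/c-KIT inhibitor"),
        ("everolimus", "MTOR", "interaction", "mTOR inhibitor"),
    ],
    "ChEMBL": [
        ("fap-2286", "FAP", "interaction", "FAP-targeted radioligand therapy"),
        ("palbociclib", "CDK4", "interaction", "CDK4/CDK6 inhibitor"),
    ],
}

_TRIAL_ROWS = [
    {"registry_id": "NCT90000001", "title": "Myxofibrosarcoma-specific targeted study",
     "conditions": ["Myxofibrosarcoma"], "phase": "2", "status": "Recruiting",
     "locations": ["US"], "genomic_keywords": ["TP53"]},
    {"registry_id": "NCT90000002", "title": "Soft tissue sarcoma pazopanib study",
     "conditions": ["Soft tissue sarcoma"], "phase": "3", "status": "Recruiting",
     "locations": ["US", "EU"], "genomic_keywords": ["KIT", "PDGFRA"]},
    {"registry_id": "NCT90000003", "title": "Pan-sarcoma CDK4/6 inhibition",
     "conditions": ["Sarcoma"], "phase": "2", "status": "Recruiting",
     "locations": ["US"], "genomic_keywords": ["CDK4", "MDM2"]},
    {"registry_id": "NCT90000004", "title": "Tumor-agnostic basket study of NTRK inhibition",
     "conditions": ["Solid tumor"], "phase": "3", "status": "Recruiting",
     "locations": ["US"], "genomic_keywords": ["NTRK1", "NTRK2", "NTRK3"]},
    {"registry_id": "NCT90000005", "title": "Completed historical sarcoma study",
     "conditions": ["Sarcoma"], "phase": "3", "status": "Completed",
     "locations": ["US"], "genomic_keywords": []},
]

_ABSTRACTS = [
    ("30000001", "Pazopanib in advanced soft tissue sarcoma",
     "Pazopanib improved progression-free survival in metastatic soft tissue sarcoma across histological subtypes."),
    ("30000002", "CDK4 amplification in dedifferentiated liposarcoma",
     "CDK4 and MDM2 amplification are near-universal in dedifferentiated liposarcoma and support CDK4/6 inhibitor therapy such as palbociclib."),
    ("30000003", "NTRK fusions and larotrectinib in sarcoma",
     "Tumor-agnostic larotrectinib produced durable responses in NTRK fusion positive sarcoma patients enrolled in basket trials."),
    ("30000004", "Neoantigen vaccines for sarcoma",
     "Personalized neoantigen mRNA vaccines are under early-phase investigation in soft tissue sarcoma with encouraging immunogenicity."),
    ("30000005", "FAP-targeted radioligand therapy",
     "Fibroblast activation protein targeted radioligand therapy has shown uptake in sarcoma lesions and is entering clinical evaluation."),
    ("30000006", "Imatinib beyond GIST",
     "Imatinib targets KIT and PDGFRA and retains activity in selected KIT mutant soft tissue sarcoma."),
]


def make_snapshots(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write every offline knowledge input and return a name -> path map.

    Content is fixed curated data (the seed is accepted for interface
    symmetry with the cohort generator; snapshots are identical under any
    seed). The trial snapshot plants one basket trial (NCT90000004) whose
    only condition is "Solid tumor", so it is discoverable exclusively via
    level-4 expansion.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    p = out_dir / "ontology.tsv"
    with open(p, "w") as fh:
        fh.write("level1\tlevel2\tlevel3\tlevel4\n")
        for row in _ONTOLOGY_ROWS:
            fh.write("\t".join(row) + "\n")
        fh.write("__default__\tSoft tissue sarcoma\tSarcoma\tSolid tumor\n")
    paths["ontology"] = p

    p = out_dir / "evidence.tsv"
    with open(p, "w") as fh:
        fh.write("gene_symbol\tvariant_spec\tsource\tsource_level\tcancer_type\n")
        for row in _EVIDENCE_ROWS:
            fh.write("\t".join(row) + "\n")
    paths["evidence"] = p

    for source, rows in _DRUG_ROWS.items():
        p = out_dir / f"{source.lower()}.tsv"
        with open(p, "w") as fh:
            fh.write("drug_name\tgene_symbol\traw_level\tmechanism\n")
            for row in rows:
                fh.write("\t".join(row) + "\n")
        paths[source] = p

    p = out_dir / "trials.jsonl"
    with open(p, "w") as fh:
        for rec in _TRIAL_ROWS:
            fh.write(json.dumps(rec) + "\n")
    paths["trials"] = p

    p = out_dir / "corpus.tsv"
    with open(p, "w") as fh:
        fh.write("pmid\ttitle\tabstract\n")
        for pmid, title, abstract in _ABSTRACTS:
            fh.write(f"{pmid}\t{title}\t{abstract}\n")
    paths["corpus"] = p
    return paths


# ---------------------------------------------------------------------------
# Scripted LLM provider
# ---------------------------------------------------------------------------

class ScriptExhaustedError(RuntimeError):
    pass


class ScriptedProvider:
    """Replays a fixed response list in order; counts calls; raises on
    exhaustion. Stands in for any live model endpoint in tests."""

    def __init__(self, script: list[str]) -> None:
        if not script:
            raise ValueError("script must be non-empty")
        self.script = list(script)
        self.calls = 0

    def complete(self, prompt: str, temperature: float = 0.0) -> str:
        if self.calls >= len(self.script):
            raise ScriptExhaustedError(
                f"scripted provider exhausted after {len(self.script)} calls"
            )
        response = self.script[self.calls]
        self.calls += 1
        return response


class ConstantWeightProvider:
    """Always returns the same in-bounds weight document (the default
    driver provider for cohort runs; context-independent by construction)."""

    def __init__(self, vector: Optional[dict[str, float]] = None) -> None:
        self.vector = vector or {
            "evidence_strength": 0.40, "access_feasibility": 0.15,
            "expected_response": 0.25, "safety_profile": 0.15, "cost": 0.05,
        }
        self.calls = 0

    def complete(self, prompt: str, temperature: float = 0.0) -> str:
        self.calls += 1
        return json.dumps(self.vector)


def weight_document(evidence_strength: float, access_feasibility: float,
                    expected_response: float, safety_profile: float,
                    cost: float) -> str:
    """JSON weight document in the provider contract's schema."""
    return json.dumps({
        "evidence_strength": evidence_strength,
        "access_feasibility": access_feasibility,
        "expected_response": expected_response,
        "safety_profile": safety_profile,
        "cost": cost,
    })
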