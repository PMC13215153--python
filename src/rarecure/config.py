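"""Version-controlled configuration defaults for the pipeline.

Every table here is deliberately plain data (dicts/tuples) so adopting
institutions can override any of it from a single config file without
touching module logic. Values with a clinical provenance (tier rules,
weight bounds, filter thresholds, the supertype panel) are the shipped
operating point of the pipeline; the component scorers and panels are
explicit package defaults.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Variant tiering
# ---------------------------------------------------------------------------

#: GDC MAF dialect Variant_Classification labels counted as coding.
CODING_CLASSIFICATIONS: frozenset[str] = frozenset({
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Nonstop_Mutation",
    "Frame_Shift_Ins",
    "Frame_Shift_Del",
    "In_Frame_Ins",
    "In_Frame_Del",
    "Splice_Site",
    "Translation_Start_Site",
})

#: Default MAF chunk size (rows) for bounded-memory parsing.
MAF_CHUNK_ROWS: int = 100_000

#: OncoKB evidence levels that place a variant in Tier 1 (cancer-type match
#: required) and Tier 2 respectively.
ONCOKB_TIER1_LEVELS: frozenset[str] = frozenset({"Level 1", "Level 2", "R1"})
ONCOKB_TIER2_LEVELS: frozenset[str] = frozenset({"Level 3A", "Level 3B", "3A", "3B"})

#: CIViC evidence levels for Tiers 1 and 2.
CIVIC_TIER1_LEVELS: frozenset[str] = frozenset({"A"})
CIVIC_TIER2_LEVELS: frozenset[str] = frozenset({"B"})

#: Hotspot rule: COSMIC recurrence count at or above this fires Tier 2.
COSMIC_HOTSPOT_MIN: int = 5

#: In-silico deleteriousness rule for Tier 3.
SIFT_DELETERIOUS_MAX: float = 0.05     # strict: sift < 0.05
POLYPHEN_DELETERIOUS_MIN: float = 0.85  # strict: polyphen > 0.85

# ---------------------------------------------------------------------------
# Neoantigen screen
# ---------------------------------------------------------------------------

#: Seven high-population-frequency HLA class I supertype alleles used when
#: patient-specific typing is unavailable (Mode B / missing typing).
SUPERTYPE_PANEL: tuple[str, ...] = (
    "HLA-A*02:01",
    "HLA-A*01:01",
    "HLA-A*03:01",
    "HLA-A*24:02",
    "HLA-B*07:02",
    "HLA-B*08:01",
    "HLA-B*44:02",
)

#: Candidate filters: IC50 strictly below 500 nM, DAI strictly above 1.0,
#: VAF at or above 0.05.
AFFINITY_MAX_NM: float = 500.0
DAI_MIN: float = 1.0
VAF_MIN: float = 0.05

#: Class I peptide lengths tiled across the mutated residue.
PEPTIDE_LENGTHS: tuple[int, ...] = (8, 9, 10, 11)

# ---------------------------------------------------------------------------
# Drug-gene matching
# ---------------------------------------------------------------------------

#: Source raw-level label -> harmonized tier (1 strongest .. 4 weakest).
#: Unmapped labels fall back to Tier 3 with a warning.
SOURCE_LEVEL_TIER_MAP: dict[str, dict[str, int]] = {
    "OncoKB": {
        "Level 1": 1, "Level 2": 1, "R1": 1,
        "Level 3A": 2, "Level 3B": 2, "3A": 2, "3B": 2,
        "Level 4": 3, "4": 3,
    },
    "CIViC": {"A": 1, "B": 2, "C": 3, "D": 3, "E": 3},
    "DGIdb": {"interaction": 3},
    "ChEMBL": {"interaction": 3},
}

#: Default tier for sources that carry no clinical evidence labels.
UNCURATED_INTERACTION_TIER: int = 3

#: Concurrency / cache contract shared by the drug and trial query layers.
CONCURRENCY_LIMIT: int = 10
CACHE_TTL_SECONDS: float = 3600.0
CACHE_MAX_ENTRIES: int = 2000

# ---------------------------------------------------------------------------
# Trial matching
# ---------------------------------------------------------------------------

#: Relevance-score component weights (sum to 1).
RELEVANCE_WEIGHTS: dict[str, float] = {
    "genomic": 0.35,
    "phase": 0.30,
    "histology": 0.20,
    "geography": 0.15,
}

#: Default phase component scores.
PHASE_SCORES: dict[str, float] = {
    "3": 1.0, "4": 1.0, "2": 0.66, "1": 0.33, "NA": 0.0,
}

#: Trial statuses allowed into the ranking.
RECRUITING_STATUSES: frozenset[str] = frozenset({
    "Recruiting", "Enrolling by invitation", "Not yet recruiting",
})

# ---------------------------------------------------------------------------
# Evidence retrieval
# ---------------------------------------------------------------------------

CHUNK_WINDOW_TOKENS: int = 512
CHUNK_OVERLAP_TOKENS: int = 0
RETRIEVE_TOP_K: int = 5
RETRIEVE_COSINE_THRESHOLD: float = 0.65
EMBEDDING_DIM: int = 64  # bundled hashed bag-of-words embedder

# ---------------------------------------------------------------------------
# Orchestration and scoring
# ---------------------------------------------------------------------------

#: Ordered scoring dimensions; all weight vectors follow this order.
WEIGHT_DIMENSIONS: tuple[str, ...] = (
    "evidence_strength",
    "access_feasibility",
    "expected_response",
    "safety_profile",
    "cost",
)

#: Clinically informed per-dimension (lower, upper) clamp bounds.
DEFAULT_WEIGHT_BOUNDS: dict[str, tuple[float, float]] = {
    "evidence_strength": (0.05, 0.60),
    "access_feasibility": (0.05, 0.40),
    "expected_response": (0.05, 0.50),
    "safety_profile": (0.03, 0.40),
    "cost": (0.02, 0.35),
}

#: Weight elicitation contract: number of samples, sampling temperature,
#: per-sample retry cap on malformed provider output, and the minimum
#: number of parseable samples for a valid median.
WEIGHT_SAMPLES: int = 5
WEIGHT_TEMPERATURE: float = 0.3
WEIGHT_RETRY_CAP: int = 2
WEIGHT_MIN_VALID: int = 3

#: Multiplicative novelty bonus applied to the weighted component sum.
NOVELTY_BONUS: float = 0.15
COMPOSITE_CAP: float = 1.0

#: Mechanism classes treated as novel (config-driven; substring match on the
#: option's mechanism text, case-insensitive).
NOVEL_MECHANISM_CLASSES: tuple[str, ...] = (
    "radioligand",
    "mrna vaccine",
    "neoantigen vaccine",
    "car-t",
    "bispecific",
)

#: Component scores derived from the harmonized evidence tier.
TIER_EVIDENCE_SCORES: dict[int, float] = {1: 1.0, 2: 0.75, 3: 0.5, 4: 0.25}

#: Component scores derived from the regulatory access pathway.
ACCESS_PATHWAY_SCORES: dict[str, float] = {
    "standard prescription": 1.0,
    "clinical trial": 0.7,
    "off-label with compendium support": 0.5,
    "compassionate use": 0.3,
}

#: Neutral default for component scores with no configured table entry.
NEUTRAL_COMPONENT_SCORE: float = 0.5

#: Prior-treatment outcomes that exclude an agent from the dossier.
FAILED_OUTCOMES: frozenset[str] = frozenset({"progression", "failed"})

#: ReAct loop iteration cap (tool steps before forced truncation).
REACT_ITERATION_CAP: int = 16

# ---------------------------------------------------------------------------
# Clinical-only mode: curated subtype gene panels
# ---------------------------------------------------------------------------

#: Frequently mutated / NCCN-recognized molecular targets per subtype.
#: Lookup walks the trial ontology toward ancestors when a subtype has no
#: entry of its own; the pan-sarcoma default is the terminal fallback.
SUBTYPE_GENE_PANELS: dict[str, tuple[str, ...]] = {
    "Leiomyosarcoma": ("TP53", "RB1", "PTEN", "ATRX", "MED12"),
    "Dedifferentiated liposarcoma": ("CDK4", "MDM2", "FRS2", "HMGA2"),
    "Liposarcoma": ("CDK4", "MDM2", "HMGA2"),
    "Synovial sarcoma": ("SS18", "SSX1", "SSX2", "PTEN"),
    "Malignant peripheral nerve sheath tumor": ("NF1", "SUZ12", "EED", "CDKN2A"),
    "Undifferentiated pleomorphic sarcoma": ("TP53", "RB1", "ATRX", "PDGFRA"),
    "Soft tissue sarcoma": ("TP53", "RB1", "CDK4", "MDM2", "NF1"),
}

#: Pan-sarcoma default panel when neither the subtype nor any ancestor has a
#: curated entry.
DEFAULT_GENE_PANEL: tuple[str, ...] = (
    "TP53", "RB1", "CDK4", "MDM2", "ATRX", "PTEN", "NF1", "KIT", "PDGFRA",
)

#: Coarse geography regions considered "local" per patient region label.
#: geography component = 1 if any trial location falls in the patient's
#: region set, else 0.
REGION_TABLE: dict[str, tuple[str, ...]] = {
    "US": ("US", "United States", "USA", "North America"),
    "EU": ("EU", "Europe"),
    "APAC": ("APAC", "Asia", "Australia"),
}
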