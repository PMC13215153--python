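# Methods

This note documents the models, rules, and numerical choices behind each
module, the defaults that matter, what the synthetic fixtures do and do not
emulate, and the design decisions taken where the design was genuinely open.

## Variant tiering

Somatic variants arrive as MAF (GDC dialect, 1-based inclusive coordinates)
or VCF 4.x (converted on read). MAF files are parsed in 100,000-row chunks
so peak memory is bounded by one chunk regardless of file size; malformed
rows are skipped and counted, never fatal, and with no threshold — a
corrupt row should cost one variant, not an entire multi-gigabyte run.
Chunking is content-neutral: output is identical for any chunk size ≥ 1.

Coding variants (Missense, Nonsense, Nonstop, Frame_Shift_Ins/Del,
In_Frame_Ins/Del, Splice_Site, Translation_Start_Site in the GDC
`Variant_Classification` vocabulary) are classified into four harmonized
evidence tiers, rules firing in strict order:

1. **Tier 1 — known actionable.** OncoKB Level 1/2/R1 or CIViC Level A
   evidence whose cancer type matches the patient's histology *or any of
   its ontology ancestors*. The ancestry relation is a deliberate choice:
   a record curated against "Sarcoma" should match a leiomyosarcoma
   patient, mirroring the same hierarchy the trial-expansion module uses.
2. **Tier 2 — likely actionable.** OncoKB Level 3A/3B, CIViC Level B (no
   cancer-type match required — the match requirement is stated only for
   the strongest tier), or a COSMIC hotspot (recurrence ≥ 5).
3. **Tier 3 — uncertain significance.** Predicted deleterious in silico
   (SIFT < 0.05 or PolyPhen-2 > 0.85) without *actionable* clinical
   evidence. "Actionable" is the operative word: a weak record (e.g. CIViC
   C) does not demote a deleterious variant to Tier 4. This keeps the
   classifier monotone — adding an evidence record can only keep the tier
   equal or strengthen it — which is the property audits care about.
4. **Tier 4 — likely passenger.** Everything else. Missing SIFT/PolyPhen
   scores are treated as non-deleterious (the Tier 3 rule cannot fire), a
   conservative default toward Tier 4; absent COSMIC counts are 0.

Patients with zero retained coding variants (or Mode B profiles, which
carry no variant file at all) are routed to clinical-only mode. Zero-variant
Mode A patients additionally get a fusion-detection assay recommendation,
since fusions — the defining lesion of several sarcoma subtypes — are
invisible to a point-mutation MAF. Clinical-only matching runs against a
curated subtype gene panel, resolved subtype → nearest ontology ancestor →
pan-sarcoma default. The shipped panels are package defaults assembled from
well-known subtype drivers (CDK4/MDM2 for liposarcoma, NF1/SUZ12/EED for
MPNST, …), not a curated clinical product.

## Neoantigen screen

HLA context resolution is dual: patient typing, when supplied in Mode A,
gives a personalized context; otherwise the screen falls back to seven
high-population-frequency class I supertype alleles (A\*02:01, A\*01:01,
A\*03:01, A\*24:02, B\*07:02, B\*08:01, B\*44:02) and sets a mandatory
warning flag that propagates to every downstream candidate — supertype
predictions are population surrogates, not the patient's immunogenetics.

Candidate peptides are 8–11-mers tiled across the substituted residue; the
wildtype counterpart reverts the single substitution (indels have no
wildtype counterpart and are excluded from DAI). Binding prediction goes
through a two-method predictor contract (`ic50(peptide, allele)`) so
NetMHCpan-class or MHCflurry-class backends can be wired in; the bundled
mock derives IC50 deterministically from a SHA-256 hash of
`peptide|allele` scaled into [10, 5000] nM, making the whole screen
reproducible offline. The differential agretopicity index is the plain
ratio DAI = wildtype IC50 / mutant IC50 (> 1 ⇔ the mutant binds more
strongly; a log-ratio variant exists in the literature but the plain ratio
matches the "above 1.0 passes" framing used here). Filters are applied
per-candidate — each (peptide, allele) pair stands alone — with exact
boundary sides: IC50 strictly < 500 nM, DAI strictly > 1.0, VAF ≥ 0.05.

## Drug–gene matching

Four sources (DGIdb, CIViC, OncoKB public tier, ChEMBL) are queried behind
adapter contracts. The shipped adapters load tab-separated snapshots once
into memory — zero network activity per patient; harmonization totality
over each snapshot's label set is checked at load, so label problems
surface as configuration errors rather than mid-cohort. Queries run
concurrently under a semaphore capping in-flight requests at 10, with a
thread-safe TTL cache (one-hour expiry, 2000 entries, least-recently-
written eviction) keyed on (source, gene).

Raw labels harmonize through a versioned mapping (OncoKB 1/2/R1 → Tier 1,
3A/3B → Tier 2; CIViC A → 1, B → 2, C/D/E → 3; uncurated DGIdb/ChEMBL
interactions → Tier 3; unmapped labels → Tier 3 with a warning).
Deduplication is by normalized (drug, gene) pair — case-fold, trim, and a
brand/generic synonym table — keeping the strongest tier; every pair whose
duplicates span more than one tier emits a conflict record for audit. The
operation is permutation-invariant by construction (value-based grouping
and tie-breaks), which the property suite asserts.

## Trial matching

Every subtype query expands to exactly four terms through the cancer-type
hierarchy (direct → parent histology → category → basket/"solid tumor");
unknown subtypes use a default fallback chain with the input term at level
1. The shipped hierarchy covers 11 sarcoma subtypes. Trials matching
several levels are kept once, tagged with the narrowest level, so the
merged set over levels 1..k grows monotonically in k — the property that
makes basket trials reachable without drowning direct matches.

Relevance is a weighted sum, weights validated to sum to 1 at load:
0.35·genomic + 0.30·phase + 0.20·histology + 0.15·geography. The component
scorers are package defaults (the weighting scheme fixes only the weights):
genomic = fraction of the patient's Tier 1–3 genes named by the trial (any
panel hit counts fully in clinical-only mode); phase ∈ {Phase 3/4: 1.0,
Phase 2: 0.66, Phase 1: 0.33, NA: 0}; histology = 1/match-level (a basket
match at level 4 scores 0.25 against a direct match's 1.0); geography = 1
iff any trial location falls in the patient's coarse region. All four are
config-replaceable. Only recruiting-type statuses enter ranking; ties break
on registry id so ranking is independent of snapshot record order.

## Evidence retrieval and citation grounding

Abstracts are chunked at 512 tokens with no overlap (overlap is exposed in
config but defaults to 0); chunking is lossless at the token level. "Token"
is whatever the configured embedder's tokenizer says: the bundled embedder
tokenizes on whitespace and embeds each chunk as a 64-dimensional signed
hashed bag-of-words vector, L2-normalized — deterministic, offline, and
adequate for exercising the retrieval contract; it does not model
semantics, and no retrieval-quality claim rests on it. Retrieval returns
the top five chunks by cosine similarity among those at or above 0.65,
threshold applied before truncation (both constraints bind), ties broken
by (PMID, chunk index).

Grounding is the module's hard guarantee: a claim is retained iff it cites
at least one PMID and every cited PMID is in the retrieval set; everything
else is excluded with a recorded reason. The property suite asserts
soundness on all pipeline outputs: no retained claim ever cites an
un-retrieved PMID.

## Orchestration: adaptive weights inside deterministic bounds

The ranking weights over five dimensions (evidence strength, access
feasibility, expected response, safety profile, cost) are elicited from an
LLM provider contract — one `complete(prompt, temperature)` method, so
cloud, local, and scripted mock providers are interchangeable and the
pipeline logic is identical across them. Five samples are drawn at
temperature 0.3 and the element-wise median taken; the median makes a
single aberrant sample per dimension irrelevant. Malformed responses are
re-requested up to 2 retries, then dropped; fewer than 3 valid samples is
an elicitation failure and the finalizer falls back to the midpoint of
each bound range (clamped and renormalized, with an audit note).

The median vector is then finalized by Euclidean projection onto the
box-intersected simplex {w : Σw = 1, lᵢ ≤ wᵢ ≤ uᵢ} with shipped bounds
evidence 0.05–0.60, access 0.05–0.40, response 0.05–0.50, safety
0.03–0.40, cost 0.02–0.35 (feasible: Σl = 0.20 ≤ 1 ≤ Σu = 2.25, checked at
load). The projection solves wᵢ = clip(rawᵢ − τ, lᵢ, uᵢ) with τ found by
bisection on the monotone sum constraint (scipy `brentq`, xtol 1e-13; the
residual ~1e-13 is absorbed into unclipped coordinates so bounds hold
exactly and the sum is 1 to machine precision). Euclidean projection was
chosen as the redistribution semantics because it is the canonical
"smallest admissible correction" operator, it is idempotent, and it
reproduces the expected boundary behavior: a degenerate safety-only
proposal (1, 0, 0, 0, 0 in safety position) finalizes at safety = 0.40
(its upper bound) with the remaining 0.60 spread equally (0.15 each)
within bounds. The `clamped` audit flag is set iff a box bound actually
clips a coordinate; the constant shift that redistributes mass for an
in-bounds proposal does not count as clamping — so a provider emitting
well-formed in-bounds weights yields a 0% trigger rate, which is exactly
the audit semantics wanted: the flag marks interventions, not bookkeeping.
The property suite checks the projection against an independent SLSQP
constrained-optimization oracle on 10⁴ random vectors (agreement < 1e-6).

Composite option score: min(1.0, (Σ wᵢ·cᵢ) · (1 + 0.15·[novel])), capped,
monotone in every component. Novelty is a config-driven mechanism-class
list (radioligand, mRNA/neoantigen vaccine, CAR-T, bispecific). Component
scores cᵢ are package defaults: evidence strength from tier (1.0 / 0.75 /
0.5 / 0.25), access feasibility from pathway (standard 1.0, trial 0.7,
off-label 0.5, compassionate 0.3), and neutral 0.5 for the dimensions with
no configured table. Agents matching a prior therapy that progressed or
failed are excluded (response/stable priors stay eligible), with synonym-
aware name matching.

The ReAct loop alternates provider-proposed thought/action documents with
tool invocations; Mode B profiles never execute the genomic-input tools;
unknown tools are re-prompted once then skipped with a trace note; an
iteration cap bounds the loop. Traces use a monotonic step counter — no
wall clock — so scripted runs are bit-reproducible. Dossiers rank options
by composite (ties: stronger tier, then agent name) and are emitted as
JSON and Markdown, labeled investigational, for clinician review.

## Reporting

Proportions carry exact Clopper–Pearson 95% intervals via the
beta-quantile characterization (lower = B(α/2; s, n−s+1), upper =
B(1−α/2; s+1, n−s); 0%/100% at the boundaries), reported to one decimal.
The unit test cross-checks against a brute-force binomial-tail inversion
on a 10⁻⁴ grid. The cohort report recomputes every percentage from raw
counts; per-agent counts attribute each Tier 1/2 patient once, to their
highest-tier agent, so the agent counts sum to the Tier 1/2 count by
construction.

## Synthetic fixtures: what they exercise and what they do not

The fixture cohort defaults to 20 patients — a desk-scale problem size
chosen so the full suite runs in seconds — with a subtype mix proportional
to the published composition of the reference sarcoma cohort, a default
20% zero-coding-variant fraction (mirroring that cohort's clinical-only
share), and per-patient variant counts drawn around a Poisson mean of 8.
Known-actionable variants are planted (KIT with Tier 1 evidence, CDK4 as a
COSMIC hotspot) and recorded in a truth file, so tier recovery is
checkable end-to-end; recovery is 100% by test. All generators are pure
functions of the seed (identical bytes on identical specs).

The fixtures exercise logic, not biology: mutation positions and alleles
are random, background genes are the usual long-gene passengers, no
mutational signatures, no subtype-specific spectra, no real trial or
literature content. Passing tests therefore demonstrate that the
machinery — parsing, tiering, harmonization, expansion, grounding,
clamping, reporting — behaves as specified, not that the pipeline's
clinical yield on real cohorts is reproduced. Real-cohort rates depend on
live knowledge-base versions and a real LLM, both outside this package's
test envelope.

## Known limitations

- The bundled embedder is a term-hashing device; retrieval quality with a
  semantic embedder is untested here.
- Clinical-only matching treats panel genes as first-class match evidence;
  it cannot distinguish a panel-derived match from a sequenced one except
  by the biomarker-matched flag.
- Single agents only: no combination regimens, toxicity overlap, or
  drug–drug interaction modeling.
- Live HTTP adapters for the drug and trial sources are documented
  contracts, not shipped implementations; snapshots are the supported
  path.
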