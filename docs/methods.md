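# Methods

## Pipeline model

The package treats vocabulary construction as a case–control enrichment
problem at the *patient* level. A concept (UMLS CUI) is a candidate ASD
phenotype term when the odds of a patient's HQ notes containing it are
substantially higher in the ASD cohort than in controls:

    OR(C1 vs C2) = [f1 (1 − f2)] / [f2 (1 − f1)],
    f = (# patients of the cohort with ≥ 1 mention) / (cohort size).

Two comparisons are computed — ASD vs non-psychiatric and ASD vs
psychiatric (non-ASD) — because psychiatric controls share much of the
behavioral vocabulary (e.g. "aggressive behavior"): a term enriched only
against the non-psychiatric cohort is likely a general psychiatric term,
not an ASD term. The filter's default mode therefore applies the `> 1.5`
cutoff to both ratios; `nonpsych_only` reproduces the single printed
cutoff. The cutoff is strict (`> 1.5`, not `≥`). Frequencies on the 2×2
patient table make the frequency form of the OR identical to the
cross-product `ad/bc`; when a boundary cell is zero the Haldane–Anscombe
correction (+0.5 to every cell) is applied and flagged, since the ratio is
otherwise infinite or undefined. No confidence intervals or p-values are
attached: the filter is a screening step, not an inference procedure.

Statistical enrichment alone is noisy, so surviving candidates are
validated semantically: a candidate is accepted when its embedding cosine
similarity to at least one gold-standard seed term is strictly greater
than 0.5. Accepted novel terms receive IDs `ASD0001…` in sorted
(CUI, surface) order; seed terms keep `S`-prefixed IDs.

## Embedding provider

The built-in provider hashes character trigrams of the normalized term
(lowercase, collapsed whitespace, padded with two spaces) into 4096
buckets via CRC-32, then projects the count vector to 700 dimensions with
a Gaussian random projection drawn from a fixed seed, and L2-normalizes.
Properties that matter here: it is fully deterministic across processes
and platforms, identical strings embed identically, and lexical overlap
(shared trigrams) translates into cosine similarity, which is what the
seed-list validation and criterion mapping need. It does **not** capture
distributional semantics: true synonyms with disjoint spellings score low.
For fidelity runs, `PrecomputedEmbedding` accepts a `term → vector` TSV
produced by any sentence-embedding model; one provider instance serves
both the validation step and the DSM-5 criterion mapping.

## Clustering

Each patient's HQ notes form one document. The default matrix is binary
(term present/absent); mention counts are available via `mode="count"`.
tf-idf uses the natural logarithm (`ln(N/df)`): the base is a documented
constant, and terms present in every patient get exact weight zero while
terms present in none are dropped with a log line rather than propagating
NaNs. When more patients are available than requested, the
"most informative" subset is selected by ranking patients on the number
of distinct validated terms in their notes (ties by patient ID).

NMF is implemented as multiplicative updates minimizing the Frobenius
objective from a fixed-seed nonnegative random start, recording the
objective every iteration (it is non-increasing, and a test asserts this
per iteration; sklearn's MU solver serves as an independent cross-check
of the attained objective). Defaults: `a = 8` components, `max_iter =
300`, relative tolerance `1e-6`, damping epsilon `1e-12` in the update
denominators. The factorization operates on the tf-idf-weighted matrix by
default (`factorize_tfidf=False` switches to the raw matrix). Cluster
assignment is `argmax` over the patient's loadings — deterministic and
testable, unlike manual reading of a scatter plot; ties break to the
lowest component index and all-zero rows are assigned component 0 and
flagged. t-SNE (fixed seed, PCA initialization) is a visualization aid
only; no result depends on its geometry beyond determinism and coarse
neighborhood preservation.

## DSM-5 mapping and the diagnostic rule

Each criterion carries a list of descriptor phrases (packaged as an
editable TSV fixture paraphrasing criterion language — replaceable data,
not code). A term maps to the criterion with the highest best-phrase
cosine; ties break in canonical order A1 < A2 < A3 < B1 < B2 < B3 < B4 <
E. There is no similarity floor by default (every term gets an argmax);
an optional `min_score` maps weak terms to no criterion. A patient
manifests a criterion when at least one of their mentions resolves (by
CUI) to a terminology node descending from that criterion's node —
transitive descendants, not direct children. The diagnostic rule is
`A1 ∧ A2 ∧ A3 ∧ (≥ 2 of B1–B4)`; criterion E participates in mapping and
the ontology but not in the rule. Exactly 11 of the 128 presence
patterns satisfy it.

## Ontology

A single `is_a` hierarchy in the OBO Foundry style: level 1 the root
"ASD"; level 2 the three domains (social interaction, repetitive
behavior, ASD and comorbidities); level 3 the sub-criteria; level 4 the
criterion descriptor phrases; level 5 the validated terminology, each
term attached to the phrase(s) it scores highest against (many-to-many
allowed; every link spans exactly one level). Node IRIs are
`http://purl.example.org/asd-phenotype#<node_id>`. RDF/XML and OWL2
writers emit node properties as annotation properties; the reader is
tolerant (unknown annotations are preserved in an `extras` map). JSON
output is canonical (sorted nodes and keys) and byte-stable under
round-tripping. `validate_ontology` checks the root/level-2 contract,
single-level links, acyclicity, root reachability and level-5 property
completeness, reporting violations rather than raising.

## Synthetic corpus

The generator is the package's study scenario, not an afterthought:

- **Cohorts.** Defaults 2000/2000/2000 (ASD / psychiatric / non-
  psychiatric), male fraction 0.8 in all cohorts (controls are matched),
  diagnosis age uniform over 18–216 months for diagnosed cohorts.
- **Visits.** Negative binomial, mean 15, shape 5 — so the <10-visit QC
  rule removes a predictable tail (~25% of patients). A visit is a
  distinct note date; clean note dates are drawn without replacement
  within ±300 days of diagnosis, inside the 365-day QC window.
- **Notes.** Filler vocabulary deliberately disjoint from every token of
  every lexicon surface form, with planted surface forms inserted whole;
  clean notes have 110 + Poisson(60) filler tokens, always above the
  100-word QC floor. Consequently the ledger of planted mentions is an
  exact oracle for the extractor (recall and precision 1.0 by
  construction). No grammar, negation or de-identification artifacts are
  modeled — the extractor is dictionary-based, so surface fidelity is the
  only property that matters; passing tests say nothing about NER quality
  on real clinical language.
- **QC noise.** Per patient, Binomial(v, 0.05) short filler-only notes
  (< 100 words), exact-copy duplicates, and (for diagnosed patients)
  fully sampled notes dated 400–700 days off-diagnosis. Flags are
  recorded per note so QC tests can assert that exactly the injected
  noise (plus low-visit patients' notes) is removed.
- **Planted rates.** ~40 DSM-5-labeled terms with per-note inclusion
  rates elevated in ASD (0.03–0.20 vs ~0.01 in psychiatric and ~0.001 in
  non-psychiatric cohorts), psychiatric confounders with the gradient
  reversed, ubiquitous terms with identical rates (planted OR ≈ 1,
  negative controls), one ASD-enriched term lexically far from every gold
  seed (exercises validation rejection), one off-whitelist pair and one
  CUI-less surface (exercise the semantic and mapping filters). With ~15
  notes per patient, per-note rates saturate to patient-level presence
  probabilities `1 − (1−r)^k`; the ledger exposes the exact per-patient
  probabilities for binomial oracles.
- **Subgroups.** Four latent ASD subgroups drawn uniformly. Three carry a
  5-term signature block (B1, B3 or B4 respectively) whose per-note rate
  is multiplied by 8 in the signature subgroup and 0.25 elsewhere
  (≈ 0.99 vs ≈ 0.11 patient-level presence); the fourth is a baseline
  with no signature, which (like a real mixed cluster) tends to
  sit among psychiatric controls. tf-idf naturally up-weights the
  signature terms (df ≈ one subgroup), which is what makes `argmax`-NMF
  recovery work: adjusted Rand index ≥ 0.8 against the planted labels in
  ≥ 9 of 10 seeds at 2000 + 2000 patients, and ≈ 0 when the multipliers
  are flattened to 1.

## Problem sizes and numerical choices

Test and demonstration runs use scaled-down corpora chosen as the
smallest sizes at which the statistical claims are comfortably away from
their thresholds: 60 patients/cohort for unit-level oracles, 150–300 for
end-to-end runs, 2000 + 2000 for subgroup recovery, 5000/cohort for term-filter recovery, 20,000 for the
demographic ratio (binomial s.e. ≈ 0.28% at n = 20,000). Determinism is
end-to-end: one global seed fans out to per-stage seeds through
`SeedSequence` spawn keys, the corpus is byte-identical per seed, and the
embedding projection uses its own fixed constant so vectors never vary
across runs or seeds.

## Known limitations

- The dictionary extractor cannot find terms absent from the lexicon;
  discovery of novel surface forms (in the original workflow, a
  fine-tuned neural NER) is out of scope — its output is ingested via
  `import_alias_list`.
- The trigram embedding validates lexical, not semantic, similarity;
  with a real embedding model the 0.5 threshold has different operating
  characteristics.
- Odds ratios are unadjusted for demographics and multiplicity; the
  filter is a screen, not a test.
- The criterion phrase fixture approximates guideline language; mapping
  quality on user vocabularies depends on replacing it with a curated
  list.
- QC applies the word-count rule to whole retained notes; section-level
  splitting of mixed notes is not modeled (the department field carries a
  coarse pre-filter instead).
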