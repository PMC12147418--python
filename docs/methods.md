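# Methods

## The retrieval model

The system is the retrieval stage of a case-based reasoning cycle: it
recalls stored maxillectomy cases whose documented oral condition resembles
a new case and presents their delivered obturator designs for clinician
review.  There is no adaptation, revision or retention stage — reuse of a
retrieved design is a human decision, and the case base is curated
externally.

A stored case is a flat keyword record: `case_id`, Aramany class, a map of
categorical attributes, and paths to the design images (polished and
intaglio composite).  A query is the same attribute map produced by the
questionnaire.  The Aramany class acts as a hard candidate filter — only
same-class cases are scored — because defect topology differs too much
across classes for attribute-level comparison to be meaningful.  The class
is therefore *not* a weighted attribute.

### Confidence score

For query `q` and stored case `c` of the same class, let `K` be the
*comparable* set — attributes present in both records — and `M ⊆ K` those
with equal values.  Then

    confidence(q, c) = Σ_{k∈M} w_k / Σ_{k∈K} w_k  ∈ [0, 1].

Keys absent from either record are excluded from numerator and denominator
alike: the skip logic makes attribute sets legitimately case-dependent
(e.g. `bounded_space_location` exists only when bounded spaces exist), and
penalising a key that could not have been asked would conflate schema
structure with clinical dissimilarity.

Weights come in two kinds:

* **Fixed weights** — default 1.0 per attribute, overridable per
  (class, key) through a YAML/JSON config.
* **Share weights** — `remaining_molar_count` and
  `both_premolars_present` (and their Class VI side-suffixed variants)
  weigh a fixed *fraction* (default 0.05) of the total comparable weight
  instead of a fixed amount.  Equivalently, with `S` the fixed-weight total
  and a single comparable share key, that key's materialised weight is
  `0.05·S/0.95 = S/19`.

The share construction is what makes the calibration exact on *every*
branch of the schema: a case agreeing with the query everywhere except the
remaining-molar count scores exactly `1 − 0.05 = 0.95` whether the
comparable set has five keys or ten, which a fixed absolute weight cannot
achieve once skip logic varies the comparable set.  Full agreement scores
exactly 1.0, and (with the all-positive default weights) only full
agreement does.  These two anchor values — 1.0 and 0.95 — are what
`scripts/acceptance.py` recomputes.

Ranking sorts by descending confidence with ties broken by ascending
`case_id`, making retrieval invariant to the case base's row order.  The
default `k` is 5 retrieved designs (configurable; the precision curve is
typically examined to k = 15), and a retrieved design is flagged *eligible*
when its confidence is **strictly** above the threshold (default 0.90),
reading "above" literally.

## The questionnaire and schemas

Each Aramany class has an ordered attribute schema; conditional items carry
predicates over earlier answers only, so the interview is a single
front-to-back walk and `next_question` is the first unanswered applicable
item.  Question order: class → abutments → defect extension → abutment
condition → bounded spaces → oronasal connection → class-specific
follow-ups.  Skip logic in force:

| condition | consequence |
|---|---|
| `bounded_space_count = none` | location (and distribution) not asked |
| class ∈ {I, IV} | `bounded_space_distribution` never asked (teeth on one side only) |
| class ∉ {II, VI} | `defect_extension` never asked (evident from the class) |
| Class II, nearest abutment anterior | `defect_side_remaining_teeth` skipped |
| Class III, arch not a distal extension | `posterior_abutments` skipped |
| last tooth a premolar | `both_premolars_present` asked |
| last tooth a molar | `remaining_molar_count` asked |
| Class VI | abutment questions and their follow-ups asked once per side (right first) |

Teeth are recorded as FDI two-digit maxillary codes (11–18, 21–28); tooth
type (incisor/canine/premolar/molar) and anterior/posterior status are
derived from the position digit, which is what the skip predicates consume.
Class III is described through the dental-arch classification (bilateral /
unilateral distal extension, bounded saddle, intact arch) plus bounded
spaces and oronasal size, with no defect-bordering abutment questions,
since the central palatal defect spares the dentition.  The condition of
the nearest abutment is asked once (for Class VI, once for the whole case),
as a single categorical token (healthy / periodontally compromised / weak
lateral incisor / overdenture root).

Controlled vocabularies are enforced everywhere: at interview time (answers
must be among the question's choices), at case-base load time, and in
`validate_case`, whose issues distinguish missing required keys,
inapplicable keys, unknown keys and out-of-vocabulary values.  The
vocabularies are a reconstruction of the clinical keyword set this kind of
database uses; they are not claimed to match any particular hospital's
spreadsheet spellings.

Interview states are immutable and answers are accepted only for the
currently pending question, which gives two useful guarantees: identical
transcripts always produce identical queries, and a transcript containing
an answer for a skipped question is rejected rather than silently absorbed.

## Synthetic data

`GeneratorConfig` defaults define the reference study conditions: 209
stored cases, class probabilities (0.35, 0.30, 0.07, 0.10, 0.08, 0.10) for
classes I–VI (a Class I/II-dominated mix typical of obturator databases;
the exact proportions are configuration, not a claim about any hospital's
distribution), 33 test queries, k = 5.  Attribute values are drawn
uniformly from each key's vocabulary by walking the schema, so every
generated record is schema-valid by construction.  Everything is
deterministic given the seed, down to byte-identical CSV output.

Test queries are made by perturbing a stored case: exactly `n` attributes
are flipped to different in-vocabulary values chosen so that no skip-logic
outcome changes (flips that would add or remove applicable keys are passed
over).  For a fixed seed the flipped key sets are nested in `n`, so
confidence against the source case is non-increasing in the perturbation
count.  Evaluation sets draw source cases without replacement, perturb each
by a uniform 0..3 flips (capped at the case's feasible flip count), and run
retrieval against the case base *with the source case removed*, emulating
held-out test cases.

Relevance labels are Bernoulli draws with logistic link
`P(relevant) = sigmoid(intercept + slope · confidence)`.  Because attribute
values are drawn independently, same-class synthetic cases are mutually
dissimilar and retrieved confidences concentrate around 0.3–0.65 — unlike a
real database, where same-class patients resemble each other and
confidences cluster near 1.  The default link (intercept −5.5, slope 12)
spans that realized range, rising from ≈0.13 at confidence 0.3 to ≈0.9 at
0.65; `slope = 0` gives a null link for calibration checks.  Consequences
to keep in mind when reading test results: synthetic runs exercise the
*machinery* (scoring, ranking, skip logic, statistics) under a known
generative link, but say nothing about real-world precision or the real
confidence distribution, both of which depend on clinical similarity
structure the generator deliberately does not model (no anatomical
covariance between attributes, no association between oral condition and
design).

## Evaluation statistics

* `precision@k` = (relevant among first k) / k, per test case;
  `precision_curve` reports the across-case **median** at each k, with
  samples shorter than k truncated (contributing only up to their own
  length) and flagged with a warning.
* `mean_top_confidence` is the arithmetic mean of the first k confidences.
* `spearman` uses mid-rank (average-rank) assignment with Pearson
  correlation of the ranks — exact under ties — backed by
  `scipy.stats.spearmanr`; the p-value is the usual t-approximation with
  n − 2 degrees of freedom, standard at n ≈ 33.  A permutation p-value
  (seeded, `permutation=<resamples>`) is available for small samples.
  Constant inputs raise rather than returning NaN.
* Summary tables report min/max/median; the median uses the mid-point
  convention for even n.

Relevance labels are *consumed*, never computed: judging whether a
retrieved design is correct for a new case (retainer arrangement, major
connector rigidity, bulb design, overall retention/support/stability) is
clinical expertise outside this package's scope.  The label file schema is
`test_id, rank, relevant(0/1)`.

## Numerical and design choices

* Confidence returns exactly 1.0 on full agreement (special-cased, so no
  floating-point dust) and is clamped to [0, 1] otherwise.
* Share weights must sum to < 1 over any comparable set; a configuration
  violating this raises rather than renormalising silently.
* An empty comparable set (impossible for same-class records under the
  shipped schemas, possible with hand-built records) raises an
  undefined-score error rather than returning 0.
* Tie-break by `case_id` is lexicographic ascending; generated IDs are
  zero-padded so lexicographic order matches numeric order.
* Problem sizes in the test suite: oracle sweeps use 1000 case bases of
  ≤ 8 cases; skip-logic soundness walks 500 random interview paths per
  class; statistical-recovery checks use 200 replicates of 33-test
  evaluations against a 209-case base.
* Opening matched design media is opt-in (`--open`); reports go to
  stdout/files and diagnostics to stderr.

## Known limitations

* The Aramany classification itself overlooks vertical defect extension,
  soft-palate-only defects and multiple discontinuous defects; cases
  outside the six classes cannot be described.
* Implant-retained designs are out of scope; retrieval only ever proposes
  conventional obturator designs already present in the case base.
* Retrieval quality is bounded by case-base coverage: classes that are
  rare in the database (typically III, V, VI) offer few candidates, and
  `retrieve` returns an empty report (with a notice) when no same-class
  case exists.
* The default weight table encodes a deliberately mild importance
  structure (two secondary keys at 5% shares); real deployments should
  calibrate overrides against clinician judgment.
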