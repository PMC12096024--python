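# Methods

This note documents the models, defaults, and numerical choices behind
`eduscore`, and what its synthetic cohorts do and do not establish about
real study data.

## Tokenization and readability

All four grade indices are computed from one deterministic tokenization:

- **Sentences** end at `.`, `!`, or `?`, except a period inside a decimal
  number (digit.digit), after a listed abbreviation (`Dr.`, `e.g.`, …), or
  followed — possibly across further dots, so ellipses inherit the rule —
  by a lowercase letter. The abbreviation list is a frozen set in
  `text_metrics.ABBREVIATIONS`.
- **Words** are maximal alphanumeric runs with internal hyphens or
  apostrophes. Numeric tokens count as one-syllable words; `2.5` splits at
  the period into two tokens (the period is sentence punctuation, not part
  of the word grammar).
- **Syllables** come from a vowel-group heuristic (a e i o u y), minus a
  silent trailing `e` (kept for consonant+`le` endings), overridden by a
  small editable exception table (`data/syllable_exceptions.txt`) for words
  the heuristic miscounts (e.g. *osteoarthritis* → 6). Unknown words fall
  back to the heuristic; every word counts at least one syllable.
- **Fog complex words** are polysyllables (≥3 syllables) minus two
  exclusions: capitalized non-sentence-initial tokens (a proper-noun proxy)
  and hyphenated compounds. Inflectional `-es`/`-ed` endings are *not*
  discounted; the classical exclusion is ambiguous and this rule is fixed
  and auditable instead.
- SMOG uses the general scaling formula at any sentence count and logs a
  warning below 30 sentences, the formula's design sample size.

These are conventions, not a reimplementation of any particular commercial
readability tool; different tools disagree at the tokenization level, so
agreement with other implementations is expected within a fraction of a
grade, not exactly. The test suite checks agreement within ±0.5 grade
against an independent reference implementation with a deliberately
different dialect.

Words per minute uses the same word count as the readability indices, so
the efficiency and readability metrics are internally consistent.

## Guideline concordance ("accuracy")

A treatment's stance per society is one of SR / CR / INC / CRA / SRA /
NOT_ADDRESSED. Consolidation takes the modal non-NOT_ADDRESSED category;
its bloc size is the consensus count. A modal tie consolidates to INC at
the tied size — societies that split evenly are, by definition here,
inconclusive. "Agreement" means the identical category, not merely the same
direction, matching the category-level weight table.

Document scoring sums score×weight over the *distinct* treatments
mentioned (duplicates collapse; mentioning is a set notion). The default
LITERAL mode ignores whether the document advised or warned against the
treatment; POLARITY_AWARE, which negates discouraged mentions, is an
explicitly labelled extension behind a flag.

The 6-point normalization divides the raw sum by the table's maximum
achievable positive sum and clips to [0, scale_max]. The mapping from an
unbounded weighted sum to a bounded scale is not uniquely determined by the
reporting convention it mirrors; this proportional reading is one
defensible choice and is isolated in `normalize_accuracy` so alternatives
can be swapped in.

No published society table ships with the package: the guideline table is
a runtime CSV input, and the generator's tables are synthetic
demonstrations, not statements of any society's guidance.

## Rubric adjudication

Instruments are fixed: personalization 30/40/30; comprehensiveness and
safety five 20-point categories each (medication treatment, nonmedication
treatment, lifestyle advice, psychological support, disease management).
Qualitative band anchors ("16–20 very safe", …) are documentation strings,
never enforced logic.

The disagreement trigger is per dimension and strict: |r1 − r2| > 10
flags; a difference of exactly 10 does not. Resolution is also per
dimension — the trigger is defined per dimension, and applying the
three-rater median at the same granularity keeps the two consistent.
Agreeing dimensions take the two-rater mean (unbiased, conventional;
half-points may result). Raw rater points are integers; adjudicated values
may be half-integers. The adjudicated sheet is invariant to rater order
wherever the flag status itself is order-invariant, and a flagged
dimension's value always lies within the three raters' range.

## Paired comparison

Normality of the within-profile differences is assessed by Shapiro-Wilk at
α = .05 (a standard choice at n = 50; the selection procedure is a
configuration knob, not a claim about the one true test). Non-rejection
routes to the paired t test, reported mean/SD; rejection routes to the
Wilcoxon signed-rank test, reported median/IQR. All tests are two-sided;
p-values print to three decimals with "<.001" below that.

Wilcoxon zero differences are dropped (classic procedure; the Pratt
variant is out of scope) and the effective n is reported. For up to 12
effective pairs the two-sided p-value is exact, computed by convolving the
signed-rank distribution on doubled (hence integral mid-)ranks; beyond
that, a normal approximation with tie correction and no continuity
correction is used, matching the common software default. The switch point
keeps exact computation instant at desk scale; tests verify the exact path
against full 2^n sign enumeration and the approximation against an
independent implementation.

No multiple-testing correction is applied across the metrics, mirroring
the reporting convention the pipeline emulates; the significance flag is
strictly p < .05.

## Synthetic cohorts

The generator emulates the study shape: 50 patient profiles × 2 arms = 100
documents, a seeded guideline table, planted treatment mentions, and two
noisy raters with occasional forced disagreement. All randomness flows
from a single seed through named substreams (table, text, mentions,
raters, timing), so cohorts are byte-identical across regenerations.

Key defaults (all `CohortConfig` fields):

- **Authoring speed**: lognormal WPM with medians 530.03 (AI) and 37.29
  (clinician), log-sigmas 0.188 and 0.079 chosen to match the reported
  interquartile ranges. Minutes are word count over the drawn WPM.
- **Text shape**: ~450-word documents (lognormal, σ=0.2); words per
  sentence 16 (AI) vs 18 (clinician); syllables per word 1.77 vs 1.80.
  Per-word syllable counts are 1 + capped-Poisson draws, and words come
  from a curated knee-OA word bank whose syllable/letter counts are taken
  from the package's own counter — which is what makes the generator's
  ledger equal the tokenizer's output exactly (a tested round-trip). These
  defaults put the AI arm roughly one grade below the clinician arm on
  Flesch-Kincaid, Fog, and SMOG. Coleman-Liau is left emergent (it tracks
  letters, which the bank ties to syllables), so its arm ordering is not
  controlled.
- **Accuracy**: per-document targets are normal on the 6-point scale
  (means 5.31 AI / 4.76 clinician, SD 0.75); a greedy-plus-local-search
  subset of treatments realizes each target as an actual mention set.
  Realized sums live on a 0.25-step lattice, so arm means carry a small
  (≲0.06 point) quantization bias; the arm *difference*, which is what the
  paired analysis estimates, is recovered within ~0.03. With the default
  means near the scale ceiling the upper arm is slightly truncated; power
  and recovery checks therefore run at means 4.25/4.75 (the same +0.5
  delta, clear of the ceiling).
- **Rubrics**: per-document truth totals are normal (arm means from the
  emulated study: personalization 54.32/33.20, comprehensiveness
  51.74/35.26, safety 61/51; SD 6), split across dimensions in proportion
  to their maxima. Raters add rounded Gaussian noise (SD 2 by default),
  clipped to dimension bounds. With probability `p_disagreement` (default
  0.1 — a placeholder; the emulated study reports no disagreement
  frequency) one dimension is rewritten to an 11-point split, guaranteeing
  an adjudication path; a third rater near the truth is emitted whenever
  any dimension flags.

`simulate_paired_metrics` computes the per-document metric table directly
from the sampled cohort plan, skipping only string rendering and
re-tokenization. Because the ledger-equals-tokenizer round-trip is itself
a tested invariant (and the fast path is tested equal to the file-based
pipeline on full cohorts), large replicate simulations — 2,000 zero-effect
cohorts for type I error calibration, 500 cohorts for power and delta
recovery — use this path and finish in a couple of minutes on one core.
Those replicate counts are the calibration sample sizes used by the test
suite and the acceptance script.

### What the synthetic cohorts do not show

Generated documents are grammatically meaningless word sequences with
controlled token statistics; they exercise tokenization, scoring,
adjudication, blinding, and statistics, not language understanding.
Passing tests demonstrate that the instruments are computed correctly and
that the statistical machinery is calibrated and powered under the
configured conditions — they say nothing about how real clinicians, real
AI systems, or real raters would score. Mention sets are planted to hit
score targets, not extracted from the text by any NLP; automatic mention
extraction is explicitly out of scope. Rater noise is independent rounded
Gaussian; real rater error is likely correlated across dimensions and
documents.

## Degenerate inputs and edge policies

- Empty/whitespace text, non-positive authoring minutes, words without
  alphabetic characters, zero-variance differences, all-zero difference
  vectors, and all-NOT_ADDRESSED stance sets are rejected with explicit
  errors rather than coerced.
- The pipeline validates every input file before computing anything and
  aborts with an itemized list (file, row, reason); partial reports are
  never written.
- Values are rounded only at presentation (2 decimals for summaries, 3
  for p); reports regenerate byte-identically from identical inputs, and
  the provenance block records the configuration hash and input checksums.
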