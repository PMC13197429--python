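# Methods

This note documents the models and procedures implemented in `semioloc`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic test bed does and does not establish about real data.

## Task model

An entry pairs one free-text seizure description (a *semiology*) with a
non-empty subset of seven canonical seizure-onset-zone regions: Temporal Lobe,
Frontal Lobe, Cingulate Gyrus, Parietal Lobe, Occipital Lobe, Insula,
Hypothalamus. The region order is fixed globally; it defines vector layout and
is the tie-break for argmax predictions and for frequency ties in the naive
baseline. A responder receives a prompt — persona prefix, instruction, optional
exemplars, optional chain-of-thought request, query — and must return a JSON
dictionary assigning a nonnegative percentage likelihood to each region.
Likelihoods are deliberately **not** forced to sum to 100: responders are
scored on what they actually emit, and renormalization happens only inside the
entropy computation.

Ground truth is multi-label (an entry can be linked to more than one region);
a single-region prediction counts as correct when it lies anywhere in the
truth set. This containment rule is the only reading under which a constant
majority-class predictor has a well-defined accuracy, which is how the naive
lower bound is defined.

## Corpus handling

Corpora are TSV (`id`, `text`, `language`, `regions`, optional `text_<lang>`
columns). Preprocessing expands clinical abbreviations (case-sensitive token
match — "LOC" is an abbreviation, "loc" is not), corrects spellings and drops
uninformative stop terms (both case-insensitive), and collapses whitespace.
The shipped rule files are minimal, editable defaults; a corpus owner is
expected to extend them. Valid rule sets must be idempotent — no output token
of a map may itself be a key or stop term — and the property suite enforces
this for the shipped defaults. Word count is the whitespace-token count of
the preprocessed text: the simplest reproducible rule, chosen because the
length analysis only needs a monotone proxy for description length.

Length bins are half-open integer intervals `[x, y)`; counts outside the
covered range are an explicit error rather than a silent clamp. Default edges
are corpus word-count quantiles into six bins; any published edge set can be
passed instead.

## Synthetic corpus generator

The generator emulates the statistical shape of a curated semiology corpus,
not its content. Defaults (chosen once; see the class docstring):

* `n = 1269` entries — the scale of the curated corpus the harness targets;
* primary-region weights with Temporal Lobe at 0.3821 — the majority-class
  prevalence implied by the published ~38.2% naive lower bound; the remaining
  weights (Frontal 0.24, Parietal 0.11, Occipital 0.09, Insula 0.08,
  Cingulate 0.05, Hypothalamus 0.0479) follow the usual clinical gradient and
  are otherwise unconstrained choices;
* `multilabel_prob = 0.2` — one extra uniformly drawn region for a fifth of
  entries; the real fraction is not published, and 0.2 keeps multi-label code
  paths exercised without dominating the scores;
* word counts ~ round(LogNormal(μ=2.1, σ=0.7)), clipped to [1, 80] — median
  ≈ 8 words with a long right tail, matching the shape of short clinical
  symptom notes;
* texts are random draws from a 50-word symptom vocabulary; pseudo-translations
  prefix each token with the language code.

What this does **not** emulate: lexical or syntactic structure, correlations
between wording and true region, inter-annotator noise, or real translation
quality. Tests passing on this corpus therefore validate the *pipeline* —
parsing, aggregation, scoring, statistics — not any claim about how well a
particular model localizes real seizures.

## Simulated responder

The mock responder is the workhorse of the test bed. In **calibrated** mode a
confidence `c ~ Uniform(c_lo, c_hi)` is drawn per query; with probability `c`
the top region is sampled from the truth set, otherwise uniformly from its
complement; the top region receives `100·c` % and the rest is spread evenly
(optionally jittered by a Dirichlet with the `concentration` parameter; the
even default keeps the closed forms exact). This gives three analytic
oracles, all recovered by the test suite at n = 10,000:

* accuracy → E[c] (0.6 for the default Uniform(0.2, 1.0));
* Brier score → E[c(1−c)] = 0.1867 for those bounds;
* reliability diagram → the diagonal (max per-bin |F_pos − Conf| < 0.05
  at M = 10).

The uniform confidence distribution was chosen precisely because it spreads
mass across calibration bins and has a closed-form Brier expectation. The
default bounds keep `c > 1/7` so the top region is always the argmax.
Likelihoods are serialized at 4-decimal precision: coarser rounding creates a
probability atom at exactly `100·c_lo` that falls on a bin boundary and lands
in the open-left neighbouring bin.

In **fixed** mode the hit probability is a constant `accuracy` and the top
region receives a constant `top_percent`. Additive accuracy deltas can be
planted per strategy, persona, prompt language, query language, or
description-length bin (clamped to [0, 1]); these drive the
parameter-recovery tests of the ablation drivers.

**Paired randomness.** All stochastic draws are keyed by
`(seed, entry id, chain index)` only — never by the prompt condition. Two
conditions evaluated on the same corpus therefore share their underlying
random numbers: a condition-blind responder returns identical likelihoods
under every persona or language (deltas are exactly zero), and a planted
delta δ is estimated with paired binomial error `sqrt(δ(1−δ)/n)` rather than
the much larger two-independent-samples error. This is the standard
common-random-numbers variance-reduction design for simulation comparisons.

**Malformation.** With probability `malform_rate` one defect is injected into
the serialized response — a removed region key, a `"None"` value, a
non-numeric token, or truncation that breaks the JSON — with configurable mix
weights. Defects operate on the serialized text so they exercise the real
parser paths; the fraction of non-clean parses recovers `malform_rate`.

## Parsing

The parser never raises on content. It extracts the first balanced `{...}`
block (chain-of-thought answers embed prose around the dictionary); if JSON
decoding fails it falls back to regex extraction of `"key": value` pairs, the
behaviour of a pragmatic regex-based extraction layer. Region keys are
canonicalized through a per-language lexicon (case- and diacritic-insensitive;
English names are always accepted as a fallback because responders often keep
English keys under translated prompts). Missing, `"None"`, or non-numeric
values become 0% with a defect record; negative values are floored to 0;
values above 100 are kept but flagged (the argmax is still defined, and no
clipping rule is published). Status is `ok` (all seven regions recovered
cleanly), `partial` (something recoverable plus defects), or `failed`
(no numeric region value at all → all-zero vector). Downstream, an all-zero
vector is a no-prediction: always incorrect, probability 0, confidence 0 —
a failed parse can never inflate accuracy or confidence.

## Self-consistency

Five chains are drawn per query. Per region the median of the five likelihoods
(the middle order statistic; no interpolation is needed for odd counts)
defines the consensus; each chain's summed absolute deviation from the
consensus ranks it, and the minimum wins, ties breaking to the lowest chain
index for order-stable determinism. The winner's vector is returned unchanged
— the vote selects, it never averages, so the output is always one of the
actual responses. Failed chains stay in as all-zero vectors to preserve the
five-chain contract; they are heavily penalized by the deviation sum whenever
the other chains agree on non-zero mass. A brute-force re-implementation
validates the vote on hundreds of random and tie-heavy matrices.

## Scoring

Predictions are argmax regions. Weighted precision/recall/F1 use one-vs-rest
confusion counts averaged with class-support weights. Multi-label entries
enter the confusion matrix under a crediting rule: a correct prediction
credits the matched truth region; an incorrect one counts the first-listed
truth region as the missed class. This is one consistent reading of
single-prediction scoring against multi-label truth; the independent oracle
(scikit-learn on the same code assignment) agrees to 1e-12.

Confidence is `1 − H/log2 7` with entropy in bits on the renormalized vector
and the 0·log 0 = 0 convention; a massless vector is maximally uncertain by
convention. Calibration pairs the *predicted-class* likelihood (÷100) with
correctness — the pairing under which "fraction of positives per bin" is
well-defined — and the true-class likelihood is available as a switch since
both pairings appear in the calibration literature. Bins are the M equal-width
intervals `((m−1)/M, m/M]` with M = 10 by default (configurable; no canonical
value exists); probabilities of exactly 0 land in bin 1 so failed parses stay
visible. Empty bins are reported as empty and excluded from summary gaps.
Bootstrap CIs are percentile intervals over entry resampling, 999 resamples
by default, seeded.

## Significance

The chance baseline permutes truth sets (as units, keeping multi-label sets
intact) while holding predictions fixed, recomputing weighted F1 each time;
999 permutations by default. The observed score is z-normalized against the
null and a two-sided p comes from the standard normal tail, which is how a
z-score-based permutation test is conventionally reported; the empirical rank
p `(1 + #{null ≥ x})/(n_perm + 1)` is reported alongside for readers who
prefer the distribution-free version. The normal p is floored at the smallest
positive normal float so downstream Benjamini–Hochberg correction (statsmodels
step-up) always receives values in (0, 1]. A degenerate null (σ = 0) is
flagged rather than silently producing infinities. Under a null simulation
(random predictor, 300 entries, 200 permutations) the measured type-I error
at α = 0.05 is within 5% ± 3%, confirming the normal approximation is
adequate at these sizes. Two-proportion comparisons use the pooled z-test.

## Factor analyses

All three drivers reuse the single scoring path end-to-end; nothing is
special-cased, so cached responses reproduce every number bit-for-bit.

* **Length**: per-bin weighted F1 ± SEM of per-entry correctness;
  Kruskal–Wallis across bins on per-entry correctness; surrogate control by
  reassigning entries to bins at random with bin sizes preserved exactly
  (`n_shuffle` = 200 by default). The KS test compares the six observed bin
  F1 values against the pooled surrogate bin values. Under a length-blind
  responder the observed bin means are exchangeable with surrogate means, so
  the test holds its size (simulations show it is, if anything, conservative);
  a planted 0.8/0.4/0.8 short/medium/long effect is detected (p < 0.05) in
  ≥ 90% of runs. With only six observed values the KS test has limited power
  against weak effects — it is a guard against artifacts, not a sensitive
  effect-size estimator.
* **Persona**: the zero-shot condition re-run per persona (zero-shot, to keep
  exemplar choice out of the comparison); deltas in F1, accuracy, recall and
  mean confidence against the first persona. For the uniform-error responder
  the planted hit-probability delta equals the weighted-recall delta exactly
  in expectation, which is what the recovery tests assert.
* **Language**: English baseline, cross-language (query translated, prompt
  English), same-language (both translated), per language, with mean ± SD and
  deltas against the baseline. Missing translations are an error naming the
  offending entries.

## Determinism and caching

Every stochastic component takes an explicit seed; per-query randomness is
derived by hashing stable identifiers through SHA-256 into a seed sequence.
Reports contain no timestamps, so a rerun with the same seeds is
byte-identical, and `run_grid(..., replay=True)` reproduces a live run
exactly from the JSONL cache (cache records do carry wall-clock timestamps;
they are provenance, not inputs). The manifest stores a hash of the resolved
configuration so mixed-provenance caches are refused.

## Problem sizes used in the checks

The behavioural checks run at sizes chosen to make their error bars decisive:
parameter recovery at n = 10,000 entries; type-I error over 200 simulations of
300 entries with 200 permutations; planted length effects over 20 runs of 800
entries (null calibration over 50 runs of 600); persona/language recovery at
n = 1269. These are the package's own verification sizes; nothing prevents
running larger grids.

## Known limitations

* The real curated corpus behind the published 1,269-entry / 38.21% figures
  is an external accession; the loader and baseline are verified on toy and
  synthetic corpora, and the real-data counts should be re-checked once that
  table is available locally.
* Exemplar selection for few-shot prompting is uniform (region-stratified
  when feasible); the original exemplar choice and expert reasoning texts are
  not published, so the shipped FS-CoT reasoning templates are clearly marked
  synthetic placeholders.
* The parser is single-shot: it never re-prompts on failure.
* Live adapters for commercial APIs are out of scope; the backend registry
  defines the contract they would implement.
* Citation verification (whether cited sources exist) is not automated.
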