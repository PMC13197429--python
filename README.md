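# semioloc

Evaluation harness for **likelihood-eliciting seizure-onset-zone (SOZ)
localization from free-text seizure descriptions**.

In epilepsy care, the observable signs and symptoms of a seizure — its
*semiology* — carry diagnostic information about where in the brain the
seizure originates. `semioloc` evaluates responders (language-model backends,
clinicians entering sliders, or a fully offline simulated responder) that read
a free-text semiology `S` and return a structured likelihood dictionary

```
D = { r : L(r | S, P, Q, I) }   for r ∈ R
R = {Temporal Lobe, Frontal Lobe, Cingulate Gyrus, Parietal Lobe,
     Occipital Lobe, Insula, Hypothalamus}
```

where the prompt is assembled from a persona `P` ("you are a {persona}"),
a query `Q`, and an instruction format `I`. The harness is aimed at people
benchmarking clinical NLP systems: it supplies the corpus handling, prompt
construction, robust response parsing, aggregation, and the statistics —
nothing in it queries a commercial model unless you register such a backend.

## What it computes

* **Prompt strategies** — zero-shot (ZS), few-shot with K=5 exemplars (FS),
  chain-of-thought (CoT), few-shot CoT (FS-CoT), and self-consistency (SC).
  SC draws five independent reasoning chains and selects one by median
  voting: per region *i*, `A_ij = |L_ij − median_j(L_ij)|`, and the winning
  chain is `W = argmin_j Σ_i A_ij` (the winner's vector is returned unchanged).
* **Correctness** — argmax prediction vs. a (possibly multi-label) truth set;
  support-weighted precision/recall/F1 with percentile-bootstrap CIs over
  entries.
* **Confidence** — `C = 1 − H/log2(7)` where
  `H = −Σ p_i log2 p_i` is the Shannon entropy of the renormalized
  likelihoods; `H` ranges from 0 (one-hot) to `log2 7 ≈ 2.807` bits (uniform).
* **Calibration** — reliability bins over `((m−1)/M, m/M]` pairing the
  predicted-class likelihood with correctness (`F_pos` vs. `Conf` per bin),
  and the Brier score `B_s = (1/N) Σ (p_j − y_j)²`.
* **Significance** — weighted F1 against a truth-permutation null:
  `z = (x − μ)/σ` with two-sided normal p (empirical permutation rank
  reported alongside), Benjamini–Hochberg correction across a grid, and a
  pooled two-proportion z-test for paired correctness/completeness rates.
* **Factor analyses** — description-length bins `[x, y)` with a
  Kruskal–Wallis test and a bin-size-preserving shuffled surrogate
  (Kolmogorov–Smirnov); persona sweeps; and English / cross-language /
  same-language conditions.
* **Synthetic module** — a corpus generator (class-imbalanced multi-label
  truth, right-skewed word counts, pseudo-translations) and a simulated
  responder with tunable accuracy, confidence calibration, likelihood
  concentration and malformation rate, so the whole pipeline is testable
  offline with closed-form oracles.

## Worked example

```python
import semioloc as sl
from semioloc.runner import RunConfig, run_grid, write_report
from semioloc.synthetic import ResponderParams

corpus = sl.generate_corpus(sl.SyntheticCorpusParams(n=1269, seed=1))
nb = sl.naive_baseline(corpus)
print(f"naive baseline: {nb.region}, accuracy {100*nb.accuracy:.2f}%")

config = RunConfig(
    strategies=("ZS", "FS", "CoT", "FS-CoT", "SC"),
    backend_params={"params": ResponderParams(
        mode="calibrated", conf_bounds=(0.2, 1.0), malform_rate=0.02, seed=1,
        strategy_effects={"FS": 0.05, "CoT": 0.08, "FS-CoT": 0.09, "SC": 0.10},
    )},
    seed=1,
)
result = run_grid(config, corpus=corpus)
write_report(result, "demo")
print(open("demo/summary.txt").read())
```

prints

```
naive baseline: Temporal Lobe, accuracy 40.43%
semioloc evaluation report (config 0b9fa6f4c205d5bd)
backend: mock   entries: 1269

ZS      persona='AI assistant'           lang=en  F1= 58.08%  CI=[55.23, 60.45]  conf=0.329  Brier=0.1947  z=30.28  p=1.95e-201
FS      persona='AI assistant'           lang=en  F1= 62.59%  CI=[59.82, 65.03]  conf=0.329  Brier=0.1862  z=34.01  p=1.64e-253
CoT     persona='AI assistant'           lang=en  F1= 65.75%  CI=[63.10, 68.34]  conf=0.328  Brier=0.1809  z=36.69  p=9.37e-295
FS-CoT  persona='AI assistant'           lang=en  F1= 66.74%  CI=[64.11, 69.31]  conf=0.328  Brier=0.1792  z=37.58  p=2.23e-308
SC      persona='AI assistant'           lang=en  F1= 80.18%  CI=[77.92, 82.25]  conf=0.217  Brier=0.2128  z=48.08  p=2.23e-308
```

Reading the table: the simulated responder was configured with a calibrated
base accuracy of E[c] = 0.6 plus planted prompt-engineering gains
(+5…+10 points), a 2% malformation rate, and 1,269 entries whose majority
region (Temporal Lobe) sets a ~40% naive lower bound. The F1 column tracks the
planted gains, the 95% CIs come from 999 bootstrap resamples, the confidence
column is the entropy-based score, and the z/p columns show every condition
far exceeding the 999-permutation chance distribution. Self-consistency
additionally aggregates five chains per query, which lifts accuracy but — by
selecting a chain near the per-region median — also selects
middle-of-the-road confidence, visible in the lower `conf` value.

The same pipeline is scriptable from the shell:

```
semioloc simulate --n 1269 --seed 1 --out corpus.tsv
semioloc run --corpus corpus.tsv --strategy ZS --strategy SC --seed 1 --out results/
semioloc ablate length --corpus corpus.tsv --seed 1 --out length.csv
```

Corpora are TSV files (`id`, `text`, `language`, `regions` with ";"-joined
canonical names, optional `text_<lang>` translation columns); every raw
query/response is appended to a JSONL cache from which all numbers can be
recomputed without re-querying.

## Layout

```
src/semioloc/
  corpus.py           corpus I/O, preprocessing rules, length bins, naive baseline
  synthetic.py        corpus generator, mock responder, backend registry, cache
  prompts.py          the five strategies, personas, exemplar selection
  parsing.py          likelihood extraction, multilingual region lexicon
  selfconsistency.py  median-based majority voting
  metrics.py          F1/confidence/calibration/bootstrap
  significance.py     permutation null, z/p, BH, two-proportion z
  ablations.py        length / persona / language drivers
  runner.py           grid orchestration and reports
  cli.py              command-line interface
docs/methods.md       model, assumptions, numerical choices, limitations
```
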