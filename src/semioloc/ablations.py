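"""Factor analyses: description length, clinical persona, and language.

Three drivers probe what moves localization performance beyond the prompt
strategy itself:

* ``length_analysis`` — entries are grouped into six half-open word-count bins
  [x, y) and the weighted F1 is computed per bin (± SEM of per-entry
  correctness). A Kruskal-Wallis test asks whether correctness differs across
  bins at all, and a surrogate control — entries reassigned to bins at random
  with bin sizes preserved, many times — feeds a two-sample Kolmogorov-Smirnov
  test between the observed per-bin F1 values and the surrogate per-bin F1
  distribution. Under a length-blind responder the observed bin means are
  exchangeable with the surrogate ones, so the KS test is calibrated; a real
  length effect shifts the observed values into the surrogate tails.
* ``persona_sweep`` — the zero-shot condition re-run under increasingly
  specialized personas; deltas are reported against the first persona
  (baseline "AI assistant").
* ``language_sweep`` — per non-English language, three conditions: English
  baseline (prompt and description in English), cross-language (description
  translated, prompt English), and same-language (both translated); deltas are
  reported against the English baseline.

All drivers reuse the single scoring path (prompts -> backend -> parsing ->
metrics); nothing is special-cased, so cached responses reproduce every
number exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import kruskal, ks_2samp

from .corpus import SemiologyEntry, assign_length_bin
from .metrics import Prediction, weighted_prf1, _codes, _weighted_prf1_from_codes
from .parsing import RegionLexicon
from .prompts import PromptSpec, spec_for
from .runner import evaluate_condition
from .synthetic import Backend


@dataclass(frozen=True)
class AblationLevel:
    label: str
    score: float            # weighted F1
    accuracy: float
    recall: float
    mean_confidence: float
    dispersion: float       # SEM (length) or SD (language/persona) of correctness
    n: int
    delta: float            # score - baseline score (0 for the baseline level)
    delta_accuracy: float
    delta_recall: float


@dataclass(frozen=True)
class AblationResult:
    axis: str               # "length" | "persona" | "language"
    baseline: str
    levels: tuple[AblationLevel, ...]
    stats: Mapping[str, float] = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        rows = [
            {
                "axis": self.axis,
                "level": lv.label,
                "f1": lv.score,
                "accuracy": lv.accuracy,
                "recall": lv.recall,
                "mean_confidence": lv.mean_confidence,
                "dispersion": lv.dispersion,
                "n": lv.n,
                "delta_f1": lv.delta,
                "delta_accuracy": lv.delta_accuracy,
            }
            for lv in self.levels
        ]
        frame = pd.DataFrame(rows)
        for key, value in self.stats.items():
            frame[key] = value
        return frame


def _level(label: str, predictions: Sequence[Prediction],
           baseline: tuple[float, float, float] | None,
           dispersion: str = "sd") -> AblationLevel:
    precision, recall, f1 = weighted_prf1(predictions)
    correct = np.array([p.correct for p in predictions], dtype=float)
    spread = float(correct.std(ddof=1)) if len(correct) > 1 else 0.0
    if dispersion == "sem":
        spread /= np.sqrt(len(correct))
    base_f1, base_acc, base_rec = baseline if baseline else (f1, correct.mean(), recall)
    return AblationLevel(
        label=label,
        score=f1,
        accuracy=float(correct.mean()),
        recall=recall,
        mean_confidence=float(np.mean([p.confidence for p in predictions])),
        dispersion=spread,
        n=len(predictions),
        delta=f1 - base_f1,
        delta_accuracy=float(correct.mean() - base_acc),
        delta_recall=recall - base_rec,
    )


# ---------------------------------------------------------------------------
# Description length
# ---------------------------------------------------------------------------

def bin_label(edges: Sequence[int], m: int) -> str:
    return f"[{edges[m]}, {edges[m + 1]})"


def _per_bin_f1(y_true: np.ndarray, y_pred: np.ndarray,
                bin_of: np.ndarray, n_bins: int) -> np.ndarray:
    out = np.full(n_bins, np.nan)
    for m in range(n_bins):
        mask = bin_of == m
        if mask.any():
            out[m] = _weighted_prf1_from_codes(y_true[mask], y_pred[mask])[2]
    return out


def length_analysis(
    predictions: Sequence[Prediction],
    edges: Sequence[int],
    n_shuffle: int = 200,
    seed: int = 0,
) -> AblationResult:
    """Per-length-bin F1 with Kruskal-Wallis and surrogate KS tests."""
    if not predictions:
        raise ValueError("no predictions to analyse")
    edges = list(edges)
    n_bins = len(edges) - 1
    bin_of = np.array([assign_length_bin(p.word_count, edges) for p in predictions])
    y_true, y_pred = _codes(predictions)
    observed = _per_bin_f1(y_true, y_pred, bin_of, n_bins)
    occupied = ~np.isnan(observed)

    correct = np.array([p.correct for p in predictions], dtype=float)
    groups = [correct[bin_of == m] for m in range(n_bins) if (bin_of == m).any()]
    if len(groups) >= 2 and any(g.std() > 0 for g in groups):
        kw_stat, kw_p = kruskal(*groups)
    else:
        kw_stat, kw_p = float("nan"), float("nan")

    # surrogate: random bin reassignment, sizes preserved exactly
    rng = np.random.default_rng(seed)
    surrogate = np.empty((n_shuffle, n_bins))
    for s in range(n_shuffle):
        shuffled_bins = bin_of[rng.permutation(len(bin_of))]
        surrogate[s] = _per_bin_f1(y_true, y_pred, shuffled_bins, n_bins)
    surrogate_values = surrogate[:, occupied].ravel()
    surrogate_values = surrogate_values[~np.isnan(surrogate_values)]
    if occupied.sum() >= 2 and surrogate_values.size:
        ks_stat, ks_p = ks_2samp(observed[occupied], surrogate_values)
    else:
        ks_stat, ks_p = float("nan"), float("nan")

    levels = []
    baseline = None
    for m in range(n_bins):
        mask = bin_of == m
        if not mask.any():
            continue  # empty bins are flagged by absence and excluded from tests
        subset = [p for p, inside in zip(predictions, mask) if inside]
        level = _level(bin_label(edges, m), subset, baseline, dispersion="sem")
        if baseline is None:
            baseline = (level.score, level.accuracy, level.recall)
            level = _level(bin_label(edges, m), subset, baseline, dispersion="sem")
        levels.append(level)
    return AblationResult(
        axis="length",
        baseline=levels[0].label,
        levels=tuple(levels),
        stats={
            "kruskal_stat": float(kw_stat),
            "kruskal_p": float(kw_p),
            "ks_stat": float(ks_stat),
            "ks_p": float(ks_p),
            "n_shuffle": float(n_shuffle),
            "n_empty_bins": float(n_bins - int(occupied.sum())),
        },
    )


# ---------------------------------------------------------------------------
# Persona sweep
# ---------------------------------------------------------------------------

def persona_sweep(
    corpus: Sequence[SemiologyEntry],
    personas: Sequence[str],
    backend: Backend,
    strategy: str = "ZS",
    language: str = "en",
    lexicon: RegionLexicon | None = None,
) -> AblationResult:
    """Zero-shot performance/confidence per persona, deltas vs. the first one."""
    if not personas:
        raise ValueError("empty persona list")
    if lexicon is None:
        lexicon = RegionLexicon.default()
    levels = []
    baseline = None
    for persona in personas:
        spec = spec_for(strategy, corpus=corpus, persona=persona,
                        language=language, lexicon=lexicon)
        predictions = evaluate_condition(corpus, spec, backend, lexicon)
        level = _level(persona, predictions, baseline)
        if baseline is None:
            baseline = (level.score, level.accuracy, level.recall)
            level = _level(persona, predictions, baseline)
        levels.append(level)
    return AblationResult(axis="persona", baseline=personas[0], levels=tuple(levels))


# ---------------------------------------------------------------------------
# Language sweep
# ---------------------------------------------------------------------------

LANGUAGE_CONDITIONS = ("baseline", "cross", "same")


def language_sweep(
    corpus: Sequence[SemiologyEntry],
    languages: Sequence[str],
    backend: Backend,
    persona: str = "AI assistant",
    strategy: str = "ZS",
    lexicon: RegionLexicon | None = None,
) -> AblationResult:
    """English baseline vs. cross-language vs. same-language conditions.

    ``cross`` translates only the semiology description; ``same`` translates
    prompt and description both. Entries missing a required translation raise
    an error naming them.
    """
    if lexicon is None:
        lexicon = RegionLexicon.default()
    for language in languages:
        missing = [
            e.id for e in corpus
            if language != e.language and language not in e.translations
        ]
        if missing:
            preview = ", ".join(missing[:5]) + ("..." if len(missing) > 5 else "")
            raise ValueError(
                f"{len(missing)} entries lack a {language!r} translation: {preview}"
            )
    base_spec = spec_for(strategy, corpus=corpus, persona=persona,
                         language="en", lexicon=lexicon)
    base_predictions = evaluate_condition(corpus, base_spec, backend, lexicon)
    base_level = _level("en:baseline", base_predictions, None)
    baseline = (base_level.score, base_level.accuracy, base_level.recall)
    levels = [_level("en:baseline", base_predictions, baseline)]
    for language in languages:
        cross_spec = spec_for(strategy, corpus=corpus, persona=persona,
                              language="en", query_language=language, lexicon=lexicon)
        same_spec = spec_for(strategy, corpus=corpus, persona=persona,
                             language=language, lexicon=lexicon)
        for condition, spec in (("cross", cross_spec), ("same", same_spec)):
            predictions = evaluate_condition(corpus, spec, backend, lexicon)
            levels.append(_level(f"{language}:{condition}", predictions, baseline))
    return AblationResult(axis="language", baseline="en:baseline", levels=tuple(levels))
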