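"""Correctness, confidence, calibration and bootstrap uncertainty.

The prediction for an entry is the argmax region of its likelihood vector
(canonical-order tie-break). Confidence is 1 minus the Shannon entropy of the
renormalized vector divided by log2(7), so a one-hot vector scores 1 and a
uniform vector 0. Calibration pairs a per-entry probability with the binary
correctness outcome: by default the probability is the likelihood assigned to
the *predicted* region (divided by 100); the likelihood of the *true* region
is available as an alternative pairing. Aggregate scores are weighted
one-vs-rest precision/recall/F1 with class-support weights; uncertainty comes
from percentile bootstrap over entries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.stats import entropy as _scipy_entropy

from .corpus import N_REGIONS, REGIONS, REGION_INDEX, SemiologyEntry
from .parsing import ParsedResponse, RegionLikelihood

MAX_ENTROPY_BITS = math.log2(N_REGIONS)  # 2.807... for 7 regions

#: integer code for "no prediction" (all-zero likelihood vector)
NO_PREDICTION = -1


# ---------------------------------------------------------------------------
# Per-entry scoring
# ---------------------------------------------------------------------------

def predict(likelihoods: RegionLikelihood) -> tuple[str | None, float]:
    """(argmax region, its likelihood); (None, 0.0) for an all-zero vector.

    Ties break toward the earlier canonical region.
    """
    vector = likelihoods.as_array()
    if not vector.any():
        return None, 0.0
    top = int(np.argmax(vector))  # first maximum = canonical-order tie-break
    return REGIONS[top], float(vector[top])


@dataclass(frozen=True)
class ConfidenceScore:
    entropy_bits: float
    normalized_entropy: float
    confidence: float


def confidence(likelihoods: RegionLikelihood) -> ConfidenceScore:
    """Entropy-based confidence C = 1 - H/log2(7), with 0·log0 := 0.

    The vector is renormalized to a probability distribution first; a vector
    with no mass is maximally uncertain by convention (H = log2 7, C = 0).
    """
    vector = likelihoods.as_array()
    total = vector.sum()
    if total <= 0:
        return ConfidenceScore(MAX_ENTROPY_BITS, 1.0, 0.0)
    h = float(_scipy_entropy(vector, base=2))  # scipy renormalizes and skips zeros
    normalized = h / MAX_ENTROPY_BITS
    return ConfidenceScore(h, normalized, 1.0 - normalized)


ProbabilityMode = Literal["predicted", "true"]


@dataclass(frozen=True)
class Prediction:
    """One scored entry: prediction, correctness, confidence, probability."""

    entry_id: str
    predicted: str | None
    truth: tuple[str, ...]
    correct: bool
    confidence: float
    probability: float  # in [0, 1]; pairing defined by ProbabilityMode
    word_count: int = 0
    parse_status: str = "ok"


def make_prediction(
    entry: SemiologyEntry,
    parsed: ParsedResponse,
    probability_mode: ProbabilityMode = "predicted",
) -> Prediction:
    """Score one parsed response against an entry's truth set."""
    region, top_value = predict(parsed.likelihoods)
    correct = region is not None and region in entry.truth
    if probability_mode == "predicted":
        raw_p = top_value
    elif probability_mode == "true":
        raw_p = max(parsed.likelihoods[r] for r in entry.truth)
    else:
        raise ValueError(f"unknown probability mode {probability_mode!r}")
    return Prediction(
        entry_id=entry.id,
        predicted=region,
        truth=entry.truth,
        correct=bool(correct),
        confidence=confidence(parsed.likelihoods).confidence,
        probability=float(np.clip(raw_p / 100.0, 0.0, 1.0)),
        word_count=entry.word_count,
        parse_status=parsed.status,
    )


# ---------------------------------------------------------------------------
# Weighted precision / recall / F1
# ---------------------------------------------------------------------------

def _codes(predictions: Sequence[Prediction]) -> tuple[np.ndarray, np.ndarray]:
    """(y_true, y_pred) integer codes under the multi-label crediting rule.

    A correct prediction credits the matched truth region; an incorrect one
    counts the first-listed truth region as the missed class. NO_PREDICTION
    codes an all-zero vector.
    """
    y_true = np.empty(len(predictions), dtype=np.int64)
    y_pred = np.empty(len(predictions), dtype=np.int64)
    for i, p in enumerate(predictions):
        pred_code = REGION_INDEX[p.predicted] if p.predicted is not None else NO_PREDICTION
        y_pred[i] = pred_code
        y_true[i] = pred_code if p.correct else REGION_INDEX[p.truth[0]]
    return y_true, y_pred


def _weighted_prf1_from_codes(
    y_true: np.ndarray, y_pred: np.ndarray
) -> tuple[float, float, float]:
    """Support-weighted one-vs-rest P/R/F1 from integer codes (vectorized)."""
    tp = np.zeros(N_REGIONS)
    pred_count = np.zeros(N_REGIONS)
    true_count = np.zeros(N_REGIONS)
    valid_pred = y_pred >= 0
    np.add.at(tp, y_true[(y_true == y_pred) & valid_pred], 1.0)
    np.add.at(pred_count, y_pred[valid_pred], 1.0)
    np.add.at(true_count, y_true, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(pred_count > 0, tp / pred_count, 0.0)
        recall = np.where(true_count > 0, tp / true_count, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    weights = true_count / true_count.sum()
    return (
        float(precision @ weights),
        float(recall @ weights),
        float(f1 @ weights),
    )


def weighted_prf1(predictions: Sequence[Prediction]) -> tuple[float, float, float]:
    """Support-weighted precision, recall and F1 over scored entries."""
    if not predictions:
        raise ValueError("cannot score an empty prediction list")
    return _weighted_prf1_from_codes(*_codes(predictions))


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationBin:
    index: int              # 1-based bin number m
    lower: float            # interval ((m-1)/M, m/M]
    upper: float
    size: int
    fraction_positive: float  # mean correctness in the bin (NaN when empty)
    mean_confidence: float    # mean probability in the bin (NaN when empty)


@dataclass(frozen=True)
class CalibrationReport:
    n_bins: int
    bins: tuple[CalibrationBin, ...]
    brier: float
    n_samples: int

    @property
    def max_gap(self) -> float:
        """Largest |F_pos - Conf| over occupied bins."""
        gaps = [
            abs(b.fraction_positive - b.mean_confidence)
            for b in self.bins
            if b.size > 0
        ]
        return max(gaps) if gaps else float("nan")


def reliability(predictions: Sequence[Prediction], n_bins: int = 10) -> CalibrationReport:
    """Equal-width reliability bins over ((m-1)/M, m/M] plus the Brier score.

    Probabilities of exactly 0 (failed parses) land in the first bin so that
    unconfident failures are not silently dropped from calibration.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    if not predictions:
        raise ValueError("cannot bin an empty prediction list")
    p = np.array([x.probability for x in predictions])
    outcome = np.array([x.correct for x in predictions], dtype=float)
    # p in ((m-1)/M, m/M]  =>  m = ceil(p*M); clamp p=0 into bin 1
    bin_index = np.maximum(np.ceil(p * n_bins).astype(int), 1)
    bins = []
    for m in range(1, n_bins + 1):
        mask = bin_index == m
        size = int(mask.sum())
        bins.append(
            CalibrationBin(
                index=m,
                lower=(m - 1) / n_bins,
                upper=m / n_bins,
                size=size,
                fraction_positive=float(outcome[mask].mean()) if size else float("nan"),
                mean_confidence=float(p[mask].mean()) if size else float("nan"),
            )
        )
    return CalibrationReport(
        n_bins=n_bins,
        bins=tuple(bins),
        brier=brier(predictions),
        n_samples=len(predictions),
    )


def brier(predictions: Sequence[Prediction]) -> float:
    """Mean squared difference between probability and binary correctness."""
    if not predictions:
        raise ValueError("cannot score an empty prediction list")
    p = np.array([x.probability for x in predictions])
    outcome = np.array([x.correct for x in predictions], dtype=float)
    return float(np.mean((p - outcome) ** 2))


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BootstrapCI:
    mean: float
    lower: float
    upper: float
    n_resamples: int
    level: float


def bootstrap_ci(
    scores: Sequence[float],
    n_resamples: int = 999,
    level: float = 95.0,
    seed: int = 0,
    statistic: Callable[[np.ndarray], float] = np.mean,
) -> BootstrapCI:
    """Percentile bootstrap CI of ``statistic`` over per-entry scores."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("cannot bootstrap an empty score list")
    if n_resamples < 1:
        raise ValueError("need at least one resample")
    rng = np.random.default_rng(seed)
    stats = np.empty(n_resamples)
    for b in range(n_resamples):
        stats[b] = statistic(scores[rng.integers(0, scores.size, scores.size)])
    alpha = (100.0 - level) / 2.0
    return BootstrapCI(
        mean=float(stats.mean()),
        lower=float(np.percentile(stats, alpha)),
        upper=float(np.percentile(stats, 100.0 - alpha)),
        n_resamples=n_resamples,
        level=level,
    )


def bootstrap_f1(
    predictions: Sequence[Prediction],
    n_resamples: int = 999,
    level: float = 95.0,
    seed: int = 0,
) -> BootstrapCI:
    """Percentile bootstrap of weighted F1, resampling entries."""
    if not predictions:
        raise ValueError("cannot bootstrap an empty prediction list")
    y_true, y_pred = _codes(predictions)
    rng = np.random.default_rng(seed)
    stats = np.empty(n_resamples)
    n = len(predictions)
    for b in range(n_resamples):
        idx = rng.integers(0, n, n)
        stats[b] = _weighted_prf1_from_codes(y_true[idx], y_pred[idx])[2]
    alpha = (100.0 - level) / 2.0
    return BootstrapCI(
        mean=float(stats.mean()),
        lower=float(np.percentile(stats, alpha)),
        upper=float(np.percentile(stats, 100.0 - alpha)),
        n_resamples=n_resamples,
        level=level,
    )


# ---------------------------------------------------------------------------
# Assembled report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricsReport:
    n_entries: int
    precision: float
    recall: float
    f1: float
    accuracy: float
    mean_confidence: float
    calibration: CalibrationReport
    f1_bootstrap: BootstrapCI
    parse_ok_fraction: float

    def as_dict(self) -> dict:
        return {
            "n_entries": self.n_entries,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "f1_pct": 100.0 * self.f1,
            "accuracy": self.accuracy,
            "mean_confidence": self.mean_confidence,
            "brier": self.calibration.brier,
            "f1_ci_lower": self.f1_bootstrap.lower,
            "f1_ci_upper": self.f1_bootstrap.upper,
            "parse_ok_fraction": self.parse_ok_fraction,
            "calibration_bins": [
                {
                    "bin": b.index,
                    "lower": b.lower,
                    "upper": b.upper,
                    "size": b.size,
                    "fraction_positive": b.fraction_positive,
                    "mean_confidence": b.mean_confidence,
                }
                for b in self.calibration.bins
            ],
        }


def evaluate(
    predictions: Sequence[Prediction],
    n_bins: int = 10,
    n_boot: int = 999,
    seed: int = 0,
) -> MetricsReport:
    """Full scoring of a prediction set (correctness, confidence, calibration)."""
    precision, recall, f1 = weighted_prf1(predictions)
    return MetricsReport(
        n_entries=len(predictions),
        precision=precision,
        recall=recall,
        f1=f1,
        accuracy=float(np.mean([p.correct for p in predictions])),
        mean_confidence=float(np.mean([p.confidence for p in predictions])),
        calibration=reliability(predictions, n_bins),
        f1_bootstrap=bootstrap_f1(predictions, n_resamples=n_boot, seed=seed),
        parse_ok_fraction=float(np.mean([p.parse_status == "ok" for p in predictions])),
    )
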