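"""Permutation chance baselines, z-scores, and multiple-testing correction.

Whether a model's weighted F1 means anything is judged against a null
distribution obtained by shuffling the ground-truth labels (multi-label sets
move as units) while holding the predictions fixed. The observed score is
z-normalized against that distribution, z = (x - mu) / sigma, and a two-sided
p-value is taken from the standard normal tail; the empirical permutation rank
p is reported alongside. Families of tests are corrected with
Benjamini-Hochberg. A pooled two-proportion z-test covers paired comparisons of
correctness/completeness rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .metrics import Prediction, _codes, _weighted_prf1_from_codes


@dataclass(frozen=True)
class SignificanceReport:
    score: float          # observed weighted F1
    null_mean: float
    null_sd: float
    z: float
    p: float              # two-sided, normal approximation of z
    p_empirical: float    # permutation-rank p, (1 + #{null >= x}) / (n_perm + 1)
    n_perm: int
    p_adjusted: float | None = None
    degenerate: bool = False


def permutation_null(
    predictions: Sequence[Prediction],
    n_perm: int = 999,
    seed: int = 0,
) -> np.ndarray:
    """Weighted-F1 null distribution from label permutations.

    Predictions stay fixed; the truth sets are permuted across entries as
    whole units before re-deriving the crediting codes, so multi-label sets
    stay intact. Deterministic for a fixed seed.
    """
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    if not predictions:
        raise ValueError("cannot permute an empty prediction list")
    rng = np.random.default_rng(seed)
    pred_codes = np.array(
        [-1 if p.predicted is None else _region_code(p.predicted) for p in predictions]
    )
    truth_matrix = np.zeros((len(predictions), 7), dtype=bool)
    first_truth = np.empty(len(predictions), dtype=np.int64)
    for i, p in enumerate(predictions):
        for region in p.truth:
            truth_matrix[i, _region_code(region)] = True
        first_truth[i] = _region_code(p.truth[0])
    null = np.empty(n_perm)
    n = len(predictions)
    for b in range(n_perm):
        perm = rng.permutation(n)
        t_matrix = truth_matrix[perm]
        t_first = first_truth[perm]
        valid = pred_codes >= 0
        correct = np.zeros(n, dtype=bool)
        correct[valid] = t_matrix[valid, pred_codes[valid]]
        y_true = np.where(correct, pred_codes, t_first)
        null[b] = _weighted_prf1_from_codes(y_true, pred_codes)[2]
    return null


def _region_code(region: str) -> int:
    from .corpus import REGION_INDEX

    return REGION_INDEX[region]


def z_and_p(x: float, null: Sequence[float], ddof: int = 1) -> SignificanceReport:
    """Z-score of an observed score against a null distribution, with p-values."""
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    mu = float(null.mean())
    sigma = float(null.std(ddof=ddof)) if null.size > 1 else 0.0
    p_empirical = float((1 + np.sum(null >= x)) / (null.size + 1))
    if sigma == 0.0:
        degenerate = True
        if np.isclose(x, mu):
            z, p = 0.0, 1.0
        else:
            z = float("inf") if x > mu else float("-inf")
            p = 0.0
    else:
        degenerate = False
        z = (x - mu) / sigma
        # floor at the smallest normal float: extreme z underflows sf() to 0,
        # which would violate the (0, 1] contract BH correction relies on
        p = max(float(2.0 * norm.sf(abs(z))), float(np.finfo(float).tiny))
    return SignificanceReport(
        score=float(x),
        null_mean=mu,
        null_sd=sigma,
        z=float(z),
        p=min(max(p, 0.0), 1.0) if np.isfinite(z) else p,
        p_empirical=p_empirical,
        n_perm=int(null.size),
        degenerate=degenerate,
    )


def permutation_test(
    predictions: Sequence[Prediction],
    n_perm: int = 999,
    seed: int = 0,
) -> SignificanceReport:
    """Observed weighted F1 vs. the label-permutation null (convenience wrapper)."""
    from .metrics import weighted_prf1

    x = weighted_prf1(predictions)[2]
    null = permutation_null(predictions, n_perm=n_perm, seed=seed)
    return z_and_p(x, null)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise ValueError("empty p-value list")
    if (pvals <= 0).any() or (pvals > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def two_proportion_z(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z statistic and two-sided normal p-value."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    z, p = proportions_ztest([k1, k2], [n1, n2], alternative="two-sided")
    return float(z), float(p)
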