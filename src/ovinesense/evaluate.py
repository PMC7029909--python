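"""Performance metrics and sheep-level group-separation statistics.

Window-level performance uses the usual confusion-matrix metrics
(overall accuracy, precision, recall, F-score, specificity).  Sheep-level
evaluation aggregates each sheep's out-of-fold predictions into a
lame-window ratio and compares the lame and non-lame groups with

    Δσ = (μ_lame − σ_lame) − (μ_nonlame + σ_nonlame),

the gap between the two groups' one-standard-deviation intervals
(positive iff they do not overlap), a Mann-Whitney U test on the ratios,
and a midpoint decision threshold (μ_lame + μ_nonlame)/2 above which an
individual sheep is declared lame.

σ is the sample standard deviation (ddof=1); a singleton group takes
σ = 0.  The Mann-Whitney test is two-sided, exact for combined n ≤ 20
(no ties), normal approximation with tie correction otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN for one binary evaluation (lame = positive class)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    """The five window-level performance metrics, each in [0, 1]."""

    overall_accuracy: float
    precision: float
    recall: float
    f_score: float
    specificity: float
    undefined: tuple[str, ...] = ()  # metrics whose denominator was 0


@dataclass(frozen=True)
class GroupSeparation:
    """Sheep-level separation between the lame and non-lame groups."""

    ratios_lame: np.ndarray
    ratios_nonlame: np.ndarray
    mu_lame: float
    sigma_lame: float
    mu_nonlame: float
    sigma_nonlame: float
    delta_sigma: float
    threshold: float
    mann_whitney_u: float
    p_value: float


def compute_metrics(counts: ConfusionCounts) -> MetricSet:
    """Accuracy, precision, recall, F-score and specificity from counts.

    A zero-denominator ratio is reported as 0 and flagged in
    ``undefined`` rather than raising.
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    undefined = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    accuracy = (counts.tp + counts.tn) / counts.total
    precision = ratio(counts.tp, counts.tp + counts.fp, "precision")
    recall = ratio(counts.tp, counts.tp + counts.fn, "recall")
    specificity = ratio(counts.tn, counts.tn + counts.fp, "specificity")
    if precision + recall > 0:
        f_score = 2 * precision * recall / (precision + recall)
    else:
        undefined.append("f_score")
        f_score = 0.0
    return MetricSet(
        overall_accuracy=accuracy,
        precision=precision,
        recall=recall,
        f_score=f_score,
        specificity=specificity,
        undefined=tuple(undefined),
    )


def per_sheep_lame_ratio(predictions: pd.DataFrame) -> pd.Series:
    """Fraction of each sheep's windows predicted lame.

    ``predictions`` needs ``sheep_id`` and ``predicted_lame`` columns
    (one row per out-of-fold window prediction); the result is indexed
    by sheep_id and invariant to row order.
    """
    required = {"sheep_id", "predicted_lame"}
    missing = required - set(predictions.columns)
    if missing:
        raise ValueError(f"predictions missing columns {sorted(missing)}")
    grouped = predictions.groupby("sheep_id")["predicted_lame"]
    return grouped.mean().astype(float)


def _group_stats(ratios: np.ndarray) -> tuple[float, float]:
    ratios = np.asarray(ratios, dtype=float)
    mu = float(np.mean(ratios))
    sigma = float(np.std(ratios, ddof=1)) if len(ratios) > 1 else 0.0
    return mu, sigma


def mann_whitney(
    ratios_lame: np.ndarray, ratios_nonlame: np.ndarray
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U on the two groups of per-sheep ratios.

    Exact distribution for combined n ≤ 20 without ties; otherwise the
    normal approximation with tie correction.  Identical constant groups
    give p = 1 (no evidence either way).
    """
    x = np.asarray(ratios_lame, dtype=float)
    y = np.asarray(ratios_nonlame, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return float(len(x) * len(y) / 2.0), 1.0
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(combined) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def sigma_difference(
    ratios_lame: np.ndarray, ratios_nonlame: np.ndarray
) -> GroupSeparation:
    """Δσ, midpoint threshold and Mann-Whitney comparison of the groups."""
    x = np.asarray(ratios_lame, dtype=float)
    y = np.asarray(ratios_nonlame, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    mu_l, sd_l = _group_stats(x)
    mu_n, sd_n = _group_stats(y)
    u, p = mann_whitney(x, y)
    return GroupSeparation(
        ratios_lame=x,
        ratios_nonlame=y,
        mu_lame=mu_l,
        sigma_lame=sd_l,
        mu_nonlame=mu_n,
        sigma_nonlame=sd_n,
        delta_sigma=(mu_l - sd_l) - (mu_n + sd_n),
        threshold=(mu_l + mu_n) / 2.0,
        mann_whitney_u=u,
        p_value=p,
    )


def sheep_level_classify(
    ratios: pd.Series, true_lame: pd.Series, threshold: float
) -> tuple[pd.DataFrame, float]:
    """Per-sheep verdicts under the midpoint threshold.

    A sheep is declared lame iff its lame-window ratio is *strictly*
    above the threshold.  Returns the verdict table and the sheep-level
    accuracy as a percentage (correct / total × 100).
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    ratios, true_lame = ratios.align(true_lame, join="inner")
    verdicts = pd.DataFrame(
        {
            "ratio": ratios,
            "threshold": threshold,
            "predicted": ratios > threshold,
            "true": true_lame.astype(bool),
        }
    )
    verdicts["correct"] = verdicts["predicted"] == verdicts["true"]
    accuracy_pct = sheep_level_accuracy(int(verdicts["correct"].sum()), len(verdicts))
    return verdicts, accuracy_pct


def sheep_level_accuracy(n_correct: int, n_total: int) -> float:
    """Sheep-level accuracy in percent, rounded to the reporting
    precision (2 decimals): correct / total × 100."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_correct <= n_total):
        raise ValueError("n_correct must be in [0, n_total]")
    return round(100.0 * n_correct / n_total, 2)


def evaluate_sheep_level(
    predictions: pd.DataFrame,
) -> tuple[GroupSeparation, pd.DataFrame, float]:
    """Full sheep-level chain from out-of-fold window predictions.

    ``predictions`` needs ``sheep_id``, ``lame`` (true label) and
    ``predicted_lame``.  Returns the group separation, the per-sheep
    verdict table and the sheep-level accuracy percentage.
    """
    required = {"sheep_id", "lame", "predicted_lame"}
    missing = required - set(predictions.columns)
    if missing:
        raise ValueError(f"predictions missing columns {sorted(missing)}")
    ratios = per_sheep_lame_ratio(predictions)
    truth = predictions.groupby("sheep_id")["lame"].first().astype(bool)
    lame_ratios = ratios[truth].to_numpy()
    nonlame_ratios = ratios[~truth].to_numpy()
    if len(lame_ratios) == 0 or len(nonlame_ratios) == 0:
        raise ValueError(
            "empty group: need at least one lame and one non-lame sheep "
            f"(got {len(lame_ratios)} lame, {len(nonlame_ratios)} non-lame)"
        )
    separation = sigma_difference(lame_ratios, nonlame_ratios)
    verdicts, accuracy = sheep_level_classify(ratios, truth, separation.threshold)
    return separation, verdicts, accuracy
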