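"""Discrimination, association and calibration of confidence metrics.

For each (model, metric) pair, a confidence score per case is related to
the binary correctness of that metric's representative answer:

* discrimination — ROC AUC with DeLong variance (95% CI, two-sided p
  against AUC = 0.5);
* association — Spearman rho with a Fisher-z CI (SE 1/sqrt(n-3)), a
  two-sided p from the t approximation, and an interpretation band
  (negligible <= 0.10 < weak <= 0.39 < moderate <= 0.69 < strong <= 0.89
  < very strong);
* calibration — fixed equal-width 10-bin expected calibration error and
  the binary Brier score, with percentile bootstrap CIs (case-level
  resampling, 1000 iterations by default).

Before calibration every metric is mapped to [0, 1]: percentage-scaled
metrics (self-reported, majority %, TWS) are divided by 100; the relative
entropy score is already in [0, 1].  ECE and Brier compare a confidence
on [0, 1] with a 0/1 outcome, so a common domain is required.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .metrics import METRIC_NAMES, ConfidenceProfile

__all__ = [
    "EvalResult",
    "CalibrationInput",
    "roc_auc_delong",
    "spearman_assoc",
    "spearman_band",
    "ece_fixed_bins",
    "reliability_table",
    "brier_binary",
    "bootstrap_ci",
    "mann_whitney",
    "evaluate_model",
    "results_to_frame",
]

logger = logging.getLogger(__name__)


class CalibrationInput(NamedTuple):
    """Per-case confidence on [0, 1] paired with binary correctness."""

    conf: np.ndarray
    correct: np.ndarray


@dataclass
class EvalResult:
    """One (model, metric) row of evaluation statistics."""

    model_id: str
    metric_name: str
    n_cases: int
    auc: float
    auc_ci: tuple[float, float]
    auc_p: float
    rho: float
    rho_ci: tuple[float, float]
    rho_p: float
    rho_band: str
    ece: float | None = None
    ece_ci: tuple[float, float] | None = None
    brier: float | None = None
    brier_ci: tuple[float, float] | None = None


# --- discrimination ---------------------------------------------------------


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def roc_auc_delong(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, tuple[float, float], float]:
    """ROC AUC with DeLong variance.

    The AUC is the Mann-Whitney estimator (ties get half credit); its
    standard error comes from the DeLong structural components
    ``V10_i = mean_j psi(x_i, y_j)`` and ``V01_j = mean_i psi(x_i, y_j)``
    with ``var(AUC) = S10/m + S01/n``.  Returns
    ``(auc, (lo, hi), p)`` where the CI is ``auc +/- 1.96 SE`` truncated
    to [0, 1] and p tests AUC = 0.5 two-sided against a normal reference.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("AUC undefined: both correctness classes required")
    # psi(x, y) = 1 if x > y, 1/2 if tied, 0 otherwise, vectorized
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    auc = float(psi.mean())
    v10 = psi.mean(axis=1)  # per-positive component
    v01 = psi.mean(axis=0)  # per-negative component
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    se = math.sqrt(s10 / m + s01 / n)
    lo = max(0.0, auc - 1.96 * se)
    hi = min(1.0, auc + 1.96 * se)
    if se > 0:
        z = (auc - 0.5) / se
        p = 2.0 * stats.norm.sf(abs(z))
    else:
        p = 1.0 if auc == 0.5 else 0.0
    return auc, (lo, hi), float(p)


# --- association ------------------------------------------------------------

_RHO_BANDS = (
    (0.10, "negligible"),
    (0.39, "weak"),
    (0.69, "moderate"),
    (0.89, "strong"),
    (float("inf"), "very strong"),
)


def spearman_band(rho: float) -> str:
    """Interpretation band for |rho| (negligible ... very strong)."""
    a = abs(rho)
    for cutoff, name in _RHO_BANDS:
        if a <= cutoff:
            return name
    raise AssertionError("unreachable")


def spearman_assoc(
    scores: Sequence[float], labels: Sequence[float]
) -> tuple[float, tuple[float, float], float, str]:
    """Spearman rho with a Fisher-z 95% CI and interpretation band.

    rho and the two-sided p (t approximation) come from
    ``scipy.stats.spearmanr`` on midranks; the CI is
    ``tanh(atanh(rho) +/- 1.96/sqrt(n-3))``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    n = len(scores)
    if n < 4:
        raise ValueError(f"need n >= 4 for Spearman, got {n}")
    if np.all(scores == scores[0]) or np.all(labels == labels[0]):
        raise ValueError("Spearman undefined on a constant vector")
    res = stats.spearmanr(scores, labels)
    rho = float(res.statistic)
    p = float(res.pvalue)
    z = math.atanh(max(min(rho, 1 - 1e-15), -1 + 1e-15))
    half = 1.96 / math.sqrt(n - 3)
    ci = (math.tanh(z - half), math.tanh(z + half))
    return rho, ci, p, spearman_band(rho)


# --- calibration ------------------------------------------------------------


def _check_calibration(conf: np.ndarray, correct: np.ndarray) -> None:
    if conf.shape != correct.shape or conf.ndim != 1:
        raise ValueError("conf and correct must be 1-d arrays of equal length")
    if len(conf) < 1:
        raise ValueError("calibration input is empty")
    if np.any(conf < 0) or np.any(conf > 1):
        raise ValueError("confidence must lie in [0, 1]; rescale before calling")


def _bin_index(conf: np.ndarray, n_bins: int) -> np.ndarray:
    # equal-width bins [lo, hi) on [0, 1], final bin closed at 1.0
    return np.minimum((conf * n_bins).astype(int), n_bins - 1)


def ece_fixed_bins(
    conf: Sequence[float], correct: Sequence[int], n_bins: int = 10
) -> float:
    """Expected calibration error on fixed equal-width bins.

    ``ECE = sum_b (n_b / n) * |mean_conf_b - accuracy_b|``; empty bins
    contribute nothing.
    """
    conf = np.asarray(conf, dtype=float)
    correct = np.asarray(correct, dtype=float)
    _check_calibration(conf, correct)
    idx = _bin_index(conf, n_bins)
    n = len(conf)
    ece = 0.0
    for b in range(n_bins):
        mask = idx == b
        nb = int(mask.sum())
        if nb == 0:
            continue
        ece += (nb / n) * abs(conf[mask].mean() - correct[mask].mean())
    return float(ece)


def reliability_table(
    conf: Sequence[float], correct: Sequence[int], n_bins: int = 10
):
    """Per-bin (mean confidence, accuracy, count) for reliability diagrams."""
    import pandas as pd

    conf = np.asarray(conf, dtype=float)
    correct = np.asarray(correct, dtype=float)
    _check_calibration(conf, correct)
    idx = _bin_index(conf, n_bins)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        nb = int(mask.sum())
        rows.append(
            {
                "bin": b,
                "bin_lo": b / n_bins,
                "bin_hi": (b + 1) / n_bins,
                "mean_conf": float(conf[mask].mean()) if nb else float("nan"),
                "accuracy": float(correct[mask].mean()) if nb else float("nan"),
                "count": nb,
            }
        )
    return pd.DataFrame(rows)


def brier_binary(conf: Sequence[float], correct: Sequence[int]) -> float:
    """Binary Brier score: mean of (confidence - correctness)^2."""
    conf = np.asarray(conf, dtype=float)
    correct = np.asarray(correct, dtype=float)
    _check_calibration(conf, correct)
    return float(np.mean((conf - correct) ** 2))


def bootstrap_ci(
    stat: Callable[[np.ndarray, np.ndarray], float],
    conf: Sequence[float],
    correct: Sequence[int],
    iters: int = 1000,
    seed: int | np.random.Generator = 0,
    max_redraws: int = 100,
) -> tuple[float, float]:
    """Percentile 95% bootstrap CI by case-level resampling.

    Cases are the exchangeable unit: each iteration resamples case indices
    with replacement and recomputes ``stat``.  A resample on which the
    statistic is undefined (e.g. a single correctness class) is redrawn;
    the number of redraws is logged.  Reproducible given ``seed``.
    """
    conf = np.asarray(conf, dtype=float)
    correct = np.asarray(correct, dtype=float)
    n = len(conf)
    if n < 2:
        raise ValueError("need >= 2 cases to bootstrap")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    values = np.empty(iters)
    redraws = 0
    for i in range(iters):
        for _ in range(max_redraws + 1):
            idx = rng.integers(0, n, size=n)
            try:
                values[i] = stat(conf[idx], correct[idx])
                break
            except (ValueError, ZeroDivisionError):
                redraws += 1
        else:
            raise RuntimeError(
                f"statistic failed on {max_redraws} consecutive resamples"
            )
    if redraws:
        logger.info("bootstrap: %d degenerate resamples redrawn", redraws)
    lo, hi = np.percentile(values, [2.5, 97.5])
    return float(lo), float(hi)


# --- group comparison -------------------------------------------------------


def mann_whitney(
    scores_correct: Sequence[float], scores_incorrect: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparing scores of correct vs incorrect cases.

    Exact enumeration when both groups have <= 8 members and no ties span
    the groups; otherwise the normal approximation with tie correction.
    """
    x = np.asarray(scores_correct, dtype=float)
    y = np.asarray(scores_incorrect, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    exact = len(x) <= 8 and len(y) <= 8 and len(np.unique(np.r_[x, y])) == len(x) + len(y)
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# --- per-model evaluation ---------------------------------------------------

#: divide-by-100 rescaling into [0, 1] for calibration, per metric
_CAL_SCALE = {
    "first_conf": 100.0,
    "mean_conf_majority": 100.0,
    "majority_pct": 100.0,
    "tws": 100.0,
    "r_h": 1.0,
}


def evaluate_model(
    profiles: Sequence[ConfidenceProfile],
    model_id: str | None = None,
    depth: int | None = None,
    *,
    bootstrap_iters: int = 1000,
    seed: int = 0,
    n_bins: int = 10,
    include_entropy: bool = True,
) -> list[EvalResult]:
    """Full discrimination/association/calibration table for one model.

    One :class:`EvalResult` per metric, each paired with its own
    representative-answer correctness.  The raw Shannon entropy is also
    evaluated with sign-flipped scores (higher = more confident); being a
    strictly monotone transform of the relative entropy score, its AUC is
    identical, and it carries no [0, 1] calibration mapping, so ECE and
    Brier are omitted for it.  A metric missing for more than half the
    cases is skipped with a warning.  ``bootstrap_iters=0`` skips the
    calibration CIs.
    """
    rows = [
        p
        for p in profiles
        if (model_id is None or p.model_id == model_id)
        and (depth is None or p.depth == depth)
    ]
    if len(rows) < 2:
        raise ValueError("need >= 2 profiles to evaluate")
    if model_id is None:
        ids = {p.model_id for p in rows}
        if len(ids) > 1:
            raise ValueError(f"profiles span several models: {sorted(ids)}")
        model_id = next(iter(ids))

    metric_list = list(METRIC_NAMES) + (["shannon_entropy"] if include_entropy else [])
    results: list[EvalResult] = []
    rng = np.random.default_rng(seed)
    for metric in metric_list:
        if metric == "shannon_entropy":
            pairs = [
                (-p.entropy_H, p.correctness["r_h"])
                for p in rows
                if p.correctness["r_h"] is not None
            ]
        else:
            pairs = [
                (getattr(p, metric), p.correctness[metric])
                for p in rows
                if getattr(p, metric) is not None
                and p.correctness[metric] is not None
            ]
        if len(pairs) <= 0.5 * len(rows):
            logger.warning(
                "metric %s missing for > 50%% of cases (model %s); skipped",
                metric,
                model_id,
            )
            continue
        scores = np.array([s for s, _ in pairs], dtype=float)
        labels = np.array([int(c) for _, c in pairs], dtype=int)
        if labels.min() == labels.max():
            raise ValueError(
                f"both correctness classes required for metric {metric!r} "
                f"(model {model_id})"
            )
        auc, auc_ci, auc_p = roc_auc_delong(scores, labels)
        try:
            rho, rho_ci, rho_p, band = spearman_assoc(scores, labels)
        except ValueError:
            rho, rho_ci, rho_p, band = (
                float("nan"),
                (float("nan"), float("nan")),
                float("nan"),
                "undefined",
            )
        res = EvalResult(
            model_id=model_id,
            metric_name=metric,
            n_cases=len(pairs),
            auc=auc,
            auc_ci=auc_ci,
            auc_p=auc_p,
            rho=rho,
            rho_ci=rho_ci,
            rho_p=rho_p,
            rho_band=band,
        )
        if metric in _CAL_SCALE:
            conf = scores / _CAL_SCALE[metric]
            res.ece = ece_fixed_bins(conf, labels, n_bins)
            res.brier = brier_binary(conf, labels)
            if bootstrap_iters > 0:
                res.ece_ci = bootstrap_ci(
                    lambda c, y: ece_fixed_bins(c, y, n_bins),
                    conf,
                    labels,
                    iters=bootstrap_iters,
                    seed=rng,
                )
                res.brier_ci = bootstrap_ci(
                    brier_binary, conf, labels, iters=bootstrap_iters, seed=rng
                )
        results.append(res)
    return results


def results_to_frame(results: Sequence[EvalResult]):
    """Tidy DataFrame: (model, metric, statistic, point, lo, hi, p)."""
    import pandas as pd

    rows = []
    for r in results:
        rows.append(
            dict(model_id=r.model_id, metric=r.metric_name, statistic="auc",
                 point=r.auc, lo=r.auc_ci[0], hi=r.auc_ci[1], p=r.auc_p,
                 n_cases=r.n_cases)
        )
        rows.append(
            dict(model_id=r.model_id, metric=r.metric_name, statistic="rho",
                 point=r.rho, lo=r.rho_ci[0], hi=r.rho_ci[1], p=r.rho_p,
                 n_cases=r.n_cases, band=r.rho_band)
        )
        if r.ece is not None:
            lo, hi = r.ece_ci if r.ece_ci else (float("nan"), float("nan"))
            rows.append(
                dict(model_id=r.model_id, metric=r.metric_name, statistic="ece",
                     point=r.ece, lo=lo, hi=hi, p=float("nan"), n_cases=r.n_cases)
            )
        if r.brier is not None:
            lo, hi = r.brier_ci if r.brier_ci else (float("nan"), float("nan"))
            rows.append(
                dict(model_id=r.model_id, metric=r.metric_name, statistic="brier",
                     point=r.brier, lo=lo, hi=hi, p=float("nan"),
                     n_cases=r.n_cases)
            )
    return pd.DataFrame(rows)
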