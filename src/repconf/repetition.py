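"""Repetition-depth accuracy, repeatability and contamination checks.

How many repeated generations are needed?  This module quantifies:

* accuracy per repetition depth — depth 1 scores the first output, deeper
  depths score the majority-vote answer over the first d repetitions;
* Cochran Q across depth conditions (are the per-case correctness
  patterns different between depths?);
* Fleiss kappa — chance-corrected agreement among the n repetitions per
  case, i.e. within-model repeatability, with the usual interpretation
  bands (>0.8 almost perfect, 0.61-0.80 substantial, 0.41-0.60 moderate,
  0.21-0.40 fair, otherwise poor);
* a temporal-holdout Fisher exact test comparing majority-vote accuracy
  on cases published before vs after a cutoff date, probing training-data
  contamination.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats import inter_rater
from statsmodels.stats.contingency_tables import cochrans_q

from .io import CaseRecord, ResponseSet
from .metrics import ConfidenceProfile, majority_vote, tally

__all__ = [
    "DepthAccuracy",
    "HoldoutResult",
    "depth_accuracy",
    "correctness_matrix",
    "cochran_q",
    "agreement_table",
    "fleiss_kappa",
    "kappa_band",
    "kappa_by_depth",
    "temporal_holdout",
]

DEFAULT_DEPTHS = (1, 5, 10, 15, 20)


@dataclass(frozen=True)
class DepthAccuracy:
    model_id: str
    depth: int
    n_correct: int
    n_cases: int

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * self.n_correct / self.n_cases


def _answer_at_depth(rset: ResponseSet, depth: int) -> str:
    """First output at depth 1, majority-vote answer at deeper depths."""
    if depth == 1:
        return rset.records[0].answer
    option, _, _ = majority_vote(tally(rset, depth))
    return option


def depth_accuracy(
    sets: Sequence[ResponseSet],
    model_id: str | None = None,
    depths: Sequence[int] = DEFAULT_DEPTHS,
) -> list[DepthAccuracy]:
    """Accuracy of the first output / majority vote at each depth."""
    sets = [s for s in sets if model_id is None or s.model_id == model_id]
    if not sets:
        raise ValueError("no response sets for the requested model")
    short = [s.case.case_id for s in sets if s.n < max(depths)]
    if short:
        raise ValueError(
            f"cases with fewer than {max(depths)} repetitions: {short}"
        )
    models = sorted({s.model_id for s in sets})
    out: list[DepthAccuracy] = []
    for mid in models:
        msets = [s for s in sets if s.model_id == mid]
        for depth in depths:
            n_correct = sum(
                _answer_at_depth(s, depth) == s.case.ground_truth for s in msets
            )
            out.append(
                DepthAccuracy(
                    model_id=mid, depth=depth, n_correct=n_correct,
                    n_cases=len(msets),
                )
            )
    return out


def correctness_matrix(
    sets: Sequence[ResponseSet], depths: Sequence[int] = DEFAULT_DEPTHS
) -> np.ndarray:
    """Binary cases x depth-conditions matrix for the Cochran Q test."""
    sets = sorted(sets, key=lambda s: s.case.case_id)
    return np.array(
        [
            [int(_answer_at_depth(s, d) == s.case.ground_truth) for d in depths]
            for s in sets
        ],
        dtype=int,
    )


def cochran_q(binary_matrix: np.ndarray) -> tuple[float, int, float]:
    """Cochran Q for related binary outcomes (cases x conditions).

    Returns ``(Q, df, p)`` with ``df = conditions - 1`` and p from the
    chi-square upper tail.  Rows constant across conditions contribute
    nothing; if *all* rows are constant, Q = 0 and p = 1 by convention.
    """
    x = np.asarray(binary_matrix, dtype=int)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a cases x conditions matrix, >= 2 of each")
    if not np.isin(x, (0, 1)).all():
        raise ValueError("matrix must be binary")
    df = x.shape[1] - 1
    row_sums = x.sum(axis=1)
    # denominator k*N - sum(R_i^2) vanishes iff every row is constant
    if x.shape[1] * row_sums.sum() == (row_sums**2).sum():
        return 0.0, df, 1.0
    res = cochrans_q(x, return_object=True)
    return float(res.statistic), df, float(res.pvalue)


def agreement_table(
    sets: Sequence[ResponseSet], depth: int | None = None
) -> np.ndarray:
    """Cases x categories count matrix with constant row sum = depth."""
    if not sets:
        raise ValueError("no response sets")
    options = sets[0].case.options
    rows = []
    for s in sets:
        if s.case.options != options:
            raise ValueError("agreement table requires a shared option set")
        rows.append([t.count for t in tally(s, depth)])
    return np.array(rows, dtype=int)


_KAPPA_BANDS = (
    (0.80, "almost perfect"),
    (0.60, "substantial"),
    (0.40, "moderate"),
    (0.20, "fair"),
)


def kappa_band(kappa: float) -> str:
    for cutoff, name in _KAPPA_BANDS:
        if kappa > cutoff:
            return name
    return "poor"


def fleiss_kappa(table: np.ndarray) -> tuple[float, str]:
    """Fleiss kappa ``(P - Pe) / (1 - Pe)`` on a cases x categories table.

    Rows are cases, columns categories, entries counts, with a constant
    row sum n >= 2 (the repetitions act as interchangeable raters).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2:
        raise ValueError("need a cases x categories table with >= 2 cases")
    row_sums = table.sum(axis=1)
    if not np.all(row_sums == row_sums[0]) or row_sums[0] < 2:
        raise ValueError("row sums must be constant and >= 2")
    if np.any(table < 0):
        raise ValueError("counts must be >= 0")
    marg = table.sum(axis=0) / table.sum()
    if np.max(marg) == 1.0:
        raise ValueError("kappa undefined: all responses in one category")
    kappa = float(inter_rater.fleiss_kappa(table, method="fleiss"))
    return kappa, kappa_band(kappa)


def kappa_by_depth(
    sets: Sequence[ResponseSet], depths: Sequence[int] = (5, 10, 15, 20)
) -> dict[int, float]:
    """Fleiss kappa over the first d repetitions, per depth d >= 2."""
    out: dict[int, float] = {}
    for d in depths:
        if d < 2:
            raise ValueError("kappa needs >= 2 repetitions per case")
        out[d] = fleiss_kappa(agreement_table(sets, d))[0]
    return out


@dataclass(frozen=True)
class HoldoutResult:
    """Temporal-holdout 2x2 table (strata x correctness) and Fisher p."""

    table: np.ndarray  # rows: (pre, post); cols: (correct, incorrect)
    p: float
    n_pre: int
    n_post: int
    n_excluded: int  # cases lacking a publication date


def temporal_holdout(
    profiles: Sequence[ConfidenceProfile],
    cases: Sequence[CaseRecord],
    cutoff_date: _dt.date,
    *,
    metric: str = "majority_pct",
) -> HoldoutResult:
    """Fisher exact test of accuracy before vs on/after ``cutoff_date``.

    Correctness is the majority-vote correctness carried by ``profiles``
    (computed at whatever depth the profiles hold, depth 20 in the
    standard pipeline).  Cases without a publication date are excluded,
    with the count reported.  Two-sided p by hypergeometric enumeration
    (all tables with probability <= the observed one).
    """
    date_by_id = {c.case_id: c.published_date for c in cases}
    table = np.zeros((2, 2), dtype=int)
    excluded = 0
    for p in profiles:
        date = date_by_id.get(p.case_id)
        if date is None:
            excluded += 1
            continue
        correct = p.correctness[metric]
        if correct is None:
            excluded += 1
            continue
        stratum = 0 if date < cutoff_date else 1
        table[stratum, 0 if correct else 1] += 1
    n_pre, n_post = int(table[0].sum()), int(table[1].sum())
    if n_pre == 0 or n_post == 0:
        raise ValueError("both temporal strata must be nonempty")
    _, pval = stats.fisher_exact(table, alternative="two-sided")
    return HoldoutResult(
        table=table, p=float(pval), n_pre=n_pre, n_post=n_post,
        n_excluded=excluded,
    )
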