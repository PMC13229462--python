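"""The five confidence metrics for repeated categorical answers.

Given n repeated answers to one multiple-choice case (k options), with a
verbalized confidence attached to each, the metrics are:

* **first self-reported confidence** — the confidence stated with the
  first response;
* **mean self-reported confidence** — mean confidence over the responses
  that chose the majority-vote answer;
* **relative entropy score** ``R_H = 1 - H / log2(k)`` where
  ``H = -sum_i p_i log2 p_i`` is the Shannon entropy (bits) of the answer
  frequencies ``p_i``; 1 means unanimous, 0 means uniform over all k;
* **majority-vote percentage** — the modal answer's share of responses;
* **Top Weighted Score (TWS)** — the maximum over options of
  ``count * mean_confidence / n``, a hybrid of consistency and verbalized
  confidence (e.g. A chosen 12/20 times at mean confidence 80 scores
  12*80/20 = 48).

Each metric has a *representative answer* whose correctness it is paired
with downstream: the majority-voted option for R_H, majority percentage
and mean self-reported confidence; the highest-weighted option for TWS;
and the first response for first self-reported confidence.

All computations can be truncated to the first ``depth`` repetitions in
generation order, so the same response set yields metric values at
repetition depths 5, 10, 15, 20, ...
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .io import ResponseSet

__all__ = [
    "METRIC_NAMES",
    "OptionTally",
    "ConfidenceProfile",
    "tally",
    "shannon_entropy",
    "relative_entropy_score",
    "majority_vote",
    "top_weighted_score",
    "self_reported",
    "build_profile",
    "build_profiles",
]

#: Canonical metric names, used as keys in correctness maps and outputs.
METRIC_NAMES = ("first_conf", "mean_conf_majority", "r_h", "majority_pct", "tws")


@dataclass(frozen=True)
class OptionTally:
    """Frequency and mean confidence for one option over the first n reps.

    ``mean_conf`` is averaged only over that option's choosers that carry
    a confidence; zero-count options carry ``None`` (never 0) so they can
    never win the Top Weighted Score spuriously.
    """

    option: str
    count: int
    mean_conf: float | None
    weighted_score: float | None  # count * mean_conf / n


@dataclass(frozen=True)
class ConfidenceProfile:
    """All metric values for one (case, model) at one repetition depth."""

    case_id: str
    model_id: str
    depth: int
    entropy_H: float
    r_h: float
    majority_option: str
    majority_pct: float
    majority_tie: bool
    first_answer: str
    first_conf: float | None
    mean_conf_majority: float | None
    tws_option: str | None
    tws: float | None
    tws_tie: bool
    correctness: dict[str, bool | None]

    def to_row(self) -> dict:
        """Flatten for CSV serialization (see ``repconf.io.write_profiles``)."""
        row = {
            "case_id": self.case_id,
            "model_id": self.model_id,
            "depth": self.depth,
            "entropy_H": self.entropy_H,
            "r_h": self.r_h,
            "majority_option": self.majority_option,
            "majority_pct": self.majority_pct,
            "majority_tie": self.majority_tie,
            "first_answer": self.first_answer,
            "first_conf": self.first_conf,
            "mean_conf_majority": self.mean_conf_majority,
            "tws_option": self.tws_option,
            "tws": self.tws,
            "tws_tie": self.tws_tie,
        }
        for name in METRIC_NAMES:
            row[f"correct_{name}"] = self.correctness.get(name)
        return row


def tally(rset: ResponseSet, depth: int | None = None) -> list[OptionTally]:
    """Tally answer frequencies and per-option mean confidence.

    Uses the first ``depth`` records in repetition order (all records when
    ``depth`` is None).  Every option of the case appears in the output,
    zero-count options included, in the case's canonical option order.
    """
    if depth is None:
        depth = rset.n
    if not 1 <= depth <= rset.n:
        raise ValueError(f"depth must be in [1, {rset.n}], got {depth}")
    records = rset.records[:depth]
    n = len(records)
    tallies: list[OptionTally] = []
    for option in rset.case.options:
        chosen = [r for r in records if r.answer == option]
        confs = [r.confidence_pct for r in chosen if r.confidence_pct is not None]
        mean_conf = sum(confs) / len(confs) if confs else None
        weighted = len(chosen) * mean_conf / n if mean_conf is not None else None
        tallies.append(
            OptionTally(
                option=option,
                count=len(chosen),
                mean_conf=mean_conf,
                weighted_score=weighted,
            )
        )
    return tallies


def _total(tallies: Sequence[OptionTally]) -> int:
    n = sum(t.count for t in tallies)
    if n < 1:
        raise ValueError("tallies are empty")
    return n


def shannon_entropy(tallies: Sequence[OptionTally]) -> float:
    """Shannon entropy (bits) of the answer frequencies; 0*log0 == 0.

    Summation runs over the sorted count multiset so that patterns that
    are permutations of one another yield bitwise-identical entropies
    (label invariance holds exactly, not just to rounding).
    """
    n = _total(tallies)
    h = 0.0
    for count in sorted(t.count for t in tallies):
        if count > 0:
            p = count / n
            h -= p * math.log2(p)
    return max(h, 0.0)  # guard -0.0


def relative_entropy_score(tallies: Sequence[OptionTally], k: int) -> float:
    """Relative entropy score ``R_H = 1 - H/log2(k)`` in [0, 1].

    1 iff the responses are unanimous; 0 iff they are uniform over all k
    options.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    r = 1.0 - shannon_entropy(tallies) / math.log2(k)
    return min(max(r, 0.0), 1.0)


def majority_vote(tallies: Sequence[OptionTally]) -> tuple[str, float, bool]:
    """Modal option and its percentage share; ties flagged.

    A frequency tie is broken by canonical option order (the first tied
    label in the case's option list) and reported via the third element.
    """
    n = _total(tallies)
    top = max(t.count for t in tallies)
    winners = [t.option for t in tallies if t.count == top]
    return winners[0], 100.0 * top / n, len(winners) > 1


def top_weighted_score(tallies: Sequence[OptionTally]) -> tuple[str, float, bool]:
    """Option with the highest weighted score ``count*mean_conf/n`` and that score.

    Options without a mean confidence (zero count, or all confidences
    missing) are excluded.  Ties broken by canonical option order and
    flagged.
    """
    scored = [t for t in tallies if t.weighted_score is not None]
    if not scored:
        raise ValueError("Top Weighted Score undefined: no confidences present")
    top = max(t.weighted_score for t in scored)
    winners = [t.option for t in scored if t.weighted_score == top]
    return winners[0], top, len(winners) > 1


def self_reported(
    rset: ResponseSet, depth: int | None = None
) -> tuple[float | None, float | None]:
    """(first, mean-over-majority) self-reported confidence at a depth.

    The first value is the confidence of repetition 1 (missing propagates).
    The mean is taken over the first ``depth`` responses whose answer
    equals the majority option *at that depth* — the majority is
    recomputed per depth, since it can change as repetitions accrue.
    """
    if depth is None:
        depth = rset.n
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    tallies = tally(rset, depth)
    majority_option, _, _ = majority_vote(tallies)
    first_conf = rset.records[0].confidence_pct
    confs = [
        r.confidence_pct
        for r in rset.records[:depth]
        if r.answer == majority_option and r.confidence_pct is not None
    ]
    mean_conf = sum(confs) / len(confs) if confs else None
    return first_conf, mean_conf


def build_profile(
    rset: ResponseSet, depth: int | None = None, ground_truth: str | None = None
) -> ConfidenceProfile:
    """Compute all five metrics and their representative-answer correctness.

    Correctness pairs each metric with its representative answer: the
    majority-voted option for ``r_h``, ``majority_pct`` and
    ``mean_conf_majority``; the highest-weighted option for ``tws``; the
    first response for ``first_conf``.  A flag is ``None`` when the
    metric itself is undefined (no confidences at all for ``tws``).
    """
    if ground_truth is None:
        ground_truth = rset.case.ground_truth
    if depth is None:
        depth = rset.n
    tallies = tally(rset, depth)
    k = rset.case.k
    entropy = shannon_entropy(tallies)
    r_h = relative_entropy_score(tallies, k)
    majority_option, majority_pct, majority_tie = majority_vote(tallies)
    first_conf, mean_conf_majority = self_reported(rset, depth)
    try:
        tws_option, tws, tws_tie = top_weighted_score(tallies)
    except ValueError:
        tws_option, tws, tws_tie = None, None, False
    first_answer = rset.records[0].answer

    majority_correct = majority_option == ground_truth
    correctness: dict[str, bool | None] = {
        "first_conf": first_answer == ground_truth,
        "mean_conf_majority": majority_correct,
        "r_h": majority_correct,
        "majority_pct": majority_correct,
        "tws": (tws_option == ground_truth) if tws_option is not None else None,
    }
    return ConfidenceProfile(
        case_id=rset.case.case_id,
        model_id=rset.model_id,
        depth=depth,
        entropy_H=entropy,
        r_h=r_h,
        majority_option=majority_option,
        majority_pct=majority_pct,
        majority_tie=majority_tie,
        first_answer=first_answer,
        first_conf=first_conf,
        mean_conf_majority=mean_conf_majority,
        tws_option=tws_option,
        tws=tws,
        tws_tie=tws_tie,
        correctness=correctness,
    )


def build_profiles(
    sets: Sequence[ResponseSet], depths: Sequence[int] = (20,)
) -> list[ConfidenceProfile]:
    """Profiles for every response set at every requested depth."""
    out: list[ConfidenceProfile] = []
    for rset in sets:
        for depth in depths:
            out.append(build_profile(rset, depth))
    return out
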