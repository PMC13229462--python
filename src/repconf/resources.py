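"""Cumulative per-case processing-time and token costs by repetition depth.

Consistency-based confidence needs many repeated calls, so its practical
cost matters.  For each (model, depth) condition this module sums each
case's first d calls (processing seconds; input, output and total tokens)
and reports the mean and SD of those cumulative costs across cases, plus
a census of extreme calls (individual calls exceeding a threshold,
500 seconds by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import ResponseRecord

__all__ = ["ResourceSummary", "summarize_resources"]


@dataclass(frozen=True)
class ResourceSummary:
    model_id: str
    depth: int
    n_cases: int
    mean_time_s: float
    sd_time_s: float
    mean_total_tokens: float
    sd_total_tokens: float
    mean_input_tokens: float
    mean_output_tokens: float
    n_extreme_calls: int
    extreme_fraction: float
    extreme_threshold_s: float
    n_missing_fields: int


def _sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1)) if len(values) > 1 else 0.0


def summarize_resources(
    records: Sequence[ResponseRecord],
    depths: Sequence[int] = (1, 5, 10, 15, 20),
    *,
    extreme_threshold_s: float = 500.0,
) -> list[ResourceSummary]:
    """Per-(model, depth) cumulative resource summaries.

    For each case the first d calls (by repetition index) are summed;
    calls missing a field are excluded from that field's sums, with the
    exclusion count reported.  ``n_extreme_calls`` counts calls among the
    first d whose individual processing time exceeds the threshold.
    """
    if not records:
        raise ValueError("no records")
    groups: dict[tuple[str, str], list[ResponseRecord]] = {}
    for rec in records:
        groups.setdefault((rec.model_id, rec.case_id), []).append(rec)
    for recs in groups.values():
        recs.sort(key=lambda r: r.repetition_index)

    models = sorted({m for m, _ in groups})
    out: list[ResourceSummary] = []
    for model_id in models:
        case_recs = [recs for (m, _), recs in groups.items() if m == model_id]
        if all(
            r.processing_time_s is None
            and r.input_tokens is None
            and r.output_tokens is None
            for recs in case_recs
            for r in recs
        ):
            raise ValueError(f"no resource data for model {model_id}")
        for depth in depths:
            times, totals, inputs, outputs = [], [], [], []
            n_extreme = 0
            n_calls = 0
            n_missing = 0
            for recs in case_recs:
                head = recs[:depth]
                n_calls += len(head)
                t = [r.processing_time_s for r in head]
                n_missing += sum(v is None for v in t)
                times.append(sum(v for v in t if v is not None))
                n_extreme += sum(
                    v is not None and v > extreme_threshold_s for v in t
                )
                ins = [r.input_tokens for r in head]
                outs = [r.output_tokens for r in head]
                n_missing += sum(v is None for v in ins)
                n_missing += sum(v is None for v in outs)
                inputs.append(sum(v for v in ins if v is not None))
                outputs.append(sum(v for v in outs if v is not None))
                totals.append(
                    sum(
                        (i or 0) + (o or 0)
                        for i, o in zip(ins, outs)
                    )
                )
            times_a = np.asarray(times, dtype=float)
            totals_a = np.asarray(totals, dtype=float)
            out.append(
                ResourceSummary(
                    model_id=model_id,
                    depth=depth,
                    n_cases=len(case_recs),
                    mean_time_s=float(times_a.mean()),
                    sd_time_s=_sd(times_a),
                    mean_total_tokens=float(totals_a.mean()),
                    sd_total_tokens=_sd(totals_a),
                    mean_input_tokens=float(np.mean(inputs)),
                    mean_output_tokens=float(np.mean(outputs)),
                    n_extreme_calls=n_extreme,
                    extreme_fraction=n_extreme / n_calls if n_calls else 0.0,
                    extreme_threshold_s=extreme_threshold_s,
                    n_missing_fields=n_missing,
                )
            )
    return out
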