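"""Reading, validating and writing response logs, case tables and profiles.

A *response log* holds one record per model call: which option the model
chose on that repetition, the verbalized confidence it attached (0-100),
and per-call resource metadata (processing time, token counts).  A *case
table* holds one row per quiz case: the ordered option labels, the ground
truth, and optional covariates (publication date, tags).

Two dialects are supported for logs: JSON-lines (one object per line,
field names exactly as in :class:`ResponseRecord`) and CSV with a header.
Case tables are CSV with the option list serialized as a ``|``-joined
string.  All files are UTF-8; dates are ISO-8601.

Malformed records can be handled strictly (raise, naming the line) or
leniently (route to a rejects report so exclusions stay auditable);
lenient is the default for logs because verbalized confidences arrive
embedded in model-generated text and parse failures are expected in the
wild.
"""

from __future__ import annotations

import csv
import dataclasses
import datetime as _dt
import json
import math
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "ResponseRecord",
    "CaseRecord",
    "ResponseSet",
    "Reject",
    "ReadResult",
    "ValidationError",
    "parse_confidence",
    "read_responses",
    "write_responses",
    "read_cases",
    "write_cases",
    "group_responses",
    "load_dataset",
    "write_profiles",
    "read_profiles",
]

RESPONSE_FIELDS = (
    "case_id",
    "model_id",
    "repetition_index",
    "answer",
    "confidence_pct",
    "processing_time_s",
    "input_tokens",
    "output_tokens",
)


class ValidationError(ValueError):
    """A record failed validation; the message names the offending line."""


@dataclass(frozen=True)
class ResponseRecord:
    """One repetition's answer plus verbalized confidence and resource use."""

    case_id: str
    model_id: str
    repetition_index: int
    answer: str
    confidence_pct: float | None = None
    processing_time_s: float | None = None
    input_tokens: int | None = None
    output_tokens: int | None = None

    def __post_init__(self) -> None:
        if self.repetition_index < 1:
            raise ValidationError(
                f"repetition_index must be >= 1, got {self.repetition_index}"
            )
        if self.confidence_pct is not None and not (
            0.0 <= self.confidence_pct <= 100.0
        ):
            raise ValidationError(
                f"confidence_pct outside [0, 100]: {self.confidence_pct}"
            )
        if self.processing_time_s is not None and self.processing_time_s < 0:
            raise ValidationError(
                f"processing_time_s must be >= 0: {self.processing_time_s}"
            )
        for name in ("input_tokens", "output_tokens"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be >= 0: {v}")


@dataclass(frozen=True)
class CaseRecord:
    """Option set, ground truth and covariates for one quiz case."""

    case_id: str
    options: tuple[str, ...]
    ground_truth: str
    published_date: _dt.date | None = None
    tags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.options) < 2:
            raise ValidationError(
                f"case {self.case_id}: need >= 2 options, got {len(self.options)}"
            )
        if len(set(self.options)) != len(self.options):
            raise ValidationError(f"case {self.case_id}: duplicate option labels")
        if self.ground_truth not in self.options:
            raise ValidationError(
                f"case {self.case_id}: ground truth {self.ground_truth!r} "
                f"not in options {self.options}"
            )

    @property
    def k(self) -> int:
        return len(self.options)


@dataclass(frozen=True)
class ResponseSet:
    """All repetitions for one (case, model), ordered by repetition index."""

    case: CaseRecord
    model_id: str
    records: tuple[ResponseRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError("ResponseSet needs at least one record")
        idx = [r.repetition_index for r in self.records]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValidationError(
                f"repetition_index not strictly increasing for "
                f"({self.case.case_id}, {self.model_id})"
            )
        for r in self.records:
            if r.case_id != self.case.case_id or r.model_id != self.model_id:
                raise ValidationError("records mixed across (case, model) groups")

    @property
    def n(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class Reject:
    """A record excluded during lenient reading/grouping, with the reason."""

    line: int | None
    reason: str
    raw: dict


@dataclass
class ReadResult:
    records: list[ResponseRecord]
    rejects: list[Reject] = field(default_factory=list)
    parse_counters: Counter = field(default_factory=Counter)


_NUMERIC_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def parse_confidence(
    raw: object,
    *,
    as_fraction: bool = False,
    counters: Counter | None = None,
) -> float | None:
    """Normalize a verbalized confidence to a float in [0, 100].

    Accepts bare numbers, numbers with a trailing ``%`` and surrounding
    whitespace.  With ``as_fraction`` set, values in (0, 1] are rescaled
    by 100 (off by default: a bare ``0.9`` in a 0-100 scale log means a
    confidence of 0.9%, not 90%).  Out-of-range values are clamped to
    [0, 100]; non-numeric input yields ``None``.  Deviations increment
    ``counters`` (keys ``clamped``, ``non_numeric``, ``missing``,
    ``rescaled``) so no normalization is silent.
    """
    if counters is None:
        counters = Counter()
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        counters["missing"] += 1
        return None
    if isinstance(raw, str):
        text = raw.strip()
        if text.endswith("%"):
            text = text[:-1].strip()
        if not text or not _NUMERIC_RE.match(text):
            counters["non_numeric"] += 1
            return None
        value = float(text)
    elif isinstance(raw, (int, float)):
        value = float(raw)
    else:
        counters["non_numeric"] += 1
        return None
    if as_fraction and 0.0 < value <= 1.0:
        value *= 100.0
        counters["rescaled"] += 1
    if value < 0.0 or value > 100.0:
        counters["clamped"] += 1
        value = min(max(value, 0.0), 100.0)
    return value


def _opt_float(value: object) -> float | None:
    if value is None or value == "":
        return None
    f = float(value)
    if math.isnan(f):
        return None
    return f


def _opt_int(value: object) -> int | None:
    f = _opt_float(value)
    return None if f is None else int(round(f))


def _record_from_raw(
    raw: dict, line: int, counters: Counter, *, as_fraction: bool = False
) -> ResponseRecord:
    try:
        return ResponseRecord(
            case_id=str(raw["case_id"]),
            model_id=str(raw["model_id"]),
            repetition_index=int(raw["repetition_index"]),
            answer=str(raw["answer"]).strip(),
            confidence_pct=parse_confidence(
                raw.get("confidence_pct"), as_fraction=as_fraction, counters=counters
            ),
            processing_time_s=_opt_float(raw.get("processing_time_s")),
            input_tokens=_opt_int(raw.get("input_tokens")),
            output_tokens=_opt_int(raw.get("output_tokens")),
        )
    except ValidationError:
        raise
    except (KeyError, TypeError, ValueError) as exc:
        raise ValidationError(f"line {line}: {exc}") from exc


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "csv" if path.suffix.lower() == ".csv" else "jsonl"


def read_responses(
    path: str | Path,
    format: str | None = None,
    *,
    mode: str = "lenient",
    as_fraction: bool = False,
) -> ReadResult:
    """Read a response log; returns records plus a rejects report.

    ``mode="strict"`` raises :class:`ValidationError` naming the first bad
    line; ``mode="lenient"`` (default) routes bad records to
    ``ReadResult.rejects`` instead of silently dropping them.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt not in ("jsonl", "csv"):
        raise ValueError(f"unknown format {fmt!r}")
    result = ReadResult(records=[])

    def handle(raw: dict, line: int) -> None:
        try:
            rec = _record_from_raw(raw, line, result.parse_counters,
                                   as_fraction=as_fraction)
        except ValidationError as exc:
            if mode == "strict":
                raise ValidationError(f"line {line}: {exc}") from exc
            result.rejects.append(Reject(line=line, reason=str(exc), raw=raw))
            return
        result.records.append(rec)

    with open(path, encoding="utf-8") as fh:
        if fmt == "jsonl":
            for line_no, text in enumerate(fh, start=1):
                text = text.strip()
                if not text:
                    continue
                try:
                    raw = json.loads(text)
                except json.JSONDecodeError as exc:
                    if mode == "strict":
                        raise ValidationError(
                            f"line {line_no}: invalid JSON: {exc}"
                        ) from exc
                    result.rejects.append(
                        Reject(line=line_no, reason=f"invalid JSON: {exc}",
                               raw={"text": text})
                    )
                    continue
                handle(raw, line_no)
        else:
            reader = csv.DictReader(fh)
            for line_no, raw in enumerate(reader, start=2):
                handle(raw, line_no)
    return result


def write_responses(
    records: Iterable[ResponseRecord], path: str | Path, format: str | None = None
) -> None:
    path = Path(path)
    fmt = _infer_format(path, format)
    records = list(records)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if fmt == "jsonl":
            for rec in records:
                fh.write(json.dumps(dataclasses.asdict(rec)) + "\n")
        else:
            writer = csv.DictWriter(fh, fieldnames=RESPONSE_FIELDS)
            writer.writeheader()
            for rec in records:
                row = dataclasses.asdict(rec)
                writer.writerow({k: ("" if v is None else v) for k, v in row.items()})


def read_cases(path: str | Path, *, option_sep: str = "|") -> list[CaseRecord]:
    """Read a case table (CSV; options ``|``-joined, dates ISO-8601)."""
    cases: list[CaseRecord] = []
    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(csv.DictReader(fh), start=2):
            date_text = (raw.get("published_date") or "").strip()
            tags_text = (raw.get("tags") or "").strip()
            try:
                cases.append(
                    CaseRecord(
                        case_id=str(raw["case_id"]),
                        options=tuple(
                            s.strip() for s in raw["options"].split(option_sep)
                        ),
                        ground_truth=str(raw["ground_truth"]).strip(),
                        published_date=(
                            _dt.date.fromisoformat(date_text) if date_text else None
                        ),
                        tags=tuple(
                            t for t in (s.strip() for s in tags_text.split(option_sep))
                            if t
                        ),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValidationError(f"case table line {line_no}: {exc}") from exc
    return cases


def write_cases(
    cases: Iterable[CaseRecord], path: str | Path, *, option_sep: str = "|"
) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["case_id", "options", "ground_truth", "published_date", "tags"]
        )
        for c in cases:
            writer.writerow(
                [
                    c.case_id,
                    option_sep.join(c.options),
                    c.ground_truth,
                    c.published_date.isoformat() if c.published_date else "",
                    option_sep.join(c.tags),
                ]
            )


def group_responses(
    records: Sequence[ResponseRecord],
    cases: Sequence[CaseRecord],
    *,
    on_invalid: str = "raise",
    rejects: list[Reject] | None = None,
) -> list[ResponseSet]:
    """Partition records into per-(case, model) response sets.

    Membership of each answer in the case's option set is enforced here,
    where the option set is first known.  ``on_invalid="reject"`` routes
    out-of-option answers to ``rejects`` instead of raising; orphan case
    ids and duplicate repetition indices always raise.
    """
    case_by_id = {c.case_id: c for c in cases}
    orphans = sorted({r.case_id for r in records} - set(case_by_id))
    if orphans:
        raise ValidationError(f"case ids absent from case table: {orphans}")

    groups: dict[tuple[str, str], list[ResponseRecord]] = {}
    for rec in records:
        case = case_by_id[rec.case_id]
        if rec.answer not in case.options:
            msg = (
                f"case {rec.case_id} repetition {rec.repetition_index}: answer "
                f"{rec.answer!r} not in option set {case.options}"
            )
            if on_invalid == "raise":
                raise ValidationError(msg)
            if rejects is not None:
                rejects.append(Reject(line=None, reason=msg,
                                      raw=dataclasses.asdict(rec)))
            continue
        groups.setdefault((rec.case_id, rec.model_id), []).append(rec)

    sets: list[ResponseSet] = []
    for (case_id, model_id), recs in groups.items():
        idx = [r.repetition_index for r in recs]
        dupes = sorted({i for i in idx if idx.count(i) > 1})
        if dupes:
            raise ValidationError(
                f"duplicate repetition_index {dupes} for ({case_id}, {model_id})"
            )
        recs = sorted(recs, key=lambda r: r.repetition_index)
        sets.append(
            ResponseSet(case=case_by_id[case_id], model_id=model_id,
                        records=tuple(recs))
        )
    sets.sort(key=lambda s: (s.case.case_id, s.model_id))
    return sets


def load_dataset(
    responses_path: str | Path,
    cases_path: str | Path,
    *,
    format: str | None = None,
    mode: str = "lenient",
) -> tuple[list[ResponseSet], list[CaseRecord], ReadResult]:
    """Read a log and case table and group them in one step."""
    cases = read_cases(cases_path)
    result = read_responses(responses_path, format, mode=mode)
    on_invalid = "raise" if mode == "strict" else "reject"
    sets = group_responses(
        result.records, cases, on_invalid=on_invalid, rejects=result.rejects
    )
    return sets, cases, result


# --- profile serialization (the metric table computed downstream) ----------

PROFILE_COLUMNS = (
    "case_id",
    "model_id",
    "depth",
    "entropy_H",
    "r_h",
    "majority_option",
    "majority_pct",
    "majority_tie",
    "first_answer",
    "first_conf",
    "mean_conf_majority",
    "tws_option",
    "tws",
    "tws_tie",
    "correct_first_conf",
    "correct_mean_conf_majority",
    "correct_r_h",
    "correct_majority_pct",
    "correct_tws",
)


def write_profiles(profiles: Sequence, path: str | Path) -> None:
    """Write confidence profiles as a flat CSV, one row per (case, model, depth).

    Values round-trip to 12 significant digits through :func:`read_profiles`.
    """
    import pandas as pd

    if not profiles:
        raise ValueError("no profiles to write")
    rows = [p.to_row() for p in profiles]
    frame = pd.DataFrame(rows, columns=PROFILE_COLUMNS)
    frame.to_csv(path, index=False, float_format="%.12g")


def read_profiles(path: str | Path):
    """Read a profile CSV back into a DataFrame (see :func:`write_profiles`)."""
    import pandas as pd

    frame = pd.read_csv(path, dtype={"case_id": str, "model_id": str})
    return frame
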