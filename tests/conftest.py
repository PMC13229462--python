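import pytest

from repconf import CaseRecord, ResponseRecord, ResponseSet


def make_set(
    answers,
    confs=None,
    options=("A", "B", "C", "D", "E"),
    truth="A",
    case_id="c1",
    model_id="m1",
):
    """Build a ResponseSet from an answer sequence and optional confidences."""
    options = tuple(options)
    if confs is None:
        confs = [80.0] * len(answers)
    records = tuple(
        ResponseRecord(
            case_id=case_id,
            model_id=model_id,
            repetition_index=i + 1,
            answer=a,
            confidence_pct=c,
        )
        for i, (a, c) in enumerate(zip(answers, confs))
    )
    case = CaseRecord(case_id=case_id, options=options, ground_truth=truth)
    return ResponseSet(case=case, model_id=model_id, records=records)


@pytest.fixture
def five_option_set():
    return make_set(list("AAABB"))
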