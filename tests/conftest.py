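import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from mrharmony import ExamRecord


def make_record(exam_id, protocol, codes, region="spine"):
    return ExamRecord(
        exam_id=exam_id,
        scanner_id="scanner1",
        site_id="siteA",
        body_region=region,
        protocol_name=protocol,
        admitting_codes=frozenset(codes),
    )


@pytest.fixture
def toy_region_records():
    """Hand-enumerable spine log: 3 protocols, 26 exams.

    Element sets: P1 -> {A, B, AB, C, D} (5), P2 -> {A, C, E} (3),
    P3 -> {F} (1). Hand-computed: oc(P1,P2) = 2/3, oc with P3 = 0,
    complements 0.5 / 2/3 / 0.
    """
    rows = (
        [("P1", c) for c in (["A01"], ["A01"], ["B02"], ["A01", "B02"], ["C03"],
                             ["A01"], ["B02"], ["C03"], ["A01", "B02"], ["D04"])]
        + [("P2", c) for c in (["A01"], ["C03"], ["E05"], ["E05"], ["C03"],
                               ["A01"], ["E05"], ["C03"], ["A01"], ["E05"])]
        + [("P3", ["F06"])] * 6
    )
    return [
        make_record(f"e{i}", protocol, codes)
        for i, (protocol, codes) in enumerate(rows)
    ]
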