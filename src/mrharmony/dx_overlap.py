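"""Admitting-diagnosis / protocol overlap pipeline stage.

For one body region, every exam contributes its canonical code combination as
one element to its protocol's element set; rarely performed protocols are
dropped (the study convention keeps protocols performed more than five times,
i.e. count >= 6); the retained protocols get a pairwise overlap-coefficient
matrix plus per-protocol complement overlap; label statistics are computed
over all region exams with nonempty codes, before the frequency filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .model import CodeSetElement, DataError, ExamRecord
from .similarity import (
    LabelStatistics,
    OverlapMatrix,
    label_statistics,
    pairwise_matrix,
)

logger = logging.getLogger("mrharmony")

#: "performed more than five times" -> retain exam count >= 6
DEFAULT_MIN_COUNT = 6

GRANULARITIES = ("codeset", "code")
LABEL_ORDER_POLICIES = ("count_desc", "alpha")


@dataclass
class DxOverlapResult:
    """Output of the diagnosis-overlap stage for one body region."""

    body_region: str
    matrix: OverlapMatrix
    stats: LabelStatistics
    included_counts: dict[str, int]
    excluded_protocols: list[tuple[str, int]]
    excluded_exams: int  # region exams with an empty code set


def build_elements(
    records: Sequence[ExamRecord],
    body_region: str,
    granularity: str = "codeset",
) -> tuple[dict[str, set], dict[str, int], int]:
    """Group exams of one body region into per-protocol element sets.

    Returns ``(assoc, counts, n_excluded_empty)`` where ``assoc`` maps each
    protocol name to its set of elements, ``counts`` to its number of
    contributing exams, and ``n_excluded_empty`` counts region exams dropped
    for having no admitting codes.

    With ``granularity="codeset"`` (default) each exam contributes one
    :class:`CodeSetElement` — its whole code combination. The ``"code"``
    variant treats every individual code as an element instead.
    """
    if granularity not in GRANULARITIES:
        raise DataError(f"unknown granularity {granularity!r}")
    region_records = [r for r in records if r.body_region == body_region]
    if not region_records:
        raise DataError(f"no exam records for body region {body_region!r}")
    assoc: dict[str, set] = {}
    counts: dict[str, int] = {}
    n_empty = 0
    for rec in region_records:
        if not rec.admitting_codes:
            n_empty += 1
            continue
        bucket = assoc.setdefault(rec.protocol_name, set())
        if granularity == "codeset":
            bucket.add(CodeSetElement.from_codes(rec.admitting_codes))
        else:
            bucket.update(rec.admitting_codes)
        counts[rec.protocol_name] = counts.get(rec.protocol_name, 0) + 1
    if n_empty:
        logger.warning(
            "region %r: excluded %d exam(s) without admitting codes",
            body_region,
            n_empty,
        )
    if not assoc:
        raise DataError(
            f"body region {body_region!r}: no exams with admitting codes"
        )
    return assoc, counts, n_empty


def filter_protocols(
    assoc: Mapping[str, set],
    counts: Mapping[str, int],
    min_count: int = DEFAULT_MIN_COUNT,
) -> tuple[dict[str, set], list[tuple[str, int]]]:
    """Retain protocols performed at least ``min_count`` times.

    Returns the filtered association and the exclusion list of
    ``(protocol_name, exam_count)`` pairs (sorted by name). Rejects when the
    filter removes every protocol.
    """
    if min_count < 1:
        raise DataError(f"min_count must be >= 1, got {min_count}")
    kept = {name: elems for name, elems in assoc.items() if counts[name] >= min_count}
    excluded = sorted(
        (name, counts[name]) for name in assoc if counts[name] < min_count
    )
    if not kept:
        raise DataError(
            f"all {len(assoc)} protocols fall below min_count={min_count}"
        )
    return kept, excluded


def order_labels(
    assoc: Mapping[str, set],
    counts: Mapping[str, int],
    policy: str = "count_desc",
) -> list[str]:
    """Deterministic label ordering for the matrix.

    ``count_desc`` (default): descending exam count, ties lexicographic;
    ``alpha``: lexicographic.
    """
    if policy == "count_desc":
        return sorted(assoc, key=lambda name: (-counts[name], name))
    if policy == "alpha":
        return sorted(assoc)
    raise DataError(f"unknown label order policy {policy!r}")


def run_dx_overlap(
    records: Sequence[ExamRecord],
    body_region: str,
    min_count: int = DEFAULT_MIN_COUNT,
    granularity: str = "codeset",
    label_order: str = "count_desc",
) -> DxOverlapResult:
    """Full diagnosis-overlap stage for one body region.

    Composes :func:`build_elements` → :func:`filter_protocols` →
    :func:`pairwise_matrix` → :func:`label_statistics`. Statistics cover all
    region exams with nonempty codes (the protocol-frequency filter applies
    to the matrix only).
    """
    assoc, counts, n_empty = build_elements(records, body_region, granularity)
    kept, excluded = filter_protocols(assoc, counts, min_count)
    order = order_labels(kept, counts, label_order)
    matrix = pairwise_matrix(kept, order)
    region_records = [
        r
        for r in records
        if r.body_region == body_region and r.admitting_codes
    ]
    stats = label_statistics(region_records)
    return DxOverlapResult(
        body_region=body_region,
        matrix=matrix,
        stats=stats,
        included_counts={name: counts[name] for name in order},
        excluded_protocols=excluded,
        excluded_exams=n_empty,
    )
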