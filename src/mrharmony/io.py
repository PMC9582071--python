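"""Readers and writers for the interchange formats.

Formats
-------
exam log (CSV, UTF-8)
    Header ``exam_id,scanner_id,site_id,body_region,protocol_name,
    admitting_codes[,exam_date]``; ``admitting_codes`` is a ``;``-separated
    list inside one cell (commas would collide with CSV). An empty codes cell
    is a retained exam with no coded diagnosis.
protocol trees (JSON)
    ``{"scanners": [{"scanner_id", "site_id", "protocols": [{"protocol_name",
    "body_region", "sequences": [...]}]}]}``; sequence objects carry the
    acquisition-parameter fields, absent optional fields defaulting to
    UNKNOWN / NONE / empty. The schema is published in
    ``docs/protocol_tree.schema.json``; validation errors name the JSON path.
matrix (CSV)
    First column the protocol label, one column per protocol in matrix order,
    and a final column literally named ``complement``; values fixed at 2
    decimals, an undefined complement rendered as an empty cell.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Any, Optional, Sequence, Union

import pandas as pd

from .model import (
    DataError,
    ExamRecord,
    ProtocolDefinition,
    ProtocolTree,
    SequenceAcquisition,
    canonicalize_code,
)
from .similarity import OverlapMatrix

logger = logging.getLogger("mrharmony")

PathLike = Union[str, Path]

EXAM_LOG_COLUMNS = (
    "exam_id",
    "scanner_id",
    "site_id",
    "body_region",
    "protocol_name",
    "admitting_codes",
)


def read_exam_log(path: PathLike) -> list[ExamRecord]:
    """Read an exam-log CSV into a list of :class:`ExamRecord`.

    Codes are canonicalized and deduplicated; an empty codes cell yields an
    empty set and a logged warning. Missing required columns and duplicate
    ``exam_id`` values are rejected.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in EXAM_LOG_COLUMNS if c not in frame.columns]
    if missing:
        raise DataError(f"exam log {path}: missing required columns {missing}")
    dupes = frame["exam_id"][frame["exam_id"].duplicated()].unique().tolist()
    if dupes:
        raise DataError(f"exam log {path}: duplicate exam_id values {dupes[:5]}")

    has_date = "exam_date" in frame.columns
    records: list[ExamRecord] = []
    n_empty = 0
    for row in frame.itertuples(index=False):
        cell = row.admitting_codes.strip()
        if cell:
            codes = frozenset(
                canonicalize_code(part) for part in cell.split(";") if part.strip()
            )
        else:
            codes = frozenset()
            n_empty += 1
        date = getattr(row, "exam_date", "").strip() if has_date else ""
        records.append(
            ExamRecord(
                exam_id=row.exam_id.strip(),
                scanner_id=row.scanner_id.strip(),
                site_id=row.site_id.strip(),
                body_region=row.body_region.strip().lower(),
                protocol_name=row.protocol_name.strip(),
                admitting_codes=codes,
                exam_date=date or None,
            )
        )
    if n_empty:
        logger.warning(
            "exam log %s: %d exam(s) without admitting-diagnosis codes", path, n_empty
        )
    return records


def write_exam_log(records: Sequence[ExamRecord], path: PathLike) -> None:
    """Write records to the exam-log CSV format (codes ``;``-joined, sorted)."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(list(EXAM_LOG_COLUMNS) + ["exam_date"])
        for rec in records:
            writer.writerow(
                [
                    rec.exam_id,
                    rec.scanner_id,
                    rec.site_id,
                    rec.body_region,
                    rec.protocol_name,
                    ";".join(sorted(rec.admitting_codes)),
                    rec.exam_date or "",
                ]
            )


# --- protocol tree JSON -----------------------------------------------------

_SEQ_OPTIONAL: dict[str, Any] = {
    "ti_ms": None,
    "flip_deg": 90.0,
    "technique": "UNKNOWN",
    "inversion_recovery": False,
    "orientation": "UNKNOWN",
    "fat_suppression": False,
    "b_values": (),
    "contrast_phase": "NONE",
    "dimensionality": "2D",
    "echo_train_length": 1,
}


def _require(obj: dict, key: str, path: str) -> Any:
    if not isinstance(obj, dict):
        raise DataError(f"{path}: expected an object")
    if key not in obj:
        raise DataError(f"{path}: missing required field {key!r}")
    return obj[key]


def _parse_sequence(obj: dict, path: str) -> SequenceAcquisition:
    kwargs: dict[str, Any] = {
        "raw_name": _require(obj, "raw_name", path),
        "tr_ms": _require(obj, "tr_ms", path),
        "te_ms": _require(obj, "te_ms", path),
    }
    for key, default in _SEQ_OPTIONAL.items():
        value = obj.get(key, default)
        if key == "b_values" and value is not None:
            if not isinstance(value, (list, tuple)):
                raise DataError(f"{path}.b_values: expected a list")
            value = tuple(float(b) for b in value)
        kwargs[key] = value
    try:
        return SequenceAcquisition(**kwargs)
    except DataError as err:
        raise DataError(f"{path}: {err}") from err
    except TypeError as err:
        raise DataError(f"{path}: bad sequence object ({err})") from err


def read_protocol_trees(path: PathLike) -> list[ProtocolTree]:
    """Read and validate a protocol-tree JSON document.

    Violations (missing fields, invariant breaks such as ``ti_ms`` without
    ``inversion_recovery``, duplicate protocol names within a scanner) are
    rejected with the JSON path of the offending node.
    """
    with open(path, encoding="utf-8") as handle:
        doc = json.load(handle)
    scanners = _require(doc, "scanners", "$")
    if not isinstance(scanners, list):
        raise DataError("$.scanners: expected an array")
    trees: list[ProtocolTree] = []
    for i, sc in enumerate(scanners):
        spath = f"$.scanners[{i}]"
        scanner_id = _require(sc, "scanner_id", spath)
        site_id = _require(sc, "site_id", spath)
        raw_protocols = _require(sc, "protocols", spath)
        if not isinstance(raw_protocols, list):
            raise DataError(f"{spath}.protocols: expected an array")
        protocols = []
        for j, proto in enumerate(raw_protocols):
            ppath = f"{spath}.protocols[{j}]"
            raw_seqs = _require(proto, "sequences", ppath)
            if not isinstance(raw_seqs, list) or not raw_seqs:
                raise DataError(f"{ppath}.sequences: expected a nonempty array")
            sequences = tuple(
                _parse_sequence(seq, f"{ppath}.sequences[{k}]")
                for k, seq in enumerate(raw_seqs)
            )
            try:
                protocols.append(
                    ProtocolDefinition(
                        protocol_name=_require(proto, "protocol_name", ppath),
                        body_region=_require(proto, "body_region", ppath),
                        sequences=sequences,
                    )
                )
            except DataError as err:
                raise DataError(f"{ppath}: {err}") from err
        try:
            trees.append(
                ProtocolTree(
                    scanner_id=scanner_id,
                    site_id=site_id,
                    protocols=tuple(protocols),
                )
            )
        except DataError as err:
            raise DataError(f"{spath}: {err}") from err
    return trees


def _sequence_to_json(seq: SequenceAcquisition) -> dict:
    return {
        "raw_name": seq.raw_name,
        "tr_ms": seq.tr_ms,
        "te_ms": seq.te_ms,
        "ti_ms": seq.ti_ms,
        "flip_deg": seq.flip_deg,
        "technique": seq.technique,
        "inversion_recovery": seq.inversion_recovery,
        "orientation": seq.orientation,
        "fat_suppression": seq.fat_suppression,
        "b_values": list(seq.b_values),
        "contrast_phase": seq.contrast_phase,
        "dimensionality": seq.dimensionality,
        "echo_train_length": seq.echo_train_length,
    }


def write_protocol_trees(trees: Sequence[ProtocolTree], path: PathLike) -> None:
    """Write protocol trees to the JSON interchange format."""
    doc = {
        "scanners": [
            {
                "scanner_id": tree.scanner_id,
                "site_id": tree.site_id,
                "protocols": [
                    {
                        "protocol_name": proto.protocol_name,
                        "body_region": proto.body_region,
                        "sequences": [
                            _sequence_to_json(seq) for seq in proto.sequences
                        ],
                    }
                    for proto in tree.protocols
                ],
            }
            for tree in trees
        ]
    }
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(doc, handle, indent=2, sort_keys=False)
        handle.write("\n")


def write_matrix_csv(matrix: OverlapMatrix, path: PathLike) -> None:
    """Write an overlap matrix as CSV with a terminal ``complement`` column.

    Values are rendered with exactly 2 decimal places; an undefined complement
    (single-protocol dataset) becomes an empty cell.
    """
    matrix.validate()
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["protocol"] + list(matrix.labels) + ["complement"])
        for i, label in enumerate(matrix.labels):
            row: list[str] = [label]
            row.extend(f"{matrix.values[i, j]:.2f}" for j in range(len(matrix.labels)))
            comp: Optional[float] = matrix.complement[i]
            row.append("" if comp is None else f"{comp:.2f}")
            writer.writerow(row)
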