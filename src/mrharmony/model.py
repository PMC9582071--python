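"""Domain types for MRI exam logs and scanner protocol trees.

An *exam log* records one row per performed MRI exam: which scanner ran it,
which protocol was selected, and the ICD-10-coded admitting diagnosis (one or
more codes) that stood in for the free-text clinical indication. A *protocol
tree* is a scanner's catalog of named protocols, each an ordered list of
parameterized pulse sequences (TR, TE, TI, flip angle, technique, ...).

All types are frozen dataclasses validated on construction; I/O lives in
:mod:`mrharmony.io`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

logger = logging.getLogger("mrharmony")


class DataError(ValueError):
    """Invalid data or parameters: malformed codes, schema violations,
    degenerate inputs a computation cannot accept."""


#: Canonical ICD-10 code shape: one uppercase letter, two digits, optionally a
#: dot followed by 1-4 alphanumerics (e.g. "M54.5", "G35", "S06.0X1A").
CODE_PATTERN = re.compile(r"^[A-Z][0-9]{2}(?:\.[A-Z0-9]{1,4})?$")

TECHNIQUES = frozenset({"SE", "TSE", "GRE", "EPI", "bSSFP", "UNKNOWN"})
ORIENTATIONS = frozenset({"SAG", "COR", "TRA", "OBL", "UNKNOWN"})
CONTRAST_PHASES = frozenset({"NONE", "PRE", "POST"})
DIMENSIONALITIES = frozenset({"2D", "3D"})


def canonicalize_code(raw: str) -> str:
    """Canonicalize an ICD-10 code string.

    Uppercases, strips surrounding whitespace, and inserts the dot after the
    third character when a longer code is given undotted ("M545" -> "M54.5").
    An existing dot is kept. Idempotent.

    Raises
    ------
    DataError
        If the input is blank or does not match the canonical code shape
        (no leading letter, fewer than 3 characters, bad dot placement, ...).
    """
    if raw is None or not str(raw).strip():
        raise DataError("blank ICD-10 code")
    code = str(raw).strip().upper()
    if "." not in code and len(code) > 3:
        code = code[:3] + "." + code[3:]
    if not CODE_PATTERN.match(code):
        raise DataError(f"malformed ICD-10 code: {raw!r}")
    return code


@dataclass(frozen=True)
class ExamRecord:
    """One performed MRI exam with its protocol and admitting-diagnosis codes.

    ``admitting_codes`` holds canonical ICD-10 codes and may be empty (exams
    without coded diagnoses are kept by I/O and excluded downstream by the
    overlap stage).
    """

    exam_id: str
    scanner_id: str
    site_id: str
    body_region: str
    protocol_name: str
    admitting_codes: frozenset[str] = frozenset()
    exam_date: Optional[str] = None  # ISO-8601 date, when known

    def __post_init__(self) -> None:
        if not self.exam_id:
            raise DataError("exam_id must be non-empty")
        if self.body_region != self.body_region.strip().lower():
            raise DataError(
                f"body_region must be a lowercase tag, got {self.body_region!r}"
            )
        for code in self.admitting_codes:
            if not CODE_PATTERN.match(code):
                raise DataError(
                    f"exam {self.exam_id!r}: non-canonical ICD-10 code {code!r}"
                )


@dataclass(frozen=True, order=True)
class CodeSetElement:
    """A canonical combination of ICD-10 codes from one exam.

    This is the unit element of all diagnosis-overlap sets: two exams
    contribute the same element exactly when their code combinations are
    identical. Codes are stored sorted and deduplicated.
    """

    codes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.codes) == 0:
            raise DataError("CodeSetElement requires at least one code")
        if list(self.codes) != sorted(set(self.codes)):
            raise DataError(
                f"CodeSetElement codes must be sorted and deduplicated: {self.codes!r}"
            )

    @classmethod
    def from_codes(cls, codes: Iterable[str]) -> "CodeSetElement":
        return cls(tuple(sorted(set(codes))))


@dataclass(frozen=True)
class SequenceAcquisition:
    """A parameterized MR pulse sequence as listed in a protocol tree.

    ``raw_name`` is the user-given sequence name (site- and scanner-specific
    spelling); everything else is acquisition parameters. Times are in
    milliseconds, the flip angle in degrees, diffusion weightings in s/mm².
    """

    raw_name: str
    tr_ms: float
    te_ms: float
    ti_ms: Optional[float] = None
    flip_deg: float = 90.0
    technique: str = "UNKNOWN"
    inversion_recovery: bool = False
    orientation: str = "UNKNOWN"
    fat_suppression: bool = False
    b_values: tuple[float, ...] = ()
    contrast_phase: str = "NONE"
    dimensionality: str = "2D"
    echo_train_length: int = 1

    def __post_init__(self) -> None:
        if self.tr_ms <= 0:
            raise DataError(f"sequence {self.raw_name!r}: tr_ms must be positive")
        if self.te_ms < 0:
            raise DataError(f"sequence {self.raw_name!r}: te_ms must be nonnegative")
        if self.ti_ms is not None and self.ti_ms < 0:
            raise DataError(f"sequence {self.raw_name!r}: ti_ms must be nonnegative")
        if not (0 <= self.flip_deg <= 180):
            raise DataError(
                f"sequence {self.raw_name!r}: flip_deg must be in [0, 180]"
            )
        if self.technique not in TECHNIQUES:
            raise DataError(
                f"sequence {self.raw_name!r}: unknown technique {self.technique!r}"
            )
        if self.orientation not in ORIENTATIONS:
            raise DataError(
                f"sequence {self.raw_name!r}: unknown orientation {self.orientation!r}"
            )
        if self.contrast_phase not in CONTRAST_PHASES:
            raise DataError(
                f"sequence {self.raw_name!r}: unknown contrast_phase "
                f"{self.contrast_phase!r}"
            )
        if self.dimensionality not in DIMENSIONALITIES:
            raise DataError(
                f"sequence {self.raw_name!r}: unknown dimensionality "
                f"{self.dimensionality!r}"
            )
        if self.echo_train_length < 1:
            raise DataError(
                f"sequence {self.raw_name!r}: echo_train_length must be >= 1"
            )
        if any(b < 0 for b in self.b_values):
            raise DataError(f"sequence {self.raw_name!r}: b_values must be >= 0")
        if self.ti_ms is not None and not self.inversion_recovery:
            raise DataError(
                f"sequence {self.raw_name!r}: ti_ms given but inversion_recovery "
                "is false"
            )
        # Diffusion is acquired with an EPI readout in practice, but vendor
        # logs are inconsistent: warn rather than reject a stated technique.
        if self.b_values and self.technique not in ("EPI", "UNKNOWN"):
            logger.warning(
                "sequence %r: diffusion b-values with non-EPI technique %s",
                self.raw_name,
                self.technique,
            )

    def parameter_key(self) -> tuple:
        """All acquisition parameters, excluding the user-given name.

        Two sequences with equal parameter keys are the same acquisition
        regardless of how a site spelled the sequence name.
        """
        return (
            self.tr_ms,
            self.te_ms,
            self.ti_ms,
            self.flip_deg,
            self.technique,
            self.inversion_recovery,
            self.orientation,
            self.fat_suppression,
            self.b_values,
            self.contrast_phase,
            self.dimensionality,
            self.echo_train_length,
        )


@dataclass(frozen=True)
class ProtocolDefinition:
    """A named MRI protocol: an ordered, nonempty list of pulse sequences."""

    protocol_name: str
    body_region: str
    sequences: tuple[SequenceAcquisition, ...]

    def __post_init__(self) -> None:
        if not self.protocol_name:
            raise DataError("protocol_name must be non-empty")
        if len(self.sequences) == 0:
            raise DataError(
                f"protocol {self.protocol_name!r}: sequences list must be nonempty"
            )


@dataclass(frozen=True)
class ProtocolTree:
    """One scanner's catalog of protocols."""

    scanner_id: str
    site_id: str
    protocols: tuple[ProtocolDefinition, ...] = ()

    def __post_init__(self) -> None:
        names = [p.protocol_name for p in self.protocols]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise DataError(
                f"scanner {self.scanner_id!r}: duplicate protocol names {sorted(dupes)}"
            )
        if not self.protocols:
            logger.warning("scanner %r: protocol tree is empty", self.scanner_id)

    def iter_sequences(self) -> Iterable[SequenceAcquisition]:
        for protocol in self.protocols:
            yield from protocol.sequences
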