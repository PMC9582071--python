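"""Set-similarity statistics for diagnosis–protocol overlap analysis.

The central quantity is the Szymkiewicz–Simpson overlap coefficient

    oc(A, B) = |A ∩ B| / min(|A|, |B|),

which is 1 whenever one set contains the other, and is therefore better
behaved than the Jaccard index J(A, B) = |A ∩ B| / |A ∪ B| for the small,
unevenly sized sets that arise when grouping admitting diagnoses by MRI
protocol (J ≤ oc always).

The *complement* overlap coefficient of a protocol compares its element set A
against the union of every other protocol's element set in the dataset; it is
0 exactly when the protocol's admitting diagnoses are unique to it, and
undefined for a single-protocol dataset.

Elements are, by default, whole per-exam code combinations
(:class:`~mrharmony.model.CodeSetElement`), not individual codes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import AbstractSet, Hashable, Mapping, Optional, Sequence

import numpy as np

from .model import CodeSetElement, DataError, ExamRecord


def jaccard(a: AbstractSet[Hashable], b: AbstractSet[Hashable]) -> float:
    """Jaccard index |a ∩ b| / |a ∪ b|. Undefined when both sets are empty."""
    if not a and not b:
        raise DataError("jaccard undefined: both sets are empty")
    return len(a & b) / len(a | b)


def overlap_coefficient(a: AbstractSet[Hashable], b: AbstractSet[Hashable]) -> float:
    """Overlap coefficient |a ∩ b| / min(|a|, |b|). Both sets must be nonempty."""
    if not a or not b:
        raise DataError("overlap coefficient undefined: empty set")
    return len(a & b) / min(len(a), len(b))


def complement_overlap(
    label: str, assoc: Mapping[str, AbstractSet[Hashable]]
) -> Optional[float]:
    """Overlap of one protocol's element set with the union of all others.

    Returns ``None`` (undefined) when the complement union is empty, i.e. the
    dataset holds a single protocol.
    """
    if label not in assoc:
        raise DataError(f"unknown protocol label {label!r}")
    others: set = set()
    for key, elements in assoc.items():
        if key != label:
            others |= set(elements)
    if not others:
        return None
    return overlap_coefficient(assoc[label], others)


@dataclass
class OverlapMatrix:
    """Symmetric pairwise overlap-coefficient matrix with a complement column.

    ``values[i, j]`` is oc between the element sets of protocols ``labels[i]``
    and ``labels[j]``; ``complement[i]`` is the complement overlap coefficient
    (``None`` when undefined); ``element_counts[i]`` is |A_i|.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    complement: tuple[Optional[float], ...]
    element_counts: tuple[int, ...]

    def validate(self) -> None:
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise DataError("matrix labels must be unique")
        if self.values.shape != (n, n):
            raise DataError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if len(self.complement) != n or len(self.element_counts) != n:
            raise DataError("complement/element_counts length mismatch")
        if not np.allclose(self.values, self.values.T):
            raise DataError("matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0):
            raise DataError("matrix diagonal must be 1")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise DataError("matrix entries must be in [0, 1]")
        for comp in self.complement:
            if comp is not None and not (0 <= comp <= 1):
                raise DataError("complement entries must be in [0, 1]")
        if any(c < 1 for c in self.element_counts):
            raise DataError("element_counts must be >= 1")


def pairwise_matrix(
    assoc: Mapping[str, AbstractSet[Hashable]], order: Sequence[str]
) -> OverlapMatrix:
    """Pairwise overlap-coefficient matrix over protocols, in a given order.

    ``order`` must be a permutation of ``assoc``'s keys; every element set
    must be nonempty.
    """
    if sorted(order) != sorted(assoc):
        raise DataError("order must be a permutation of the association's keys")
    for label in order:
        if not assoc[label]:
            raise DataError(f"protocol {label!r} has an empty element set")
    n = len(order)
    sets = [set(assoc[label]) for label in order]
    values = np.ones((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            oc = overlap_coefficient(sets[i], sets[j])
            values[i, j] = values[j, i] = oc
    complement = tuple(complement_overlap(label, assoc) for label in order)
    counts = tuple(len(s) for s in sets)
    matrix = OverlapMatrix(
        labels=tuple(order),
        values=values,
        complement=complement,
        element_counts=counts,
    )
    matrix.validate()
    return matrix


@dataclass
class LabelStatistics:
    """Multi-label statistics of the admitting-diagnosis annotation.

    cardinality
        mean number of codes per exam (over exams with at least one code);
    density
        cardinality divided by the number of unique codes;
    diversity
        number of distinct code combinations observed.
    """

    n_exams: int
    n_unique_codes: int
    cardinality: float
    density: float
    diversity: int

    def to_dict(self) -> dict:
        """JSON-ready mapping; density at full precision plus 2-decimal display."""
        return {
            "n_exams": self.n_exams,
            "n_unique_codes": self.n_unique_codes,
            "cardinality": self.cardinality,
            "density": self.density,
            "density_display": f"{self.density:.2f}",
            "diversity": self.diversity,
        }


def label_statistics(records: Sequence[ExamRecord]) -> LabelStatistics:
    """Compute label cardinality / density / diversity over exam records.

    Records with an empty code set must have been excluded upstream; at least
    one eligible record is required.
    """
    eligible = [r for r in records if r.admitting_codes]
    if not eligible:
        raise DataError("label statistics require >= 1 record with nonempty codes")
    sizes = [len(r.admitting_codes) for r in eligible]
    union: set[str] = set()
    combos: set[CodeSetElement] = set()
    for rec in eligible:
        union |= rec.admitting_codes
        combos.add(CodeSetElement.from_codes(rec.admitting_codes))
    cardinality = sum(sizes) / len(sizes)
    n_unique = len(union)
    return LabelStatistics(
        n_exams=len(eligible),
        n_unique_codes=n_unique,
        cardinality=cardinality,
        density=cardinality / n_unique,
        diversity=len(combos),
    )
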