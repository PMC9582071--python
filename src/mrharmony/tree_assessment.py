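"""Protocol-tree heterogeneity assessment across scanners.

Quantifies how similar the protocol trees of several scanners are, at three
name levels — raw sequence names, standardized sequence names, protocol
names — by the overlap coefficient of each scanner's name set against a
reference scanner. Because standardized names are a pure function of
acquisition parameters, comparing the raw-level and standardized-level
coefficients separates genuine differences in sequence content from mere
naming inconsistency.

A chi-square test of homogeneity on the raw-vs-standardized unique-name
counts across scanners quantifies whether standardization changes the
distribution of name-count variability (rows: raw / standardized counts,
columns: scanners, df = K - 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as scipy_stats

from .model import DataError, ProtocolTree
from .similarity import overlap_coefficient
from .standardize import StandardizationRuleSet, standardize

logger = logging.getLogger("mrharmony")

NAME_LEVELS = ("raw", "standardized", "protocol")


def name_sets(
    tree: ProtocolTree,
    level: str,
    rules: Optional[StandardizationRuleSet] = None,
) -> set[str]:
    """Distinct names of one tree at a level: raw / standardized / protocol."""
    if level not in NAME_LEVELS:
        raise DataError(f"unknown name level {level!r}")
    if level == "standardized" and rules is None:
        raise DataError("level 'standardized' requires a rule set")
    if not tree.protocols:
        logger.warning("scanner %r: empty tree, empty name set", tree.scanner_id)
        return set()
    if level == "protocol":
        return {p.protocol_name for p in tree.protocols}
    if level == "raw":
        return {s.raw_name for s in tree.iter_sequences()}
    return {standardize(s, rules) for s in tree.iter_sequences()}


def mean_counts(counts: Sequence[int]) -> tuple[float, int]:
    """Arithmetic mean of counts plus its display integer.

    The display value rounds half away from zero (310/3 = 103.33 → 103;
    103.5 → 104), matching how per-scanner averages are conventionally
    printed.
    """
    if not counts:
        raise DataError("mean_counts requires a nonempty list")
    mean = sum(counts) / len(counts)
    display = int(math.floor(mean + 0.5)) if mean >= 0 else int(math.ceil(mean - 0.5))
    return mean, display


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    dof: int
    p_value: float


def variability_chisq(
    raw_counts: Sequence[int], std_counts: Sequence[int]
) -> ChiSquareResult:
    """Chi-square homogeneity test on the raw-vs-standardized count table.

    Builds the 2×K contingency table with rows (raw counts, standardized
    counts) and one column per scanner; expected counts from the margins;
    df = K − 1. Identical or proportional rows give statistic 0, p = 1.
    """
    if len(raw_counts) != len(std_counts) or not raw_counts:
        raise DataError("count lists must be nonempty and equal length")
    if any(c <= 0 for c in raw_counts) or any(c <= 0 for c in std_counts):
        raise DataError("all counts must be > 0")
    table = np.array([list(raw_counts), list(std_counts)], dtype=float)
    expected = scipy_stats.contingency.expected_freq(table)
    if np.any(expected <= 0):
        raise DataError(
            "zero expected cell in the contingency table; "
            "merge scanners or check the counts"
        )
    result = scipy_stats.chi2_contingency(table, correction=False)
    return ChiSquareResult(
        statistic=float(result.statistic),
        dof=int(result.dof),
        p_value=float(result.pvalue),
    )


@dataclass
class ScannerEntry:
    """Per-scanner block of the comparison report."""

    scanner_id: str
    site_id: str
    n_unique_raw: int
    n_unique_standardized: int
    n_unique_protocols: int
    # oc vs the reference scanner per level; absent for the reference itself,
    # None where a level's name set is empty (undefined).
    oc_vs_reference: Optional[dict[str, Optional[float]]] = None


@dataclass
class TreeComparisonReport:
    """Per-scanner unique-name counts and overlap vs a reference scanner."""

    reference_scanner: str
    scanners: dict[str, ScannerEntry]
    mean_counts: dict[str, tuple[float, int]]  # level -> (mean, display int)
    chisq: Optional[ChiSquareResult]
    all_pairs: Optional[dict[tuple[str, str], dict[str, Optional[float]]]] = None

    def to_dict(self) -> dict:
        doc: dict = {
            "reference_scanner": self.reference_scanner,
            "scanners": {},
            "mean_counts": {
                level: {"mean": mean, "display": display}
                for level, (mean, display) in self.mean_counts.items()
            },
            "chisq": None
            if self.chisq is None
            else {
                "statistic": self.chisq.statistic,
                "dof": self.chisq.dof,
                "p_value": self.chisq.p_value,
            },
        }
        for sid, entry in self.scanners.items():
            doc["scanners"][sid] = {
                "site_id": entry.site_id,
                "n_unique_raw": entry.n_unique_raw,
                "n_unique_standardized": entry.n_unique_standardized,
                "n_unique_protocols": entry.n_unique_protocols,
                "oc_vs_reference": entry.oc_vs_reference,
            }
        if self.all_pairs is not None:
            doc["all_pairs"] = {
                f"{a}|{b}": ocs for (a, b), ocs in self.all_pairs.items()
            }
        return doc


def _pair_oc(
    sets_a: Mapping[str, set[str]], sets_b: Mapping[str, set[str]]
) -> dict[str, Optional[float]]:
    ocs: dict[str, Optional[float]] = {}
    for level in NAME_LEVELS:
        a, b = sets_a[level], sets_b[level]
        ocs[level] = overlap_coefficient(a, b) if a and b else None
    return ocs


def compare_trees(
    trees: Sequence[ProtocolTree],
    reference_scanner: str,
    rules: Optional[StandardizationRuleSet] = None,
    all_pairs: bool = False,
) -> TreeComparisonReport:
    """Compare protocol trees against a reference scanner at all three levels.

    Requires at least two trees with unique scanner ids, the reference among
    them. Scanner entries are keyed by id, so the result is invariant to the
    order of non-reference trees. A level with an empty name set yields an
    undefined (None) coefficient. The chi-square block is omitted (None, with
    a warning) when any unique-name count is zero.
    """
    if len(trees) < 2:
        raise DataError("compare_trees requires at least 2 trees")
    ids = [t.scanner_id for t in trees]
    if len(set(ids)) != len(ids):
        raise DataError(f"duplicate scanner ids: {ids}")
    if reference_scanner not in ids:
        raise DataError(f"unknown reference scanner {reference_scanner!r}")

    per_scanner_sets: dict[str, dict[str, set[str]]] = {}
    entries: dict[str, ScannerEntry] = {}
    # entries keyed and processed in sorted id order: the report (including
    # the chi-square arithmetic) is independent of the input tree order
    for tree in sorted(trees, key=lambda t: t.scanner_id):
        sets = {level: name_sets(tree, level, rules) for level in NAME_LEVELS}
        per_scanner_sets[tree.scanner_id] = sets
        entries[tree.scanner_id] = ScannerEntry(
            scanner_id=tree.scanner_id,
            site_id=tree.site_id,
            n_unique_raw=len(sets["raw"]),
            n_unique_standardized=len(sets["standardized"]),
            n_unique_protocols=len(sets["protocol"]),
        )

    ref_sets = per_scanner_sets[reference_scanner]
    for sid, sets in per_scanner_sets.items():
        if sid == reference_scanner:
            continue
        entries[sid].oc_vs_reference = _pair_oc(ref_sets, sets)

    means = {
        "raw": mean_counts([e.n_unique_raw for e in entries.values()]),
        "standardized": mean_counts(
            [e.n_unique_standardized for e in entries.values()]
        ),
        "protocol": mean_counts([e.n_unique_protocols for e in entries.values()]),
    }

    raw_counts = [e.n_unique_raw for e in entries.values()]
    std_counts = [e.n_unique_standardized for e in entries.values()]
    if all(c > 0 for c in raw_counts + std_counts):
        chisq: Optional[ChiSquareResult] = variability_chisq(raw_counts, std_counts)
    else:
        logger.warning("zero unique-name count: skipping the chi-square block")
        chisq = None

    pairs: Optional[dict[tuple[str, str], dict[str, Optional[float]]]] = None
    if all_pairs:
        pairs = {}
        sorted_ids = sorted(per_scanner_sets)
        for i, a in enumerate(sorted_ids):
            for b in sorted_ids[i + 1 :]:
                pairs[(a, b)] = _pair_oc(per_scanner_sets[a], per_scanner_sets[b])

    return TreeComparisonReport(
        reference_scanner=reference_scanner,
        scanners=entries,
        mean_counts=means,
        chisq=chisq,
        all_pairs=pairs,
    )
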