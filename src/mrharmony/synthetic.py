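"""Synthetic exam logs and protocol trees with the structure the analyses assume.

The study dataset behind this kind of analysis (exam logs with ICD-10
admitting diagnoses, per-scanner protocol trees) is typically private, so
this module generates stand-ins that reproduce its *statistical* shape:

* per-exam code-set size drawn from a configurable cardinality distribution
  (defaults give the mean ~1.1 codes/exam seen for spine exams);
* Zipf-like code popularity, so single-code occurrence spans roughly 1 to a
  few hundred;
* heavy-tailed protocol frequencies within a configured range (e.g. 6-341);
* *planted* pairwise overlaps: for chosen protocol pairs the element sets are
  constructed explicitly (shared / private code combinations) so the
  realized overlap coefficient equals the target exactly — parameter
  recovery is an exact check, not a statistical one;
* multi-scanner protocol trees built from a shared core of parameter tuples
  plus site-specific tuples, where each tuple's raw name is drawn per scanner
  from a synonym pool — same parameters, different spellings — so sequence
  name standardization provably increases cross-scanner name overlap.

Everything is deterministic under the root seed; each component (codes,
frequencies, trees, ...) draws from its own seed stream so adding one does
not perturb the others. No clinical semantics are simulated: which diagnosis
truly warrants which protocol is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np

from .model import (
    CodeSetElement,
    DataError,
    ExamRecord,
    ProtocolDefinition,
    ProtocolTree,
    SequenceAcquisition,
    canonicalize_code,
)

logger = logging.getLogger("mrharmony")

# seed-stream component ids (root seed stays the first entry everywhere)
_STREAM_VOCAB = 10
_STREAM_EXAMS = 11
_STREAM_SHUFFLE = 12
_STREAM_CORE = 20
_STREAM_EXTRAS = 21
_STREAM_SCANNER = 22


@dataclass(frozen=True)
class RegionConfig:
    """Exam-log generation parameters for one body region."""

    n_protocols: int
    n_exams: int
    code_vocabulary_size: int
    # probability of 1, 2, 3, ... codes per exam
    cardinality_distribution: dict[int, float]
    protocol_frequency_range: tuple[int, int]
    planted_overlaps: tuple[tuple[str, str, float], ...] = ()
    zipf_exponent: float = 1.2  # code-popularity skew
    frequency_exponent: float = 1.2  # protocol-frequency skew

    def __post_init__(self) -> None:
        if self.n_protocols < 1 or self.n_exams < 1:
            raise DataError("n_protocols and n_exams must be >= 1")
        if self.code_vocabulary_size < 1:
            raise DataError("code_vocabulary_size must be >= 1")
        total = sum(self.cardinality_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise DataError(
                f"cardinality_distribution must sum to 1, got {total}"
            )
        if any(k < 1 for k in self.cardinality_distribution):
            raise DataError("cardinality sizes must be >= 1")
        low, high = self.protocol_frequency_range
        if not (1 <= low <= high):
            raise DataError(
                f"ill-formed protocol_frequency_range {self.protocol_frequency_range}"
            )
        seen: set[str] = set()
        for pi, pj, target in self.planted_overlaps:
            if not (0.0 <= target <= 1.0):
                raise DataError(f"planted target oc {target} outside [0, 1]")
            if pi == pj or pi in seen or pj in seen:
                raise DataError(
                    f"planted pair ({pi!r}, {pj!r}): each protocol may appear "
                    "in at most one planted pair"
                )
            seen.update((pi, pj))


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generator configuration; the seed determines all output."""

    regions: dict[str, RegionConfig]
    seed: int = 0
    n_scanners: int = 3
    n_sites: int = 2
    n_core_parameter_tuples: int = 200
    synonym_noise_rate: float = 0.15
    site_specific_sequence_rate: float = 0.15
    protocols_per_scanner: int = 100

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise DataError("seed must be nonnegative")
        if not (1 <= self.n_sites <= self.n_scanners):
            raise DataError("need 1 <= n_sites <= n_scanners")
        for name, rate in (
            ("synonym_noise_rate", self.synonym_noise_rate),
            ("site_specific_sequence_rate", self.site_specific_sequence_rate),
        ):
            if not (0.0 <= rate <= 1.0):
                raise DataError(f"{name} must be in [0, 1]")
        if self.n_core_parameter_tuples < 2:
            raise DataError("n_core_parameter_tuples must be >= 2")
        if self.protocols_per_scanner < 1:
            raise DataError("protocols_per_scanner must be >= 1")

    def scanner_ids(self) -> list[str]:
        return [f"scanner{i + 1}" for i in range(self.n_scanners)]

    def site_of(self, scanner_index: int) -> str:
        # scanners fill sites in contiguous blocks (3 scanners / 2 sites:
        # scanners 1-2 at site A, scanner 3 at site B)
        return f"site{chr(ord('A') + scanner_index * self.n_sites // self.n_scanners)}"


def study_scale() -> SyntheticConfig:
    """Defaults at the scale of the study conditions.

    Spine: 727 exams, 127-code vocabulary, cardinality mean 1.1, protocol
    frequencies 6-341, planted overlaps 0.5 (cervical pair) and 1/6 (lumbar
    pair; prints as 0.17). Brain/head: 249 exams, 98 codes, mean 1.2. Trees:
    3 scanners on 2 sites, 200 core parameter tuples.
    """
    return SyntheticConfig(
        regions={
            "spine": RegionConfig(
                n_protocols=12,
                n_exams=727,
                code_vocabulary_size=127,
                cardinality_distribution={1: 0.9, 2: 0.1},
                protocol_frequency_range=(6, 341),
                planted_overlaps=(
                    ("CERVICAL/WITHOUT", "CERVICAL/POST OP METAL", 0.5),
                    ("LUMBAR/WITHOUT", "LUMBAR/LUMBAR METAL", 1 / 6),
                ),
            ),
            "brain/head": RegionConfig(
                n_protocols=10,
                n_exams=249,
                code_vocabulary_size=98,
                cardinality_distribution={1: 0.8, 2: 0.2},
                protocol_frequency_range=(6, 42),
            ),
        },
    )


def toy() -> SyntheticConfig:
    """A tiny configuration for quick runs and examples."""
    return SyntheticConfig(
        regions={
            "spine": RegionConfig(
                n_protocols=4,
                n_exams=60,
                code_vocabulary_size=20,
                cardinality_distribution={1: 0.9, 2: 0.1},
                protocol_frequency_range=(6, 30),
                planted_overlaps=(("TOY/A", "TOY/B", 0.5),),
            )
        },
        n_core_parameter_tuples=30,
        protocols_per_scanner=12,
        synonym_noise_rate=0.3,
        site_specific_sequence_rate=0.2,
    )


# --- code vocabulary --------------------------------------------------------

_CODE_LETTERS = "CDEFGHIJKLMNRS"


def generate_code_vocabulary(size: int, seed) -> list[str]:
    """Generate ``size`` distinct canonical-form ICD-10-shaped codes.

    ``seed`` may be an integer or a numpy ``Generator``. Deterministic under
    a fixed seed.
    """
    if size < 1:
        raise DataError("vocabulary size must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codes: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(codes) < size:
        attempts += 1
        if attempts > size * 10000:
            raise DataError(f"cannot generate {size} distinct codes")
        letter = _CODE_LETTERS[rng.integers(len(_CODE_LETTERS))]
        body = f"{rng.integers(100):02d}"
        code = f"{letter}{body}"
        if rng.random() < 0.6:
            sub = rng.integers(100)
            code += f".{sub}" if rng.random() < 0.5 else f".{sub % 10}"
        code = canonicalize_code(code)
        if code not in seen:
            seen.add(code)
            codes.append(code)
    return codes


# --- protocol frequencies ---------------------------------------------------


def _power_law_counts(
    n: int,
    total: int,
    low: int,
    high: int,
    exponent: float,
    pinned: dict[int, int],
) -> list[int]:
    """Integer counts ~ i^-exponent within [low, high], summing to ``total``.

    The first position is anchored near ``high`` and the last near ``low``;
    ``pinned`` positions are kept fixed while the remainder absorbs the
    rounding difference.
    """
    if n * low > total or n * high < total:
        raise DataError(
            f"cannot place {total} exams on {n} protocols with counts in "
            f"[{low}, {high}]"
        )
    if n == 1:
        return [total]
    ideal = [high * (i + 1) ** (-exponent) for i in range(n)]
    counts = [int(min(high, max(low, round(x)))) for x in ideal]
    counts[0] = high
    counts[-1] = low
    for pos, value in pinned.items():
        counts[pos] = value
    free = [i for i in range(1, n - 1) if i not in pinned]
    diff = total - sum(counts)
    # distribute the difference, starting with the tail so the head keeps
    # its skew; extremes are touched only as a last resort
    for pool in (list(reversed(free)), [i for i in (n - 1, 0) if i not in pinned]):
        while diff != 0:
            progressed = False
            for i in pool:
                if diff > 0 and counts[i] < high:
                    counts[i] += 1
                    diff += -1
                    progressed = True
                elif diff < 0 and counts[i] > low:
                    counts[i] -= 1
                    diff += 1
                    progressed = True
                if diff == 0:
                    break
            if not progressed:
                break
        if diff == 0:
            break
    if diff != 0:
        raise DataError(
            "cannot balance protocol frequencies to the requested exam total; "
            "relax the frequency range or planted overlaps"
        )
    return counts


@dataclass(frozen=True)
class PlantedPlacement:
    protocol_hi: str
    protocol_lo: str
    target: float
    realized: float
    count_hi: int
    count_lo: int
    n_shared: int


def _place_planted(
    region: str, cfg: RegionConfig
) -> tuple[list[str], dict[int, int], list[tuple[int, int, Fraction, int]]]:
    """Assign protocol names to count positions and pin planted counts.

    Planted pairs sit on adjacent positions in the low-frequency tail (just
    above the pinned minimum), with the smaller partner's count adjusted to a
    multiple of the target's reduced denominator so that
    shared / min(|A|, |B|) equals the target exactly.
    """
    n = cfg.n_protocols
    low, high = cfg.protocol_frequency_range
    pairs = sorted(
        cfg.planted_overlaps,
        key=lambda p: -Fraction(p[2]).limit_denominator(1000).denominator,
    )
    if pairs and n < 2 * len(pairs) + 2:
        raise DataError(
            f"region {region!r}: {len(pairs)} planted pair(s) need at least "
            f"{2 * len(pairs) + 2} protocols, got {n}"
        )
    ideal = [int(min(high, max(low, round(high * (i + 1) ** (-cfg.frequency_exponent)))))
             for i in range(n)]
    names = [""] * n
    pinned: dict[int, int] = {}
    placements: list[tuple[int, int, Fraction, int]] = []
    next_hi = n - 3
    for pi, pj, target in pairs:
        frac = Fraction(target).limit_denominator(1000)
        pos_hi, pos_lo = next_hi, next_hi + 1
        next_hi -= 2
        if pos_hi < 1:
            raise DataError(f"region {region!r}: no room for planted pair ({pi}, {pj})")
        c_hi = ideal[pos_hi]
        den = frac.denominator
        # nearest feasible multiple of the denominator, never above c_hi
        upper = min(c_hi, high) // den
        if upper < 1 or den > min(c_hi, high):
            raise DataError(
                f"region {region!r}: cannot realize planted oc {target} for "
                f"({pi!r}, {pj!r}): denominator {den} exceeds the feasible "
                f"set size {min(c_hi, high)}"
            )
        k = max(max(low + den - 1, den) // den, min(upper, round(ideal[pos_lo] / den)))
        c_lo = k * den
        if not (low <= c_lo <= min(c_hi, high)):
            raise DataError(
                f"region {region!r}: planted pair ({pi!r}, {pj!r}) needs a set "
                f"size multiple of {den} within [{low}, {min(c_hi, high)}]"
            )
        n_shared = int(frac * c_lo)
        names[pos_hi], names[pos_lo] = pi, pj
        pinned[pos_hi] = c_hi
        pinned[pos_lo] = c_lo
        placements.append((pos_hi, pos_lo, frac, n_shared))
    tag = region.upper()
    generic = 0
    for i in range(n):
        if not names[i]:
            names[i] = f"{tag} {generic:02d}"
            generic += 1
    if len(set(names)) != n:
        raise DataError(f"region {region!r}: planted names collide with generic names")
    return names, pinned, placements


# --- exam log ---------------------------------------------------------------


def _draw_combo(
    rng: np.random.Generator,
    vocab: list[str],
    weights: np.ndarray,
    sizes: np.ndarray,
    probs: np.ndarray,
) -> tuple[str, ...]:
    size = int(rng.choice(sizes, p=probs))
    size = min(size, len(vocab))
    idx = rng.choice(len(vocab), size=size, replace=False, p=weights)
    return tuple(sorted(vocab[i] for i in idx))


def _draw_distinct_combos(
    rng: np.random.Generator,
    vocab: list[str],
    weights: np.ndarray,
    sizes: np.ndarray,
    probs: np.ndarray,
    count: int,
    taken: set[tuple[str, ...]],
) -> list[tuple[str, ...]]:
    out: list[tuple[str, ...]] = []
    attempts = 0
    while len(out) < count:
        attempts += 1
        if attempts > 1000 * count + 1000:
            raise DataError(
                "cannot draw enough distinct code combinations; enlarge the "
                "code vocabulary or reduce the planted set sizes"
            )
        combo = _draw_combo(rng, vocab, weights, sizes, probs)
        if combo not in taken:
            taken.add(combo)
            out.append(combo)
    return out


def generate_exam_log(
    config: SyntheticConfig, with_meta: bool = False
) -> list[ExamRecord] | tuple[list[ExamRecord], dict]:
    """Generate the synthetic exam log for all configured regions.

    With ``with_meta=True`` also returns per-region protocol frequencies and
    the planted-overlap placements (including the exactly realized oc).
    """
    if not config.regions:
        raise DataError("config defines no body regions")
    scanner_ids = config.scanner_ids()
    records: list[ExamRecord] = []
    meta: dict = {"regions": {}}
    exam_counter = 0
    for region_idx, region in enumerate(sorted(config.regions)):
        cfg = config.regions[region]
        rng_vocab = np.random.default_rng([config.seed, _STREAM_VOCAB, region_idx])
        rng = np.random.default_rng([config.seed, _STREAM_EXAMS, region_idx])
        vocab = generate_code_vocabulary(cfg.code_vocabulary_size, rng_vocab)
        weights = np.arange(1, len(vocab) + 1, dtype=float) ** (-cfg.zipf_exponent)
        weights /= weights.sum()
        sizes = np.array(sorted(cfg.cardinality_distribution), dtype=int)
        probs = np.array(
            [cfg.cardinality_distribution[int(s)] for s in sizes], dtype=float
        )
        probs /= probs.sum()

        names, pinned, placements = _place_planted(region, cfg)
        low, high = cfg.protocol_frequency_range
        counts = _power_law_counts(
            cfg.n_protocols, cfg.n_exams, low, high, cfg.frequency_exponent, pinned
        )

        # planted pairs first: explicit shared/private element allocation
        combos_by_protocol: dict[str, list[tuple[str, ...]]] = {}
        planted_meta = []
        for pos_hi, pos_lo, frac, n_shared in placements:
            c_hi, c_lo = counts[pos_hi], counts[pos_lo]
            taken: set[tuple[str, ...]] = set()
            try:
                shared = _draw_distinct_combos(
                    rng, vocab, weights, sizes, probs, n_shared, taken
                )
                only_hi = _draw_distinct_combos(
                    rng, vocab, weights, sizes, probs, c_hi - n_shared, taken
                )
                only_lo = _draw_distinct_combos(
                    rng, vocab, weights, sizes, probs, c_lo - n_shared, taken
                )
            except DataError as err:
                raise DataError(
                    f"region {region!r}: infeasible planted overlap for "
                    f"({names[pos_hi]!r}, {names[pos_lo]!r}): {err}"
                ) from err
            combos_by_protocol[names[pos_hi]] = shared + only_hi
            combos_by_protocol[names[pos_lo]] = shared + only_lo
            planted_meta.append(
                PlantedPlacement(
                    protocol_hi=names[pos_hi],
                    protocol_lo=names[pos_lo],
                    target=float(frac),
                    realized=n_shared / c_lo,
                    count_hi=c_hi,
                    count_lo=c_lo,
                    n_shared=n_shared,
                )
            )

        region_rows: list[tuple[int, str, str, tuple[str, ...]]] = []
        for pos, protocol in enumerate(names):
            planted_combos = combos_by_protocol.get(protocol)
            for k in range(counts[pos]):
                if planted_combos is not None:
                    combo = planted_combos[k]
                else:
                    combo = _draw_combo(rng, vocab, weights, sizes, probs)
                scanner_idx = int(rng.integers(config.n_scanners))
                day = int(rng.integers(181))  # Jan 1 - Jun 30, 2019
                date = str(np.datetime64("2019-01-01") + np.timedelta64(day, "D"))
                region_rows.append((scanner_idx, date, protocol, combo))
        shuffle_rng = np.random.default_rng([config.seed, _STREAM_SHUFFLE, region_idx])
        for i in shuffle_rng.permutation(len(region_rows)):
            scanner_idx, date, protocol, combo = region_rows[int(i)]
            exam_counter += 1
            records.append(
                ExamRecord(
                    exam_id=f"E{exam_counter:05d}",
                    scanner_id=scanner_ids[scanner_idx],
                    site_id=config.site_of(scanner_idx),
                    body_region=region,
                    protocol_name=protocol,
                    admitting_codes=frozenset(combo),
                    exam_date=date,
                )
            )
        meta["regions"][region] = {
            "protocol_counts": dict(zip(names, counts)),
            "planted": planted_meta,
        }
    if with_meta:
        return records, meta
    return records


# --- protocol trees ---------------------------------------------------------

# (weighting label, family label, parameter sampler)
_ARCHETYPES: tuple[tuple[str, str, dict], ...] = (
    ("t1", "se", dict(technique="SE", tr=(400, 700), te=(8, 20), flip=(80, 100))),
    ("t2", "tse", dict(technique="TSE", tr=(3000, 6000), te=(90, 130), etl=(12, 25))),
    ("pd", "tse", dict(technique="TSE", tr=(2200, 4000), te=(10, 25), etl=(6, 12))),
    (
        "flair",
        "tse",
        dict(technique="TSE", tr=(8000, 10000), te=(90, 140), ti=(2000, 2600)),
    ),
    (
        "stir",
        "tse",
        dict(technique="TSE", tr=(3000, 5000), te=(30, 60), ti=(140, 260)),
    ),
    (
        "dwi",
        "epi",
        dict(technique="EPI", tr=(3000, 6000), te=(60, 90), b=(600, 1000)),
    ),
    ("t1", "gre", dict(technique="GRE", tr=(200, 600), te=(3, 8), flip=(55, 80))),
    ("swi", "gre", dict(technique="GRE", tr=(500, 900), te=(15, 25), flip=(12, 25))),
)

_ORIENTATIONS = ("SAG", "COR", "TRA", "OBL")
_ORIENTATION_P = (0.3, 0.25, 0.4, 0.05)


@dataclass(frozen=True)
class _CoreTuple:
    params: SequenceAcquisition  # raw_name holds the canonical spelling
    spellings: tuple[str, ...]  # synonym pool, canonical first


def _draw_parameters(
    rng: np.random.Generator, force_like: Optional[SequenceAcquisition] = None
) -> tuple[SequenceAcquisition, list[str]]:
    """One parameterized sequence plus its descriptive name parts.

    ``force_like`` reuses another sequence's categorical fields (same
    archetype, orientation, flags) with fresh numeric jitter, guaranteeing a
    pair of distinct parameter tuples that standardize to the same name.
    """
    arch_idx = int(rng.integers(len(_ARCHETYPES)))
    weight, family, spec = _ARCHETYPES[arch_idx]
    if force_like is not None:
        for i, (w, f, s) in enumerate(_ARCHETYPES):
            if s["technique"] == force_like.technique and (
                ("ti" in s) == (force_like.ti_ms is not None)
            ):
                arch_idx, (weight, family, spec) = i, (w, f, s)
                break
    lo, hi = spec["tr"]
    tr = float(rng.integers(lo // 10, hi // 10 + 1) * 10)
    lo, hi = spec["te"]
    te = float(rng.integers(lo, hi + 1))
    ti = None
    if "ti" in spec:
        lo, hi = spec["ti"]
        ti = float(rng.integers(lo // 10, hi // 10 + 1) * 10)
    flip = float(rng.integers(*spec["flip"])) if "flip" in spec else 90.0
    etl = int(rng.integers(*spec["etl"])) if "etl" in spec else 1
    b_values: tuple[float, ...] = ()
    if "b" in spec:
        lo, hi = spec["b"]
        b_values = (0.0, float(rng.integers(lo // 50, hi // 50 + 1) * 50))
    if force_like is not None:
        orientation = force_like.orientation
        fs = force_like.fat_suppression
        dim = force_like.dimensionality
        contrast = force_like.contrast_phase
        tr = tr + 10.0  # guarantee a distinct parameter tuple
    else:
        orientation = str(rng.choice(_ORIENTATIONS, p=_ORIENTATION_P))
        fs = bool(rng.random() < 0.2)
        dim = "3D" if rng.random() < 0.15 else "2D"
        contrast = "POST" if rng.random() < 0.15 else "NONE"
    seq = SequenceAcquisition(
        raw_name="",
        tr_ms=tr,
        te_ms=te,
        ti_ms=ti,
        flip_deg=flip,
        technique=spec["technique"],
        inversion_recovery=ti is not None,
        orientation=orientation,
        fat_suppression=fs,
        b_values=b_values,
        contrast_phase=contrast,
        dimensionality=dim,
        echo_train_length=etl,
    )
    parts = [weight, family, orientation.lower()]
    if dim == "3D":
        parts.append("3d")
    if fs:
        parts.append("fs")
    if contrast == "POST":
        parts.append("km")
    if rng.random() < 0.5:
        parts.append(f"{int(rng.integers(2, 6))}mm")
    return seq, parts


def _spelling_pool(parts: Sequence[str], registry: set[str]) -> tuple[str, ...]:
    """Three spellings of one acquisition, globally disjoint across tuples.

    Disjoint pools make the raw name a *refinement* of the parameter tuple:
    equal raw names imply equal parameters, so standardization can only merge
    names, never split them.
    """
    base = (
        "_".join(parts).lower(),
        " ".join(p.upper() for p in parts),
        "-".join(p.capitalize() for p in parts),
    )
    variants = base
    suffix = 0
    while any(v in registry for v in variants):
        suffix += 1
        variants = (
            f"{base[0]}_{suffix}",
            f"{base[1]} {suffix}",
            f"{base[2]}-{suffix}",
        )
    registry.update(variants)
    return variants


def _make_tuples(
    rng: np.random.Generator, count: int, registry: set[str], forced_merge: bool
) -> list[_CoreTuple]:
    tuples: list[_CoreTuple] = []
    for k in range(count):
        force_like = tuples[0].params if (forced_merge and k == 1) else None
        seq, parts = _draw_parameters(rng, force_like=force_like)
        spellings = _spelling_pool(parts, registry)
        tuples.append(
            _CoreTuple(
                params=replace(seq, raw_name=spellings[0]), spellings=spellings
            )
        )
    return tuples


def generate_trees(config: SyntheticConfig) -> list[ProtocolTree]:
    """Generate one protocol tree per scanner.

    A shared core of parameter tuples is reused on every scanner (the first
    two core tuples always survive and share a standardized name, so
    standardization strictly reduces unique-name counts); each site adds its
    own tuples at ``site_specific_sequence_rate``, and each scanner drops a
    fraction of the remaining core at half that rate. Raw spellings come from
    per-tuple synonym pools: the canonical spelling unless the synonym noise
    fires (and, whenever the noise rate is positive, the very first core
    tuple is deliberately spelled differently on scanner 1 than elsewhere).
    Every pool tuple is used by at least one protocol, so per-scanner
    unique-raw-name counts equal pool sizes.
    """
    regions = sorted(config.regions) if config.regions else ["spine"]
    registry: set[str] = set()
    rng_core = np.random.default_rng([config.seed, _STREAM_CORE])
    core = _make_tuples(
        rng_core, config.n_core_parameter_tuples, registry, forced_merge=True
    )
    n_extras = round(config.site_specific_sequence_rate * config.n_core_parameter_tuples)
    extras_by_site: dict[str, list[_CoreTuple]] = {}
    for site_idx in range(config.n_sites):
        rng_x = np.random.default_rng([config.seed, _STREAM_EXTRAS, site_idx])
        extras_by_site[f"site{chr(ord('A') + site_idx)}"] = _make_tuples(
            rng_x, n_extras, registry, forced_merge=False
        )
    drop_rate = config.site_specific_sequence_rate / 2.0
    n_site_protocols = round(config.site_specific_sequence_rate
                             * config.protocols_per_scanner / 2)

    trees: list[ProtocolTree] = []
    for s_idx, scanner_id in enumerate(config.scanner_ids()):
        site = config.site_of(s_idx)
        rng_s = np.random.default_rng([config.seed, _STREAM_SCANNER, s_idx])
        pool: list[_CoreTuple] = []
        for k, tup in enumerate(core):
            if k < 2 or rng_s.random() >= drop_rate:
                pool.append(tup)
        pool.extend(extras_by_site[site])

        spelling: dict[int, str] = {}
        for k, tup in enumerate(pool):
            forced_first = (
                config.synonym_noise_rate > 0 and tup is core[0]
            )
            if forced_first:
                spelling[k] = tup.spellings[0 if s_idx == 0 else 1]
            elif rng_s.random() < config.synonym_noise_rate:
                spelling[k] = tup.spellings[int(rng_s.integers(1, 3))]
            else:
                spelling[k] = tup.spellings[0]

        # shared protocol slots, with per-scanner dropouts and site extras
        kept_slots = [
            i
            for i in range(config.protocols_per_scanner)
            if i == 0 or rng_s.random() >= drop_rate
        ]
        names = [f"PROT {i:03d}" for i in kept_slots]
        names += [f"{site.upper()} SPECIAL {j:02d}" for j in range(n_site_protocols)]

        pool_weights = np.arange(1, len(pool) + 1, dtype=float) ** -0.8
        pool_weights /= pool_weights.sum()
        members: list[list[int]] = []
        for _ in names:
            n_seq = int(rng_s.integers(3, 8))
            chosen = rng_s.choice(
                len(pool), size=min(n_seq, len(pool)), replace=False, p=pool_weights
            )
            members.append([int(c) for c in chosen])
        # coverage: every pool tuple appears in at least one protocol
        used = {idx for m in members for idx in m}
        unused = [i for i in range(len(pool)) if i not in used]
        for j, idx in enumerate(unused):
            members[j % len(members)].append(idx)

        protocols = []
        for slot, (name, member_idx) in enumerate(zip(names, members)):
            region = regions[slot % len(regions)]
            sequences = tuple(
                replace(pool[idx].params, raw_name=spelling[idx])
                for idx in member_idx
            )
            protocols.append(
                ProtocolDefinition(
                    protocol_name=name, body_region=region, sequences=sequences
                )
            )
        trees.append(
            ProtocolTree(
                scanner_id=scanner_id, site_id=site, protocols=tuple(protocols)
            )
        )
    return trees


# --- YAML configuration -----------------------------------------------------


def config_from_yaml(path, seed: Optional[int] = None) -> SyntheticConfig:
    """Load a :class:`SyntheticConfig` from YAML; ``seed`` overrides the file.

    Region blocks carry the :class:`RegionConfig` fields;
    ``cardinality_distribution`` maps code counts to probabilities,
    ``protocol_frequency_range`` is a 2-list, ``planted_overlaps`` a list of
    ``[protocol_a, protocol_b, target_oc]`` triples.
    """
    import yaml

    with open(path, encoding="utf-8") as handle:
        doc = yaml.safe_load(handle)
    if not isinstance(doc, dict) or "regions" not in doc:
        raise DataError(f"config {path}: expected a mapping with a 'regions' block")
    regions = {}
    for tag, block in doc["regions"].items():
        try:
            regions[str(tag)] = RegionConfig(
                n_protocols=block["n_protocols"],
                n_exams=block["n_exams"],
                code_vocabulary_size=block["code_vocabulary_size"],
                cardinality_distribution={
                    int(k): float(v)
                    for k, v in block["cardinality_distribution"].items()
                },
                protocol_frequency_range=tuple(block["protocol_frequency_range"]),
                planted_overlaps=tuple(
                    (str(a), str(b), float(t))
                    for a, b, t in block.get("planted_overlaps", [])
                ),
                zipf_exponent=float(block.get("zipf_exponent", 1.2)),
                frequency_exponent=float(block.get("frequency_exponent", 1.2)),
            )
        except (KeyError, TypeError, ValueError) as err:
            raise DataError(f"config {path}: bad region {tag!r} ({err})") from err
    kwargs = {
        key: doc[key]
        for key in (
            "seed",
            "n_scanners",
            "n_sites",
            "n_core_parameter_tuples",
            "synonym_noise_rate",
            "site_specific_sequence_rate",
            "protocols_per_scanner",
        )
        if key in doc
    }
    if seed is not None:
        kwargs["seed"] = seed
    return SyntheticConfig(regions=regions, **kwargs)
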