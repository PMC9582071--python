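"""Rule-based MR sequence-name standardization.

User-given sequence names ("t1_se_sag", "T1 SAGITTAL", ...) vary across
scanners and sites even when the underlying acquisition is identical. This
module rebuilds a standardized name *purely* from acquisition parameters —
the raw name is never consulted — so that identically parameterized sequences
receive identical names everywhere.

A :class:`StandardizationRuleSet` is an ordered list of rules, first match
wins, terminated by a catch-all. Each rule is a conjunction of conditions
over :class:`~mrharmony.model.SequenceAcquisition` fields (numeric ranges,
categorical matches, boolean flags) and yields a weighting token (T1, T2, PD,
FLAIR, STIR, DWI, OTHER). The default table is a conventional MR-contrast
heuristic — diffusion before inversion recovery before relaxation-based rules
to keep DWI/FLAIR unambiguous — and is fully externalized to YAML
(``rules/default.yaml``) so sites can replace it:

=========  ==================================================  =======
rule        condition                                          token
=========  ==================================================  =======
diffusion   any b-value > 50 s/mm²                             DWI
flair       inversion recovery, TI in [1800, 2800] ms          FLAIR
stir        inversion recovery, TI in [120, 300] ms            STIR
t1-se       SE/TSE, TR < 800 ms, TE < 30 ms                    T1
t2          TR > 2000 ms, TE > 80 ms                           T2
pd          TR > 2000 ms, TE < 30 ms                           PD
t1-gre      GRE/bSSFP, flip > 50°, TR < 800 ms                 T1
catch-all   (always)                                           OTHER
=========  ==================================================  =======

The standardized name assembles tokens in a fixed order: weighting,
technique family, orientation (omitted when UNKNOWN), dimensionality,
``FS`` for fat suppression, ``C+`` for a post-contrast acquisition — e.g.
``"T1 SE SAG 2D"``, ``"FLAIR TSE TRA 2D FS"``, ``"DWI EPI TRA 2D"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from numbers import Real
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence, Union

import yaml

from .model import DataError, ProtocolDefinition, ProtocolTree, SequenceAcquisition

#: Fields a rule condition may reference. ``max_b_value`` is derived:
#: max(b_values) or absent when no diffusion weighting is listed.
RULE_FIELDS = frozenset(
    {
        "tr_ms",
        "te_ms",
        "ti_ms",
        "flip_deg",
        "technique",
        "inversion_recovery",
        "orientation",
        "fat_suppression",
        "contrast_phase",
        "dimensionality",
        "echo_train_length",
        "max_b_value",
    }
)

_BOUND_KEYS = frozenset({"ge", "gt", "le", "lt"})


@dataclass(frozen=True)
class Rule:
    """One classification rule: AND of field conditions → weighting token.

    Condition values: a scalar (equality), a list (categorical any-of), or a
    mapping with ``ge``/``gt``/``le``/``lt`` bounds (numeric range). A rule
    with no conditions always matches (the catch-all).
    """

    name: str
    when: Mapping[str, Any]
    token: str

    def __post_init__(self) -> None:
        for fname, cond in self.when.items():
            if fname not in RULE_FIELDS:
                raise DataError(f"rule {self.name!r}: unknown field {fname!r}")
            if isinstance(cond, Mapping):
                bad = set(cond) - _BOUND_KEYS
                if bad:
                    raise DataError(
                        f"rule {self.name!r}: unknown bound keys {sorted(bad)}"
                    )
                low = cond.get("ge", cond.get("gt"))
                high = cond.get("le", cond.get("lt"))
                if low is not None and high is not None and low > high:
                    raise DataError(
                        f"rule {self.name!r}: empty interval on {fname!r} "
                        f"({low} > {high})"
                    )

    def matches(self, seq: SequenceAcquisition) -> bool:
        for fname, cond in self.when.items():
            if fname == "max_b_value":
                value: Any = max(seq.b_values) if seq.b_values else None
            else:
                value = getattr(seq, fname)
            if isinstance(cond, Mapping):
                if value is None or not isinstance(value, Real):
                    return False
                if "ge" in cond and not value >= cond["ge"]:
                    return False
                if "gt" in cond and not value > cond["gt"]:
                    return False
                if "le" in cond and not value <= cond["le"]:
                    return False
                if "lt" in cond and not value < cond["lt"]:
                    return False
            elif isinstance(cond, (list, tuple)):
                if value not in cond:
                    return False
            else:
                if value != cond:
                    return False
        return True


@dataclass(frozen=True)
class StandardizationRuleSet:
    """Ordered rules (first match wins) plus token-assembly options."""

    rules: tuple[Rule, ...]
    include_dimensionality: bool = True
    include_contrast: bool = True

    def __post_init__(self) -> None:
        if not self.rules:
            raise DataError("rule set must contain at least one rule")
        if self.rules[-1].when:
            raise DataError(
                "rule set must end with a catch-all rule (empty condition)"
            )


def default_rules() -> StandardizationRuleSet:
    """The built-in MR-contrast heuristic rule table (see module docstring)."""
    return StandardizationRuleSet(
        rules=(
            Rule("diffusion", {"max_b_value": {"gt": 50}}, "DWI"),
            Rule(
                "flair",
                {"inversion_recovery": True, "ti_ms": {"ge": 1800, "le": 2800}},
                "FLAIR",
            ),
            Rule(
                "stir",
                {"inversion_recovery": True, "ti_ms": {"ge": 120, "le": 300}},
                "STIR",
            ),
            Rule(
                "t1-spin-echo",
                {"technique": ["SE", "TSE"], "tr_ms": {"lt": 800}, "te_ms": {"lt": 30}},
                "T1",
            ),
            Rule("t2", {"tr_ms": {"gt": 2000}, "te_ms": {"gt": 80}}, "T2"),
            Rule("pd", {"tr_ms": {"gt": 2000}, "te_ms": {"lt": 30}}, "PD"),
            Rule(
                "t1-gradient-echo",
                {
                    "technique": ["GRE", "bSSFP"],
                    "flip_deg": {"gt": 50},
                    "tr_ms": {"lt": 800},
                },
                "T1",
            ),
            Rule("catch-all", {}, "OTHER"),
        )
    )


def load_rules(path: Union[str, Path]) -> StandardizationRuleSet:
    """Load a rule set from its YAML representation.

    Format: ``{options: {include_dimensionality, include_contrast},
    rules: [{name, when: {field: value|list|{ge,gt,le,lt}}, token}, ...]}``.
    """
    with open(path, encoding="utf-8") as handle:
        doc = yaml.safe_load(handle)
    if not isinstance(doc, Mapping) or "rules" not in doc:
        raise DataError(f"rule file {path}: expected a mapping with a 'rules' list")
    options = doc.get("options") or {}
    rules = []
    for i, entry in enumerate(doc["rules"]):
        try:
            rules.append(
                Rule(
                    name=entry["name"],
                    when=entry.get("when") or {},
                    token=entry["token"],
                )
            )
        except (KeyError, TypeError) as err:
            raise DataError(f"rule file {path}: bad rule at index {i} ({err})")
    return StandardizationRuleSet(
        rules=tuple(rules),
        include_dimensionality=bool(options.get("include_dimensionality", True)),
        include_contrast=bool(options.get("include_contrast", True)),
    )


def classify_weighting(
    seq: SequenceAcquisition, rules: Optional[StandardizationRuleSet] = None
) -> str:
    """Weighting token of the first matching rule (catch-all guarantees one)."""
    ruleset = rules if rules is not None else default_rules()
    for rule in ruleset.rules:
        if rule.matches(seq):
            return rule.token
    # unreachable: the terminal catch-all always matches
    raise AssertionError("no rule matched despite catch-all")


def standardize(
    seq: SequenceAcquisition, rules: Optional[StandardizationRuleSet] = None
) -> str:
    """Standardized sequence name assembled from acquisition parameters only.

    Token order: weighting, technique family, orientation (UNKNOWN omitted),
    dimensionality, ``FS``, ``C+``. The user-given ``raw_name`` is never
    consulted.
    """
    ruleset = rules if rules is not None else default_rules()
    tokens = [classify_weighting(seq, ruleset)]
    if seq.technique != "UNKNOWN":
        tokens.append(seq.technique)
    if seq.orientation != "UNKNOWN":
        tokens.append(seq.orientation)
    if ruleset.include_dimensionality:
        tokens.append(seq.dimensionality)
    if seq.fat_suppression:
        tokens.append("FS")
    if ruleset.include_contrast and seq.contrast_phase == "POST":
        tokens.append("C+")
    return " ".join(tokens)


@dataclass(frozen=True)
class TreeStandardizationSummary:
    """Unique-name counts of one tree before and after standardization."""

    scanner_id: str
    n_unique_raw: int
    n_unique_standardized: int


def standardize_tree(
    tree: ProtocolTree, rules: Optional[StandardizationRuleSet] = None
) -> tuple[ProtocolTree, TreeStandardizationSummary]:
    """Standardize every sequence name in a protocol tree.

    Returns a tree copy whose sequences carry the standardized name in place
    of the raw one, together with the unique-name counts before/after.
    """
    ruleset = rules if rules is not None else default_rules()
    raw_names = {seq.raw_name for seq in tree.iter_sequences()}
    std_names: set[str] = set()
    new_protocols = []
    for proto in tree.protocols:
        new_sequences = []
        for seq in proto.sequences:
            std = standardize(seq, ruleset)
            std_names.add(std)
            new_sequences.append(replace(seq, raw_name=std))
        new_protocols.append(replace(proto, sequences=tuple(new_sequences)))
    new_tree = replace(tree, protocols=tuple(new_protocols))
    summary = TreeStandardizationSummary(
        scanner_id=tree.scanner_id,
        n_unique_raw=len(raw_names),
        n_unique_standardized=len(std_names),
    )
    return new_tree, summary
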