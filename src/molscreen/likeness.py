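"""Drug-, lead- and fragment-likeness rule evaluation.

A rule set is a list of single-descriptor threshold rules plus a tolerated
violation count; verdicts are a pure function of (descriptor block, rule
set).  Boundary equality passes for ``le``/``ge`` comparators, so a molecule
of exactly 500 g/mol satisfies ``mw <= 500``.
"""

from __future__ import annotations

import operator
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import yaml

from .descriptors import DescriptorBlock, compute_all
from .model import CompoundSet

__all__ = [
    "Rule",
    "RuleSet",
    "LikenessVerdict",
    "builtin_rulesets",
    "load_ruleset_file",
    "evaluate",
    "appraise_set",
]

_COMPARATORS = {"le": operator.le, "ge": operator.ge,
                "lt": operator.lt, "gt": operator.gt}


@dataclass(frozen=True)
class Rule:
    descriptor: str
    comparator: str  # le | ge | lt | gt
    bound: float

    def __post_init__(self) -> None:
        if self.comparator not in _COMPARATORS:
            raise ValueError(f"unknown comparator {self.comparator!r}")
        if self.descriptor not in DescriptorBlock.field_names():
            raise ValueError(f"unknown descriptor {self.descriptor!r}")

    def check(self, block: DescriptorBlock) -> tuple[float, bool]:
        value = getattr(block, self.descriptor)
        if value is None:
            raise ValueError(f"descriptor {self.descriptor!r} not populated")
        return value, _COMPARATORS[self.comparator](value, self.bound)


@dataclass(frozen=True)
class RuleSet:
    name: str
    rules: tuple[Rule, ...]
    max_violations: int = 0

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError("rule set must contain at least one rule")
        if not 0 <= self.max_violations < len(self.rules):
            raise ValueError("max_violations must be < number of rules")


@dataclass(frozen=True)
class LikenessVerdict:
    ruleset_name: str
    per_rule: tuple[tuple[Rule, float, bool], ...]  # (rule, observed, passed)
    violations: int
    passed: bool


def _ruleset_from_mapping(name: str, body: dict) -> RuleSet:
    rules = tuple(Rule(r["descriptor"], r["comparator"], float(r["bound"]))
                  for r in body["rules"])
    return RuleSet(name=name, rules=rules,
                   max_violations=int(body.get("max_violations", 0)))


def load_ruleset_file(path: Union[str, Path]) -> dict[str, RuleSet]:
    """Load rule sets from a YAML file (same layout as the packaged one)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or not doc:
        raise ValueError(f"{path}: no rule sets found")
    return {name: _ruleset_from_mapping(name, body) for name, body in doc.items()}


def builtin_rulesets() -> dict[str, RuleSet]:
    """The three packaged rule sets: drug_like, lead_like, fragment_like."""
    ref = resources.files("molscreen.data") / "rulesets.yaml"
    with resources.as_file(ref) as path:
        return load_ruleset_file(path)


def evaluate(block: DescriptorBlock, ruleset: RuleSet) -> LikenessVerdict:
    """Check every rule; pass iff violations <= max_violations."""
    per_rule = []
    violations = 0
    for rule in ruleset.rules:
        observed, ok = rule.check(block)
        per_rule.append((rule, observed, ok))
        if not ok:
            violations += 1
    return LikenessVerdict(
        ruleset_name=ruleset.name,
        per_rule=tuple(per_rule),
        violations=violations,
        passed=violations <= ruleset.max_violations,
    )


def appraise_set(cset: CompoundSet,
                 rulesets: Optional[list[RuleSet]] = None,
                 catalogue=None) -> CompoundSet:
    """The appraisal task: descriptors + likeness verdicts + interference
    screening for every record, in place, preserving order.  Idempotent.

    ``catalogue`` (a :class:`molscreen.pains.FilterCatalogue`) defaults to
    the packaged combined PAINS catalogue; pass ``False`` to skip screening.
    """
    from . import pains as _pains  # local import to keep module graph acyclic

    if rulesets is None:
        rulesets = list(builtin_rulesets().values())
    if catalogue is None:
        catalogue = _pains.default_catalogue()
    for rec in cset:
        compute_all(rec)
        rec.likeness = {rs.name: evaluate(rec.descriptors, rs) for rs in rulesets}
        if catalogue is not False:
            rec.pains_hits = _pains.match_compound(rec.mol, catalogue,
                                                   compound_id=rec.compound_id)
    return cset
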