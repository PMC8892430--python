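"""Declarative isotopologue-pattern rules and the two built-in rule sets.

A pattern is described relative to its principal isotopologue X (offset 0).
An offset ``nu`` denotes the isotopologue in which ``nu`` carbon atoms have
been exchanged between the light and the heavy isotope: positive offsets
(X+nu) describe incorporation of a heavy tracer into a light background
(standard tracer approach), negative offsets (X-nu) the incorporation of a
light tracer into a globally heavy-labelled background (reversed approach).

Rules are small immutable predicate objects evaluated in order against a map
``offset -> intensity`` (scan intensities and chromatographic peak areas are
treated identically). Users can register their own rule subtypes: anything
with ``referenced_offsets``/``required_offsets``/``forbidden_offsets``
attributes and an ``evaluate(intensities)`` method participates without any
change to the engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import yaml

__all__ = [
    "DELTA_MASS_C13",
    "expected_mz",
    "Rule",
    "PresenceRule",
    "AbsenceRule",
    "RatioRule",
    "AnyIntensityRule",
    "AllIntensityRule",
    "RuleSet",
    "Verdict",
    "evaluate_on_intensities",
    "standard_tracer_ruleset",
    "reversed_tracer_ruleset",
    "ruleset_from_dict",
    "ruleset_to_dict",
    "load_ruleset",
    "get_ruleset",
]

#: Exact mass difference between 13C and 12C in Daltons.
DELTA_MASS_C13 = 1.0033548378


def expected_mz(x_mz: float, nu: int, charge: int = 1, delta_mass: float = DELTA_MASS_C13) -> float:
    """m/z of the isotopologue ``nu`` carbon exchanges away from X.

    For a ``charge``-fold charged ion each exchange shifts m/z by
    ``delta_mass / charge``. ``delta_mass`` is configurable so the engine can
    serve non-carbon tracers, although the built-in rule sets are carbon-only.
    """
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return x_mz + nu * delta_mass / charge


def _fmt(nu: int) -> str:
    return "X" if nu == 0 else f"X{nu:+d}"


class Rule:
    """Base class for pattern rules. Subclasses implement :meth:`evaluate`."""

    #: offsets this rule needs intensity information for
    @property
    def referenced_offsets(self) -> frozenset[int]:
        return frozenset()

    #: offsets that must correspond to a real (coeluting) signal
    @property
    def required_offsets(self) -> frozenset[int]:
        return frozenset()

    #: offsets that must NOT correspond to a real signal
    @property
    def forbidden_offsets(self) -> frozenset[int]:
        return frozenset()

    #: lower intensity bound this rule implies for ``nu`` (pre-filter aid)
    def min_intensity_bound(self, nu: int) -> float:
        return 0.0

    def evaluate(self, intensities: Mapping[int, float | None]) -> str | None:
        """Return None on pass, or a human-readable violation description."""
        raise NotImplementedError


def _get(intensities: Mapping[int, float | None], nu: int) -> float | None:
    value = intensities.get(nu)
    return None if value is None else float(value)


@dataclass(frozen=True)
class PresenceRule(Rule):
    """Listed isotopologues must be present (optionally above ``min_intensity``
    and within relative-abundance windows against anchor isotopologues)."""

    offsets: tuple[int, ...]
    min_intensity: float | None = None
    #: offset -> (anchor offsets, low fraction, high fraction); each anchor
    #: is checked separately (conservative reading of "relative to A and B").
    relative_ranges: Mapping[int, tuple[tuple[int, ...], float, float]] | None = None
    verify_chrom_peak_similarity: bool = True

    def __post_init__(self):
        object.__setattr__(self, "offsets", tuple(self.offsets))
        if self.relative_ranges:
            for nu, (anchors, lo, hi) in self.relative_ranges.items():
                if not (0 < lo < hi):
                    raise ValueError(f"invalid relative range for {_fmt(nu)}: ({lo}, {hi})")

    @property
    def referenced_offsets(self) -> frozenset[int]:
        refs = set(self.offsets)
        if self.relative_ranges:
            for nu, (anchors, _, _) in self.relative_ranges.items():
                refs.add(nu)
                refs.update(anchors)
        return frozenset(refs)

    @property
    def required_offsets(self) -> frozenset[int]:
        return self.referenced_offsets

    def min_intensity_bound(self, nu: int) -> float:
        if self.min_intensity is not None and nu in self.offsets:
            return float(self.min_intensity)
        return 0.0

    def evaluate(self, intensities: Mapping[int, float | None]) -> str | None:
        for nu in self.offsets:
            value = _get(intensities, nu)
            if value is None or value <= 0:
                return f"missing isotopolog {_fmt(nu)}"
            if self.min_intensity is not None and value < self.min_intensity:
                return f"{_fmt(nu)} below minimum intensity ({value:.3g} < {self.min_intensity:.3g})"
        if self.relative_ranges:
            for nu, (anchors, lo, hi) in self.relative_ranges.items():
                value = _get(intensities, nu)
                if value is None or value <= 0:
                    return f"missing isotopolog {_fmt(nu)}"
                for anchor in anchors:
                    ref = _get(intensities, anchor)
                    if ref is None or ref <= 0:
                        return f"missing isotopolog {_fmt(anchor)}"
                    ratio = value / ref
                    if not (lo <= ratio <= hi):
                        return (
                            f"{_fmt(nu)}/{_fmt(anchor)} ratio {ratio:.3g} "
                            f"outside [{lo:g}, {hi:g}]"
                        )
        return None


@dataclass(frozen=True)
class AbsenceRule(Rule):
    """Listed isotopologues must be absent; signals up to
    ``max_fraction_of_X`` of X are tolerated as noise."""

    offsets: tuple[int, ...]
    max_fraction_of_X: float = 0.05

    def __post_init__(self):
        object.__setattr__(self, "offsets", tuple(self.offsets))
        if not (0 <= self.max_fraction_of_X < 1):
            raise ValueError("max_fraction_of_X must be in [0, 1)")

    @property
    def referenced_offsets(self) -> frozenset[int]:
        return frozenset(self.offsets) | {0}

    @property
    def forbidden_offsets(self) -> frozenset[int]:
        return frozenset(self.offsets)

    def evaluate(self, intensities: Mapping[int, float | None]) -> str | None:
        x = _get(intensities, 0)
        if x is None or x <= 0:
            return "missing isotopolog X"
        for nu in self.offsets:
            value = _get(intensities, nu) or 0.0  # no signal counts as absent
            if value > self.max_fraction_of_X * x:
                return (
                    f"forbidden isotopolog {_fmt(nu)} at "
                    f"{100 * value / x:.1f}% of X (> {100 * self.max_fraction_of_X:g}%)"
                )
        return None


@dataclass(frozen=True)
class RatioRule(Rule):
    """Intensity-ratio constraint between (groups of summed) isotopologues.

    ``range`` mode checks a single ratio against ``(low, high)`` bounds.
    ``equality`` mode checks that the ratios of two or more groups agree
    pairwise within ``rel_tolerance``: |r_i - r_j| / min(r_i, r_j) <= tol.
    """

    mode: str  # 'range' | 'equality'
    groups: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]
    range: tuple[float, float] | None = None
    rel_tolerance: float | None = None

    def __post_init__(self):
        groups = tuple((tuple(num), tuple(den)) for num, den in self.groups)
        object.__setattr__(self, "groups", groups)
        if self.mode == "range":
            if len(groups) != 1 or self.range is None:
                raise ValueError("range mode needs exactly one group and bounds")
            if not (0 < self.range[0] < self.range[1]):
                raise ValueError("range bounds must satisfy 0 < low < high")
        elif self.mode == "equality":
            if len(groups) < 2 or self.rel_tolerance is None:
                raise ValueError("equality mode needs >= 2 groups and a tolerance")
        else:
            raise ValueError(f"unknown RatioRule mode {self.mode!r}")

    @property
    def referenced_offsets(self) -> frozenset[int]:
        refs: set[int] = set()
        for num, den in self.groups:
            refs.update(num)
            refs.update(den)
        return frozenset(refs)

    @property
    def required_offsets(self) -> frozenset[int]:
        return self.referenced_offsets

    def _group_ratio(self, intensities, num, den) -> tuple[float | None, str | None]:
        total_num = total_den = 0.0
        for nu in num:
            value = _get(intensities, nu)
            if value is None:
                return None, f"missing isotopolog {_fmt(nu)}"
            total_num += value
        for nu in den:
            value = _get(intensities, nu)
            if value is None:
                return None, f"missing isotopolog {_fmt(nu)}"
            total_den += value
        if total_den <= 0:
            label = "+".join(_fmt(nu) for nu in den)
            return None, f"zero denominator ({label})"
        return total_num / total_den, None

    def evaluate(self, intensities: Mapping[int, float | None]) -> str | None:
        ratios = []
        for num, den in self.groups:
            ratio, err = self._group_ratio(intensities, num, den)
            if err is not None:
                return err
            ratios.append(ratio)
        if self.mode == "range":
            lo, hi = self.range
            if not (lo <= ratios[0] <= hi):
                num, den = self.groups[0]
                label = "+".join(map(_fmt, num)) + " / " + "+".join(map(_fmt, den))
                return f"ratio {label} = {ratios[0]:.3g} outside [{lo:g}, {hi:g}]"
            return None
        for i in range(len(ratios)):
            for j in range(i + 1, len(ratios)):
                ri, rj = ratios[i], ratios[j]
                if min(ri, rj) <= 0 or abs(ri - rj) / min(ri, rj) > self.rel_tolerance:
                    return (
                        f"ratio constancy violated: group {i} = {ri:.3g} vs "
                        f"group {j} = {rj:.3g} (tol {100 * self.rel_tolerance:g}%)"
                    )
        return None


@dataclass(frozen=True)
class AnyIntensityRule(Rule):
    """At least one listed isotopologue must exceed ``threshold``."""

    offsets: tuple[int, ...]
    threshold: float

    def __post_init__(self):
        object.__setattr__(self, "offsets", tuple(self.offsets))
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")

    @property
    def referenced_offsets(self) -> frozenset[int]:
        return frozenset(self.offsets)

    def evaluate(self, intensities: Mapping[int, float | None]) -> str | None:
        for nu in self.offsets:
            value = _get(intensities, nu)
            if value is not None and value >= self.threshold:
                return None
        label = ", ".join(map(_fmt, self.offsets))
        return f"none of {label} reaches {self.threshold:.3g}"


@dataclass(frozen=True)
class AllIntensityRule(Rule):
    """Every listed isotopologue must exceed ``threshold``."""

    offsets: tuple[int, ...]
    threshold: float

    def __post_init__(self):
        object.__setattr__(self, "offsets", tuple(self.offsets))
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")

    @property
    def referenced_offsets(self) -> frozenset[int]:
        return frozenset(self.offsets)

    @property
    def required_offsets(self) -> frozenset[int]:
        return frozenset(self.offsets)

    def min_intensity_bound(self, nu: int) -> float:
        return float(self.threshold) if nu in self.offsets else 0.0

    def evaluate(self, intensities: Mapping[int, float | None]) -> str | None:
        for nu in self.offsets:
            value = _get(intensities, nu)
            if value is None or value < self.threshold:
                return f"{_fmt(nu)} below {self.threshold:.3g}"
        return None


class Verdict(NamedTuple):
    passed: bool
    rule: Rule | None = None
    reason: str | None = None


@dataclass(frozen=True)
class RuleSet:
    """An ordered collection of rules describing one target pattern."""

    rules: tuple[Rule, ...]
    charge: int = 1
    description: str = ""

    def __post_init__(self):
        object.__setattr__(self, "rules", tuple(self.rules))
        if self.charge < 1:
            raise ValueError("charge must be >= 1")

    @property
    def referenced_offsets(self) -> frozenset[int]:
        refs: set[int] = {0}
        for rule in self.rules:
            refs.update(rule.referenced_offsets)
        return frozenset(refs)

    @property
    def required_offsets(self) -> frozenset[int]:
        req: set[int] = {0}
        for rule in self.rules:
            req.update(rule.required_offsets)
        return frozenset(req)

    @property
    def forbidden_offsets(self) -> frozenset[int]:
        forb: set[int] = set()
        for rule in self.rules:
            forb.update(rule.forbidden_offsets)
        return frozenset(forb)

    @property
    def coelution_offsets(self) -> frozenset[int]:
        """Offsets whose chromatographic peaks must coelute with X."""
        offs: set[int] = {0}
        for rule in self.rules:
            if getattr(rule, "verify_chrom_peak_similarity", False):
                offs.update(rule.required_offsets)
        return frozenset(offs)

    @property
    def min_x_intensity(self) -> float:
        """Hard lower bound on the X intensity implied by the rules (0 if none)."""
        return max((rule.min_intensity_bound(0) for rule in self.rules), default=0.0)

    def evaluate(self, intensities: Mapping[int, float | None]) -> Verdict:
        if _get(intensities, 0) is None:
            return Verdict(False, None, "missing isotopolog X")
        for rule in self.rules:
            reason = rule.evaluate(intensities)
            if reason is not None:
                return Verdict(False, rule, reason)
        return Verdict(True)


def evaluate_on_intensities(ruleset: RuleSet, intensities: Mapping[int, float | None]) -> Verdict:
    """Evaluate a rule set on an ``offset -> intensity`` map.

    The function is pure and works identically on scan intensities and on
    chromatographic peak areas. Rules are checked in order and the first
    violation is reported.
    """
    return ruleset.evaluate(intensities)


# ---------------------------------------------------------------------------
# Built-in rule sets
# ---------------------------------------------------------------------------

def standard_tracer_ruleset(
    x_min_intensity: float = 1e5,
    satellite_min_intensity: float = 5e4,
    absence_max_fraction: float = 0.05,
    even_range: tuple[float, float] = (0.10, 3.00),
    odd_range: tuple[float, float] = (0.10, 2.00),
    equality_tolerance: float = 0.10,
    charge: int = 1,
) -> RuleSet:
    """Rule set for a heavy (13C2) tracer incorporated into a light background.

    Required isotopologues are X, X+1 ... X+4 (one and two tracer-derived C2
    extension units plus the partially labelled satellites in between);
    X-1/X-2 must be absent because X is already monoisotopic. The even
    isotopologues must fall within ``even_range`` of their lighter even
    neighbour, the odd ones within ``odd_range`` of each of their two even
    neighbours, and the odd/even summed ratios (X + X+2)/X+1 and
    (X+2 + X+4)/X+3 must agree within ``equality_tolerance`` — the constancy
    that natural 13C abundance plus constant tracer impurity imposes.
    """
    rules: tuple[Rule, ...] = (
        # intensity stage
        PresenceRule(offsets=(0,), min_intensity=x_min_intensity),
        PresenceRule(offsets=(2, 4), min_intensity=satellite_min_intensity),
        PresenceRule(offsets=(1, 3)),
        # absence stage
        AbsenceRule(offsets=(-1, -2), max_fraction_of_X=absence_max_fraction),
        # ratio stage
        RatioRule(mode="range", groups=(((2,), (0,)),), range=even_range),
        RatioRule(mode="range", groups=(((4,), (2,)),), range=even_range),
        RatioRule(mode="range", groups=(((1,), (0,)),), range=odd_range),
        RatioRule(mode="range", groups=(((1,), (2,)),), range=odd_range),
        RatioRule(mode="range", groups=(((3,), (2,)),), range=odd_range),
        RatioRule(mode="range", groups=(((3,), (4,)),), range=odd_range),
        RatioRule(
            mode="equality",
            groups=(((0, 2), (1,)), ((2, 4), (3,))),
            rel_tolerance=equality_tolerance,
        ),
    )
    return RuleSet(rules=rules, charge=charge, description="standard tracer (heavy C2 units)")


def reversed_tracer_ruleset(
    x_min_intensity: float = 1e5,
    satellite_min_intensity: float = 5e4,
    absence_max_fraction: float = 0.05,
    even_range: tuple[float, float] = (0.10, 3.00),
    odd_range: tuple[float, float] = (0.10, 2.00),
    equality_tolerance: float = 0.10,
    charge: int = 1,
) -> RuleSet:
    """Rule set for a light (12C2) tracer in a globally 13C-labelled organism.

    The mirror image of the standard set, extended to three extension units:
    X, X-1 ... X-6 required, X+1/X+2 forbidden, with a three-way odd/even
    ratio-constancy check.
    """
    rules: tuple[Rule, ...] = (
        # intensity stage
        PresenceRule(offsets=(0,), min_intensity=x_min_intensity),
        PresenceRule(offsets=(-2, -4, -6), min_intensity=satellite_min_intensity),
        PresenceRule(offsets=(-1, -3, -5)),
        # absence stage
        AbsenceRule(offsets=(1, 2), max_fraction_of_X=absence_max_fraction),
        # ratio stage
        RatioRule(mode="range", groups=(((-2,), (0,)),), range=even_range),
        RatioRule(mode="range", groups=(((-4,), (-2,)),), range=even_range),
        RatioRule(mode="range", groups=(((-6,), (-4,)),), range=even_range),
        RatioRule(mode="range", groups=(((-1,), (0,)),), range=odd_range),
        RatioRule(mode="range", groups=(((-1,), (-2,)),), range=odd_range),
        RatioRule(mode="range", groups=(((-3,), (-2,)),), range=odd_range),
        RatioRule(mode="range", groups=(((-3,), (-4,)),), range=odd_range),
        RatioRule(mode="range", groups=(((-5,), (-4,)),), range=odd_range),
        RatioRule(mode="range", groups=(((-5,), (-6,)),), range=odd_range),
        RatioRule(
            mode="equality",
            groups=(((0, -2), (-1,)), ((-2, -4), (-3,)), ((-4, -6), (-5,))),
            rel_tolerance=equality_tolerance,
        ),
    )
    return RuleSet(rules=rules, charge=charge, description="reversed tracer (light C2 units)")


# ---------------------------------------------------------------------------
# Config (YAML/JSON) serialization
# ---------------------------------------------------------------------------

_RULE_TYPES = {
    "presence": PresenceRule,
    "absence": AbsenceRule,
    "ratio_range": RatioRule,
    "ratio_equality": RatioRule,
    "any_intensity": AnyIntensityRule,
    "all_intensity": AllIntensityRule,
}


def _rule_from_dict(entry: Mapping) -> Rule:
    kind = entry.get("type")
    if kind not in _RULE_TYPES:
        raise ValueError(f"unknown rule type {kind!r}; expected one of {sorted(_RULE_TYPES)}")
    if kind == "presence":
        ranges = None
        if entry.get("relative_ranges"):
            ranges = {
                int(nu): (tuple(spec["anchors"]), float(spec["low"]), float(spec["high"]))
                for nu, spec in entry["relative_ranges"].items()
            }
        return PresenceRule(
            offsets=tuple(entry["offsets"]),
            min_intensity=entry.get("min_intensity"),
            relative_ranges=ranges,
            verify_chrom_peak_similarity=entry.get("verify_chrom_peak_similarity", True),
        )
    if kind == "absence":
        return AbsenceRule(
            offsets=tuple(entry["offsets"]),
            max_fraction_of_X=float(entry.get("max_fraction_of_x", 0.05)),
        )
    if kind == "ratio_range":
        return RatioRule(
            mode="range",
            groups=((tuple(entry["numerator"]), tuple(entry["denominator"])),),
            range=(float(entry["low"]), float(entry["high"])),
        )
    if kind == "ratio_equality":
        groups = tuple(
            (tuple(g["numerator"]), tuple(g["denominator"])) for g in entry["groups"]
        )
        return RatioRule(mode="equality", groups=groups, rel_tolerance=float(entry["rel_tolerance"]))
    cls = _RULE_TYPES[kind]
    return cls(offsets=tuple(entry["offsets"]), threshold=float(entry["threshold"]))


def _rule_to_dict(rule: Rule) -> dict:
    if isinstance(rule, PresenceRule):
        out: dict = {"type": "presence", "offsets": list(rule.offsets)}
        if rule.min_intensity is not None:
            out["min_intensity"] = rule.min_intensity
        if rule.relative_ranges:
            out["relative_ranges"] = {
                int(nu): {"anchors": list(anchors), "low": lo, "high": hi}
                for nu, (anchors, lo, hi) in rule.relative_ranges.items()
            }
        out["verify_chrom_peak_similarity"] = rule.verify_chrom_peak_similarity
        return out
    if isinstance(rule, AbsenceRule):
        return {
            "type": "absence",
            "offsets": list(rule.offsets),
            "max_fraction_of_x": rule.max_fraction_of_X,
        }
    if isinstance(rule, RatioRule):
        if rule.mode == "range":
            (num, den), = rule.groups
            return {
                "type": "ratio_range",
                "numerator": list(num),
                "denominator": list(den),
                "low": rule.range[0],
                "high": rule.range[1],
            }
        return {
            "type": "ratio_equality",
            "groups": [
                {"numerator": list(num), "denominator": list(den)} for num, den in rule.groups
            ],
            "rel_tolerance": rule.rel_tolerance,
        }
    if isinstance(rule, AnyIntensityRule):
        return {"type": "any_intensity", "offsets": list(rule.offsets), "threshold": rule.threshold}
    if isinstance(rule, AllIntensityRule):
        return {"type": "all_intensity", "offsets": list(rule.offsets), "threshold": rule.threshold}
    raise TypeError(f"cannot serialize rule of type {type(rule).__name__}")


def ruleset_from_dict(data: Mapping) -> RuleSet:
    return RuleSet(
        rules=tuple(_rule_from_dict(entry) for entry in data.get("rules", [])),
        charge=int(data.get("charge", 1)),
        description=data.get("description", ""),
    )


def ruleset_to_dict(ruleset: RuleSet) -> dict:
    return {
        "charge": ruleset.charge,
        "description": ruleset.description,
        "rules": [_rule_to_dict(rule) for rule in ruleset.rules],
    }


def load_ruleset(path: str) -> RuleSet:
    """Load a rule-set config file (YAML; JSON is valid YAML)."""
    with open(path, "r", encoding="utf-8") as handle:
        data = yaml.safe_load(handle)
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: rule config must be a mapping")
    return ruleset_from_dict(data)


def get_ruleset(name_or_path: str) -> RuleSet:
    """Resolve a built-in rule-set name ('standard' / 'reversed') or a config path."""
    if name_or_path == "standard":
        return standard_tracer_ruleset()
    if name_or_path == "reversed":
        return reversed_tracer_ruleset()
    return load_ruleset(name_or_path)
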