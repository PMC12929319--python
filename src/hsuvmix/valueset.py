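"""EQ-5D-3L profile scoring with user-supplied additive value sets.

An EQ-5D-3L profile is a 5-tuple of ordinal levels in {1, 2, 3} for the
dimensions mobility, self-care, usual activities, pain/discomfort and
anxiety/depression; (1, 1, 1, 1, 1) denotes full health.  A value set
(tariff) maps profiles to utilities additively:

    u = full_health - sum(per-dimension decrements) - sum(extra terms)

where extra terms are (indicator rule, constant) pairs such as an
"any problem" constant (applied once if any dimension is above level 1)
or an "any level 3" constant.  This covers the shape of the French and
UK 3L tariffs; the actual country coefficients are supplied by the user
in a small YAML file (see :func:`load_value_set`).

Value-set file schema (YAML)::

    full_health: 1.0
    decrements:            # positive numbers, subtracted from full_health
      mobility:        {2: 0.0897, 3: 0.5741}
      self_care:       {2: 0.1281, 3: 0.1722}
      usual_activities: {2: 0.0366, 3: 0.0776}
      pain_discomfort: {2: 0.0620, 3: 0.3939}
      anxiety_depression: {2: 0.0524, 3: 0.2699}
    constants:             # optional, each subtracted when its rule fires
      any_problem: 0.0809  # any dimension > 1
      any_level3:  0.0    # any dimension == 3
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

from .errors import InvalidProfileError, ValueSetParseError

__all__ = [
    "DIMENSIONS",
    "Eq5dProfile",
    "ValueSet",
    "score_profile",
    "enumerate_grid",
    "load_value_set",
]

DIMENSIONS = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)


@dataclass(frozen=True)
class Eq5dProfile:
    """One EQ-5D-3L descriptive profile (five ordinal levels in {1,2,3})."""

    mobility: int
    self_care: int
    usual_activities: int
    pain_discomfort: int
    anxiety_depression: int

    def __post_init__(self) -> None:
        for dim in DIMENSIONS:
            level = getattr(self, dim)
            if level not in (1, 2, 3):
                raise InvalidProfileError(
                    f"level for {dim} must be in {{1, 2, 3}}, got {level!r}"
                )

    @classmethod
    def from_string(cls, digits: str) -> "Eq5dProfile":
        """Parse a 5-digit profile string such as ``"21131"``."""
        digits = str(digits).strip()
        if len(digits) != 5 or not digits.isdigit():
            raise InvalidProfileError(f"expected 5 digits, got {digits!r}")
        return cls(*(int(d) for d in digits))

    @property
    def levels(self) -> tuple[int, ...]:
        return tuple(getattr(self, dim) for dim in DIMENSIONS)

    def __str__(self) -> str:
        return "".join(str(level) for level in self.levels)


@dataclass(frozen=True)
class ValueSet:
    """Additive EQ-5D-3L tariff.

    ``decrements[dim][level]`` is the positive utility loss for reporting
    ``level`` (2 or 3) on ``dim``; ``constants`` holds the optional
    ``any_problem`` and ``any_level3`` terms.
    """

    full_health: float = 1.0
    decrements: Mapping[str, Mapping[int, float]] = field(default_factory=dict)
    constants: Mapping[str, float] = field(default_factory=dict)

    _KNOWN_CONSTANTS = ("any_problem", "any_level3")

    def __post_init__(self) -> None:
        for dim in self.decrements:
            if dim not in DIMENSIONS:
                raise ValueSetParseError(f"unknown dimension {dim!r}")
            for level in self.decrements[dim]:
                if level not in (2, 3):
                    raise ValueSetParseError(
                        f"decrement levels must be 2 or 3, got {level!r} for {dim}"
                    )
        for name in self.constants:
            if name not in self._KNOWN_CONSTANTS:
                raise ValueSetParseError(f"unknown constant term {name!r}")

    def decrement(self, dim: str, level: int) -> float:
        return float(self.decrements.get(dim, {}).get(level, 0.0))

    @property
    def min_attainable(self) -> float:
        return float(min(enumerate_grid(self)))

    @property
    def max_attainable(self) -> float:
        return float(max(enumerate_grid(self)))


def score_profile(profile: Eq5dProfile | str, vs: ValueSet) -> float:
    """Score one profile under an additive value set.

    Returns ``full_health`` minus the applicable per-dimension decrements
    and extra constants; full health (1,1,1,1,1) scores ``full_health``
    exactly.
    """
    if not isinstance(profile, Eq5dProfile):
        profile = Eq5dProfile.from_string(profile)
    u = vs.full_health
    for dim, level in zip(DIMENSIONS, profile.levels):
        if level > 1:
            u -= vs.decrement(dim, level)
    if any(level > 1 for level in profile.levels):
        u -= float(vs.constants.get("any_problem", 0.0))
    if any(level == 3 for level in profile.levels):
        u -= float(vs.constants.get("any_level3", 0.0))
    return float(u)


def enumerate_grid(vs: ValueSet) -> list[float]:
    """All attainable utilities of a value set, deduplicated and ascending.

    Enumerates the 3^5 = 243 profiles; the result has at most 243 values,
    its first element is the minimum attainable utility and its last the
    ``full_health`` value.
    """
    values = set()
    for mob in (1, 2, 3):
        for sc in (1, 2, 3):
            for ua in (1, 2, 3):
                for pd_ in (1, 2, 3):
                    for ad in (1, 2, 3):
                        values.add(
                            round(score_profile(Eq5dProfile(mob, sc, ua, pd_, ad), vs), 12)
                        )
    return sorted(values)


def _as_level_map(obj, dim: str) -> dict[int, float]:
    if not isinstance(obj, Mapping):
        raise ValueSetParseError(f"decrements for {dim!r} must be a mapping of level: value")
    out = {}
    for level, value in obj.items():
        try:
            out[int(level)] = float(value)
        except (TypeError, ValueError) as exc:
            raise ValueSetParseError(f"bad decrement entry {level!r}: {value!r} for {dim}") from exc
    return out


def load_value_set(path: str | Path) -> ValueSet:
    """Load a value set from the YAML schema documented in this module."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ValueSetParseError(f"cannot parse value-set file {path}: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise ValueSetParseError(f"value-set file {path} must be a mapping")
    try:
        full_health = float(raw.get("full_health", 1.0))
    except (TypeError, ValueError) as exc:
        raise ValueSetParseError(f"bad full_health in {path}") from exc
    decrements = {
        dim: _as_level_map(spec, dim)
        for dim, spec in (raw.get("decrements") or {}).items()
    }
    constants = {}
    for name, value in (raw.get("constants") or {}).items():
        try:
            constants[name] = float(value)
        except (TypeError, ValueError) as exc:
            raise ValueSetParseError(f"bad constant {name!r} in {path}") from exc
    return ValueSet(full_health=full_health, decrements=decrements, constants=constants)


def score_profiles(profiles: Iterable[Eq5dProfile | str], vs: ValueSet) -> np.ndarray:
    """Vectorised convenience wrapper around :func:`score_profile`."""
    return np.array([score_profile(p, vs) for p in profiles], dtype=float)
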