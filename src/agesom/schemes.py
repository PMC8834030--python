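"""Ordered age-group schemes for lifespan cohorts.

Samples are binned into ordered, disjoint, closed-open age intervals.
Two canonical schemes are provided: a six-group postnatal scheme used for
expression cohorts (newborn ... late_adult) and a seven-group scheme for
methylation cohorts that prepends a prenatal ("fetal") group coded with
negative ages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

__all__ = [
    "AgeGroupScheme",
    "EXPRESSION_SCHEME",
    "METHYLATION_SCHEME",
    "assign_age_group",
]

_MONTH = 1.0 / 12.0


@dataclass(frozen=True)
class AgeGroupScheme:
    """Ordered partition of the age axis into labeled groups.

    Parameters
    ----------
    labels:
        Group names ordered from youngest to oldest.
    ranges:
        Per-label closed-open age interval ``[lo, hi)`` in years. A prenatal
        group uses negative ages (``lo`` may be ``-inf``); the last group may
        be open-ended (``hi = inf``).
    """

    labels: Tuple[str, ...]
    ranges: Dict[str, Tuple[float, float]] = field(hash=False)

    def __post_init__(self) -> None:
        if tuple(self.ranges) != self.labels:
            object.__setattr__(
                self, "ranges", {lab: self.ranges[lab] for lab in self.labels}
            )
        prev_hi = -np.inf
        for lab in self.labels:
            lo, hi = self.ranges[lab]
            if not lo < hi:
                raise ValueError(f"empty age range for group {lab!r}: [{lo}, {hi})")
            if lo < prev_hi:
                raise ValueError(f"age ranges overlap at group {lab!r}")
            prev_hi = hi

    @property
    def n_groups(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def midpoints(self) -> np.ndarray:
        """Representative age per group (midpoint; open-ended bounds clipped)."""
        mids = []
        for lab in self.labels:
            lo, hi = self.ranges[lab]
            lo = max(lo, -0.75)
            hi = min(hi, 90.0)
            mids.append(0.5 * (lo + hi))
        return np.asarray(mids)

    def assign(self, age_years: float) -> str:
        return assign_age_group(age_years, self)

    def assign_many(self, ages: Sequence[float]) -> List[str]:
        return [assign_age_group(a, self) for a in ages]


def assign_age_group(age_years: float, scheme: AgeGroupScheme) -> str:
    """Map an age in years to its group label.

    Negative ages are prenatal and are only accepted when the scheme has a
    group whose range extends below zero.
    """
    if not np.isfinite(age_years):
        raise ValueError(f"age must be finite, got {age_years!r}")
    for lab in scheme.labels:
        lo, hi = scheme.ranges[lab]
        if lo <= age_years < hi:
            return lab
    raise ValueError(f"age {age_years!r} years falls outside all groups of the scheme")


_POSTNATAL = {
    "newborn": (0.0, 5 * _MONTH),
    "baby": (5 * _MONTH, 13 * _MONTH),
    "infant": (13 * _MONTH, 10.0),
    "teenager": (10.0, 20.0),
    "adult": (20.0, 60.0),
    "late_adult": (60.0, np.inf),
}

#: Six postnatal groups (newborn 0-4 months ... late adult >60 years).
EXPRESSION_SCHEME = AgeGroupScheme(labels=tuple(_POSTNATAL), ranges=dict(_POSTNATAL))

#: Same postnatal groups preceded by a prenatal "fetal" group (negative ages).
METHYLATION_SCHEME = AgeGroupScheme(
    labels=("fetal",) + tuple(_POSTNATAL),
    ranges={"fetal": (-np.inf, 0.0), **_POSTNATAL},
)
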