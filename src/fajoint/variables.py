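"""Fatty-acid exposure variables: names, model units, and sum-variable
composition.

Intakes are stored in g/day; each variable is analysed on its own model unit
(1 g, 100 mg or 10 mg per day, or the same numerator per MJ once
energy-adjusted), so a hazard ratio is always "per one model unit".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["Unit", "FattyAcidVariable", "VARIABLES", "LC_N3_COMPONENTS",
           "compose_sum_variable", "rescale_intake"]

#: long-chain n-3 PUFA constituents (g/day columns), 20:3n-3 ... 22:6n-3
LC_N3_COMPONENTS = (
    "fa_20_3_n3", "fa_20_4_n3", "fa_20_5_n3", "fa_21_5_n3",
    "fa_22_4_n3", "fa_22_5_n3", "fa_22_6_n3",
)

_UNIT_SCALE = {"g_per_day": 1.0, "mg100_per_day": 0.1, "mg10_per_day": 0.01}


@dataclass(frozen=True)
class Unit:
    name: str

    def __post_init__(self):
        if self.name not in _UNIT_SCALE:
            raise ValueError(f"unknown unit {self.name!r}")

    @property
    def grams(self) -> float:
        """Grams per model unit (1, 0.1 or 0.01)."""
        return _UNIT_SCALE[self.name]


@dataclass(frozen=True)
class FattyAcidVariable:
    """One analysed exposure: a single fatty acid or a sum variable."""

    name: str
    unit: Unit
    components: tuple[str, ...] = field(default_factory=tuple)

    @property
    def is_sum(self) -> bool:
        return len(self.components) > 0


def _v(name, unit, components=()):
    return FattyAcidVariable(name, Unit(unit), tuple(components))


#: the 12 analysed fat variables with their presentation units
VARIABLES: dict[str, FattyAcidVariable] = {v.name: v for v in [
    _v("total_fat", "g_per_day"),
    _v("sfa", "g_per_day"),
    _v("myristic_acid", "mg100_per_day"),
    _v("palmitic_acid", "mg100_per_day"),
    _v("mufa", "g_per_day"),
    _v("n6_pufa", "mg100_per_day"),
    _v("linoleic_acid", "mg100_per_day"),
    _v("arachidonic_acid", "mg10_per_day"),
    _v("cla", "mg10_per_day"),
    _v("n3_pufa", "mg100_per_day"),
    _v("alpha_linolenic_acid", "mg100_per_day"),
    _v("lc_n3_pufa", "mg100_per_day", LC_N3_COMPONENTS),
]}


def compose_sum_variable(intakes: Mapping[str, float] | pd.DataFrame,
                         variable: FattyAcidVariable):
    """Sum the component intakes (g/day) of a sum variable.

    Accepts a single record (mapping) or a record table (DataFrame with one
    column per fatty acid); missing components contribute 0 with a warning.
    """
    if not variable.is_sum:
        raise ValueError(f"{variable.name} is not a sum variable")
    if isinstance(intakes, pd.DataFrame):
        present = [c for c in variable.components if c in intakes.columns]
        missing = set(variable.components) - set(present)
        if missing:
            warnings.warn(f"missing components treated as 0: {sorted(missing)}")
        if not present:
            return pd.Series(0.0, index=intakes.index)
        return intakes[present].fillna(0.0).sum(axis=1)
    missing = [c for c in variable.components if c not in intakes]
    if missing:
        warnings.warn(f"missing components treated as 0: {sorted(missing)}")
    return float(sum(intakes.get(c, 0.0) for c in variable.components))


def rescale_intake(intake, unit: Unit):
    """Convert a g/day intake to model units/day (divide by grams-per-unit)."""
    arr = np.asarray(intake, dtype=float)
    if np.any(arr < 0):
        raise ValueError("intake must be nonnegative")
    out = arr / unit.grams
    return float(out) if np.ndim(intake) == 0 else out
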