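"""Dietary computations upstream of modelling.

Covers energy imputation for breastfed infants (total energy requirement from
age and body weight, breastmilk energy as the shortfall between requirement
and recorded food energy), breastmilk quantity, nutrient-density energy
adjustment (units/MJ), the mean early-intake covariate, and the
reverse-causality sensitivity exclusion of food records collected within a
window before a T1D diagnosis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "EnergyRequirement",
    "impute_breastfed_energy",
    "breastmilk_amount",
    "energy_adjust",
    "mean_early_intake",
    "exclude_prediagnosis_records",
    "BREASTMILK_ENERGY_DENSITY_KJ_PER_G",
    "DEFAULT_BREASTMILK_COMPOSITION",
]

#: energy density of mature human milk, kJ per gram (config-overridable)
BREASTMILK_ENERGY_DENSITY_KJ_PER_G = 2.8

#: fatty acids in mature human milk, g per 100 g of milk (config-overridable)
DEFAULT_BREASTMILK_COMPOSITION = {
    "total_fat": 4.2, "sfa": 1.9, "myristic_acid": 0.27, "palmitic_acid": 0.95,
    "mufa": 1.6, "n6_pufa": 0.48, "linoleic_acid": 0.44,
    "arachidonic_acid": 0.017, "cla": 0.012, "n3_pufa": 0.072,
    "alpha_linolenic_acid": 0.045, "fa_22_6_n3": 0.012, "fa_20_5_n3": 0.004,
}


def _load_table(name: str) -> pd.DataFrame:
    with resources.files("fajoint.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, comment="#")


@dataclass
class EnergyRequirement:
    """Required total energy (MJ/day) as a function of age band and weight.

    The table carries a per-kg requirement by age band (months); the
    requirement is per-kg value x weight, hence monotone in weight within a
    band.  Default median weight-for-age is used when no weight is given.
    """

    table: pd.DataFrame
    default_weights: pd.DataFrame

    @classmethod
    def default(cls) -> "EnergyRequirement":
        return cls(table=_load_table("energy_requirements.csv"),
                   default_weights=_load_table("weight_for_age.csv"))

    def _band(self, age_years: float) -> float:
        months = age_years * 12.0
        tab = self.table.sort_values("age_months")
        idx = np.searchsorted(tab["age_months"].to_numpy(), months - 1e-9)
        if idx >= len(tab):
            raise ValueError(f"no energy-requirement band for age {age_years} y")
        return float(tab["kj_per_kg_day"].iloc[idx])

    def default_weight(self, age_years: float) -> float:
        months = age_years * 12.0
        tab = self.default_weights.sort_values("age_months")
        idx = np.searchsorted(tab["age_months"].to_numpy(), months - 1e-9)
        if idx >= len(tab):
            raise ValueError(f"no default weight for age {age_years} y")
        return float(tab["median_weight_kg"].iloc[idx])

    def requirement(self, age_years: float, weight_kg: float) -> float:
        """Required energy in MJ/day."""
        if weight_kg is None or not np.isfinite(weight_kg):
            raise ValueError(
                "missing body weight: pass a measured weight or use "
                "EnergyRequirement.default_weight(age) from the config table")
        if weight_kg <= 0:
            raise ValueError("weight must be positive")
        return self._band(age_years) * weight_kg / 1000.0


def impute_breastfed_energy(recorded_energy_mj: float, age_years: float,
                            breastfed: bool, req: EnergyRequirement,
                            weight_kg: float | None = None):
    """Total and breastmilk energy (MJ/day) for one record.

    For a breastfed infant the total energy intake is set to the estimated
    requirement for the child's age and weight, and the breastmilk
    contribution is the (floored) difference between requirement and the
    energy recorded from foods.  Non-breastfed children pass through.
    """
    if not breastfed:
        return float(recorded_energy_mj), 0.0
    if weight_kg is None:
        weight_kg = req.default_weight(age_years)
    total = req.requirement(age_years, weight_kg)
    bm = total - recorded_energy_mj
    if bm < 0:
        log.warning("recorded energy %.2f MJ exceeds requirement %.2f MJ at "
                    "age %.2f y; breastmilk energy floored at 0",
                    recorded_energy_mj, total, age_years)
        bm = 0.0
    return float(total), float(bm)


def breastmilk_amount(breastmilk_energy_mj: float,
                      energy_density_kj_per_g: float = BREASTMILK_ENERGY_DENSITY_KJ_PER_G
                      ) -> float:
    """Breastmilk quantity (g/day) from its energy share."""
    if energy_density_kj_per_g <= 0:
        raise ValueError("energy density must be positive")
    if breastmilk_energy_mj < 0:
        raise ValueError("breastmilk energy must be nonnegative")
    return 1000.0 * breastmilk_energy_mj / energy_density_kj_per_g


def add_breastmilk_nutrients(intakes: dict[str, float], amount_g: float,
                             composition: dict[str, float] | None = None
                             ) -> dict[str, float]:
    """Add per-100 g breastmilk fatty acids x amount to food-based intakes."""
    comp = DEFAULT_BREASTMILK_COMPOSITION if composition is None else composition
    out = dict(intakes)
    for name, per100 in comp.items():
        out[name] = out.get(name, 0.0) + per100 * amount_g / 100.0
    return out


def energy_adjust(intake, energy_mj):
    """Nutrient density: model units/day divided by total energy (MJ/day)."""
    energy = np.asarray(energy_mj, dtype=float)
    if np.any(energy <= 0):
        raise ValueError("energy must be positive for density adjustment")
    out = np.asarray(intake, dtype=float) / energy
    return float(out) if np.ndim(intake) == 0 and np.ndim(energy_mj) == 0 else out


def mean_early_intake(records: pd.DataFrame, column: str,
                      energy_adjusted: bool = True,
                      early_ages=(0.25, 0.5)) -> float:
    """Mean (energy-adjusted) intake over the 3- and 6-month records of one
    child; NaN sentinel when neither record exists (child excluded upstream)."""
    sel = records[np.isin(records["age"].to_numpy(), early_ages)]
    if sel.empty:
        return float("nan")
    vals = sel[column].to_numpy(dtype=float)
    if energy_adjusted:
        vals = energy_adjust(vals, sel["energy_mj"].to_numpy(dtype=float))
    return float(np.mean(vals))


def exclude_prediagnosis_records(records: pd.DataFrame, children: pd.DataFrame,
                                 window: float = 1.5):
    """Sensitivity exclusion: drop food records within ``window`` years before
    a T1D diagnosis (records with age > t1d_age - window for diagnosed
    children).  Returns ``(filtered records, n dropped)``.
    """
    if window < 0:
        raise ValueError("window must be nonnegative")
    diag = children.loc[children["t1d_status"] == 1, ["child_id", "t1d_age"]]
    merged = records.merge(diag, on="child_id", how="left")
    drop = merged["t1d_age"].notna() & (
        merged["age"].to_numpy() > merged["t1d_age"].to_numpy() - window)
    n_dropped = int(drop.sum())
    if n_dropped:
        log.info("sensitivity exclusion dropped %d records within %.2f y of a "
                 "T1D diagnosis", n_dropped, window)
    return records.loc[~drop.to_numpy()].reset_index(drop=True), n_dropped
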