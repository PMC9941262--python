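"""Progression-to-T1D analysis among seroconverted children.

Follow-up runs from first seroconversion until T1D or age 6 (the
since-seroconversion time scale); the baseline change points 1.99/3.99 apply
on that scale, and models are additionally adjusted for age at
seroconversion.  Because nobody has an intake measurement exactly at
seroconversion, a pseudo-record at time zero is created by linear
interpolation between the nearest record before and the nearest record after
seroconversion (each nutrient and energy independently); children without a
pre-seroconversion record get no pseudo-record (no extrapolation), and
children without any record at or after seroconversion are excluded.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .joint import JointConfig, PosteriorSummary, fit_joint

log = logging.getLogger(__name__)

__all__ = ["interpolate_at_seroconversion", "build_progression_dataset",
           "fit_progression"]

_META_COLS = ("child_id", "age", "n_days")


def interpolate_at_seroconversion(child_records: pd.DataFrame,
                                  sc_age: float) -> pd.Series | None:
    """Pseudo-record at seroconversion for one child, or None.

    Requires at least one record at/after ``sc_age``; interpolates linearly
    between the nearest bracketing records.  If seroconversion coincides with
    a record age, that record's values are returned exactly; without a record
    strictly before seroconversion nothing is returned.
    """
    recs = child_records.sort_values("age")
    ages = recs["age"].to_numpy(float)
    if not np.any(ages >= sc_age - 1e-9):
        raise ValueError("child has no record at or after seroconversion")
    exact = np.isclose(ages, sc_age)
    if exact.any():
        out = recs.iloc[int(np.argmax(exact))].copy()
        out["age"] = sc_age
        return out
    before = ages < sc_age
    if not before.any():
        return None
    i0 = int(np.where(before)[0][-1])
    i1 = int(np.argmax(ages >= sc_age))
    lo, hi = recs.iloc[i0], recs.iloc[i1]
    w = (sc_age - lo["age"]) / (hi["age"] - lo["age"])
    out = lo.copy()
    out["age"] = sc_age
    for col in recs.columns:
        if col in _META_COLS:
            continue
        if pd.api.types.is_numeric_dtype(recs[col]):
            out[col] = (1 - w) * lo[col] + w * hi[col]
    out["n_days"] = 0  # interpolated, not observed
    return out


def build_progression_dataset(children: pd.DataFrame, records: pd.DataFrame):
    """Seroconversion-anchored cohort: eligible children and their
    longitudinal data re-expressed as time since seroconversion.

    Eligible: seroconverted (``ia_status == 1``) with at least one record at
    or after the seroconversion age within the 6-year follow-up.  Returns
    ``(children_prog, records_prog, n_excluded)``; ``records_prog['age']`` is
    time since seroconversion and includes the interpolated pseudo-record at
    zero where one could be formed.
    """
    sero = children[children["ia_status"] == 1].copy()
    sc_col = "sc_age" if "sc_age" in sero.columns else "ia_age"
    keep_rows, rec_rows = [], []
    n_excluded = 0
    rec_by_child = dict(tuple(records.groupby("child_id", sort=False)))
    for _, child in sero.iterrows():
        sc = float(child[sc_col])
        recs = rec_by_child.get(child["child_id"])
        if recs is None or sc > 6.0:
            n_excluded += 1
            continue
        post = recs[recs["age"] >= sc - 1e-9]
        post = post[post["age"] <= 6.0 + 1e-9]
        if post.empty:
            n_excluded += 1
            continue
        pseudo = interpolate_at_seroconversion(recs, sc)
        use = post.copy()
        if pseudo is not None and not np.any(np.isclose(post["age"], sc)):
            use = pd.concat([pseudo.to_frame().T, use], ignore_index=True)
        use["age"] = use["age"].astype(float) - sc
        rec_rows.append(use)
        row = child.copy()
        row["sc_age"] = sc
        keep_rows.append(row)
    if not keep_rows:
        raise ValueError("no eligible children for the progression analysis")
    children_prog = pd.DataFrame(keep_rows).reset_index(drop=True)
    records_prog = pd.concat(rec_rows, ignore_index=True)
    for col in records_prog.columns:
        if col not in ("child_id",):
            records_prog[col] = pd.to_numeric(records_prog[col])
    log.info("progression cohort: %d children, %d excluded",
             len(children_prog), n_excluded)
    return children_prog, records_prog, n_excluded


def fit_progression(children: pd.DataFrame, records: pd.DataFrame, variable,
                    energy_adjusted: bool = False,
                    config: JointConfig | None = None,
                    prebuilt: bool = False) -> PosteriorSummary:
    """Joint model for progression from seroconversion to T1D.

    Same structure as the whole-cohort T1D model, but on the
    since-seroconversion time scale and adjusted for age at seroconversion
    (centred).  ``prebuilt=True`` means ``children``/``records`` already come
    from :func:`build_progression_dataset`.
    """
    if prebuilt:
        children_prog, records_prog = children, records
    else:
        children_prog, records_prog, _ = build_progression_dataset(children,
                                                                   records)
    sc = children_prog["sc_age"].to_numpy(float)
    extra = pd.DataFrame({"age_at_sc": sc - sc.mean()})
    if np.ptp(extra["age_at_sc"].to_numpy()) == 0:
        # degenerate (all seroconversions coincide): drop the covariate
        log.info("age-at-seroconversion constant; dropped from the model")
        extra = None
    # survival times on the since-seroconversion scale
    kids = children_prog.copy()
    kids["censor_age"] = np.minimum(kids["censor_age"].to_numpy(float), 6.0)
    summary = fit_joint(kids, records_prog, variable, outcome="t1d",
                        energy_adjusted=energy_adjusted, config=config,
                        extra_covariates=extra,
                        time_origin=pd.Series(sc))
    summary.outcome = "progression"
    return summary
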