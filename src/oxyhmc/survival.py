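"""Survival association of 5hmC cluster membership.

Multivariable Cox proportional-hazards regression (Efron tie handling,
via lifelines) of overall survival on the low-5hmC-cluster indicator,
adjusted for age at diagnosis and sex; samples carrying the clinical
``excluded_flag`` (e.g. a methylator-phenotype outlier) are dropped
before fitting.  Kaplan-Meier coordinates are exportable for plotting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SurvivalFit", "cox_fit", "km_coordinates"]


@dataclass
class SurvivalFit:
    """Hazard ratio for the group indicator with Wald CI and p-value."""

    hr: float
    ci_low: float
    ci_high: float
    p: float
    covariates: list[str] = field(default_factory=list)
    n: int = 0
    n_events: int = 0
    warnings: list[str] = field(default_factory=list)
    summary: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.hr > 0:
            raise ValueError("hazard ratio must be positive")


def _design(
    clinical: pd.DataFrame, groups: pd.Series, adjust: tuple[str, ...]
) -> pd.DataFrame:
    common = clinical.index.intersection(groups.index)
    df = clinical.loc[common].copy()
    df = df[~df["excluded_flag"].astype(bool)]
    lev = sorted(groups.loc[df.index].unique())
    if len(lev) != 2:
        raise ValueError(f"group indicator must be binary, got levels {lev}")
    # indicator = 1 for the "low" cluster when present, else the first level
    ref = "low" if "low" in lev else lev[0]
    out = pd.DataFrame(index=df.index)
    out["duration"] = df["survival_months"].astype(float)
    out["event"] = df["event"].astype(int)
    out["group_low"] = (groups.loc[df.index] == ref).astype(float)
    for cov in adjust:
        if cov == "sex":
            out["sex_male"] = (df["sex"] == "male").astype(float)
        elif cov == "age":
            out["age"] = df["age_at_diagnosis"].astype(float)
        else:
            out[cov] = pd.to_numeric(df[cov])
    return out


def cox_fit(
    clinical: pd.DataFrame,
    groups: pd.Series,
    adjust: tuple[str, ...] = ("age", "sex"),
) -> SurvivalFit:
    """Cox PH fit of survival on the low-cluster indicator.

    ``groups`` maps sample -> {"low", "high"} (any binary labelling
    works; "low" is the indicator level when present).  Raises on zero
    events; monotone-likelihood / separation warnings from the partial
    likelihood are captured and surfaced on the result instead of being
    silently dropped.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    df = _design(clinical, groups, adjust)
    if int(df["event"].sum()) == 0:
        raise ValueError("no events: all samples censored")

    cph = CoxPHFitter()
    captured: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        try:
            cph.fit(df, duration_col="duration", event_col="event")
        except ConvergenceError as exc:
            raise ValueError(f"Cox partial likelihood did not converge: {exc}") from exc
    for w in wlist:
        msg = str(w.message)
        if "convergence" in msg.lower() or "monotone" in msg.lower() or "separation" in msg.lower():
            captured.append(msg)

    s = cph.summary
    row = s.loc["group_low"]
    return SurvivalFit(
        hr=float(np.exp(row["coef"])),
        ci_low=float(np.exp(row["coef lower 95%"])),
        ci_high=float(np.exp(row["coef upper 95%"])),
        p=float(row["p"]),
        covariates=[c for c in df.columns if c not in ("duration", "event")],
        n=int(df.shape[0]),
        n_events=int(df["event"].sum()),
        warnings=captured,
        summary=s,
    )


def km_coordinates(clinical: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Kaplan-Meier survival-curve coordinates per group, long format."""
    from lifelines import KaplanMeierFitter

    common = clinical.index.intersection(groups.index)
    df = clinical.loc[common]
    df = df[~df["excluded_flag"].astype(bool)]
    frames = []
    for g in sorted(groups.loc[df.index].unique()):
        sub = df[groups.loc[df.index] == g]
        km = KaplanMeierFitter()
        km.fit(sub["survival_months"], sub["event"], label=str(g))
        sf = km.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        sf["group"] = g
        frames.append(sf)
    return pd.concat(frames, ignore_index=True)
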