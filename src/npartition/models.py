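"""Partitioning statistics: the urinary-N ~ N-intake regression and the
repeated-measures treatment comparison.

The regression pools cow-days (each observation is one cow on one day) and
is plain OLS. The treatment comparison is a linear mixed model with a fixed
treatment effect and a random cow intercept, fitted by REML — the
animal-as-experimental-unit convention: the treatment test uses between-cow
denominator degrees of freedom (n_cows - n_treatments).
"""
from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import (
    DegenerateInputError,
    InsufficientReplicationError,
    InvalidArgumentError,
)
from .types import LinearFit, NBalanceResult, SkewnessScreen, Treatment, TreatmentComparison


def balance_frame(results: Iterable[NBalanceResult]) -> pd.DataFrame:
    """Long-format DataFrame of balance results, one row per cow-day, with
    the derived milk N % and urine N concentration columns used by the
    treatment comparison."""
    rows = []
    for r in results:
        rows.append(
            {
                "cow_id": r.cow_id,
                "day": r.day,
                "dmi_kg": r.dmi_kg,
                "n_intake_g": r.n_intake_g,
                "fecal_n_g": r.fecal_n_g,
                "milk_n_g": r.milk_n_g,
                "urine_n_est_g": r.urine_n_est_g,
                "diet_cp_pct": r.diet_cp_pct,
                "urine_n_conc_g_per_l": r.urine_n_conc_g_per_l,
                "flagged": r.flagged,
            }
        )
    return pd.DataFrame(rows)


def fit_urine_regression(
    balance: Iterable[NBalanceResult] | pd.DataFrame,
) -> LinearFit:
    """OLS of estimated urinary N (g/d) on total N intake (g/d), pooled over
    cows and days."""
    df = balance if isinstance(balance, pd.DataFrame) else balance_frame(balance)
    df = df[np.isfinite(df["n_intake_g"]) & np.isfinite(df["urine_n_est_g"])]
    if len(df) < 3:
        raise InvalidArgumentError("need >= 3 cow-day rows for the regression")
    x = df["n_intake_g"].to_numpy(dtype=float)
    y = df["urine_n_est_g"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateInputError("zero variance in N intake")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    r2 = float(res.rsquared) if np.ptp(y) > 0 else 0.0
    return LinearFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        r2=max(0.0, min(1.0, r2)),
        se_intercept=float(res.bse[0]),
        se_slope=float(res.bse[1]),
        n=int(res.nobs),
        p_value_slope=float(res.pvalues[1]),
    )


def _lsmeans_closed_form(df: pd.DataFrame, parameter: str) -> dict:
    """Fallback LS means via per-cow means (exact for balanced designs and
    for degenerate, zero-variance data where REML cannot iterate)."""
    cow_means = df.groupby(["treatment", "cow_id"], observed=True)[parameter].mean()
    group_means = cow_means.groupby(level="treatment", observed=True).mean()
    resid = cow_means - group_means.reindex(cow_means.index.get_level_values(0)).values
    n_cows = cow_means.index.get_level_values("cow_id").nunique()
    k = group_means.size
    df_resid = n_cows - k
    var_between = float((resid**2).sum() / df_resid) if df_resid > 0 else 0.0
    n_per = cow_means.groupby(level="treatment", observed=True).size()
    sem = float(np.sqrt(var_between / n_per.min())) if n_per.min() > 0 else float("nan")
    means = group_means.to_dict()
    diff = float(abs(np.subtract(*list(means.values())[:2]))) if k == 2 else np.nan
    se_diff = float(np.sqrt(var_between * (1.0 / n_per).sum())) if k == 2 else np.nan
    if se_diff and se_diff > 0:
        t = diff / se_diff
        p = float(2 * stats.t.sf(abs(t), df_resid))
    else:
        p = 1.0 if diff == 0 else 0.0
    return {"means": means, "sem": sem, "p": p, "n_cows": n_cows}


def compare_treatments(
    data: pd.DataFrame, parameter: str
) -> TreatmentComparison:
    """Repeated-measures comparison of ``parameter`` between the low-N and
    medium-N groups.

    ``data`` is a long-format frame with columns ``cow_id``, ``treatment``
    and ``parameter`` (one row per cow-day). The model is
    value ~ treatment + (1 | cow), fitted by REML; LS means are the fixed-
    effect group means, the SEM their standard error, and the p-value a
    t-test of the treatment contrast on n_cows - 2 denominator df.
    """
    for col in ("cow_id", "treatment", parameter):
        if col not in data.columns:
            raise InvalidArgumentError(f"data lacks required column '{col}'")
    df = data[["cow_id", "treatment", parameter]].dropna().copy()
    df["treatment"] = df["treatment"].map(
        lambda t: t.value if isinstance(t, Treatment) else str(t)
    )
    levels = sorted(df["treatment"].unique())
    if len(levels) != 2:
        raise InvalidArgumentError(
            f"comparison needs exactly 2 treatment groups, got {levels}"
        )
    counts = df.groupby("treatment")["cow_id"].nunique()
    if counts.min() < 2:
        raise InsufficientReplicationError(
            f"each treatment needs >= 2 cows, got {counts.to_dict()}"
        )
    n_cows = df["cow_id"].nunique()
    n_days = int(df.groupby("cow_id")["cow_id"].size().max())
    df_denom = n_cows - 2

    result = None
    if df[parameter].nunique() > 1:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(
                    f"value ~ C(treatment)",
                    df.rename(columns={parameter: "value"}),
                    groups="cow_id",
                )
                fit = model.fit(reml=True)
            fe = fit.fe_params
            cov = fit.cov_params().iloc[:2, :2]
            # LS mean rows in the (Intercept, treatment-dummy) basis
            rows = {levels[0]: np.array([1.0, 0.0]), levels[1]: np.array([1.0, 1.0])}
            means = {lv: float(r @ fe.values[:2]) for lv, r in rows.items()}
            sems = {
                lv: float(np.sqrt(r @ cov.values @ r)) for lv, r in rows.items()
            }
            coef = float(fe.values[1])
            se = float(np.sqrt(cov.values[1, 1]))
            if se > 0 and np.isfinite(se):
                t = coef / se
                p = float(2 * stats.t.sf(abs(t), df_denom))
            else:
                p = 1.0 if coef == 0 else 0.0
            if all(np.isfinite(v) for v in means.values()):
                result = {
                    "means": means,
                    "sem": float(np.nanmax(list(sems.values()))),
                    "p": p,
                    "n_cows": n_cows,
                }
        except (np.linalg.LinAlgError, ValueError):
            result = None
    if result is None:
        result = _lsmeans_closed_form(df, parameter)

    m = result["means"]
    low_key = Treatment.LOW_N.value if Treatment.LOW_N.value in m else levels[0]
    other = [k for k in m if k != low_key][0]
    return TreatmentComparison(
        parameter=parameter,
        lsmean_low=float(m[low_key]),
        lsmean_medium=float(m[other]),
        sem=float(result["sem"]),
        p_value=min(1.0, max(0.0, float(result["p"]))),
        n_cows=int(result["n_cows"]),
        n_days=n_days,
    )


def normality_screen(
    values: Sequence[float], threshold: float = 1.0
) -> SkewnessScreen:
    """Sample skewness (adjusted Fisher-Pearson) with a pass/fail flag at
    ``|skew| > threshold``. Requires n >= 8 and non-constant data."""
    v = np.asarray(values, dtype=float)
    if v.size < 8:
        raise InvalidArgumentError(f"need n >= 8 for a skewness screen, got {v.size}")
    if np.ptp(v) == 0:
        raise DegenerateInputError("constant data: skewness undefined")
    skew = float(stats.skew(v, bias=False))
    return SkewnessScreen(skewness=skew, flagged=abs(skew) > threshold, threshold=threshold)
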