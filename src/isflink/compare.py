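"""Statistical comparison of the identification-method cohorts.

Produces the reporting layer of the analysis:

* stratified proportions with exact binomial confidence intervals, per cohort
  (A, B, C and the set differences B\\A, C\\A, B\\C, C\\B) and stratifier
  (demographics, parental composition, perinatal outcomes);
* linear temporal trends in annual identified counts (ordinary least
  squares on calendar year) with an explicit-year outlier sensitivity
  analysis;
* rate ratios of annual identified proportions versus a reference year, from
  a Poisson log-linear model with the log of total annual births as offset;
* the step-change decomposition attributing Method-C-only identifications to
  the introduction of the child-status field on the midwives' record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.proportion import proportion_confint
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

__all__ = [
    "binomial_ci",
    "stratified_proportions",
    "TrendFit",
    "fit_linear_trend",
    "fit_rate_ratios",
    "step_change_report",
    "COHORT_DEFINITIONS",
    "cohort_masks",
]

#: cohort label -> function of (in_A, in_B, in_C) boolean arrays
COHORT_DEFINITIONS = {
    "A": lambda a, b, c: a,
    "B": lambda a, b, c: b,
    "C": lambda a, b, c: c,
    "B_not_A": lambda a, b, c: b & ~a,
    "C_not_A": lambda a, b, c: c & ~a,
    "B_not_C": lambda a, b, c: b & ~c,
    "C_not_B": lambda a, b, c: c & ~b,
}


def binomial_ci(successes: int, n: int, level: float = 0.95, method: str = "clopper-pearson"):
    """Binomial confidence interval for a proportion.

    ``clopper-pearson`` (default) is the exact interval obtained by inverting
    the binomial tail probabilities; ``wilson`` is offered as an option.
    Accepts scalars or arrays.  ``n`` must be >= 1 everywhere.
    """
    k = np.asarray(successes)
    nn = np.asarray(n)
    if (nn < 1).any():
        raise ValueError("n must be >= 1")
    if ((k < 0) | (k > nn)).any():
        raise ValueError("successes must lie in [0, n]")
    sm_method = {"clopper-pearson": "beta", "wilson": "wilson"}[method]
    low, high = proportion_confint(k, nn, alpha=1 - level, method=sm_method)
    if np.asarray(successes).ndim == 0:
        return float(low), float(high)
    return np.asarray(low, float), np.asarray(high, float)


# ---------------------------------------------------------------------------
# stratified proportion tables
# ---------------------------------------------------------------------------

DEMOGRAPHIC_VARIABLES = (
    "birth_year_band", "irsd_quintile", "remoteness", "indigenous_region",
    "parental_composition",
)
PERINATAL_VARIABLES = ("preterm_category", "lbw", "sga", "apgar_ge9")
LIVE_BORN_ONLY = {"lbw", "sga", "apgar_ge9"}  # live-birth-gated characteristics


def _year_band(years: pd.Series) -> pd.Series:
    y = years.astype(float)
    start = (np.floor((y - 2000) / 2) * 2 + 2000).astype(int)
    return start.astype(str) + " - " + (start + 1).astype(str)


def cohort_masks(cohorts: pd.DataFrame) -> dict[str, np.ndarray]:
    a = cohorts["in_A"].to_numpy(bool)
    b = cohorts["in_B"].to_numpy(bool)
    c = cohorts["in_C"].to_numpy(bool)
    return {name: fn(a, b, c) for name, fn in COHORT_DEFINITIONS.items()}


def stratified_proportions(
    cohorts: pd.DataFrame,
    persons: pd.DataFrame,
    perinatal_class: pd.DataFrame | None = None,
    variables=DEMOGRAPHIC_VARIABLES,
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-cohort stratified proportions with exact binomial CIs.

    Missing values form their own stratum level, and within each cohort and
    variable the level proportions (including missing) sum to 1.  Perinatal
    binaries (LBW, SGA, Apgar >= 9) are tabulated among live births only.
    """
    data = cohorts.merge(
        persons[persons["role"] == "child"].rename(columns={"person_id": "child_id"}),
        on="child_id", how="left", suffixes=("", "_p"),
    )
    if perinatal_class is not None:
        data = data.merge(perinatal_class, on="child_id", how="left",
                          suffixes=("", "_peri"))
    data["birth_year_band"] = _year_band(data["birth_year"])

    masks = cohort_masks(data)
    rows = []
    for var in variables:
        if var not in data.columns:
            raise KeyError(f"unknown stratification variable {var!r}")
        col = data[var]
        if var in LIVE_BORN_ONLY:
            gate = data["live_born"].fillna(False).astype(bool).to_numpy()
        else:
            gate = np.ones(len(data), dtype=bool)
        values = col.where(pd.notna(col), "missing").astype(str)
        for cohort, mask in masks.items():
            sel = values[mask & gate]
            denom = int(len(sel))
            if denom == 0:
                continue
            counts = sel.value_counts()
            for lev, cnt in counts.items():
                low, high = binomial_ci(int(cnt), denom, level=level)
                rows.append({
                    "cohort": cohort, "variable": var, "level": lev,
                    "count": int(cnt), "denominator": denom,
                    "proportion": cnt / denom, "ci_low": low, "ci_high": high,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# temporal trend (OLS on calendar year)
# ---------------------------------------------------------------------------

@dataclass
class TrendFit:
    """OLS linear trend of annual identified counts on calendar year."""

    cohort: str
    slope: float                      # births per year
    slope_ci: tuple[float, float]     # 95% interval from the t distribution
    intercept: float
    r_squared: float
    residuals: pd.Series = field(repr=False)
    outliers_removed: tuple[int, ...] = ()

    @property
    def diagnostics(self) -> dict:
        r = self.residuals
        return {
            "r_squared": self.r_squared,
            "resid_mean": float(r.mean()),
            "resid_sd": float(r.std(ddof=1)) if len(r) > 2 else 0.0,
            "resid_max_abs": float(r.abs().max()),
        }


def fit_linear_trend(
    annual_counts, exclude_years=None, cohort: str = "", level: float = 0.95
) -> TrendFit:
    """Fit counts = a + slope * year by ordinary least squares.

    ``annual_counts`` maps year -> count (dict or Series).  ``exclude_years``
    removes explicitly named years before fitting (outlier sensitivity
    analysis); at least 3 years must remain.
    """
    s = pd.Series(dict(annual_counts)).sort_index().astype(float)
    excluded = tuple(sorted(exclude_years)) if exclude_years else ()
    s = s[~s.index.isin(excluded)]
    if len(s) < 3:
        raise ValueError(f"need >= 3 years after exclusions, have {len(s)}")
    X = sm.add_constant(s.index.to_numpy(float))
    with np.errstate(divide="ignore", invalid="ignore"):  # exact fits
        fit = sm.OLS(s.to_numpy(), X).fit()
        ci = fit.conf_int(alpha=1 - level)
        return TrendFit(
            cohort=cohort,
            slope=float(fit.params[1]),
            slope_ci=(float(ci[1][0]), float(ci[1][1])),
            intercept=float(fit.params[0]),
            r_squared=float(fit.rsquared),
            residuals=pd.Series(fit.resid, index=s.index),
            outliers_removed=excluded,
        )


# ---------------------------------------------------------------------------
# Poisson rate ratios vs a reference year
# ---------------------------------------------------------------------------

def fit_rate_ratios(
    annual_counts, annual_totals, reference_year: int = 2000, level: float = 0.95
) -> pd.DataFrame:
    """Rate ratios of identified proportion per year versus the reference year.

    A Poisson log-linear model of annual identified counts with categorical
    year and the log of total annual births as offset; the exponentiated year
    coefficients are the rate ratios, with Wald confidence intervals.  The
    reference year's rate ratio is identically 1.
    """
    counts = pd.Series(dict(annual_counts)).sort_index().astype(float)
    totals = pd.Series(dict(annual_totals)).sort_index().astype(float)
    years = counts.index
    if reference_year not in years:
        raise ValueError(f"reference year {reference_year} not in data")
    totals = totals.reindex(years)
    if totals.isna().any() or (totals <= 0).any():
        raise ValueError("every year needs a positive total-births offset")
    if (totals < counts).any():
        raise ValueError("totals must be >= identified counts")

    df = pd.DataFrame({
        "count": counts.to_numpy(),
        "year": pd.Categorical(years, categories=[reference_year]
                               + [y for y in years if y != reference_year]),
        "offset": np.log(totals.to_numpy()),
    })
    model = smf.glm(
        "count ~ C(year)", data=df, family=sm.families.Poisson(),
        offset=df["offset"],
    )
    with warnings.catch_warnings():
        # a zero count in some year is legitimate (RR estimate 0); statsmodels
        # flags it as perfect separation
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        with np.errstate(divide="ignore", over="ignore"):
            fit = model.fit(maxiter=200, tol=1e-12)
            ci = fit.conf_int(alpha=1 - level)
    rows = [{"year": reference_year, "count": counts[reference_year],
             "total": totals[reference_year], "rate_ratio": 1.0,
             "rr_low": 1.0, "rr_high": 1.0}]
    with np.errstate(over="ignore"):
        for y in years:
            if y == reference_year:
                continue
            name = f"C(year)[T.{y}]"
            rows.append({
                "year": y, "count": counts[y], "total": totals[y],
                "rate_ratio": float(np.exp(fit.params[name])),
                "rr_low": float(np.exp(ci.loc[name, 0])),
                "rr_high": float(np.exp(ci.loc[name, 1])),
            })
    out = pd.DataFrame(rows).sort_values("year").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# step-change decomposition
# ---------------------------------------------------------------------------

def step_change_report(cohorts: pd.DataFrame, mns_child_status_from: int = 2012) -> pd.DataFrame:
    """Annual counts of C-not-B children attributable to the midwives'
    child-status field (identified by that field and by no other route).

    With era-aware records the attribution is structurally zero before the
    field's introduction year.
    """
    df = cohorts.copy()
    df["year"] = df["birth_year"].astype(int)
    g = df.groupby("year")
    out = pd.DataFrame({
        "n_C": g["in_C"].sum().astype(int),
        "n_C_not_B": g.apply(
            lambda x: int((x["in_C"] & ~x["in_B"]).sum()), include_groups=False),
        "n_attributed_mns_child_status": g.apply(
            lambda x: int((x["in_C"] & ~x["in_B"] & x["mns_child_pathway"]).sum()),
            include_groups=False),
    }).reset_index()
    out["field_available"] = out["year"] >= mns_child_status_from
    return out
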