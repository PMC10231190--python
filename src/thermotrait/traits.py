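"""Survey-level trait estimation and trait-climate statistics.

Fits the square-root model per site x process, collects the trait indices
(Tmin, Topt, Tmax, Q10, niche width) and runs the comparative statistics:
simple trait-climate regressions, ANCOVA with sampling season, the paired
seasonal t test, multiple regression with collinearity diagnostics, the
niche-width versus seasonal-amplitude check, and the carbon-availability
correlation.  All analyses are complete-case: a site missing a trait simply
drops out of that analysis (degrees of freedom shrink accordingly).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .curves import GROWTH_PROCESSES, PROCESSES, RateCurve
from .ratkowsky import compute_q10, fit_full, fit_suboptimal

__all__ = [
    "RegressionResult",
    "PairedTestResult",
    "fit_survey",
    "regress_trait",
    "ancova_season",
    "paired_season_test",
    "multiple_regression",
    "width_vs_amplitude",
    "c_availability_correlation",
]

#: sub-optimal window per process; respiration never reaches an optimum so
#: every assay point is eligible for the linear fit
SUB_RANGES = {
    "bacterial_growth": (0.0, 25.0),
    "fungal_growth": (0.0, 25.0),
    "respiration": (0.0, 45.0),
}

TRAIT_COLUMNS = ["a", "b", "t_min", "t_opt", "t_max", "q10", "width",
                 "r_squared_suboptimal", "converged", "n_excluded"]


@dataclass
class RegressionResult:
    """Simple OLS summary: F = t^2 of the slope, df = (1, n-2)."""

    slope: float
    intercept: float
    slope_se: float
    r_squared: float
    f_stat: float
    df1: int
    df2: int
    p_value: float

    def __post_init__(self):
        # internal consistency: F = (R^2 / (1 - R^2)) * df2 for simple OLS
        if self.r_squared < 1.0 and np.isfinite(self.f_stat):
            implied = self.r_squared / (1.0 - self.r_squared) * self.df2
            assert abs(implied - self.f_stat) <= 1e-6 * max(1.0, abs(self.f_stat))


@dataclass
class PairedTestResult:
    statistic: float
    df: int
    p_value: float
    mean_diff: float
    degenerate: bool = False


def fit_survey(curves: list[RateCurve], q10_interval=(5.0, 15.0),
               full: bool = True) -> pd.DataFrame:
    """Fit every curve and tabulate the trait indices per site x process.

    Growth processes get the full model (Tmin, Topt, Tmax, Q10, width);
    respiration gets the sub-optimal model only (Tmin, Q10).  Sites whose
    sub-optimal fit fails (non-positive slope, too few points) are retained
    with missing entries so downstream degrees of freedom shrink honestly.
    """
    if not curves:
        raise ValueError("empty survey: no rate curves supplied")
    rows = []
    for curve in curves:
        row = {"site_id": curve.site_id, "process": curve.process}
        row.update({c: np.nan for c in TRAIT_COLUMNS})
        row["converged"] = False
        row["n_excluded"] = 0
        try:
            row.update(_fit_one(curve, q10_interval, full))
        except (ValueError, RuntimeError) as exc:
            warnings.warn(
                f"fit failed for site {curve.site_id} ({curve.process}): {exc}",
                UserWarning, stacklevel=2,
            )
            row = {k: (np.nan if k in TRAIT_COLUMNS else v) for k, v in row.items()}
            row["converged"] = False
        rows.append(row)
    out = pd.DataFrame(rows)
    out["process"] = pd.Categorical(out["process"], categories=PROCESSES)
    return out.sort_values(["site_id", "process"]).reset_index(drop=True)


def _fit_one(curve, q10_interval, full):
    sub_range = SUB_RANGES[curve.process]
    if curve.process in GROWTH_PROCESSES and full:
        fit = fit_full(curve, sub_range=sub_range)
        sub = fit.suboptimal_
        if not sub.valid_:
            raise ValueError("sub-optimal slope is non-positive")
        rec = {
            "a": fit.a_, "t_min": fit.t_min_,
            "r_squared_suboptimal": sub.r_squared_,
            "n_excluded": int(sub.auto_excluded_.size),
            "q10": compute_q10(fit.t_min_, q10_interval),
            "converged": bool(fit.converged_),
        }
        if fit.converged_:
            rec.update({"b": fit.b_, "t_opt": fit.t_opt_, "t_max": fit.t_max_,
                        "width": fit.t_max_ - fit.t_min_})
        return rec
    sub = fit_suboptimal(curve, sub_range=sub_range)
    if not sub.valid_:
        raise ValueError("sub-optimal slope is non-positive")
    return {
        "a": sub.a_, "t_min": sub.t_min_,
        "r_squared_suboptimal": sub.r_squared_,
        "n_excluded": int(sub.auto_excluded_.size),
        "q10": compute_q10(sub.t_min_, q10_interval),
        "converged": True,
    }


def _merge(indices: pd.DataFrame, sites: pd.DataFrame, process: str,
           trait: str, covariates: list[str]) -> pd.DataFrame:
    sub = indices.loc[indices["process"] == process, ["site_id", trait]]
    data = sub.merge(sites[["site_id", *covariates]], on="site_id")
    return data.dropna(subset=[trait, *[c for c in covariates if c != "season"]])


def _simple_ols(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    if x.size < 3:
        raise ValueError("need at least 3 complete (x, y) pairs")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the predictor")
    if np.ptp(y) == 0:
        return RegressionResult(0.0, float(y[0]), 0.0, 0.0, 0.0, 1,
                                int(x.size - 2), 1.0)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    t_slope = float(model.tvalues[1])
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        slope_se=float(model.bse[1]),
        r_squared=float(model.rsquared),
        f_stat=t_slope**2,
        df1=1,
        df2=int(model.df_resid),
        p_value=float(model.pvalues[1]),
    )


def regress_trait(indices: pd.DataFrame, sites: pd.DataFrame, trait: str,
                  process: str, covariate: str = "mat") -> RegressionResult:
    """Simple OLS of one trait index on one site covariate (default MAT)."""
    data = _merge(indices, sites, process, trait, [covariate])
    return _simple_ols(data[covariate].to_numpy(float), data[trait].to_numpy(float))


def ancova_season(indices: pd.DataFrame, sites: pd.DataFrame, trait: str,
                  process: str, covariate: str = "mat") -> pd.DataFrame:
    """ANCOVA of a trait on MAT with sampling season as covariate.

    Sequential (type-I) sums of squares with the climate predictor entered
    first, then season, then the interaction; returns a table with F and p
    per term.
    """
    data = _merge(indices, sites, process, trait, [covariate, "season"])
    if data["season"].nunique() < 2:
        raise ValueError("both seasons must be represented")
    data = data.rename(columns={trait: "y"})
    model = smf.ols(f"y ~ {covariate} + C(season) + {covariate}:C(season)",
                    data=data).fit()
    table = sm.stats.anova_lm(model, typ=1)
    table = table.rename(index={
        covariate: covariate,
        "C(season)": "season",
        f"{covariate}:C(season)": f"{covariate}:season",
    })
    return table.rename(columns={"PR(>F)": "p_value"})


def paired_season_test(summer: np.ndarray, winter: np.ndarray) -> PairedTestResult:
    """Classical paired t test on winter - summer trait differences."""
    summer = np.asarray(summer, dtype=float)
    winter = np.asarray(winter, dtype=float)
    ok = np.isfinite(summer) & np.isfinite(winter)
    summer, winter = summer[ok], winter[ok]
    if summer.size < 2:
        raise ValueError("need at least 2 complete pairs")
    d = winter - summer
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return PairedTestResult(0.0, d.size - 1, 1.0, 0.0)
        return PairedTestResult(np.nan, d.size - 1, np.nan, float(d.mean()),
                                degenerate=True)
    res = stats.ttest_rel(winter, summer)
    return PairedTestResult(float(res.statistic), d.size - 1,
                            float(res.pvalue), float(d.mean()))


def multiple_regression(indices: pd.DataFrame, sites: pd.DataFrame, trait: str,
                        process: str,
                        predictors=("ph", "som", "mat", "map")) -> dict:
    """OLS of a trait on pH, SOM, MAT and MAP with VIF diagnostics.

    VIF_j = 1/(1 - R^2_j) from regressing predictor j on the remaining
    predictors; VIF > 10 raises a multicollinearity warning, exact
    collinearity is an error naming the offending predictors.
    """
    predictors = list(predictors)
    data = _merge(indices, sites, process, trait, predictors)
    n = len(data)
    if n <= len(predictors) + 2:
        raise ValueError(f"need more than {len(predictors) + 2} complete sites, got {n}")
    X = data[predictors].to_numpy(float)
    Xc = X - X.mean(axis=0)
    if np.linalg.matrix_rank(Xc, tol=1e-8 * np.abs(Xc).max()) < len(predictors):
        corr = np.corrcoef(X, rowvar=False)
        pairs = [
            f"{predictors[i]}~{predictors[j]}"
            for i in range(len(predictors)) for j in range(i + 1, len(predictors))
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError("perfectly collinear predictors: " + ", ".join(pairs or predictors))

    vif = {}
    for j, name in enumerate(predictors):
        others = np.delete(X, j, axis=1)
        r2 = sm.OLS(X[:, j], sm.add_constant(others)).fit().rsquared
        vif[name] = float(1.0 / (1.0 - r2)) if r2 < 1 else np.inf
        if vif[name] > 10:
            warnings.warn(f"VIF > 10 for predictor {name} ({vif[name]:.1f})",
                          UserWarning, stacklevel=2)

    model = sm.OLS(data[trait].to_numpy(float), sm.add_constant(X)).fit()
    coef = pd.DataFrame({
        "estimate": model.params, "se": model.bse,
        "t": model.tvalues, "p_value": model.pvalues,
    }, index=["intercept", *predictors])
    coef["vif"] = [np.nan, *[vif[p] for p in predictors]]
    return {
        "coefficients": coef,
        "f_stat": float(model.fvalue),
        "df1": int(model.df_model),
        "df2": int(model.df_resid),
        "r_squared": float(model.rsquared),
        "p_value": float(model.f_pvalue),
        "n": n,
    }


def width_vs_amplitude(indices: pd.DataFrame, sites: pd.DataFrame,
                       process: str) -> RegressionResult:
    """OLS of thermal niche width (Tmax - Tmin) on seasonal amplitude.

    Tests whether seasonally more variable sites host communities with wider
    temperature relationships.  Defined for growth processes only.
    """
    if process not in GROWTH_PROCESSES:
        raise ValueError(f"width undefined for process {process!r}: no Tmax")
    data = _merge(indices, sites, process, "width", ["summer_temp", "winter_temp"])
    amp = (data["summer_temp"] - data["winter_temp"]).to_numpy(float)
    return _simple_ols(amp, data["width"].to_numpy(float))


def c_availability_correlation(curves: list[RateCurve], sites: pd.DataFrame,
                               reference_temp: float = 20.0):
    """Pearson correlation of carbon availability with MAT.

    C availability is proxied by the rate of microbial C use — the
    respiration rate at the reference assay temperature (nearest point to
    ``reference_temp``) — per unit SOM.  Sites without SOM are dropped with
    a warning.
    """
    per_site = {}
    for c in curves:
        if c.process != "respiration":
            continue
        t, r = c.active()
        per_site[c.site_id] = float(r[np.argmin(np.abs(t - reference_temp))])
    data = sites.set_index("site_id")
    xs, ys = [], []
    for site, rate in per_site.items():
        if site not in data.index:
            continue
        som, mat = data.at[site, "som"], data.at[site, "mat"]
        if not np.isfinite(som):
            warnings.warn(f"site {site} dropped: missing SOM", UserWarning,
                          stacklevel=2)
            continue
        xs.append(mat)
        ys.append(rate / som)
    if len(xs) < 3:
        raise ValueError("need at least 3 sites with respiration and SOM")
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(p)
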