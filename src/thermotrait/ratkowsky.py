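"""Square-root (Ratkowsky) temperature model for microbial community rates.

The model describes the temperature relationship of a community rate R as

    sqrt(R) = a * (T - Tmin) * (1 - exp(b * (T - Tmax)))

with cardinal temperatures Tmin (lower x-intercept) and Tmax (upper
x-intercept), slope parameters a and b, and a rate maximum at the optimum
temperature Topt strictly between them.  Below the optimum the exponential
term is near 1 and sqrt(R) is effectively linear in T,

    sqrt(R) = a * (T - Tmin),

which is the form used to estimate (a, Tmin) from the sub-optimal window and
the only form applicable to respiration, whose rate keeps rising through the
assayed interval without reaching an optimum.

Fitting follows the classic two-stage scheme — ordinary least squares of
sqrt(R) on T over the sub-optimal window for (a, Tmin), then bounded least
squares for (b, Tmax) over all points — followed, by default, by a joint
polish of all four parameters.  The polish matters when b is small: the
exponential term then leaks into the sub-optimal window and a strictly fixed
(a, Tmin) would be biased.  Set ``refine_all=False`` for the literal
two-stage estimates.

Estimators follow scikit-learn conventions (``fit``/``predict``, fitted
attributes with a trailing underscore) and compose with sklearn tooling.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq, least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .curves import RateCurve

__all__ = [
    "ratkowsky_sqrt_rate",
    "SquareRootSuboptimalModel",
    "RatkowskyModel",
    "fit_suboptimal",
    "fit_full",
    "compute_topt",
    "predict_rate",
    "normalize_curve",
    "compute_q10",
]


def ratkowsky_sqrt_rate(T, a, t_min, b, t_max):
    """Modelled sqrt-rate at temperature(s) T (may be negative outside the niche)."""
    T = np.asarray(T, dtype=float)
    return a * (T - t_min) * (1.0 - np.exp(b * (T - t_max)))


def _as_temperatures(X):
    X = np.asarray(X, dtype=float)
    if X.ndim == 2 and X.shape[1] == 1:
        X = X[:, 0]
    if X.ndim != 1:
        raise ValueError("X must be a 1-D temperature array or an (n, 1) column")
    return X


class SquareRootSuboptimalModel(RegressorMixin, BaseEstimator):
    """Linear sub-optimal square-root model: sqrt(R) = a (T - Tmin).

    Fits ordinary least squares of sqrt-rate on temperature over the points
    inside ``sub_range``, with automatic iterative exclusion of gross
    outliers (internally studentized residual beyond ``studentized_threshold``,
    at most ``max_exclusions`` points, never leaving fewer than
    ``min_points``).

    Parameters
    ----------
    sub_range : (low, high) degC window of points eligible for the fit.
        (0, 25) for growth processes; (0, 45) — every assay point — for
        respiration, which stays sub-optimal throughout.
    studentized_threshold : |studentized residual| above which a point is
        dropped, one at a time.
    max_exclusions : cap on automatically dropped points.
    min_points : minimum points that must remain in the fit.

    Attributes
    ----------
    a_ : slope (sqrt-rate per degC); the fit is flagged invalid if a_ <= 0.
    t_min_ : apparent minimum temperature, -intercept/slope (degC).
    intercept_ : OLS intercept on the sqrt scale.
    r_squared_ : coefficient of determination of the sub-optimal line.
    n_points_ : number of points used.
    temps_used_ : temperatures of the points used.
    auto_excluded_ : temperatures dropped by the residual rule.
    valid_ : True when the slope is positive (a usable fit).
    """

    def __init__(self, sub_range=(0.0, 25.0), studentized_threshold=3.0,
                 max_exclusions=2, min_points=4):
        self.sub_range = sub_range
        self.studentized_threshold = studentized_threshold
        self.max_exclusions = max_exclusions
        self.min_points = min_points

    def fit(self, X, y):
        T = _as_temperatures(X)
        R = np.asarray(y, dtype=float)
        if np.any(R < 0):
            i = int(np.where(R < 0)[0][0])
            raise ValueError(f"negative rate {R[i]:g} at {T[i]:g} degC")
        lo, hi = self.sub_range
        keep = (T >= lo) & (T <= hi)
        if keep.sum() < self.min_points:
            raise ValueError(
                f"need at least {self.min_points} points in the sub-optimal window "
                f"[{lo:g}, {hi:g}] degC, got {int(keep.sum())}"
            )
        t, s = T[keep], np.sqrt(R[keep])
        dropped: list[float] = []
        while True:
            slope, intercept, resid, hat = _ols_line(t, s)
            if (
                len(dropped) >= self.max_exclusions
                or t.size <= self.min_points
                or t.size <= 3
                # numerically perfect fit: nothing to exclude
                or np.max(np.abs(resid)) < 1e-9 * (1.0 + np.max(np.abs(s)))
            ):
                break
            r_stud = _studentized(resid, hat)
            worst = int(np.argmax(np.abs(r_stud)))
            if np.abs(r_stud[worst]) <= self.studentized_threshold:
                break
            dropped.append(float(t[worst]))
            t = np.delete(t, worst)
            s = np.delete(s, worst)

        sst = float(np.sum((s - s.mean()) ** 2))
        sse = float(np.sum(resid**2))
        self.a_ = float(slope)
        self.intercept_ = float(intercept)
        self.t_min_ = float(-intercept / slope) if slope != 0 else np.nan
        self.r_squared_ = 1.0 - sse / sst if sst > 0 else 1.0
        self.n_points_ = int(t.size)
        self.temps_used_ = t.copy()
        self.auto_excluded_ = np.asarray(dropped, dtype=float)
        self.valid_ = bool(slope > 0)
        return self

    def predict(self, X):
        """Rates on the original scale; zero below the apparent minimum."""
        check_is_fitted(self, "a_")
        T = _as_temperatures(X)
        s = self.a_ * (T - self.t_min_)
        return np.where(s > 0, s**2, 0.0)


def _ols_line(t, s):
    tm, sm = t.mean(), s.mean()
    sxx = float(np.sum((t - tm) ** 2))
    slope = float(np.sum((t - tm) * (s - sm)) / sxx)
    intercept = sm - slope * tm
    resid = s - (intercept + slope * t)
    hat = 1.0 / t.size + (t - tm) ** 2 / sxx
    return slope, intercept, resid, hat


def _studentized(resid, hat):
    """Externally (deletion) studentized residuals of a straight-line fit.

    The internal variant is bounded by sqrt(n - 2), which would make an
    outlier threshold of 3 unreachable at typical window sizes.
    """
    n = resid.size
    mse = float(np.sum(resid**2)) / max(n - 2, 1)
    if mse <= 0:
        return np.zeros_like(resid)
    r = resid / np.sqrt(mse * (1.0 - hat))
    denom = np.maximum(n - 2 - r**2, 1e-12)
    return r * np.sqrt((n - 3) / denom)


class RatkowskyModel(RegressorMixin, BaseEstimator):
    """Full square-root model fit for growth processes.

    Stage 1 estimates (a, Tmin) on the sub-optimal window; stage 2 holds them
    fixed and fits (b, Tmax) over all points by bounded least squares on the
    sqrt scale; stage 3 (``refine_all=True``, default) jointly polishes all
    four parameters starting from the staged estimates.  Topt is then the
    unique stationary point of the modelled curve between Tmin and Tmax.

    Curves that keep rising through the warmest assay temperature (the
    respiration phenotype) push Tmax into its upper bound; such fits are
    flagged ``no_optimum_`` and ``converged_ = False`` so that downstream
    analyses fall back on the sub-optimal parameters only.

    Attributes: ``a_``, ``b_``, ``t_min_``, ``t_max_``, ``t_opt_``,
    ``rate_at_topt_``, ``residual_sse_`` (sqrt-rate^2 units), ``converged_``,
    ``no_optimum_``, plus the stage-1 estimator under ``suboptimal_``.
    """

    #: flag fits whose Tmax lands within this margin of the upper bound
    _BOUND_MARGIN = 2.0

    def __init__(self, sub_range=(0.0, 25.0), b_init=0.1, b_max=5.0,
                 t_max_cap=80.0, refine_all=True, n_restarts=3, random_state=0,
                 studentized_threshold=3.0, max_exclusions=2):
        self.sub_range = sub_range
        self.b_init = b_init
        self.b_max = b_max
        self.t_max_cap = t_max_cap
        self.refine_all = refine_all
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.studentized_threshold = studentized_threshold
        self.max_exclusions = max_exclusions

    def fit(self, X, y, init_t_max=None):
        T = _as_temperatures(X)
        R = np.asarray(y, dtype=float)
        sub = SquareRootSuboptimalModel(
            sub_range=self.sub_range,
            studentized_threshold=self.studentized_threshold,
            max_exclusions=self.max_exclusions,
        ).fit(T, R)
        self.suboptimal_ = sub
        if not sub.valid_:
            self._mark_failed(sub)
            return self
        if T.max() <= self.sub_range[1]:
            raise ValueError(
                "full fit needs observations above the sub-optimal window; "
                "use the sub-optimal model alone"
            )

        s = np.sqrt(R)
        a0, tmin0 = sub.a_, sub.t_min_
        # Tmax must exceed the warmest temperature at which the rate is still rising
        t_rise = float(T[int(np.argmax(s))])
        tmax_lo = max(t_rise, self.sub_range[1]) + 1e-6
        tmax0 = init_t_max if init_t_max is not None else float(T.max()) + 5.0
        tmax0 = float(np.clip(tmax0, tmax_lo + 1e-3, self.t_max_cap - 1e-3))

        # observed rates floor at zero beyond the niche, so the modelled
        # sqrt-rate is clipped at zero in the residuals (and its Jacobian
        # vanishes there)
        def resid_stage2(p):
            b, tmax = p
            return np.clip(ratkowsky_sqrt_rate(T, a0, tmin0, b, tmax), 0.0, None) - s

        def jac_stage2(p):
            b, tmax = p
            J = _model_jacobian(T, a0, tmin0, b, tmax)
            return J[:, 2:]

        sol = self._solve(resid_stage2, [self.b_init, tmax0],
                          ([1e-6, tmax_lo], [self.b_max, self.t_max_cap]),
                          jac=jac_stage2)
        b_, tmax_ = float(sol.x[0]), float(sol.x[1])
        a_, tmin_ = a0, tmin0
        ok = bool(sol.success)

        if self.refine_all and ok:
            def resid_joint(p):
                a, tmin, b, tmax = p
                return np.clip(ratkowsky_sqrt_rate(T, a, tmin, b, tmax), 0.0, None) - s

            def jac_joint(p):
                return _model_jacobian(T, *p)

            lo = [1e-10, -60.0, 1e-6, tmax_lo]
            hi = [np.inf, float(T.min()) - 1e-6, self.b_max, self.t_max_cap]
            x0 = np.clip([a_, tmin_, b_, tmax_],
                         np.asarray(lo) + 1e-12, np.asarray(hi) - 1e-12)
            sol = self._solve(resid_joint, x0, (lo, hi), jac=jac_joint)
            if sol.success:
                a_, tmin_, b_, tmax_ = map(float, sol.x)

        self.a_, self.t_min_, self.b_, self.t_max_ = a_, tmin_, b_, tmax_
        self.residual_sse_ = float(2.0 * sol.cost)
        self.no_optimum_ = bool(tmax_ >= self.t_max_cap - self._BOUND_MARGIN)
        self.converged_ = bool(ok and sol.success and not self.no_optimum_)
        self.t_opt_ = np.nan
        self.rate_at_topt_ = np.nan
        if self.converged_:
            t_opt = compute_topt(b_, tmin_, tmax_)
            if t_opt >= T.max():
                # optimum not supported by the data: rates still rising at the
                # warmest assay point (the respiration phenotype)
                self.no_optimum_ = True
                self.converged_ = False
            else:
                self.t_opt_ = t_opt
                self.rate_at_topt_ = float(
                    ratkowsky_sqrt_rate(t_opt, a_, tmin_, b_, tmax_) ** 2
                )
        return self

    def _solve(self, fun, x0, bounds, jac="2-point"):
        tol = dict(xtol=1e-12, ftol=1e-10, gtol=1e-10)
        sol = least_squares(fun, x0, bounds=bounds, method="trf", jac=jac, **tol)
        if sol.success:
            return sol
        rng = np.random.default_rng(self.random_state)
        best = sol
        lo, hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
        for _ in range(self.n_restarts):
            jitter = np.asarray(x0) * (1.0 + 0.2 * rng.standard_normal(len(x0)))
            jitter = np.clip(jitter, lo + 1e-9, np.where(np.isfinite(hi), hi - 1e-9, jitter))
            trial = least_squares(fun, jitter, bounds=bounds, method="trf",
                                  jac=jac, **tol)
            if trial.success and trial.cost < best.cost:
                best = trial
            if best.success:
                break
        return best

    def _mark_failed(self, sub):
        self.a_ = sub.a_
        self.t_min_ = sub.t_min_
        self.b_ = np.nan
        self.t_max_ = np.nan
        self.t_opt_ = np.nan
        self.rate_at_topt_ = np.nan
        self.residual_sse_ = np.nan
        self.no_optimum_ = False
        self.converged_ = False

    def predict(self, X):
        """Rates on the original scale; zero outside [Tmin, Tmax]."""
        check_is_fitted(self, "a_")
        T = _as_temperatures(X)
        s = ratkowsky_sqrt_rate(T, self.a_, self.t_min_, self.b_, self.t_max_)
        inside = (T >= self.t_min_) & (T <= self.t_max_)
        return np.where(inside & (s > 0), s**2, 0.0)


def _model_jacobian(T, a, t_min, b, t_max):
    """d sqrt-rate / d(a, t_min, b, t_max); zero where the clipped model is zero."""
    E = np.exp(b * (T - t_max))
    s = a * (T - t_min) * (1.0 - E)
    J = np.column_stack([
        (T - t_min) * (1.0 - E),
        -a * (1.0 - E),
        -a * (T - t_min) * (T - t_max) * E,
        a * (T - t_min) * b * E,
    ])
    J[s <= 0.0] = 0.0
    return J


# ---------------------------------------------------------------------------
# functional wrappers over the estimators

def fit_suboptimal(curve: RateCurve, sub_range=(0.0, 25.0)) -> SquareRootSuboptimalModel:
    """Fit the sub-optimal linear model to a curve's non-excluded points."""
    t, r = curve.active()
    return SquareRootSuboptimalModel(sub_range=sub_range).fit(t, r)


def fit_full(curve: RateCurve, sub_range=(0.0, 25.0), init_b=0.1,
             init_t_max=None, refine_all=True, random_state=0) -> RatkowskyModel:
    """Two-stage (plus optional joint polish) full-model fit of a curve."""
    t, r = curve.active()
    model = RatkowskyModel(sub_range=sub_range, b_init=init_b,
                           refine_all=refine_all, random_state=random_state)
    return model.fit(t, r, init_t_max=init_t_max)


def compute_topt(b: float, t_min: float, t_max: float, xtol: float = 1e-9) -> float:
    """Optimum temperature: the stationary point of the modelled curve.

    Solves (1 - e^{b(T - Tmax)}) - (T - Tmin) b e^{b(T - Tmax)} = 0, the
    derivative of the sqrt-rate with respect to T (the factor a drops out),
    by bracketed root search on (Tmin, Tmax).
    """
    if not (b > 0):
        raise ValueError("b must be positive")
    if not (t_min < t_max):
        raise ValueError("t_min must be below t_max")

    def g(T):
        e = np.exp(b * (T - t_max))
        return (1.0 - e) - (T - t_min) * b * e

    lo = t_min + 1e-9 * max(1.0, abs(t_min))
    hi = t_max - 1e-12 * max(1.0, abs(t_max))
    if not (g(lo) > 0 > g(hi)):
        raise ValueError("no sign change in (t_min, t_max): degenerate parameters")
    return float(brentq(g, lo, hi, xtol=xtol))


def predict_rate(fit, T):
    """Modelled rate at temperature(s) T; zero outside the thermal niche."""
    return fit.predict(np.atleast_1d(np.asarray(T, dtype=float)))


def normalize_curve(curve: RateCurve, fit: RatkowskyModel) -> RateCurve:
    """Rates divided by the modelled rate at Topt (unit-less curve).

    The denominator is the model's off-grid maximum, not the largest
    observation.  Undefined for fits without an optimum (respiration-like).
    """
    check_is_fitted(fit, "a_")
    if not getattr(fit, "converged_", False) or not np.isfinite(fit.rate_at_topt_):
        raise ValueError("normalization undefined: fit has no temperature optimum")
    if fit.rate_at_topt_ <= 0:
        raise ValueError("normalization undefined: modelled rate at Topt is zero")
    return RateCurve(
        curve.site_id,
        curve.process,
        curve.temperatures.copy(),
        curve.rates / fit.rate_at_topt_,
        curve.excluded_mask.copy(),
    )


def compute_q10(t_min: float, interval=(5.0, 15.0)) -> float:
    """Temperature sensitivity over a 10 degC interval implied by Tmin.

    Q10 = [a((T+10) - Tmin)]^2 / [a(T - Tmin)]^2 = ((T_hi - Tmin)/(T_lo - Tmin))^2
    over the default 5-15 degC interval; the slope a cancels, so Q10 is a
    pure function of Tmin.  Warm-shifted communities (higher Tmin) are more
    temperature sensitive.
    """
    t_lo, t_hi = interval
    if not (t_min < t_lo):
        raise ValueError(
            f"t_min={t_min:g} must lie below the interval start {t_lo:g} degC"
        )
    return float(((t_hi - t_min) / (t_lo - t_min)) ** 2)
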