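"""Statistical layer: OLS, diagnostics, and random-intercept mixed models.

Station-level relationships (diversity or composition vs mean salinity) use
simple OLS with t-based 95% CIs, plus two sensitivity checks: a second-order
polynomial is preferred only when it lowers AIC by more than 2 *and* the
F-test for the added term is significant, and any flagged outlier station is
refit side by side with the full fit.

Monthly-scale relationships use a random-intercept linear mixed model

    y_ij = beta0 + beta' x_ij + u_j + e_ij,   u_j ~ N(0, s2_station),
                                              e_ij ~ N(0, s2_resid)

with station as the grouping factor.  Candidate fixed structures are the six
hierarchy-respecting subsets of {ln DIN, sqrt silicate, ln DIN x salinity}
that always retain mean station-level salinity; they are compared by AIC and
Akaike weights under ML (REML likelihoods are not comparable across fixed
structures; the REML route is kept for the random-structure choice, where the
fixed part is constant).  Fit quality is summarised by marginal and
conditional r2:

    r2_m = s2_fixed / (s2_fixed + s2_station + s2_resid)
    r2_c = (s2_fixed + s2_station) / (s2_fixed + s2_station + s2_resid)

where s2_fixed is the variance of the fixed-effect linear predictor over the
data.  Wald 95% CIs (normal quantile) are reported for LMM fixed effects.

AIC counts parameters as fixed effects + variance components + residual
variance; for the random-intercept model that is p + 2, for a fixed-only
model p + 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .core import DomainError, SaltgradError

logger = logging.getLogger("saltgrad")

_Z975 = 1.959964  # normal 97.5% quantile used for Wald CIs


class DegenerateDesignError(SaltgradError):
    """Design matrix unusable (constant predictor, too few points, ...)."""


class ConvergenceError(SaltgradError):
    """Mixed-model optimiser failed to converge."""


@dataclass(frozen=True)
class Coefficient:
    term: str
    estimate: float
    se: float
    lower: float
    upper: float


@dataclass
class ModelSpec:
    """A model formula: response, fixed terms, optional random intercept.

    Interaction terms are written "a:b" and must appear only when the
    salinity main effect does too (salinity is a between-station covariate
    that every candidate model retains; ln DIN must also be present).
    """

    response: str
    fixed_terms: tuple[str, ...]
    random_intercept: str | None = None
    estimation: str = "ML"  # OLS | ML | REML

    def __post_init__(self):
        self.fixed_terms = tuple(self.fixed_terms)
        for term in self.fixed_terms:
            if ":" in term:
                a, b = term.split(":")
                if a not in self.fixed_terms or b not in self.fixed_terms:
                    raise DomainError(
                        f"interaction {term!r} requires both main effects in the model"
                    )

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.fixed_terms) if self.fixed_terms else "1"
        return f"{self.response} ~ {rhs}"


@dataclass
class ModelFit:
    """A fitted model with everything the reporting layer needs."""

    spec: ModelSpec
    coefficients: dict[str, Coefficient]
    n_obs: int
    loglik: float
    n_params: int
    aic: float
    aic_weight: float | None = None
    r2: float | None = None  # OLS only
    r2_marginal: float | None = None
    r2_conditional: float | None = None
    sigma2_random: float | None = None
    sigma2_resid: float | None = None
    diagnostics: dict = field(default_factory=dict)

    def coef(self, term: str) -> Coefficient:
        return self.coefficients[term]


# ---------------------------------------------------------------------------
# Simple linear regression
# ---------------------------------------------------------------------------


def fit_ols(x, y, x_name: str = "x", response: str = "y") -> ModelFit:
    """OLS of y on x with t-based 95% CIs and residual diagnostics.

    Diagnostics (Shapiro-Wilk normality p, Breusch-Pagan heteroscedasticity
    p) are attached for the run log, not used to gate anything.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise DomainError("x and y must have equal length")
    if len(x) < 3:
        raise DegenerateDesignError(f"OLS needs >= 3 points, got {len(x)}")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("constant predictor")
    X = sm.add_constant(pd.DataFrame({x_name: x}))
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=0.05)
    coefs = {
        ("intercept" if term == "const" else term): Coefficient(
            term=("intercept" if term == "const" else term),
            estimate=float(res.params[term]),
            se=float(res.bse[term]),
            lower=float(ci.loc[term, 0]),
            upper=float(ci.loc[term, 1]),
        )
        for term in res.params.index
    }
    diagnostics = {}
    if 3 <= len(x) <= 5000:
        diagnostics["shapiro_p"] = float(st.shapiro(res.resid)[1])
    try:
        bp = sm.stats.diagnostic.het_breuschpagan(res.resid, X.values)
        diagnostics["breusch_pagan_p"] = float(bp[1])
    except Exception:  # pragma: no cover - tiny-n edge
        pass
    spec = ModelSpec(response=response, fixed_terms=(x_name,), estimation="OLS")
    return ModelFit(
        spec=spec,
        coefficients=coefs,
        n_obs=len(x),
        loglik=float(res.llf),
        n_params=int(res.df_model + 2),  # slope(s) + intercept + resid var
        aic=float(res.aic),
        r2=float(res.rsquared),
        sigma2_resid=float(res.mse_resid),
        diagnostics=diagnostics,
    )


@dataclass(frozen=True)
class PolynomialCheck:
    decision: str  # "linear" | "quadratic"
    aic_linear: float
    aic_quadratic: float
    delta_aic: float  # aic_linear - aic_quadratic (> 0 favours quadratic)
    f_stat: float
    f_p: float


def compare_polynomial(x, y, delta_aic_threshold: float = 2.0) -> PolynomialCheck:
    """Linear vs linear+quadratic fit, decided by AIC (delta > 2) AND F-test.

    The quadratic term is kept only when both criteria agree; otherwise the
    relationship is treated as linear.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise DegenerateDesignError("polynomial comparison needs >= 4 points")
    X1 = sm.add_constant(np.column_stack([x]))
    X2 = sm.add_constant(np.column_stack([x, x**2]))
    r1 = sm.OLS(y, X1).fit()
    r2 = sm.OLS(y, X2).fit()
    rss1, rss2 = float(r1.ssr), float(r2.ssr)
    df2 = len(x) - 3
    f = (rss1 - rss2) / (rss2 / df2) if rss2 > 0 else np.inf
    p = float(st.f.sf(f, 1, df2))
    delta = float(r1.aic - r2.aic)
    decision = (
        "quadratic" if (delta > delta_aic_threshold and p < 0.05) else "linear"
    )
    return PolynomialCheck(
        decision=decision,
        aic_linear=float(r1.aic),
        aic_quadratic=float(r2.aic),
        delta_aic=delta,
        f_stat=float(f),
        f_p=p,
    )


def refit_excluding(x, y, exclude, x_name: str = "x") -> tuple[ModelFit, ModelFit]:
    """Paired OLS fits with and without the excluded point indices."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    full = fit_ols(x, y, x_name=x_name)
    mask = np.ones(len(x), dtype=bool)
    mask[list(exclude)] = False
    if mask.sum() < 3:
        raise DegenerateDesignError("exclusion leaves fewer than 3 points")
    reduced = fit_ols(x[mask], y[mask], x_name=x_name)
    return full, reduced


def pearson_ci(a, b, alpha: float = 0.05) -> tuple[float, float, float]:
    """Pearson correlation with a Fisher-z 95% CI."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    n = len(a)
    if n < 4:
        raise DomainError(f"pearson_ci needs >= 4 complete pairs, got {n}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DomainError("zero variance in one of the variables")
    r = float(st.pearsonr(a, b)[0])
    if abs(r) >= 1.0 - 1e-12:  # perfectly collinear: degenerate interval
        r = float(np.sign(r))
        return r, r, r
    z = np.arctanh(r)
    half = st.norm.ppf(1 - alpha / 2) / np.sqrt(n - 3)
    return r, float(np.tanh(z - half)), float(np.tanh(z + half))


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per predictor, 1 / (1 - R2_j).

    Perfectly collinear predictors report ``inf``.  Values above 10 are the
    conventional trouble threshold and are logged.
    """
    if design.shape[1] < 2:
        raise DomainError("VIF needs >= 2 predictors")
    if len(design) <= design.shape[1]:
        raise DomainError("VIF needs n > number of predictors")
    out = {}
    for col in design.columns:
        others = sm.add_constant(design.drop(columns=col))
        r2 = sm.OLS(design[col], others).fit().rsquared
        out[col] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    s = pd.Series(out, name="vif")
    high = s[s > 10]
    if len(high):
        logger.warning("high variance inflation (>10): %s", dict(high))
    return s


# ---------------------------------------------------------------------------
# Random-intercept linear mixed models
# ---------------------------------------------------------------------------


def _lmm_param_count(n_fixed: int, random_intercept: bool) -> int:
    return n_fixed + (2 if random_intercept else 1)


def fit_lmm(spec: ModelSpec, data: pd.DataFrame) -> ModelFit:
    """Fit a random-intercept LMM with Wald (normal) 95% CIs.

    Requires complete covariates (rows with missing response or predictors
    are dropped) and at least two groups.  A singular random-effect variance
    is retained but flagged in ``diagnostics['singular']``.
    """
    if spec.random_intercept is None:
        raise DomainError("fit_lmm requires a random intercept; use fit_ols otherwise")
    cols = [spec.response] + [
        c for t in spec.fixed_terms for c in t.split(":")
    ]
    cols = list(dict.fromkeys(cols))
    sub = data.dropna(subset=cols)
    groups = sub[spec.random_intercept]
    if groups.nunique() < 2:
        raise DegenerateDesignError("LMM needs >= 2 grouping levels")
    singleton = (groups.value_counts() == 1).all()
    reml = spec.estimation == "REML"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(spec.formula, sub, groups=groups)
        # Different optimisers can stall at the zero-variance boundary on
        # different datasets; keep the best likelihood across a small ladder.
        candidates = []
        last_exc: Exception | None = None
        for method in ("bfgs", "lbfgs", "powell"):
            try:
                r = model.fit(reml=reml, method=method)
            except Exception as exc:  # singular Hessians etc.
                last_exc = exc
                continue
            llf_r = float(r.llf)
            if r.converged and np.isfinite(llf_r):
                candidates.append((llf_r, r))
        if not candidates:
            raise ConvergenceError(
                f"mixed-model fit failed for {spec.formula}: {last_exc}"
            )
        llf, res = max(candidates, key=lambda t: t[0])
        fe = res.fe_params
        se = res.bse_fe
        s2_random = float(res.cov_re.iloc[0, 0])
        s2_resid = float(res.scale)

    # Profile likelihood of the boundary model (no between-station variance):
    # the LMM nests it, so if it matches or beats the optimiser's optimum the
    # variance is effectively zero and the fit degenerates to iid errors.
    X = np.asarray(res.model.exog, dtype=float)
    yv = np.asarray(res.model.endog, dtype=float)
    ols = sm.OLS(yv, X).fit()
    if reml:
        llf_boundary = _reml_loglik_fixed_only(yv, X)
    else:
        s2_ml = float(ols.ssr / len(yv))
        llf_boundary = -0.5 * len(yv) * (np.log(2 * np.pi * s2_ml) + 1.0)
    singular = (
        llf_boundary >= llf - 1e-6
        or s2_random < 1e-8 * max(s2_resid, 1e-12)
        or not np.all(np.isfinite(np.asarray(se, dtype=float)))
    )
    if singular:
        # Boundary variance parameter stays in the AIC count; estimates and
        # Wald SEs come from the equivalent fixed-effects fit.
        llf = max(llf, llf_boundary)
        fe = pd.Series(np.asarray(ols.params), index=fe.index)
        se = pd.Series(np.asarray(ols.bse), index=fe.index)
        s2_random = 0.0
        s2_resid = float(ols.ssr / len(yv))
    coefs = {
        ("intercept" if t == "Intercept" else t): Coefficient(
            term=("intercept" if t == "Intercept" else t),
            estimate=float(fe[t]),
            se=float(se[t]),
            lower=float(fe[t] - _Z975 * se[t]),
            upper=float(fe[t] + _Z975 * se[t]),
        )
        for t in fe.index
    }
    n_params = _lmm_param_count(len(fe), random_intercept=True)
    aic = -2.0 * llf + 2 * n_params
    fixed_pred = np.asarray(res.model.exog @ fe.values, dtype=float)
    r2m, r2c = r2_mixed(
        sigma2_fixed=float(np.var(fixed_pred)),
        sigma2_random=s2_random,
        sigma2_resid=s2_resid,
    )
    if singular or singleton:
        logger.warning(
            "LMM %s: %s", spec.formula,
            "singular random-effect variance" if singular else
            "one observation per group; variance components unidentifiable",
        )
    return ModelFit(
        spec=spec,
        coefficients=coefs,
        n_obs=int(res.nobs),
        loglik=llf,
        n_params=n_params,
        aic=aic,
        r2_marginal=r2m,
        r2_conditional=r2c,
        sigma2_random=s2_random,
        sigma2_resid=s2_resid,
        diagnostics={"singular": bool(singular), "singleton_groups": bool(singleton)},
    )


def _reml_loglik_fixed_only(y: np.ndarray, X: np.ndarray) -> float:
    """Closed-form REML log-likelihood of the iid-error linear model.

    With V = s2*I profiled at s2 = RSS/(n-p):
    l_R = -0.5 [ (n-p)(ln(2 pi s2) + 1) + ln|X'X| ].
    """
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    s2 = rss / (n - p)
    sign, logdet = np.linalg.slogdet(X.T @ X)
    if sign <= 0:
        raise DegenerateDesignError("singular design matrix")
    return -0.5 * ((n - p) * (np.log(2 * np.pi * s2) + 1.0) + logdet)


@dataclass(frozen=True)
class RandomStructureChoice:
    decision: str  # "with_station" | "without_station"
    aic_with: float
    aic_without: float


def random_structure_choice(
    spec: ModelSpec, data: pd.DataFrame, delta_threshold: float = 2.0
) -> RandomStructureChoice:
    """Decide whether the station random intercept earns its keep.

    Both the fixed-effects-only model and the random-intercept model are
    evaluated under REML (valid: the fixed structure is identical) and the
    random intercept is kept only when its AIC is lower by more than the
    threshold.
    """
    reml_spec = ModelSpec(
        response=spec.response,
        fixed_terms=spec.fixed_terms,
        random_intercept=spec.random_intercept,
        estimation="REML",
    )
    with_fit = fit_lmm(reml_spec, data)
    cols = [spec.response] + [c for t in spec.fixed_terms for c in t.split(":")]
    cols = list(dict.fromkeys(cols))
    sub = data.dropna(subset=cols + [spec.random_intercept])
    import patsy

    ymat, X = patsy.dmatrices(spec.formula, sub, return_type="dataframe")
    ll_fixed = _reml_loglik_fixed_only(
        np.asarray(ymat).ravel(), np.asarray(X, dtype=float)
    )
    k_fixed = _lmm_param_count(X.shape[1], random_intercept=False)
    aic_without = -2.0 * ll_fixed + 2 * k_fixed
    k_with = _lmm_param_count(X.shape[1], random_intercept=True)
    aic_with = -2.0 * with_fit.loglik + 2 * k_with
    decision = (
        "with_station" if aic_with < aic_without - delta_threshold else "without_station"
    )
    logger.info(
        "random-structure choice: AIC with=%0.2f without=%0.2f -> %s",
        aic_with,
        aic_without,
        decision,
    )
    return RandomStructureChoice(decision, aic_with, aic_without)


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

#: The six candidate fixed structures: salinity always retained; the
#: DIN x salinity interaction only alongside the ln DIN main effect.
CANDIDATE_TERMS = (
    ("salinity",),
    ("salinity", "ln_din"),
    ("salinity", "sqrt_silicate"),
    ("salinity", "ln_din", "sqrt_silicate"),
    ("salinity", "ln_din", "ln_din:salinity"),
    ("salinity", "ln_din", "sqrt_silicate", "ln_din:salinity"),
)


def akaike_weights(aics) -> np.ndarray:
    """exp(-delta_i / 2) normalised; anti-monotone in AIC."""
    aics = np.asarray(aics, dtype=float)
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def model_selection(
    data: pd.DataFrame,
    response: str,
    random_intercept: str = "station_id",
    candidates=CANDIDATE_TERMS,
    estimation: str = "ML",
) -> list[ModelFit]:
    """Fit the candidate set, attach AIC weights, sort by AIC.

    A single best model exists iff its AIC is >= 2 below every other; the
    fits within 2 of the minimum form the reported equivalence set, flagged
    in ``diagnostics['in_equivalence_set']``.
    """
    fits = []
    for terms in candidates:
        spec = ModelSpec(
            response=response,
            fixed_terms=terms,
            random_intercept=random_intercept,
            estimation=estimation,
        )
        fits.append(fit_lmm(spec, data))
    weights = akaike_weights([f.aic for f in fits])
    amin = min(f.aic for f in fits)
    for f, w in zip(fits, weights):
        f.aic_weight = float(w)
        f.diagnostics["delta_aic"] = f.aic - amin
        f.diagnostics["in_equivalence_set"] = (f.aic - amin) < 2.0
    fits.sort(key=lambda f: f.aic)
    n_equiv = sum(f.diagnostics["in_equivalence_set"] for f in fits)
    fits[0].diagnostics["single_best"] = n_equiv == 1
    return fits


def r2_mixed(
    sigma2_fixed: float, sigma2_random: float, sigma2_resid: float
) -> tuple[float, float]:
    """Marginal and conditional r2 from variance components.

    r2_m = fixed / (fixed + random + resid); r2_c adds the random-intercept
    variance to the numerator.
    """
    denom = sigma2_fixed + sigma2_random + sigma2_resid
    if denom <= 0:
        return 0.0, 0.0
    return sigma2_fixed / denom, (sigma2_fixed + sigma2_random) / denom


# ---------------------------------------------------------------------------
# Lagged covariates
# ---------------------------------------------------------------------------


def lag_covariates(
    data: pd.DataFrame, variables, lag: int = 1
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replace covariates by their value ``lag`` months earlier.

    Returns ``(lagged, unlagged)`` on the *same* row subset: rows without a
    value for every lagged variable are dropped from both, so lagged and
    unlagged model fits stay comparable.  Calendar wrap is handled (January
    looks up the previous December).
    """
    variables = list(variables)
    if lag == 0:
        return data.copy(), data.copy()
    key = ["station_id", "year", "month"]
    df = data.copy()
    prev_total = df["year"] * 12 + df["month"] - lag
    lookup = df[key + variables].copy()
    lookup["_total"] = lookup["year"] * 12 + lookup["month"]
    lookup = lookup.drop(columns=["year", "month"]).rename(
        columns={v: f"{v}_lagged" for v in variables}
    )
    df["_total"] = prev_total
    merged = df.merge(lookup, on=["station_id", "_total"], how="left")
    lag_cols = [f"{v}_lagged" for v in variables]
    keep = merged.dropna(subset=lag_cols)
    unlagged = keep.drop(columns=lag_cols + ["_total"]).reset_index(drop=True)
    lagged = keep.drop(columns=variables + ["_total"]).rename(
        columns={f"{v}_lagged": v for v in variables}
    )[unlagged.columns].reset_index(drop=True)
    n_dropped = len(df) - len(keep)
    if n_dropped:
        logger.info(
            "lag_covariates: dropped %d row(s) without a previous-month value",
            n_dropped,
        )
    return lagged, unlagged
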