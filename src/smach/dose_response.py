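"""Litter-clustered dose-response modelling and benchmark-dose estimation.

The animal response (anogenital distance normalized by body weight) is
modelled on the transformed dose scale x = log10(dose_multiple + 1) by a
quadratic with a random litter intercept,

    y_il = b0 + b1 x + b2 x^2 + u_l + e_il,   u_l ~ N(0, s_l^2).

The benchmark dose for a fractional decline ``bmr`` relative to the modelled
control mean b0 is the smallest positive root of

    b1 x + b2 x^2 + bmr * b0 = 0,

its standard error follows from the delta method via implicit
differentiation, and the sufficient-similarity radius is the gap between the
benchmark dose and the effective dose of a larger decline (8% by default).
Group-versus-control screening uses a mixed-effects ANOVA with Dunnett
adjustment based on the joint multivariate-t distribution of the contrast
statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "QuadraticFit",
    "BmdResult",
    "dose_scale",
    "back_transform",
    "fit_quadratic_mixed",
    "dunnett_anova",
    "bmd",
    "bmd_se_delta",
    "effective_dose",
    "similarity_radius",
    "bmdl",
    "bmd_analysis",
]


def dose_scale(dose_multiple) -> np.ndarray:
    """x = log10(dose + 1); maps the control dose 0 to x = 0."""
    d = np.asarray(dose_multiple, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose multiples must be non-negative")
    return np.log10(d + 1.0)


def back_transform(x: float) -> float:
    """Inverse of the dose scale: 10**x - 1, in multiples of the 1X anchor."""
    return float(10.0 ** x - 1.0)


@dataclass
class QuadraticFit:
    """Fixed effects and covariance of the litter-clustered quadratic model."""

    beta: np.ndarray  # (b0, b1, b2)
    vcov: np.ndarray  # 3x3 covariance of beta
    litter_variance: float
    residual_variance: float
    n_obs: int
    n_params: int = 3
    method: str = "ml"
    df_resid: int | None = None

    @property
    def df(self) -> int:
        if self.df_resid is not None:
            return self.df_resid
        return self.n_obs - self.n_params

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.beta[0] + self.beta[1] * x + self.beta[2] * x * x


@dataclass
class BmdResult:
    """Benchmark-dose summary on the log10(dose+1) scale."""

    bmr: float
    bmd: float
    se_bmd: float
    bmdl: float
    ed8: float
    radius: float
    df: int
    unstable_se: bool = False

    @property
    def bmd_multiple(self) -> float:
        """BMD back-transformed to multiples of the 1X anchor."""
        return back_transform(self.bmd)

    @property
    def ed8_multiple(self) -> float:
        return back_transform(self.ed8)


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    needed = {"litter_id", "dose_multiple", "response"}
    missing = needed - set(records.columns)
    if missing:
        raise KeyError(f"animal table missing columns: {sorted(missing)}")
    return records.dropna(subset=list(needed))


def fit_quadratic_mixed(
    records: pd.DataFrame,
    method: str = "ml",
    cov_method: str = "litter",
) -> QuadraticFit:
    """Fit the quadratic mixed model by maximum likelihood.

    ``records`` needs columns litter_id, dose_multiple and response.  ML
    estimation (rather than REML) keeps the fixed-effect point estimates
    coherent with the delta-method BMD variance; pass ``method='reml'`` to
    switch.

    Because dose varies only between litters, the dose coefficients are
    whole-litter effects and their plug-in ML covariance (which conditions on
    the estimated variance components) is anti-conservative when litters are
    few.  The default ``cov_method='litter'`` therefore rebuilds the
    fixed-effect covariance at the litter level: litter means are weighted by
    the inverse of their model variance (s_litter^2 + s_resid^2 / n_pups) and
    the covariance is scaled by the observed between-litter dispersion, with
    between-litter degrees of freedom (litters − 3).  ``cov_method='plugin'``
    keeps the raw ML covariance and df = n_obs − 3.

    Degenerate data (an exact polynomial fit where the likelihood is
    singular) fall back to ordinary least squares on the same design, with
    litter variance reported as zero.
    """
    if cov_method not in ("litter", "plugin"):
        raise ValueError("cov_method must be 'litter' or 'plugin'")
    rec = _validate_records(records)
    x = dose_scale(rec["dose_multiple"].to_numpy())
    if np.unique(x).size < 3:
        raise ValueError("at least 3 distinct dose levels are required to "
                         "identify a quadratic")
    y = rec["response"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(x), x, x * x])
    groups = rec["litter_id"].to_numpy()

    reml = method == "reml"
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.MixedLM(y, X, groups=groups)
            fit = model.fit(reml=reml, method="lbfgs")
            if not (np.all(np.isfinite(fit.fe_params))
                    and np.all(np.isfinite(np.asarray(fit.cov_params())[:3, :3]))):
                fit = None
        except (np.linalg.LinAlgError, ValueError, ZeroDivisionError):
            fit = None

    if fit is None:
        # OLS fallback for boundary or degenerate likelihoods (litter
        # variance estimated at zero, or an exact noise-free fit)
        coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < 3:
            raise np.linalg.LinAlgError("singular quadratic design")
        resid = y - X @ coef
        dof = max(y.size - 3, 1)
        sigma2 = float(resid @ resid) / dof
        beta = coef
        litter_var = 0.0
        resid_var = sigma2
        vcov = sigma2 * np.linalg.pinv(X.T @ X)
    else:
        beta = np.asarray(fit.fe_params, dtype=float)
        litter_var = float(np.asarray(fit.cov_re)[0, 0])
        resid_var = float(fit.scale)
        vcov = np.asarray(fit.cov_params(), dtype=float)[:3, :3]
    df_resid = None

    if cov_method == "litter":
        agg = (
            rec.assign(_x=x)
            .groupby("litter_id")
            .agg(x=("_x", "first"), ybar=("response", "mean"), n=("response", "size"))
        )
        n_litters = len(agg)
        if n_litters - 3 >= 1:
            xl = agg["x"].to_numpy()
            Xl = np.column_stack([np.ones_like(xl), xl, xl * xl])
            v_l = litter_var + resid_var / agg["n"].to_numpy()
            if np.all(v_l > 0):
                w = 1.0 / v_l
                r = agg["ybar"].to_numpy() - Xl @ beta
                scale = float((w * r * r).sum()) / (n_litters - 3)
                xtwx = Xl.T @ (w[:, None] * Xl)
                vcov = scale * np.linalg.pinv(xtwx)
                df_resid = n_litters - 3

    return QuadraticFit(
        beta=beta,
        vcov=vcov,
        litter_variance=litter_var,
        residual_variance=resid_var,
        n_obs=int(y.size),
        method=method,
        df_resid=df_resid,
    )


def dunnett_anova(
    records: pd.DataFrame,
    alpha: float = 0.05,
    n_mc: int = 20000,
    mc_seed: int = 12345,
) -> pd.DataFrame:
    """Mixed-effects group-versus-control comparisons with Dunnett adjustment.

    Fits response ~ dose-group dummies with a random litter intercept and
    compares each non-control group mean to the control (dose 0).  Adjusted
    p-values are family-wise: p_adj = P(max_j |T_j| >= |t_obs|) under the
    joint multivariate-t null of the contrast statistics, evaluated by a
    seeded Monte Carlo draw from the estimated contrast correlation (exact
    quadrature is only available for product-correlation designs, which an
    unbalanced litter layout does not guarantee).  Degrees of freedom are the
    between-litter df (number of litters minus number of dose groups), the
    conservative choice for whole-litter contrasts.

    Returns a DataFrame indexed by dose with estimate, se, t, p_adj and a
    significance flag at ``alpha``.
    """
    rec = _validate_records(records)
    doses = np.sort(rec["dose_multiple"].unique())
    if 0.0 not in doses:
        raise ValueError("a control group (dose_multiple == 0) is required")
    if doses.size < 2:
        raise ValueError("at least one non-control dose group is required")
    non_control = doses[doses > 0]

    y = rec["response"].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(rec))]
        + [(rec["dose_multiple"].to_numpy() == d).astype(float) for d in non_control]
    )
    groups = rec["litter_id"].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.MixedLM(y, X, groups=groups).fit(reml=False, method="lbfgs")
            litter_var = float(np.asarray(fit.cov_re)[0, 0])
            resid_var = float(fit.scale)
        except (np.linalg.LinAlgError, ValueError, ZeroDivisionError):
            litter_var, resid_var = 0.0, float(np.var(y))

    # litter-level inference: dose is a whole-litter factor, so contrasts are
    # formed from variance-weighted litter means with between-litter df
    agg = (
        rec.groupby("litter_id")
        .agg(dose=("dose_multiple", "first"), ybar=("response", "mean"),
             n=("response", "size"))
    )
    v_l = litter_var + resid_var / agg["n"].to_numpy()
    if np.any(v_l <= 0):
        v_l = np.full(len(agg), max(float(np.var(agg["ybar"])), 1e-12))
    w_l = 1.0 / v_l
    n_litters = len(agg)
    df = max(n_litters - doses.size, 1)

    group_mean = {}
    group_var_unscaled = {}
    for d in doses:
        mask = (agg["dose"] == d).to_numpy()
        wsum = w_l[mask].sum()
        group_mean[d] = float((w_l[mask] * agg["ybar"].to_numpy()[mask]).sum() / wsum)
        group_var_unscaled[d] = 1.0 / wsum
    resid_lm = agg["ybar"].to_numpy() - np.array([group_mean[d] for d in agg["dose"]])
    scale = float((w_l * resid_lm ** 2).sum()) / df

    est = np.array([group_mean[d] - group_mean[0.0] for d in non_control])
    var_c = scale * group_var_unscaled[0.0]
    var_d = np.array([scale * group_var_unscaled[d] for d in non_control])
    se = np.sqrt(var_d + var_c)
    tvals = est / se
    # contrasts share the control mean: product correlation structure
    V = np.diag(var_d) + var_c

    # joint null of the contrast statistics: multivariate t with the
    # estimated contrast correlation
    denom = np.outer(se, se)
    R = V / denom
    R = (R + R.T) / 2.0
    rng = np.random.default_rng(mc_seed)
    L = np.linalg.cholesky(R + 1e-12 * np.eye(R.shape[0]))
    Z = rng.standard_normal((n_mc, R.shape[0])) @ L.T
    s = rng.chisquare(df, size=n_mc) / df
    maxabs = np.abs(Z / np.sqrt(s)[:, None]).max(axis=1)
    p_adj = np.array([(maxabs >= abs(t)).mean() for t in tvals])

    return pd.DataFrame(
        {
            "estimate": est,
            "se": se,
            "t": tvals,
            "p_adj": p_adj,
            "significant": p_adj < alpha,
        },
        index=pd.Index(non_control, name="dose_multiple"),
    )


def _decline_root(beta: np.ndarray, decline: float) -> float:
    """Smallest positive root of b1 x + b2 x^2 + decline*b0 = 0."""
    b0, b1, b2 = (float(b) for b in beta)
    if not 0 < decline < 1:
        raise ValueError("decline must be in (0, 1)")
    c = decline * b0
    if b2 == 0.0:
        if b1 == 0.0:
            raise ValueError("flat dose-response: benchmark response not reached")
        root = -c / b1
        if root <= 0:
            raise ValueError("benchmark response not reached at a positive dose")
        return root
    disc = b1 * b1 - 4.0 * b2 * c
    if disc < 0:
        raise ValueError("benchmark response not reached (complex roots)")
    sq = np.sqrt(disc)
    roots = np.array([(-b1 - sq) / (2.0 * b2), (-b1 + sq) / (2.0 * b2)])
    pos = roots[roots > 0]
    if pos.size == 0:
        raise ValueError("benchmark response not reached at a positive dose")
    return float(pos.min())


def bmd(fit: QuadraticFit, bmr: float = 0.05) -> float:
    """Benchmark dose: smallest positive x with mu(x) = (1 - bmr) * mu(0)."""
    return _decline_root(fit.beta, bmr)


def _bmd_gradient(beta: np.ndarray, x: float, bmr: float) -> np.ndarray:
    """d x*/d beta by implicit differentiation of F = b1 x + b2 x^2 + bmr b0."""
    _, b1, b2 = (float(b) for b in beta)
    fx = b1 + 2.0 * b2 * x
    return -np.array([bmr, x, x * x]) / fx


def bmd_se_delta(fit: QuadraticFit, bmd_value: float, bmr: float = 0.05):
    """Delta-method standard error of the benchmark dose.

    Returns (se, unstable) where ``unstable`` flags a near-zero slope of the
    defining equation at the root (nearly coincident roots), which makes the
    linearization unreliable.
    """
    g = _bmd_gradient(fit.beta, bmd_value, bmr)
    var = float(g @ fit.vcov @ g)
    fx = fit.beta[1] + 2.0 * fit.beta[2] * bmd_value
    scale = abs(fit.beta[1]) + abs(2.0 * fit.beta[2] * bmd_value)
    unstable = bool(scale > 0 and abs(fx) < 1e-3 * scale)
    if unstable:
        warnings.warn("near-zero discriminant: delta-method SE is unstable",
                      stacklevel=2)
    return float(np.sqrt(max(var, 0.0))), unstable


def effective_dose(fit: QuadraticFit, decline: float) -> float:
    """Dose producing a given fractional decline from the modelled control mean."""
    return _decline_root(fit.beta, decline)


def similarity_radius(bmd_value: float, ed: float) -> float:
    """Radius of the similarity region: ED(larger decline) - BMD."""
    if ed < bmd_value:
        raise ValueError("effective dose below BMD: non-monotone fit")
    return float(ed - bmd_value)


def bmdl(
    bmd_value: float,
    se: float,
    df: int | None,
    level: float = 0.95,
) -> float:
    """One-sided lower confidence bound on the BMD.

    Uses the t quantile at ``level`` with ``df`` degrees of freedom; pass
    ``df=None`` for the normal quantile.
    """
    if se < 0:
        raise ValueError("se must be non-negative")
    if df is None:
        q = stats.norm.ppf(level)
    else:
        if df <= 0:
            raise ValueError("df must be positive")
        q = stats.t.ppf(level, df)
    return float(bmd_value - q * se)


def bmd_analysis(
    records: pd.DataFrame,
    bmr: float = 0.05,
    ed_decline: float = 0.08,
    method: str = "ml",
) -> tuple[QuadraticFit, BmdResult]:
    """Fit the mixed quadratic and derive the full benchmark-dose summary."""
    fit = fit_quadratic_mixed(records, method=method)
    b = bmd(fit, bmr)
    se, unstable = bmd_se_delta(fit, b, bmr)
    ed = effective_dose(fit, ed_decline)
    res = BmdResult(
        bmr=bmr,
        bmd=b,
        se_bmd=se,
        bmdl=bmdl(b, se, fit.df),
        ed8=ed,
        radius=similarity_radius(b, ed),
        df=fit.df,
        unstable_se=unstable,
    )
    return fit, res
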