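"""Weighted quantile sum (WQS) regression and "bad actor" selection.

WQS regresses a continuous outcome on a single empirically weighted index of
quantile-scored exposures,

    y = b0 + b1 * sum_j w_j q_j + covariates + error,
    w_j >= 0,  sum_j w_j = 1,  sign(b1) fixed a priori,

so that the mixture effect is concentrated in one direction and the weights
apportion it across components.  Weights are estimated by an ensemble of
bootstrap fits on a training split; final inference on b1 comes from an
ordinary linear model of the outcome on the fixed final index in a held-out
evaluation split.  Components whose weight exceeds 1/c (c = number of
components) are designated "bad actors".

Numerically the simplex constraint is handled by a softmax
reparameterization and the direction constraint by b1 = sign * exp(theta);
each replicate is an unconstrained smooth least-squares problem solved with
L-BFGS using analytic gradients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

__all__ = [
    "QuantiledMatrix",
    "WqsConfig",
    "WqsResult",
    "BadActorSet",
    "quantile_scores",
    "fit_wqs",
    "select_bad_actors",
]


@dataclass(frozen=True)
class QuantiledMatrix:
    """Integer quantile scores (subjects x components)."""

    scores: np.ndarray
    components: tuple[str, ...]
    n_quantiles: int

    def __post_init__(self) -> None:
        s = self.scores
        if s.ndim != 2 or s.shape[1] != len(self.components):
            raise ValueError("scores must be 2-D with one column per component")
        if s.min() < 0 or s.max() > self.n_quantiles - 1:
            raise ValueError("scores out of range for n_quantiles")


@dataclass(frozen=True)
class WqsConfig:
    """Settings for a WQS fit.

    direction: 'negative' or 'positive' — the a-priori sign of the index
    effect.  split_fraction is the share of subjects used for weight
    estimation (the rest form the evaluation split).  When the training split
    would be too small to support the parameter count, the fit falls back to
    train = evaluate = all subjects and flags the result (`small_sample`).
    signif_weighting: average bootstrap weights weighted by each replicate's
    |t(b1)| (True, default) or unweighted (False).
    """

    direction: str = "negative"
    n_bootstrap: int = 100
    split_fraction: float = 0.4
    n_quantiles: int = 4
    seed: int = 0
    signif_weighting: bool = True

    def __post_init__(self) -> None:
        if self.direction not in ("negative", "positive"):
            raise ValueError("direction must be 'negative' or 'positive'")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")


@dataclass
class WqsResult:
    """Estimated index effect, weights and diagnostics."""

    beta1: float
    se_beta1: float
    p_value: float
    weights: pd.Series
    covariate_coefficients: pd.Series
    intercept: float
    n_components: int
    n_replicates_used: int
    small_sample: bool = False
    direction: str = "negative"
    dropped_replicates: int = 0

    @property
    def threshold(self) -> float:
        return 1.0 / self.n_components


@dataclass(frozen=True)
class BadActorSet:
    """Components whose weight strictly exceeds the 1/c threshold."""

    components: tuple[str, ...]
    threshold: float
    weights: pd.Series = field(repr=False, default=None)

    def __contains__(self, name: str) -> bool:
        return name in self.components


def quantile_scores(
    data: pd.DataFrame | np.ndarray,
    n_quantiles: int = 4,
    components: Sequence[str] | None = None,
) -> QuantiledMatrix:
    """Score each component into empirical quantile bins 0..n_quantiles-1.

    Bin edges are the empirical quantiles at k/n_quantiles; values tied with
    an edge fall in the lower bin.  A constant column cannot be binned and
    yields all-zero scores with a warning.
    """
    if isinstance(data, pd.DataFrame):
        cols = tuple(data.columns)
        mat = data.to_numpy(dtype=float)
    else:
        mat = np.asarray(data, dtype=float)
        if mat.ndim == 1:
            mat = mat[:, None]
        cols = tuple(components) if components is not None else tuple(
            f"x{j}" for j in range(mat.shape[1])
        )
    scores = np.empty(mat.shape, dtype=np.int64)
    probs = np.arange(1, n_quantiles) / n_quantiles
    for j in range(mat.shape[1]):
        col = mat[:, j]
        if np.ptp(col) == 0:
            warnings.warn(
                f"component {cols[j]!r} is constant; all scores set to 0",
                stacklevel=2,
            )
            scores[:, j] = 0
            continue
        cuts = np.quantile(col, probs)
        scores[:, j] = np.searchsorted(cuts, col, side="left")
    return QuantiledMatrix(scores=scores, components=cols, n_quantiles=n_quantiles)


def _softmax(t: np.ndarray) -> np.ndarray:
    t = t - t.max()
    e = np.exp(t)
    return e / e.sum()


def _replicate_objective(Q: np.ndarray, y: np.ndarray, X: np.ndarray, sign: float):
    """Closure returning (sse, gradient) for the softmax/exp parameterization."""
    c = Q.shape[1]
    k = X.shape[1]

    def fun(p: np.ndarray):
        w = _softmax(p[:c])
        b1 = sign * np.exp(min(p[c], 30.0))
        b0 = p[c + 1]
        g = p[c + 2:]
        z = Q @ w
        r = y - b0 - b1 * z - (X @ g if k else 0.0)
        sse = float(r @ r)
        grad = np.empty(c + 2 + k)
        dw = -2.0 * b1 * (Q.T @ r)
        grad[:c] = w * (dw - w @ dw)  # softmax Jacobian
        grad[c] = -2.0 * b1 * (r @ z)
        grad[c + 1] = -2.0 * r.sum()
        if k:
            grad[c + 2:] = -2.0 * (X.T @ r)
        return sse, grad

    return fun


def _linear_fit(y: np.ndarray, design: np.ndarray):
    """OLS coefficients, standard errors and residual df via least squares."""
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    df = y.size - design.shape[1]
    if df <= 0 or rank < design.shape[1]:
        return coef, np.full(design.shape[1], np.nan), df
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.pinv(design.T @ design)
    se = np.sqrt(np.clip(sigma2 * np.diag(xtx_inv), 0, np.inf))
    return coef, se, df


def fit_wqs(
    q: QuantiledMatrix,
    outcome: np.ndarray | pd.Series,
    covariates: pd.DataFrame | np.ndarray | None,
    cfg: WqsConfig,
) -> WqsResult:
    """Fit WQS regression with bootstrap weight estimation and split inference.

    Complete cases only: rows with any NaN in outcome or covariates are
    dropped.  Each bootstrap replicate resamples the training split, solves
    the sign- and simplex-constrained least-squares problem, and contributes
    its weight vector; the final weights are the |t|-weighted (or plain)
    average over replicates.  The reported b1/SE/p come from an OLS fit of
    the outcome on the fixed final index plus covariates in the evaluation
    split (two-sided p).
    """
    y = np.asarray(outcome, dtype=float)
    Q = q.scores.astype(float)
    if covariates is None:
        X = np.empty((y.size, 0))
        cov_names: tuple[str, ...] = ()
    elif isinstance(covariates, pd.DataFrame):
        cov_names = tuple(covariates.columns)
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        cov_names = tuple(f"c{j}" for j in range(X.shape[1]))

    keep = np.isfinite(y)
    if X.shape[1]:
        keep &= np.isfinite(X).all(axis=1)
    y, Q, X = y[keep], Q[keep], X[keep]
    n, c = Q.shape
    k = X.shape[1]
    sign = -1.0 if cfg.direction == "negative" else 1.0
    rng = np.random.default_rng(cfg.seed)

    n_train = int(round(cfg.split_fraction * n))
    small_sample = n_train < 5 * (c + k + 2)
    if small_sample:
        warnings.warn(
            "training split too small to support the model; "
            "using all subjects for both weight estimation and inference",
            stacklevel=2,
        )
        train_idx = eval_idx = np.arange(n)
    else:
        perm = rng.permutation(n)
        train_idx, eval_idx = perm[:n_train], perm[n_train:]

    yt, Qt, Xt = y[train_idx], Q[train_idx], X[train_idx]
    nt = yt.size

    # scale-aware starting magnitude for |b1|
    tb0 = np.log(max(np.std(yt) / max(q.n_quantiles - 1, 1), 1e-3))
    p0 = np.zeros(c + 2 + k)
    p0[c] = tb0
    p0[c + 1] = float(np.mean(yt))

    weight_stack = []
    t_stats = []
    dropped = 0
    for _ in range(cfg.n_bootstrap):
        idx = rng.integers(0, nt, size=nt)
        yb, Qb, Xb = yt[idx], Qt[idx], Xt[idx]
        try:
            res = minimize(
                _replicate_objective(Qb, yb, Xb, sign),
                p0,
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": 500},
            )
            w_b = _softmax(res.x[:c])
            if not np.all(np.isfinite(w_b)):
                raise FloatingPointError("non-finite weights")
            # replicate-level t statistic for b1 from OLS on the fixed index
            design = np.column_stack([np.ones(nt), Qb @ w_b, Xb])
            coef, se, df = _linear_fit(yb, design)
            tval = coef[1] / se[1] if np.isfinite(se[1]) and se[1] > 0 else 0.0
        except (np.linalg.LinAlgError, FloatingPointError, ValueError):
            dropped += 1
            continue
        weight_stack.append(w_b)
        t_stats.append(abs(tval))
    if not weight_stack:
        raise RuntimeError("all bootstrap replicates failed to converge")

    W = np.vstack(weight_stack)
    tarr = np.asarray(t_stats)
    if cfg.signif_weighting and tarr.sum() > 0:
        w_final = (W * tarr[:, None]).sum(axis=0) / tarr.sum()
    else:
        w_final = W.mean(axis=0)
    w_final = w_final / w_final.sum()

    ye, Qe, Xe = y[eval_idx], Q[eval_idx], X[eval_idx]
    design = np.column_stack([np.ones(ye.size), Qe @ w_final, Xe])
    coef, se, df = _linear_fit(ye, design)
    beta1, se_beta1 = float(coef[1]), float(se[1])
    p_value = float(2.0 * stats.t.sf(abs(beta1 / se_beta1), df)) if se_beta1 > 0 else np.nan

    return WqsResult(
        beta1=beta1,
        se_beta1=se_beta1,
        p_value=p_value,
        weights=pd.Series(w_final, index=list(q.components), name="weight"),
        covariate_coefficients=pd.Series(coef[2:], index=list(cov_names)),
        intercept=float(coef[0]),
        n_components=c,
        n_replicates_used=len(weight_stack),
        small_sample=small_sample,
        direction=cfg.direction,
        dropped_replicates=dropped,
    )


def select_bad_actors(result: WqsResult) -> BadActorSet:
    """Components with weight strictly above 1/c, in input order."""
    thr = result.threshold
    selected = tuple(
        name for name, w in result.weights.items() if w > thr
    )
    return BadActorSet(components=selected, threshold=thr, weights=result.weights)
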