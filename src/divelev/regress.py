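"""Regression engines for band statistics.

Two model families are used:

* **Beta regression** (logit mean link, constant precision φ) for DivElev,
  which lives in (0, 1) after boundary compression.  Goodness of fit is the
  Ferrari–Cribari-Neto pseudo-R²: the squared Pearson correlation between
  the linear predictor and the logit of the observed response.
* **Poisson-family GLM with identity link** for AgeElev.  The response is a
  continuous mean age (Ma), so the fit is quasi-likelihood scoring with the
  Poisson variance function and the deviance formula extended continuously;
  an optional integer-rounding mode gives a strict Poisson likelihood.
  Fit quality is the Kullback–Leibler (deviance-ratio) R² = 1 − D/D₀.

Model comparison uses likelihood-ratio tests of nested fits and the
small-sample corrected Akaike criterion AICc.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.othermod.betareg import BetaModel
from statsmodels.tools.sm_exceptions import DomainWarning

__all__ = [
    "BetaFit",
    "GLMFit",
    "ModelComparison",
    "beta_fit",
    "pseudo_r2",
    "glm_fit",
    "quadratic_vertex",
    "lr_test",
    "aicc",
    "design_matrix",
    "compress_unit_interval",
]


def _logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p / (1.0 - p))


def compress_unit_interval(y: np.ndarray) -> np.ndarray:
    """Smithson–Verkuilen compression (y·(n−1) + 0.5)/n.

    Applied to the whole response vector whenever any value sits on a
    boundary of [0, 1], so that e.g. bands holding only monospecific genera
    (DivElev = 0) remain usable by the beta likelihood.
    """
    y = np.asarray(y, dtype=float)
    if y.min() < 0 or y.max() > 1:
        raise ValueError("responses must lie in [0, 1] before compression")
    if 0 < y.min() and y.max() < 1:
        return y
    n = len(y)
    return (y * (n - 1) + 0.5) / n


@dataclass
class BetaFit:
    terms: list[str]              # mean-model column names, intercept first
    params: pd.Series             # mean-model coefficients (logit link)
    bse: pd.Series
    pvalues: pd.Series
    phi: float                    # precision
    loglik: float
    pseudo_r2: float | None
    n: int
    k: int                        # mean coefficients + precision
    linpred: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)

    @property
    def aicc(self) -> float:
        return aicc(self.loglik, self.k, self.n)


@dataclass
class GLMFit:
    terms: list[str]
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    deviance: float
    null_deviance: float
    loglik: float
    aic: float
    aicc: float
    kl_r2: float
    n: int
    k: int
    fitted: np.ndarray = field(repr=False, default=None)


@dataclass
class ModelComparison:
    statistic: float
    df: int
    p: float
    delta_aicc: float | None
    preferred: str


def design_matrix(df: pd.DataFrame, formula: str) -> tuple[np.ndarray, pd.DataFrame, str]:
    """Parse a small formula like ``"div_elev ~ bio1 + bio1^2"``.

    Terms are column names, optionally squared/cubed with ``^k``.  Returns
    (response vector, predictor frame without intercept, response name).
    """
    lhs, _, rhs = formula.partition("~")
    resp = lhs.strip()
    if not resp or not rhs.strip():
        raise ValueError(f"cannot parse formula {formula!r}")
    cols = {}
    for term in rhs.split("+"):
        term = term.strip()
        if not term:
            continue
        if "^" in term:
            base, power = term.split("^")
            cols[term] = df[base.strip()].to_numpy(dtype=float) ** int(power)
        else:
            cols[term] = df[term].to_numpy(dtype=float)
    X = pd.DataFrame(cols)
    y = df[resp].to_numpy(dtype=float)
    keep = np.isfinite(y) & np.isfinite(X.to_numpy()).all(axis=1)
    return y[keep], X[keep].reset_index(drop=True), resp


def beta_fit(X: pd.DataFrame, y, compress: bool = True) -> BetaFit:
    """ML beta regression with logit mean link and constant precision.

    ``X`` holds the named predictor columns (no intercept column; one is
    added).  Responses on the boundary of [0, 1] are compressed first
    (see :func:`compress_unit_interval`) unless ``compress=False``, in which
    case boundary values raise.
    """
    y = np.asarray(y, dtype=float)
    if compress:
        y = compress_unit_interval(y)
    if y.min() <= 0 or y.max() >= 1:
        raise ValueError("responses must lie strictly inside (0, 1)")
    X = pd.DataFrame(X).reset_index(drop=True)
    exog = sm.add_constant(X, has_constant="add")
    n, p = exog.shape
    if n <= p + 1:
        raise ValueError(f"too few observations (n={n}) for {p} mean terms")
    b_exact, *_ = np.linalg.lstsq(exog.to_numpy(dtype=float), _logit(y), rcond=None)
    if np.allclose(_logit(y), exog.to_numpy() @ b_exact, atol=1e-10):
        # degenerate inputs (constant y, or y exactly on the logistic curve):
        # the mean model fits exactly and the ML precision diverges, so the
        # analytic limit is returned instead of chasing phi -> infinity
        terms = ["const"] + list(X.columns)
        fit = BetaFit(
            terms=terms, params=pd.Series(b_exact, index=terms),
            bse=pd.Series(0.0, index=terms),
            pvalues=pd.Series(np.nan, index=terms),
            phi=np.inf, loglik=np.inf, pseudo_r2=None, n=n, k=p + 1,
            linpred=exog.to_numpy() @ b_exact, y=y,
        )
        fit.pseudo_r2 = pseudo_r2(fit, y)
        return fit
    model = BetaModel(y, exog)
    # deterministic initializer: least squares on logit(y) for the mean
    # coefficients, method of moments for the precision
    Xa = exog.to_numpy(dtype=float)
    b0, *_ = np.linalg.lstsq(Xa, _logit(y), rcond=None)
    mu0 = 1.0 / (1.0 + np.exp(-(Xa @ b0)))
    s2 = float(np.var(y - mu0))
    phi0 = max(float(np.mean(mu0 * (1 - mu0))) / max(s2, 1e-12) - 1.0, 2.0)
    start = np.r_[b0, np.log(phi0)]
    # Newton can land on a spurious stationary point from a poor curvature
    # region, so every optimizer is tried and the best converged solution
    # kept; the ascent check below rejects anything worse than the start
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("newton", "lbfgs", "bfgs"):
            try:
                cand = model.fit(start_params=start, method=method,
                                 maxiter=500, disp=False)
            except (ValueError, np.linalg.LinAlgError):
                continue
            if (cand.mle_retvals.get("converged", False)
                    and np.isfinite(cand.params.to_numpy()).all()
                    and (res is None or cand.llf > res.llf)):
                res = cand
    if res is None:
        raise RuntimeError("beta regression did not converge")
    ll_start = float(model.loglike(start))
    if float(res.llf) < ll_start - 1e-6:  # ascent check on the optimizer
        raise RuntimeError("beta regression ended below its initializer")
    mean_params = res.params[: p]
    linpred = exog.to_numpy() @ mean_params.to_numpy()
    phi = float(np.exp(res.params.iloc[p]))  # precision uses a log link
    terms = ["const"] + list(X.columns)
    fit = BetaFit(
        terms=terms,
        params=pd.Series(mean_params.to_numpy(), index=terms),
        bse=pd.Series(res.bse[:p].to_numpy(), index=terms),
        pvalues=pd.Series(res.pvalues[:p].to_numpy(), index=terms),
        phi=phi,
        loglik=float(res.llf),
        pseudo_r2=None,
        n=n,
        k=p + 1,
        linpred=linpred,
        y=y,
    )
    fit.pseudo_r2 = pseudo_r2(fit, y)
    return fit


def pseudo_r2(fit: BetaFit, y=None) -> float | None:
    """Ferrari–Cribari-Neto pseudo-R²: corr(η̂, logit y)².

    Returns None (reported as missing) when either vector has zero
    variance, where the correlation is undefined.
    """
    y = fit.y if y is None else np.asarray(y, dtype=float)
    eta = fit.linpred
    gy = _logit(y)
    if np.std(eta) == 0 or np.std(gy) == 0:
        return None
    r = np.corrcoef(eta, gy)[0, 1]
    return float(r * r)


def glm_fit(X: pd.DataFrame, y, round_response: bool = False) -> GLMFit:
    """Identity-link GLM with Poisson variance for nonnegative responses.

    Continuous responses are handled as quasi-likelihood scoring (the
    Poisson deviance extends continuously); ``round_response=True`` rounds y
    to integers first for a strict Poisson likelihood.  Fitted means are
    kept positive by step-halving inside the IRLS; a fit whose means are
    driven to zero raises.
    """
    y = np.asarray(y, dtype=float)
    if (y < 0).any():
        raise ValueError("responses must be nonnegative")
    if round_response:
        y = np.round(y)
    X = pd.DataFrame(X).reset_index(drop=True)
    exog = sm.add_constant(X, has_constant="add")
    n, p = exog.shape
    if n <= p:
        raise ValueError(f"too few observations (n={n}) for {p} terms")
    Xa = exog.to_numpy(dtype=float)
    start, *_ = np.linalg.lstsq(Xa, y, rcond=None)
    mu0 = Xa @ start
    if mu0.min() <= 0:  # shift intercept so scoring starts in the domain
        start = start.copy()
        start[0] += 1e-3 - mu0.min()
    with warnings.catch_warnings():
        # the identity link is non-canonical for Poisson (DomainWarning) and a
        # zero-deviance fit trips a separation warning; both are checked for
        # explicitly below instead
        warnings.simplefilter("ignore")
        model = sm.GLM(y, exog, family=sm.families.Poisson(sm.families.links.Identity()))
        try:
            res = model.fit(start_params=start, maxiter=200)
        except (ValueError, np.linalg.LinAlgError) as exc:
            raise RuntimeError(f"identity-link Poisson fit failed: {exc}") from exc
    if np.any(res.fittedvalues <= 0):
        raise RuntimeError("fitted means driven to <= 0; identity link untenable here")
    null_dev = float(res.null_deviance)
    # intercept-only fits have D = D0, so the deviance ratio carries no
    # information: KL-R2 is 0 by convention (also guards 0/0)
    if X.shape[1] == 0 or null_dev <= 1e-10:
        kl = 0.0
    else:
        kl = max(0.0, 1.0 - float(res.deviance) / null_dev)
    terms = ["const"] + list(X.columns)
    k = p
    return GLMFit(
        terms=terms,
        params=pd.Series(res.params.to_numpy(), index=terms),
        bse=pd.Series(res.bse.to_numpy(), index=terms),
        pvalues=pd.Series(res.pvalues.to_numpy(), index=terms),
        deviance=float(res.deviance),
        null_deviance=null_dev,
        loglik=float(res.llf),
        aic=float(-2 * res.llf + 2 * k),
        aicc=aicc(float(res.llf), k, n),
        kl_r2=kl,
        n=n,
        k=k,
        fitted=np.asarray(res.fittedvalues),
    )


def quadratic_vertex(beta1: float, beta2: float) -> tuple[float, str]:
    """Stationary point −β₁/(2β₂) of a quadratic predictor.

    Returns the location and whether it is a ``"maximum"`` (β₂ < 0) or
    ``"minimum"`` (β₂ > 0); β₂ = 0 has no vertex and raises.
    """
    if beta2 == 0:
        raise ValueError("quadratic coefficient is zero: no vertex")
    return -beta1 / (2.0 * beta2), ("maximum" if beta2 < 0 else "minimum")


def _fit_terms(fit) -> set[str]:
    return set(fit.terms)


def lr_test(fit_small, fit_large, alpha: float = 0.05) -> ModelComparison:
    """Likelihood-ratio test of nested fits (smaller within larger).

    The statistic is 2(ℓ_large − ℓ_small) on χ² with df = Δk.  ΔAICc
    (small − large) is reported whenever both fits carry an AICc.
    """
    small_terms, large_terms = _fit_terms(fit_small), _fit_terms(fit_large)
    if not small_terms <= large_terms:
        raise ValueError(
            f"models are not nested: {sorted(small_terms - large_terms)} "
            "only in the smaller model"
        )
    df = fit_large.k - fit_small.k
    stat = 2.0 * (fit_large.loglik - fit_small.loglik)
    if stat < 0 and stat > -1e-8:
        stat = 0.0
    p = 1.0 if df == 0 else float(st.chi2.sf(stat, df))
    if df == 0 and stat == 0:
        p = 1.0
    try:
        d_aicc = fit_small.aicc - fit_large.aicc
    except Exception:
        d_aicc = None
    preferred = "large" if (df > 0 and p < alpha) else "small"
    return ModelComparison(statistic=float(stat), df=df, p=p,
                           delta_aicc=d_aicc, preferred=preferred)


def aicc(logL: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike criterion −2ℓ + 2k + 2k(k+1)/(n−k−1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * logL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)
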