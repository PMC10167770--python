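"""Ridge-regression BLUP for hybrid genomic prediction.

The partial (additive-only) model is

    y = 1 mu + K_A a + eps,    a ~ N(0, sigma2_a I),  eps ~ N(0, sigma2_e I)

which is equivalent to a GBLUP with kernel G_A = K_A K_A'.  The variance
ratio lambda = sigma2_e / sigma2_a is estimated by restricted maximum
likelihood via a single spectral decomposition of the intercept-projected
kernel, after which marker effects follow in closed form:

    a_hat = K_A' (G_A + lambda I)^-1 (y - 1 mu_hat)

with mu_hat the generalized-least-squares intercept.  The full model adds
dominance, y = 1 mu + K_A a + K_D d + eps with d ~ N(0, sigma2_d I); its
two variance ratios are found by derivative-free search over log ratios
with the residual variance profiled out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

# keeps lambda finite when a variance component collapses
_VAR_FLOOR_FRACTION = 1e-9
_RATIO_LOG_BOUNDS = (-20.0, 20.0)


@dataclass
class GPModelFit:
    """Fitted genomic prediction model.

    ``a`` (and ``d`` for the full model) are marker-effect vectors indexed
    by marker ID; ``mu`` is the sole fixed effect (the grand mean of hybrid
    entry means); variances are on the phenotype scale.
    """

    mu: float
    a: pd.Series
    d: pd.Series | None
    var_a: float
    var_d: float | None
    var_e: float
    model: str  # "partial" | "full"

    @property
    def markers(self) -> list[str]:
        return list(self.a.index)


def _as_matrix(k) -> tuple[np.ndarray, list[str]]:
    if isinstance(k, pd.DataFrame):
        return k.to_numpy(dtype=float), [str(c) for c in k.columns]
    k = np.asarray(k, dtype=float)
    return k, [f"m{j}" for j in range(k.shape[1])]


def _as_response(y, n_expected: int) -> np.ndarray:
    arr = np.asarray(y.to_numpy() if isinstance(y, pd.Series) else y, dtype=float)
    if arr.ndim != 1 or len(arr) != n_expected:
        raise ValueError(
            f"response length {arr.shape} does not match {n_expected} design rows"
        )
    return arr


def _projected_spectrum(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenpairs of S(G+I)S restricted to the complement of the intercept,
    returned as (theta, U) with theta the eigenvalues of the projected G."""
    n = g.shape[0]
    s = np.eye(n) - np.full((n, n), 1.0 / n)
    vals, vecs = np.linalg.eigh(s @ (g + np.eye(n)) @ s)
    # exactly one eigenvalue belongs to the projected-out intercept (= 0)
    keep = np.argsort(vals)[1:]
    theta = np.maximum(vals[keep] - 1.0, 0.0)
    return theta, vecs[:, keep]


def _reml_lambda(y: np.ndarray, g: np.ndarray) -> float:
    """REML estimate of lambda = sigma2_e / sigma2_a for one kernel."""
    n = len(y)
    theta, u = _projected_spectrum(g)
    eta2 = (u.T @ y) ** 2

    def crit(log_lam: float) -> float:
        lam = np.exp(log_lam)
        denom = theta + lam
        return float((n - 1) * np.log(np.sum(eta2 / denom)) + np.sum(np.log(denom)))

    res = optimize.minimize_scalar(
        crit, bounds=_RATIO_LOG_BOUNDS, method="bounded",
        options={"xatol": 1e-8},
    )
    return float(np.exp(res.x))


def fit_partial(y, k_a, *, lambda_: float | None = None) -> GPModelFit:
    """Fit the additive-only RR-BLUP model to hybrid entry means.

    Parameters
    ----------
    y
        Per-hybrid means, aligned with the rows of ``k_a``.
    k_a
        Additive design matrix (hybrids x markers), DataFrame or array.
    lambda_
        Optional fixed variance ratio sigma2_e / sigma2_a; when omitted it
        is estimated by REML.
    """
    ka, marker_ids = _as_matrix(k_a)
    n = ka.shape[0]
    if n < 3:
        raise ValueError("need at least 3 hybrids to fit")
    yv = _as_response(y, n)
    if np.var(yv) == 0:
        raise ValueError("constant response: genetic variance unidentifiable")

    g = ka @ ka.T
    lam = _reml_lambda(yv, g) if lambda_ is None else float(lambda_)
    theta, u = _projected_spectrum(g)
    eta2 = (u.T @ yv) ** 2
    var_a = float(np.sum(eta2 / (theta + lam)) / (n - 1))
    var_a = max(var_a, _VAR_FLOOR_FRACTION * float(np.var(yv)))
    var_e = lam * var_a

    h = g + lam * np.eye(n)
    hinv_y = np.linalg.solve(h, yv)
    hinv_1 = np.linalg.solve(h, np.ones(n))
    mu = float(np.sum(hinv_y) / np.sum(hinv_1))
    a_hat = ka.T @ np.linalg.solve(h, yv - mu)
    return GPModelFit(
        mu=mu,
        a=pd.Series(a_hat, index=marker_ids, name="additive_effect"),
        d=None,
        var_a=var_a,
        var_d=None,
        var_e=var_e,
        model="partial",
    )


def fit_full(y, k_a, k_d) -> GPModelFit:
    """Fit the additive + dominance RR-BLUP model.

    The restricted likelihood is maximized over the two log variance ratios
    (gamma_a, gamma_d) = (sigma2_a, sigma2_d) / sigma2_e by Nelder-Mead
    (start at log 0.5, function tolerance 1e-6 on the log-likelihood scale),
    profiling out sigma2_e; effect vectors are recovered by back-solving.
    """
    ka, marker_ids = _as_matrix(k_a)
    kd, marker_ids_d = _as_matrix(k_d)
    if ka.shape != kd.shape:
        raise ValueError("K_A and K_D must share hybrids and markers")
    n = ka.shape[0]
    if n < 3:
        raise ValueError("need at least 3 hybrids to fit")
    yv = _as_response(y, n)
    if np.var(yv) == 0:
        raise ValueError("constant response: genetic variance unidentifiable")
    if not kd.any():
        warnings.warn(
            "K_D is identically zero; falling back to the partial model",
            stacklevel=2,
        )
        return fit_partial(yv, k_a)

    g_a = ka @ ka.T
    g_d = kd @ kd.T
    eye = np.eye(n)
    ones = np.ones(n)

    def neg_rll(log_gammas: np.ndarray) -> float:
        if np.any(np.abs(log_gammas) > _RATIO_LOG_BOUNDS[1]):
            return np.inf
        ga, gd = np.exp(log_gammas)
        v0 = ga * g_a + gd * g_d + eye
        try:
            c = np.linalg.cholesky(v0)
        except np.linalg.LinAlgError:
            return np.inf
        vi_y = np.linalg.solve(v0, yv)
        vi_1 = np.linalg.solve(v0, ones)
        xtvx = float(ones @ vi_1)
        mu = float(ones @ vi_y) / xtvx
        resid = yv - mu
        quad = float(resid @ np.linalg.solve(v0, resid))
        sigma2 = quad / (n - 1)
        logdet_v = 2.0 * float(np.sum(np.log(np.diag(c))))
        return 0.5 * ((n - 1) * np.log(sigma2) + logdet_v + np.log(xtvx))

    res = optimize.minimize(
        neg_rll,
        x0=np.log([0.5, 0.5]),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-6, "maxiter": 4000},
    )
    gam_a, gam_d = np.exp(res.x)
    v0 = gam_a * g_a + gam_d * g_d + eye
    vi_y = np.linalg.solve(v0, yv)
    vi_1 = np.linalg.solve(v0, ones)
    mu = float(ones @ vi_y) / float(ones @ vi_1)
    resid_rot = np.linalg.solve(v0, yv - mu)
    var_e = float((yv - mu) @ resid_rot) / (n - 1)
    var_e = max(var_e, _VAR_FLOOR_FRACTION * float(np.var(yv)))
    a_hat = gam_a * (ka.T @ resid_rot)
    d_hat = gam_d * (kd.T @ resid_rot)
    return GPModelFit(
        mu=mu,
        a=pd.Series(a_hat, index=marker_ids, name="additive_effect"),
        d=pd.Series(d_hat, index=marker_ids_d, name="dominance_effect"),
        var_a=gam_a * var_e,
        var_d=gam_d * var_e,
        var_e=var_e,
        model="full",
    )


def predict(fit: GPModelFit, k_a_new, k_d_new=None) -> pd.DataFrame:
    """Genomic estimated breeding values for new hybrids.

    Returns a table with the predicted genetic value (``gebv``) and the
    predicted phenotype (``mu + gebv``), one row per input hybrid row.
    """
    ka, _ = _as_matrix(k_a_new)
    if ka.shape[1] != len(fit.a):
        raise ValueError(
            f"design has {ka.shape[1]} markers but fit has {len(fit.a)}"
        )
    value = ka @ fit.a.to_numpy()
    if fit.model == "full":
        if k_d_new is None:
            raise ValueError("full-model prediction requires K_D rows")
        kd, _ = _as_matrix(k_d_new)
        if kd.shape != ka.shape:
            raise ValueError("K_D rows must match K_A rows")
        value = value + kd @ fit.d.to_numpy()
    index = k_a_new.index if isinstance(k_a_new, pd.DataFrame) else None
    return pd.DataFrame(
        {"gebv": value, "predicted_phenotype": fit.mu + value}, index=index
    )
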