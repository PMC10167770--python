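"""Variance components and broad-sense heritability from multi-environment
replicated hybrid trials.

The trial model is

    y_ijk = mu + g_i + e_j + (ge)_ij + r_k(j) + eps_ijk

with genotype g_i and genotype-by-environment (ge)_ij random, environment
e_j and replicate-within-environment r_k(j) fixed, and a homogeneous
residual.  For balanced data the components are solved in closed form from
the expected mean squares of the genotype, genotype x environment and
residual strata:

    E[MS_G]  = sigma2_e + r * sigma2_ge + e * r * sigma2_g
    E[MS_GE] = sigma2_e + r * sigma2_ge
    E[MS_R]  = sigma2_e

Unbalanced tables go through a restricted-maximum-likelihood fit of the
same model.  Broad-sense heritability on an entry-mean basis is

    H = sigma2_g / (sigma2_g + sigma2_ge / e + sigma2_e / (e * r)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

PHENOTYPE_COLUMNS = ("hybrid", "environment", "replicate", "trait", "value")


def validate_phenotypes(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format phenotype table contract and return it."""
    missing = [c for c in PHENOTYPE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    keys = ["hybrid", "environment", "replicate", "trait"]
    if table.duplicated(subset=keys).any():
        raise ValueError("duplicate (hybrid, environment, replicate, trait) keys")
    if not np.isfinite(table["value"].to_numpy(dtype=float)).all():
        raise ValueError("non-finite phenotype values")
    return table


@dataclass
class VarianceComponents:
    """Estimated variance components for one trait.

    ``var_g`` genetic, ``var_ge`` genotype-by-environment, ``var_e``
    residual variance (all >= 0 after truncation); ``n_reps`` replicates
    per environment and ``n_envs`` environments as found in the data.
    """

    var_g: float
    var_ge: float
    var_e: float
    n_reps: int
    n_envs: int
    trait: str = ""
    method: str = "moments"

    def __post_init__(self) -> None:
        if min(self.var_g, self.var_ge, self.var_e) < 0:
            raise ValueError("variance components must be non-negative")
        if self.n_reps < 1 or self.n_envs < 1:
            raise ValueError("replicate and environment counts must be >= 1")

    @property
    def heritability(self) -> float:
        return broad_sense_heritability(self)


def broad_sense_heritability(vc: VarianceComponents) -> float:
    """Entry-mean broad-sense heritability, clipped to [0, 1]."""
    e, r = vc.n_envs, vc.n_reps
    denom = vc.var_g + vc.var_ge / e + vc.var_e / (e * r)
    if denom <= 0:
        raise ValueError("all variance components are zero: H undefined")
    return float(np.clip(vc.var_g / denom, 0.0, 1.0))


def hybrid_means(phenotypes: pd.DataFrame, trait: str) -> pd.Series:
    """Arithmetic mean over all environment x replicate observations per
    hybrid — the response vector for the genomic prediction models."""
    sub = phenotypes.loc[phenotypes["trait"] == trait]
    if sub.empty:
        raise KeyError(f"trait {trait!r} not present in phenotype table")
    means = sub.groupby("hybrid", sort=False)["value"].mean()
    means.name = trait
    return means


def _is_balanced(sub: pd.DataFrame) -> bool:
    counts = sub.groupby(["hybrid", "environment"], sort=False)["value"].count()
    if counts.nunique() != 1:
        return False
    n_hyb = sub["hybrid"].nunique()
    n_env = sub["environment"].nunique()
    return len(counts) == n_hyb * n_env


def estimate_components(
    phenotypes: pd.DataFrame,
    trait: str,
    method: str = "auto",
) -> VarianceComponents:
    """Estimate (sigma2_g, sigma2_ge, sigma2_e) for one trait.

    ``method`` is "moments" (balanced closed form), "reml" (iterative,
    works unbalanced) or "auto" (moments when balanced, else reml).
    Negative moment estimates are truncated to zero.
    """
    validate_phenotypes(phenotypes)
    sub = phenotypes.loc[phenotypes["trait"] == trait]
    if sub.empty:
        raise KeyError(f"trait {trait!r} not present in phenotype table")
    n_hyb = sub["hybrid"].nunique()
    n_env = sub["environment"].nunique()
    if n_hyb < 2 or n_env < 2:
        raise ValueError("need >= 2 hybrids and >= 2 environments")
    balanced = _is_balanced(sub)
    if method == "auto":
        method = "moments" if balanced else "reml"
    if method == "moments":
        if not balanced:
            raise ValueError(
                "unbalanced phenotype table: the moment estimator needs every "
                "hybrid in every environment x replicate cell; use method='reml'"
            )
        return _estimate_moments(sub, trait)
    if method == "reml":
        return _estimate_reml(sub, trait)
    raise ValueError(f"unknown method {method!r}")


def _estimate_moments(sub: pd.DataFrame, trait: str) -> VarianceComponents:
    g = sub["hybrid"].nunique()
    e = sub["environment"].nunique()
    r = int(sub.groupby(["hybrid", "environment"])["value"].count().iloc[0])
    if r < 2:
        raise ValueError("need >= 2 replicates per environment for the residual stratum")

    grand = sub["value"].mean()
    hyb_means = sub.groupby("hybrid")["value"].mean()
    cell_means = sub.groupby(["hybrid", "environment"])["value"].mean()
    env_means = sub.groupby("environment")["value"].mean()
    rep_means = sub.groupby(["environment", "replicate"])["value"].mean()

    ss_g = e * r * ((hyb_means - grand) ** 2).sum()
    inter = (
        cell_means
        - hyb_means.reindex(cell_means.index.get_level_values("hybrid")).to_numpy()
        - env_means.reindex(cell_means.index.get_level_values("environment")).to_numpy()
        + grand
    )
    ss_ge = r * (inter**2).sum()
    # residual: within-cell deviation after removing the rep-within-env effect
    resid = (
        sub["value"].to_numpy()
        - cell_means.reindex(
            pd.MultiIndex.from_frame(sub[["hybrid", "environment"]])
        ).to_numpy()
        - rep_means.reindex(
            pd.MultiIndex.from_frame(sub[["environment", "replicate"]])
        ).to_numpy()
        + env_means.reindex(sub["environment"]).to_numpy()
    )
    ss_r = float((resid**2).sum())

    ms_g = ss_g / (g - 1)
    ms_ge = ss_ge / ((g - 1) * (e - 1))
    ms_r = ss_r / (e * (g - 1) * (r - 1))

    var_e = max(ms_r, 0.0)
    var_ge = max((ms_ge - ms_r) / r, 0.0)
    var_g = max((ms_g - ms_ge) / (e * r), 0.0)
    return VarianceComponents(
        var_g=var_g, var_ge=var_ge, var_e=var_e,
        n_reps=r, n_envs=e, trait=trait, method="moments",
    )


def _estimate_reml(sub: pd.DataFrame, trait: str) -> VarianceComponents:
    """REML for the two-random-effect model by direct maximization of the
    restricted likelihood over log variance ratios (residual profiled out).

    Intended for unbalanced tables of moderate size; the balanced closed
    form is both the default and the test oracle.
    """
    y = sub["value"].to_numpy(dtype=float)
    n = len(y)
    hyb = pd.Categorical(sub["hybrid"])
    env = pd.Categorical(sub["environment"])
    rep = pd.Categorical(
        sub["environment"].astype(str) + "/" + sub["replicate"].astype(str)
    )
    # fixed effects: intercept + environment + rep-within-environment
    x = np.column_stack(
        [np.ones(n), _dummies(env.codes)[:, 1:], _dummies(rep.codes)[:, 1:]]
    )
    x = x[:, _independent_columns(x)]
    z_g = _dummies(hyb.codes)
    cell = pd.Categorical(
        sub["hybrid"].astype(str) + "/" + sub["environment"].astype(str)
    )
    z_ge = _dummies(cell.codes)
    g_g = z_g @ z_g.T
    g_ge = z_ge @ z_ge.T
    p = x.shape[1]

    def neg_restricted_ll(log_ratios: np.ndarray) -> float:
        gam_g, gam_ge = np.exp(log_ratios)
        v0 = gam_g * g_g + gam_ge * g_ge + np.eye(n)
        try:
            c = np.linalg.cholesky(v0)
        except np.linalg.LinAlgError:
            return np.inf
        vi_y = np.linalg.solve(v0, y)
        vi_x = np.linalg.solve(v0, x)
        xtvx = x.T @ vi_x
        beta = np.linalg.solve(xtvx, x.T @ vi_y)
        resid = y - x @ beta
        quad = float(resid @ np.linalg.solve(v0, resid))
        sigma2 = quad / (n - p)
        logdet_v = 2.0 * float(np.sum(np.log(np.diag(c))))
        sign, logdet_x = np.linalg.slogdet(xtvx)
        if sign <= 0:
            return np.inf
        return 0.5 * ((n - p) * np.log(sigma2) + logdet_v + logdet_x)

    res = optimize.minimize(
        neg_restricted_ll,
        x0=np.log([0.5, 0.5]),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
    )
    gam_g, gam_ge = np.exp(res.x)
    v0 = gam_g * g_g + gam_ge * g_ge + np.eye(n)
    vi_y = np.linalg.solve(v0, y)
    vi_x = np.linalg.solve(v0, x)
    beta = np.linalg.solve(x.T @ vi_x, x.T @ vi_y)
    resid = y - x @ beta
    sigma2_e = float(resid @ np.linalg.solve(v0, resid)) / (n - p)
    # report the modal replicate/environment counts seen in the data
    r = int(sub.groupby(["hybrid", "environment"])["value"].count().median())
    return VarianceComponents(
        var_g=gam_g * sigma2_e,
        var_ge=gam_ge * sigma2_e,
        var_e=sigma2_e,
        n_reps=max(r, 1),
        n_envs=sub["environment"].nunique(),
        trait=trait,
        method="reml",
    )


def _dummies(codes: np.ndarray) -> np.ndarray:
    n_levels = codes.max() + 1
    out = np.zeros((len(codes), n_levels))
    out[np.arange(len(codes)), codes] = 1.0
    return out


def _independent_columns(x: np.ndarray) -> np.ndarray:
    """Boolean mask of a maximal linearly independent column subset."""
    _, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    # pivotless QR: fall back to rank via incremental selection when needed
    if (diag > 1e-10 * diag.max()).all():
        return np.ones(x.shape[1], dtype=bool)
    keep = np.zeros(x.shape[1], dtype=bool)
    basis: list[np.ndarray] = []
    for j in range(x.shape[1]):
        candidate = basis + [x[:, j]]
        if np.linalg.matrix_rank(np.column_stack(candidate)) == len(candidate):
            keep[j] = True
            basis = candidate
    return keep
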