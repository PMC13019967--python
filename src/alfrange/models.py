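"""Weighted linear mixed models for the four space-use hypotheses.

Each species-season dataset is modeled four ways:

* H1 — log home-range area against the availability of every ALF type
  and habitat attribute (does ALF density shrink or inflate the range?);
* H2 — double-log shape index against ALF availability plus the two
  movement-cost attributes, roughness and snow (do ALFs distort shape?);
* H3 — logSR of a focal ALF type against that ALF's availability (does
  avoidance of the feature erode or intensify as it becomes denser?);
* H4 — logSR of a focal habitat attribute against ALF availability
  (does ALF density compromise habitat selection?).

All models share a male indicator with ALF interactions, a random
intercept per animal (repeated folds from the same individual), and
observation weights proportional to n_points * n_days (normalized to
mean 1). The H3/H4 rosters include the logSRs of the *other* attributes
as covariates — a response never appears among its own predictors.

Estimation: residual maximum likelihood for the single-variance-ratio
random-intercept model with fixed observation weights
(Var(e_i) = sigma^2 / w_i), profiled down to a one-dimensional search
over the variance ratio. When the random intercept is singular or the
grouping degenerate, the model falls back to weighted least squares
with ``used_random_effect=False``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import qr as _qr
from scipy.optimize import minimize_scalar

from .synthetic import ALF_TYPES, ATTRIBUTES

ENV_ATTRIBUTES = ATTRIBUTES  # elevation, roughness, forage, shrub, tree, snow

INTERCEPT = "Intercept"


# ---------------------------------------------------------------------------
# model specifications (the full-model rosters)
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class ModelSpec:
    hypothesis: str  # H1 | H2 | H3 | H4
    response: str
    fixed_terms: tuple[str, ...]
    focal: str | None = None
    group_col: str = "animal_id"
    weight_col: str = "weight"


def _sex_alf_interactions() -> list[str]:
    return [f"I_male:avail_{t}" for t in ALF_TYPES]


def model_spec(hypothesis: str, focal: str | None = None) -> ModelSpec:
    """The full fixed-effect roster for one hypothesis.

    H3 takes a focal ALF type (paved/unpaved/fence), H4 a focal habitat
    attribute; for both, the focal attribute's own logSR is excluded
    from the predictors.
    """
    avail_alf = [f"avail_{t}" for t in ALF_TYPES]
    if hypothesis == "H1":
        terms = (
            avail_alf
            + [f"avail_{a}" for a in ENV_ATTRIBUTES]
            + ["I_male"]
            + _sex_alf_interactions()
            + ["nDays"]
        )
        return ModelSpec("H1", "log_area", tuple(terms))
    if hypothesis == "H2":
        terms = (
            avail_alf
            + ["avail_roughness", "avail_snow", "I_male"]
            + _sex_alf_interactions()
            + ["nDays"]
        )
        return ModelSpec("H2", "loglog_si", tuple(terms))
    if hypothesis == "H3":
        if focal not in ALF_TYPES:
            raise ValueError(f"H3 focal must be an ALF type, got {focal!r}")
        terms = (
            [f"avail_{focal}"]
            + [f"logSR_{t}" for t in ALF_TYPES if t != focal]
            + [f"logSR_{a}" for a in ENV_ATTRIBUTES]
            + ["I_male", f"I_male:avail_{focal}"]
        )
        return ModelSpec("H3", f"logSR_{focal}", tuple(terms), focal=focal)
    if hypothesis == "H4":
        if focal not in ENV_ATTRIBUTES:
            raise ValueError(f"H4 focal must be a habitat attribute, got {focal!r}")
        terms = (
            [f"avail_{focal}"]
            + [f"logSR_{t}" for t in ALF_TYPES]
            + [f"logSR_{a}" for a in ENV_ATTRIBUTES if a != focal]
            + ["I_male"]
            + _sex_alf_interactions()
        )
        return ModelSpec("H4", f"logSR_{focal}", tuple(terms), focal=focal)
    raise ValueError(f"unknown hypothesis {hypothesis!r}")


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------
def build_dataset(
    manifest: pd.DataFrame,
    metrics: pd.DataFrame,
    selections: pd.DataFrame,
    species: str | None = None,
    season: str | None = None,
) -> pd.DataFrame:
    """One row per fold: responses, predictors, weight, grouping.

    ``manifest`` carries fold_id, animal_id, species, sex, season, year,
    n_points, n_days, weight; ``metrics`` fold_id plus the shape
    responses; ``selections`` the long fold x attribute table with
    ``log_sr``, ``available``. Pivots selections into ``logSR_*`` and
    ``avail_*`` columns and inner-joins everything on fold_id.
    """
    wide_sr = selections.pivot(index="fold_id", columns="attribute", values="log_sr")
    wide_av = selections.pivot(index="fold_id", columns="attribute", values="available")
    wide_sr.columns = [f"logSR_{c}" for c in wide_sr.columns]
    wide_av.columns = [f"avail_{c}" for c in wide_av.columns]

    df = (
        manifest.merge(metrics, on="fold_id", how="inner")
        .merge(wide_sr, on="fold_id", how="inner")
        .merge(wide_av, on="fold_id", how="inner")
    )
    if species is not None:
        df = df[df["species"] == species]
    if season is not None:
        df = df[df["season"] == season]
    df = df.copy()
    df["I_male"] = (df["sex"] == "M").astype(float)
    df["nDays"] = df["n_days"].astype(float)
    if df.empty:
        raise ValueError(f"no folds for species={species!r}, season={season!r}")
    return df.reset_index(drop=True)


def design_matrix(table: pd.DataFrame, terms: tuple[str, ...]) -> np.ndarray:
    """Intercept + one column per term; ':' terms are products."""
    cols = [np.ones(len(table))]
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            cols.append(table[a].to_numpy(float) * table[b].to_numpy(float))
        else:
            cols.append(table[t].to_numpy(float))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------
@dataclass
class ModelFit:
    spec: ModelSpec
    terms: tuple[str, ...]  # Intercept + fixed terms
    beta: np.ndarray
    se: np.ndarray
    cov_beta: np.ndarray
    sigma2: float
    tau2: float  # random-intercept variance (0 when not used)
    converged: bool
    used_random_effect: bool
    n_obs: int
    n_groups: int
    n_dropped: int
    table: pd.DataFrame = field(repr=False, default=None)

    def coef(self, term: str) -> float:
        return float(self.beta[self.terms.index(term)])

    def coef_se(self, term: str) -> float:
        return float(self.se[self.terms.index(term)])

    def coef_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"term": self.terms, "beta": self.beta, "se": self.se})


class RankDeficientDesign(ValueError):
    def __init__(self, aliased: list[str]):
        self.aliased = aliased
        super().__init__(f"rank-deficient design; aliased terms: {aliased}")


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    # scale columns to unit norm first so the tolerance is not dominated
    # by large-magnitude predictors (elevation vs binary indicators)
    norms = np.linalg.norm(X, axis=0)
    zero = norms == 0
    if zero.any():
        raise RankDeficientDesign([n for n, z in zip(names, zero) if z])
    Xs = X / norms
    sv = np.linalg.svd(Xs, compute_uv=False)
    tol = sv[0] * max(X.shape) * np.finfo(float).eps
    rank = int((sv > tol).sum())
    if rank < X.shape[1]:
        _, r, piv = _qr(Xs, pivoting=True, mode="economic")
        raise RankDeficientDesign([names[i] for i in piv[rank:]])


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Closed-form weighted least squares with Var(e_i) = sigma^2 / w_i."""
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    xtx = Xw.T @ Xw
    beta = np.linalg.solve(xtx, Xw.T @ yw)
    resid = yw - Xw @ beta
    dof = max(len(y) - X.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(xtx)
    return beta, cov, sigma2


def _reml_profile(X, y, w, group_idx, n_groups, log_lam):
    """Profiled REML criterion and GLS pieces at variance ratio lam.

    With V = diag(1/w) + lam * Z Z' (random intercept per group), the
    Woodbury identity reduces every group's solve to rank one.
    """
    lam = np.exp(log_lam)
    n, p = X.shape
    # per-group sums under W = diag(w)
    Sw = np.bincount(group_idx, weights=w, minlength=n_groups)
    denom = 1.0 + lam * Sw  # 1 + lam * sum(w) per group
    # V^{-1} = W - lam * (W 1)(1' W) / (1 + lam * S)
    wX = X * w[:, None]
    wy = y * w
    gX = np.zeros((n_groups, p))
    for j in range(p):
        gX[:, j] = np.bincount(group_idx, weights=wX[:, j], minlength=n_groups)
    gy = np.bincount(group_idx, weights=wy, minlength=n_groups)
    xtvx = X.T @ wX - (gX.T * (lam / denom)) @ gX
    xtvy = X.T @ wy - (gX.T * (lam / denom)) @ gy
    ytvy = y @ wy - np.sum(lam / denom * gy**2)
    beta = np.linalg.solve(xtvx, xtvy)
    quad = ytvy - beta @ xtvy  # r' V^{-1} r at the GLS solution
    quad = max(quad, 1e-300)
    logdet_v = -np.sum(np.log(w)) + np.sum(np.log(denom))
    sign, logdet_x = np.linalg.slogdet(xtvx)
    crit = (n - p) * np.log(quad) + logdet_v + logdet_x
    return crit, beta, xtvx, quad


_LAM_LO, _LAM_HI = -16.0, 10.0  # bounds on log variance ratio


def fit_model(table: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Fit one hypothesis model on one species-season table.

    Rows missing the response or any predictor are dropped (counted in
    ``n_dropped``). The mixed fit needs at least two groups with more
    than one observation; otherwise, or when REML drives the
    random-intercept variance to zero or fails, the model is refit as
    weighted least squares.
    """
    used_cols = [spec.response, spec.weight_col, spec.group_col] + [
        c for t in spec.fixed_terms for c in t.split(":")
    ]
    used_cols = list(dict.fromkeys(used_cols))
    ok = table[used_cols].notna().all(axis=1)
    data = table.loc[ok]
    n_dropped = int((~ok).sum())
    names = [INTERCEPT, *spec.fixed_terms]
    if len(data) < len(names) + 2:
        raise ValueError(
            f"too few rows ({len(data)}) for {len(names)} fixed-effect terms"
        )
    X = design_matrix(data, spec.fixed_terms)
    y = data[spec.response].to_numpy(float)
    w = data[spec.weight_col].to_numpy(float)
    groups, group_idx = np.unique(data[spec.group_col], return_inverse=True)
    n_groups = len(groups)
    _check_rank(X, names)

    multi_obs_groups = int((np.bincount(group_idx) > 1).sum())
    use_re = multi_obs_groups >= 2
    converged = True
    tau2 = 0.0
    if use_re:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = minimize_scalar(
                    lambda ll: _reml_profile(X, y, w, group_idx, n_groups, ll)[0],
                    bounds=(_LAM_LO, _LAM_HI),
                    method="bounded",
                    options={"xatol": 1e-8},
                )
            if not res.success or not np.isfinite(res.fun):
                raise RuntimeError("REML optimizer did not converge")
            log_lam = float(res.x)
            if log_lam <= _LAM_LO + 1e-3:
                use_re = False  # singular random-intercept variance
            else:
                _, beta, xtvx, quad = _reml_profile(X, y, w, group_idx, n_groups, log_lam)
                sigma2 = quad / (len(y) - X.shape[1])
                tau2 = np.exp(log_lam) * sigma2
                cov = sigma2 * np.linalg.inv(xtvx)
        except (RuntimeError, np.linalg.LinAlgError):
            use_re = False
            converged = False
    if not use_re:
        beta, cov, sigma2 = _wls(X, y, w)
        tau2 = 0.0
    return ModelFit(
        spec=spec,
        terms=tuple(names),
        beta=np.asarray(beta, float),
        se=np.sqrt(np.diag(cov)),
        cov_beta=cov,
        sigma2=float(sigma2),
        tau2=float(tau2),
        converged=converged,
        used_random_effect=use_re,
        n_obs=len(data),
        n_groups=n_groups,
        n_dropped=n_dropped,
        table=data,
    )


# ---------------------------------------------------------------------------
# prediction curves
# ---------------------------------------------------------------------------
def predict_response_curve(
    fit: ModelFit,
    focal_term: str,
    n_grid: int = 100,
    male: bool = False,
    ci_mult: float = 1.96,
) -> pd.DataFrame:
    """Marginal prediction curve for one predictor.

    The focal predictor sweeps its observed range; every other numeric
    predictor sits at its weighted mean; the sex indicator defaults to
    female (the reference class). Interval half-width is
    ``ci_mult * SE(y_hat)`` from the fixed-effect covariance.
    """
    base_terms = list(
        dict.fromkeys(p for t in fit.spec.fixed_terms for p in t.split(":"))
    )
    if focal_term not in base_terms:
        raise ValueError(f"focal term {focal_term!r} not among the fixed effects")
    data = fit.table
    w = data[fit.spec.weight_col].to_numpy(float)
    xobs = data[focal_term].to_numpy(float)
    xgrid = np.linspace(xobs.min(), xobs.max(), n_grid)

    values: dict[str, np.ndarray] = {}
    for t in base_terms:
        if t == focal_term:
            values[t] = xgrid
        elif t == "I_male":
            values[t] = np.full(n_grid, 1.0 if male else 0.0)
        else:
            col = data[t].to_numpy(float)
            values[t] = np.full(n_grid, float(np.average(col, weights=w)))
    if "I_male" in values and male:
        values["I_male"] = np.full(n_grid, 1.0)

    cols = [np.ones(n_grid)]
    for t in fit.spec.fixed_terms:
        if ":" in t:
            a, b = t.split(":")
            cols.append(values[a] * values[b])
        else:
            cols.append(values[t])
    Xg = np.column_stack(cols)
    yhat = Xg @ fit.beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", Xg, fit.cov_beta, Xg))
    return pd.DataFrame(
        {
            "x": xgrid,
            "y_hat": yhat,
            "lo95": yhat - ci_mult * se,
            "hi95": yhat + ci_mult * se,
            "se": se,
        }
    )
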