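"""Maximum-likelihood population-effects (MLPE) mixed models.

Pairwise distance regressions violate independence because two pairs that
share an endpoint population are correlated.  The MLPE model handles this
with a random effect for each endpoint:

    y_ij = x_ij' beta + u_i + u_j + e_ij,
    u ~ N(0, sigma_u^2), e ~ N(0, sigma_e^2)

so V = sigma_e^2 * (I + phi * Z Z'), phi = sigma_u^2 / sigma_e^2, with Z
the pair × population incidence matrix carrying two unit entries per row.
beta is profiled out by GLS, sigma_e^2 has a closed form given phi, and
phi is found by bounded scalar search on the profile (restricted)
log-likelihood.  The eigendecomposition of Z Z' is computed once per site
set and reused for every candidate model and phi value.

Model ranking uses AICc and BIC computed on the number of pairs, with
k = (#predictors + 1 intercept) + 2 variance components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .distance import DistanceMatrix

__all__ = [
    "CandidateModel",
    "MLPEFit",
    "build_response_design",
    "mlpe_fit",
    "information_criteria",
    "rank_models",
    "fit_candidates",
]


@dataclass(frozen=True)
class CandidateModel:
    """A named hypothesis: a set of resistance predictors (possibly one,
    the uniform IBD layer).  ``k`` counts intercept + slopes + 2 variance
    components, so a single-predictor model has k = 4."""

    name: str
    predictors: tuple

    def __init__(self, name: str, predictors):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "predictors", tuple(predictors))
        if not self.predictors:
            raise ValueError("a candidate model needs at least one predictor")

    @property
    def k(self) -> int:
        return len(self.predictors) + 1 + 2


@dataclass
class MLPEFit:
    beta: np.ndarray
    beta_names: list
    sigma_u2: float
    sigma_e2: float
    loglik: float
    method: str
    n_pairs: int
    converged: bool
    phi: float = 0.0


def _pair_incidence(n_sites: int) -> np.ndarray:
    """Z: one row per unordered pair (i>j, row-major), unit entries at
    both endpoint columns."""
    rows = []
    for i in range(1, n_sites):
        for j in range(i):
            z = np.zeros(n_sites)
            z[i] = z[j] = 1.0
            rows.append(z)
    return np.array(rows)


def build_response_design(
    y: DistanceMatrix, predictors: dict, model: CandidateModel,
    standardize: bool = True,
):
    """Vectorize a population distance matrix and predictors for one model.

    Returns ``(y_vec, X, Z, pair_labels)``; X has an intercept column
    followed by (by default z-standardized) predictor columns; Z is the
    pair × site incidence matrix.
    """
    labels = y.labels
    for name in model.predictors:
        if name not in predictors:
            raise KeyError(f"predictor {name!r} not in predictor set")
        if predictors[name].labels != labels:
            raise ValueError(
                f"predictor {name!r} labels do not match the response"
            )
    y_vec = y.condensed()
    cols = [np.ones(len(y_vec))]
    for name in model.predictors:
        v = predictors[name].condensed()
        if standardize:
            sd = v.std(ddof=1)
            if sd == 0:
                raise ValueError(f"predictor {name!r} is constant")
            v = (v - v.mean()) / sd
        cols.append(v)
    X = np.column_stack(cols)
    Z = _pair_incidence(len(labels))
    return y_vec, X, Z, y.pairs()


class _SpectralBasis:
    """Eigenbasis of Z Z' shared by all fits on one site set."""

    def __init__(self, Z: np.ndarray):
        M = Z @ Z.T
        lam, Q = np.linalg.eigh(M)
        self.lam = np.clip(lam, 0.0, None)
        self.Q = Q

    def rotate(self, v: np.ndarray) -> np.ndarray:
        return self.Q.T @ v


_basis_cache: dict = {}


def _get_basis(Z: np.ndarray) -> _SpectralBasis:
    key = (Z.shape, hash(Z.tobytes()))
    b = _basis_cache.get(key)
    if b is None:
        if len(_basis_cache) > 32:
            _basis_cache.clear()
        b = _basis_cache[key] = _SpectralBasis(Z)
    return b


def _profile_loglik(phi, lam, yt, Xt, method):
    """Profile log-likelihood at variance ratio phi (beta, sigma_e2 out).

    Returns (loglik, beta, sigma_e2). Works in the eigenbasis where
    W = I + phi ZZ' is diagonal with entries 1 + phi*lam.
    """
    n, p = Xt.shape
    d = 1.0 + phi * lam
    sw = 1.0 / np.sqrt(d)
    Xw = Xt * sw[:, None]
    yw = yt * sw
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    r = yw - Xw @ beta
    rss = float(r @ r)
    logdet_w = float(np.sum(np.log(d)))
    if method == "ML":
        sigma_e2 = rss / n
        if sigma_e2 <= 0:
            sigma_e2 = np.finfo(float).tiny
        ll = -0.5 * (n * np.log(2 * np.pi * sigma_e2) + logdet_w + n)
    else:  # REML
        sigma_e2 = rss / (n - p)
        if sigma_e2 <= 0:
            sigma_e2 = np.finfo(float).tiny
        xtx = Xw.T @ Xw
        sign, logdet_x = np.linalg.slogdet(xtx)
        if sign <= 0:
            raise np.linalg.LinAlgError("rank-deficient design")
        ll = -0.5 * (
            (n - p) * np.log(2 * np.pi * sigma_e2)
            + logdet_w
            + logdet_x
            + (n - p)
        )
    return ll, beta, sigma_e2


def mlpe_fit(y, X, Z, method: str = "ML") -> MLPEFit:
    """Fit the MLPE model by profiled (restricted) maximum likelihood.

    The variance ratio phi = sigma_u^2 / sigma_e^2 is optimized by bounded
    search over log(phi + eps) with several restarts, plus an explicit
    check of the phi = 0 boundary (independent errors).
    """
    if method not in ("ML", "REML"):
        raise ValueError("method must be 'ML' or 'REML'")
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n <= p:
        raise ValueError("more parameters than pairwise observations")
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    basis = _get_basis(np.ascontiguousarray(Z, dtype=float))
    lam = basis.lam
    yt = basis.rotate(y)
    Xt = basis.Q.T @ X

    eps = 1e-8

    def neg(t):
        return -_profile_loglik(np.exp(t) - eps, lam, yt, Xt, method)[0]

    best_t, best_val = None, np.inf
    converged = True
    # restarts over log-phi subintervals; phi in [0, ~1000]
    brackets = [(np.log(eps), 0.0), (-4.0, 3.0), (0.0, 7.0)]
    for lo, hi in brackets:
        res = minimize_scalar(
            neg, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10},
        )
        if res.fun < best_val:
            best_val, best_t = float(res.fun), float(res.x)
        converged = converged and bool(res.success)
    # boundary phi = 0
    ll0 = _profile_loglik(0.0, lam, yt, Xt, method)[0]
    if ll0 >= -best_val - 1e-12:
        phi = 0.0
    else:
        phi = float(np.exp(best_t) - eps)
        phi = max(phi, 0.0)
    ll, beta, sigma_e2 = _profile_loglik(phi, lam, yt, Xt, method)
    return MLPEFit(
        beta=beta,
        beta_names=[f"b{i}" for i in range(p)],
        sigma_u2=phi * sigma_e2,
        sigma_e2=sigma_e2,
        loglik=float(ll),
        method=method,
        n_pairs=n,
        converged=converged,
        phi=phi,
    )


def information_criteria(loglik: float, k: int, n: int):
    """(AICc, BIC) from a maximized log-likelihood.

    AICc = -2 l + 2k + 2k(k+1)/(n-k-1); BIC = -2 l + k ln n.  ``n`` is the
    number of pairwise observations.
    """
    if n - k - 1 <= 0:
        raise ValueError("AICc undefined: n <= k + 1")
    aic = -2.0 * loglik + 2.0 * k
    aicc = aic + 2.0 * k * (k + 1) / (n - k - 1)
    bic = -2.0 * loglik + k * np.log(n)
    return float(aicc), float(bic)


def rank_models(criteria: dict) -> pd.DataFrame:
    """Selection table from per-model IC values.

    ``criteria`` maps model name → (AICc, BIC, k).  Returns a DataFrame
    with delta values, Akaike-type weights for both criteria, and ranks;
    ties in delta (within 1e-9) break by smaller k then name.
    """
    if not criteria:
        raise ValueError("no models to rank")
    df = pd.DataFrame(
        [(name, a, b, k) for name, (a, b, k) in criteria.items()],
        columns=["model", "AICc", "BIC", "k"],
    ).set_index("model")
    for ic in ("AICc", "BIC"):
        delta = df[ic] - df[ic].min()
        w = np.exp(-delta / 2.0)
        df[f"d{ic}"] = delta
        df[f"w{ic}"] = w / w.sum()
    tmp = df.reset_index()
    tmp["_d"] = np.round(tmp["dAICc"], 9)
    tmp = tmp.sort_values(["_d", "k", "model"], kind="stable")
    df["rank"] = pd.Series(
        np.arange(1, len(tmp) + 1), index=tmp["model"]
    )
    return df


def fit_candidates(
    y: DistanceMatrix,
    predictors: dict,
    models,
    method: str = "ML",
    standardize: bool = True,
):
    """Fit every candidate model and rank by AICc/BIC.

    Returns ``(table, fits)``: the selection DataFrame (indexed by model
    name, including per-model delta and weight columns for both criteria)
    and a dict of :class:`MLPEFit` per model.  Non-converged fits are
    excluded from the ranking and reported in ``table.attrs['excluded']``.
    """
    fits, crit, excluded = {}, {}, []
    for model in models:
        y_vec, X, Z, _ = build_response_design(
            y, predictors, model, standardize=standardize
        )
        try:
            fit = mlpe_fit(y_vec, X, Z, method=method)
        except np.linalg.LinAlgError:
            excluded.append(model.name)
            continue
        fits[model.name] = fit
        if not fit.converged:
            excluded.append(model.name)
            continue
        aicc, bic = information_criteria(fit.loglik, model.k, fit.n_pairs)
        crit[model.name] = (aicc, bic, model.k)
    table = rank_models(crit)
    table.attrs["excluded"] = excluded
    table.attrs["method"] = method
    return table, fits
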