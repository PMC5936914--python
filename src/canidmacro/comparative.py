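"""Phylogenetic signal, PGLS, and likelihood-based selection among six
Gaussian trait-evolution models.

All six models imply a multivariate normal distribution of tip values
whose mean and covariance are simple functions of the shared
path-length matrix ``C`` and the tip depths ``T``:

========  =====================  =========================================
model     mean                   covariance
========  =====================  =========================================
BM        z0                     sigma2 * C
OU        z0 (root at optimum)   sigma2/(2a) * exp(-a(Ti+Tj-2Cij))
                                 * (1 - exp(-2a Cij))
ACDC      z0                     sigma2 * (exp(r Cij) - 1)/r
Trend     z0                     sigma2 * (Cij + b Cij^2/2)
Drift     z0 + mu * Ti           sigma2 * C
Div       z0                     integral of (sigma0^2 + psi n(t)) over
                                 the shared path, n(t) = lineage count
========  =====================  =========================================

ACDC/Trend/Div are time-inhomogeneous Brownian models whose rate depends
only on time since the root, so their covariance is an elementwise
monotone transform of ``C``. Every model contains BM as a boundary case
(OU a->0, ACDC r->0, Trend b->0, Drift mu->0, Div psi->0).

Fitting profiles the location and scale parameters analytically (GLS),
leaving at most one shape parameter per model; that parameter is
maximized by a grid scan (which always includes the BM boundary) plus
bounded Brent refinement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_solve, cholesky, solve_triangular

from .trees import PhyloData, as_phylo_data, prune_to

__all__ = [
    "MODEL_NAMES",
    "ModelSpec",
    "ModelFit",
    "model_mean_cov",
    "loglik",
    "fit_model",
    "fit_all_models",
    "aicc",
    "aicc_weights",
    "pagel_lambda_ml",
    "blomberg_k",
    "pgls_fit",
    "pgls_compare",
    "fit_over_posterior",
    "PosteriorSummary",
]

MODEL_NAMES = ("BM", "OU", "ACDC", "Trend", "Drift", "Div")
_LOG2PI = float(np.log(2.0 * np.pi))

# free parameters: BM (z0, sigma2); all others add one shape/direction term
MODEL_K = {"BM": 2, "OU": 3, "ACDC": 3, "Trend": 3, "Drift": 3, "Div": 3}


@dataclass(frozen=True)
class ModelSpec:
    """A named trait-evolution model with fully specified parameters."""

    name: str
    params: Mapping[str, float]

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; expected one of {MODEL_NAMES}")


def _check(cond, msg):
    if not cond:
        raise ValueError(msg)


def _shape_cov(pdata: PhyloData, name: str, shape: float) -> np.ndarray:
    """Unit-scale covariance V such that cov = sigma2 * V.

    ``shape`` is the model's single shape parameter (alpha, r, b_rate,
    or psi/sigma0^2 for Div); shape == 0 gives V = C for every model.
    """
    C = pdata.C
    if name == "BM" or shape == 0.0:
        return C.copy()
    if name == "OU":
        a = shape
        T = pdata.depths
        D = T[:, None] + T[None, :] - 2.0 * C
        return np.exp(-a * D) * (-np.expm1(-2.0 * a * C)) / (2.0 * a)
    if name == "ACDC":
        r = shape
        return np.expm1(r * C) / r
    if name == "Trend":
        b = shape
        _check(1.0 + b * pdata.max_depth >= 0.0, "Trend rate negative within tree span")
        return C + 0.5 * b * C * C
    if name == "Div":
        rel = shape
        span = pdata.ltt_times <= pdata.max_depth
        _check(
            np.all(1.0 + rel * pdata.ltt_counts[span] >= 0.0),
            "Div rate negative within tree span",
        )
        return C + rel * pdata.ltt_integral(C)
    if name == "Drift":
        return C.copy()
    raise ValueError(f"unknown model {name!r}")


def model_mean_cov(tree, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray]:
    """Exact MVN mean vector and covariance matrix of the tip values."""
    pdata = as_phylo_data(tree)
    p = dict(spec.params)
    name = spec.name
    ones = np.ones(pdata.n)
    if name == "Div":
        s0 = p["sigma0_sq"]
        psi = p["psi"]
        _check(s0 > 0, "sigma0_sq must be > 0")
        cov = s0 * _shape_cov(pdata, "Div", psi / s0)
        mean = p["z0"] * ones
        return mean, cov
    s2 = p["sigma2"]
    _check(s2 > 0, "sigma2 must be > 0")
    if name == "BM":
        return p["z0"] * ones, s2 * pdata.C
    if name == "OU":
        a = p["alpha"]
        _check(a >= 0, "OU alpha must be >= 0")
        return p["z0"] * ones, s2 * _shape_cov(pdata, "OU", a)
    if name == "ACDC":
        return p["z0"] * ones, s2 * _shape_cov(pdata, "ACDC", p["r"])
    if name == "Trend":
        return p["z0"] * ones, s2 * _shape_cov(pdata, "Trend", p["b_rate"])
    if name == "Drift":
        mean = p["z0"] + p["mu_drift"] * pdata.depths
        return mean, s2 * pdata.C
    raise ValueError(f"unknown model {name!r}")


def _align_trait(pdata: PhyloData, trait) -> np.ndarray:
    if isinstance(trait, pd.Series):
        missing = [l for l in pdata.labels if l not in trait.index]
        if missing:
            raise ValueError(f"trait values missing for tips: {missing[:5]}")
        return trait.reindex(list(pdata.labels)).to_numpy(dtype=float)
    x = np.asarray(trait, dtype=float)
    if x.shape != (pdata.n,):
        raise ValueError("trait vector length does not match number of tips")
    return x


def _chol(V: np.ndarray) -> np.ndarray:
    try:
        return cholesky(V, lower=True)
    except np.linalg.LinAlgError as err:
        dup = _duplicate_tips(V)
        raise np.linalg.LinAlgError(
            f"singular model covariance; exchangeable duplicate tips: {dup}"
        ) from err


def _duplicate_tips(V):
    n = V.shape[0]
    dups = []
    for i in range(n):
        for j in range(i + 1, n):
            if V[i, i] == V[j, j] == V[i, j]:
                dups.append((i, j))
    return dups


def loglik(tree, trait, spec: ModelSpec) -> float:
    """Multivariate normal log-likelihood of tip values under a model."""
    pdata = as_phylo_data(tree)
    x = _align_trait(pdata, trait)
    mean, cov = model_mean_cov(pdata, spec)
    L = _chol(cov)
    r = solve_triangular(L, x - mean, lower=True)
    return float(-0.5 * (pdata.n * _LOG2PI + r @ r) - np.log(np.diag(L)).sum())


def _gls_profile(V: np.ndarray, X: np.ndarray, y: np.ndarray):
    """Profiled Gaussian log-likelihood with mean X@beta and cov sigma2*V.

    Returns (loglik, beta_hat, sigma2_hat). sigma2 uses the ML (1/n)
    normalization.
    """
    n = len(y)
    L = _chol(V)
    A = solve_triangular(L, X, lower=True)
    b = solve_triangular(L, y, lower=True)
    beta, *_ = np.linalg.lstsq(A, b, rcond=None)
    r = b - A @ beta
    rss = float(r @ r)
    logdet = 2.0 * float(np.log(np.diag(L)).sum())
    if rss <= 0.0:
        return np.inf, beta, 0.0
    sigma2 = rss / n
    ll = -0.5 * (n * (_LOG2PI + np.log(sigma2) + 1.0) + logdet)
    return ll, beta, sigma2


def _optimize_shape(objective, lo, hi, grid):
    """Grid scan + bounded Brent refinement; returns (best_shape, best_val)."""
    vals = np.array([objective(s) for s in grid])
    i = int(np.nanargmax(vals))
    best_s, best_v = float(grid[i]), float(vals[i])
    left = grid[i - 1] if i > 0 else lo
    right = grid[i + 1] if i < len(grid) - 1 else hi
    if right > left:
        res = optimize.minimize_scalar(
            lambda s: -objective(s),
            bounds=(left, right),
            method="bounded",
            options={"xatol": 1e-10 * max(1.0, abs(right - left))},
        )
        if np.isfinite(res.fun) and -res.fun > best_v:
            best_s, best_v = float(res.x), float(-res.fun)
    return best_s, best_v


@dataclass
class ModelFit:
    """Maximum-likelihood fit of one trait-evolution model."""

    name: str
    params: dict
    loglik: float
    k: int
    n: int
    aicc: float
    converged: bool = True
    weight: float | None = None


def _shape_bounds(pdata: PhyloData, name: str):
    T = pdata.max_depth
    if name == "OU":
        lo, hi = 0.0, 50.0 / T
        grid = np.concatenate([[0.0], np.geomspace(1e-3 / T, hi, 24)])
    elif name == "ACDC":
        lo, hi = -10.0 / T, 10.0 / T
        grid = np.linspace(lo, hi, 33)
    elif name == "Trend":
        lo, hi = -(1.0 - 1e-9) / T, 10.0 / T
        grid = np.unique(np.concatenate([np.linspace(lo, hi, 33), [0.0]]))
    elif name == "Div":
        nmax = max(pdata.max_lineages, 1)
        lo, hi = -(1.0 - 1e-6) / nmax, 50.0 / nmax
        grid = np.unique(np.concatenate([np.linspace(lo, hi, 33), [0.0]]))
    else:
        raise ValueError(name)
    return lo, hi, grid


def fit_model(tree, trait, model_name: str, weight: float | None = None) -> ModelFit:
    """Fit one model by ML; z0 and the scale are profiled analytically."""
    pdata = as_phylo_data(tree)
    x = _align_trait(pdata, trait)
    n = pdata.n
    k = MODEL_K[model_name]
    _check(n >= k + 2, f"need n >= k+2 = {k + 2} tips for AICc of {model_name}")
    ones = np.ones((n, 1))

    if model_name == "BM":
        ll, beta, s2 = _gls_profile(pdata.C, ones, x)
        params = {"z0": float(beta[0]), "sigma2": s2}
        shape_ok = True
    elif model_name == "Drift":
        X = np.column_stack([np.ones(n), pdata.depths])
        ll, beta, s2 = _gls_profile(pdata.C, X, x)
        params = {"z0": float(beta[0]), "mu_drift": float(beta[1]), "sigma2": s2}
        shape_ok = True
    else:
        lo, hi, grid = _shape_bounds(pdata, model_name)

        def obj(s):
            try:
                V = _shape_cov(pdata, model_name, s)
                ll, _, _ = _gls_profile(V, ones, x)
            except (ValueError, np.linalg.LinAlgError):
                return -np.inf
            return ll

        shape, ll = _optimize_shape(obj, lo, hi, grid)
        V = _shape_cov(pdata, model_name, shape)
        ll, beta, s2 = _gls_profile(V, ones, x)
        shape_ok = np.isfinite(ll)
        if model_name == "OU":
            params = {"z0": float(beta[0]), "sigma2": s2, "alpha": shape}
        elif model_name == "ACDC":
            params = {"z0": float(beta[0]), "sigma2": s2, "r": shape}
        elif model_name == "Trend":
            params = {"z0": float(beta[0]), "sigma2": s2, "b_rate": shape}
        else:  # Div: sigma2 is sigma0^2, shape = psi/sigma0^2
            params = {"z0": float(beta[0]), "sigma0_sq": s2, "psi": shape * s2}

    return ModelFit(
        name=model_name,
        params=params,
        loglik=float(ll),
        k=k,
        n=n,
        aicc=aicc(ll, k, n),
        converged=bool(np.isfinite(ll) and shape_ok),
        weight=weight,
    )


def fit_all_models(tree, trait, models: Sequence[str] = MODEL_NAMES) -> list[ModelFit]:
    """Fit several models and attach small-sample Akaike weights."""
    pdata = as_phylo_data(tree)
    fits = [fit_model(pdata, trait, m) for m in models]
    _, w = aicc_weights([f.aicc for f in fits])
    for f, wi in zip(fits, w):
        f.weight = float(wi)
    return fits


def aicc(loglik_value: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion."""
    _check(n - k - 1 > 0, "AICc requires n > k + 1")
    return float(-2.0 * loglik_value + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1))


def aicc_weights(aicc_values=None, fits=None, n=None):
    """Akaike weights from AICc values, or from (loglik, k) pairs with n.

    Returns ``(aicc_array, weights)``; weights sum to one.
    """
    if aicc_values is None:
        _check(fits is not None and n is not None, "need aicc_values or (fits, n)")
        aicc_values = [aicc(ll, k, n) for ll, k in fits]
    a = np.asarray(list(aicc_values), dtype=float)
    _check(a.size > 0, "empty model set")
    delta = a - a.min()
    w = np.exp(-0.5 * delta)
    return a, w / w.sum()


# ---------------------------------------------------------------------------
# phylogenetic signal
# ---------------------------------------------------------------------------


@dataclass
class LambdaResult:
    lambda_: float
    loglik: float
    loglik0: float
    p: float
    z0: float
    sigma2: float


def pagel_lambda_ml(tree, trait, boundary_halving: bool = False) -> LambdaResult:
    """Maximum-likelihood Pagel's lambda in [0, 1] with LR test vs lambda=0.

    z0 and sigma2 are profiled analytically; the p-value uses a chi^2(1)
    reference (optionally a 50:50 boundary mixture).
    """
    pdata = as_phylo_data(tree)
    x = _align_trait(pdata, trait)
    _check(pdata.n >= 4, "need at least 4 tips")
    _check(np.ptp(x) > 0, "degenerate trait (zero variance)")
    ones = np.ones((pdata.n, 1))

    def obj(lam):
        ll, _, _ = _gls_profile(pdata.lambda_cov(lam), ones, x)
        return ll

    grid = np.linspace(0.0, 1.0, 21)
    lam, ll = _optimize_shape(obj, 0.0, 1.0, grid)
    ll0, _, _ = _gls_profile(pdata.lambda_cov(0.0), ones, x)
    if ll0 > ll:  # lambda = 0 is in the parameter space
        lam, ll = 0.0, ll0
    _, beta, s2 = _gls_profile(pdata.lambda_cov(lam), ones, x)
    lr = max(0.0, 2.0 * (ll - ll0))
    p = float(stats.chi2.sf(lr, df=1))
    if boundary_halving:
        p = 0.5 * p if lr > 0 else 1.0
    return LambdaResult(float(lam), float(ll), float(ll0), max(p, np.finfo(float).tiny), float(beta[0]), s2)


@dataclass
class KResult:
    K: float
    p: float
    n_perm: int


def _k_statistic(Cinv, trC, one_Cinv_one, n, X):
    """Blomberg's K for each column of X (vectorized over permutations)."""
    CiX = Cinv @ X
    ahat = (np.ones(n) @ CiX) / one_Cinv_one
    R = X - ahat[None, :]
    CiR = CiX - np.outer(Cinv @ np.ones(n), ahat)
    num = np.einsum("ij,ij->j", R, R)
    den = np.einsum("ij,ij->j", R, CiR)
    expected = (trC - n / one_Cinv_one) / (n - 1)
    return (num / den) / expected


def blomberg_k(tree, trait, n_perm: int = 999, seed=None) -> KResult:
    """Blomberg's K with a tip-label permutation test.

    K compares the observed mean-square ratio of the trait to its
    Brownian expectation on the tree; K = 1 under BM, K -> small when
    trait values are independent of the phylogeny. The permutation p is
    (1 + #{K_perm >= K_obs}) / (1 + n_perm), so its floor is
    1/(1 + n_perm).
    """
    _check(n_perm >= 1, "n_perm must be >= 1")
    pdata = as_phylo_data(tree)
    x = _align_trait(pdata, trait)
    _check(pdata.n >= 4, "need at least 4 tips")
    n = pdata.n
    Cinv = np.linalg.inv(pdata.C)
    trC = float(np.trace(pdata.C))
    oco = float(np.ones(n) @ Cinv @ np.ones(n))
    K_obs = float(_k_statistic(Cinv, trC, oco, n, x[:, None])[0])
    rng = np.random.default_rng(seed)
    perms = np.empty((n, n_perm))
    for j in range(n_perm):
        perms[:, j] = x[rng.permutation(n)]
    K_perm = _k_statistic(Cinv, trC, oco, n, perms)
    p = (1.0 + np.sum(K_perm >= K_obs)) / (1.0 + n_perm)
    return KResult(K_obs, float(p), n_perm)


# ---------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------


@dataclass
class PglsResult:
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    lambda_: float
    lambda_mode: str
    loglik: float
    k: int
    n: int
    aicc: float
    sigma2: float
    df_resid: int
    perfect_fit: bool = False


def _design(predictors) -> tuple[np.ndarray, list[str]]:
    if isinstance(predictors, pd.DataFrame):
        names = list(predictors.columns)
        X = predictors.to_numpy(dtype=float)
    elif isinstance(predictors, pd.Series):
        names = [predictors.name or "x"]
        X = predictors.to_numpy(dtype=float)[:, None]
    else:
        X = np.asarray(predictors, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i}" for i in range(X.shape[1])]
    return X, names


def pgls_fit(tree, response, predictors, lambda_mode="ml") -> PglsResult:
    """Phylogenetic GLS with covariance sigma2 * C(lambda).

    ``lambda_mode`` is "ml" (lambda estimated by maximum likelihood), or
    a fixed value: 1 (Brownian residuals) or 0 (ordinary least squares).
    Predictors are aligned to tree tips by index when pandas objects are
    given; an intercept is always added. Coefficient t-tests use the
    unbiased residual variance with n - p - 1 degrees of freedom.
    """
    pdata = as_phylo_data(tree)
    y = _align_trait(pdata, response)
    if isinstance(predictors, (pd.DataFrame, pd.Series)):
        predictors = predictors.reindex(list(pdata.labels))
        if np.any(pd.isna(predictors).to_numpy()):
            raise ValueError("predictor values missing for some tips (complete cases only)")
    Xr, names = _design(predictors)
    n, p = Xr.shape
    _check(n > p + 2, "need n > p + 2 observations")
    X = np.column_stack([np.ones(n), Xr])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear predictors (design matrix is rank deficient)")
    names = ["intercept"] + names

    if lambda_mode == "ml":
        def obj(lam):
            ll, _, _ = _gls_profile(pdata.lambda_corr(lam), X, y)
            return ll

        lam, _ = _optimize_shape(obj, 0.0, 1.0, np.linspace(0.0, 1.0, 21))
        k = X.shape[1] + 2  # coefficients + sigma2 + lambda
        mode = "ml"
    else:
        lam = float(lambda_mode)
        _check(0.0 <= lam <= 1.0, "lambda must be in [0, 1]")
        k = X.shape[1] + 1  # coefficients + sigma2
        mode = f"fixed:{lam:g}"

    V = pdata.lambda_corr(lam)
    ll, beta, s2_ml = _gls_profile(V, X, y)
    L = _chol(V)
    A = solve_triangular(L, X, lower=True)
    b = solve_triangular(L, y, lower=True)
    resid = b - A @ beta
    rss = float(resid @ resid)
    df = n - X.shape[1]
    perfect = rss <= 1e-12 * max(1.0, float(b @ b))
    XtX_inv = np.linalg.inv(A.T @ A)
    s2_unbiased = rss / df if df > 0 else np.nan
    if perfect:
        warnings.warn("perfect fit: zero residual variance; SEs set to 0")
        bse = np.zeros(X.shape[1])
        tvals = np.full(X.shape[1], np.inf)
        pvals = np.zeros(X.shape[1])
        ll = np.inf
    else:
        bse = np.sqrt(s2_unbiased * np.diag(XtX_inv))
        tvals = beta / bse
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df=df)
    return PglsResult(
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        tvalues=pd.Series(tvals, index=names),
        pvalues=pd.Series(pvals, index=names),
        lambda_=float(lam),
        lambda_mode=mode,
        loglik=float(ll),
        k=k,
        n=n,
        aicc=aicc(ll, k, n) if np.isfinite(ll) else -np.inf,
        sigma2=s2_ml,
        df_resid=df,
        perfect_fit=perfect,
    )


def pgls_compare(tree, response, predictors) -> pd.DataFrame:
    """Fit PGLS under lambda = ML, 1, 0 and compare by AICc weights."""
    fits = {
        "ml": pgls_fit(tree, response, predictors, "ml"),
        "brownian": pgls_fit(tree, response, predictors, 1.0),
        "null": pgls_fit(tree, response, predictors, 0.0),
    }
    a, w = aicc_weights([f.aicc for f in fits.values()])
    rows = []
    for (label, f), ai, wi in zip(fits.items(), a, w):
        rows.append(
            {
                "model": label,
                "lambda": f.lambda_,
                "loglik": f.loglik,
                "k": f.k,
                "AICc": ai,
                "AICw": wi,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model selection over a posterior sample of trees
# ---------------------------------------------------------------------------


@dataclass
class PosteriorSummary:
    """Per-tree Akaike weights and their across-tree medians."""

    weights: pd.DataFrame  # rows = trees, columns = models
    median_weights: pd.Series
    n_trees: int
    skipped: list = field(default_factory=list)


def fit_over_posterior(
    trees,
    trait: pd.Series,
    models: Sequence[str] = MODEL_NAMES,
    n_trees: int | None = None,
    species: Sequence[str] | None = None,
) -> PosteriorSummary:
    """Fit models across a posterior tree sample; summarize by median weight.

    Each tree is pruned to the species shared with ``trait`` (optionally
    first restricted to ``species``, e.g. one subfamily); per-tree Akaike
    weights are computed and the per-model median across trees reported.
    Trees missing more than half of the trait's species are skipped.
    """
    target = set(trait.index.astype(str))
    if species is not None:
        target &= set(map(str, species))
    if len(target) < 4:
        raise ValueError("fewer than 4 species available for posterior fitting")
    rows, skipped = [], []
    it = list(trees)
    if n_trees is not None:
        it = it[:n_trees]
    for i, tree in enumerate(it):
        present = {lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon}
        shared = target & present
        if len(shared) < max(4, len(target) // 2):
            skipped.append(i)
            warnings.warn(f"tree {i} shares too few tips ({len(shared)}); skipped")
            continue
        if shared != target:
            warnings.warn(f"tree {i}: {len(target - shared)} trait species absent; pruned")
        sub = prune_to(tree, shared)
        fits = fit_all_models(sub, trait.loc[sorted(shared)], models)
        rows.append({f.name: f.weight for f in fits})
    if not rows:
        raise ValueError("no usable trees in posterior sample")
    weights = pd.DataFrame(rows)
    return PosteriorSummary(
        weights=weights,
        median_weights=weights.median(axis=0),
        n_trees=len(rows),
        skipped=skipped,
    )
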