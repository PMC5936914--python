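"""Specialization-duration analyses: median split, quantile regression
with bootstrap, side-specific OLS/PGLS, and nested interactive models.

The carnivory axis is split at its median; each species' degree of
dietary specialization is its absolute distance from that median within
its half ("less" vs "more" carnivorous). Duration is regressed on
specialization per side — by OLS when the side shows no phylogenetic
signal, by PGLS otherwise — and, because duration variance shrinks
toward the dietary extremes (heteroscedasticity from preservation),
also by quantile regression at upper quantiles of duration.

Quantile fits minimize the pinball loss
``sum rho_tau(y - a - b x)``, ``rho_tau(u) = u (tau - 1{u < 0})``,
solved exactly as a linear program (HiGHS); standard errors come from an
xy-pair bootstrap, with two-sided p-values from a normal reference on
t = estimate / SE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from scipy.optimize import linprog

from .comparative import aicc, aicc_weights, pagel_lambda_ml, pgls_fit
from .trees import as_phylo_data, prune_to

__all__ = [
    "build_specialization_dataset",
    "quantile_fit",
    "quantile_regression",
    "fit_side_regressions",
    "nested_duration_models",
    "DEFAULT_TAUS",
]

DEFAULT_TAUS = (0.6, 0.7, 0.8, 0.9)


def build_specialization_dataset(
    scores: pd.DataFrame,
    durations: pd.DataFrame,
    exclusions: list | None = None,
    extra: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Merge carnivory scores with durations; split at the median.

    Species at or below the median carnivory go to the "less"
    carnivorous side, strictly above to "more" (the deterministic rule
    for ties at the median). specialization = |carnivory - median|.
    ``exclusions`` flags outlier species: they stay in the table but are
    excluded from every regression. ``extra`` (indexed by species) may
    carry log10_mass / maxLocCover columns for the nested models.
    """
    if scores.empty:
        raise ValueError("empty carnivory score table")
    df = scores[["species", "pc1"]].rename(columns={"pc1": "carnivory"}).copy()
    df = df.merge(durations[["species", "duration"]], on="species", how="inner")
    if df.empty:
        raise ValueError("no species shared between scores and durations")
    med = float(df["carnivory"].median())
    df["specialization"] = (df["carnivory"] - med).abs()
    df["side"] = np.where(df["carnivory"] > med, "more", "less")
    df["outlier"] = df["species"].isin(set(exclusions or []))
    if extra is not None:
        df = df.merge(extra, on="species", how="left")
    df.attrs["carnivory_median"] = med
    return df


def _pinball_loss(y, x, intercept, slope, tau):
    u = y - intercept - slope * x
    return float(np.sum(u * (tau - (u < 0))))


def quantile_fit(y, x, tau: float):
    """Exact pinball-loss minimizer (intercept, slope) via the LP
    formulation: min tau*1'u+ + (1-tau)*1'u- s.t. y = a + b x + u+ - u-."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(y)
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must be in (0, 1)")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor (zero variance)")
    c = np.concatenate([[0.0, 0.0], np.full(n, tau), np.full(n, 1.0 - tau)])
    A = np.hstack([np.ones((n, 1)), x[:, None], np.eye(n), -np.eye(n)])
    bounds = [(None, None), (None, None)] + [(0, None)] * (2 * n)
    res = linprog(c, A_eq=A, b_eq=y, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"quantile LP failed: {res.message}")
    return float(res.x[0]), float(res.x[1])


@dataclass
class QuantileFit:
    tau: float
    intercept: float
    intercept_se: float
    intercept_t: float
    intercept_p: float
    slope: float
    slope_se: float
    slope_t: float
    slope_p: float
    n_bootstrap: int
    slope_ci: tuple = field(default=(np.nan, np.nan))


def quantile_regression(
    y,
    x,
    taus=DEFAULT_TAUS,
    n_bootstrap: int = 10_000,
    seed=None,
) -> pd.DataFrame:
    """Quantile fits at each tau with xy-pair bootstrap SEs.

    Returns one row per tau: point estimates, bootstrap SEs, t =
    estimate/SE, two-sided normal-reference p, and 95% percentile CIs
    for the slope.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(y)
    if n < 5:
        raise ValueError("need at least 5 observations")
    rng = np.random.default_rng(seed)
    boot_idx = rng.integers(0, n, size=(n_bootstrap, n)) if n_bootstrap > 0 else None
    rows = []
    for tau in taus:
        a_hat, b_hat = quantile_fit(y, x, tau)
        if n_bootstrap > 0:
            boots = np.full((n_bootstrap, 2), np.nan)
            for r in range(n_bootstrap):
                idx = boot_idx[r]
                xb = x[idx]
                if np.ptp(xb) == 0:
                    continue
                boots[r] = quantile_fit(y[idx], xb, tau)
            se_a = float(np.nanstd(boots[:, 0], ddof=1))
            se_b = float(np.nanstd(boots[:, 1], ddof=1))
            ci = tuple(np.nanpercentile(boots[:, 1], [2.5, 97.5]))
        else:
            se_a = se_b = np.nan
            ci = (np.nan, np.nan)
        t_a = a_hat / se_a if se_a and se_a > 0 else np.nan
        t_b = b_hat / se_b if se_b and se_b > 0 else np.nan
        rows.append(
            QuantileFit(
                tau=tau,
                intercept=a_hat,
                intercept_se=se_a,
                intercept_t=t_a,
                intercept_p=float(2 * stats.norm.sf(abs(t_a))) if np.isfinite(t_a) else np.nan,
                slope=b_hat,
                slope_se=se_b,
                slope_t=t_b,
                slope_p=float(2 * stats.norm.sf(abs(t_b))) if np.isfinite(t_b) else np.nan,
                n_bootstrap=n_bootstrap,
                slope_ci=ci,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def fit_side_regressions(
    dataset: pd.DataFrame,
    tree=None,
    taus=DEFAULT_TAUS,
    n_bootstrap: int = 10_000,
    lambda_threshold: float = 0.1,
    seed=None,
) -> dict:
    """Duration ~ specialization per carnivory side.

    Per side (outliers excluded): Pagel's lambda of the PGLS residual
    structure decides the method — OLS when lambda is ~0 (below
    ``lambda_threshold``), PGLS with ML lambda otherwise. Quantile
    regressions run on both sides at every tau. Requires a tree whenever
    PGLS is selected.
    """
    out = {}
    rng = np.random.default_rng(seed)
    for side in ("less", "more"):
        sub = dataset[(dataset["side"] == side) & (~dataset["outlier"])]
        if len(sub) < 5:
            raise ValueError(f"side {side!r} has fewer than 5 non-outlier species")
        y = sub["duration"].to_numpy(dtype=float)
        x = sub["specialization"].to_numpy(dtype=float)
        lam = None
        if tree is not None:
            ptree = prune_to(tree, sub["species"])
            pdata = as_phylo_data(ptree)
            ys = pd.Series(y, index=sub["species"])
            xs = pd.DataFrame({"specialization": x}, index=sub["species"])
            fit_ml = pgls_fit(pdata, ys, xs, lambda_mode="ml")
            lam = fit_ml.lambda_
        if lam is not None and lam > lambda_threshold:
            method = "pgls"
            fit = fit_ml
            slope = float(fit.params["specialization"])
            slope_p = float(fit.pvalues["specialization"])
        else:
            if lam is None and tree is None:
                warnings.warn(f"no tree supplied; side {side!r} analysed by OLS")
            method = "ols"
            ols = sm.OLS(y, sm.add_constant(x)).fit()
            slope = float(ols.params[1])
            slope_p = float(ols.pvalues[1])
            fit = ols
        qr = quantile_regression(
            y, x, taus=taus, n_bootstrap=n_bootstrap, seed=rng.integers(2**31)
        )
        out[side] = {
            "n": len(sub),
            "method": method,
            "lambda": lam,
            "slope": slope,
            "slope_p": slope_p,
            "fit": fit,
            "quantile": qr,
        }
    return out


# the five nested duration models; interaction models are full factorial
NESTED_FORMULAS = {
    "body mass only": "duration ~ log10_mass",
    "carnivory only": "duration ~ carnivory",
    "maxLocCover only": "duration ~ maxLocCover",
    "body mass and carnivory": "duration ~ log10_mass * carnivory",
    "body mass, carnivory and maxLocCover": "duration ~ log10_mass * carnivory * maxLocCover",
}


def nested_duration_models(table: pd.DataFrame) -> pd.DataFrame:
    """Five nested OLS models of duration (complete cases only).

    Single-predictor models have k = 2 mean parameters; the two- and
    three-way interactive models are full factorial (k = 4 and k = 8).
    AICc counts only mean parameters; weights, adjusted R^2 and the
    overall F-test p are reported per model.
    """
    need = ["duration", "log10_mass", "carnivory", "maxLocCover"]
    missing = [c for c in need if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    df = table[need].dropna()
    n = len(df)
    if n <= 9:
        raise ValueError("need n > 9 complete cases for the full factorial model")
    rows = []
    fits = []
    for name, formula in NESTED_FORMULAS.items():
        res = smf.ols(formula, data=df).fit()
        k = int(res.df_model) + 1  # mean parameters incl. intercept
        fits.append((name, res, k))
    _, w = aicc_weights(fits=[(r.llf, k) for _, r, k in fits], n=n)
    for (name, res, k), wi in zip(fits, w):
        rows.append(
            {
                "model": name,
                "loglik": float(res.llf),
                "k": k,
                "AICc": aicc(res.llf, k, n),
                "AICw": float(wi),
                "adj_R2": float(res.rsquared_adj),
                "p": float(res.f_pvalue),
                "n": n,
            }
        )
    return pd.DataFrame(rows)
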