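"""Fossil-record statistics: filtering, grid-cell occupancy, and
preservation-adjusted species durations.

Durations: the observed stratigraphic range (FAD to LAD) understates a
species' true lifespan because preservation is incomplete. We model each
species' occurrence ages as a homogeneous Poisson process at rate ``q``
(occurrences/Myr) on its true lifespan (TE, TS), so the per-species
likelihood given k occurrences is ``q^k * exp(-q (TS - TE))`` with
TS >= oldest and TE <= youngest occurrence age. Across species, (TS, TE)
follow a constant-rate birth-death prior with rates (lambda_bd, mu_bd):
``L_BD = lambda^S * mu^E * exp(-(lambda + mu) * sum durations)`` for S
species and E extinct species. Sampling is Metropolis-within-Gibbs:
sliding-window Metropolis updates for every TS_i and TE_i (vectorized —
the posterior factorizes over species given the rates) and conjugate
gamma Gibbs draws for q, lambda_bd and mu_bd. Posterior medians of TS
and TE give the sampling-adjusted duration median(TS) - median(TE).

Occupancy: occurrences are binned to half-degree cells and to time
slices (by age-interval midpoint); a species' occupancy in a slice is
the number of cells it occupies divided by the number of cells occupied
by any included species in that slice, and maximum locality coverage is
the maximum over slices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "filter_species",
    "assign_grid_cell",
    "TimeSliceTable",
    "default_time_slices",
    "occupancy_by_slice",
    "max_locality_coverage",
    "MCMCSettings",
    "DurationResult",
    "estimate_durations",
]

OCCURRENCE_COLUMNS = [
    "species", "subfamily", "locality_id", "lat", "lon",
    "max_age_ma", "min_age_ma", "extant",
]


def _validate_occurrences(occ: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("species", "max_age_ma", "min_age_ma") if c not in occ.columns]
    if missing:
        raise ValueError(f"occurrence table missing columns: {missing}")
    if np.any(occ["max_age_ma"].to_numpy() < occ["min_age_ma"].to_numpy()):
        raise ValueError("max_age_ma < min_age_ma for some occurrences")
    if np.any(occ["min_age_ma"].to_numpy() < 0):
        raise ValueError("negative ages")
    return occ


def filter_species(occ: pd.DataFrame):
    """Exclude extant species and singletons (single-locality species).

    Duration and coverage estimates for single-locality species are
    dominated by preservation failure, and extant ranges are
    anthropogenically constrained, so both are dropped. Returns
    ``(included_species, report)`` where report counts species per
    exclusion reason; the three groups partition the species set.
    """
    _validate_occurrences(occ)
    included, singletons, extants = [], [], []
    for sp, grp in occ.groupby("species", sort=True):
        if "extant" in occ.columns and bool(grp["extant"].any()):
            extants.append(sp)
        elif grp["locality_id"].nunique() <= 1:
            singletons.append(sp)
        else:
            included.append(sp)
    report = {
        "included": len(included),
        "singleton": len(singletons),
        "extant": len(extants),
        "singleton_species": singletons,
        "extant_species": extants,
    }
    return included, report


def assign_grid_cell(lat, lon, cell_size: float = 0.5):
    """Half-open grid cells [x, x+size) on each axis; returns index pair."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise ValueError("coordinates out of range")
    la = np.floor(lat / cell_size).astype(int)
    lo = np.floor(lon / cell_size).astype(int)
    if np.ndim(lat) == 0:
        return int(la), int(lo)
    return la, lo


@dataclass(frozen=True)
class TimeSliceTable:
    """Ordered, contiguous time slices (ages in Ma, old to young)."""

    names: tuple[str, ...]
    old: tuple[float, ...]
    young: tuple[float, ...]

    def __post_init__(self):
        o, y = np.asarray(self.old), np.asarray(self.young)
        if len(self.names) == 0:
            raise ValueError("empty slice table")
        if not np.all(o > y):
            raise ValueError("each slice needs old > young")
        if not np.allclose(o[1:], y[:-1]):
            raise ValueError("slices must be contiguous (old[i+1] == young[i])")

    @property
    def boundaries(self) -> np.ndarray:
        return np.concatenate([[self.old[0]], np.asarray(self.young)])

    def assign(self, ages) -> np.ndarray:
        """Slice index per age; -1 outside the table's span.

        A slice covers (young, old]; the youngest slice also includes
        its young boundary (so an age of exactly 0 is assigned).
        """
        ages = np.asarray(ages, dtype=float)
        b = self.boundaries  # descending
        idx = np.searchsorted(-b, -ages, side="left") - 1
        idx = np.where(ages == b[0], 0, idx)
        idx = np.where(ages == b[-1], len(self.names) - 1, idx)
        out = np.where((ages > b[0]) | (ages < b[-1]), -1, idx)
        return out.astype(int)

    @classmethod
    def from_boundaries(cls, boundaries, names=None) -> "TimeSliceTable":
        b = np.asarray(boundaries, dtype=float)
        old, young = b[:-1], b[1:]
        if names is None:
            names = tuple(f"slice_{i + 1:02d}_{o:g}-{y:g}Ma" for i, (o, y) in enumerate(zip(old, young)))
        return cls(names=tuple(names), old=tuple(old), young=tuple(young))

    @classmethod
    def from_csv(cls, path) -> "TimeSliceTable":
        df = pd.read_csv(path)
        return cls(names=tuple(df["name"]), old=tuple(df["old_ma"]), young=tuple(df["young_ma"]))

    def to_csv(self, path) -> None:
        pd.DataFrame({"name": self.names, "old_ma": self.old, "young_ma": self.young}).to_csv(
            path, index=False
        )


def default_time_slices() -> TimeSliceTable:
    """Approximate 18-slice subdivision of the North American land-mammal
    ages spanning the canid record (~40-0 Ma); user-replaceable."""
    from .simulate import DEFAULT_SLICE_BOUNDARIES

    return TimeSliceTable.from_boundaries(DEFAULT_SLICE_BOUNDARIES)


def occupancy_by_slice(
    occ: pd.DataFrame,
    slices: TimeSliceTable,
    species: list | None = None,
    cell_size: float = 0.5,
) -> pd.DataFrame:
    """Per-species, per-slice occupancy proportions.

    An occurrence belongs to the slice containing its age-interval
    midpoint. occupancy(s, t) = cells occupied by s in t / cells
    occupied by any included species in t; slices with an empty
    denominator yield NaN for every species.
    """
    _validate_occurrences(occ)
    if species is not None:
        occ = occ[occ["species"].isin(set(species))]
    occ = occ.copy()
    mid = (occ["max_age_ma"].to_numpy() + occ["min_age_ma"].to_numpy()) / 2.0
    occ["slice_idx"] = slices.assign(mid)
    occ = occ[occ["slice_idx"] >= 0]
    la, lo = assign_grid_cell(occ["lat"].to_numpy(), occ["lon"].to_numpy(), cell_size)
    occ["cell"] = list(zip(la, lo))
    all_species = sorted(occ["species"].unique())
    table = pd.DataFrame(np.nan, index=all_species, columns=list(slices.names))
    for idx, grp in occ.groupby("slice_idx"):
        denom = grp["cell"].nunique()
        if denom == 0:
            continue
        counts = grp.groupby("species")["cell"].nunique()
        table.loc[counts.index, slices.names[idx]] = counts.to_numpy() / denom
    return table


def max_locality_coverage(occupancy: pd.DataFrame) -> pd.DataFrame:
    """Maximum per-species occupancy over slices; ties go to the older
    slice (columns are ordered old to young)."""
    rows = []
    for sp, row in occupancy.iterrows():
        vals = row.to_numpy(dtype=float)
        if np.all(np.isnan(vals)):
            continue
        i = int(np.nanargmax(vals))  # first (= oldest) argmax on ties
        rows.append({"species": sp, "maxLocCover": float(vals[i]), "argmax_slice": row.index[i]})
    return pd.DataFrame(rows, columns=["species", "maxLocCover", "argmax_slice"])


# ---------------------------------------------------------------------------
# duration MCMC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MCMCSettings:
    """Desk-scale default chain; raise ``iterations`` for production runs
    (the classic setting is 1e7 iterations with 2e5 burn-in)."""

    iterations: int = 500_000
    burnin: int | None = None  # None -> 10% of iterations
    thin: int = 100
    seed: int = 0
    proposal_sd: float = 0.5  # Myr, sliding-window TS/TE updates
    pad: float = 15.0  # Myr, uniform prior window beyond FAD/LAD
    gamma_prior: tuple[float, float] = (1.01, 0.01)  # shape, rate (vague)

    def __post_init__(self):
        if self.iterations <= 0:
            raise ValueError("iterations must be positive")
        bi = self.burnin if self.burnin is not None else self.iterations // 10
        if bi >= self.iterations:
            raise ValueError("burnin must be < iterations")

    @property
    def burnin_(self) -> int:
        return self.burnin if self.burnin is not None else self.iterations // 10


@dataclass
class DurationResult:
    """Posterior summaries and thinned samples of (TS, TE, q)."""

    table: pd.DataFrame  # species, FAD, LAD, TS/TE medians, duration, q_mean, ESS
    species: list
    ts_samples: np.ndarray  # (n_samples, n_species)
    te_samples: np.ndarray
    q_samples: np.ndarray
    lambda_samples: np.ndarray
    mu_samples: np.ndarray
    settings: MCMCSettings = field(repr=False, default=None)

    def credible_interval(self, which: str = "ts", level: float = 0.95) -> pd.DataFrame:
        s = {"ts": self.ts_samples, "te": self.te_samples}[which]
        lo = np.percentile(s, 100 * (1 - level) / 2, axis=0)
        hi = np.percentile(s, 100 * (1 + level) / 2, axis=0)
        return pd.DataFrame({"species": self.species, "lower": lo, "upper": hi})


def _ess(x: np.ndarray) -> float:
    """Autocorrelation-time effective sample size (initial positive
    sequence truncation)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 10 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1) * np.var(x))
    tau = 1.0
    for k in range(1, min(n // 2, 1000)):
        if acf[k] <= 0:
            break
        tau += 2.0 * acf[k]
    return float(n / tau)


def estimate_durations(
    occ: pd.DataFrame,
    mcmc: MCMCSettings | None = None,
    q_fixed: float | None = None,
    bd_prior: bool = True,
    age_mode: str = "midpoint",
) -> DurationResult:
    """Sampling-adjusted species durations from occurrence data.

    Occurrence ages enter as interval midpoints (``age_mode="midpoint"``,
    default) or as latent ages redrawn within their dating intervals
    during the chain (``age_mode="resample"``). ``q_fixed`` pins the
    preservation rate (useful for oracles and the perfect-sampling
    limit); ``bd_prior=False`` drops the birth-death prior, leaving
    uniform priors on TS and TE within the padded window. Extant species
    have TE fixed at 0.
    """
    _validate_occurrences(occ)
    if occ.empty:
        raise ValueError("no occurrences")
    if age_mode not in ("midpoint", "resample"):
        raise ValueError("age_mode must be 'midpoint' or 'resample'")
    mcmc = mcmc or MCMCSettings()
    rng = np.random.default_rng(mcmc.seed)
    a0, b0 = mcmc.gamma_prior

    occ = occ.sort_values("species", kind="stable").reset_index(drop=True)
    species = list(dict.fromkeys(occ["species"]))
    sp_idx = occ["species"].map({s: i for i, s in enumerate(species)}).to_numpy()
    S = len(species)
    lo_i = occ["min_age_ma"].to_numpy(dtype=float)
    hi_i = occ["max_age_ma"].to_numpy(dtype=float)
    ages = (lo_i + hi_i) / 2.0
    k = np.bincount(sp_idx, minlength=S).astype(float)
    extant = np.zeros(S, dtype=bool)
    if "extant" in occ.columns:
        for i, s in enumerate(species):
            extant[i] = bool(occ.loc[occ["species"] == s, "extant"].any())

    def _fad_lad(a):
        fad = np.full(S, -np.inf)
        lad = np.full(S, np.inf)
        np.maximum.at(fad, sp_idx, a)
        np.minimum.at(lad, sp_idx, a)
        return fad, lad

    fad, lad = _fad_lad(ages)
    ts_hi = fad + mcmc.pad
    te_lo = np.maximum(lad - mcmc.pad, 0.0)
    ts = fad + 0.1 * mcmc.pad
    te = np.where(extant, 0.0, np.maximum(lad - 0.1 * mcmc.pad, te_lo))

    q = q_fixed if q_fixed is not None else 1.0
    lam = mu = 0.0
    if bd_prior:
        lam, mu = 0.2, 0.2

    n_iter, burn, thin = mcmc.iterations, mcmc.burnin_, mcmc.thin
    keep = max((n_iter - burn) // thin, 1)
    ts_out = np.empty((keep, S))
    te_out = np.empty((keep, S))
    q_out = np.empty(keep)
    lam_out = np.empty(keep)
    mu_out = np.empty(keep)
    kept = 0
    sd = mcmc.proposal_sd

    for it in range(n_iter):
        total_rate = q + (lam + mu if bd_prior else 0.0)
        # vectorized sliding-window Metropolis on TS (posterior
        # factorizes over species given the rates)
        prop = ts + rng.normal(0.0, sd, S)
        ok = (prop >= fad) & (prop <= ts_hi) & (prop >= te)
        acc = ok & (np.log(rng.uniform(size=S)) < -total_rate * (prop - ts))
        ts = np.where(acc, prop, ts)
        # TE update (extant species pinned at 0)
        prop = te + rng.normal(0.0, sd, S)
        ok = (prop <= lad) & (prop >= te_lo) & (prop <= ts) & ~extant
        acc = ok & (np.log(rng.uniform(size=S)) < -total_rate * (te - prop))
        te = np.where(acc, prop, te)

        dur_sum = float(np.sum(ts - te))
        if q_fixed is None:  # conjugate gamma full conditional
            q = rng.gamma(a0 + k.sum(), 1.0 / (b0 + dur_sum))
        if bd_prior:
            lam = rng.gamma(a0 + S, 1.0 / (b0 + dur_sum))
            mu = rng.gamma(a0 + float(np.sum(~extant)), 1.0 / (b0 + dur_sum))

        if age_mode == "resample":
            # latent occurrence ages: uniform priors on the dating
            # intervals; likelihood depends on them only through the
            # order constraints TE <= age <= TS
            prop_a = rng.uniform(lo_i, hi_i)
            ok = (prop_a <= ts[sp_idx]) & (prop_a >= te[sp_idx])
            ages = np.where(ok, prop_a, ages)
            fad, lad = _fad_lad(ages)

        if it >= burn and (it - burn) % thin == 0 and kept < keep:
            ts_out[kept] = ts
            te_out[kept] = te
            q_out[kept] = q
            lam_out[kept] = lam
            mu_out[kept] = mu
            kept += 1

    ts_out, te_out = ts_out[:kept], te_out[:kept]
    q_out, lam_out, mu_out = q_out[:kept], lam_out[:kept], mu_out[:kept]
    ts_med = np.median(ts_out, axis=0)
    te_med = np.median(te_out, axis=0)
    if age_mode == "midpoint":
        fad_rep, lad_rep = fad, lad
    else:
        fad_rep, lad_rep = _fad_lad((lo_i + hi_i) / 2.0)
    table = pd.DataFrame(
        {
            "species": species,
            "n_occurrences": k.astype(int),
            "FAD": fad_rep,
            "LAD": lad_rep,
            "TS_median": ts_med,
            "TE_median": te_med,
            "duration": ts_med - te_med,
            "q_mean": float(np.mean(q_out)),
            "q_ESS": _ess(q_out),
        }
    )
    return DurationResult(
        table=table,
        species=species,
        ts_samples=ts_out,
        te_samples=te_out,
        q_samples=q_out,
        lambda_samples=lam_out,
        mu_samples=mu_out,
        settings=mcmc,
    )
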