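"""Synthetic data with known ground truth for every pipeline stage.

Generates (a) constant-rate birth-death trees retaining extinct tips,
(b) tip traits drawn from the exact multivariate normal law of any of the
six trait-evolution models, (c) fossil occurrence records produced by a
homogeneous-Poisson preservation process on each species' true lifespan,
placed on a half-degree-style geographic grid, and (d) extant
morphometric tables with diet-category structure for training the
carnivory index.

All randomness flows through a single :class:`numpy.random.Generator`;
a fixed seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .comparative import ModelSpec, model_mean_cov
from .trees import PhyloData, as_phylo_data

__all__ = [
    "DEFAULT_SLICE_BOUNDARIES",
    "DEFAULT_DIET_CENTROIDS",
    "SimulationConfig",
    "TrueHistory",
    "simulate_tree",
    "simulate_trait",
    "simulate_posterior_sample",
    "simulate_fossil_record",
    "simulate_extant_morphoset",
    "simulate_fossil_morphoset",
]

# 18 contiguous time slices subdividing the North American land-mammal
# ages over the span of the canid fossil record (~40 Ma to present).
# Approximate boundaries; user-replaceable via a slice table CSV.
DEFAULT_SLICE_BOUNDARIES = (
    40.0, 37.0, 34.5, 32.0, 30.0, 28.0, 26.0, 24.0, 22.0,
    20.0, 18.0, 16.0, 14.0, 12.0, 10.0, 8.0, 6.0, 3.0, 0.0,
)

# (RBL, RUGA, JD/DL) centroids per diet category. Ordering constraints:
# the hyaenid-like (bone-cracking) centroid has the highest RBL and
# JD/DL and the lowest RUGA; hypocarnivores the reverse.
DEFAULT_DIET_CENTROIDS = {
    "hypocarnivore": (0.55, 1.10, 0.115),
    "mesocarnivore": (0.66, 0.80, 0.135),
    "hypercarnivore": (0.80, 0.50, 0.160),
    "hyaenid": (0.93, 0.33, 0.195),
}
# matches the 45-species extant comparative set (3 hyaenids)
DEFAULT_N_PER_CATEGORY = {
    "hypocarnivore": 12,
    "mesocarnivore": 15,
    "hypercarnivore": 15,
    "hyaenid": 3,
}
# per-ratio Gaussian noise SD around the centroid, scaled by noise_sd
_RATIO_NOISE_BASE = np.array([0.035, 0.15, 0.015])


@dataclass(frozen=True)
class SimulationConfig:
    """Rates and geometry of one synthetic study system.

    Rates are per-lineage per Myr; the preservation rate ``q`` is
    occurrences per species per Myr. ``grid_extent`` is
    (lat_min, lat_max, lon_min, lon_max) in degrees.
    """

    seed: int = 0
    n_tips: int = 60
    birth_rate: float = 0.25
    death_rate: float = 0.18
    preservation_rate_q: float = 1.5
    grid_extent: tuple[float, float, float, float] = (25.0, 50.0, -125.0, -95.0)
    slice_boundaries: tuple[float, ...] = DEFAULT_SLICE_BOUNDARIES
    trait_model_spec: ModelSpec = field(
        default_factory=lambda: ModelSpec("BM", {"z0": 0.0, "sigma2": 0.05})
    )
    geo_sd: float = 1.5  # per-species geographic kernel SD, degrees
    dating_halfwidth: float | None = None  # None -> half the enclosing slice
    locality_res: float = 0.1  # degrees; occurrences binned to localities

    def __post_init__(self):
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be > 0")
        if self.death_rate < 0:
            raise ValueError("death_rate must be >= 0")
        if self.preservation_rate_q <= 0:
            raise ValueError("preservation_rate_q must be > 0")
        b = np.asarray(self.slice_boundaries)
        if not np.all(np.diff(b) < 0):
            raise ValueError("slice_boundaries must be strictly decreasing in age")
        lat0, lat1, lon0, lon1 = self.grid_extent
        if not (lat0 < lat1 and lon0 < lon1):
            raise ValueError("grid_extent must be (lat_min, lat_max, lon_min, lon_max)")


@dataclass
class TrueHistory:
    """Ground truth: per-species true origination/extinction ages (Ma).

    ``table`` columns: species, subfamily, ts, te, extant; ts >= te >= 0
    and extinct species have te > 0. ``model`` records the generating
    trait model once a trait has been simulated.
    """

    table: pd.DataFrame
    present: float
    model: ModelSpec | None = None

    def __post_init__(self):
        t = self.table
        if not np.all(t["ts"].to_numpy() >= t["te"].to_numpy() - 1e-12):
            raise ValueError("every species must have ts >= te")
        if not np.all(t["te"].to_numpy() >= 0):
            raise ValueError("te must be >= 0")


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_tree(
    config: SimulationConfig,
    rng=None,
    stop: str = "n_tips",
    max_age: float | None = None,
    retries: int = 1000,
):
    """Simulate a constant-rate birth-death tree, extinct lineages kept.

    The process starts from the root split (two lineages at time 0).
    With ``stop="n_tips"`` (default) the simulation runs until the total
    number of tips (extinct so far + alive) reaches ``config.n_tips``;
    the present is placed uniformly between that moment and the next
    event, so the tree is conditioned on tip count. With ``stop="age"``
    the simulation runs to ``max_age`` and the realized tip count is
    random. Replicates where the clade dies out first are retried (up to
    ``retries``); exhausting the budget signals an infeasible rate
    combination.

    Returns ``(dendropy.Tree, TrueHistory)``. Tip ages: a species'
    ``ts`` is the age at which its terminal branch began (budding
    speciation convention), ``te`` its extinction age (0 if extant).
    """
    rng = _as_rng(rng if rng is not None else config.seed)
    b, d = config.birth_rate, config.death_rate
    if stop == "age" and max_age is None:
        raise ValueError("stop='age' requires max_age")
    for _ in range(retries):
        out = _bd_attempt(config.n_tips, b, d, rng, stop, max_age)
        if out is not None:
            return out
    raise RuntimeError(
        f"birth-death simulation failed to reach {config.n_tips} tips in "
        f"{retries} attempts (birth={b}, death={d})"
    )


def _bd_attempt(n_tips, b, d, rng, stop, max_age):
    # active lineages: (birth_time, dendropy node)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    root.birth_time = 0.0
    kids = [dendropy.Node(), dendropy.Node()]
    for k in kids:
        root.add_child(k)
        k.birth_time = 0.0
    alive = list(kids)
    done = []  # (node, birth, death)
    t = 0.0
    rate_per = b + d
    while True:
        n_total = len(alive) + len(done)
        if stop == "n_tips" and n_total >= n_tips and alive:
            # the present falls at a random instant while the clade has
            # n tips; by memorylessness the elapsed time since the last
            # event at such an instant is again Exp(n * total rate)
            present = t + rng.exponential(1.0 / (len(alive) * rate_per))
            break
        if not alive:
            return None  # clade extinct before reaching the stopping rule
        wait = rng.exponential(1.0 / (len(alive) * rate_per))
        if stop == "age" and t + wait > max_age:
            present = max_age
            break
        t += wait
        i = rng.integers(len(alive))
        node = alive.pop(i)
        if rng.uniform() < b / rate_per:
            c1, c2 = dendropy.Node(), dendropy.Node()
            node.add_child(c1)
            node.add_child(c2)
            node.edge.length = t - node.birth_time
            c1.birth_time = c2.birth_time = t
            alive.extend([c1, c2])
        else:
            done.append((node, node.birth_time, t))
    if stop == "age" and len(alive) + len(done) < 2:
        return None
    if stop == "age" and not alive and len(done) < 2:
        return None

    records = []
    counter = 0
    for node, birth, death in done:
        counter += 1
        node.edge.length = death - birth
        node._tip_info = (birth, death)
    for node in alive:
        node.edge.length = present - node.birth_time
        node._tip_info = (node.birth_time, present)
    # deterministic labels in traversal order
    width = max(3, len(str(len(alive) + len(done))))
    i = 0
    rows = []
    clade_of = {}
    for child, name in zip(tree.seed_node.child_nodes(), ("A", "B")):
        for nd in child.preorder_iter():
            clade_of[nd] = name
    for leaf in tree.leaf_node_iter():
        i += 1
        label = f"t{str(i).zfill(width)}"
        leaf.taxon = taxa.new_taxon(label)
        birth, death = leaf._tip_info
        rows.append(
            {
                "species": label,
                "subfamily": f"subfamily_{clade_of[leaf]}",
                "ts": present - birth,
                "te": present - death,
                "extant": bool(death == present),
            }
        )
    history = TrueHistory(table=pd.DataFrame(rows), present=float(present))
    return tree, history


def simulate_trait(tree, spec: ModelSpec, seed=None) -> pd.Series:
    """Draw tip values from the exact MVN law implied by ``spec``."""
    rng = _as_rng(seed)
    pdata = as_phylo_data(tree)
    mean, cov = model_mean_cov(pdata, spec)
    L = np.linalg.cholesky(cov)
    x = mean + L @ rng.standard_normal(pdata.n)
    return pd.Series(x, index=list(pdata.labels), name=spec.name)


def simulate_posterior_sample(tree, n_trees: int, jitter_sd: float = 0.1, seed=None):
    """Emulate a tip-dated posterior: lognormal edge-length jitter.

    Returns a :class:`dendropy.TreeList` of ``n_trees`` copies of
    ``tree`` with every edge length multiplied by an independent
    lognormal(0, jitter_sd) factor — same topology and tip set,
    perturbed divergence times, as in a posterior sample of
    time-calibrated trees.
    """
    rng = _as_rng(seed)
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    out = dendropy.TreeList(taxon_namespace=tree.taxon_namespace)
    for _ in range(n_trees):
        t = tree.clone(depth=1)
        for edge in t.preorder_edge_iter():
            if edge.length is not None:
                edge.length = float(edge.length) * float(rng.lognormal(0.0, jitter_sd))
        out.append(t)
    return out


def _slice_halfwidth(age, boundaries):
    b = np.asarray(boundaries)
    widths = -np.diff(b)  # positive
    idx = np.clip(np.searchsorted(-b, -age, side="left") - 1, 0, len(widths) - 1)
    return widths[idx] / 2.0


def simulate_fossil_record(history: TrueHistory, config: SimulationConfig, rng=None) -> pd.DataFrame:
    """Homogeneous-Poisson preservation of every species' true lifespan.

    For each species, occurrence ages are a Poisson process at rate
    ``q`` on [te, ts]; coordinates come from a per-species Gaussian
    kernel inside ``grid_extent``; the dating interval is the true age
    plus/minus ``dating_halfwidth`` (default: half the enclosing time
    slice, mimicking land-mammal-age binning). Species with zero
    occurrences are omitted.
    """
    if history.table.empty:
        raise ValueError("empty history")
    rng = _as_rng(rng if rng is not None else config.seed)
    q = config.preservation_rate_q
    lat0, lat1, lon0, lon1 = config.grid_extent
    res = config.locality_res
    rows = []
    for rec in history.table.itertuples(index=False):
        dur = rec.ts - rec.te
        n_occ = rng.poisson(q * dur) if dur > 0 else 0
        if n_occ == 0:
            continue
        ages = np.sort(rng.uniform(rec.te, rec.ts, size=n_occ))[::-1]
        c_lat = rng.uniform(lat0, lat1)
        c_lon = rng.uniform(lon0, lon1)
        lats = np.clip(rng.normal(c_lat, config.geo_sd, n_occ), lat0, lat1)
        lons = np.clip(rng.normal(c_lon, config.geo_sd, n_occ), lon0, lon1)
        if config.dating_halfwidth is not None:
            hw = np.full(n_occ, config.dating_halfwidth)
        else:
            hw = _slice_halfwidth(ages, config.slice_boundaries)
        for j in range(n_occ):
            rows.append(
                {
                    "species": rec.species,
                    "subfamily": rec.subfamily,
                    "locality_id": f"L{int(np.floor(lats[j] / res))}x{int(np.floor(lons[j] / res))}",
                    "lat": lats[j],
                    "lon": lons[j],
                    "max_age_ma": ages[j] + hw[j],
                    "min_age_ma": max(ages[j] - hw[j], 0.0),
                    "extant": bool(rec.extant),
                    # synthetic ground truth, not part of the standard schema
                    "true_age_ma": ages[j],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "species", "subfamily", "locality_id", "lat", "lon",
            "max_age_ma", "min_age_ma", "extant", "true_age_ma",
        ],
    )


def simulate_extant_morphoset(
    n_per_category: dict | None = None,
    category_means: dict | None = None,
    noise_sd: float = 1.0,
    seed=None,
) -> pd.DataFrame:
    """Extant comparative morphometrics with diet-category structure.

    Each species' three dietary ratios are its category centroid plus
    Gaussian noise (``noise_sd`` scales the per-ratio base SDs; 0 puts
    every species exactly on its centroid). Raw characters (m1 length,
    blade length, grinding area, P4 length, jaw depth, dentary length)
    are reconstructed consistently with the ratios so the table can also
    train the dentary-length imputer.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = _as_rng(seed)
    n_per_category = dict(DEFAULT_N_PER_CATEGORY if n_per_category is None else n_per_category)
    centroids = dict(DEFAULT_DIET_CENTROIDS if category_means is None else category_means)
    typical_m1 = {"hypocarnivore": 12.0, "mesocarnivore": 18.0, "hypercarnivore": 25.0, "hyaenid": 28.0}
    rows = []
    for cat, n in n_per_category.items():
        if n == 0:
            continue
        mu = np.asarray(centroids[cat], dtype=float)
        for i in range(n):
            rbl, ruga, jddl = mu + noise_sd * _RATIO_NOISE_BASE * rng.standard_normal(3)
            rbl = float(np.clip(rbl, 0.05, 1.0))
            ruga = float(max(ruga, 0.05))
            jddl = float(max(jddl, 0.02))
            m1 = float(typical_m1.get(cat, 18.0) * rng.lognormal(0.0, 0.15))
            p4 = 0.95 * m1
            dentary = 10 ** (0.95 + 1.0 * np.log10(m1))
            rows.append(
                {
                    "species": f"ext_{cat[:5]}_{i + 1:02d}",
                    "diet_category": cat,
                    "subfamily": "extant_caniform",
                    "m1_length": m1,
                    "trigonid_blade_length": rbl * m1,
                    "upper_grinding_area": (ruga * p4) ** 2,
                    "p4_length": p4,
                    "jaw_depth": jddl * dentary,
                    "dentary_length": dentary,
                }
            )
    return pd.DataFrame(rows)


# direction in ratio space along which the carnivory score moves
# (more carnivorous: longer blade, less grinding area, deeper jaw)
_CARNIVORY_DIRECTION = np.array([0.06, -0.16, 0.012])


def simulate_fossil_morphoset(
    carnivory: pd.Series,
    log10_mass: pd.Series,
    subfamily: pd.Series | None = None,
    mass_coeffs=(-2.27, 2.97),
    dentary_missing_frac: float = 0.35,
    noise_sd: float = 0.3,
    seed=None,
) -> pd.DataFrame:
    """Fossil morphometrics whose carnivory index tracks a known trait.

    Ratios are the mesocarnivore centroid shifted along a fixed
    carnivory direction by the (standardized) input trait plus noise;
    m1 length is back-calculated from log10 body mass through the mass
    regression; dentary length (and hence the measured jaw-depth ratio's
    denominator) is deleted for a random fraction of species to exercise
    the imputation path. Subfamilies get slightly different dentary
    allometries, as in real canid subfamilies.
    """
    rng = _as_rng(seed)
    a, b = mass_coeffs
    c = carnivory.astype(float)
    z = (c - c.mean()) / (c.std(ddof=1) if c.std(ddof=1) > 0 else 1.0)
    base = np.asarray(DEFAULT_DIET_CENTROIDS["mesocarnivore"])
    sf_intercept = {"subfamily_A": 0.93, "subfamily_B": 0.97}
    rows = []
    for sp in c.index:
        ratios = base + z[sp] * _CARNIVORY_DIRECTION + noise_sd * _RATIO_NOISE_BASE * rng.standard_normal(3)
        rbl = float(np.clip(ratios[0], 0.05, 1.0))
        ruga = float(max(ratios[1], 0.05))
        jddl = float(max(ratios[2], 0.02))
        m1 = float(10 ** ((log10_mass[sp] - a) / b))
        p4 = 0.95 * m1
        sf = subfamily[sp] if subfamily is not None else "subfamily_A"
        dentary = 10 ** (sf_intercept.get(sf, 0.95) + 1.0 * np.log10(m1))
        missing = rng.uniform() < dentary_missing_frac
        rows.append(
            {
                "species": sp,
                "diet_category": np.nan,
                "subfamily": sf,
                "m1_length": m1,
                "trigonid_blade_length": rbl * m1,
                "upper_grinding_area": (ruga * p4) ** 2,
                "p4_length": p4,
                "jaw_depth": jddl * dentary,
                "dentary_length": np.nan if missing else dentary,
            }
        )
    return pd.DataFrame(rows)
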