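"""End-to-end orchestration: from occurrence + morphometric + tree inputs
(or a fully synthetic study system) to the four result tables.

Stage order: dietary ratios and carnivory index -> body mass ->
preservation-adjusted durations -> grid occupancy -> merged species
table -> phylogenetic-signal summary -> median-split specialization and
quantile regressions -> nested duration models -> trait-evolution model
selection over the posterior tree sample.

A master seed drives every stochastic stage through spawned child seeds,
so a rerun with the same configuration is byte-identical. A JSON
manifest records the configuration, seeds and package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .comparative import (
    MODEL_NAMES,
    ModelSpec,
    blomberg_k,
    fit_over_posterior,
    pagel_lambda_ml,
)
from .ecomorph import (
    DEFAULT_MASS_COEFFS,
    MassCoefficients,
    compute_dietary_ratios,
    estimate_body_mass,
    fit_carnivory_index,
    fit_dentary_imputer,
    project_carnivory,
)
from .fossilrecord import (
    MCMCSettings,
    TimeSliceTable,
    default_time_slices,
    estimate_durations,
    filter_species,
    max_locality_coverage,
    occupancy_by_slice,
)
from .regression import (
    DEFAULT_TAUS,
    build_specialization_dataset,
    fit_side_regressions,
    nested_duration_models,
)
from .simulate import (
    SimulationConfig,
    simulate_extant_morphoset,
    simulate_fossil_morphoset,
    simulate_fossil_record,
    simulate_posterior_sample,
    simulate_trait,
    simulate_tree,
)
from .trees import prune_to, read_trees

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("canidmacro.pipeline")

# R-style MAD constant (consistent with median-based summaries in the
# comparative literature)
_MAD_SCALE = 1.4826


@dataclass
class PipelineConfig:
    """Flat, serializable configuration of one pipeline run."""

    seed: int = 0
    # --- synthetic study system (used when no input paths are given) ---
    n_species: int = 60
    birth_rate: float = 0.25
    death_rate: float = 0.18
    preservation_rate_q: float = 1.5
    n_trees: int = 50
    tree_jitter_sd: float = 0.1
    # log10 body mass evolves with a directional drift (Cope's-rule-like
    # size increase); carnivory evolves as plain Brownian motion
    mass_model: str = "Drift"
    mass_params: dict = field(
        default_factory=lambda: {"z0": 0.8, "sigma2": 0.01, "mu_drift": 0.02}
    )
    carnivory_model: str = "BM"
    carnivory_params: dict = field(default_factory=lambda: {"z0": 0.0, "sigma2": 0.05})
    # --- user data mode (all four set -> no simulation) ---
    occurrences_path: str | None = None
    extant_morpho_path: str | None = None
    fossil_morpho_path: str | None = None
    trees_path: str | None = None
    slices_path: str | None = None
    # --- analysis settings ---
    mass_a: float = DEFAULT_MASS_COEFFS.a
    mass_b: float = DEFAULT_MASS_COEFFS.b
    outlier_species: list = field(default_factory=list)
    taus: list = field(default_factory=lambda: list(DEFAULT_TAUS))
    n_bootstrap: int = 10_000
    mcmc_iterations: int = 500_000
    mcmc_burnin: int | None = None
    mcmc_thin: int = 100
    models: list = field(default_factory=lambda: list(MODEL_NAMES))
    lambda_threshold: float = 0.1
    n_permutations: int = 999
    subfamily_fits: bool = True
    min_clade_size: int = 8

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and context."""


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as err:
                raise StageError(f"stage {name!r} failed: {err}") from err
            log.info("stage %s done in %.1fs", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the full analysis; returns the result tables and writes
    them (plus a manifest) under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    child = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ["tree", "posterior", "mass", "carnivory", "record", "extant",
             "fossil_morpho", "mcmc", "boot", "perm"],
            ss.spawn(10),
        )
    }
    results: dict = {}

    # ------------------------------------------------------------------
    # inputs: read or simulate
    # ------------------------------------------------------------------
    user_mode = config.occurrences_path is not None
    slices = (
        TimeSliceTable.from_csv(config.slices_path)
        if config.slices_path
        else default_time_slices()
    )
    truth = None
    if user_mode:
        occ = pd.read_csv(config.occurrences_path)
        extant_morpho = pd.read_csv(config.extant_morpho_path)
        fossil_morpho = pd.read_csv(config.fossil_morpho_path)
        trees = read_trees(config.trees_path) if config.trees_path else None
        base_tree = trees[0] if trees else None
    else:
        occ, extant_morpho, fossil_morpho, trees, base_tree, truth = _simulate_inputs(
            config, slices, child, out_dir
        )
    if trees is None:
        log.warning("no trees available: signal, PGLS and model-fit stages will be skipped")

    # ------------------------------------------------------------------
    # ecomorphology
    # ------------------------------------------------------------------
    scores, mass_table = _ecomorph_stage(config, extant_morpho, fossil_morpho, out_dir)

    # ------------------------------------------------------------------
    # durations + occupancy
    # ------------------------------------------------------------------
    included, report = filter_species(occ)
    log.info(
        "species filter: %d included, %d singletons, %d extant",
        report["included"], report["singleton"], report["extant"],
    )
    durations = _duration_stage(config, occ, included, child["mcmc"])
    occupancy = occupancy_by_slice(occ, slices, species=included)
    mlc = max_locality_coverage(occupancy)
    results["durations"] = durations.table
    results["occupancy"] = occupancy
    results["exclusion_report"] = report

    # ------------------------------------------------------------------
    # merged species table (drops are logged, never silent)
    # ------------------------------------------------------------------
    merged = (
        scores.merge(durations.table[["species", "duration"]], on="species", how="inner")
        .merge(mlc[["species", "maxLocCover"]], on="species", how="inner")
        .merge(mass_table, on="species", how="inner")
        .rename(columns={"pc1": "carnivory"})
    )
    for name, frame in [("carnivory", scores), ("durations", durations.table), ("coverage", mlc)]:
        dropped = set(frame["species"]) - set(merged["species"])
        if dropped:
            log.info("merge dropped %d species absent from other stages (%s)", len(dropped), name)
    results["merged"] = merged

    # ------------------------------------------------------------------
    # signal summary (Table 1 shape)
    # ------------------------------------------------------------------
    results["signal"] = _signal_stage(config, merged, base_tree, child["perm"])

    # ------------------------------------------------------------------
    # specialization + quantile regressions (Table 2 shape)
    # ------------------------------------------------------------------
    dataset = build_specialization_dataset(
        merged.rename(columns={"carnivory": "pc1"}),
        merged,
        exclusions=config.outlier_species,
    )
    side_tree = prune_to(base_tree, merged["species"]) if base_tree is not None else None
    sides = fit_side_regressions(
        dataset,
        tree=side_tree,
        taus=config.taus,
        n_bootstrap=config.n_bootstrap,
        lambda_threshold=config.lambda_threshold,
        seed=child["boot"],
    )
    q_rows = []
    for side, info in sides.items():
        for row in info["quantile"].itertuples(index=False):
            q_rows.append({"side": side, "n": info["n"], "method": info["method"],
                           "lambda": info["lambda"], **row._asdict()})
    results["quantile"] = pd.DataFrame(q_rows)
    results["specialization"] = dataset

    # ------------------------------------------------------------------
    # nested models (Table 3 shape)
    # ------------------------------------------------------------------
    results["nested"] = nested_duration_models(merged)

    # ------------------------------------------------------------------
    # model selection over the posterior (Fig 5 shape)
    # ------------------------------------------------------------------
    if trees is not None:
        results["model_weights"] = _posterior_stage(config, merged, trees)

    _write_outputs(config, results, out_dir, child, report, truth)
    return results


@_stage("simulate-inputs")
def _simulate_inputs(config, slices, child, out_dir):
    sim_cfg = SimulationConfig(
        seed=child["tree"],
        n_tips=config.n_species,
        birth_rate=config.birth_rate,
        death_rate=config.death_rate,
        preservation_rate_q=config.preservation_rate_q,
        slice_boundaries=tuple(slices.boundaries),
    )
    tree, history = simulate_tree(sim_cfg)
    trees = simulate_posterior_sample(tree, config.n_trees, config.tree_jitter_sd, child["posterior"])
    mass = simulate_trait(tree, ModelSpec(config.mass_model, config.mass_params), child["mass"])
    carn = simulate_trait(
        tree, ModelSpec(config.carnivory_model, config.carnivory_params), child["carnivory"]
    )
    occ = simulate_fossil_record(history, sim_cfg, np.random.default_rng(child["record"]))
    extant = simulate_extant_morphoset(seed=child["extant"])
    sf = history.table.set_index("species")["subfamily"]
    fossil = simulate_fossil_morphoset(
        carn, mass, subfamily=sf,
        mass_coeffs=(config.mass_a, config.mass_b),
        seed=child["fossil_morpho"],
    )
    inputs = out_dir / "inputs"
    inputs.mkdir(exist_ok=True)
    occ.to_csv(inputs / "occurrences.csv", index=False)
    extant.to_csv(inputs / "extant_morphometrics.csv", index=False)
    fossil.to_csv(inputs / "fossil_morphometrics.csv", index=False)
    history.table.to_csv(inputs / "true_history.csv", index=False)
    trees.write(path=str(inputs / "posterior_trees.nex"), schema="nexus")
    return occ, extant, fossil, trees, tree, history


@_stage("ecomorph")
def _ecomorph_stage(config, extant_morpho, fossil_morpho, out_dir):
    imputer = None
    trainable = fossil_morpho.dropna(subset=["m1_length", "dentary_length"])
    if len(trainable) >= 3 and "subfamily" in fossil_morpho.columns:
        try:
            imputer = fit_dentary_imputer(fossil_morpho)
        except ValueError:
            log.warning("dentary imputer could not be trained; JD/DL left missing where dentary absent")
    extant_ratios = compute_dietary_ratios(extant_morpho)
    fossil_ratios = compute_dietary_ratios(fossil_morpho, imputer=imputer)
    model = fit_carnivory_index(extant_ratios)
    scores, excluded = project_carnivory(model, fossil_ratios)
    if excluded:
        log.info("carnivory projection excluded %d species with missing ratios", len(excluded))
    model.to_yaml(out_dir / "carnivory_model.yml")
    coeffs = MassCoefficients(config.mass_a, config.mass_b)
    mass_kg, log10_mass = estimate_body_mass(fossil_morpho["m1_length"].to_numpy(), coeffs)
    mass_table = pd.DataFrame(
        {"species": fossil_morpho["species"], "mass_kg": mass_kg, "log10_mass": log10_mass}
    )
    if "subfamily" in fossil_morpho.columns:
        mass_table["subfamily"] = fossil_morpho["subfamily"]
    return scores, mass_table


@_stage("durations")
def _duration_stage(config, occ, included, seed):
    sub = occ[occ["species"].isin(set(included))]
    settings = MCMCSettings(
        iterations=config.mcmc_iterations,
        burnin=config.mcmc_burnin,
        thin=config.mcmc_thin,
        seed=seed,
    )
    return estimate_durations(sub, settings)


@_stage("signal")
def _signal_stage(config, merged, base_tree, perm_seed):
    metrics = ["log10_mass", "carnivory", "duration", "maxLocCover"]
    rows = []
    tree = prune_to(base_tree, merged["species"]) if base_tree is not None else None
    rng = np.random.default_rng(perm_seed)
    for metric in metrics:
        x = merged.set_index("species")[metric].astype(float)
        row = {
            "metric": metric,
            "median": float(x.median()),
            "mad": float(_MAD_SCALE * (x - x.median()).abs().median()),
        }
        if tree is not None:
            lam = pagel_lambda_ml(tree, x)
            kk = blomberg_k(tree, x, n_perm=config.n_permutations, seed=int(rng.integers(2**31)))
            row.update(
                {"lambda": lam.lambda_, "lambda_p": lam.p, "K": kk.K, "K_p": kk.p}
            )
        rows.append(row)
    return pd.DataFrame(rows)


@_stage("posterior-fits")
def _posterior_stage(config, merged, trees):
    rows = []
    traits = {
        "log10_mass": merged.set_index("species")["log10_mass"].astype(float),
        "carnivory": merged.set_index("species")["carnivory"].astype(float),
    }
    clades = {"all": None}
    if config.subfamily_fits and "subfamily" in merged.columns:
        for sf, grp in merged.groupby("subfamily"):
            if len(grp) >= config.min_clade_size:
                clades[sf] = list(grp["species"])
    for trait_name, trait in traits.items():
        for clade, splist in clades.items():
            try:
                summ = fit_over_posterior(trees, trait, models=config.models, species=splist)
            except ValueError as err:
                log.warning("posterior fits skipped for %s/%s: %s", trait_name, clade, err)
                continue
            for model, w in summ.median_weights.items():
                rows.append(
                    {
                        "trait": trait_name,
                        "clade": clade,
                        "model": model,
                        "median_weight": float(w),
                        "n_trees": summ.n_trees,
                    }
                )
    return pd.DataFrame(rows)


def _write_outputs(config, results, out_dir, child_seeds, report, truth):
    float_fmt = "%.10g"
    name_map = {
        "signal": "table1_signal.csv",
        "quantile": "table2_quantile.csv",
        "nested": "table3_nested_models.csv",
        "model_weights": "fig5_model_weights.csv",
        "durations": "durations.csv",
        "occupancy": "occupancy.csv",
        "merged": "merged_species_table.csv",
        "specialization": "specialization.csv",
    }
    for key, fname in name_map.items():
        if key in results:
            df = results[key]
            df.to_csv(out_dir / fname, index=key == "occupancy", float_format=float_fmt)
    manifest = {
        "package": "canidmacro",
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "child_seeds": child_seeds,
        "species_filter": {k: report[k] for k in ("included", "singleton", "extant")},
        "ground_truth_available": truth is not None,
        "outputs": sorted(name_map[k] for k in results if k in name_map),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
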