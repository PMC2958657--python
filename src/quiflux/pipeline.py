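"""Orchestration: synthesize -> preprocess -> fit -> compare, with
stage-level logging, deterministic seeding and provenance records.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import ExperimentDataset
from .ensemble import compare_flux_distributions, summarize_fluxes
from .fit import (CostBlock, CostSpec, FitContext, GaConfig,
                  SolutionEnsemble, collect_consistent_solutions)
from .io import (ensemble_from_json, ensemble_to_json, read_dataset,
                 write_dataset, write_provenance)
from .network import FluxParameterSet, MetabolicNetwork, build_network
from .preprocess import latent_pool_fraction
from .synthetic import (NoiseModel, SamplingDesign, make_condition_preset,
                        simulate_dataset)

__all__ = ["RunConfig", "run_condition", "run_comparison"]

log = logging.getLogger("quiflux.pipeline")

#: free fluxes fitted by default, plus the unmeasured pools
DEFAULT_GENES = ("F0", "F1", "F2", "F3", "F4", "F5", "F7", "F8", "F10",
                 "F11", "F12", "pool:accoa", "pool:fa")


@dataclass
class RunConfig:
    """Configuration for one fitting run.

    ``dataset_dir``: optional directory of per-condition dataset
    subdirectories written by :func:`quiflux.io.write_dataset`; when
    absent, datasets are generated from the condition presets with
    ``noise`` and per-condition seeds derived from ``master_seed``.
    """

    outdir: Path
    master_seed: int = 0
    n_solutions: int = 5
    ga: GaConfig = field(default_factory=lambda: GaConfig(
        population=40, max_generations=60, convergence_window=15))
    genes: tuple[str, ...] = DEFAULT_GENES
    cost_spec: CostSpec | None = None
    noise: NoiseModel = field(default_factory=NoiseModel)
    design: SamplingDesign = field(default_factory=SamplingDesign)
    dataset_dir: Path | None = None
    #: alternative network configuration (dict); default: packaged model
    network_config: dict | None = None

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        if self.dataset_dir is not None:
            self.dataset_dir = Path(self.dataset_dir)


def _condition_seed(master_seed: int, condition: str) -> int:
    import zlib
    h = np.random.SeedSequence([master_seed,
                                zlib.crc32(condition.encode()) % (2 ** 31)])
    return int(h.generate_state(1)[0] % (2 ** 31))


def _load_or_generate(config: RunConfig, condition: str,
                      net: MetabolicNetwork) -> ExperimentDataset:
    if config.dataset_dir is not None:
        path = config.dataset_dir / condition
        if not path.exists():
            raise FileNotFoundError(f"dataset directory missing: {path}")
        return read_dataset(path)
    preset = make_condition_preset(condition, net)
    return simulate_dataset(preset, design=config.design, noise=config.noise,
                            seed=_condition_seed(config.master_seed, condition),
                            net=net)


def _base_params(data: ExperimentDataset, net: MetabolicNetwork,
                 latent_citrate: float) -> FluxParameterSet:
    """Dataset-calibrated fixed parameters for fitting.

    Measured pools and exchange rates come from the data; the latent
    hexose-P sub-pool starts at half the observed hexose-P pool; the
    unmeasured pools get order-of-magnitude starting values (overridden
    when configured as genes).
    """
    pools = {}
    for met in net.pool_metabolites:
        node = net.metabolites[met]
        if node.unmeasured:
            pools[met] = 0.05
        else:
            total = float(data.pool_sizes[met])
            pools[met] = 0.5 * total if node.latent == "pool" else total
    free = {s: 0.01 for s in net.free_fluxes}
    if set(net.free_fluxes) >= {"F0", "F1", "F2", "F4", "F5", "F7", "F8"}:
        # heuristic starting point consistent with the measured rates:
        # lower glycolysis must carry the lactate excretion, hexose uptake
        # must cover the upper-glycolysis and PPP demands, and the TCA
        # drains must stay within the glutamine supply.
        A = max(float(data.rates["A"]), 1e-6)
        B = max(float(data.rates["B"]), 0.1 * A)
        C = max(float(data.rates["C"]), 1e-6)
        free["F5"] = 0.05 * B
        free["F2"] = 1.1 * B                    # Y0 = 0.05 B
        free["F4"] = 0.1 * A
        free["F1"] = 0.55 * free["F2"]
        free["F0"] = max(A + 2 / 3 * free["F4"] - free["F1"] - 0.05 * A,
                         1.5 * free["F4"])
        free["F3"] = 0.02 * B
        free["F7"] = 0.5 * (free["F5"] + free["F3"])
        free["F11"] = 0.2 * free["F7"]
        free["F10"] = 1.5 * free["F7"]
        free["F8"] = free["F7"] + 0.1 * C
        free["F12"] = 0.2 * free["F1"]
    return FluxParameterSet(
        free_fluxes=free, rates=dict(data.rates), pools=pools,
        latent_hexp_pool=0.5 * float(data.pool_sizes.get("hexp", 0.0)),
        latent_citrate_fraction=latent_citrate)


def run_condition(config: RunConfig, condition: str) -> SolutionEnsemble:
    """Full pipeline for one condition: dataset, preprocessing, GA
    ensemble, summary tables and provenance.

    Writes ``<outdir>/<condition>/ensemble.json``, ``summary.csv`` and
    ``provenance.json``.
    """
    net = build_network(config.network_config)
    out = config.outdir / condition
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    try:
        data = _load_or_generate(config, condition, net)
    except Exception as err:
        raise RuntimeError(f"stage 'dataset' failed for {condition!r}: {err}") from err
    log.info("dataset ready for %s (%.1fs)", condition, time.perf_counter() - t0)

    t1 = time.perf_counter()
    latent = data.latent_citrate_fraction
    if latent is None:
        has_cit = any(n.latent == "fraction" for n in net.metabolites.values())
        latent = (latent_pool_fraction(data.labeling, metabolite="cit")
                  if has_cit else 0.0)
    spec = config.cost_spec
    if spec is None:
        spec = CostSpec((CostBlock("labeling_dynamics"),
                         CostBlock("pool_sizes"),
                         CostBlock("uptake_rates"),
                         CostBlock("convergence_ratio")))
    context = FitContext(net=net, data=data, spec=spec,
                         base=_base_params(data, net, latent),
                         genes=tuple(config.genes))
    log.info("preprocess done for %s (latent citrate %.3f, %.1fs)",
             condition, latent, time.perf_counter() - t1)

    t2 = time.perf_counter()
    base = context.base

    def _gene_value(g: str) -> float:
        if g.startswith("pool:"):
            return base.pools[g[5:]]
        if g == "latent_hexp_pool":
            return base.latent_hexp_pool
        return base.free_fluxes[g]

    warm = tuple(max(_gene_value(g), 1e-12) for g in context.genes)
    ga = GaConfig(**{**config.ga.__dict__,
                     "seed": _condition_seed(config.master_seed, condition) + 1,
                     "initial_population": (warm,)})
    try:
        ens = collect_consistent_solutions(context, ga, config.n_solutions)
    except Exception as err:
        raise RuntimeError(f"stage 'fit' failed for {condition!r}: {err}") from err
    log.info("fit done for %s: %d members, best cost %.4f (%.1fs)",
             condition, len(ens), ens.best_cost, time.perf_counter() - t2)

    ensemble_to_json(ens, out / "ensemble.json")
    summarize_fluxes(ens).to_csv(out / "summary.csv")
    if config.dataset_dir is None:
        write_dataset(data, out / "dataset",
                      seed=_condition_seed(config.master_seed, condition))
    write_provenance(out / "provenance.json",
                     inputs={"condition": condition,
                             "dataset_dir": str(config.dataset_dir)},
                     parameters={"genes": list(config.genes),
                                 "n_solutions": config.n_solutions,
                                 "ga": ga.__dict__},
                     seed=config.master_seed)
    return ens


def run_comparison(config: RunConfig, condition_a: str, condition_b: str
                   ) -> pd.DataFrame:
    """Non-overlap flux comparison between two fitted conditions.

    Reads the two ensemble JSON files under ``outdir`` and writes
    ``comparison_<A>_vs_<B>.tsv`` plus a machine-readable
    edge-annotation table (flux, substrates, products, verdict).
    """
    net = build_network(config.network_config)
    ens = {}
    for c in (condition_a, condition_b):
        path = config.outdir / c / "ensemble.json"
        if not path.exists():
            raise FileNotFoundError(f"no fitted ensemble at {path}")
        ens[c] = ensemble_from_json(path)
    comps = compare_flux_distributions(ens[condition_a], ens[condition_b])
    rows = [(c.parameter, c.verdict, *c.range_a, *c.range_b) for c in comps]
    table = pd.DataFrame(rows, columns=[
        "parameter", "verdict", "a_min", "a_max", "b_min", "b_max"])
    stem = f"comparison_{condition_a}_vs_{condition_b}"
    table.to_csv(config.outdir / f"{stem}.tsv", sep="\t", index=False)
    edges = []
    for c in comps:
        rxn = net.reactions.get(c.parameter)
        if rxn is None:
            continue
        edges.append((c.parameter,
                      "+".join(sorted(rxn.substrates)),
                      "+".join(sorted(rxn.products)) or "(drain)",
                      c.verdict))
    pd.DataFrame(edges, columns=["flux", "from", "to", "verdict"]).to_csv(
        config.outdir / f"{stem}_edges.tsv", sep="\t", index=False)
    return table
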