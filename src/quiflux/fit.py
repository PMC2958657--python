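"""Cost evaluation and genetic-algorithm flux identification.

The cost of a candidate parameter set against a dataset is

    cost = 1 + sum_b w_b * mean_b( ((simulated - observed) / sigma)^2 )

over the configured data blocks (labeling dynamics, asymptotic labeling,
pool sizes, exchange rates, convergence ratio), so a perfect fit scores
exactly 1.  Fluxes are identified by a tournament genetic algorithm on
log10-transformed parameters; independent restarts whose converged cost
lies within a tolerance of the best cost found form the ensemble of
consistent solutions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import ExperimentDataset
from .errors import InfeasibleFluxError, QuifluxError
from .network import (FluxParameterSet, MetabolicNetwork,
                      evaluate_all_fluxes)
from .simulate import (assemble_labeling_odes, integrate_raw,
                       ppp_convergence_ratio, steady_state_fractions)

__all__ = [
    "CostBlock", "CostSpec", "GaConfig", "FluxSolution", "SolutionEnsemble",
    "FitContext", "evaluate_cost", "run_ga", "collect_consistent_solutions",
    "INFEASIBLE_COST", "default_cost_spec",
]

#: Sentinel cost for steady-state-infeasible candidates.
INFEASIBLE_COST = float("inf")

_BLOCK_KINDS = ("labeling_dynamics", "steady_state_labeling", "pool_sizes",
                "uptake_rates", "convergence_ratio")


@dataclass(frozen=True)
class CostBlock:
    """One weighted data block.

    ``sigma_rel``/``sigma_abs`` floor the uncertainty used to scale
    residuals when the dataset carries no (or tiny) SDs.
    """

    kind: str
    weight: float = 1.0
    sigma_rel: float = 0.05
    sigma_abs: float = 1e-3

    def __post_init__(self):
        if self.kind not in _BLOCK_KINDS:
            raise ValueError(f"unknown block kind {self.kind!r}")
        if self.weight < 0:
            raise ValueError("block weight must be >= 0")


@dataclass(frozen=True)
class CostSpec:
    blocks: tuple[CostBlock, ...]

    def __post_init__(self):
        if not any(b.weight > 0 for b in self.blocks):
            raise ValueError("at least one block must have positive weight")


def default_cost_spec() -> CostSpec:
    return CostSpec(tuple(CostBlock(k) for k in _BLOCK_KINDS))


@dataclass(frozen=True)
class GaConfig:
    """Genetic-algorithm settings (log10 gene space)."""

    population: int = 200
    max_generations: int = 300
    tournament: int = 3
    crossover_p: float = 0.7
    mutation_p: float = 0.1
    mutation_sigma_decades: float = 0.3
    bounds: tuple[float, float] = (1e-4, 1e2)
    elitism: int = 2
    convergence_window: int = 30
    convergence_tol: float = 1e-4
    init_retries: int = 20
    seed: int = 0
    consistency_delta: float = 0.05
    #: optional gene vectors (natural scale) injected into the initial
    #: population, e.g. a warm start
    initial_population: tuple = ()

    def __post_init__(self):
        for p in (self.crossover_p, self.mutation_p):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if not (0 < self.bounds[0] < self.bounds[1]):
            raise ValueError("bounds must be positive and increasing")


@dataclass(frozen=True)
class FluxSolution:
    params: FluxParameterSet
    cost: float
    converged: bool
    seed: int
    n_generations: int = 0
    best_cost_trajectory: tuple[float, ...] = field(default=(), repr=False)


@dataclass
class SolutionEnsemble:
    """Consistent flux solutions for one condition.

    ``table`` has one row per member and one column per reported
    parameter (free fluxes, dependent X/Y/Z and derived fluxes, fitted
    pools and latent pools), plus ``cost``.
    """

    condition: str
    solutions: list[FluxSolution]
    table: pd.DataFrame
    best_cost: float
    config: GaConfig | None = None
    n_requested: int | None = None

    def __len__(self) -> int:
        return len(self.table)

    def values(self, name: str) -> np.ndarray:
        return self.table[name].to_numpy(dtype=float)

    @property
    def parameters(self) -> list[str]:
        return [c for c in self.table.columns if c != "cost"]


# ---------------------------------------------------------------------------
# cost evaluation

def _sigma(sd: np.ndarray, obs: np.ndarray, block: CostBlock) -> np.ndarray:
    return np.maximum.reduce([np.asarray(sd, dtype=float),
                              block.sigma_rel * np.abs(obs),
                              np.full(np.shape(obs), block.sigma_abs)])


def _labeling_residuals(net, params, data: ExperimentDataset,
                        block: CostBlock, steady: bool) -> np.ndarray:
    source = data.steady_state if steady else data.labeling
    res = []
    for tracer, sub in source.groupby("tracer"):
        system = assemble_labeling_odes(net, params, tracer)
        index = {(s.metabolite, s.n_labeled): i
                 for i, s in enumerate(system.state_index)}
        if steady:
            ss = steady_state_fractions(system)
            sim_by_state = {(s.metabolite, s.n_labeled): v for s, v in ss.items()}
            sim = np.array([sim_by_state[(m, n)] for m, n in
                            zip(sub["metabolite"], sub["n_labeled"])])
        else:
            times = np.unique(sub["time_h"].to_numpy(dtype=float))
            if times[0] != 0.0:
                times = np.concatenate([[0.0], times])
            raw = integrate_raw(system, times)
            obs_rows = np.stack([system.observed_fractions(raw[k])
                                 for k in range(len(times))])
            t_pos = {t: k for k, t in enumerate(times)}
            sim = np.array([
                obs_rows[t_pos[t], index[(m, n)]]
                for m, n, t in zip(sub["metabolite"], sub["n_labeled"],
                                   sub["time_h"])])
        obs = sub["fraction"].to_numpy(dtype=float)
        sd = sub["sd"].to_numpy(dtype=float)
        res.append((sim - obs) / _sigma(sd, obs, block))
    return np.concatenate(res) if res else np.array([])


def _observed_pool(net: MetabolicNetwork, params: FluxParameterSet,
                   met: str) -> float:
    node = net.metabolites[met]
    total = params.pools[met]
    if node.latent == "pool":
        total = total + params.latent_hexp_pool
    return total


def evaluate_cost(params: FluxParameterSet, data: ExperimentDataset,
                  spec: CostSpec | None = None,
                  net: MetabolicNetwork | None = None) -> float:
    """Block-weighted cost of a candidate against a dataset (>= 1).

    Steady-state-infeasible candidates score the sentinel
    ``INFEASIBLE_COST`` instead of raising.
    """
    from .network import build_network as _bn
    if net is None:
        net = _bn()
    if spec is None:
        spec = default_cost_spec()
    total = 1.0
    try:
        for block in spec.blocks:
            if block.weight == 0:
                continue
            if block.kind == "labeling_dynamics":
                r = _labeling_residuals(net, params, data, block, steady=False)
            elif block.kind == "steady_state_labeling":
                r = _labeling_residuals(net, params, data, block, steady=True)
            elif block.kind == "pool_sizes":
                obs = data.pool_sizes
                sim = np.array([_observed_pool(net, params, m) for m in obs.index])
                sd = data.pool_sd.reindex(obs.index).fillna(0.0).to_numpy()
                r = (sim - obs.to_numpy(dtype=float)) \
                    / _sigma(sd, obs.to_numpy(dtype=float), block)
            elif block.kind == "uptake_rates":
                keys = sorted(data.rates)
                obs = np.array([data.rates[k] for k in keys])
                sim = np.array([params.rates[k] for k in keys])
                sd = np.array([data.rate_sd.get(k, 0.0) for k in keys])
                r = (sim - obs) / _sigma(sd, obs, block)
            elif block.kind == "convergence_ratio":
                sim = ppp_convergence_ratio(params, net)
                obs = np.array([data.convergence_ratio])
                sd = np.array([data.convergence_ratio_sd])
                r = (sim - obs) / _sigma(sd, obs, block)
            if r.size:
                total += block.weight * float(np.mean(r ** 2))
    except InfeasibleFluxError:
        return INFEASIBLE_COST
    return total


# ---------------------------------------------------------------------------
# GA machinery

@dataclass
class FitContext:
    """Everything needed to evaluate one candidate.

    ``genes`` are parameter names accepted by
    :meth:`FluxParameterSet.updated` (free fluxes, ``pool:<met>``,
    ``latent_hexp_pool``); all other parameters stay at ``base`` values.
    """

    net: MetabolicNetwork
    data: ExperimentDataset
    spec: CostSpec
    base: FluxParameterSet
    genes: tuple[str, ...]

    def make_params(self, vector: np.ndarray) -> FluxParameterSet:
        return self.base.updated(**dict(zip(self.genes, vector)))

    def evaluate(self, vector: np.ndarray) -> float:
        try:
            params = self.make_params(vector)
        except ValueError:
            return INFEASIBLE_COST
        return evaluate_cost(params, self.data, self.spec, self.net)


def run_ga(context: FitContext, config: GaConfig) -> FluxSolution:
    """Minimize the cost with a tournament GA; deterministic given seed.

    Elitism makes the best-of-generation cost non-increasing.
    """
    rng = np.random.default_rng(config.seed)
    n_genes = len(context.genes)
    lo, hi = np.log10(config.bounds[0]), np.log10(config.bounds[1])

    def random_pop(size):
        return rng.uniform(lo, hi, size=(size, n_genes))

    pop = random_pop(config.population)
    for k, guess in enumerate(config.initial_population):
        if k < len(pop):
            pop[k] = np.clip(np.log10(np.asarray(guess, dtype=float)), lo, hi)
    costs = np.array([context.evaluate(10 ** ind) for ind in pop])
    tries = 0
    while not np.any(np.isfinite(costs)):
        tries += 1
        if tries > config.init_retries:
            raise QuifluxError("no feasible individual found during GA "
                               "initialization")
        pop = random_pop(config.population)
        costs = np.array([context.evaluate(10 ** ind) for ind in pop])

    trajectory = []
    best_idx = int(np.argmin(costs))
    best = (pop[best_idx].copy(), costs[best_idx])
    stall = 0
    gen = 0
    for gen in range(1, config.max_generations + 1):
        order = np.argsort(costs)
        elite = pop[order[: config.elitism]].copy()
        elite_costs = costs[order[: config.elitism]].copy()
        children = []
        while len(children) < config.population - config.elitism:
            # tournament selection
            parents = []
            for _ in range(2):
                cand = rng.integers(0, config.population, config.tournament)
                parents.append(pop[cand[np.argmin(costs[cand])]].copy())
            a, b = parents
            if rng.random() < config.crossover_p:
                mask = rng.random(n_genes) < 0.5
                a[mask], b[mask] = b[mask].copy(), a[mask].copy()
            for child in (a, b):
                mut = rng.random(n_genes) < config.mutation_p
                child[mut] += config.mutation_sigma_decades \
                    * rng.standard_normal(int(mut.sum()))
                children.append(np.clip(child, lo, hi))
        children = np.array(children[: config.population - config.elitism])
        child_costs = np.array([context.evaluate(10 ** ind) for ind in children])
        pop = np.vstack([elite, children])
        costs = np.concatenate([elite_costs, child_costs])
        gen_best = int(np.argmin(costs))
        if costs[gen_best] < best[1] - config.convergence_tol:
            best = (pop[gen_best].copy(), costs[gen_best])
            stall = 0
        else:
            if costs[gen_best] < best[1]:
                best = (pop[gen_best].copy(), costs[gen_best])
            stall += 1
        trajectory.append(float(best[1]))
        if stall >= config.convergence_window:
            break
    converged = stall >= config.convergence_window
    return FluxSolution(params=context.make_params(10 ** best[0]),
                        cost=float(best[1]), converged=converged,
                        seed=config.seed, n_generations=gen,
                        best_cost_trajectory=tuple(trajectory))


def _solution_row(net: MetabolicNetwork, sol: FluxSolution,
                  genes: Sequence[str]) -> dict[str, float]:
    row = dict(sol.params.free_fluxes)
    values = evaluate_all_fluxes(net, sol.params.free_fluxes, sol.params.rates)
    for sym in list(net.dependent_fluxes) + list(net.derived_fluxes):
        row[sym] = values[sym]
    for g in genes:
        if g.startswith("pool:") or g == "latent_hexp_pool":
            row[g] = (sol.params.pools[g[5:]] if g.startswith("pool:")
                      else sol.params.latent_hexp_pool)
    row["cost"] = sol.cost
    return row


def collect_consistent_solutions(context: FitContext, config: GaConfig,
                                 n: int, max_restarts: int | None = None
                                 ) -> SolutionEnsemble:
    """Run independent GA restarts until ``n`` consistent solutions exist.

    A restart is consistent when its converged cost is within
    ``(1 + consistency_delta)`` of the best cost found over all restarts.
    Restart seeds derive deterministically from ``config.seed``.  If the
    restart budget (default ``4 * n``) is exhausted first, a partial
    ensemble is returned with a warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if max_restarts is None:
        max_restarts = 4 * n
    seeds = np.random.SeedSequence(config.seed).generate_state(max_restarts)
    all_solutions: list[FluxSolution] = []
    best = np.inf
    for i in range(max_restarts):
        sol = run_ga(context, replace(config, seed=int(seeds[i] % (2 ** 31))))
        if np.isfinite(sol.cost):
            all_solutions.append(sol)
            best = min(best, sol.cost)
        consistent = [s for s in all_solutions
                      if s.cost <= (1 + config.consistency_delta) * best]
        if len(consistent) >= n:
            break
    consistent = [s for s in all_solutions
                  if s.cost <= (1 + config.consistency_delta) * best]
    if len(consistent) < n:
        warnings.warn(
            f"restart budget exhausted: {len(consistent)}/{n} consistent "
            "solutions collected", stacklevel=2)
    members = consistent[:n]
    rows = [_solution_row(context.net, s, context.genes) for s in members]
    table = pd.DataFrame(rows)
    return SolutionEnsemble(condition=context.data.condition,
                            solutions=members, table=table,
                            best_cost=float(best), config=config,
                            n_requested=n)
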