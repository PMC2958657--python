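"""Network model: metabolites, reactions, steady-state flux balance and
labeled-form enumeration.

The network is described by a JSON-serializable configuration (see
:mod:`quiflux.netdef` for the packaged central-carbon model).  All fluxes
are in nmol/min/ug protein; pools in nmol/ug protein.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources as _resources
from typing import Any, Mapping

from .errors import ConfigurationError, InfeasibleFluxError

__all__ = [
    "MetaboliteNode", "ReactionSpec", "LabelState", "FluxParameterSet",
    "MetabolicNetwork", "build_network", "load_default_config",
    "solve_dependent_fluxes", "evaluate_all_fluxes", "arc_fluxes",
    "node_balance_residuals", "enumerate_label_states", "audit_label_rules",
]

UNMEASURED = "unmeasured"


@dataclass(frozen=True)
class MetaboliteNode:
    """A metabolite pool in the network.

    ``latent`` is ``"pool"`` when a constant never-labeling sub-pool of
    explicit size accompanies the active pool (hexose phosphate, sized by
    the F9 parameter), ``"fraction"`` when the sub-pool is a proportion of
    the total (citrate), and ``None`` otherwise.
    """

    name: str
    carbons: int
    latent: str | None = None
    unmeasured: bool = False
    virtual: bool = False
    reservoir: bool = False
    pool_size: float | str | None = None


@dataclass(frozen=True)
class ReactionSpec:
    id: str
    flux_expr: Mapping[str, float]
    substrates: Mapping[str, float]
    products: Mapping[str, float]
    reversible_exchange: bool = False


@dataclass(frozen=True, order=True)
class LabelState:
    """One coarse isotopologue: a metabolite carrying ``n_labeled`` 13C."""

    metabolite: str
    n_labeled: int
    tracer: str = field(compare=False, default="")


@dataclass(frozen=True)
class FluxParameterSet:
    """A complete candidate parameterization of the network.

    Fields
    ------
    free_fluxes : symbol -> nmol/min/ug protein
    rates : uptake/excretion rates A (glucose in), B (lactate out),
        C (glutamine in), D (glutamate out)
    pools : metabolite -> active pool size, nmol/ug protein
    latent_hexp_pool : size of the never-labeling hexose-P sub-pool (F9)
    latent_citrate_fraction : proportion of the citrate pool that never
        labels, in [0, 1)
    """

    free_fluxes: Mapping[str, float]
    rates: Mapping[str, float]
    pools: Mapping[str, float]
    latent_hexp_pool: float = 0.0
    latent_citrate_fraction: float = 0.0

    def __post_init__(self):
        for name, v in {**self.free_fluxes, **self.rates}.items():
            if v < 0:
                raise ValueError(f"negative flux/rate {name}={v}")
        if not (0.0 <= self.latent_citrate_fraction < 1.0):
            raise ValueError("latent citrate fraction must be in [0, 1)")
        if self.latent_hexp_pool < 0:
            raise ValueError("latent hexose-P pool must be >= 0")

    def updated(self, **mapping: float) -> "FluxParameterSet":
        """Return a copy with named parameters replaced.

        Names are looked up among free fluxes, rates, pools and the two
        latent-pool parameters (keys ``latent_hexp_pool`` /
        ``latent_citrate_fraction``; pool names use a ``pool:`` prefix).
        """
        ff = dict(self.free_fluxes)
        rr = dict(self.rates)
        pp = dict(self.pools)
        other = {}
        for k, v in mapping.items():
            if k in ff:
                ff[k] = v
            elif k in rr:
                rr[k] = v
            elif k.startswith("pool:"):
                pp[k[5:]] = v
            elif k in ("latent_hexp_pool", "latent_citrate_fraction"):
                other[k] = v
            else:
                raise KeyError(f"unknown parameter {k!r}")
        return replace(self, free_fluxes=ff, rates=rr, pools=pp, **other)


class MetabolicNetwork:
    """Validated, immutable view over a network configuration."""

    def __init__(self, config: Mapping[str, Any]):
        self._config = config
        self.name = config.get("name", "network")
        self.metabolites: dict[str, MetaboliteNode] = {}
        for m in config["metabolites"]:
            node = MetaboliteNode(
                name=m["name"], carbons=int(m["carbons"]),
                latent=m.get("latent"), unmeasured=bool(m.get("unmeasured", False)),
                virtual=bool(m.get("virtual", False)),
                reservoir=bool(m.get("reservoir", False)),
                pool_size=m.get("pool_size"),
            )
            if node.name in self.metabolites:
                raise ConfigurationError(f"duplicate metabolite {node.name!r}")
            self.metabolites[node.name] = node
        self.externals: dict[str, int] = dict(config.get("externals", {}))
        self.free_fluxes: list[str] = list(config["free_fluxes"])
        self.rates: list[str] = list(config.get("rates", []))
        self.dependent_fluxes: dict[str, dict] = dict(config.get("dependent_fluxes", {}))
        self.derived_fluxes: dict[str, dict] = dict(config.get("derived_fluxes", {}))
        exchange = set(config.get("exchange_reactions", []))
        self.reactions: dict[str, ReactionSpec] = {}
        for r in config["reactions"]:
            if r["id"] in self.reactions:
                raise ConfigurationError(f"duplicate reaction id {r['id']!r}")
            self.reactions[r["id"]] = ReactionSpec(
                id=r["id"], flux_expr=dict(r["flux"]),
                substrates=dict(r["substrates"]), products=dict(r["products"]),
                reversible_exchange=r["id"] in exchange,
            )
        self.tracers: dict[str, dict] = dict(config.get("tracers", {}))
        self._validate()

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        symbols = self.free_fluxes + self.rates + list(self.dependent_fluxes) \
            + list(self.derived_fluxes)
        seen = set()
        for s in symbols:
            if s in seen:
                raise ConfigurationError(f"duplicate flux symbol {s!r}")
            seen.add(s)
        known_species = set(self.metabolites) | set(self.externals)
        for r in self.reactions.values():
            for met in list(r.substrates) + list(r.products):
                if met not in known_species:
                    raise ConfigurationError(
                        f"reaction {r.id!r} references unknown metabolite {met!r}")
            for sym in r.flux_expr:
                if sym not in seen:
                    raise ConfigurationError(
                        f"reaction {r.id!r} references unknown flux symbol {sym!r}")
        self._check_connected()
        for tracer, model in self.tracers.items():
            for met, forms in model["states"].items():
                if met not in self.metabolites:
                    raise ConfigurationError(
                        f"tracer {tracer!r} tracks unknown metabolite {met!r}")
                cmax = self.metabolites[met].carbons
                if any(not (0 <= n <= cmax) for n in forms):
                    raise ConfigurationError(
                        f"tracer {tracer!r}: label count out of range for {met!r}")

    def _check_connected(self) -> None:
        reached = set(self.externals)
        frontier = True
        while frontier:
            frontier = False
            for r in self.reactions.values():
                if all(s in reached for s in r.substrates) and r.substrates:
                    new = set(r.products) - reached
                    if new:
                        reached |= new
                        frontier = True
        unreached = set(self.metabolites) - reached
        if unreached:
            raise ConfigurationError(
                f"metabolites unreachable from entry points: {sorted(unreached)}")

    # -- convenience --------------------------------------------------------

    @property
    def pool_metabolites(self) -> list[str]:
        return [m for m, node in self.metabolites.items()
                if not node.virtual]

    def carbons(self, met: str) -> int:
        if met in self.metabolites:
            return self.metabolites[met].carbons
        return self.externals[met]

    def tracer_model(self, tracer: str) -> dict:
        try:
            return self.tracers[tracer]
        except KeyError:
            raise ConfigurationError(f"tracer {tracer!r} not configured") from None

    def state_dimension(self) -> int:
        return sum(len(enumerate_label_states(self, t)) for t in self.tracers)


def load_default_config() -> dict:
    """Load the packaged central-carbon network configuration."""
    ref = _resources.files("quiflux").joinpath("resources/central_carbon_network.json")
    return json.loads(ref.read_text())


def build_network(config: Mapping[str, Any] | None = None) -> MetabolicNetwork:
    """Build and validate a :class:`MetabolicNetwork`.

    With no argument, the packaged central-carbon model (glycolysis, PPP,
    truncatable TCA cycle, glutamine entry) is loaded.
    """
    if config is None:
        config = load_default_config()
    net = MetabolicNetwork(config)
    audit_label_rules(net)
    return net


# ---------------------------------------------------------------------------
# flux algebra

def _eval_expr(expr: Mapping[str, float], values: Mapping[str, float]) -> float:
    return sum(c * values[s] for s, c in expr.items())


def evaluate_all_fluxes(net: MetabolicNetwork,
                        free_fluxes: Mapping[str, float],
                        rates: Mapping[str, float]) -> dict[str, float]:
    """Evaluate every flux symbol (free, measured, dependent, derived).

    Raises
    ------
    InfeasibleFluxError
        If any dependent or derived flux comes out negative; the error
        carries the node whose balance is violated.
    """
    values: dict[str, float] = {}
    for s in net.free_fluxes:
        if s not in free_fluxes:
            raise ConfigurationError(f"missing free flux {s!r}")
        values[s] = float(free_fluxes[s])
    for s in net.rates:
        if s not in rates:
            raise ConfigurationError(f"missing rate {s!r}")
        values[s] = float(rates[s])
    # dependent (X/Y/Z) first, then derived closure arcs (may reference them)
    for group in (net.dependent_fluxes, net.derived_fluxes):
        for sym, spec in group.items():
            v = _eval_expr(spec["expr"], values)
            if v < -1e-12:
                raise InfeasibleFluxError(spec["node"], v)
            values[sym] = max(v, 0.0)
    return values


def solve_dependent_fluxes(net: MetabolicNetwork,
                           free_fluxes: Mapping[str, float],
                           rates: Mapping[str, float]) -> tuple[float, ...]:
    """Solve the dependent fluxes (X, Y, Z for the central-carbon model).

    Returns them in the order they are declared in the configuration.
    """
    values = evaluate_all_fluxes(net, free_fluxes, rates)
    return tuple(values[s] for s in net.dependent_fluxes)


def arc_fluxes(net: MetabolicNetwork, params: FluxParameterSet) -> dict[str, float]:
    """Net molecular flux (nmol/min/ug) carried by every reaction."""
    values = evaluate_all_fluxes(net, params.free_fluxes, params.rates)
    return {r.id: _eval_expr(r.flux_expr, values) for r in net.reactions.values()}


def node_balance_residuals(net: MetabolicNetwork,
                           params: FluxParameterSet,
                           arc_overrides: Mapping[str, float] | None = None
                           ) -> dict[str, float]:
    """Inflow minus outflow at every balanced node (nmol/min/ug protein).

    Reservoir pools (biomass-like, e.g. bulk fatty-acyl chains) are exempt
    from steady-state balance and omitted.  ``arc_overrides`` replaces
    individual reaction fluxes before balancing (useful to localize the
    effect of a perturbation).
    """
    arcs = arc_fluxes(net, params)
    if arc_overrides:
        unknown = set(arc_overrides) - set(arcs)
        if unknown:
            raise KeyError(f"unknown reactions {sorted(unknown)}")
        arcs.update(arc_overrides)
    residuals = {m: 0.0 for m, node in net.metabolites.items() if not node.reservoir}
    for r in net.reactions.values():
        v = arcs[r.id]
        for met, stoich in r.substrates.items():
            if met in residuals:
                residuals[met] -= stoich * v
        for met, stoich in r.products.items():
            if met in residuals:
                residuals[met] += stoich * v
    return residuals


# ---------------------------------------------------------------------------
# labeled-form enumeration and the carbon audit

def enumerate_label_states(net: MetabolicNetwork, tracer: str) -> list[LabelState]:
    """Deterministically ordered labeled-form states for one tracer model.

    Ordering follows the configured metabolite declaration order, then
    ascending label count.  The pseudo-tracer ``"unlabeled"`` yields one
    (unlabeled) state per pool metabolite.
    """
    if tracer == "unlabeled":
        return [LabelState(m, 0, tracer) for m in net.pool_metabolites]
    model = net.tracer_model(tracer)
    order = {m: i for i, m in enumerate(net.metabolites)}
    states: list[LabelState] = []
    for met in sorted(model["states"], key=order.__getitem__):
        for n in sorted(model["states"][met]):
            states.append(LabelState(met, int(n), tracer))
    return states


def _channel_books(net: MetabolicNetwork, tracer: str,
                   channel: Mapping[str, Any]) -> tuple[int, int, int, int]:
    """(labels_in, labels_out, carbons_in, carbons_out) incl. declared terms."""
    rxn = net.reactions[channel["reaction"]]
    labels_in = carbons_in = 0
    for met, n in channel["inputs"]:
        stoich = rxn.substrates[met]
        labels_in += int(stoich * n)
        carbons_in += int(stoich * net.carbons(met))
    labels_out = channel["labeled_loss"] + channel.get("label_writedown", 0)
    carbons_out = channel["labeled_loss"] + channel["unlabeled_loss"]
    for met, n, count in channel["outputs"]:
        labels_out += count * n
        carbons_out += count * net.carbons(met)
    carbons_in += channel.get("unlabeled_gain", 0)
    return labels_in, labels_out, carbons_in, carbons_out


def audit_label_rules(net: MetabolicNetwork) -> None:
    """Verify label-rule bookkeeping for every tracer.

    Checks, channel by channel, that 13C atoms in equal 13C atoms out plus
    the explicitly declared labeled loss, and that total carbon balances
    up to declared CO2 losses/gains; and that every combination of tracked
    substrate forms is covered by exactly one channel (so molecule counts
    are conserved by the rate law).
    """
    for tracer in net.tracers:
        model = net.tracer_model(tracer)
        states = model["states"]
        ext = model.get("external_dists", {})
        mixer_forms: dict[str, list[int]] = {
            met: sorted({int(v) for src in sources for v in src["map"].values()})
            for met, sources in model.get("mixers", {}).items()
        }
        covered: dict[str, set[tuple]] = {}
        for chan in model["channels"]:
            li, lo, ci, co = _channel_books(net, tracer, chan)
            if li != lo:
                raise ConfigurationError(
                    f"{tracer}: channel of {chan['reaction']!r} loses/creates "
                    f"label ({li} in, {lo} out)")
            if ci != co:
                raise ConfigurationError(
                    f"{tracer}: channel of {chan['reaction']!r} breaks carbon "
                    f"count ({ci} in, {co} out)")
            for met, n, _count in chan["outputs"]:
                if met not in states or n not in states[met]:
                    raise ConfigurationError(
                        f"{tracer}: channel of {chan['reaction']!r} produces "
                        f"untracked form {met}+{n}")
            key = tuple(tuple(i) for i in sorted(chan["inputs"]))
            covered.setdefault(chan["reaction"], set())
            if key in covered[chan["reaction"]]:
                raise ConfigurationError(
                    f"{tracer}: duplicate channel {key} for {chan['reaction']!r}")
            covered[chan["reaction"]].add(key)
        # completeness: any reaction producing a tracked form (and any
        # reaction given channels at all) must cover the full combination
        # space of its substrates' tracked forms, so molecule counts are
        # conserved by the multilinear rate law.  Reactions feeding virtual
        # mixing nodes are handled by the mixer declarations instead.
        need = set(covered)
        for rid, rxn in net.reactions.items():
            if any(p in states for p in rxn.products):
                need.add(rid)
        for rid in sorted(need):
            rxn = net.reactions[rid]
            combos = covered.get(rid, set())
            expected = [[]]
            for met in sorted(rxn.substrates):
                if met in states:
                    forms = states[met]
                elif met in mixer_forms:
                    forms = mixer_forms[met]
                elif met in ext:
                    forms = [int(k) for k, w in ext[met].items() if w > 0]
                else:
                    forms = [0]  # implicitly unlabeled species
                expected = [combo + [(met, n)] for combo in expected for n in forms]
            expected_keys = {tuple(sorted(c)) for c in expected}
            if expected_keys != combos:
                missing = expected_keys - combos
                extra = combos - expected_keys
                raise ConfigurationError(
                    f"{tracer}: reaction {rid!r} channel set mismatch; "
                    f"missing {sorted(missing)[:3]}, extra {sorted(extra)[:3]}")
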