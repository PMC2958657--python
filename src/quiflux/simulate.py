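"""Tracer-switch labeling dynamics: ODE assembly, integration, steady
state, and the glycolysis-PPP convergence ratio for [1,2-13C]-glucose.

The ODE state is the vector of labeled-form fractions for one tracer
model.  Consumption of a pool removes every form in proportion to its
fraction; production follows the configured labeling channels, whose rate
is the reaction flux times the product of the substrate form fractions
(multilinear mass action on fractions).  Latent sub-pools (citrate, the
F9 hexose-phosphate pool) are constant and unlabeled; they are mixed into
the *observed* fractions after integration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import SolverError
from .network import (FluxParameterSet, LabelState, MetabolicNetwork,
                      arc_fluxes, enumerate_label_states)
from .units import MINUTES_PER_HOUR

__all__ = [
    "OdeSystem", "assemble_labeling_odes", "integrate",
    "steady_state_fractions", "ppp_convergence_ratio",
    "TIMECOURSE_COLUMNS",
]

TIMECOURSE_COLUMNS = ["metabolite", "n_labeled", "time_h", "fraction",
                      "sd", "tracer", "condition"]

_RTOL = 1e-8
_ATOL = 1e-10


@dataclass
class OdeSystem:
    """Compiled labeling ODE system for one tracer experiment."""

    network: MetabolicNetwork
    params: FluxParameterSet
    tracer: str
    state_index: list[LabelState]

    # compiled arrays (set by assemble_labeling_odes)
    _out_rate: np.ndarray = None          # per-state total outflux (nmol/min/ug)
    _pools: np.ndarray = None             # per-state active pool (nmol/ug)
    _ch_flux: np.ndarray = None           # per-channel event rate
    _ch_in1: np.ndarray = None            # indices into the extended vector
    _ch_in2: np.ndarray = None
    _ch_out_ch: np.ndarray = None         # flattened (channel, state, count)
    _ch_out_state: np.ndarray = None
    _ch_out_count: np.ndarray = None
    _n_ext: int = 0                       # extended-vector length
    _const_slots: np.ndarray = None       # values for constant slots
    _mixer_slots: list = None             # [(slot, [(weight_flux, src_slot_or_const, ...)])]

    @property
    def n_states(self) -> int:
        return len(self.state_index)

    def max_turnover_min(self) -> float:
        mask = self._out_rate > 0
        return float(np.max(self._pools[mask] / self._out_rate[mask]))

    def initial_state(self) -> np.ndarray:
        y0 = np.zeros(self.n_states)
        for i, st in enumerate(self.state_index):
            if st.n_labeled == 0:
                y0[i] = 1.0
        return y0

    def _extended(self, y: np.ndarray) -> np.ndarray:
        ye = np.empty(self._n_ext)
        ye[: self.n_states] = y
        ye[self.n_states:] = self._const_slots
        for slot, sources in self._mixer_slots:
            num = 0.0
            den = 0.0
            for w, src in sources:
                den += w
                num += w * (ye[src] if src >= 0 else 0.0)
            ye[slot] = num / den if den > 0 else (1.0 if slot in self._mixer_unlab else 0.0)
        return ye

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        # production rates use fractions clamped to [0, 1]: the solver may
        # step marginally outside the simplex, and the bilinear channels
        # must not amplify that; the linear consumption term keeps the raw
        # state self-restoring.
        ye = self._extended(np.clip(y, 0.0, 1.0))
        rates = self._ch_flux * ye[self._ch_in1] * ye[self._ch_in2]
        damt = -self._out_rate * y
        np.add.at(damt, self._ch_out_state,
                  self._ch_out_count * rates[self._ch_out_ch])
        return damt / self._pools

    # observed (latent-including) fractions -------------------------------

    def observed_fractions(self, y: np.ndarray) -> np.ndarray:
        """Mix constant latent sub-pools into the raw model fractions."""
        obs = y.copy()
        lat_cit = self.params.latent_citrate_fraction
        p = self.params
        for i, st in enumerate(self.state_index):
            node = self.network.metabolites[st.metabolite]
            if node.latent == "fraction" and lat_cit > 0:
                obs[i] = y[i] * (1 - lat_cit) + (lat_cit if st.n_labeled == 0 else 0.0)
            elif node.latent == "pool" and p.latent_hexp_pool > 0:
                total = p.pools[st.metabolite] + p.latent_hexp_pool
                active = p.pools[st.metabolite]
                obs[i] = (y[i] * active
                          + (p.latent_hexp_pool if st.n_labeled == 0 else 0.0)) / total
        return obs


def assemble_labeling_odes(net: MetabolicNetwork, params: FluxParameterSet,
                           tracer: str) -> OdeSystem:
    """Compile the labeling ODE system for one tracer experiment.

    Raises :class:`quiflux.errors.InfeasibleFluxError` (via the flux
    algebra) when the parameter set is not steady-state feasible.
    """
    arcs = arc_fluxes(net, params)                 # validates feasibility
    model = net.tracer_model(tracer)
    states = enumerate_label_states(net, tracer)
    idx = {(s.metabolite, s.n_labeled): i for i, s in enumerate(states)}
    n = len(states)

    # per-metabolite totals
    influx: dict[str, float] = {m: 0.0 for m in net.metabolites}
    outflux: dict[str, float] = {m: 0.0 for m in net.metabolites}
    for r in net.reactions.values():
        v = arcs[r.id]
        for met, stoich in r.substrates.items():
            if met in outflux:
                outflux[met] += stoich * v
        for met, stoich in r.products.items():
            if met in influx:
                influx[met] += stoich * v

    out_rate = np.zeros(n)
    pools = np.zeros(n)
    for i, st in enumerate(states):
        node = net.metabolites[st.metabolite]
        # reservoir (biomass-like) pools relax with their inflow
        out_rate[i] = influx[st.metabolite] if node.reservoir else outflux[st.metabolite]
        pools[i] = params.pools[st.metabolite]
        if node.latent == "fraction":
            pools[i] = params.pools[st.metabolite] * (1 - params.latent_citrate_fraction)
        if pools[i] <= 0:
            raise ValueError(f"non-positive active pool for {st.metabolite!r}")

    # extended-vector layout: states | const slots | mixer slots
    ext_values: list[float] = []
    ext_index: dict[tuple, int] = {}
    ext_dists = model.get("external_dists", {})

    def const_slot(value: float) -> int:
        key = ("const", value)
        if key not in ext_index:
            ext_index[key] = n + len(ext_values)
            ext_values.append(value)
        return ext_index[key]

    mixers = model.get("mixers", {})
    mixer_slot_index: dict[tuple, int] = {}
    mixer_slots: list = []
    mixer_unlab: set[int] = set()

    def mixer_slot(met: str, form: int) -> int:
        key = ("mixer", met, form)
        if key in mixer_slot_index:
            return mixer_slot_index[key]
        slot = n + len(ext_values)
        ext_values.append(0.0)
        mixer_slot_index[key] = slot
        sources = []
        for src in mixers[met]:
            w = arcs[src["flux"]] if src["flux"] in arcs else None
            if w is None:
                raise KeyError(f"mixer flux {src['flux']!r} is not a reaction id")
            # which source form maps onto this target form?
            src_form = None
            for k, v in src["map"].items():
                if int(v) == form:
                    src_form = int(k)
            if src_form is None:
                sources.append((w, -1))          # contributes nothing to this form
            else:
                sources.append((w, frac_slot(src["source"], src_form)))
        mixer_slots.append((slot, sources))
        if form == 0:
            mixer_unlab.add(slot)
        return slot

    def frac_slot(met: str, form: int) -> int:
        if (met, form) in idx:
            return idx[(met, form)]
        if met in ext_dists:
            return const_slot(float(ext_dists[met].get(str(form), 0.0)))
        if met in mixers:
            return mixer_slot(met, form)
        # implicitly unlabeled species
        return const_slot(1.0 if form == 0 else 0.0)

    ch_flux, ch_in1, ch_in2 = [], [], []
    out_ch, out_state, out_count = [], [], []
    one = None
    for c, chan in enumerate(model["channels"]):
        v = arcs[chan["reaction"]]
        ch_flux.append(v)
        ins = [frac_slot(met, nn) for met, nn in chan["inputs"]]
        if len(ins) == 1:
            if one is None:
                one = const_slot(1.0)
            ins.append(one)
        if len(ins) != 2:
            raise ValueError("channels support at most two distinct substrates")
        ch_in1.append(ins[0])
        ch_in2.append(ins[1])
        for met, nn, count in chan["outputs"]:
            out_ch.append(c)
            out_state.append(idx[(met, nn)])
            out_count.append(float(count))

    sys = OdeSystem(network=net, params=params, tracer=tracer, state_index=states)
    sys._out_rate = out_rate
    sys._pools = pools
    sys._ch_flux = np.asarray(ch_flux)
    sys._ch_in1 = np.asarray(ch_in1, dtype=int)
    sys._ch_in2 = np.asarray(ch_in2, dtype=int)
    sys._ch_out_ch = np.asarray(out_ch, dtype=int)
    sys._ch_out_state = np.asarray(out_state, dtype=int)
    sys._ch_out_count = np.asarray(out_count)
    sys._n_ext = n + len(ext_values)
    sys._const_slots = np.asarray(ext_values)
    sys._mixer_slots = mixer_slots
    sys._mixer_unlab = mixer_unlab
    return sys


# ---------------------------------------------------------------------------

def integrate_raw(system: OdeSystem, times_h: Sequence[float],
                  rtol: float = _RTOL, atol: float = _ATOL) -> np.ndarray:
    """Integrate and return raw model fractions, shape (n_times, n_states)."""
    times_h = np.asarray(times_h, dtype=float)
    if times_h.ndim != 1 or len(times_h) == 0 or times_h[0] != 0.0 \
            or np.any(np.diff(times_h) <= 0):
        raise ValueError("times must be strictly increasing and start at 0")
    t_min = times_h * MINUTES_PER_HOUR
    sol = solve_ivp(system.rhs, (0.0, t_min[-1]), system.initial_state(),
                    t_eval=t_min, method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise SolverError(
            f"integration failed for tracer {system.tracer!r} at "
            f"t={sol.t[-1] / MINUTES_PER_HOUR:.3g} h: {sol.message}")
    return sol.y.T


def integrate(system: OdeSystem, times_h: Sequence[float],
              condition: str = "", observed: bool = True,
              rtol: float = _RTOL, atol: float = _ATOL) -> pd.DataFrame:
    """Integrate the labeling ODEs over a time grid (hours).

    Returns a tidy time-course with columns
    ``metabolite, n_labeled, time_h, fraction, sd, tracer, condition``.
    With ``observed=True`` the constant latent sub-pools are mixed into
    the reported fractions.
    """
    raw = integrate_raw(system, times_h, rtol=rtol, atol=atol)
    rows = []
    for k, t in enumerate(times_h):
        y = system.observed_fractions(raw[k]) if observed else raw[k]
        for i, st in enumerate(system.state_index):
            rows.append((st.metabolite, st.n_labeled, float(t), float(y[i]),
                         0.0, system.tracer, condition))
    return pd.DataFrame(rows, columns=TIMECOURSE_COLUMNS)


def steady_state_fractions(system: OdeSystem, t_cap_h: float = 2000.0,
                           tol: float = 1e-4, observed: bool = True
                           ) -> dict[LabelState, float]:
    """Asymptotic labeling pattern, by integration to quasi-stationarity.

    Integrates to 50 times the slowest pool turnover (capped), then checks
    that a further doubling of the horizon moves no fraction by more than
    ``tol``.
    """
    horizon_h = min(50 * system.max_turnover_min() / MINUTES_PER_HOUR, t_cap_h)
    y1 = integrate_raw(system, [0.0, horizon_h])[-1]
    y2 = integrate_raw(system, [0.0, 2 * horizon_h])[-1]
    if np.max(np.abs(y2 - y1)) > tol:
        raise SolverError(
            f"labeling did not reach steady state within {t_cap_h} h "
            f"(max drift {np.max(np.abs(y2 - y1)):.2g})")
    y = system.observed_fractions(y2) if observed else y2
    return {st: float(y[i]) for i, st in enumerate(system.state_index)}


# ---------------------------------------------------------------------------
# [1,2-13C]-glucose convergence ratio (positional bookkeeping)

# positional atom maps for the non-oxidative PPP (transketolase moves C1-C2
# of the ketose donor, transaldolase C1-C3):
#   TK1:  X5P(c) + R5P(d) -> S7P(c1,c2,d1..d5) + GAP(c3,c4,c5)
#   TA:   S7P(s) + GAP(g) -> F6P(s1,s2,s3,g1,g2,g3) + E4P(s4..s7)
#   TK2:  X5P(e) + E4P(f) -> F6P(e1,e2,f1..f4) + GAP(e3,e4,e5)
# with TA consuming the TK1-produced GAP, one cycle consumes three
# pentoses and yields F6P_a(c1,c2,d1,c3,c4,c5), F6P_b(e1,e2,d2..d5) and a
# free GAP(e3,e4,e5).

def _hexose_to_pentose(pattern: frozenset) -> frozenset:
    """Oxidative PPP: lose C1 (as CO2), renumber C2..C6 -> C1..C5."""
    return frozenset(p - 1 for p in pattern if p != 1)


def _triose_counts(pattern: frozenset) -> tuple[int, int]:
    """Label counts of the two trioses from one hexose (C1-3, C4-6)."""
    return (len(pattern & {1, 2, 3}), len(pattern & {4, 5, 6}))


def _cycle_products(c: frozenset, d: frozenset, e: frozenset):
    """Patterns of F6P_a, F6P_b and the free GAP for one non-ox cycle."""
    # position maps: F6P_a: 1<-c1, 2<-c2, 3<-d1, 4<-c3, 5<-c4, 6<-c5
    f6p_a = frozenset(
        ({1} if 1 in c else set()) | ({2} if 2 in c else set())
        | ({3} if 1 in d else set()) | ({4} if 3 in c else set())
        | ({5} if 4 in c else set()) | ({6} if 5 in c else set()))
    f6p_b = frozenset(
        ({1} if 1 in e else set()) | ({2} if 2 in e else set())
        | ({3} if 2 in d else set()) | ({4} if 3 in d else set())
        | ({5} if 4 in d else set()) | ({6} if 5 in d else set()))
    gap = frozenset({i - 2 for i in (3, 4, 5) if i in e})
    return f6p_a, f6p_b, gap


def ppp_convergence_ratio(params: FluxParameterSet,
                          net: MetabolicNetwork | None = None,
                          single_pass: bool = True,
                          time_h: float | None = None,
                          _max_iter: int = 200, _tol: float = 1e-12) -> float:
    """Expected 1x-13C : 2x-13C lactate production ratio under
    [1,2-13C]-glucose at metabolic steady state.

    ``single_pass=True`` (default) forbids re-entry of PPP-returned hexose
    phosphate into the oxidative branch; with ``single_pass=False`` the
    hexose-pool positional composition is solved by fixed-point iteration.
    ``time_h`` is accepted for symmetry with the sampling protocol (the
    ratio of two forms filling the same well-mixed lactate pool is
    time-invariant, so the value equals the asymptotic one; pass 2.0 to
    mirror the experiment).

    Raises ``ZeroDivisionError`` when no 2x-lactate is produced.
    """
    from .network import build_network as _bn
    if net is None:
        net = _bn()
    values = arc_fluxes(net, params)
    A = values["glc_uptake"]
    F0 = values["F0"]
    F1 = values["F1"]
    drain = values["hexp_drain"]
    F4_cycles = values["tk1"]                   # cycles/min = F4/3
    fresh = frozenset({1, 2})

    if single_pass:
        # explicit probability chain: fresh glucose routes among oxidative
        # PPP, glycolysis and the biosynthetic drain in proportion to the
        # fluxes; returned hexose phosphate never re-enters the PPP.
        out = F0 + F1 + drain
        if out <= 0:
            raise ZeroDivisionError("no hexose-phosphate consumption")
        p_ppp, p_gly = F0 / out, F1 / out
        q_ret = F1 / (F1 + drain) if (F1 + drain) > 0 else 0.0
        cycles = A * p_ppp * (F4_cycles / F0) if F0 > 0 else 0.0
        m1 = cycles * q_ret                      # F6P_b (one label, C1)
        m2 = A * p_gly + cycles * q_ret          # direct glycolysis + F6P_a
        if m2 <= 0:
            raise ZeroDivisionError("no 2x-13C lactate produced; ratio undefined")
        return m1 / m2

    # re-entry: hexose-pool positional composition solved by fixed point;
    # every molecule in the pool routes proportionally to the fluxes.
    hex_pool = {fresh: 1.0}
    for _ in range(_max_iter):
        # pentose distribution produced by the oxidative branch
        pent: dict[frozenset, float] = {}
        for pat, w in hex_pool.items():
            key = _hexose_to_pentose(pat)
            pent[key] = pent.get(key, 0.0) + w
        # expected return-hexose distribution over independent pentose triples
        ret: dict[frozenset, float] = {}
        for c, wc in pent.items():
            for d, wd in pent.items():
                for e, we in pent.items():
                    fa, fb, _gap = _cycle_products(c, d, e)
                    w = wc * wd * we
                    ret[fa] = ret.get(fa, 0.0) + 0.5 * w
                    ret[fb] = ret.get(fb, 0.0) + 0.5 * w
        new_pool: dict[frozenset, float] = {}
        total = A + 2.0 * F4_cycles
        new_pool[fresh] = A / total
        for pat, w in ret.items():
            new_pool[pat] = new_pool.get(pat, 0.0) + 2.0 * F4_cycles * w / total
        drift = max(abs(new_pool.get(p, 0.0) - hex_pool.get(p, 0.0))
                    for p in set(new_pool) | set(hex_pool))
        hex_pool = new_pool
        if drift < _tol:
            break

    # lactate (triose) production, by label count
    m = {0: 0.0, 1: 0.0, 2: 0.0, 3: 0.0}
    for pat, w in hex_pool.items():
        top, bottom = _triose_counts(pat)
        m[top] += F1 * w
        m[bottom] += F1 * w
    pent = {}
    for pat, w in hex_pool.items():
        key = _hexose_to_pentose(pat)
        pent[key] = pent.get(key, 0.0) + w
    for e, we in pent.items():
        gap = frozenset({i - 2 for i in (3, 4, 5) if i in e})
        m[len(gap)] += F4_cycles * we
    if m[2] <= 0:
        raise ZeroDivisionError("no 2x-13C lactate produced; ratio undefined")
    return m[1] / m[2]
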