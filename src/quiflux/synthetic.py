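"""Synthetic-data generation: ground-truth condition presets and noisy
datasets with the statistical structure the analysis assumes.

The four presets encode the study's qualitative contrasts: CI14SS7
glycolytic fluxes at half the proliferating values (2-fold lower glucose
consumption), near-zero forward citrate -> alpha-ketoglutarate flux in
proliferating cells (truncated TCA cycle), higher non-oxidative PPP
return, pyruvate->OAA anaplerosis and reductive alpha-ketoglutarate ->
citrate flux under contact inhibition, and a 40% latent citrate pool in
proliferating cells.  Absolute magnitudes are implementer-chosen fixtures
in the 1e-4..1e-1 nmol/min/ug range; pool sizes are derived from target
turnover times so that labeling dynamics span the sampling grids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import ExperimentDataset
from .network import (FluxParameterSet, MetabolicNetwork, arc_fluxes,
                      build_network)
from .preprocess import MediumTimecourse, ProteinCurve, PoolTable
from .simulate import (assemble_labeling_odes, integrate,
                       ppp_convergence_ratio, steady_state_fractions,
                       TIMECOURSE_COLUMNS)
from .units import MINUTES_PER_HOUR

__all__ = [
    "ConditionPreset", "NoiseModel", "SamplingDesign", "CONDITIONS",
    "make_condition_preset", "simulate_dataset", "generate_pool_table",
    "generate_medium_experiment",
]

CONDITIONS = ("proliferating", "CI7", "CI14", "CI14SS7")

# free fluxes and exchange rates, nmol/min/ug protein
_PRESET_FLUXES = {
    "proliferating": dict(
        A=0.070, B=0.080, C=0.030, D=0.008,
        F0=0.020, F1=0.050, F2=0.095, F3=0.0005, F4=0.006, F5=0.012,
        F7=0.0002, F8=0.010, F10=0.004, F11=0.00003, F12=0.020),
    "CI7": dict(
        A=0.068, B=0.075, C=0.016, D=0.005,
        F0=0.022, F1=0.048, F2=0.092, F3=0.003, F4=0.014, F5=0.011,
        F7=0.005, F8=0.007, F10=0.014, F11=0.005, F12=0.020),
    "CI14": dict(
        A=0.066, B=0.072, C=0.015, D=0.004,
        F0=0.023, F1=0.046, F2=0.090, F3=0.004, F4=0.018, F5=0.009,
        F7=0.006, F8=0.007, F10=0.016, F11=0.006, F12=0.020),
    "CI14SS7": dict(
        A=0.035, B=0.040, C=0.014, D=0.002,
        F0=0.015, F1=0.025, F2=0.0475, F3=0.002, F4=0.012, F5=0.004,
        F7=0.005, F8=0.006, F10=0.013, F11=0.005, F12=0.010),
}

_LATENT_CITRATE = {"proliferating": 0.40, "CI7": 0.25, "CI14": 0.25,
                   "CI14SS7": 0.20}

# target turnover times (min) from which pool sizes are derived;
# the fatty-acyl reservoir is deliberately slow.
_TURNOVER_MIN = {
    "hexp": 8.0, "fbp": 4.0, "dhap": 4.0, "pg3": 3.0, "pep": 3.0,
    "pyr": 6.0, "lac": 15.0, "penp": 10.0, "s7p": 8.0, "accoa": 4.0,
    "fa": 2000.0, "cit": 9.0, "akg": 8.0, "suc": 8.0, "mal": 8.0,
    "glu": 30.0,
}

#: initial medium composition (mM): standard DMEM glucose/glutamine
_MEDIUM_MM0 = {"glucose": 25.0, "glutamine": 4.0, "lactate": 0.0,
               "glutamate": 0.0}
_MEDIUM_RATE_KEY = {"glucose": "A", "lactate": "B", "glutamine": "C",
                    "glutamate": "D"}

#: protein growth: (initial ug, doubling time h or None for constant)
_PROTEIN_GROWTH = {"proliferating": (100.0, 30.0), "CI7": (300.0, None),
                   "CI14": (300.0, None), "CI14SS7": (280.0, None)}


@dataclass(frozen=True)
class ConditionPreset:
    """Ground-truth parameter set for one proliferative condition."""

    name: str
    params: FluxParameterSet
    protein_0_ug: float
    protein_doubling_h: float | None
    constraint_tags: tuple[str, ...] = ()


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise parameters for synthetic data.

    labeling_sd: additive SD on labeled-form fractions (clipped to [0,1]).
    pool_cv: multiplicative CV on pool sizes and raw signals.
    medium_rel_sd: relative SD on medium concentrations.
    rate_rel_sd: relative SD applied to the reported exchange rates.
    """

    labeling_sd: float = 0.02
    pool_cv: float = 0.10
    medium_rel_sd: float = 0.01
    rate_rel_sd: float = 0.02

    def __post_init__(self):
        for name in ("labeling_sd", "pool_cv", "medium_rel_sd", "rate_rel_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


ZERO_NOISE = NoiseModel(0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SamplingDesign:
    """Sampling grids mirroring the tracer-switch protocols: dense points
    within the first 2 h, plus late points for the glutamine switch."""

    glucose_times_h: tuple = (0.0, 1 / 12, 1 / 6, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0)
    glutamine_times_h: tuple = (0.0, 1 / 12, 1 / 6, 0.25, 0.5, 0.75, 1.0, 1.5,
                                2.0, 4.0, 8.0)
    medium_times_h: tuple = (0.0, 6.0, 12.0, 18.0, 24.0, 30.0, 36.0, 42.0, 48.0)
    #: three experiments with five replicate plates per time point
    medium_replicates: int = 15
    medium_volume_ml: float = 10.0
    convergence_time_h: float = 2.0


def _protein_curve(p0: float, doubling_h: float | None,
                   times_h: np.ndarray) -> np.ndarray:
    if doubling_h is None:
        return np.full(len(times_h), p0)
    return p0 * np.exp(np.log(2.0) / doubling_h * np.asarray(times_h))


def make_condition_preset(name: str,
                          net: MetabolicNetwork | None = None) -> ConditionPreset:
    """Build the ground-truth preset for one condition.

    Pool sizes are set to (target turnover time) x (total pool outflux) so
    the preset is balance-feasible by construction; the encoded qualitative
    contrasts are re-checked at construction time.
    """
    if name not in _PRESET_FLUXES:
        raise KeyError(f"unknown condition {name!r}; expected one of {CONDITIONS}")
    if net is None:
        net = build_network()
    vals = _PRESET_FLUXES[name]
    free = {k: v for k, v in vals.items() if k.startswith("F")}
    rates = {k: vals[k] for k in ("A", "B", "C", "D")}
    # provisional params to obtain arc fluxes (pools irrelevant for arcs)
    prov = FluxParameterSet(free, rates, {m: 1.0 for m in net.pool_metabolites})
    arcs = arc_fluxes(net, prov)
    outflux = {m: 0.0 for m in net.metabolites}
    influx = {m: 0.0 for m in net.metabolites}
    for r in net.reactions.values():
        for met, st in r.substrates.items():
            if met in outflux:
                outflux[met] += st * arcs[r.id]
        for met, st in r.products.items():
            if met in influx:
                influx[met] += st * arcs[r.id]
    lat = _LATENT_CITRATE[name]
    pools = {}
    for met in net.pool_metabolites:
        node = net.metabolites[met]
        turn = influx[met] if node.reservoir else outflux[met]
        active = _TURNOVER_MIN[met] * turn
        if active <= 0:
            raise ValueError(f"preset {name!r}: zero turnover for {met!r}")
        # pools stores the total observed pool for fraction-latent pools
        pools[met] = active / (1 - lat) if node.latent == "fraction" else active
    params = FluxParameterSet(
        free_fluxes=free, rates=rates, pools=pools,
        latent_hexp_pool=0.5 * pools["hexp"],
        latent_citrate_fraction=lat)
    _check_contrasts(name, params)
    p0, dbl = _PROTEIN_GROWTH[name]
    return ConditionPreset(name=name, params=params, protein_0_ug=p0,
                           protein_doubling_h=dbl,
                           constraint_tags=_contrast_tags(name))


def _contrast_tags(name: str) -> tuple[str, ...]:
    tags = []
    if name == "proliferating":
        tags += ["truncated_tca", "latent_citrate_0.40"]
    if name.startswith("CI"):
        tags += ["higher_nonox_return", "higher_pyr_oaa", "higher_reverse_f11"]
    if name == "CI14SS7":
        tags += ["half_glycolysis"]
    return tuple(tags)


def _check_contrasts(name: str, params: FluxParameterSet) -> None:
    ref = _PRESET_FLUXES["proliferating"]
    ff, rr = params.free_fluxes, params.rates
    if name == "proliferating":
        assert ff["F7"] <= 0.001, "proliferating TCA must be truncated at citrate"
        assert abs(params.latent_citrate_fraction - 0.40) < 1e-12
    if name.startswith("CI"):
        y = ff["F2"] - rr["B"] - ff["F5"]
        y_ref = ref["F2"] - ref["B"] - ref["F5"]
        assert ff["F4"] > ref["F4"] and ff["F11"] > ref["F11"] and y > y_ref, \
            f"{name}: contact-inhibition contrasts not encoded"
    if name == "CI14SS7":
        assert abs(ff["F1"] / ref["F1"] - 0.5) < 1e-9
        assert abs(ff["F2"] / ref["F2"] - 0.5) < 1e-9
        assert abs(rr["A"] / ref["A"] - 0.5) < 1e-9


# ---------------------------------------------------------------------------

def generate_medium_experiment(preset: ConditionPreset,
                               design: SamplingDesign = SamplingDesign(),
                               noise: NoiseModel = NoiseModel(),
                               rng: np.random.Generator | None = None
                               ) -> tuple[MediumTimecourse, ProteinCurve]:
    """Medium depletion/accumulation curves consistent with the preset's
    per-protein exchange rates, plus the protein growth curve."""
    if rng is None:
        rng = np.random.default_rng(0)
    times = np.asarray(design.medium_times_h, dtype=float)
    protein = _protein_curve(preset.protein_0_ug, preset.protein_doubling_h, times)
    # cumulative protein integral, ug*min
    fine_t = np.linspace(times[0], times[-1], 481)
    fine_p = _protein_curve(preset.protein_0_ug, preset.protein_doubling_h, fine_t)
    cum = np.concatenate([[0.0], np.cumsum(
        0.5 * (fine_p[1:] + fine_p[:-1]) * np.diff(fine_t))]) * MINUTES_PER_HOUR
    cum_at = np.interp(times, fine_t, cum)
    conc = {}
    for met, c0 in _MEDIUM_MM0.items():
        rate = preset.params.rates[_MEDIUM_RATE_KEY[met]]
        sign = -1.0 if met in ("glucose", "glutamine") else +1.0
        # nmol exchanged -> mM in the medium volume
        clean = c0 + sign * rate * cum_at / (design.medium_volume_ml * 1e3)
        if np.any(clean < 0):
            raise ValueError(f"medium {met} would be exhausted; shorten the "
                             "time-course or lower the rate")
        reps = np.tile(clean, (design.medium_replicates, 1))
        if noise.medium_rel_sd > 0:
            reps = reps * (1 + noise.medium_rel_sd
                           * rng.standard_normal(reps.shape))
        conc[met] = np.clip(reps, 0.0, None)
    medium = MediumTimecourse(times_h=times, concentrations=conc,
                              volume_ml=design.medium_volume_ml,
                              condition=preset.name)
    curve = ProteinCurve(times_h=times, protein_ug=protein)
    return medium, curve


def simulate_dataset(preset: ConditionPreset,
                     design: SamplingDesign = SamplingDesign(),
                     noise: NoiseModel = NoiseModel(),
                     seed: int = 0,
                     net: MetabolicNetwork | None = None) -> ExperimentDataset:
    """Generate a complete noisy dataset for one condition.

    Contains [U-13C]-glucose and [U-13C]-glutamine labeling time-courses,
    asymptotic labeling patterns, measured pool sizes, exchange rates,
    medium/protein curves and the 2 h convergence-ratio observation.  The
    generating parameter set is stored in ``ground_truth``.
    """
    if net is None:
        net = build_network()
    rng = np.random.default_rng(seed)
    params = preset.params

    frames = []
    ss_rows = []
    grids = {"U13C-glucose": design.glucose_times_h,
             "U13C-glutamine": design.glutamine_times_h}
    for tracer, grid in grids.items():
        system = assemble_labeling_odes(net, params, tracer)
        df = integrate(system, list(grid), condition=preset.name)
        df["sd"] = max(noise.labeling_sd, 1e-3)
        if noise.labeling_sd > 0:
            noisy = df["fraction"].to_numpy() \
                + noise.labeling_sd * rng.standard_normal(len(df))
            df["fraction"] = np.clip(noisy, 0.0, 1.0)
        frames.append(df)
        ss = steady_state_fractions(system)
        for st, frac in ss.items():
            val = frac
            if noise.labeling_sd > 0:
                val = float(np.clip(frac + noise.labeling_sd
                                    * rng.standard_normal(), 0.0, 1.0))
            ss_rows.append((st.metabolite, st.n_labeled, np.inf, val,
                            max(noise.labeling_sd, 1e-3), tracer, preset.name))
    labeling = pd.concat(frames, ignore_index=True)
    steady = pd.DataFrame(ss_rows, columns=TIMECOURSE_COLUMNS)

    # measured pools: every non-virtual, measured metabolite; hexose-P is
    # observed as active + latent sub-pool
    pool_obs, pool_sd = {}, {}
    for met in net.pool_metabolites:
        node = net.metabolites[met]
        if node.unmeasured:
            continue
        total = params.pools[met]
        if node.latent == "pool":
            total = total + params.latent_hexp_pool
        mult = 1.0 + noise.pool_cv * rng.standard_normal() if noise.pool_cv else 1.0
        pool_obs[met] = total * max(mult, 0.05)
        pool_sd[met] = max(noise.pool_cv * total, 1e-6)

    rates_obs, rates_sd = {}, {}
    for k, v in params.rates.items():
        mult = 1.0 + noise.rate_rel_sd * rng.standard_normal() if noise.rate_rel_sd else 1.0
        rates_obs[k] = v * max(mult, 0.05)
        rates_sd[k] = max(noise.rate_rel_sd * v, 1e-9)

    ratio = ppp_convergence_ratio(params, net,
                                  time_h=design.convergence_time_h)
    ratio_sd = max(0.05 * ratio, 1e-4)
    ratio_obs = ratio
    if noise.rate_rel_sd > 0:
        ratio_obs = max(ratio * (1 + 0.05 * rng.standard_normal()), 0.0)

    medium, protein = generate_medium_experiment(preset, design, noise, rng)

    return ExperimentDataset(
        condition=preset.name, labeling=labeling, steady_state=steady,
        pool_sizes=pd.Series(pool_obs), pool_sd=pd.Series(pool_sd),
        rates=rates_obs, rate_sd=rates_sd,
        convergence_ratio=ratio_obs, convergence_ratio_sd=ratio_sd,
        latent_citrate_fraction=None, medium=medium, protein=protein,
        ground_truth=params)


# ---------------------------------------------------------------------------

def generate_pool_table(n_real: int, n_blank_only: int,
                        effect: dict | None = None,
                        noise: NoiseModel = NoiseModel(),
                        seed: int = 0,
                        conditions: tuple[str, ...] = ("proliferating", "CI14"),
                        replicates: int = 4) -> PoolTable:
    """Raw-signal fixture for the blank filter and the FDR screen.

    ``n_real`` metabolites reach >= 5x the blank in at least one sample;
    ``n_blank_only`` stay below that threshold.  ``effect`` optionally
    injects a shift: ``{"metabolite": name, "n_sd": k, "condition": c}``
    multiplies that metabolite's levels in condition ``c`` by
    ``1 + k * pool_cv``.
    """
    if n_real < 0 or n_blank_only < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    mets = [f"met{i:02d}" for i in range(n_real + n_blank_only)]
    samples, cond_labels = [], []
    for c in conditions:
        for r in range(replicates):
            samples.append(f"{c}_{r}")
            cond_labels.append(c)
    blank = pd.Series(100.0 * np.exp(rng.uniform(0, 1.5, len(mets))), index=mets)
    base = np.empty((len(mets), len(samples)))
    for i, met in enumerate(mets):
        if i < n_real:
            level = blank[met] * rng.uniform(8.0, 40.0)
        else:
            level = blank[met] * rng.uniform(0.3, 3.0)
        base[i] = level
    cv = max(noise.pool_cv, 1e-12)
    signals = base * np.exp(cv * rng.standard_normal(base.shape))
    if effect:
        met = effect["metabolite"]
        cond = effect.get("condition", conditions[-1])
        k = float(effect["n_sd"])
        cols = [s for s, c in zip(samples, cond_labels) if c == cond]
        i = mets.index(met)
        j = [samples.index(s) for s in cols]
        signals[i, j] *= np.exp(k * cv)
    sig = pd.DataFrame(signals, index=mets, columns=samples)
    # enforce the blank-enrichment design exactly
    fold = sig.div(blank, axis=0)
    for i, met in enumerate(mets):
        if i < n_real and fold.loc[met].max() < 5.0:
            sig.loc[met, sig.columns[0]] = blank[met] * 6.0
        elif i >= n_real:
            sig.loc[met] = np.minimum(sig.loc[met], blank[met] * 4.5)
    protein = pd.Series(50.0 + 5.0 * rng.standard_normal(len(samples)),
                        index=samples).clip(lower=10.0)
    return PoolTable(signals=sig, blank=blank, protein_ug=protein,
                     condition=pd.Series(cond_labels, index=samples))


# ---------------------------------------------------------------------------

def simulate_toy_dataset(params: FluxParameterSet, net: MetabolicNetwork,
                         times_h=(0.0, 0.05, 0.1, 0.2, 0.4, 0.8, 1.5),
                         noise: NoiseModel = ZERO_NOISE, seed: int = 0,
                         condition: str = "toy") -> ExperimentDataset:
    """Dataset for a small network (single tracer, no medium curves).

    Used with a cost specification restricted to the labeling, pool and
    rate blocks; the convergence-ratio field is a placeholder.
    """
    rng = np.random.default_rng(seed)
    tracer = next(iter(net.tracers))
    system = assemble_labeling_odes(net, params, tracer)
    df = integrate(system, list(times_h), condition=condition)
    df["sd"] = max(noise.labeling_sd, 1e-3)
    if noise.labeling_sd > 0:
        df["fraction"] = np.clip(
            df["fraction"].to_numpy()
            + noise.labeling_sd * rng.standard_normal(len(df)), 0.0, 1.0)
    ss_rows = []
    for st, frac in steady_state_fractions(system).items():
        ss_rows.append((st.metabolite, st.n_labeled, np.inf, frac,
                        max(noise.labeling_sd, 1e-3), tracer, condition))
    steady = pd.DataFrame(ss_rows, columns=TIMECOURSE_COLUMNS)
    pool_obs = {m: params.pools[m] for m in net.pool_metabolites}
    return ExperimentDataset(
        condition=condition, labeling=df, steady_state=steady,
        pool_sizes=pd.Series(pool_obs),
        pool_sd=pd.Series({m: 0.05 * v for m, v in pool_obs.items()}),
        rates=dict(params.rates),
        rate_sd={k: 0.02 * v for k, v in params.rates.items()},
        convergence_ratio=0.0, convergence_ratio_sd=1.0,
        ground_truth=params)
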