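"""Measurement-side computations: uptake/excretion rates from medium
time-courses, pool normalization and filtering, isotopomer ratios, the
latent-pool estimator and the glutathione redox ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .units import MINUTES_PER_HOUR

__all__ = [
    "MediumTimecourse", "ProteinCurve", "PoolTable", "NormalizedPools",
    "integrated_protein_hours", "uptake_excretion_rate",
    "normalize_pool_sizes", "blank_enrichment_filter", "differential_pools",
    "lactate_isotopomer_ratio", "latent_pool_fraction", "anaplerosis_ratio",
    "gsh_gssg_ratio", "SENTINEL_BELOW_DETECTION",
]

#: Raw-signal value assigned to measurements below the detection limit.
SENTINEL_BELOW_DETECTION = 100.0

#: Sign convention: +1 means consumption from the medium is reported as a
#: positive rate, -1 means excretion into the medium is positive.
RATE_SIGN = {"glucose": -1.0, "glutamine": -1.0, "lactate": +1.0,
             "glutamate": +1.0}


@dataclass
class MediumTimecourse:
    """Concentrations of medium nutrients over time for one condition.

    ``concentrations`` maps metabolite -> array of mM values, either
    shape (n_times,) or (n_replicates, n_times).
    """

    times_h: np.ndarray
    concentrations: Mapping[str, np.ndarray]
    volume_ml: float
    condition: str = ""

    def __post_init__(self):
        self.times_h = np.asarray(self.times_h, dtype=float)
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("medium sampling times must be increasing")
        conc = {}
        for met, c in self.concentrations.items():
            c = np.atleast_2d(np.asarray(c, dtype=float))
            if c.shape[-1] != len(self.times_h):
                raise ValueError(f"{met}: concentration grid mismatch")
            if np.any(c < 0):
                raise ValueError(f"{met}: negative concentration")
            conc[met] = c
        self.concentrations = conc


@dataclass
class ProteinCurve:
    """Protein mass (ug) on the plate over time."""

    times_h: np.ndarray
    protein_ug: np.ndarray

    def __post_init__(self):
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.protein_ug = np.asarray(self.protein_ug, dtype=float)
        if np.any(self.protein_ug <= 0):
            raise ValueError("protein mass must be positive")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("protein sampling times must be increasing")


@dataclass
class PoolTable:
    """Raw intracellular signals (arbitrary units) per metabolite x sample.

    ``signals``: DataFrame indexed by metabolite, one column per sample.
    ``blank``: per-metabolite signal from a medium-only control plate.
    ``protein_ug``: per-sample protein amount.
    ``condition``: per-sample condition label.
    """

    signals: pd.DataFrame
    blank: pd.Series
    protein_ug: pd.Series
    condition: pd.Series

    def __post_init__(self):
        if (self.signals.to_numpy() < 0).any():
            raise ValueError("negative raw signal")
        missing = set(self.signals.index) - set(self.blank.index)
        if missing:
            raise ValueError(f"blank signal missing for {sorted(missing)}")


@dataclass
class NormalizedPools:
    """Protein-normalized pool levels with a censoring mask."""

    levels: pd.DataFrame          # signal per ug protein
    censored: pd.DataFrame        # True where the raw signal was the sentinel
    condition: pd.Series = field(default=None)


# ---------------------------------------------------------------------------

def integrated_protein_hours(curve: ProteinCurve, t0: float, t1: float) -> float:
    """Trapezoidal area under the protein curve over [t0, t1], in ug*h."""
    if not (t0 < t1):
        raise ValueError("need t0 < t1")
    if t0 < curve.times_h[0] - 1e-9 or t1 > curve.times_h[-1] + 1e-9:
        raise ValueError(
            f"interval [{t0}, {t1}] outside measured range "
            f"[{curve.times_h[0]}, {curve.times_h[-1]}]")
    grid = np.unique(np.clip(
        np.concatenate([[t0], curve.times_h, [t1]]), t0, t1))
    vals = np.interp(grid, curve.times_h, curve.protein_ug)
    return float(np.trapezoid(vals, grid))


def _cumulative_protein_min(curve: ProteinCurve, times_h: np.ndarray) -> np.ndarray:
    """Integral of protein from times[0] to each time, in ug*min."""
    out = np.zeros(len(times_h))
    for i, t in enumerate(times_h[1:], start=1):
        out[i] = integrated_protein_hours(curve, times_h[0], t) * MINUTES_PER_HOUR
    return out


def uptake_excretion_rate(medium: MediumTimecourse, curve: ProteinCurve,
                          metabolite: str, method: str = "integral") -> float:
    """Per-protein uptake or excretion rate, nmol/min/ug protein.

    The rate is the amount appearing in (or disappearing from) the medium
    divided by the time integral of plate protein mass.  Consumption is
    reported positive for glucose and glutamine, excretion positive for
    lactate and glutamate.

    ``method="integral"`` (default) regresses the concentration against
    the cumulative protein-integral regressor over all time points and
    replicates, which for two time points reduces exactly to
    delta-amount / protein-integral.  ``method="endpoint_protein"``
    normalizes the endpoint difference by the final protein mass instead
    of the integral.
    """
    if metabolite not in medium.concentrations:
        raise KeyError(f"{metabolite!r} not measured in this medium time-course")
    conc = medium.concentrations[metabolite]       # (reps, times)
    times = medium.times_h
    if len(times) < 2:
        raise ValueError("need at least two medium time points")
    sign = RATE_SIGN.get(metabolite, -1.0)
    if method == "endpoint_protein":
        d_nmol = (conc[:, -1].mean() - conc[:, 0].mean()) * medium.volume_ml * 1e3
        p_end = float(np.interp(times[-1], curve.times_h, curve.protein_ug))
        dt_min = (times[-1] - times[0]) * MINUTES_PER_HOUR
        return sign * d_nmol / (p_end * dt_min)
    if method != "integral":
        raise ValueError(f"unknown method {method!r}")
    g = _cumulative_protein_min(curve, times)      # ug*min
    if g[-1] <= 0:
        raise ZeroDivisionError("zero protein integral")
    # c(t) [mM] = c0 + slope * g(t), slope in mM per ug*min;
    # rate [nmol/min/ug] = -sign-adjusted slope * volume_ml * 1e3
    x = np.tile(g, conc.shape[0])
    ycs = conc.reshape(-1)
    x_c = x - x.mean()
    slope = float(np.dot(x_c, ycs) / np.dot(x_c, x_c))
    return sign * slope * medium.volume_ml * 1e3


# ---------------------------------------------------------------------------

def normalize_pool_sizes(pools: PoolTable) -> NormalizedPools:
    """Normalize raw signals by per-sample protein (signal per ug).

    Sentinel (below-detection) entries are flagged as censored rather than
    treated as measurements.
    """
    missing = set(pools.signals.columns) - set(pools.protein_ug.index)
    if missing:
        raise ValueError(f"protein amount missing for samples {sorted(missing)}")
    protein = pools.protein_ug[pools.signals.columns]
    if (protein <= 0).any():
        raise ValueError("non-positive protein amount")
    censored = pools.signals == SENTINEL_BELOW_DETECTION
    levels = pools.signals / protein
    return NormalizedPools(levels=levels, censored=censored,
                           condition=pools.condition)


def blank_enrichment_filter(pools: PoolTable, threshold: float = 5.0) -> list[str]:
    """Metabolites enriched >= ``threshold``-fold over the medium-only blank
    in at least one sample.

    A zero blank signal is replaced by the below-detection sentinel before
    ratioing.
    """
    blank = pools.blank[pools.signals.index].astype(float).copy()
    blank[blank <= 0] = SENTINEL_BELOW_DETECTION
    fold = pools.signals.div(blank, axis=0)
    keep = fold.max(axis=1) >= threshold
    return list(pools.signals.index[keep])


def differential_pools(norm: NormalizedPools, reference: str | None = None,
                       fdr: float = 0.05, log_transform: bool = True
                       ) -> list[str]:
    """Metabolites whose levels differ between conditions at the given FDR.

    Welch's two-sample t-test on (log) levels, each non-reference
    condition against the reference (default: first condition label),
    with Benjamini-Hochberg correction across all tests.  Metabolites
    with fewer than two replicates in a group are excluded with a warning.
    """
    cond = norm.condition
    if cond is None:
        raise ValueError("NormalizedPools carries no condition labels")
    labels = list(dict.fromkeys(cond))
    if reference is None:
        reference = labels[0]
    others = [c for c in labels if c != reference]
    ref_cols = cond[cond == reference].index
    pvals, keys = [], []
    for met in norm.levels.index:
        row = norm.levels.loc[met]
        cens = norm.censored.loc[met]
        a = row[ref_cols][~cens[ref_cols]].to_numpy(dtype=float)
        for other in others:
            cols = cond[cond == other].index
            b = row[cols][~cens[cols]].to_numpy(dtype=float)
            if len(a) < 2 or len(b) < 2:
                warnings.warn(
                    f"{met}: fewer than 2 uncensored replicates; excluded",
                    stacklevel=2)
                continue
            xa, xb = (np.log(a), np.log(b)) if log_transform else (a, b)
            if np.ptp(xa) == 0 and np.ptp(xb) == 0 and xa.mean() == xb.mean():
                p = 1.0
            else:
                p = stats.ttest_ind(xa, xb, equal_var=False).pvalue
            pvals.append(p)
            keys.append(met)
    if not pvals:
        return []
    reject, *_ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    return sorted({m for m, r in zip(keys, reject) if r})


# ---------------------------------------------------------------------------

def lactate_isotopomer_ratio(abundance_1x: float, abundance_2x: float) -> float:
    """Ratio of 1x-13C to 2x-13C lactate under [1,2-13C]-glucose."""
    if abundance_2x <= 0:
        raise ZeroDivisionError("zero 2x-13C lactate abundance; ratio undefined")
    if abundance_1x < 0:
        raise ValueError("negative abundance")
    return abundance_1x / abundance_2x


def latent_pool_fraction(timecourses: pd.DataFrame | Iterable[pd.DataFrame],
                         metabolite: str = "cit") -> float:
    """Never-labeling sub-pool fraction of a metabolite.

    Estimated as the lowest unlabeled fraction observed across all time
    points and experiments (tracer switches), clipped to [0, 1].
    """
    if isinstance(timecourses, pd.DataFrame):
        frames = [timecourses]
    else:
        frames = list(timecourses)
    if not frames:
        raise ValueError("no time-courses given")
    vals = []
    for df in frames:
        sel = df[(df["metabolite"] == metabolite) & (df["n_labeled"] == 0)]
        vals.append(sel["fraction"].to_numpy(dtype=float))
    vals = np.concatenate(vals) if vals else np.array([])
    if vals.size == 0:
        raise ValueError(f"no unlabeled-fraction observations for {metabolite!r}")
    est = float(np.clip(np.min(vals), 0.0, 1.0))
    if est >= 1.0:
        warnings.warn(f"{metabolite!r} shows no labeling at all; latent "
                      "fraction at the upper boundary", stacklevel=2)
    return est


def anaplerosis_ratio(abundance_1x: float, abundance_unlabeled: float) -> float:
    """Descriptive 1x-13C : unlabeled ratio (e.g. citrate or malate under
    [3-13C]-glucose).  Not an input to flux fitting."""
    if abundance_unlabeled <= 0:
        raise ZeroDivisionError("zero unlabeled abundance; ratio undefined")
    if abundance_1x < 0:
        raise ValueError("negative abundance")
    return abundance_1x / abundance_unlabeled


def gsh_gssg_ratio(total_glutathione: float, gssg: float) -> float:
    """Reduced:oxidized glutathione ratio from a recycling assay.

    The assay reports total glutathione equivalents GSH + 2*GSSG, so the
    reduced pool is total - 2*GSSG and the ratio is (total - 2*GSSG)/GSSG.
    """
    if gssg <= 0:
        raise ZeroDivisionError("zero GSSG; ratio undefined")
    if total_glutathione < 2 * gssg:
        raise ValueError("total glutathione below 2*GSSG is inconsistent "
                         "with the recycling-assay convention")
    return (total_glutathione - 2.0 * gssg) / gssg
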