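"""Ensemble summaries, the distribution non-overlap comparison rule, and
log-scale flux histograms.

A flux is declared different between two conditions only when the two
ensembles' value ranges share no common point — a deliberately stringent
rule that minimizes false positives when many alternative flux solutions
fit the data comparably well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fit import SolutionEnsemble

__all__ = ["FluxComparison", "summarize_fluxes", "compare_flux_distributions",
           "flux_histograms"]


@dataclass(frozen=True)
class FluxComparison:
    """Verdict for one parameter: is A higher, lower, or indistinguishable
    relative to B under the range non-overlap rule?"""

    parameter: str
    verdict: str                       # "higher" | "lower" | "indistinguishable"
    range_a: tuple[float, float]
    range_b: tuple[float, float]


def summarize_fluxes(ens: SolutionEnsemble) -> pd.DataFrame:
    """Median and best (minimum-cost member) value per parameter."""
    if len(ens) == 0:
        raise ValueError("empty ensemble")
    best_row = ens.table.loc[ens.table["cost"].idxmin()]
    out = pd.DataFrame({
        "median": ens.table[ens.parameters].median(axis=0),
        "best": best_row[ens.parameters],
    })
    out.index.name = "parameter"
    return out


def _trimmed_range(values: np.ndarray, trim_q: float) -> tuple[float, float]:
    if trim_q > 0:
        return (float(np.quantile(values, trim_q)),
                float(np.quantile(values, 1 - trim_q)))
    return float(np.min(values)), float(np.max(values))


def compare_flux_distributions(ens_a: SolutionEnsemble, ens_b: SolutionEnsemble,
                               trim_q: float = 0.0) -> list[FluxComparison]:
    """Per-parameter non-overlap verdicts between two ensembles.

    ``trim_q`` optionally discards that quantile per side before taking
    ranges (off by default: full observed ranges).
    """
    if len(ens_a) == 0 or len(ens_b) == 0:
        raise ValueError("empty ensemble")
    if set(ens_a.parameters) != set(ens_b.parameters):
        raise ValueError("ensembles carry different parameterizations")
    out = []
    for p in ens_a.parameters:
        ra = _trimmed_range(ens_a.values(p), trim_q)
        rb = _trimmed_range(ens_b.values(p), trim_q)
        if ra[0] > rb[1]:
            verdict = "higher"
        elif ra[1] < rb[0]:
            verdict = "lower"
        else:
            verdict = "indistinguishable"
        out.append(FluxComparison(p, verdict, ra, rb))
    return out


def flux_histograms(ens: SolutionEnsemble, bins: int = 20) -> dict[str, pd.DataFrame]:
    """Per-parameter histograms on a log10 axis.

    Zero-valued fluxes go into a dedicated underflow bin (bin_lo = -inf).
    Counts per parameter sum to the ensemble size.
    """
    if len(ens) == 0:
        raise ValueError("empty ensemble")
    out = {}
    for p in ens.parameters:
        v = ens.values(p)
        pos = v[v > 0]
        n_zero = int(np.sum(v <= 0))
        rows = []
        if n_zero:
            rows.append((-np.inf, -np.inf, n_zero))
        if pos.size:
            logv = np.log10(pos)
            lo, hi = logv.min(), logv.max()
            if lo == hi:
                lo, hi = lo - 0.5, hi + 0.5
            counts, edges = np.histogram(logv, bins=bins, range=(lo, hi))
            for c, e0, e1 in zip(counts, edges[:-1], edges[1:]):
                rows.append((float(e0), float(e1), int(c)))
        out[p] = pd.DataFrame(rows, columns=["log10_lo", "log10_hi", "count"])
    return out
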