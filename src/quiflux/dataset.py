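"""The per-condition experiment dataset consumed by the flux fitter."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .network import FluxParameterSet
from .preprocess import MediumTimecourse, ProteinCurve


@dataclass
class ExperimentDataset:
    """All fitted (and auxiliary) measurements for one condition.

    ``labeling``: tidy time-course (metabolite, n_labeled, time_h,
    fraction, sd, tracer, condition) pooled over tracer switches.
    ``steady_state``: asymptotic labeling pattern rows (same columns,
    time_h = inf by convention).
    ``pool_sizes``/``pool_sd``: measured pools, nmol/ug protein.
    ``rates``/``rate_sd``: A, B, C, D in nmol/min/ug protein.
    ``convergence_ratio``: the 1x:2x lactate ratio observed after 2 h of
    [1,2-13C]-glucose feeding.
    """

    condition: str
    labeling: pd.DataFrame
    steady_state: pd.DataFrame
    pool_sizes: pd.Series
    pool_sd: pd.Series
    rates: Mapping[str, float]
    rate_sd: Mapping[str, float]
    convergence_ratio: float
    convergence_ratio_sd: float
    latent_citrate_fraction: float | None = None
    medium: MediumTimecourse | None = None
    protein: ProteinCurve | None = None
    ground_truth: FluxParameterSet | None = field(default=None, repr=False)

    def tracers(self) -> list[str]:
        return sorted(self.labeling["tracer"].unique())
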