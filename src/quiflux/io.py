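"""Readers and writers for the package's tidy CSV/JSON interchange formats.

Every artifact written here can be re-read by the corresponding reader
(round-trip property), and dataset directories carry a provenance record.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dataset import ExperimentDataset
from .fit import FluxSolution, GaConfig, SolutionEnsemble
from .network import FluxParameterSet
from .preprocess import MediumTimecourse, PoolTable, ProteinCurve
from .simulate import TIMECOURSE_COLUMNS

__all__ = [
    "write_timecourse", "read_timecourse", "write_medium", "read_medium",
    "write_protein", "read_protein", "write_pool_table", "read_pool_table",
    "ensemble_to_json", "ensemble_from_json", "params_to_dict",
    "params_from_dict", "write_provenance", "write_dataset", "read_dataset",
]


# -- labeling time-courses ---------------------------------------------------

def write_timecourse(df: pd.DataFrame, path: str | Path) -> None:
    missing = set(TIMECOURSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"time-course missing columns {sorted(missing)}")
    df[TIMECOURSE_COLUMNS].to_csv(path, index=False)


def read_timecourse(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TIMECOURSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = df[(df["fraction"] < -1e-9) | (df["fraction"] > 1 + 1e-9)]
    if len(bad):
        raise ValueError(f"{path}: fractions outside [0, 1]")
    return df


# -- medium / protein / pools ------------------------------------------------

def write_medium(medium: MediumTimecourse, path: str | Path) -> None:
    rows = []
    for met, arr in medium.concentrations.items():
        for rep in range(arr.shape[0]):
            for t, c in zip(medium.times_h, arr[rep]):
                rows.append((medium.condition, met, rep, t,
                             medium.volume_ml, c))
    pd.DataFrame(rows, columns=["condition", "metabolite", "replicate",
                                "time_h", "volume_ml", "conc_mM"]
                 ).to_csv(path, index=False)


def read_medium(path: str | Path) -> MediumTimecourse:
    df = pd.read_csv(path)
    times = np.sort(df["time_h"].unique())
    conc = {}
    for met, sub in df.groupby("metabolite"):
        reps = []
        for _, rep in sub.groupby("replicate"):
            rep = rep.sort_values("time_h")
            reps.append(rep["conc_mM"].to_numpy())
        conc[met] = np.vstack(reps)
    return MediumTimecourse(times_h=times, concentrations=conc,
                            volume_ml=float(df["volume_ml"].iloc[0]),
                            condition=str(df["condition"].iloc[0]))


def write_protein(curve: ProteinCurve, path: str | Path) -> None:
    pd.DataFrame({"time_h": curve.times_h, "protein_ug": curve.protein_ug}
                 ).to_csv(path, index=False)


def read_protein(path: str | Path) -> ProteinCurve:
    df = pd.read_csv(path)
    return ProteinCurve(times_h=df["time_h"].to_numpy(),
                        protein_ug=df["protein_ug"].to_numpy())


def write_pool_table(pools: PoolTable, path: str | Path) -> None:
    rows = []
    for met in pools.signals.index:
        for sample in pools.signals.columns:
            rows.append((met, sample, pools.signals.loc[met, sample],
                         pools.blank[met], pools.protein_ug[sample],
                         pools.condition[sample]))
    pd.DataFrame(rows, columns=["metabolite", "sample", "signal", "blank",
                                "protein_ug", "condition"]
                 ).to_csv(path, index=False)


def read_pool_table(path: str | Path) -> PoolTable:
    df = pd.read_csv(path)
    signals = df.pivot(index="metabolite", columns="sample", values="signal")
    blank = df.groupby("metabolite")["blank"].first()
    per_sample = df.groupby("sample").first()
    return PoolTable(signals=signals, blank=blank,
                     protein_ug=per_sample["protein_ug"],
                     condition=per_sample["condition"])


# -- parameter sets and ensembles -------------------------------------------

def params_to_dict(p: FluxParameterSet) -> dict:
    return {"free_fluxes": dict(p.free_fluxes), "rates": dict(p.rates),
            "pools": dict(p.pools), "latent_hexp_pool": p.latent_hexp_pool,
            "latent_citrate_fraction": p.latent_citrate_fraction}


def params_from_dict(d: dict) -> FluxParameterSet:
    return FluxParameterSet(**d)


def ensemble_to_json(ens: SolutionEnsemble, path: str | Path) -> None:
    doc = {
        "condition": ens.condition,
        "best_cost": ens.best_cost,
        "n_requested": ens.n_requested,
        "config": asdict(ens.config) if ens.config else None,
        "solutions": [
            {"params": params_to_dict(s.params), "cost": s.cost,
             "converged": s.converged, "seed": s.seed,
             "n_generations": s.n_generations}
            for s in ens.solutions],
        "table": {"columns": list(ens.table.columns),
                  "data": ens.table.to_dict(orient="list")},
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def ensemble_from_json(path: str | Path) -> SolutionEnsemble:
    doc = json.loads(Path(path).read_text())
    solutions = [FluxSolution(params=params_from_dict(s["params"]),
                              cost=s["cost"], converged=s["converged"],
                              seed=s["seed"], n_generations=s["n_generations"])
                 for s in doc["solutions"]]
    cfg = doc.get("config")
    if cfg:
        cfg["bounds"] = tuple(cfg["bounds"])
        cfg = GaConfig(**cfg)
    table = pd.DataFrame(doc["table"]["data"])[doc["table"]["columns"]]
    return SolutionEnsemble(condition=doc["condition"], solutions=solutions,
                            table=table,
                            best_cost=doc["best_cost"], config=cfg,
                            n_requested=doc.get("n_requested"))


# -- provenance and dataset directories -------------------------------------

def write_provenance(path: str | Path, inputs: dict, parameters: dict,
                     seed: int | None) -> None:
    import scipy
    doc = {
        "inputs": inputs,
        "parameters": parameters,
        "seed": seed,
        "versions": {"quiflux": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__, "scipy": scipy.__version__,
                     "python": platform.python_version()},
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def write_dataset(data: ExperimentDataset, outdir: str | Path,
                  seed: int | None = None) -> None:
    """Write an ExperimentDataset as a directory of CSV/JSON files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_timecourse(data.labeling, out / "labeling.csv")
    ss = data.steady_state.copy()
    ss["time_h"] = np.inf
    write_timecourse(ss, out / "steady_state.csv")
    scalars = {
        "condition": data.condition,
        "pool_sizes": data.pool_sizes.to_dict(),
        "pool_sd": data.pool_sd.to_dict(),
        "rates": dict(data.rates), "rate_sd": dict(data.rate_sd),
        "convergence_ratio": data.convergence_ratio,
        "convergence_ratio_sd": data.convergence_ratio_sd,
        "latent_citrate_fraction": data.latent_citrate_fraction,
    }
    (out / "scalars.json").write_text(json.dumps(scalars, indent=1, sort_keys=True))
    if data.medium is not None:
        write_medium(data.medium, out / "medium.csv")
    if data.protein is not None:
        write_protein(data.protein, out / "protein.csv")
    if data.ground_truth is not None:
        (out / "ground_truth.json").write_text(
            json.dumps(params_to_dict(data.ground_truth), indent=1,
                       sort_keys=True))
    write_provenance(out / "provenance.json",
                     inputs={"generator": "quiflux.synthetic"},
                     parameters={"condition": data.condition}, seed=seed)


def read_dataset(indir: str | Path) -> ExperimentDataset:
    ind = Path(indir)
    if not ind.exists():
        raise FileNotFoundError(f"dataset directory not found: {ind}")
    scalars = json.loads((ind / "scalars.json").read_text())
    labeling = read_timecourse(ind / "labeling.csv")
    steady = read_timecourse(ind / "steady_state.csv")
    medium = read_medium(ind / "medium.csv") if (ind / "medium.csv").exists() else None
    protein = read_protein(ind / "protein.csv") if (ind / "protein.csv").exists() else None
    gt = None
    if (ind / "ground_truth.json").exists():
        gt = params_from_dict(json.loads((ind / "ground_truth.json").read_text()))
    return ExperimentDataset(
        condition=scalars["condition"], labeling=labeling, steady_state=steady,
        pool_sizes=pd.Series(scalars["pool_sizes"]),
        pool_sd=pd.Series(scalars["pool_sd"]),
        rates=scalars["rates"], rate_sd=scalars["rate_sd"],
        convergence_ratio=scalars["convergence_ratio"],
        convergence_ratio_sd=scalars["convergence_ratio_sd"],
        latent_citrate_fraction=scalars.get("latent_citrate_fraction"),
        medium=medium, protein=protein, ground_truth=gt)
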