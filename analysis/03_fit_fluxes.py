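"""Fit flux ensembles to the synthetic datasets with the genetic algorithm.

Scaled-down ensembles (small populations, a handful of consistent
restarts, a reduced gene set) keep the run in the minutes range; pass
``--full`` to fit all free fluxes with a larger budget.  Ensemble JSON
and median/best summaries land under ``results/fits/<condition>/``.
"""

import argparse
from pathlib import Path

from quiflux.fit import CostBlock, CostSpec, GaConfig
from quiflux.pipeline import RunConfig, run_condition

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--conditions", nargs="*",
                    default=["proliferating", "CI14"])
    ap.add_argument("--n", type=int, default=4, help="ensemble size")
    ap.add_argument("--full", action="store_true",
                    help="fit all free fluxes with a larger GA budget")
    args = ap.parse_args()

    if args.full:
        ga = GaConfig(population=120, max_generations=150,
                      convergence_window=30, consistency_delta=0.05)
        genes = None                                    # pipeline default
    else:
        ga = GaConfig(population=24, max_generations=30,
                      convergence_window=10, consistency_delta=0.25,
                      bounds=(1e-4, 1.0))
        genes = ("F0", "F1", "F8", "F7", "F11")
    cfg = RunConfig(outdir=ROOT / "fits", master_seed=args.seed,
                    n_solutions=args.n, ga=ga,
                    dataset_dir=ROOT / "datasets",
                    cost_spec=CostSpec((CostBlock("labeling_dynamics"),
                                        CostBlock("pool_sizes"),
                                        CostBlock("uptake_rates"),
                                        CostBlock("convergence_ratio"))))
    if genes:
        cfg.genes = genes
    for condition in args.conditions:
        ens = run_condition(cfg, condition)
        print(f"{condition}: {len(ens)} consistent solutions, "
              f"best cost {ens.best_cost:.3f}")
        print((ROOT / "fits" / condition / "summary.csv").read_text())


if __name__ == "__main__":
    main()
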