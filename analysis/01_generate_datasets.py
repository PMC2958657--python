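"""Generate synthetic tracer-switch datasets for all four conditions.

Writes one dataset directory per condition (labeling time-courses for the
[U-13C]-glucose and [U-13C]-glutamine switches, asymptotic labeling,
pool sizes, medium/protein curves, exchange rates, the 2 h convergence-
ratio observation, and the generating ground truth) under
``results/datasets/``.
"""

import sys
from pathlib import Path

from quiflux.io import write_dataset
from quiflux.network import build_network
from quiflux.synthetic import CONDITIONS, make_condition_preset, simulate_dataset

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results" / "datasets"


def main():
    net = build_network()
    for i, condition in enumerate(CONDITIONS):
        preset = make_condition_preset(condition, net)
        ds = simulate_dataset(preset, seed=SEED + i, net=net)
        write_dataset(ds, OUT / condition, seed=SEED + i)
        print(f"{condition:>14}: {len(ds.labeling):4d} labeling rows, "
              f"A={preset.params.rates['A']:.3f} nmol/min/ug, "
              f"latent citrate {preset.params.latent_citrate_fraction:.2f}")
    print(f"\ndatasets written to {OUT}")


if __name__ == "__main__":
    main()
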