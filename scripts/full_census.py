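"""Full six-state census over an (R, T0) grid with all four initializations.

This is the long-running companion to ``scripts/acceptance.py``: it sweeps a
coarse grid of interaction radii and torque strengths with every
initialization family and several seeds, classifies each run, and writes the
resulting state diagram (per-cell label multisets) as JSON.  At the default
system size (N = 1000, 1000 + 1000 tau_R) a single cell takes hours of CPU
time; use --scale to run a reduced version (smaller N and shorter windows).

Usage:
    python scripts/full_census.py --out diagram.json [--scale small] [--seed 0]
"""

from __future__ import annotations

import argparse
import json

from cohesim import InitialCondition, SimParams
from cohesim.classify import sweep

SCALES = {
    # full-scale study conditions
    "full": dict(N=1000, t_equil=1000.0, t_collect=1000.0, dt=5e-5,
                 sample_interval=0.5),
    # reduced size for a single-CPU overnight run
    "small": dict(N=100, t_equil=50.0, t_collect=50.0, dt=1e-4,
                  sample_interval=0.25),
}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", required=True)
    ap.add_argument("--scale", choices=sorted(SCALES), default="full")
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-seeds", type=int, default=2)
    args = ap.parse_args()

    base = SimParams(Phi=0.025, Pe=80.0, **SCALES[args.scale])
    inits = [InitialCondition(k) for k in InitialCondition.KINDS]
    R_values = [1.0, 1.5, 2.0, 3.0]
    T0_values = [1.0, 5.0, 10.0, 30.0, 60.0, 100.0, 150.0]
    seeds = [args.seed + k for k in range(args.n_seeds)]

    diagram = sweep(base, R_values, T0_values, inits, seeds, progress=True)
    with open(args.out, "w") as fh:
        json.dump(diagram.to_dict(), fh, indent=1)
    labels = {e.get("label") for e in diagram.entries if "label" in e}
    print(f"observed states: {sorted(labels)}")


if __name__ == "__main__":
    main()
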