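#!/usr/bin/env python
"""Solvophobe-solvent selectivity sweep (a_AW).

Lowers the solvophobe-solvent repulsion from its reference value 115
toward 35, which makes the A19 homopolymer progressively more soluble.
The expected qualitative sequence is multicore (or single-core at desk
scale) -> single-core -> partially soluble particles / dispersed chains,
with the aggregate order parameter falling as A and solvent become more
compatible.

Writes results/aaw_sweep.csv and prints the morphology map.
"""

import argparse
from pathlib import Path

import dpdmc
from dpdmc import pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--box-edge", type=float, default=12.0)
    ap.add_argument("--steps", type=int, default=60_000)
    ap.add_argument("--seeds", type=int, nargs="+", default=[11])
    ap.add_argument("--grid", type=float, nargs="+",
                    default=[35, 45, 55, 65, 75, 85, 95, 105, 115])
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    df = pipeline.run_sweep(
        dpdmc.SystemSpec(box_edge=args.box_edge),
        dpdmc.InteractionTable.reference(), "a_AW", args.grid, args.seeds,
        dpdmc.IntegratorSettings(n_steps=args.steps,
                                 snapshot_interval=1000))
    args.out_dir.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out_dir / "aaw_sweep.csv", index=False)
    cols = ["value", "seed", "label", "n_a_cores", "core_Xn", "core_P",
            "phi_aggregate", "delta", "error"]
    print(df[cols].to_string(index=False))
    phi = df.groupby("value")["phi_aggregate"].mean()
    print("\naggregate order parameter vs a_AW (expect increase with a_AW):")
    print(phi.to_string())


if __name__ == "__main__":
    main()
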