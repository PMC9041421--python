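#!/usr/bin/env python
"""Build the shear exposure design.

The flume delivers four shared jet velocities; each life stage resolves them
into its own strain-rate ladder through its body width (e = v/y).  This
script writes the full treatment grid and prints each stage's ladder,
confirming that small stages (eggs, early larvae) face strain rates an order
of magnitude above juveniles at identical flume settings.
"""

from pathlib import Path

from pshpassage.shear import (
    DEFAULT_JET_VELOCITIES,
    design_treatments,
    treatments_to_frame,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    grid = treatments_to_frame(design_treatments())
    OUT.mkdir(exist_ok=True)
    path = OUT / "shear_treatments.csv"
    grid.to_csv(path, index=False)

    print(f"jet velocities (m/s): {DEFAULT_JET_VELOCITIES}")
    for stage, block in grid.groupby("life_stage", sort=False):
        ladder = sorted(round(s) for s in block.loc[~block.is_control, "strain_rate_per_s"])
        print(f"{stage:>12}: strains {ladder} s^-1 (+ control at 0)")
    print(f"wrote {path} ({len(grid)} rows)")


if __name__ == "__main__":
    main()
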