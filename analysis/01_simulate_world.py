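#!/usr/bin/env python
"""Generate the synthetic world: climate stack, scenarios, virtual species.

Writes the taxon table and raw occurrence records under results/data/ as
CSV, the (binary) climate rasters under scratch/world/, and prints what was
generated. Downstream scripts regenerate the world deterministically from
the same seed, so these files are for inspection, not a required cache.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from hybridrange import (
    StudyDesign,
    apply_scenario,
    default_scenarios,
    make_climate,
    make_study,
    write_climate,
    write_occurrences,
    write_taxa,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    rng = np.random.default_rng(np.random.SeedSequence(args.seed))
    design = StudyDesign()
    stack = make_climate(design.nrows, design.ncols, seed=int(rng.integers(2**31 - 1)))
    from dataclasses import replace

    study = make_study(replace(design, seed=int(rng.integers(2**31 - 1))), stack)

    world_dir = ROOT / "scratch" / "world"
    world_dir.mkdir(parents=True, exist_ok=True)
    write_climate(stack, world_dir / "climate_BASE.nc")
    for delta in default_scenarios():
        write_climate(apply_scenario(stack, delta), world_dir / f"climate_{delta.label}.nc")

    data_dir = ROOT / "results" / "data"
    data_dir.mkdir(parents=True, exist_ok=True)
    write_taxa(study.taxa, data_dir / "taxa.csv")
    occ = pd.concat([o.records for o in study.occurrences.values()], ignore_index=True)
    occ.to_csv(data_dir / "occurrences_raw.csv", index=False)
    design.to_yaml(data_dir / "study_design.yaml")

    land = stack.land_mask.mean()
    print(f"world: {design.nrows}x{design.ncols} cells at 10', {land:.0%} land")
    print(
        f"species: {len(study.taxa)} total — "
        f"{(study.taxa.group == 'garden').sum()} garden plants, "
        f"{(study.taxa.group == 'congener').sum()} congeners in "
        f"{study.taxa.genus.nunique()} genera"
    )
    truth_sizes = {
        sp: int(np.nansum(t.values >= 0.5)) for sp, t in study.truth.items()
    }
    print(
        "truth ranges (suitability >= 0.5): "
        f"median {int(np.median(list(truth_sizes.values())))} cells, "
        f"range {min(truth_sizes.values())}-{max(truth_sizes.values())}"
    )
    print(f"wrote rasters to {world_dir} and tables to {data_dir}")


if __name__ == "__main__":
    main()
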