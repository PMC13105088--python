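#!/usr/bin/env python
"""Generate the synthetic study inputs.

Writes a target map, an 8-map feature panel (2 coupled at mix weight 0.8,
6 independent), and the parcel geometry (P = 180 on an 80 mm sphere,
GRFs with 30 mm correlation length) under results/data/, in the same
parcel-table format the CLI pipeline consumes.
"""

import sys
from pathlib import Path

import numpy as np

import cortmatch as cm

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 42


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    geom = cm.make_sphere_geometry(180, 80.0)
    rng = np.random.default_rng(SEED)
    sampler = cm.GRFSampler(geom, cm.GRFParams(range_mm=30.0))

    target = cm.BrainMap(name="target", values=sampler.draw(rng, 1)[0],
                         geometry=geom)
    cm.write_parcel_table(target, OUT / "target.tsv")
    cm.write_geometry(geom, OUT / "geometry.csv")

    feat_dir = OUT / "features"
    feat_dir.mkdir(exist_ok=True)
    names = []
    for i in range(8):
        indep = sampler.draw(rng, 1)[0]
        if i < 2:
            name = f"coupled_{i + 1}"
            vals = 0.8 * target.values + 0.2 * indep
        else:
            name = f"independent_{i - 1}"
            vals = indep
        cm.write_parcel_table(
            cm.BrainMap(name=name, values=vals, geometry=geom),
            feat_dir / f"{name}.tsv",
        )
        names.append(name)
    print(f"wrote target, geometry and {len(names)} feature maps to {OUT}")
    print("features:", ", ".join(names))


if __name__ == "__main__":
    sys.exit(main())
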