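#!/usr/bin/env python
"""Rank-regression models and the smoothness asymmetry of their null.

Builds a target with known three-predictor rank-linear structure
(population rank-R^2 calibrated to ~0.30) and fits two models against the
same surrogate ensemble of the target:

* the true predictors (informative, spatially rough relative to the
  composite target), and
* three covariance-matched GRFs that are pure noise with the target's
  smoothness.

The first model should achieve R^2 near 0.30 with a small surrogate p;
the noise model illustrates how matched smoothness alone raises the null
R^2 median — the reason a nominally similar R^2 can fail to reach
significance.

Writes results/regression_models.csv and per-model residual tables.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

import cortmatch as cm
from cortmatch.rank_regression import residual_map, surrogate_r2_test
from cortmatch.surrogates import SurrogateParams
from cortmatch.synthetic import ScenarioSpec

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 42


def main():
    ROOT.mkdir(parents=True, exist_ok=True)
    geom = cm.make_sphere_geometry(180, 80.0)
    rng = np.random.default_rng(SEED)
    y, X_true, realized = cm.make_regression_scenario(geom, ScenarioSpec(), rng)
    sampler = cm.GRFSampler(geom, cm.GRFParams(range_mm=30.0))
    X_matched = [
        cm.BrainMap(name=f"matched_{j + 1}", values=v, geometry=geom)
        for j, v in enumerate(sampler.draw(rng, 3))
    ]
    ensemble = cm.generate_ensemble(
        y, params=SurrogateParams(n_surrogates=1000, seed=SEED)
    )

    rows = []
    for label, X in (("informative", X_true), ("matched_noise", X_matched)):
        res = surrogate_r2_test(y, X, ensemble)
        rows.append({
            "model": label,
            "r2": res.r2,
            "p_one_sided": res.p_one_sided,
            "null_r2_median": res.null_r2_median,
        })
        cm.write_parcel_table(residual_map(res), ROOT / f"residuals_{label}.tsv")

    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "regression_models.csv", index=False, float_format="%.6g")
    print(f"realized rank-R^2 of the generating scenario: {realized:.3f}\n")
    print(df.to_string(index=False))
    print("\nMatched-smoothness noise predictors raise the null R^2 median, "
          "shrinking the evidence an equal observed R^2 would carry.")


if __name__ == "__main__":
    sys.exit(main())
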