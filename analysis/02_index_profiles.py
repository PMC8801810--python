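#!/usr/bin/env python
"""Characterise the engineered indices on a clean scene.

Computes per-class seasonal NIRv profiles and annual (GA, DI) centroids
from a small noise-free scene — the feature-space picture that makes
the four land-cover classes separable: vegetation classes arc high in
GA, bare soil sits at high DI / near-zero GA, water at negative GA and
very low DI.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from amtdr import indices, preprocess
from amtdr.containers import CLASS_CODES
from amtdr.synthetic_scene import ScenarioConfig, generate_stack

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg = ScenarioConfig(
        grid_rows=20, grid_cols=20, years=(2001,), cloud_fraction=0.0,
        noise_sd=0.0, rng_seed=1,
    )
    stack, truth = generate_stack(cfg)
    daily, _ = preprocess.interpolate_year(stack, 2001)
    coeffs = indices.load_tc_coefficients()
    tc = indices.compute_tasseled_cap(daily, coeffs, band_axis=1)
    lo, hi = indices.GROWING_SEASON
    veg = (truth == CLASS_CODES["grassland"]) | (truth == CLASS_CODES["forest"])
    ref = np.moveaxis(tc[lo - 1 : hi][:, :, veg], 1, -1).reshape(-1, 3)
    stats = indices.fit_standardization(ref, provenance="clean scene, year-1 vegetation")
    stats.save(RESULTS / "standardization_stats.json")
    grids = indices.features_for_year(daily, stats, coeffs)

    rows = []
    nirv = indices.compute_nirv(daily[:, 0], daily[:, 1])
    for name, code in CLASS_CODES.items():
        m = truth == code
        if not m.any():
            continue
        prof = nirv[:, m].mean(axis=1)
        rows.append(
            {
                "class": name,
                "ga": float(grids["ga"][m].mean()),
                "di": float(grids["di"][m].mean()),
                "nirv_peak": float(prof.max()),
                "nirv_peak_doy": int(prof.argmax()) + 1,
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "class_index_centroids.csv", index=False)
    print("Per-class (GA, DI) centroids and NIRv seasonal peaks (noise-free):")
    print(table.to_string(index=False))
    print("\nVegetation classes peak in May-September; forest NIRv peak "
          "exceeds grassland's; water NIRv stays negative (NIR < red).")


if __name__ == "__main__":
    main()
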