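#!/usr/bin/env python
"""Write one exemplar synthetic input per assay, with ground-truth sidecars.

Produces, under results/simulated/: an isotropic and an aligned collagen
fiber field, a zymography spot stack, a round and a stellate cell mask,
and a baseline/follow-up gel silhouette pair. These are the same
generators every downstream analysis consumes in memory; the files exist
so the inputs can be inspected with any TIFF viewer.
"""

import dataclasses
import json
from pathlib import Path

import ecmquant as eq
from ecmquant import io

OUT = Path("results/simulated")
OUT.mkdir(parents=True, exist_ok=True)
SEED = 20260101


def emit(path, params, ground_truth):
    io.write_sidecar(path, {"params": dataclasses.asdict(params), "ground_truth": ground_truth})
    print(f"  wrote {path}")


def main():
    print("Simulating exemplar inputs (seed %d)" % SEED)

    for label, kappa in (("isotropic", 0.0), ("aligned30", 8.0)):
        p = eq.FiberFieldParams(kappa=kappa, mean_angle_deg=30.0, seed=SEED)
        img, gt = eq.generate_fiber_image(p)
        path = OUT / f"fibers_{label}.tif"
        io.write_image(path, img)
        gt = {k: v for k, v in gt.items() if k != "fiber_angles"}
        emit(path, p, gt)

    p = eq.SpotStackParams(stack_shape=(16, 128, 128), n_spots=10, seed=SEED)
    stack, gt = eq.generate_spot_stack(p)
    path = OUT / "zymo_stack.tif"
    io.write_stack(path, stack)
    emit(path, p, [{k: v for k, v in s.items() if k != "voxels"} for s in gt])

    for label, n_arms in (("round", 0), ("stellate", 5)):
        p = eq.CellShapeParams(n_arms=n_arms, arm_length_px=80.0, seed=SEED)
        img, gt = eq.generate_cell_mask(p)
        path = OUT / f"cell_{label}.tif"
        io.write_image(path, img)
        emit(path, p, gt)

    p = eq.GelSeriesParams(area_contraction_fraction=0.5, seed=SEED)
    baseline, followup, gt = eq.generate_gel_series(p)
    io.write_image(OUT / "gel_baseline.tif", baseline)
    path = OUT / "gel_followup.tif"
    io.write_image(path, followup)
    emit(path, p, gt)

    counts = eq.generate_count_table(8, 100, 0.6, seed=SEED)
    counts.to_csv(OUT / "sma_counts.csv", index=False)
    print(f"  wrote {OUT / 'sma_counts.csv'}")


if __name__ == "__main__":
    main()
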