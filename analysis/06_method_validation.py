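#!/usr/bin/env python
"""Method-level validation sweeps against generator ground truth.

Runs the checks that justify trusting the measurements in scripts 02-05:
the alignment index versus angular concentration curve, fiber-axis
recovery across mean angles, arm-length recovery, and contraction
recovery. Writes a tidy table per sweep under results/validation/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import ecmquant as eq

OUT = Path("results/validation")
OUT.mkdir(parents=True, exist_ok=True)


def kappa_sweep(n_seeds=10):
    rows = []
    for kappa in (0.0, 1.0, 2.0, 5.0, 10.0):
        for seed in range(n_seeds):
            img, _ = eq.generate_fiber_image(
                eq.FiberFieldParams(kappa=kappa, mean_angle_deg=30.0, seed=seed)
            )
            ctrl, _ = eq.generate_fiber_image(
                eq.FiberFieldParams(kappa=0.0, seed=seed + 10_000)
            )
            res = eq.fiber_alignment_pipeline(img, ctrl)
            rows.append({"kappa": kappa, "seed": seed, "alignment_index": res.alignment_index})
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "alignment_vs_kappa.csv", index=False)
    means = df.groupby("kappa")["alignment_index"].mean()
    print("alignment index vs kappa:", ", ".join(f"{k:g}->{v:.1f}" for k, v in means.items()))
    print("  strictly increasing:", bool(means.is_monotonic_increasing))


def axis_sweep():
    rows = []
    for mean_angle in (0.0, 30.0, 60.0, 90.0, 120.0, 150.0):
        for seed in range(3):
            img, _ = eq.generate_fiber_image(
                eq.FiberFieldParams(kappa=8.0, mean_angle_deg=mean_angle, seed=seed)
            )
            ctrl, _ = eq.generate_fiber_image(
                eq.FiberFieldParams(kappa=0.0, seed=seed + 10_000)
            )
            res = eq.fiber_alignment_pipeline(img, ctrl)
            err = abs(res.peak_angle_deg - mean_angle) % 180.0
            rows.append(
                {
                    "mean_angle_deg": mean_angle,
                    "seed": seed,
                    "recovered_deg": res.peak_angle_deg,
                    "error_deg": min(err, 180.0 - err),
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "axis_recovery.csv", index=False)
    print(f"axis recovery: max error {df.error_deg.max():.1f} deg over {len(df)} fields")


def arm_sweep():
    rows = []
    for arm_len in (40.0, 60.0, 80.0, 100.0):
        img, _ = eq.generate_cell_mask(eq.CellShapeParams(n_arms=4, arm_length_px=arm_len))
        for length in eq.extension_lengths(img.pixels > 0.5):
            rows.append({"arm_length_px": arm_len, "measured_px": length})
    df = pd.DataFrame(rows)
    df["error_px"] = (df.measured_px - df.arm_length_px).abs()
    df.to_csv(OUT / "arm_recovery.csv", index=False)
    print(f"arm-length recovery: max error {df.error_px.max():.2f} px")


def contraction_sweep():
    rows = []
    for fraction in (0.0, 0.25, 0.5, 0.75):
        baseline, followup, gt = eq.generate_gel_series(
            eq.GelSeriesParams(area_contraction_fraction=fraction)
        )
        res = eq.measure_contraction(baseline, followup)
        rows.append(
            {
                "true_percent": gt["percent_contraction"],
                "measured_percent": res.percent_contraction,
            }
        )
    df = pd.DataFrame(rows)
    df["error_points"] = (df.measured_percent - df.true_percent).abs()
    df.to_csv(OUT / "contraction_recovery.csv", index=False)
    print(f"contraction recovery: max error {df.error_points.max():.3f} points")


if __name__ == "__main__":
    kappa_sweep()
    axis_sweep()
    arm_sweep()
    contraction_sweep()
    print(f"tables under {OUT}/")
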