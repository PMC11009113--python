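#!/usr/bin/env python
"""Cellular brightness and maturation kinetics on synthetic bicistronic fields.

Simulates green/red co-expression fields for FPs whose true per-molecule
brightness is 0.22, 0.51 and 1.00 relative to a reference, runs the masked
ratio + throughput correction + reference normalization pipeline over
replicate seeds, and fits a single-exponential maturation course. Writes
results/cellular_brightness.csv and results/maturation_fit.csv.
"""

import math
from pathlib import Path

import numpy as np
import pandas as pd

from fpquant.brightness import (
    CellField,
    cellular_brightness,
    fit_maturation,
    maturation_curve,
    signal_mask,
)
from fpquant.simulate import SimulationConfig, gen_bicistronic_field, gen_maturation_course

N_SEEDS = 12


def corrected(g_per_mol: float, seed: int) -> float:
    cfg = SimulationConfig(seed=seed, n_cells=60, noise_sd=2.0, image_shape=(192, 192))
    green, red, _, _ = gen_bicistronic_field(cfg, g_per_mol, 1.0)
    bg_cfg = SimulationConfig(seed=seed + 50_000, n_cells=0, noise_sd=2.0, image_shape=(192, 192))
    green_bg, _, _, _ = gen_bicistronic_field(bg_cfg, g_per_mol, 1.0)
    mask = signal_mask(green, green_bg).mask
    return cellular_brightness(
        CellField(green, red), throughput_green=1.0, mask=mask, background=cfg.background
    ).throughput_corrected


def main() -> None:
    Path("results").mkdir(exist_ok=True)
    rows = []
    for truth in (0.22, 0.51, 1.00):
        vals = np.array(
            [corrected(truth, s) / corrected(1.0, s + 100_000) for s in range(N_SEEDS)]
        )
        rows.append(
            {
                "true_normalized_brightness": truth,
                "recovered_mean": round(float(vals.mean()), 4),
                "recovered_se": round(float(vals.std(ddof=1) / math.sqrt(N_SEEDS)), 5),
                "n_seeds": N_SEEDS,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv("results/cellular_brightness.csv", index=False)
    print(df.to_string(index=False))

    # maturation: recover the rate from a noiseless 48-h course
    k_true = 4.0e-5  # s⁻¹ ≈ 4.8-h half-rise, a fast-maturing green FP
    t = np.linspace(0.0, 48 * 3600.0, 97)
    table, red_final, _ = gen_maturation_course(k_true, 5.0, t, red_final=10.0)
    curve = maturation_curve(table["green"], t, red_final, throughput_green=1.0)
    k_fit, plateau = fit_maturation(t, curve)
    fit_df = pd.DataFrame(
        [
            {
                "k_mat_true_per_s": k_true,
                "k_mat_fit_per_s": k_fit,
                "half_rise_h": math.log(2) / k_fit / 3600.0,
                "plateau_ratio": round(plateau, 4),
            }
        ]
    )
    fit_df.to_csv("results/maturation_fit.csv", index=False)
    print("\n" + fit_df.to_string(index=False))


if __name__ == "__main__":
    main()
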