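#!/usr/bin/env python
"""Generate the synthetic study inputs with known ground truth.

Writes, under results/sim/: an excitation/emission spectrum pair for a
StayGold-like green FP, photobleaching traces (mono- and biexponential),
a pH titration, dispersibility assay counts, and a colocalization pixel
pair — each with a JSON ground-truth sidecar. Time-lapse motion stacks
(binary TIFF) go to scratch/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from fpquant.io import (
    write_ground_truth,
    write_spectrum_csv,
    write_stack_tiff,
    write_trace_csv,
)
from fpquant.simulate import (
    gen_assay_counts,
    gen_bleach_trace,
    gen_coloc_pair,
    gen_motion_stack,
    gen_spectrum_pair,
    gen_titration_series,
)

OUT = Path("results/sim")
SCRATCH = Path("scratch/sim")
SEED = 20260926


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    grid = np.arange(350.0, 651.0)

    ex, em = gen_spectrum_pair(496, 505, 25, 20, grid)
    write_spectrum_csv(ex, OUT / "excitation.csv")
    write_spectrum_csv(em, OUT / "emission.csv")

    k = np.log(2) / 300.0
    mono, gt = gen_bleach_trace([(1.0, k)], duration=1200.0, dt=6.0, noise_sd=0.01, seed=SEED)
    write_trace_csv(mono, OUT / "bleach_mono.csv")
    write_ground_truth(gt, OUT / "bleach_mono.gt.json")

    bi, gt = gen_bleach_trace(
        [(0.6, 0.01), (0.4, 0.001)], duration=2000.0, dt=2.0, noise_sd=0.01, seed=SEED + 1
    )
    write_trace_csv(bi, OUT / "bleach_biexp.csv")
    write_ground_truth(gt, OUT / "bleach_biexp.gt.json")

    table, gt = gen_titration_series(
        4.8, 1.0, 100.0, np.arange(3.0, 11.5, 0.5), noise_sd=2.0, seed=SEED + 2
    )
    pd.DataFrame(table).to_csv(OUT / "titration.csv", index=False)
    write_ground_truth(gt, OUT / "titration.gt.json")

    rows = []
    for construct, p in [("monomer-like", 0.95), ("dimer-like", 0.45)]:
        (n_normal, n_total), _ = gen_assay_counts(p, 200, seed=SEED + hash(construct) % 1000)
        rows.append({"construct": construct, "assay": "OSER", "n_normal": n_normal, "n_total": n_total})
    pd.DataFrame(rows).to_csv(OUT / "assay_counts.csv", index=False)

    a, b, gt = gen_coloc_pair(
        0.8, 10_000, saturation_fraction=0.02, background_fraction=0.5, seed=SEED + 3
    )
    pd.DataFrame({"channel_a": a, "channel_b": b}).to_csv(
        OUT / "coloc_pixels.csv", index=False, float_format="%.2f"
    )
    write_ground_truth(gt, OUT / "coloc_pixels.gt.json")

    for mode, kwargs in [
        ("static", {}),
        ("shifting", {"shift_per_frame": 3}),
        ("remodeling", {"texture_corr": 0.5}),
    ]:
        stack, gt = gen_motion_stack(mode, n_frames=20, seed=SEED + 4, shape=(96, 96), **kwargs)
        write_stack_tiff(stack, SCRATCH / f"motion_{mode}.tif")
        write_ground_truth(gt, SCRATCH / f"motion_{mode}.gt.json")

    print(f"wrote synthetic inputs to {OUT} (tables) and {SCRATCH} (stacks)")


if __name__ == "__main__":
    main()
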