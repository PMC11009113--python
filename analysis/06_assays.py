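#!/usr/bin/env python
"""Dispersibility scores, pKa fit and colocalization on the synthetic inputs.

Consumes the tables written by 01_simulate_inputs.py (regenerating when
missing): scores the assay count table with Wilson intervals, fits the
Hill model to the pH titration, and runs threshold-filtered correlation on
the colocalization pixel pair. Writes results/assay_scores.csv,
results/pka_fit.csv and results/colocalization.csv.
"""

from pathlib import Path

import pandas as pd

from fpquant.assays import AssayCount, colocalize, fit_pka, proportion_score

SIM = Path("results/sim")


def main() -> None:
    if not (SIM / "assay_counts.csv").exists():
        import runpy

        runpy.run_path(Path(__file__).with_name("01_simulate_inputs.py"), run_name="__main__")

    Path("results").mkdir(exist_ok=True)

    counts = pd.read_csv(SIM / "assay_counts.csv")
    rows = []
    for _, rec in counts.iterrows():
        score = proportion_score(
            AssayCount(rec["construct"], rec["assay"], int(rec["n_normal"]), int(rec["n_total"]))
        )
        rows.append(
            {
                "construct": rec["construct"],
                "assay": rec["assay"],
                "score_pct": round(score.percent, 1),
                "wilson_lo_pct": round(score.ci_low, 1),
                "wilson_hi_pct": round(score.ci_high, 1),
            }
        )
    scores = pd.DataFrame(rows)
    scores.to_csv("results/assay_scores.csv", index=False)
    print(scores.to_string(index=False))

    tit = pd.read_csv(SIM / "titration.csv")
    fit = fit_pka(tit["ph"].to_numpy(), tit["fluorescence"].to_numpy())
    pka_df = pd.DataFrame(
        [{"pka": round(fit.pka, 3), "hill": round(fit.hill, 3), "f_max": round(fit.f_max, 2)}]
    )
    pka_df.to_csv("results/pka_fit.csv", index=False)
    print("\n" + pka_df.to_string(index=False))

    pix = pd.read_csv(SIM / "coloc_pixels.csv")
    res = colocalize(
        pix["channel_a"].to_numpy(), pix["channel_b"].to_numpy(), saturation_value=4095.0
    )
    coloc_df = pd.DataFrame(
        [
            {
                "pearson_r": round(res.r, 4),
                "n_total": res.n_total,
                "n_included": res.n_included,
                "n_below_both": res.n_below_both,
                "n_saturated": res.n_saturated,
            }
        ]
    )
    coloc_df.to_csv("results/colocalization.csv", index=False)
    print("\n" + coloc_df.to_string(index=False))


if __name__ == "__main__":
    main()
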