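#!/usr/bin/env python
"""Psychometric slope and PSE analysis of the fixed-offset discrimination
experiment.

Reads results/discrimination_counts.csv; fits the cumulative Gaussian per
participant, phase, and condition; t-tests the main-minus-baseline slope
(sharpening index) and PSE (shift index) deltas for expected (d0) and
unexpected (d25) orientations.  Writes results/psych_fits.csv and
results/psych_stats.json.
"""

import json
from pathlib import Path

import pandas as pd

from expectprofile import experiments as ex
from expectprofile import psychometric as psy
from expectprofile import stats as st

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    counts = pd.read_csv(OUT / "discrimination_counts.csv")
    fit_rows, delta_rows = [], []
    for pid, part in counts.groupby("participant"):
        fits_b, fits_m = {}, {}
        for (phase, cond, group), sub in part.groupby(
                ["phase", "condition", "delta_group"]):
            data = ex.psychometric_data_from_counts(sub, f"{cond}-{group}")
            fit = psy.fit_cumnorm(data)
            key = f"E{cond[1:]}-{group}"
            (fits_b if phase == "baseline" else fits_m)[key] = fit
            fit_rows.append({"participant": pid, "phase": phase,
                             "condition": cond, "delta_group": group,
                             "pse": fit.pse, "sigma_p": fit.sigma_p,
                             "slope": fit.slope, "deviance": fit.deviance})
        deltas = psy.psych_deltas(fits_b, fits_m)
        delta_rows.append({"participant": pid, **{
            k: v for k, v in deltas.items() if k != "per_condition"}})

    table = pd.DataFrame(delta_rows)
    stats_out = {}
    print("Main-minus-baseline psychometric deltas "
          f"({len(table)} participants; PSE on the expectward axis, "
          "negative = attracted toward the expected orientation):")
    for col in [c for c in table.columns if c != "participant"]:
        res = st.one_sample_t(table[col])
        stats_out[col] = {"mean": float(table[col].mean()),
                          "t": res.statistic, "df": res.df,
                          "p": res.p_value, "d": res.effect_size}
        print(f"  {col}: {table[col].mean():+.4f}  "
              f"t({res.df}) = {res.statistic:.3f}, p = {res.p_value:.4g}, "
              f"d = {res.effect_size:.3f}")

    pd.DataFrame(fit_rows).to_csv(OUT / "psych_fits.csv", index=False)
    (OUT / "psych_stats.json").write_text(json.dumps(stats_out, indent=2))
    print(f"Wrote {OUT / 'psych_fits.csv'} and {OUT / 'psych_stats.json'}")


if __name__ == "__main__":
    main()
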