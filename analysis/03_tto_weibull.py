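#!/usr/bin/env python
"""Time-to-onset distribution and Weibull hazard-shape analysis.

Pools onset intervals (therapy start to event date) over the simulated
target cases, summarises the distribution, fits the two-parameter Weibull
by maximum likelihood and classifies the failure mode from the shape CI.
Run 01_simulate.py first.
"""

from pathlib import Path

import pandas as pd

from pvsignal.faers_io import AnalysisConfig, assemble_dataset, read_table
from pvsignal.tto import (
    collect_ttos,
    cumulative_incidence,
    fit_weibull,
    monthly_histogram,
    summarize,
)

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    src = ROOT / "scratch" / "synthetic"
    tables = {k: read_table(src / f"{k}.txt", k) for k in ("DEMO", "DRUG", "REAC", "THER")}
    ds = assemble_dataset(tables["DEMO"], tables["DRUG"], tables["REAC"],
                          tables["THER"],
                          AnalysisConfig(window_start="20211001", window_end="20240630"))
    sample = collect_ttos(ds)
    s = summarize(sample)
    fit = fit_weibull(sample)

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    pd.DataFrame([{
        "n": s.n,
        "mean_d": round(s.mean, 1),
        "median_d (IQR)": f"{s.median:g} ({s.q1:g}-{s.q3:g})",
        "alpha (95% CI)": f"{fit.alpha:.2f} ({fit.alpha_ci[0]:.2f}-{fit.alpha_ci[1]:.2f})",
        "beta (95% CI)": f"{fit.beta:.2f} ({fit.beta_ci[0]:.2f}-{fit.beta_ci[1]:.2f})",
        "type": fit.failure_type,
    }]).to_csv(results / "tto_summary.tsv", sep="\t", index=False)
    cumulative_incidence(sample).to_csv(results / "tto_ecdf.tsv", sep="\t", index=False)
    hist = monthly_histogram(sample)
    hist.to_csv(results / "tto_histogram.tsv", sep="\t", index=False)

    first_month = hist.iloc[0]["count"] / s.n
    print(f"n={s.n} onset times (excluded: {sample.excluded_negative} negative, "
          f"{sample.excluded_missing} missing)")
    print(f"mean {s.mean:.1f} d, median {s.median:g} d (IQR {s.q1:g}-{s.q3:g}); "
          f"{100 * first_month:.1f}% within the first month")
    print(f"Weibull alpha={fit.alpha:.2f} ({fit.alpha_ci[0]:.2f}-{fit.alpha_ci[1]:.2f}), "
          f"beta={fit.beta:.2f} ({fit.beta_ci[0]:.2f}-{fit.beta_ci[1]:.2f}) "
          f"-> {fit.failure_type} failure mode")


if __name__ == "__main__":
    main()
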