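#!/usr/bin/env python
"""Descriptive characteristics and SOC burden of the simulated database.

Tabulates the target cases by sex, age band, reporter occupation, country
and receipt year, and each SOC's share of the target drug's
report-reaction pairs.  Run 01_simulate.py first.
"""

from pathlib import Path

from pvsignal.disprop import run_screen
from pvsignal.faers_io import AnalysisConfig, assemble_dataset, read_table
from pvsignal.reporting import demographics, soc_proportions
from pvsignal.synthetic import packaged_pt_soc_map

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    src = ROOT / "scratch" / "synthetic"
    tables = {k: read_table(src / f"{k}.txt", k) for k in ("DEMO", "DRUG", "REAC", "THER")}
    ds = assemble_dataset(tables["DEMO"], tables["DRUG"], tables["REAC"],
                          tables["THER"],
                          AnalysisConfig(window_start="20211001", window_end="20240630"))
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    demo = demographics(ds.cases)
    demo.to_csv(results / "demographics.tsv", sep="\t", index=False)
    soc = run_screen(ds, packaged_pt_soc_map(), "soc")
    shares = soc_proportions(soc)
    shares.rename("share").to_csv(results / "soc_shares.tsv", sep="\t")

    total = len(ds.cases)
    fem = demo.query("section == 'sex' and category == 'female'").iloc[0]
    con = demo.query("section == 'reporter' and category == 'consumer'").iloc[0]
    print(f"{total} target cases; female {fem['count']} ({fem['proportion']}%), "
          f"consumer-reported {con['count']} ({con['proportion']}%)")
    top = shares.index[0]
    print(f"largest SOC burden: {top} ({100 * shares.iloc[0]:.1f}% of target pairs)")
    print(f"tables in {results}")


if __name__ == "__main__":
    main()
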