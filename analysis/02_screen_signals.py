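#!/usr/bin/env python
"""Disproportionality screen of the simulated database at PT and SOC level.

Runs the full ingestion pipeline (dedup -> window -> primary-suspect
filter) on the tables from 01_simulate.py, computes ROR/PRR/EBGM/IC for
every event at both MedDRA levels, and tallies the 4-algorithm
concordance.  Run 01_simulate.py first.
"""

import json
from pathlib import Path

from pvsignal.disprop import format_paper_layout, run_screen
from pvsignal.faers_io import AnalysisConfig, assemble_dataset, read_table
from pvsignal.reporting import concordance_counts
from pvsignal.synthetic import packaged_pt_soc_map

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    src = ROOT / "scratch" / "synthetic"
    tables = {k: read_table(src / f"{k}.txt", k) for k in ("DEMO", "DRUG", "REAC", "THER")}
    ds = assemble_dataset(tables["DEMO"], tables["DRUG"], tables["REAC"],
                          tables["THER"],
                          AnalysisConfig(window_start="20211001", window_end="20240630"))
    print("pipeline counts:", ds.counts)

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    pt_map = packaged_pt_soc_map()
    pt = run_screen(ds, pt_map, "pt")
    soc = run_screen(ds, pt_map, "soc")
    pt.to_csv(results / "pt_screen.tsv", sep="\t", index=False)
    soc.to_csv(results / "soc_screen.tsv", sep="\t", index=False)
    format_paper_layout(pt.head(50)).to_csv(results / "pt_screen_formatted.tsv",
                                            sep="\t", index=False)

    tally_pt, sets_pt = concordance_counts(pt)
    tally_soc, _ = concordance_counts(soc)
    (results / "concordance.json").write_text(json.dumps(
        {"pt": tally_pt, "soc": tally_soc,
         "four_algorithm_pts": sorted(sets_pt["ROR"] & sets_pt["PRR"]
                                      & sets_pt["MGPS"] & sets_pt["BCPNN"])},
        indent=1))

    four = pt[pt["n_positive"] == 4]["event"].tolist()
    print(f"screened {len(pt)} PTs / {len(soc)} SOCs")
    print(f"{len(four)} PTs positive in all four algorithms: {', '.join(four[:10])}"
          + (" ..." if len(four) > 10 else ""))
    print(f"PT concordance tally {tally_pt}; outputs in {results}")


if __name__ == "__main__":
    main()
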