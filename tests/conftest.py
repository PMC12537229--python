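"""Shared fixtures: a hand-enumerable toy FAERS file set."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pytest

from pvsignal.faers_io import AnalysisConfig


@pytest.fixture
def toy_tables() -> dict[str, pd.DataFrame]:
    """Three cases, one duplicated, two with the target drug as PS.

    Hand enumeration: case 100 has versions 1001 (20220101) and 1002
    (20220301) -> dedup keeps 1002; cases 200 and 300 are single-version.
    Cases 100 and 200 name TYRVAYA as PS, case 300 another drug.  After
    the join the target pairs are 1002:{SNEEZING, COUGH} and
    2001:{HEADACHE} (listed twice, collapses) = 3 pairs; the background
    contributes 3001:{NAUSEA} for a grand total of 4 pairs.
    """
    demo = pd.DataFrame(
        [
            ("1001", "100", "20220101", "", "45", "YR", "F", "CN", "US"),
            ("1002", "100", "20220301", "", "45", "YR", "F", "CN", "US"),
            ("2001", "200", "20220401", "20220320", "70", "YR", "M", "MD", "US"),
            ("3001", "300", "20230101", "", "", "", "", "", "US"),
        ],
        columns=["primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod",
                 "sex", "occp_cod", "occr_country"],
    )
    drug = pd.DataFrame(
        [
            ("1001", "TYRVAYA", "PS"),
            ("1002", "TYRVAYA", "PS"),
            ("2001", "tyrvaya ", "PS"),
            ("3001", "SOME OTHER DRUG", "PS"),
        ],
        columns=["primaryid", "drugname", "role_cod"],
    )
    reac = pd.DataFrame(
        [
            ("1001", "SNEEZING"),
            ("1002", "SNEEZING"),
            ("1002", "COUGH"),
            ("2001", "HEADACHE"),
            ("2001", "HEADACHE"),
            ("3001", "NAUSEA"),
        ],
        columns=["primaryid", "pt"],
    )
    ther = pd.DataFrame(
        [("1002", "20220210"), ("2001", "20220315")],
        columns=["primaryid", "start_dt"],
    )
    return {"DEMO": demo, "DRUG": drug, "REAC": reac, "THER": ther}


@pytest.fixture
def toy_dir(toy_tables, tmp_path) -> Path:
    """The toy tables written in the '$'-delimited ASCII dialect."""
    for kind, df in toy_tables.items():
        df.to_csv(tmp_path / f"{kind}.txt", sep="$", index=False, na_rep="")
    return tmp_path


@pytest.fixture
def toy_config() -> AnalysisConfig:
    return AnalysisConfig(synonyms={"TYRVAYA"}, window_start="20211001",
                          window_end="20240630")
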