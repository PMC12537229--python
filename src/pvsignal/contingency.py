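"""Report-reaction pair counting and 2x2 contingency tables.

The counting unit throughout is the *report-reaction pair*: each
(primaryid, PT) combination contributes one pair, duplicated listings of
the same PT on one report collapse to one.  This is the unit under which a
database of ~2000 cases carries ~5000 analysable events.  At SOC level each
pair contributes one count to the System Organ Class of its PT.

For one event E and the target drug, the 2x2 table is

            event E    other events
  target       a            b
  others       c            d

with N = a + b + c + d the grand pair total; every disproportionality
statistic is a function of these four cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ContingencyTable", "load_pt_soc_map", "count_pairs", "make_table"]

UNMAPPED_SOC = "UNMAPPED"


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 drug-event pair counts (a, b, c, d)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for cell in ("a", "b", "c", "d"):
            if getattr(self, cell) < 0:
                raise ValueError(f"negative cell {cell} in {self}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def target_total(self) -> int:
        return self.a + self.b

    @property
    def event_total(self) -> int:
        return self.a + self.c


def load_pt_soc_map(path: str | Path) -> dict[str, str]:
    """Load a two-column ``pt<TAB>soc`` mapping (header row optional).

    PT keys are case-normalised (upper, collapsed whitespace); each PT must
    map to exactly one SOC.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, names=["pt", "soc"])
    if not df.empty and df.iloc[0]["pt"].strip().lower() in {"pt", "preferred term"}:
        df = df.iloc[1:]
    mapping: dict[str, str] = {}
    for pt, soc in zip(df["pt"], df["soc"]):
        key = _norm(pt)
        soc = str(soc).strip()
        if key in mapping and mapping[key] != soc:
            raise ValueError(f"PT {pt!r} maps to multiple SOCs")
        mapping[key] = soc
    return mapping


def _norm(term: str) -> str:
    return " ".join(str(term).upper().split())


def count_pairs(
    reactions: pd.DataFrame,
    target_ids: set[str],
    level: str = "pt",
    pt_soc_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-event pair counts at PT or SOC level.

    ``reactions`` needs columns ``primaryid`` and ``pt``; duplicate
    (primaryid, event) pairs collapse to one.  Returns a DataFrame indexed
    by event with columns ``n_target`` and ``n_total``.  At SOC level,
    unmapped PTs are tallied under ``UNMAPPED`` with a warning.
    """
    level = level.lower()
    if level not in {"pt", "soc"}:
        raise ValueError(f"level must be 'pt' or 'soc', got {level!r}")
    df = reactions.loc[:, ["primaryid", "pt"]].copy()
    df["event"] = df["pt"].map(_norm)
    # the pair is defined at PT level; SOC mapping happens after collapsing,
    # so a report listing two PTs of one SOC contributes two SOC pairs
    df = df.drop_duplicates(subset=["primaryid", "event"])
    if level == "soc":
        if pt_soc_map is None:
            raise ValueError("SOC-level counting requires a PT->SOC map")
        normalized_map = {_norm(k): v for k, v in pt_soc_map.items()}
        df["event"] = df["event"].map(normalized_map)
        n_unmapped = int(df["event"].isna().sum())
        if n_unmapped:
            logger.warning("%d pairs with PTs missing from the SOC map -> %s",
                           n_unmapped, UNMAPPED_SOC)
        df["event"] = df["event"].fillna(UNMAPPED_SOC)
    df["is_target"] = df["primaryid"].isin(target_ids)
    grouped = df.groupby("event", sort=True).agg(
        n_target=("is_target", "sum"), n_total=("is_target", "size")
    )
    grouped["n_target"] = grouped["n_target"].astype(int)
    grouped["n_total"] = grouped["n_total"].astype(int)
    return grouped


def make_table(
    event_target_count: int,
    target_total: int,
    event_grand_count: int,
    grand_total: int,
) -> ContingencyTable:
    """Build the 2x2 table from an event's target count and the margins.

    a = target pairs with the event, b = other target pairs, c = the
    event's pairs under all other drugs, d = everything else.  Any negative
    derived cell means the inputs were inconsistent.
    """
    a = int(event_target_count)
    b = int(target_total) - a
    c = int(event_grand_count) - a
    d = int(grand_total) - a - b - c
    if min(a, b, c, d) < 0:
        raise ValueError(
            "inconsistent margins: "
            f"(a={a}, b={b}, c={c}, d={d}) from event_target={event_target_count}, "
            f"target_total={target_total}, event_grand={event_grand_count}, "
            f"grand_total={grand_total}"
        )
    return ContingencyTable(a, b, c, d)
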