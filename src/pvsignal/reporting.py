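"""Descriptive tables, algorithm concordance and the pipeline orchestrator.

The descriptive table mirrors the layout customary in pharmacovigilance
reports: counts and percentage proportions by sex, age band, reporting
country, reporter occupation and receipt year.  Proportions are rounded
half away from zero at 1 decimal place (receipt-year rows at 2).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from . import __version__
from .disprop import SignalThresholds, run_screen
from .tto import (
    TTOSample,
    collect_ttos,
    cumulative_incidence,
    fit_weibull,
    monthly_histogram,
    summarize,
)

logger = logging.getLogger(__name__)

__all__ = [
    "round_half_up",
    "proportion",
    "demographics",
    "concordance_counts",
    "soc_proportions",
    "run_pipeline",
    "ReportBundle",
]

AGE_BIN_LABELS = ("18-65", "65-85", ">85", "missing")
REPORTER_ORDER = ("consumer", "health_professional", "physician", "pharmacist", "missing")


def round_half_up(x: float, decimals: int) -> float:
    """Round half *away from zero* (4.85 -> 4.9 at 1 d.p.), unlike banker's."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def proportion(count: int, total: int, decimals: int = 1) -> float:
    """Percentage 100*count/total rounded half away from zero."""
    if total == 0:
        return float("nan")
    return round_half_up(100.0 * count / total, decimals)


def _age_bin(age_years) -> str:
    # [18, 65) / [65, 85] / (85, inf); under-18 and unknown fall to missing
    if age_years is None or pd.isna(age_years):
        return "missing"
    if 18 <= age_years < 65:
        return "18-65"
    if 65 <= age_years <= 85:
        return "65-85"
    if age_years > 85:
        return ">85"
    return "missing"


def demographics(cases: pd.DataFrame) -> pd.DataFrame:
    """Characteristics table: section / category / count / proportion (%).

    Year rows carry 2-decimal proportions, everything else 1 decimal.
    Empty input yields an empty table with a warning.
    """
    if cases.empty:
        logger.warning("demographics over an empty case set")
        return pd.DataFrame(columns=["section", "category", "count", "proportion"])
    total = len(cases)
    rows: list[dict] = []

    sex = cases["sex"].map(lambda s: {"M": "male", "F": "female"}.get(s, "missing")
                           if s is not None and not pd.isna(s) else "missing")
    for cat in ("male", "female", "missing"):
        rows.append({"section": "sex", "category": cat, "count": int((sex == cat).sum())})

    bins = cases["age_years"].map(_age_bin)
    for cat in AGE_BIN_LABELS:
        rows.append({"section": "age", "category": cat, "count": int((bins == cat).sum())})

    country = cases["country"].fillna("missing")
    for cat, cnt in country.value_counts().sort_index().items():
        rows.append({"section": "country", "category": str(cat), "count": int(cnt)})

    rep = cases["reporter_category"].fillna("missing")
    for cat in REPORTER_ORDER:
        rows.append({"section": "reporter", "category": cat, "count": int((rep == cat).sum())})

    years = cases["report_year"].dropna().astype(int)
    for year, cnt in years.value_counts().sort_index().items():
        rows.append({"section": "year", "category": str(year), "count": int(cnt)})

    out = pd.DataFrame(rows)
    out["proportion"] = [
        proportion(r["count"], total, 2 if r["section"] == "year" else 1)
        for r in rows
    ]
    return out


def concordance_counts(results: pd.DataFrame) -> tuple[dict[int, int], dict[str, set[str]]]:
    """Tally screened events by concordance level (0-4) and per-algorithm sets.

    The per-algorithm positive sets are what a Venn diagram of the four
    algorithms would render.
    """
    tally = {k: 0 for k in (4, 3, 2, 1, 0)}
    sets: dict[str, set[str]] = {"ROR": set(), "PRR": set(), "MGPS": set(), "BCPNN": set()}
    for row in results.itertuples():
        tally[int(row.n_positive)] += 1
        for algo, flag_col in (("ROR", "flag_ror"), ("PRR", "flag_prr"),
                               ("MGPS", "flag_mgps"), ("BCPNN", "flag_bcpnn")):
            if getattr(row, flag_col):
                sets[algo].add(row.event)
    return tally, sets


def soc_proportions(soc_results: pd.DataFrame) -> pd.Series:
    """Each SOC's share of the target drug's pairs, descending."""
    total = soc_results["a"].sum()
    shares = (soc_results.set_index("event")["a"] / total) if total else \
        soc_results.set_index("event")["a"]
    return shares.sort_values(ascending=False)


@dataclass
class ReportBundle:
    """Everything one pipeline run produces."""

    counts: dict[str, int]
    demographics: pd.DataFrame
    pt_screen: pd.DataFrame
    soc_screen: pd.DataFrame
    concordance_pt: dict[int, int]
    concordance_soc: dict[int, int]
    soc_shares: pd.Series
    tto_summary: object | None
    weibull_fit: object | None
    tto_curve: pd.DataFrame | None
    tto_histogram: pd.DataFrame | None
    manifest: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.demographics.to_csv(out / "demographics.tsv", sep="\t", index=False)
        self.pt_screen.to_csv(out / "pt_screen.tsv", sep="\t", index=False)
        self.soc_screen.to_csv(out / "soc_screen.tsv", sep="\t", index=False)
        self.soc_shares.rename("share").to_csv(out / "soc_shares.tsv", sep="\t")
        if self.tto_curve is not None:
            self.tto_curve.to_csv(out / "tto_ecdf.tsv", sep="\t", index=False)
        if self.tto_histogram is not None:
            self.tto_histogram.to_csv(out / "tto_histogram.tsv", sep="\t", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=1,
                                                      sort_keys=True, default=str))


def run_pipeline(config) -> ReportBundle:
    """Ingest -> dedup -> filter -> screen (PT, SOC) -> TTO -> report.

    ``config`` is a :class:`pvsignal.config.PipelineConfig`; every
    threshold and mode that affects the results lands in the manifest.
    """
    from .config import PipelineConfig, load_tables

    if not isinstance(config, PipelineConfig):
        raise TypeError("run_pipeline expects a PipelineConfig")
    config.check()

    from .faers_io import assemble_dataset

    demo, drug, reac, ther = load_tables(config)
    dataset = assemble_dataset(demo, drug, reac, ther, config.analysis)

    pt_map = config.resolve_pt_soc_map()
    thresholds = config.thresholds or SignalThresholds()
    pt_screen = run_screen(dataset, pt_map, "pt", thresholds,
                           config.ic_mode, config.yates, config.top)
    soc_screen = run_screen(dataset, pt_map, "soc", thresholds,
                            config.ic_mode, config.yates)
    tally_pt, _ = concordance_counts(pt_screen)
    tally_soc, _ = concordance_counts(soc_screen)
    shares = soc_proportions(soc_screen)

    sample = collect_ttos(dataset, config.zero_day_value)
    if sample.n >= 1:
        tto_summary = summarize(sample)
        curve = cumulative_incidence(sample)
        hist = monthly_histogram(sample)
    else:
        tto_summary = curve = hist = None
    fit = fit_weibull(sample) if sample.n >= 3 else None

    manifest = {
        "pvsignal_version": __version__,
        "counts": dataset.counts,
        "thresholds": dataclasses.asdict(thresholds),
        "ic_mode": config.ic_mode,
        "chi2_yates": config.yates,
        "counting_unit": "report-reaction pair",
        "age_bins": "[18,65) / [65,85] / (85,inf); under-18 and unknown -> missing",
        "zero_day_tto": config.zero_day_value,
        "synonyms": sorted(config.analysis.synonyms),
        "roles": sorted(config.analysis.roles),
        "window": [config.analysis.window_start, config.analysis.window_end],
        "seed": getattr(config.synthetic, "seed", None) if config.synthetic else None,
        "tto_excluded": {"negative": sample.excluded_negative,
                         "missing": sample.excluded_missing},
    }
    if fit is not None:
        manifest["weibull"] = {
            "alpha": fit.alpha, "alpha_ci": fit.alpha_ci,
            "beta": fit.beta, "beta_ci": fit.beta_ci,
            "n": fit.n, "failure_type": fit.failure_type,
        }

    bundle = ReportBundle(
        counts=dataset.counts,
        demographics=demographics(dataset.cases),
        pt_screen=pt_screen,
        soc_screen=soc_screen,
        concordance_pt=tally_pt,
        concordance_soc=tally_soc,
        soc_shares=shares,
        tto_summary=tto_summary,
        weibull_fit=fit,
        tto_curve=curve,
        tto_histogram=hist,
        manifest=manifest,
    )
    if config.out_dir:
        bundle.write(config.out_dir)
    return bundle
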