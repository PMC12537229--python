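"""Synthetic FAERS-shaped database with known ground truth.

Emits DEMO/DRUG/REAC/THER tables in the same '$'-delimited ASCII dialect
:mod:`pvsignal.faers_io` reads, with everything the downstream pipeline
must detect planted by construction:

* one target drug reported as primary suspect on ``n_target_reports``
  cases against ``n_background_reports`` background cases,
* per-PT reporting-rate multipliers on the target (the disproportionality
  signals; multiplier 1 everywhere is the null database),
* a fixed share of cases emitted as two report versions with increasing
  ``primaryid`` and ``fda_dt`` (exercising the deduplication rule; a tie
  mode emits equal dates so only the primaryid tie-break decides),
* demographic mixes and missingness at configurable rates,
* Weibull-distributed onset times wired into ``event_dt``/``start_dt``
  for a configurable subset of target cases.

Reactions are drawn per report (1 + truncated-geometric count, then PTs
with replacement from the catalog probabilities, normalised within a
report); the analysis counts distinct (report, PT) pairs, and
:func:`expected_contingency` gives the exact expected cells under that
scheme: the chance a report contributes a pair for PT j is
``E_k[1 - (1 - p_j)^k]``.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EventSpec",
    "SyntheticConfig",
    "GroundTruth",
    "ExpectedCells",
    "SyntheticTables",
    "default_catalog",
    "generate",
    "expected_contingency",
    "sample_ttos",
]


@dataclass(frozen=True)
class EventSpec:
    """One catalog entry: a MedDRA PT, its SOC and a baseline weight."""

    pt: str
    soc: str
    baseline: float


#: Baseline reporting weights for the default catalog (normalised in use).
_DEFAULT_BASELINES: dict[str, float] = {
    "HEADACHE": 0.080, "NAUSEA": 0.070, "FATIGUE": 0.065, "DIZZINESS": 0.055,
    "RASH": 0.050, "PAIN": 0.050, "DYSPNOEA": 0.045, "VOMITING": 0.040,
    "PRURITUS": 0.035, "ANXIETY": 0.033, "INSOMNIA": 0.032, "URTICARIA": 0.027,
    "ERYTHEMA": 0.025, "FEELING ABNORMAL": 0.025, "DRUG HYPERSENSITIVITY": 0.023,
    "HYPERSENSITIVITY": 0.022, "MIGRAINE": 0.020, "SINUSITIS": 0.018,
    "NASOPHARYNGITIS": 0.018, "DRY MOUTH": 0.015, "COUGH": 0.040,
    "VERTIGO": 0.012, "TINNITUS": 0.012, "VISION BLURRED": 0.015,
    "EYE PAIN": 0.008, "EYE IRRITATION": 0.007, "OCULAR HYPERAEMIA": 0.006,
    "EYE PRURITUS": 0.005, "PHOTOPHOBIA": 0.004, "EYE SWELLING": 0.004,
    "LACRIMATION INCREASED": 0.004, "SNEEZING": 0.006, "THROAT IRRITATION": 0.006,
    "NASAL DISCOMFORT": 0.002, "RHINORRHOEA": 0.009, "EPISTAXIS": 0.007,
    "OROPHARYNGEAL PAIN": 0.012, "NASAL CONGESTION": 0.009,
    "NASAL DRYNESS": 0.002, "RHINALGIA": 0.001, "ABNORMAL DREAMS": 0.002,
    "PRODUCT AFTER TASTE": 0.001,
}

#: Target-drug reporting-rate multipliers emulating an intranasal profile.
DEFAULT_SIGNAL_MULTIPLIERS: dict[str, float] = {
    "SNEEZING": 150.0, "NASAL DISCOMFORT": 200.0, "THROAT IRRITATION": 40.0,
    "RHINORRHOEA": 30.0, "EPISTAXIS": 27.0, "COUGH": 5.0, "RHINALGIA": 90.0,
    "NASAL CONGESTION": 6.0, "NASAL DRYNESS": 40.0, "OROPHARYNGEAL PAIN": 7.5,
    "EYE IRRITATION": 16.0, "LACRIMATION INCREASED": 21.0, "EYE PAIN": 10.0,
    "OCULAR HYPERAEMIA": 10.5, "VISION BLURRED": 3.7, "EYE PRURITUS": 6.2,
    "PHOTOPHOBIA": 9.2, "EYE SWELLING": 5.2, "ABNORMAL DREAMS": 13.0,
    "PRODUCT AFTER TASTE": 60.0, "HEADACHE": 2.5, "INSOMNIA": 2.2,
    "HYPERSENSITIVITY": 3.0, "VERTIGO": 3.0, "DRY MOUTH": 2.3, "SINUSITIS": 2.0,
}


def packaged_pt_soc_map() -> dict[str, str]:
    """The PT->SOC map shipped with the package (toy 42-term MedDRA stand-in)."""
    text = resources.files("pvsignal.data").joinpath("pt_soc_map.tsv").read_text()
    mapping = {}
    for line in text.strip().splitlines()[1:]:
        pt, soc = line.split("\t")
        mapping[pt] = soc
    return mapping


def default_catalog() -> list[EventSpec]:
    soc_map = packaged_pt_soc_map()
    return [EventSpec(pt, soc_map[pt], w) for pt, w in _DEFAULT_BASELINES.items()]


@dataclass
class SyntheticConfig:
    """Full parameterisation of the simulated reporting database.

    Demographic and onset-time defaults emulate a post-marketing profile of
    an intranasal ophthalmic agent: predominantly female (0.740) consumer
    (0.851) reports, 71.2% missing age, and onset times Weibull(shape 0.60,
    scale 16.73 d) observable on a small fraction (125/2178) of target
    cases.
    """

    seed: int = 0
    n_background_reports: int = 20000
    n_target_reports: int = 2178
    catalog: list[EventSpec] = field(default_factory=default_catalog)
    signal_multipliers: dict[str, float] = field(default_factory=dict)
    reactions_per_report: dict = field(
        default_factory=lambda: {"kind": "geometric", "p": 1.0 / 2.4, "max": 10}
    )
    duplicate_fraction: float = 0.05
    tie_mode: bool = False
    female_fraction: float = 0.740
    male_fraction: float = 0.118
    age_missing_fraction: float = 0.712
    reporter_mix: dict[str, float] = field(
        default_factory=lambda: {
            "consumer": 0.851, "physician": 0.086,
            "health_professional": 0.060, "pharmacist": 0.002,
        }
    )
    tto_shape: float = 0.60
    tto_scale: float = 16.73
    tto_usable_fraction: float = 125.0 / 2178.0
    negative_tto_fraction: float = 0.01
    window_start: str = "20211001"
    window_end: str = "20240630"
    target_drugname: str = "TYRVAYA"
    country: str = "US"

    def validate(self) -> None:
        bad: list[str] = []
        for name in ("duplicate_fraction", "female_fraction", "male_fraction",
                     "age_missing_fraction", "tto_usable_fraction",
                     "negative_tto_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                bad.append(name)
        if self.female_fraction + self.male_fraction > 1.0 + 1e-12:
            bad.append("female_fraction+male_fraction")
        if sum(self.reporter_mix.values()) > 1.0 + 1e-12:
            bad.append("reporter_mix")
        if self.tto_shape <= 0:
            bad.append("tto_shape")
        if self.tto_scale <= 0:
            bad.append("tto_scale")
        if self.n_background_reports < 0:
            bad.append("n_background_reports")
        if self.n_target_reports < 0:
            bad.append("n_target_reports")
        if not self.catalog:
            bad.append("catalog")
        if any(e.baseline <= 0 for e in self.catalog):
            bad.append("catalog.baseline")
        if any(m <= 0 for m in self.signal_multipliers.values()):
            bad.append("signal_multipliers")
        kind = self.reactions_per_report.get("kind")
        if kind not in {"fixed", "geometric"}:
            bad.append("reactions_per_report.kind")
        elif kind == "geometric" and not (0 < self.reactions_per_report.get("p", 0) <= 1):
            bad.append("reactions_per_report.p")
        elif kind == "fixed" and self.reactions_per_report.get("k", 0) < 1:
            bad.append("reactions_per_report.k")
        if bad:
            raise ValueError(f"invalid synthetic config fields: {', '.join(sorted(bad))}")

    # -- probability helpers -------------------------------------------------

    def pt_names(self) -> list[str]:
        return [e.pt for e in self.catalog]

    def background_probs(self) -> np.ndarray:
        w = np.array([e.baseline for e in self.catalog], dtype=float)
        return w / w.sum()

    def target_probs(self) -> np.ndarray:
        w = np.array(
            [e.baseline * self.signal_multipliers.get(e.pt, 1.0) for e in self.catalog],
            dtype=float,
        )
        return w / w.sum()

    def reaction_count_pmf(self) -> np.ndarray:
        """pmf over k = 1..max reactions per report."""
        spec = self.reactions_per_report
        if spec["kind"] == "fixed":
            k = int(spec["k"])
            pmf = np.zeros(k)
            pmf[-1] = 1.0
            return pmf
        p, kmax = float(spec["p"]), int(spec.get("max", 10))
        # k = 1 + min(G, kmax-1), G ~ Geometric(p) on {0, 1, ...}
        pmf = np.array([(1 - p) ** j * p for j in range(kmax - 1)] + [(1 - p) ** (kmax - 1)])
        return pmf


@dataclass(frozen=True)
class ExpectedCells:
    """Analytic expected 2x2 cells for one PT under a config."""

    a: float
    b: float
    c: float
    d: float

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def odds_ratio(self) -> float:
        return (self.a * self.d) / (self.b * self.c)


@dataclass
class GroundTruth:
    """What the generator planted; the oracle for end-to-end tests."""

    true_unique_case_count: int
    n_target_cases: int
    n_tto_eligible: int
    tto_shape: float
    tto_scale: float
    expected_cells: dict[str, tuple[float, float, float, float]]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


@dataclass
class SyntheticTables:
    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    ground_truth: GroundTruth

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the four ASCII tables plus a ground-truth JSON sidecar."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("demo", "drug", "reac", "ther"):
            path = out / f"{name.upper()}.txt"
            getattr(self, name).to_csv(path, sep="$", index=False, na_rep="")
            paths[name] = path
        gt_path = out / "ground_truth.json"
        gt_path.write_text(self.ground_truth.to_json())
        paths["ground_truth"] = gt_path
        return paths


def _pair_probability(p: np.ndarray, k_pmf: np.ndarray) -> np.ndarray:
    """P(report contributes a distinct pair for each PT) = E_k[1-(1-p)^k]."""
    ks = np.arange(1, k_pmf.size + 1)
    return np.einsum("k,kj->j", k_pmf, 1.0 - (1.0 - p[None, :]) ** ks[:, None])


def expected_contingency(config: SyntheticConfig, pt: str) -> ExpectedCells:
    """Closed-form expected (a, b, c, d) at the report-reaction-pair level."""
    names = config.pt_names()
    if pt not in names:
        raise KeyError(f"PT {pt!r} not in catalog")
    j = names.index(pt)
    k_pmf = config.reaction_count_pmf()
    q_t = _pair_probability(config.target_probs(), k_pmf)
    q_b = _pair_probability(config.background_probs(), k_pmf)
    n_t, n_b = config.n_target_reports, config.n_background_reports
    a = n_t * q_t[j]
    target_total = n_t * q_t.sum()
    c = n_b * q_b[j]
    grand_total = target_total + n_b * q_b.sum()
    return ExpectedCells(a=a, b=target_total - a, c=c, d=grand_total - target_total - c)


def sample_ttos(config: SyntheticConfig, n: int, seed: int | None = None) -> np.ndarray:
    """n i.i.d. Weibull(shape, scale) onset durations in days (unrounded)."""
    if config.tto_shape <= 0 or config.tto_scale <= 0:
        raise ValueError("tto_shape and tto_scale must be positive")
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    return config.tto_scale * rng.weibull(config.tto_shape, size=n)


def _date_range(config: SyntheticConfig) -> tuple[dt.date, int]:
    start = dt.datetime.strptime(config.window_start, "%Y%m%d").date()
    end = dt.datetime.strptime(config.window_end, "%Y%m%d").date()
    # keep a 30-day margin so duplicate versions stay inside the window
    span = (end - start).days - 30
    if span < 1:
        raise ValueError("date window too short for duplicate emission margin")
    return start, span


def _ymd(d: dt.date) -> str:
    return d.strftime("%Y%m%d")


def generate(config: SyntheticConfig) -> SyntheticTables:
    """Generate the four tables; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_t, n_b = config.n_target_reports, config.n_background_reports
    n = n_t + n_b
    start, span = _date_range(config)

    caseids = 1000000 + np.arange(n)
    primaryids = caseids * 100 + 1
    is_target = np.zeros(n, dtype=bool)
    is_target[:n_t] = True
    fda_offsets = rng.integers(0, span + 1, size=n)
    fda_dates = np.array([start + dt.timedelta(days=int(o)) for o in fda_offsets])

    # demographics
    p_miss_sex = max(0.0, 1.0 - config.female_fraction - config.male_fraction)
    sex = rng.choice(["F", "M", ""], size=n,
                     p=[config.female_fraction, config.male_fraction, p_miss_sex])
    age_missing = rng.random(n) < config.age_missing_fraction
    bin_probs = np.array([227.0, 368.0, 32.0])
    bin_probs /= bin_probs.sum()
    age_bin = rng.choice(3, size=n, p=bin_probs)
    lo = np.array([18, 65, 86])[age_bin]
    hi = np.array([64, 85, 95])[age_bin]
    ages = rng.integers(lo, hi + 1)
    mix = config.reporter_mix
    occp_codes = ["CN", "MD", "HP", "PH", ""]
    occp_probs = [mix.get("consumer", 0.0), mix.get("physician", 0.0),
                  mix.get("health_professional", 0.0), mix.get("pharmacist", 0.0)]
    occp_probs.append(max(0.0, 1.0 - sum(occp_probs)))
    occp = rng.choice(occp_codes, size=n, p=occp_probs)

    # reactions: counts then PT draws (with replacement; counting dedupes)
    k_pmf = config.reaction_count_pmf()
    ks = rng.choice(np.arange(1, k_pmf.size + 1), size=n, p=k_pmf)
    pt_names = np.array(config.pt_names())
    draws_t = rng.choice(len(pt_names), size=int(ks[:n_t].sum()), p=config.target_probs()) \
        if n_t else np.empty(0, dtype=int)
    draws_b = rng.choice(len(pt_names), size=int(ks[n_t:].sum()), p=config.background_probs()) \
        if n_b else np.empty(0, dtype=int)
    reac_pid: list[int] = []
    reac_pt: list[str] = []
    offs_t = np.concatenate([[0], np.cumsum(ks[:n_t])]).astype(int)
    offs_b = np.concatenate([[0], np.cumsum(ks[n_t:])]).astype(int)
    for i in range(n):
        if i < n_t:
            idx = draws_t[offs_t[i]:offs_t[i + 1]]
        else:
            j = i - n_t
            idx = draws_b[offs_b[j]:offs_b[j + 1]]
        reac_pid.extend([primaryids[i]] * len(idx))
        reac_pt.extend(pt_names[idx])

    # onset times: a fixed-count random subset of target cases gets usable dates
    event_dt = np.array([""] * n, dtype=object)
    ther_pid: list[int] = []
    ther_start: list[str] = []
    n_elig = int(round(config.tto_usable_fraction * n_t))
    elig = rng.choice(n_t, size=n_elig, replace=False) if n_t else np.empty(0, dtype=int)
    raw_ttos = config.tto_scale * rng.weibull(config.tto_shape, size=n_elig)
    tto_days = np.maximum(np.round(raw_ttos), 1.0).astype(int)
    event_lag = rng.integers(0, 31, size=n_elig)
    for j, i in enumerate(elig):
        event = fda_dates[i] - dt.timedelta(days=int(event_lag[j]))
        event_dt[i] = _ymd(event)
        ther_pid.append(primaryids[i])
        ther_start.append(_ymd(event - dt.timedelta(days=int(tto_days[j]))))
    remaining_t = np.setdiff1d(np.arange(n_t), elig)
    n_neg = int(round(config.negative_tto_fraction * n_t))
    neg = rng.choice(remaining_t, size=min(n_neg, remaining_t.size), replace=False)
    neg_gap = rng.integers(1, 16, size=neg.size)
    for j, i in enumerate(neg):
        start_d = fda_dates[i] - dt.timedelta(days=10)
        event_dt[i] = _ymd(start_d - dt.timedelta(days=int(neg_gap[j])))
        ther_pid.append(primaryids[i])
        ther_start.append(_ymd(start_d))
    rest_t = np.setdiff1d(remaining_t, neg)
    has_start = rest_t[rng.random(rest_t.size) < 0.5]
    start_lag_t = rng.integers(0, 91, size=has_start.size)
    for j, i in enumerate(has_start):
        ther_pid.append(primaryids[i])
        ther_start.append(_ymd(fda_dates[i] - dt.timedelta(days=int(start_lag_t[j]))))
    bg_idx = np.arange(n_t, n)
    bg_with_start = bg_idx[rng.random(bg_idx.size) < 0.3]
    start_lag_b = rng.integers(0, 91, size=bg_with_start.size)
    for j, i in enumerate(bg_with_start):
        ther_pid.append(primaryids[i])
        ther_start.append(_ymd(fda_dates[i] - dt.timedelta(days=int(start_lag_b[j]))))

    bg_drugs = np.array([f"BACKGROUND DRUG {i:02d}" for i in range(40)])
    drugnames = np.where(is_target, config.target_drugname,
                         bg_drugs[caseids % 40])

    demo = pd.DataFrame({
        "primaryid": primaryids.astype(str),
        "caseid": caseids.astype(str),
        "fda_dt": [_ymd(d) for d in fda_dates],
        "event_dt": [str(e) for e in event_dt],
        "age": np.where(age_missing, "", ages.astype(str)),
        "age_cod": np.where(age_missing, "", "YR"),
        "sex": sex,
        "occp_cod": occp,
        "occr_country": config.country,
    })
    drug = pd.DataFrame({
        "primaryid": primaryids.astype(str),
        "drugname": drugnames,
        "role_cod": "PS",
    })
    reac = pd.DataFrame({"primaryid": [str(p) for p in reac_pid],
                         "pt": reac_pt})
    ther = pd.DataFrame({"primaryid": [str(p) for p in ther_pid],
                         "start_dt": ther_start})

    # duplicate versions: strictly later fda_dt and higher primaryid (or an
    # equal-date tie in tie_mode, leaving the primaryid tie-break to decide)
    n_dup = int(round(config.duplicate_fraction * n))
    if n_dup:
        dup_idx = np.sort(rng.choice(n, size=n_dup, replace=False))
        dup_lag = np.zeros(n_dup, dtype=int) if config.tie_mode \
            else rng.integers(1, 31, size=n_dup)
        d2 = demo.iloc[dup_idx].copy()
        d2["primaryid"] = (caseids[dup_idx] * 100 + 2).astype(str)
        d2["fda_dt"] = [_ymd(fda_dates[i] + dt.timedelta(days=int(l)))
                        for i, l in zip(dup_idx, dup_lag)]
        old_new = dict(zip(primaryids[dup_idx].astype(str),
                           (caseids[dup_idx] * 100 + 2).astype(str)))
        demo = pd.concat([demo, d2], ignore_index=True)
        for name, df in (("drug", drug), ("reac", reac), ("ther", ther)):
            extra = df[df["primaryid"].isin(old_new)].copy()
            extra["primaryid"] = extra["primaryid"].map(old_new)
            if name == "drug":
                drug = pd.concat([drug, extra], ignore_index=True)
            elif name == "reac":
                reac = pd.concat([reac, extra], ignore_index=True)
            else:
                ther = pd.concat([ther, extra], ignore_index=True)

    expected = {
        e.pt: dataclasses.astuple(expected_contingency(config, e.pt))
        for e in config.catalog
    }
    truth = GroundTruth(
        true_unique_case_count=n,
        n_target_cases=n_t,
        n_tto_eligible=n_elig,
        tto_shape=config.tto_shape,
        tto_scale=config.tto_scale,
        expected_cells=expected,
    )
    return SyntheticTables(demo=demo, drug=drug, reac=reac, ther=ther,
                           ground_truth=truth)
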