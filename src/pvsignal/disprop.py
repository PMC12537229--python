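"""Disproportionality statistics and multi-algorithm signal classification.

Four algorithms are computed on each 2x2 table (cells a, b, c, d, N):

* **ROR** — reporting odds ratio, ``ad/(bc)``, with a lognormal 95% CI
  from ``se = sqrt(1/a + 1/b + 1/c + 1/d)``.
* **PRR** — proportional reporting ratio, ``[a/(a+b)] / [c/(c+d)]``,
  accompanied by the Pearson chi-squared statistic of the table
  (uncorrected by default; Yates continuity correction by flag).
* **MGPS / EBGM** — the empirical Bayes geometric mean in its simplified
  relative-reporting-ratio form ``a*N / [(a+b)(a+c)]``, with EBGM05 the
  lower one-sided 95% lognormal bound (1.64 sigma).
* **BCPNN / IC** — the information component ``log2(a*N / [(a+b)(a+c)])``
  (identically ``log2(EBGM)`` in this form); IC025 either as a constant
  1.66-bit offset below IC (``fixed_offset``, the default) or from the
  closed-form BCPNN posterior standard deviation (``bate``).

An event is a *signal* for an algorithm when it passes that algorithm's
conventional positivity criterion (see :class:`SignalThresholds`); events
are then graded by how many of the four algorithms concur (0-4).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import pandas as pd

from .contingency import ContingencyTable, count_pairs, make_table

logger = logging.getLogger(__name__)

__all__ = [
    "SignalThresholds",
    "DisproportionalityResult",
    "compute_ror",
    "compute_prr",
    "compute_ebgm",
    "compute_ic",
    "compute_all",
    "evaluate_signal",
    "run_screen",
    "format_paper_layout",
]

ALGORITHMS = ("ROR", "PRR", "MGPS", "BCPNN")
NAN = float("nan")


def _se_log(t: ContingencyTable) -> float:
    return math.sqrt(1.0 / t.a + 1.0 / t.b + 1.0 / t.c + 1.0 / t.d)


def compute_ror(t: ContingencyTable, z: float = 1.96) -> tuple[float, float, float]:
    """Reporting odds ratio with lognormal CI; (ror, lo, hi).

    a = 0 yields (0, nan, nan); b*c = 0 yields (nan, nan, nan) — both are
    flagged as undefined rather than raised.
    """
    if t.a == 0:
        return 0.0, NAN, NAN
    if t.b == 0 or t.c == 0:
        return NAN, NAN, NAN
    ror = (t.a * t.d) / (t.b * t.c)
    if t.d == 0:
        return ror, NAN, NAN
    se = _se_log(t)
    return ror, ror * math.exp(-z * se), ror * math.exp(z * se)


def compute_prr(t: ContingencyTable, yates: bool = False) -> tuple[float, float]:
    """Proportional reporting ratio and Pearson chi-squared; (prr, chi2)."""
    if t.c == 0 or t.a + t.b == 0 or t.c + t.d == 0:
        return NAN, NAN
    prr = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))
    num = t.a * t.d - t.b * t.c
    if yates:
        num = max(abs(num) - t.n / 2.0, 0.0)
    else:
        num = abs(num)
    denom = (t.a + t.b) * (t.c + t.d) * (t.a + t.c) * (t.b + t.d)
    chi2 = t.n * num * num / denom if denom > 0 else NAN
    return prr, chi2


def compute_ebgm(t: ContingencyTable, z_low: float = 1.64) -> tuple[float, float]:
    """Simplified EBGM (relative reporting ratio) and EBGM05; (ebgm, ebgm05)."""
    if t.target_total == 0 or t.event_total == 0:
        return NAN, NAN
    if t.a == 0:
        return 0.0, NAN
    ebgm = t.a * t.n / (t.target_total * t.event_total)
    if min(t.b, t.c, t.d) == 0:
        return ebgm, NAN
    ebgm05 = ebgm * math.exp(-z_low * _se_log(t))
    return ebgm, ebgm05


def _bate_sd(t: ContingencyTable) -> float:
    # Closed-form BCPNN posterior sd (Bate et al. 1998) with alpha1=beta1=1,
    # alpha=beta=2, gamma11=1 and gamma chosen so the prior IC is 0.
    a, n = t.a, t.n
    cx, cy = t.target_total, t.event_total
    alpha1 = beta1 = gamma11 = 1.0
    alpha = beta = 2.0
    gamma = gamma11 * (n + alpha) * (n + beta) / ((cx + alpha1) * (cy + beta1))
    var = (
        (n - a + gamma - gamma11) / ((a + gamma11) * (1 + n + gamma))
        + (n - cx + alpha - alpha1) / ((cx + alpha1) * (1 + n + alpha))
        + (n - cy + beta - beta1) / ((cy + beta1) * (1 + n + beta))
    ) / (math.log(2.0) ** 2)
    return math.sqrt(var)


def compute_ic(
    t: ContingencyTable,
    mode: str = "fixed_offset",
    offset: float = 1.66,
    z: float = 1.96,
) -> tuple[float, float]:
    """Information component and its lower bound; (ic, ic025).

    ``ic = log2(a*N / [(a+b)(a+c)])``.  ``mode='fixed_offset'`` places
    IC025 a constant ``offset`` bits below IC; ``mode='bate'`` subtracts
    ``z`` posterior standard deviations (closed-form BCPNN posterior).
    """
    if t.a == 0 or t.target_total == 0 or t.event_total == 0:
        return NAN, NAN
    ic = math.log2(t.a * t.n / (t.target_total * t.event_total))
    if mode == "fixed_offset":
        return ic, ic - offset
    if mode == "bate":
        return ic, ic - z * _bate_sd(t)
    raise ValueError(f"unknown IC mode {mode!r}")


@dataclass(frozen=True)
class SignalThresholds:
    """Positivity criteria for the four algorithms.

    Defaults are the conventional cutoffs: at least ``min_a`` reports, ROR
    lower CI bound > 1, PRR >= 2 with chi2 >= 4, EBGM05 > 2, IC025 > 0.
    """

    min_a: int = 3
    ror_lo_gt: float = 1.0
    prr_ge: float = 2.0
    chi2_ge: float = 4.0
    ebgm05_gt: float = 2.0
    ic025_gt: float = 0.0


@dataclass
class DisproportionalityResult:
    """All four statistics with bounds, per-algorithm flags and concordance."""

    event: str
    a: int
    ror: float
    ror_lo: float
    ror_hi: float
    prr: float
    chi2: float
    ebgm: float
    ebgm05: float
    ic: float
    ic025: float
    flags: dict[str, bool] = field(default_factory=dict)

    @property
    def n_positive(self) -> int:
        return sum(self.flags.values())


def evaluate_signal(result: DisproportionalityResult,
                    thresholds: SignalThresholds | None = None) -> DisproportionalityResult:
    """Apply positivity thresholds; returns a copy with flags filled in.

    Every algorithm's flag additionally requires ``a >= min_a``; undefined
    (NaN) statistics never satisfy a criterion.
    """
    th = thresholds or SignalThresholds()
    gate = result.a >= th.min_a
    flags = {
        "ROR": bool(gate and result.ror_lo > th.ror_lo_gt),
        "PRR": bool(gate and result.prr >= th.prr_ge and result.chi2 >= th.chi2_ge),
        "MGPS": bool(gate and result.ebgm05 > th.ebgm05_gt),
        "BCPNN": bool(gate and result.ic025 > th.ic025_gt),
    }
    return replace(result, flags=flags)


def compute_all(
    event: str,
    t: ContingencyTable,
    thresholds: SignalThresholds | None = None,
    ic_mode: str = "fixed_offset",
    yates: bool = False,
) -> DisproportionalityResult:
    """Compute all four statistics on one table and evaluate the flags."""
    ror, lo, hi = compute_ror(t)
    prr, chi2 = compute_prr(t, yates=yates)
    ebgm, ebgm05 = compute_ebgm(t)
    ic, ic025 = compute_ic(t, mode=ic_mode)
    res = DisproportionalityResult(
        event=event, a=t.a, ror=ror, ror_lo=lo, ror_hi=hi,
        prr=prr, chi2=chi2, ebgm=ebgm, ebgm05=ebgm05, ic=ic, ic025=ic025,
    )
    return evaluate_signal(res, thresholds)


def run_screen(
    dataset,
    pt_soc_map: dict[str, str] | None = None,
    level: str = "pt",
    thresholds: SignalThresholds | None = None,
    ic_mode: str = "fixed_offset",
    yates: bool = False,
    top: int | None = None,
) -> pd.DataFrame:
    """Screen every event at the chosen level; one result row per event.

    Rows are sorted by pair count ``a`` descending (ties: event name
    ascending).  ``top`` truncates to the most frequent events.
    """
    counts = count_pairs(dataset.reactions, dataset.target_ids, level, pt_soc_map)
    if counts.empty:
        logger.warning("empty dataset: screen returns no rows")
        return _results_frame([])
    target_total = int(counts["n_target"].sum())
    grand_total = int(counts["n_total"].sum())
    results = []
    for event, row in counts.iterrows():
        t = make_table(int(row["n_target"]), target_total, int(row["n_total"]), grand_total)
        results.append(compute_all(event, t, thresholds, ic_mode, yates))
    frame = _results_frame(results)
    frame = frame.sort_values(["a", "event"], ascending=[False, True],
                              kind="mergesort").reset_index(drop=True)
    if top is not None:
        frame = frame.head(top)
    return frame


def _results_frame(results: list[DisproportionalityResult]) -> pd.DataFrame:
    cols = ["event", "a", "ror", "ror_lo", "ror_hi", "prr", "chi2",
            "ebgm", "ebgm05", "ic", "ic025",
            "flag_ror", "flag_prr", "flag_mgps", "flag_bcpnn", "n_positive"]
    rows = []
    for r in results:
        rows.append({
            "event": r.event, "a": r.a, "ror": r.ror, "ror_lo": r.ror_lo,
            "ror_hi": r.ror_hi, "prr": r.prr, "chi2": r.chi2, "ebgm": r.ebgm,
            "ebgm05": r.ebgm05, "ic": r.ic, "ic025": r.ic025,
            "flag_ror": r.flags.get("ROR", False),
            "flag_prr": r.flags.get("PRR", False),
            "flag_mgps": r.flags.get("MGPS", False),
            "flag_bcpnn": r.flags.get("BCPNN", False),
            "n_positive": r.n_positive,
        })
    return pd.DataFrame(rows, columns=cols)


def format_paper_layout(frame: pd.DataFrame) -> pd.DataFrame:
    """Render a screen as `ROR (95% CI)` / `PRR (chi2)` / ... strings at 2 d.p."""
    def f(x):
        return "NA" if pd.isna(x) else f"{x:.2f}"

    out = pd.DataFrame({
        "event": frame["event"],
        "case numbers": frame["a"],
        "ROR (95% CI)": [f"{f(r.ror)} ({f(r.ror_lo)}-{f(r.ror_hi)})"
                         for r in frame.itertuples()],
        "PRR (chi2)": [f"{f(r.prr)} ({f(r.chi2)})" for r in frame.itertuples()],
        "EBGM (EBGM05)": [f"{f(r.ebgm)} ({f(r.ebgm05)})" for r in frame.itertuples()],
        "IC (IC025)": [f"{f(r.ic)} ({f(r.ic025)})" for r in frame.itertuples()],
        "n_positive": frame["n_positive"],
    })
    return out
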