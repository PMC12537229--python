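"""The synthetic report-database generator and its analytic oracles."""

from __future__ import annotations

import hashlib

import numpy as np
import pytest
from scipy.stats import weibull_min

from pvsignal.faers_io import AnalysisConfig, assemble_dataset
from pvsignal.synthetic import (
    EventSpec,
    SyntheticConfig,
    expected_contingency,
    generate,
    sample_ttos,
)


def _assemble(tables, config):
    return assemble_dataset(
        tables.demo, tables.drug, tables.reac, tables.ther,
        AnalysisConfig(window_start=config.window_start, window_end=config.window_end),
    )


def test_minimal_config_row_counts():
    cfg = SyntheticConfig(seed=0, n_background_reports=0, n_target_reports=5,
                          catalog=[EventSpec("PT1", "S1", 1.0)], duplicate_fraction=0.0)
    t = generate(cfg)
    assert len(t.demo) == 5
    assert (t.drug["role_cod"] == "PS").sum() == 5
    assert len(t.reac) >= 5


def test_generation_is_byte_deterministic(tmp_path):
    cfg = SyntheticConfig(seed=9, n_background_reports=300, n_target_reports=100)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    generate(cfg).write(d1)
    generate(cfg).write(d2)
    for f in sorted(p.name for p in d1.iterdir()):
        assert hashlib.md5((d1 / f).read_bytes()).digest() == \
            hashlib.md5((d2 / f).read_bytes()).digest()


def test_duplicate_emission_exact_counts():
    cfg = SyntheticConfig(seed=1, n_background_reports=50, n_target_reports=50,
                          duplicate_fraction=0.5)
    t = generate(cfg)
    assert len(t.demo) == 150
    assert t.demo["caseid"].nunique() == 100


def test_duplicates_resolved_by_dedup_pipeline():
    cfg = SyntheticConfig(seed=2, n_background_reports=400, n_target_reports=100,
                          duplicate_fraction=0.3)
    t = generate(cfg)
    ds = _assemble(t, cfg)
    assert ds.counts["dedup_cases"] == t.ground_truth.true_unique_case_count
    assert ds.counts["ps_cases"] == t.ground_truth.n_target_cases


def test_tie_mode_exercises_primaryid_tiebreak():
    cfg = SyntheticConfig(seed=3, n_background_reports=0, n_target_reports=40,
                          duplicate_fraction=0.5, tie_mode=True)
    t = generate(cfg)
    from pvsignal.faers_io import deduplicate

    kept = deduplicate(t.demo)
    dup_cases = t.demo["caseid"].value_counts()
    dup_cases = set(dup_cases[dup_cases > 1].index)
    # for every duplicated case the later *version* (primaryid suffix 2) wins
    suffix = kept[kept["caseid"].isin(dup_cases)]["primaryid"].str[-1]
    assert (suffix == "2").all()


def test_invalid_config_names_offending_fields():
    cfg = SyntheticConfig(duplicate_fraction=1.5, tto_shape=-1.0)
    with pytest.raises(ValueError, match="duplicate_fraction"):
        cfg.validate()
    with pytest.raises(ValueError, match="tto_shape"):
        cfg.validate()


# ------------------------------------------------------- analytic oracles

def test_expected_contingency_degenerate_single_pt():
    cfg = SyntheticConfig(n_background_reports=100, n_target_reports=50,
                          catalog=[EventSpec("PT1", "S1", 1.0)],
                          reactions_per_report={"kind": "fixed", "k": 1})
    e = expected_contingency(cfg, "PT1")
    assert e.a == pytest.approx(50) and e.c == pytest.approx(100)
    assert e.b == pytest.approx(0) and e.d == pytest.approx(0)


def test_expected_contingency_two_pt_multiplier_three():
    cat = [EventSpec("PT1", "S1", 0.5), EventSpec("PT2", "S1", 0.5)]
    cfg = SyntheticConfig(n_background_reports=100, n_target_reports=100,
                          catalog=cat, signal_multipliers={"PT1": 3.0},
                          reactions_per_report={"kind": "fixed", "k": 1})
    e = expected_contingency(cfg, "PT1")
    assert e.a / (e.a + e.b) == pytest.approx(0.75)
    assert e.c / (e.c + e.d) == pytest.approx(0.5)


def test_expected_contingency_null_gives_unit_odds_ratio():
    cfg = SyntheticConfig(n_background_reports=500, n_target_reports=100)
    for e in cfg.catalog[:5]:
        cells = expected_contingency(cfg, e.pt)
        assert cells.odds_ratio == pytest.approx(1.0)


def test_expected_contingency_unknown_pt():
    with pytest.raises(KeyError):
        expected_contingency(SyntheticConfig(), "NO SUCH TERM")


def test_empirical_pair_counts_track_expectation():
    """Observed pair counts fall near their closed-form expectations."""
    cat = [EventSpec("PT1", "S1", 0.3), EventSpec("PT2", "S1", 0.7)]
    cfg = SyntheticConfig(seed=17, n_background_reports=0, n_target_reports=4000,
                          catalog=cat, duplicate_fraction=0.0,
                          negative_tto_fraction=0.0, tto_usable_fraction=0.0)
    t = generate(cfg)
    counts = t.reac.drop_duplicates(["primaryid", "pt"])["pt"].value_counts()
    for pt in ("PT1", "PT2"):
        expected_a = expected_contingency(cfg, pt).a
        # binomial-ish spread: 4 sigma with sigma <= sqrt(n p)
        assert abs(counts[pt] - expected_a) < 4 * np.sqrt(expected_a)


# ----------------------------------------------------------------- onset

def test_sample_ttos_empty():
    assert sample_ttos(SyntheticConfig(), 0).size == 0


def test_sample_ttos_exponential_special_case():
    cfg = SyntheticConfig(tto_shape=1.0, tto_scale=10.0)
    x = sample_ttos(cfg, 40000, seed=123)
    se = 10.0 / np.sqrt(x.size)  # exponential: sd == mean
    assert abs(x.mean() - 10.0) < 3 * se


def test_sample_ttos_weibull_median():
    cfg = SyntheticConfig(tto_shape=0.60, tto_scale=16.73)
    n = 10000
    x = sample_ttos(cfg, n, seed=7)
    med_true = 16.73 * np.log(2.0) ** (1 / 0.60)
    density = weibull_min.pdf(med_true, 0.60, scale=16.73)
    mc_se = 1.0 / (2.0 * density * np.sqrt(n))
    assert abs(np.median(x) - med_true) < 3 * mc_se


def test_sample_ttos_invalid_params():
    cfg = SyntheticConfig()
    cfg.tto_scale = -1.0
    with pytest.raises(ValueError):
        sample_ttos(cfg, 5)


def test_tto_eligible_subset_has_exact_size():
    cfg = SyntheticConfig(seed=4, n_background_reports=200, n_target_reports=500,
                          duplicate_fraction=0.0)
    t = generate(cfg)
    ds = _assemble(t, cfg)
    from pvsignal.tto import collect_ttos

    sample = collect_ttos(ds)
    assert sample.n == t.ground_truth.n_tto_eligible
    assert sample.excluded_negative == round(cfg.negative_tto_fraction * 500)


def test_planted_ror_ci_covers_analytic_odds_ratio():
    """Across seeds, the planted PT's ROR interval covers the true odds ratio."""
    cat = [EventSpec(f"PT{i}", "S1", 0.1) for i in range(10)]
    covered = 0
    n_seeds = 20
    for seed in range(n_seeds):
        cfg = SyntheticConfig(seed=seed, n_background_reports=4000,
                              n_target_reports=800, catalog=cat,
                              signal_multipliers={"PT0": 10.0},
                              duplicate_fraction=0.0)
        t = generate(cfg)
        ds = _assemble(t, cfg)
        from pvsignal.disprop import run_screen

        frame = run_screen(ds).set_index("event")
        truth = expected_contingency(cfg, "PT0").odds_ratio
        row = frame.loc["PT0"]
        assert row["a"] >= 50
        if row["ror_lo"] <= truth <= row["ror_hi"]:
            covered += 1
    assert covered >= 0.9 * n_seeds
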