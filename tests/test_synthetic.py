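"""Synthetic cohort generator tests: exact ledgers, determinism, and
configured arm effects."""
import numpy as np
import pandas as pd
import pytest

from eduscore.rubrics import INSTRUMENTS, Instrument, ScoreSheet, needs_adjudication
from eduscore.synthetic import (
    CohortConfig,
    TextTarget,
    WordBank,
    default_bank,
    generate_cohort,
    generate_guideline_table,
    generate_text,
    metrics_from_plan,
    sample_cohort_plan,
    simulate_paired_metrics,
    simulate_raters,
)
from eduscore.text_metrics import compute_token_stats, count_syllables


def test_word_bank_consistent_with_syllable_counter():
    bank = default_bank()
    for word, syllables, letters, is_complex in bank.entries:
        assert count_syllables(word) == syllables
        assert sum(c.isalpha() for c in word) == letters
        assert is_complex == (syllables >= 3)


def test_word_bank_requires_all_classes():
    with pytest.raises(ValueError):
        WordBank([("knee", 1, 4, False)])


@pytest.mark.parametrize("seed", range(20))
def test_generated_text_round_trips_exactly(seed):
    rng = np.random.default_rng(seed)
    target = TextTarget(
        n_sentences=int(rng.integers(2, 15)),
        words_per_sentence=int(rng.integers(4, 18)),
        syllables_per_word=float(rng.uniform(1.0, 3.0)),
    )
    text, ledger = generate_text(target, seed=seed)
    assert compute_token_stats(text) == ledger
    assert ledger.n_sentences == target.n_sentences
    assert ledger.n_words == target.n_sentences * target.words_per_sentence
    assert ledger.n_syllables == round(
        target.syllables_per_word * ledger.n_words
    )


def test_generate_text_determinism_and_seed_invariant_ledger():
    target = TextTarget(10, 10, 1.5)
    t1, l1 = generate_text(target, seed=7)
    t1b, _ = generate_text(target, seed=7)
    t2, l2 = generate_text(target, seed=8)
    assert t1 == t1b
    assert t1 != t2          # different word order
    assert l1 == l2          # identical ledger


def test_generate_text_unsatisfiable_mix():
    with pytest.raises(ValueError):
        generate_text(TextTarget(2, 5, 5.6), seed=0)


def test_all_monosyllable_text_hits_smog_floor():
    from eduscore.text_metrics import smog_index
    _, ledger = generate_text(TextTarget(5, 8, 1.0), seed=0)
    assert smog_index(ledger) == pytest.approx(3.1291)


def test_guideline_table_spans_weight_classes():
    table = generate_guideline_table(12, seed=5)
    assert set(table["weight"]) == {1.0, 0.75, 0.5, 0.25}
    assert (table["weighted_score"] > 0).any()
    single = generate_guideline_table(1, seed=0)
    assert len(single) == 1
    again = generate_guideline_table(12, seed=5)
    assert table.to_csv(index=False) == again.to_csv(index=False)


def _truth_sheet(total=60):
    dims = INSTRUMENTS[Instrument.SAFETY].dimensions
    return ScoreSheet("D1", Instrument.SAFETY, "truth",
                      {d: total * mx / 100 for d, mx in dims})


def test_raters_noiseless_equal_truth():
    r1, r2, r3 = simulate_raters(_truth_sheet(60), 0.0, 0.0,
                                 np.random.default_rng(0))
    assert r1.points == r2.points == _truth_sheet(60).points
    assert r3 is None


def test_raters_forced_disagreement_always_flags():
    rng = np.random.default_rng(1)
    for _ in range(100):
        r1, r2, r3 = simulate_raters(_truth_sheet(55), 2.0, 1.0, rng)
        assert needs_adjudication(r1, r2)
        assert r3 is not None


def test_raters_unbiased():
    rng = np.random.default_rng(2)
    truth = _truth_sheet(50)
    totals = [
        sum(simulate_raters(truth, 2.0, 0.0, rng)[0].points.values())
        for _ in range(1000)
    ]
    # Monte-Carlo error of the mean total is ~0.14 points here
    assert np.mean(totals) == pytest.approx(50.0, abs=0.6)


def test_cohort_shape_and_determinism(small_config):
    cohort = generate_cohort(small_config)
    assert len(cohort.documents) == 2 * small_config.n_profiles
    arms = {(d.profile_id, d.arm.value) for d in cohort.documents}
    assert len(arms) == 2 * small_config.n_profiles
    again = generate_cohort(small_config)
    assert [d.text for d in cohort.documents] == [d.text for d in again.documents]
    assert cohort.mentions.equals(again.mentions)
    assert cohort.ratings.equals(again.ratings)
    assert cohort.guidelines.equals(again.guidelines)


def test_cohort_files_round_trip(small_config, tmp_path):
    cohort = generate_cohort(small_config)
    paths = cohort.write(tmp_path / "a")
    paths2 = generate_cohort(small_config).write(tmp_path / "b")
    for name in paths:
        assert paths[name].read_bytes() == paths2[name].read_bytes()


def test_fast_path_equals_full_pipeline(small_config):
    """The plan-level metric table is exactly the table the file-based
    pipeline computes on the rendered cohort."""
    from eduscore.pipeline import run_evaluation
    cohort = generate_cohort(small_config)
    fast = cohort.metrics_table()
    report = run_evaluation(cohort.documents, cohort.guidelines,
                            cohort.mentions, cohort.ratings)
    merged = fast.merge(report.metric_table, on=["profile_id", "arm", "metric"],
                        suffixes=("_fast", "_full"))
    assert len(merged) == len(fast)
    assert np.allclose(merged["value_fast"], merged["value_full"])


def test_configured_arm_effects_have_expected_direction():
    cfg = CohortConfig(n_profiles=60, seed=9)
    table = simulate_paired_metrics(cfg)
    wide = table.pivot_table(index=["profile_id", "metric"], columns="arm",
                             values="value").reset_index()
    by_metric = wide.groupby("metric")[["AI", "CLINICIAN"]].mean()
    assert by_metric.loc["wpm", "AI"] > 5 * by_metric.loc["wpm", "CLINICIAN"]
    for metric in ("flesch_kincaid", "gunning_fog", "smog"):
        assert by_metric.loc[metric, "AI"] < by_metric.loc[metric, "CLINICIAN"]
    for metric in ("accuracy", "personalization", "comprehensiveness", "safety"):
        assert by_metric.loc[metric, "AI"] > by_metric.loc[metric, "CLINICIAN"]


def test_wpm_median_tracks_configured_medians():
    cfg = CohortConfig(n_profiles=120, seed=3)
    table = simulate_paired_metrics(cfg, metrics=("wpm",))
    wide = table.pivot_table(index="profile_id", columns="arm", values="value")
    assert wide["AI"].median() == pytest.approx(cfg.wpm_median_ai, rel=0.08)
    assert wide["CLINICIAN"].median() == pytest.approx(cfg.wpm_median_clin, rel=0.05)


def test_zero_delta_config_removes_arm_effects():
    cfg = CohortConfig(n_profiles=40, seed=4).zero_delta()
    assert cfg.wpm_median_ai == cfg.wpm_median_clin
    assert cfg.accuracy_mean_ai == cfg.accuracy_mean_clin
    table = simulate_paired_metrics(cfg, metrics=("accuracy", "personalization"))
    wide = table.pivot_table(index=["profile_id", "metric"], columns="arm",
                             values="value").reset_index()
    deltas = (wide["AI"] - wide["CLINICIAN"]).groupby(wide["metric"]).mean().abs()
    assert (deltas < 4.0).all()  # mean signed difference compatible with zero


def test_config_yaml_round_trip(tmp_path, small_config):
    path = tmp_path / "cohort.yaml"
    small_config.to_yaml(path)
    assert CohortConfig.from_yaml(path) == small_config


def test_config_validation():
    with pytest.raises(ValueError):
        CohortConfig(n_profiles=1)
    with pytest.raises(ValueError):
        CohortConfig(p_disagreement=1.5)
    with pytest.raises(ValueError):
        CohortConfig(rater_noise_sd=-1)
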