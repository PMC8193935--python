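"""Fold orchestration, repeated CV, holdout, cross-cohort, final model."""

import json

import numpy as np
import pytest

from abapipe.evaluation import (
    EvaluationError,
    FinalModel,
    PipelineConfig,
    compute_metrics,
    cross_cohort,
    fit_final_model,
    holdout,
    repeated_cv,
    run_fold,
    selection_frequency_report,
)
from abapipe.feature_selection import SelectionConfig
from abapipe.synthetic_data import CohortConfig, Stratum, generate_cohort

from conftest import make_table

FAST = PipelineConfig(
    seed=3,
    selection=SelectionConfig(inner_folds=3),
    aba_penalty=0.1,
    psi=64,
    n_trees=50,
)


def _split(table, frac=0.75, seed=0):
    rng = np.random.default_rng(seed)
    idx = rng.permutation(table.n_subjects)
    cut = int(frac * table.n_subjects)
    return table.take(np.sort(idx[:cut])), table.take(np.sort(idx[cut:]))


def test_compute_metrics_worked_confusion_counts():
    m = compute_metrics(30, 104, 3, 4)
    assert round(m["accuracy"], 2) == 95.04
    assert m["ad_recall"] == pytest.approx(100 * 30 / 34)
    assert m["ad_precision"] == pytest.approx(100 * 30 / 33)


def test_compute_metrics_degenerate_and_errors():
    with pytest.warns(UserWarning, match="recall undefined"):
        m = compute_metrics(0, 50, 0, 0)
    assert m["accuracy"] == 100.0 and np.isnan(m["ad_recall"])
    with pytest.raises(EvaluationError, match="negative"):
        compute_metrics(-1, 2, 3, 4)
    with pytest.raises(EvaluationError, match="empty"):
        compute_metrics(0, 0, 0, 0)


def test_compute_metrics_random_counts_match_arithmetic():
    rng = np.random.default_rng(8)
    for _ in range(20):
        tp, tn, fp, fn = rng.integers(1, 50, size=4)
        m = compute_metrics(tp, tn, fp, fn)
        assert m["accuracy"] == pytest.approx(100 * (tp + tn) / (tp + tn + fp + fn))
        assert m["ad_recall"] == pytest.approx(100 * tp / (tp + fn))
        assert m["ad_precision"] == pytest.approx(100 * tp / (tp + fp))


def test_run_fold_null_effect_near_majority_rate(small_cohort):
    cfg, _, _ = small_cohort
    null_cfg = CohortConfig(
        **{**{k: getattr(cfg, k) for k in (
            "strata", "n_features", "ad_informative", "age_only", "slope",
            "noise_sd", "seed")}, "acceleration": 0.0},
    )
    table, _ = generate_cohort(null_cfg)
    train, test = _split(table, seed=1)
    fr = run_fold(train, test, FAST)
    acc = compute_metrics(*fr.confusion)["accuracy"]
    majority = 100 * np.mean(test.labels == 0)
    assert abs(acc - majority) < 15.0


def test_run_fold_huge_effect_near_perfect():
    strata = (
        Stratum("M", "synthetic", "AD", 60, 75.0, 7.5, 55.0, 91.0),
        Stratum("M", "synthetic", "CN", 120, 73.5, 7.0, 55.0, 91.0),
    )
    cfg = CohortConfig(
        strata=strata, n_features=12, ad_informative=3, age_only=2,
        acceleration=25.0, noise_sd=0.1, seed=21,
    )
    table, _ = generate_cohort(cfg)
    train, test = _split(table, seed=2)
    fr = run_fold(train, test, FAST)
    assert compute_metrics(*fr.confusion)["accuracy"] >= 95.0


def test_run_fold_rejects_overlapping_partitions(small_cohort):
    _, table, _ = small_cohort
    train, _ = _split(table)
    with pytest.raises(EvaluationError, match="overlap"):
        run_fold(train, train, FAST)


def test_run_fold_invariants(small_cohort):
    _, table, _ = small_cohort
    train, test = _split(table, seed=3)
    fr = run_fold(train, test, FAST)
    tp, tn, fp, fn = fr.confusion
    n_eval = int(fr.predictions["evaluated"].sum())
    assert tp + tn + fp + fn == n_eval
    assert set(fr.f2) <= set(fr.selected_f1) <= set(table.feature_names)
    assert np.allclose(
        fr.predictions["ads"], fr.predictions["aba"] - fr.predictions["age"]
    )


def test_run_fold_models_ignore_test_rows(small_cohort):
    """Mutating test labels and features leaves every fitted model alone."""
    _, table, _ = small_cohort
    train, test = _split(table, seed=4)
    fr1 = run_fold(train, test, FAST)
    meta = test.meta.copy()
    meta["group"] = np.where(meta["group"] == "AD", "CN", "AD")
    mutated = type(test)(meta, test.features * 3.0 + 1.0)
    fr2 = run_fold(train, mutated, FAST)
    assert fr1.model_hash() == fr2.model_hash()


def test_repeated_cv_is_deterministic(small_cohort):
    _, table, _ = small_cohort
    r1 = repeated_cv(table, FAST, folds=3, repeats=2)
    r2 = repeated_cv(table, FAST, folds=3, repeats=2)
    assert r1.fold_hashes == r2.fold_hashes
    assert r1.accuracy_mean == r2.accuracy_mean
    assert r1.per_repeat.equals(r2.per_repeat)


def test_repeated_cv_partitions_each_subject_once_per_repeat(small_cohort):
    _, table, _ = small_cohort
    res = repeated_cv(table, FAST, folds=3, repeats=2)
    for rep in range(2):
        ids = res.predictions.loc[res.predictions["repeat"] == rep, "subject_id"]
        flagged = res.predictions.loc[res.predictions["repeat"] == rep]
        # every evaluated subject appears exactly once per repeat
        assert ids.is_unique
        assert len(ids) <= table.n_subjects


def test_repeated_cv_leakage_freedom(small_cohort):
    """Perturbing test partitions must not move any fitted model hash."""
    _, table, _ = small_cohort

    def scramble(part):
        rng = np.random.default_rng(99)
        return type(part)(
            part.meta, part.features + rng.normal(0, 10, part.features.shape)
        )

    clean = repeated_cv(table, FAST, folds=3, repeats=2)
    perturbed = repeated_cv(table, FAST, folds=3, repeats=2, perturb_test=scramble)
    assert clean.fold_hashes == perturbed.fold_hashes


def test_repeated_cv_class_size_guard():
    table = make_table(n=20, groups=["AD"] * 4 + ["CN"] * 16)
    with pytest.raises(EvaluationError, match="needs >="):
        repeated_cv(table, FAST, folds=5, repeats=1)


def test_repeat_to_repeat_accuracy_sd_is_small(cv_runs):
    assert cv_runs["m6"].accuracy_sd < 3.0


def test_holdout_small_split_is_stratified():
    table = make_table(
        n=10, p=2, seed=5, groups=["AD"] * 4 + ["CN"] * 6,
        genders=["M"] * 10,
    )
    cfg = PipelineConfig(
        use_ffs=False, outlier_filtering=False, aba_penalty=0.1, seed=0
    )
    res = holdout(table, cfg, train_frac=0.5)
    n_test = len(res.fold.predictions)
    assert n_test == 5
    assert set(res.fold.predictions["group"]) == {"AD", "CN"}
    assert int((res.fold.predictions["group"] == "AD").sum()) == 2


def test_holdout_reports_and_quartiles(small_cohort):
    _, table, _ = small_cohort
    res = holdout(table, FAST, train_frac=0.8)
    assert res.quartiles is not None
    assert len(res.test_reports) == res.fold.predictions.shape[0]
    # quartile context comes from training rows only
    train_ids = set(res.fold.train_ids)
    assert {r.subject_id for r in res.train_reports} <= train_ids
    # a strongly atrophied AD test subject scores inside the AD upper box
    ad_rows = res.quartiles[res.quartiles["group"] == "AD"]
    top = max(
        (r for r in res.test_reports if r.scores), key=lambda r: r.score_sum
    )
    feat, s = max(top.scores.items(), key=lambda kv: kv[1])
    q3 = ad_rows.loc[ad_rows["feature"] == feat, "q3"]
    if not q3.empty:
        assert s >= float(ad_rows.loc[ad_rows["feature"] == feat, "q1"].iloc[0])


def test_cross_cohort_trains_only_on_requested_cohorts(small_cohort):
    _, table, _ = small_cohort
    meta = table.meta.copy()
    rng = np.random.default_rng(17)
    meta["cohort"] = np.where(rng.random(len(meta)) < 0.5, "A", "B")
    two = type(table)(meta, table.features)
    fr = cross_cohort(two, {"A"}, {"B"}, FAST)
    train_cohorts = set(
        meta.set_index("subject_id").loc[list(fr.train_ids), "cohort"]
    )
    assert train_cohorts == {"A"}
    with pytest.raises(EvaluationError, match="not in table"):
        cross_cohort(two, {"A"}, {"C"}, FAST)
    with pytest.raises(EvaluationError, match="overlap"):
        cross_cohort(two, {"A"}, {"A"}, FAST)


def test_cross_cohort_matches_within_cohort_cv_when_cohorts_identical():
    strata = tuple(
        Stratum("M", c, g, n, 74.0, 7.0, 55.0, 91.0)
        for c in ("A", "B")
        for g, n in (("AD", 100), ("CN", 200))
    )
    cfg = CohortConfig(
        strata=strata, n_features=15, ad_informative=3, age_only=3,
        acceleration=10.0, noise_sd=0.2, seed=31,
    )
    table, _ = generate_cohort(cfg)
    pcfg = PipelineConfig(use_ffs=False, aba_penalty=0.1, seed=5)
    fr = cross_cohort(table, {"A"}, {"B"}, pcfg)
    xc_acc = compute_metrics(*fr.confusion)["accuracy"]
    within = repeated_cv(
        table.where((table.meta["cohort"] == "A").to_numpy()),
        pcfg, folds=5, repeats=1,
    )
    assert abs(xc_acc - within.accuracy_mean) <= 3.0


def test_selection_frequency_report_percentages(cv_runs):
    res = cv_runs["m6"]
    report = selection_frequency_report(res)
    assert (report["pct"] > 0).all() and (report["pct"] <= 100).all()
    top = report.iloc[0]
    assert res.selection_counts[top["feature"]] == res.n_fold_models * top[
        "pct"
    ] / 100.0
    assert {"hemisphere", "roi"} <= set(report.columns)


def test_selection_frequency_top_rows_are_informative(cv_runs, fixture_cohort):
    _, _, truth = fixture_cohort
    report = selection_frequency_report(cv_runs["m6"])
    assert set(report.head(5)["feature"]) == set(truth.informative_features)


def test_final_model_round_trip_and_consistency(small_cohort):
    _, table, _ = small_cohort
    model = fit_final_model(table, FAST)
    preds = model.predict(table)
    assert len(preds) == table.n_subjects
    back = FinalModel.from_json(model.to_json())
    preds2 = back.predict(table)
    assert np.array_equal(preds["aba"].to_numpy(), preds2["aba"].to_numpy())
    assert list(preds["predicted"]) == list(preds2["predicted"])
    assert np.array_equal(
        preds["flagged_outlier"].to_numpy(), preds2["flagged_outlier"].to_numpy()
    )
    # final-model F1 overlaps the CV-frequent features
    cv_features = {
        f for f, c in repeated_cv(table, FAST, folds=3, repeats=1)
        .selection_counts.items()
    }
    assert set(model.selected_f1) & cv_features


def test_final_model_explain_reports(small_cohort):
    _, table, _ = small_cohort
    model = fit_final_model(table, FAST)
    reports = model.explain(table.take(np.arange(5)))
    assert len(reports) == 5
    for r in reports:
        assert set(r.scores) == set(model.aba_model.support)
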