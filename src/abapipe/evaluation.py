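"""Leakage-safe orchestration: per-fold pipeline, repeated CV, holdout,
cross-cohort validation, final-model fitting and summary reporting.

Every fold executes the same sequence with all models fitted on the
training partition only:

    standardize -> outlier filter -> rank -> forward-select -> CN LASSO ABA
    -> logistic classification on (age, ABA)

Test rows flagged as outliers by the training-fitted forest + cutoff are,
by default, excluded from metric computation and reported separately (a
config flag forces their inclusion).  The main estimator of predictive
performance is a repeated stratified k-fold cross-validation: within each
repeat the test predictions of all folds are pooled into one confusion
matrix, and mean/SD of the metrics are taken across repeats.

Ablation switch: ``use_ffs=False`` skips the wrapper and offers every
feature to the LASSO (the "no feature selection" configuration the full
method is compared against); ``use_ffs=True`` is the full method.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .brain_age import AbaModel, fit_aba, predict_aba, regression_metrics
from .classification_explain import (
    AD,
    CN,
    ClassifierModel,
    FeatureScoreReport,
    feature_scores,
    fit_classifier,
    predict,
    quartile_context,
)
from .feature_selection import (
    SelectionConfig,
    SelectionTrace,
    forward_select,
    rank_features,
)
from .io_features import (
    FeatureTable,
    StandardizationModel,
    apply_standardizer,
    fit_standardizer,
)
from .outlier_detection import (
    OutlierModel,
    filter_outliers,
    fit_outlier_stage,
    score_outliers,
)


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    """Hyper-parameters of every stage, with one master seed."""

    use_ffs: bool = True
    outlier_filtering: bool = True
    psi: int = 256
    n_trees: int = 100
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    aba_penalty: float | str = "auto"
    include_flagged_test: bool = False
    seed: int = 0


@dataclass
class FoldResult:
    """Everything one train/test execution produced."""

    predictions: pd.DataFrame  # per test subject, incl. flagged rows
    confusion: tuple[int, int, int, int]  # TP, TN, FP, FN (AD positive)
    selected_f1: tuple[str, ...]
    f2: tuple[str, ...]
    standardizer: StandardizationModel
    outlier_model: OutlierModel | None
    aba_model: AbaModel
    classifier: ClassifierModel
    selection_trace: SelectionTrace | None
    train_ids: tuple[str, ...]
    removed_train_ids: tuple[str, ...]
    flagged_test_ids: tuple[str, ...]

    def model_hash(self) -> str:
        """Stable digest of every fitted sub-model (leakage sentinel)."""
        payload = {
            "standardizer": self.standardizer.to_json(),
            "outlier": self.outlier_model.to_json() if self.outlier_model else None,
            "f1": list(self.selected_f1),
            "aba": self.aba_model.to_json(),
            "classifier": self.classifier.to_json_dict(),
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()


def _seed_for(cfg_seed: int, *path: int) -> int:
    return int(np.random.SeedSequence([cfg_seed, *path]).generate_state(1)[0] % (2**31))


def run_fold(
    train: FeatureTable,
    test: FeatureTable,
    cfg: PipelineConfig,
    seed: int | None = None,
) -> FoldResult:
    """Execute the full pipeline on one train/test split."""
    if set(train.subject_ids) & set(test.subject_ids):
        raise EvaluationError("train and test partitions overlap")
    seed = cfg.seed if seed is None else seed

    standardizer = fit_standardizer(train)
    train_z = apply_standardizer(standardizer, train)
    test_z = apply_standardizer(standardizer, test)

    outlier_model = None
    removed_ids: tuple[str, ...] = ()
    flagged_test = np.zeros(test.n_subjects, dtype=bool)
    if cfg.outlier_filtering:
        outlier_model, train_scores = fit_outlier_stage(
            train_z, psi=cfg.psi, n_trees=cfg.n_trees, seed=_seed_for(seed, 0)
        )
        train_z, removed = filter_outliers(
            train_z, train_scores, outlier_model.cutoff
        )
        removed_ids = tuple(removed.subject_ids)
        if test.n_subjects:
            test_scores = score_outliers(outlier_model, test_z)
            flagged_test = test_scores > outlier_model.cutoff

    ranking = rank_features(train_z)
    trace = None
    if cfg.use_ffs:
        trace = forward_select(
            train_z, ranking, replace(cfg.selection, seed=_seed_for(seed, 1))
        )
        f1 = trace.selected
    else:
        f1 = tuple(train_z.feature_names)

    cn_train = train_z.where(train_z.labels == 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        aba_model = fit_aba(
            cn_train, f1, penalty=cfg.aba_penalty, seed=_seed_for(seed, 2)
        )
    train_preds = predict_aba(aba_model, train_z)
    classifier = fit_classifier(
        train_preds["age"], train_preds["aba"], train_z.labels
    )

    test_preds = predict_aba(aba_model, test_z)
    pred_labels, prob_ad = predict(
        classifier, test_preds["age"], test_preds["aba"]
    )
    predictions = test_preds.assign(
        gender=test.meta["gender"].to_numpy(),
        predicted=pred_labels,
        prob_ad=prob_ad,
        flagged_outlier=flagged_test,
        evaluated=(~flagged_test) | cfg.include_flagged_test,
    )
    ev = predictions[predictions["evaluated"]]
    tp = int(((ev["predicted"] == AD) & (ev["group"] == AD)).sum())
    tn = int(((ev["predicted"] == CN) & (ev["group"] == CN)).sum())
    fp = int(((ev["predicted"] == AD) & (ev["group"] == CN)).sum())
    fn = int(((ev["predicted"] == CN) & (ev["group"] == AD)).sum())

    return FoldResult(
        predictions=predictions,
        confusion=(tp, tn, fp, fn),
        selected_f1=tuple(f1),
        f2=aba_model.support,
        standardizer=standardizer,
        outlier_model=outlier_model,
        aba_model=aba_model,
        classifier=classifier,
        selection_trace=trace,
        train_ids=tuple(train.subject_ids),
        removed_train_ids=removed_ids,
        flagged_test_ids=tuple(test.subject_ids[flagged_test]),
    )


def compute_metrics(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    """Accuracy / AD recall / AD precision, in percent (AD positive)."""
    for name, v in (("TP", tp), ("TN", tn), ("FP", fp), ("FN", fn)):
        if v < 0:
            raise EvaluationError(f"negative confusion count {name}={v}")
    total = tp + tn + fp + fn
    if total == 0:
        raise EvaluationError("empty confusion matrix")
    out = {"accuracy": 100.0 * (tp + tn) / total}
    if tp + fn == 0:
        warnings.warn("no AD subjects evaluated; recall undefined", stacklevel=2)
        out["ad_recall"] = float("nan")
    else:
        out["ad_recall"] = 100.0 * tp / (tp + fn)
    if tp + fp == 0:
        warnings.warn("no AD predictions made; precision undefined", stacklevel=2)
        out["ad_precision"] = float("nan")
    else:
        out["ad_precision"] = 100.0 * tp / (tp + fp)
    return out


@dataclass
class CvResult:
    """Repeated-CV summary: per-repeat pooled metrics, mean/SD across repeats."""

    folds: int
    repeats: int
    per_repeat: pd.DataFrame
    accuracy_mean: float
    accuracy_sd: float
    ad_recall_mean: float
    ad_recall_sd: float
    ad_precision_mean: float
    ad_precision_sd: float
    selection_counts: dict[str, int]
    n_fold_models: int
    fold_hashes: tuple[str, ...]
    predictions: pd.DataFrame  # pooled test predictions of every repeat


def repeated_cv(
    table: FeatureTable,
    cfg: PipelineConfig,
    folds: int = 10,
    repeats: int = 10,
    perturb_test: Callable[[FeatureTable], FeatureTable] | None = None,
) -> CvResult:
    """Repeated stratified k-fold CV of the whole pipeline.

    ``perturb_test`` is a hook applied to each *test* partition after the
    fold split and before the fold runs; fitted models must be invariant to
    it (the leakage sentinel used in the test suite).
    """
    labels = table.labels
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2 or counts.min() < folds:
        raise EvaluationError(
            f"each class needs >= {folds} members for {folds}-fold CV"
        )
    repeat_rows = []
    hashes: list[str] = []
    selection_counts: dict[str, int] = {}
    all_preds = []
    for rep in range(repeats):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=_seed_for(cfg.seed, 10, rep)
        )
        fold_results = []
        for fold_id, (tr, te) in enumerate(skf.split(np.zeros(len(labels)), labels)):
            test_part = table.take(te)
            if perturb_test is not None:
                test_part = perturb_test(test_part)
            fr = run_fold(
                table.take(tr), test_part, cfg,
                seed=_seed_for(cfg.seed, 20, rep, fold_id),
            )
            fold_results.append(fr)
            hashes.append(fr.model_hash())
            for f in fr.selected_f1:
                selection_counts[f] = selection_counts.get(f, 0) + 1
        tp, tn, fp, fn = (
            sum(fr.confusion[i] for fr in fold_results) for i in range(4)
        )
        if tp + tn + fp + fn == 0:
            warnings.warn(
                f"repeat {rep}: no evaluated test subjects (all flagged as "
                "outliers); metrics undefined", stacklevel=2,
            )
            metrics = {k: float("nan") for k in
                       ("accuracy", "ad_recall", "ad_precision")}
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                metrics = compute_metrics(tp, tn, fp, fn)
        pooled = pd.concat(
            [fr.predictions[fr.predictions["evaluated"]] for fr in fold_results],
            ignore_index=True,
        ).assign(repeat=rep)
        all_preds.append(pooled)
        row = {"repeat": rep, **metrics}
        for group in (CN, AD):
            sub = pooled[pooled["group"] == group]
            if len(sub) >= 2:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UserWarning)
                    mae, r = regression_metrics(sub)
            else:
                mae, r = float("nan"), float("nan")
            row[f"mae_{group.lower()}"] = mae
            row[f"r_{group.lower()}"] = r
        repeat_rows.append(row)
    per_repeat = pd.DataFrame(repeat_rows)
    acc_m, acc_s = per_repeat["accuracy"].mean(), per_repeat["accuracy"].std(ddof=1)
    rec_m, rec_s = per_repeat["ad_recall"].mean(), per_repeat["ad_recall"].std(ddof=1)
    pre_m, pre_s = per_repeat["ad_precision"].mean(), per_repeat["ad_precision"].std(ddof=1)
    return CvResult(
        folds=folds,
        repeats=repeats,
        per_repeat=per_repeat,
        accuracy_mean=float(acc_m),
        accuracy_sd=float(acc_s) if repeats > 1 else 0.0,
        ad_recall_mean=float(rec_m),
        ad_recall_sd=float(rec_s) if repeats > 1 else 0.0,
        ad_precision_mean=float(pre_m),
        ad_precision_sd=float(pre_s) if repeats > 1 else 0.0,
        selection_counts=selection_counts,
        n_fold_models=folds * repeats,
        fold_hashes=tuple(hashes),
        predictions=pd.concat(all_preds, ignore_index=True),
    )


@dataclass
class HoldoutResult:
    fold: FoldResult
    metrics: dict[str, float]
    train_reports: list[FeatureScoreReport]
    test_reports: list[FeatureScoreReport]
    quartiles: pd.DataFrame | None


def holdout(
    table: FeatureTable,
    cfg: PipelineConfig,
    train_frac: float = 0.8,
    seed: int | None = None,
) -> HoldoutResult:
    """Single stratified holdout split plus per-subject score reports.

    The quartile context for the reports is computed from the (filtered)
    training rows only, exactly as the explanation box plots require.
    """
    seed = cfg.seed if seed is None else seed
    labels = table.labels
    idx = np.arange(table.n_subjects)
    tr, te = train_test_split(
        idx, train_size=train_frac, stratify=labels,
        random_state=_seed_for(seed, 30),
    )
    fr = run_fold(table.take(np.sort(tr)), table.take(np.sort(te)), cfg, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        metrics = compute_metrics(*fr.confusion)

    train_z = apply_standardizer(fr.standardizer, table.take(np.sort(tr)))
    if fr.removed_train_ids:
        keep = ~np.isin(train_z.subject_ids, fr.removed_train_ids)
        train_z = train_z.where(keep)
    test_z = apply_standardizer(fr.standardizer, table.take(np.sort(te)))

    def _reports(part: FeatureTable) -> list[FeatureScoreReport]:
        out = []
        for i in range(part.n_subjects):
            out.append(
                feature_scores(
                    fr.classifier,
                    fr.aba_model,
                    part.features.iloc[i],
                    float(part.ages[i]),
                    subject_id=str(part.subject_ids[i]),
                )
            )
        return out

    train_reports = _reports(train_z)
    test_reports = _reports(test_z)
    by_group: dict[str, list[FeatureScoreReport]] = {AD: [], CN: []}
    for rep, grp in zip(train_reports, train_z.meta["group"]):
        by_group[grp].append(rep)
    quartiles = None
    if fr.f2 and min(len(v) for v in by_group.values()) >= 4:
        quartiles = quartile_context(by_group)
    return HoldoutResult(
        fold=fr,
        metrics=metrics,
        train_reports=train_reports,
        test_reports=test_reports,
        quartiles=quartiles,
    )


def cross_cohort(
    table: FeatureTable,
    train_cohorts: Iterable[str],
    test_cohorts: Iterable[str],
    cfg: PipelineConfig,
) -> FoldResult:
    """Train on one set of cohort tags, test on a disjoint set."""
    train_cohorts, test_cohorts = set(train_cohorts), set(test_cohorts)
    if train_cohorts & test_cohorts:
        raise EvaluationError("train and test cohort sets overlap")
    tags = table.meta["cohort"].to_numpy()
    present = set(tags)
    missing = (train_cohorts | test_cohorts) - present
    if missing:
        raise EvaluationError(f"cohort tag(s) not in table: {sorted(missing)}")
    train_mask = np.isin(tags, sorted(train_cohorts))
    test_mask = np.isin(tags, sorted(test_cohorts))
    if not train_mask.any() or not test_mask.any():
        raise EvaluationError("empty train or test cohort side")
    return run_fold(table.where(train_mask), table.where(test_mask), cfg)


def selection_frequency_report(cv: CvResult) -> pd.DataFrame:
    """Percentage of fold models whose F1 contained each feature.

    If feature names carry lh_/rh_ hemisphere prefixes, rows are aggregated
    per ROI with per-hemisphere and either-hemisphere percentages.
    """
    total = cv.n_fold_models
    frame = pd.DataFrame(
        [(f, 100.0 * c / total) for f, c in cv.selection_counts.items()],
        columns=["feature", "pct"],
    )
    frame = frame[frame["pct"] > 0].sort_values(
        ["pct", "feature"], ascending=[False, True]
    ).reset_index(drop=True)
    has_hemi = frame["feature"].str.match(r"^(lh|rh)_").all() and len(frame) > 0
    if has_hemi:
        frame["hemisphere"] = frame["feature"].str[:2].str.upper()
        frame["roi"] = frame["feature"].str[3:]
    return frame


@dataclass
class FinalModel:
    """Deployment bundle: all stages fitted on the full input table."""

    standardizer: StandardizationModel
    outlier_model: OutlierModel | None
    selected_f1: tuple[str, ...]
    aba_model: AbaModel
    classifier: ClassifierModel

    def predict(self, table: FeatureTable) -> pd.DataFrame:
        z = apply_standardizer(self.standardizer, table)
        preds = predict_aba(self.aba_model, z)
        labels, prob = predict(self.classifier, preds["age"], preds["aba"])
        out = preds.assign(predicted=labels, prob_ad=prob)
        if self.outlier_model is not None:
            scores = score_outliers(self.outlier_model, z)
            out["flagged_outlier"] = scores > self.outlier_model.cutoff
        return out

    def explain(self, table: FeatureTable) -> list[FeatureScoreReport]:
        z = apply_standardizer(self.standardizer, table)
        return [
            feature_scores(
                self.classifier,
                self.aba_model,
                z.features.iloc[i],
                float(z.ages[i]),
                subject_id=str(z.subject_ids[i]),
            )
            for i in range(z.n_subjects)
        ]

    def to_json(self) -> str:
        return json.dumps(
            {
                "standardizer": json.loads(self.standardizer.to_json()),
                "outlier_model": (
                    json.loads(self.outlier_model.to_json())
                    if self.outlier_model is not None
                    else None
                ),
                "selected_f1": list(self.selected_f1),
                "aba_model": json.loads(self.aba_model.to_json()),
                "classifier": self.classifier.to_json_dict(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FinalModel":
        d = json.loads(text)
        return cls(
            standardizer=StandardizationModel.from_json(
                json.dumps(d["standardizer"])
            ),
            outlier_model=(
                OutlierModel.from_json(json.dumps(d["outlier_model"]))
                if d["outlier_model"] is not None
                else None
            ),
            selected_f1=tuple(d["selected_f1"]),
            aba_model=AbaModel.from_json(json.dumps(d["aba_model"])),
            classifier=ClassifierModel.from_json_dict(d["classifier"]),
        )


def fit_final_model(table: FeatureTable, cfg: PipelineConfig) -> FinalModel:
    """Fit every stage on all available rows (no held-out test side)."""
    standardizer = fit_standardizer(table)
    table_z = apply_standardizer(standardizer, table)
    outlier_model = None
    if cfg.outlier_filtering:
        outlier_model, scores = fit_outlier_stage(
            table_z, psi=cfg.psi, n_trees=cfg.n_trees, seed=_seed_for(cfg.seed, 0)
        )
        table_z, _ = filter_outliers(table_z, scores, outlier_model.cutoff)
    if cfg.use_ffs:
        ranking = rank_features(table_z)
        trace = forward_select(
            table_z, ranking, replace(cfg.selection, seed=_seed_for(cfg.seed, 1))
        )
        f1 = trace.selected
    else:
        f1 = tuple(table_z.feature_names)
    cn = table_z.where(table_z.labels == 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        aba_model = fit_aba(cn, f1, penalty=cfg.aba_penalty, seed=_seed_for(cfg.seed, 2))
    preds = predict_aba(aba_model, table_z)
    classifier = fit_classifier(preds["age"], preds["aba"], table_z.labels)
    return FinalModel(
        standardizer=standardizer,
        outlier_model=outlier_model,
        selected_f1=tuple(f1),
        aba_model=aba_model,
        classifier=classifier,
    )
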