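"""Classification-biased wrapper feature selection.

Features are first ranked by the absolute point-biserial correlation of
their values with the AD/CN label — i.e. plain Pearson correlation against
the label coded 0/1 — so regions whose measurements differ most between
groups are examined first.  A forward wrapper then walks the ranked list
once: for each candidate it fits, on inner cross-validation splits of the
(outer) training partition only, the CN-trained LASSO age model plus the
(age, ABA) logistic classifier, and keeps the candidate iff the mean inner
validation *classification* accuracy strictly improves.  The output subset
F1 is therefore biased toward the diagnosis, not toward age-regression
quality — the inductive bias that makes ABA disease-specific.

The top-ranked feature is always retained so the ABA model is never
featureless.  Ties in the ranking break lexicographically by feature name.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .brain_age import fit_lasso_arrays
from .classification_explain import AD, CN, fit_classifier, predict
from .io_features import FeatureTable


class SelectionError(ValueError):
    pass


def point_biserial(values, labels) -> float:
    """Point-biserial r: Pearson correlation with labels coded 0/1.

    Zero-variance values are defined to have r = 0.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.shape != y.shape:
        raise SelectionError("values and labels have different lengths")
    classes = np.unique(y)
    if len(classes) != 2:
        raise SelectionError("both classes must be present")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc**2))
    sy = np.sqrt(np.sum(yc**2))
    if sx == 0.0:
        return 0.0
    return float(np.dot(xc, yc) / (sx * sy))


@dataclass(frozen=True)
class FeatureRanking:
    """(feature, r, |r|) rows sorted by |r| descending, names break ties."""

    table: pd.DataFrame

    @property
    def order(self) -> list[str]:
        return list(self.table["feature"])


def rank_features(train: FeatureTable) -> FeatureRanking:
    labels = train.labels
    if len(np.unique(labels)) != 2:
        raise SelectionError("ranking requires both AD and CN subjects")
    X = train.features.to_numpy()
    rows = [
        (name, point_biserial(X[:, j], labels))
        for j, name in enumerate(train.feature_names)
    ]
    frame = pd.DataFrame(rows, columns=["feature", "r"])
    frame["abs_r"] = frame["r"].abs()
    frame = frame.sort_values(
        ["abs_r", "feature"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return FeatureRanking(frame)


@dataclass(frozen=True)
class SelectionConfig:
    """Knobs of the forward wrapper.

    ``rule`` picks the acceptance criterion applied to the paired fold-wise
    accuracy differences d between the candidate subset and the current one:

    * ``"consistent"`` (default): mean(d) > epsilon, mean(d) greater than
      one standard error of d, and d > 0 in a majority of inner folds — a
      guard against accepting features whose apparent gain is inner-CV
      noise;
    * ``"strict"``: mean(d) > epsilon only.
    """

    inner_folds: int = 5
    epsilon: float = 0.0  # additive improvement margin
    rule: str = "consistent"
    top_k: int | None = None  # truncate the candidate list; None = all
    lasso_alpha: float = 0.1  # fixed penalty for the wrapper's inner fits
    seed: int = 0


@dataclass(frozen=True)
class SelectionTrace:
    """Per-candidate audit trail plus the final subset F1."""

    records: pd.DataFrame  # feature, rank, acc_without, acc_with, accepted
    selected: tuple[str, ...]


def forward_select(
    train: FeatureTable,
    ranking: FeatureRanking,
    cfg: SelectionConfig = SelectionConfig(),
) -> SelectionTrace:
    """One forward pass over the ranked features with inner-CV acceptance.

    ``train`` must be an outer-fold training partition (standardized,
    outlier-filtered); inner splits are stratified on the AD/CN label so no
    inner fold loses a class.
    """
    labels = train.labels
    ages = train.ages
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise SelectionError("forward selection requires both classes")
    if counts.min() < cfg.inner_folds:
        raise SelectionError(
            f"minority class has {counts.min()} subjects; cannot stratify "
            f"{cfg.inner_folds} inner folds"
        )
    X = train.features.to_numpy()
    col = {name: j for j, name in enumerate(train.feature_names)}
    skf = StratifiedKFold(
        n_splits=cfg.inner_folds, shuffle=True, random_state=cfg.seed % (2**31)
    )
    splits = list(skf.split(X, labels))

    def inner_accuracies(cols: list[int]) -> np.ndarray:
        accs = []
        for tr, va in splits:
            cn_tr = tr[labels[tr] == 0]
            a0, w = fit_lasso_arrays(X[np.ix_(cn_tr, cols)], ages[cn_tr],
                                     cfg.lasso_alpha)
            aba_tr = a0 + X[np.ix_(tr, cols)] @ w
            aba_va = a0 + X[np.ix_(va, cols)] @ w
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # separation fallback is fine here
                clf = fit_classifier(ages[tr], aba_tr, labels[tr], max_iter=200)
            pred, _ = predict(clf, ages[va], aba_va)
            accs.append(float(np.mean((pred == AD) == (labels[va] == 1))))
        return np.asarray(accs)

    def accept(diffs: np.ndarray) -> bool:
        if cfg.rule == "strict":
            return diffs.mean() > cfg.epsilon
        if cfg.rule != "consistent":
            raise SelectionError(f"unknown acceptance rule {cfg.rule!r}")
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        return (
            diffs.mean() > cfg.epsilon
            and diffs.mean() > se
            and int((diffs > 0).sum()) > len(diffs) // 2
        )

    order = ranking.order
    if cfg.top_k is not None:
        order = order[: cfg.top_k]
    current = [col[order[0]]]
    best_accs = inner_accuracies(current)
    records = [
        {
            "feature": order[0],
            "rank": 0,
            "acc_without": np.nan,
            "acc_with": float(best_accs.mean()),
            "accepted": True,
        }
    ]
    for rank, name in enumerate(order[1:], start=1):
        candidate = current + [col[name]]
        accs = inner_accuracies(candidate)
        accepted = accept(accs - best_accs)
        records.append(
            {
                "feature": name,
                "rank": rank,
                "acc_without": float(best_accs.mean()),
                "acc_with": float(accs.mean()),
                "accepted": accepted,
            }
        )
        if accepted:
            current = candidate
            best_accs = accs
    names = train.feature_names
    return SelectionTrace(
        records=pd.DataFrame(records),
        selected=tuple(names[j] for j in current),
    )
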