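"""CN-trained sparse age regression: the Apparent Brain Age (ABA) model.

The ABA of a subject is a linear prediction of chronological age,

    aba = a0 + sum_i a_i * f_i,

fitted by LASSO on *cognitively normal* training subjects only, over the
feature subset offered by the wrapper selection stage (F1).  The L1 penalty
zeroes redundant coefficients, so the model's support F2 (nonzero a_i) is a
further, embedded selection within F1.  Because the regression is trained
on healthy ageing but the offered features are the ones most affected by
the disease, AD subjects receive systematically overestimated ages; the
Age Deviation Score ADS = ABA - age carries the diagnostic signal.

The penalty is either a fixed value or "auto": K-fold cross-validation on
the CN training subjects minimising the mean absolute error of the age
prediction over a 50-point logarithmic grid (ties go to the sparser, i.e.
larger, penalty).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, LinearRegression
from sklearn.model_selection import KFold

from .io_features import FeatureTable


class BrainAgeError(ValueError):
    pass


@dataclass(frozen=True)
class AbaModel:
    """Intercept a0 (years) and sparse coefficients over the offered set."""

    intercept: float
    coef: dict[str, float]  # keyed by feature name; support = nonzero entries
    offered: tuple[str, ...]
    penalty: float
    n_train_cn: int

    @property
    def support(self) -> tuple[str, ...]:
        """F2: the features with nonzero LASSO coefficients."""
        return tuple(f for f in self.offered if self.coef.get(f, 0.0) != 0.0)

    def to_json(self) -> str:
        return json.dumps(
            {
                "intercept": self.intercept,
                "coef": self.coef,
                "offered": list(self.offered),
                "penalty": self.penalty,
                "n_train_cn": self.n_train_cn,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "AbaModel":
        d = json.loads(text)
        return cls(
            intercept=d["intercept"],
            coef={k: float(v) for k, v in d["coef"].items()},
            offered=tuple(d["offered"]),
            penalty=d["penalty"],
            n_train_cn=d["n_train_cn"],
        )


def fit_lasso_arrays(
    X: np.ndarray, y: np.ndarray, alpha: float
) -> tuple[float, np.ndarray]:
    """L1-penalized least squares (intercept unpenalized).

    Minimises (1/2n)||y - a0 - Xw||^2 + alpha * ||w||_1.  alpha = 0 falls
    back to ordinary least squares.
    """
    if alpha < 0:
        raise BrainAgeError("penalty must be non-negative")
    if alpha == 0:
        model = LinearRegression().fit(X, y)
    else:
        model = Lasso(alpha=alpha, max_iter=10_000, tol=1e-7).fit(X, y)
    return float(model.intercept_), np.asarray(model.coef_, dtype=float)


def _auto_penalty(
    X: np.ndarray,
    y: np.ndarray,
    cv_folds: int,
    seed: int,
    n_alphas: int = 50,
) -> float:
    alphas = np.logspace(np.log10(5.0), -3, n_alphas)  # descending for warm start
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    mae = np.zeros((n_alphas, cv_folds))
    for j, (tr, va) in enumerate(kf.split(X)):
        model = Lasso(alpha=alphas[0], max_iter=10_000, tol=1e-7, warm_start=True)
        for i, alpha in enumerate(alphas):
            model.set_params(alpha=alpha)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X[tr], y[tr])
            pred = model.predict(X[va])
            mae[i, j] = np.mean(np.abs(pred - y[va]))
    mean_mae = mae.mean(axis=1)
    # first argmin on a descending grid = largest (sparsest) alpha among ties
    return float(alphas[int(np.argmin(mean_mae))])


def fit_aba(
    train_cn: FeatureTable,
    offered_features: Sequence[str],
    penalty: float | str = "auto",
    cv_folds: int = 5,
    seed: int = 0,
) -> AbaModel:
    """Fit the LASSO age regression on CN training subjects only."""
    if train_cn.n_subjects == 0:
        raise BrainAgeError("empty CN training set")
    if np.any(train_cn.labels != 0):
        raise BrainAgeError("ABA training table must contain only CN subjects")
    offered = tuple(offered_features)
    if not offered:
        raise BrainAgeError("at least one offered feature is required")
    X = train_cn.select_features(offered).features.to_numpy()
    y = train_cn.ages
    if penalty == "auto":
        folds = min(cv_folds, len(y))
        if folds < 2:
            raise BrainAgeError("too few CN subjects for penalty selection")
        alpha = _auto_penalty(X, y, folds, seed)
    else:
        alpha = float(penalty)
    a0, w = fit_lasso_arrays(X, y, alpha)
    # coordinate descent can leave ~1e-16 residue on eliminated coefficients
    w = np.where(np.abs(w) <= 1e-12, 0.0, w)
    model = AbaModel(
        intercept=a0,
        coef={f: float(c) for f, c in zip(offered, w)},
        offered=offered,
        penalty=alpha,
        n_train_cn=train_cn.n_subjects,
    )
    if not model.support:
        warnings.warn(
            "LASSO zeroed every coefficient; ABA is intercept-only",
            stacklevel=2,
        )
    return model


def predict_aba(model: AbaModel, table: FeatureTable) -> pd.DataFrame:
    """Per-subject (age, aba, ads = aba - age) predictions, in years."""
    missing = [f for f in model.support if f not in table.features.columns]
    if missing:
        raise BrainAgeError(f"table lacks support feature(s): {missing}")
    aba = np.full(table.n_subjects, model.intercept, dtype=float)
    for f in model.support:
        aba += model.coef[f] * table.features[f].to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "subject_id": table.subject_ids,
            "group": table.meta["group"].to_numpy(),
            "age": table.ages,
            "aba": aba,
            "ads": aba - table.ages,
        }
    )


def regression_metrics(
    preds: pd.DataFrame, group: str | None = None
) -> tuple[float, float]:
    """(MAE in years, Pearson r of aba vs age), optionally within one group."""
    if group is not None:
        preds = preds[preds["group"] == group]
    if len(preds) < 2:
        raise BrainAgeError("need at least 2 subjects for regression metrics")
    age = preds["age"].to_numpy(dtype=float)
    aba = preds["aba"].to_numpy(dtype=float)
    mae = float(np.mean(np.abs(aba - age)))
    if np.std(age) == 0 or np.std(aba) == 0:
        warnings.warn("zero variance in age or aba; r undefined", stacklevel=2)
        return mae, float("nan")
    r = float(stats.pearsonr(aba, age).statistic)
    return mae, r
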