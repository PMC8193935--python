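"""Logistic AD classification on (age, ABA) and its score decomposition.

The classifier is a two-input logistic regression with a linear decision
boundary; in the sign convention used throughout, a subject is classified
AD when

    c0 + c1 * age + c2 * aba < 0.

Substituting the ABA regression aba = a0 + sum_i a_i * f_i expresses the
boundary directly in feature space, and dividing by the subject-specific
denominator D = c0 + c1 * age + c2 * a0 yields one *score* per support
feature,

    s_i = -c2 * a_i * f_i / D,

whose sum plays the role of the boundary value: algebraically,
boundary = D * (1 - sum_i s_i).  A high positive score flags a feature
(standardized ROI measurement) as pushing the subject toward the AD side —
i.e. abnormal atrophy in that region — while a near-zero or negative score
indicates the region looks age-typical.  The printed-rule direction
"sum s_i > 1 means AD" only holds when D > 0, so the decision here is
derived from the runtime sign of D and is exactly equivalent to the
boundary inequality whenever D != 0.

Quartile context: the training-set distribution of each feature score,
summarised per diagnostic group as a five-number box, situates an
individual subject's scores against typical AD and CN training profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .brain_age import AbaModel

AD, CN = "AD", "CN"


class ClassifierError(ValueError):
    pass


@dataclass(frozen=True)
class ClassifierModel:
    """Boundary coefficients; AD iff c0 + c1*age + c2*aba < 0."""

    c0: float
    c1: float  # per year of chronological age
    c2: float  # per year of apparent brain age
    ridged: bool = False  # True if a small ridge was needed (separation)

    def boundary_value(self, age, aba):
        return self.c0 + self.c1 * np.asarray(age, dtype=float) + self.c2 * np.asarray(
            aba, dtype=float
        )

    def to_json_dict(self) -> dict:
        return {"c0": self.c0, "c1": self.c1, "c2": self.c2, "ridged": self.ridged}

    @classmethod
    def from_json_dict(cls, d: Mapping) -> "ClassifierModel":
        return cls(c0=d["c0"], c1=d["c1"], c2=d["c2"], ridged=d.get("ridged", False))


def fit_classifier(age, aba, labels, max_iter: int = 500) -> ClassifierModel:
    """Maximum-likelihood logistic fit of AD (coded 1) on (age, aba).

    Perfectly separated data make the unpenalized likelihood unbounded; in
    that case the fit falls back to a weak ridge penalty with a warning.
    """
    age = np.asarray(age, dtype=float)
    aba = np.asarray(aba, dtype=float)
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ClassifierError("both classes (AD and CN) must be present")
    X = np.column_stack([age, aba])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        fit = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=max_iter).fit(X, y)
    ridged = False
    separated = bool(np.all(fit.predict(X) == y))
    if separated or not np.all(np.isfinite(fit.coef_)):
        warnings.warn(
            "training data are (near-)perfectly separated; refitting the "
            "logistic model with a small ridge penalty",
            stacklevel=2,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            fit = LogisticRegression(
                C=1000.0, solver="lbfgs", max_iter=max_iter
            ).fit(X, y)
        ridged = True
    # sklearn: P(AD) = sigmoid(b + w . x); the "< 0 means AD" convention
    # therefore takes c = -(b, w).
    (w1, w2), b = fit.coef_[0], float(fit.intercept_[0])
    return ClassifierModel(c0=-b, c1=-float(w1), c2=-float(w2), ridged=ridged)


def predict(model: ClassifierModel, age, aba):
    """(labels, P(AD)) from the linear boundary; exact ties go to CN."""
    score = model.boundary_value(age, aba)
    prob_ad = expit(-score)
    labels = np.where(score < 0, AD, CN)
    if labels.ndim == 0:
        return labels.item(), float(prob_ad)
    return labels, prob_ad


# ---------------------------------------------------------------------------
# Feature-score decomposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureScoreReport:
    """Per-feature decomposition of one subject's classification."""

    subject_id: str
    age: float
    aba: float
    scores: dict[str, float]  # s_i over the ABA support (F2)
    denominator: float  # D = c0 + c1*age + c2*a0
    score_sum: float
    boundary_value: float  # c0 + c1*age + c2*aba
    decision: str
    degenerate: bool = False  # D == 0: scores undefined

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "age": self.age,
            "aba": self.aba,
            "scores": dict(self.scores),
            "denominator": self.denominator,
            "score_sum": self.score_sum,
            "boundary_value": self.boundary_value,
            "decision": self.decision,
            "degenerate": self.degenerate,
        }


def feature_scores(
    clf: ClassifierModel,
    aba_model: AbaModel,
    features: Mapping[str, float] | pd.Series,
    age: float,
    subject_id: str = "?",
) -> FeatureScoreReport:
    """Decompose one subject's decision into per-feature scores s_i.

    ``features`` must be the subject's *standardized* feature values (the
    same representation the ABA model was trained on).
    """
    support = aba_model.support
    aba = aba_model.intercept + sum(
        aba_model.coef[f] * float(features[f]) for f in support
    )
    boundary = float(clf.boundary_value(age, aba))
    decision = AD if boundary < 0 else CN
    D = float(clf.boundary_value(age, aba_model.intercept))
    if D == 0.0:
        warnings.warn(
            f"boundary-degenerate subject {subject_id!r}: D = 0, feature "
            "scores are undefined",
            stacklevel=2,
        )
        return FeatureScoreReport(
            subject_id=str(subject_id), age=float(age), aba=float(aba),
            scores={}, denominator=0.0, score_sum=float("nan"),
            boundary_value=boundary, decision=decision, degenerate=True,
        )
    scores = {
        f: -clf.c2 * aba_model.coef[f] * float(features[f]) / D for f in support
    }
    return FeatureScoreReport(
        subject_id=str(subject_id),
        age=float(age),
        aba=float(aba),
        scores=scores,
        denominator=D,
        score_sum=float(sum(scores.values())),
        boundary_value=boundary,
        decision=decision,
    )


def score_decision(report: FeatureScoreReport) -> str:
    """Classify from the score sum alone.

    boundary = D * (1 - sum s_i), so with D > 0 the AD condition
    (boundary < 0) reads sum s_i > 1, and with D < 0 it flips to
    sum s_i < 1.  Exact ties (sum s_i = 1, boundary = 0) go to CN.
    """
    if report.degenerate or report.denominator == 0.0:
        raise ClassifierError("decision undefined for a boundary-degenerate subject")
    if report.denominator > 0:
        return AD if report.score_sum > 1.0 else CN
    return AD if report.score_sum < 1.0 else CN


def quartile_context(
    reports_by_group: Mapping[str, Sequence[FeatureScoreReport]],
    min_group_size: int = 4,
) -> pd.DataFrame:
    """Five-number summaries of training feature scores per (feature, group).

    Rows: feature x group with columns (n, min, q1, median, q3, max).
    Quartiles use linear interpolation between order statistics.
    """
    rows = []
    for group, reports in reports_by_group.items():
        usable = [r for r in reports if not r.degenerate]
        if len(usable) < min_group_size:
            raise ClassifierError(
                f"need >= {min_group_size} training subjects in group {group!r}"
            )
        features = sorted({f for r in usable for f in r.scores})
        for f in features:
            vals = np.array([r.scores[f] for r in usable if f in r.scores])
            q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
            rows.append(
                {
                    "feature": f,
                    "group": group,
                    "n": len(vals),
                    "min": float(vals.min()),
                    "q1": float(q1),
                    "median": float(med),
                    "q3": float(q3),
                    "max": float(vals.max()),
                }
            )
    return pd.DataFrame(rows)


def reports_to_frame(
    reports: Sequence[FeatureScoreReport],
    quartiles: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Long-format (subject_id, feature, score, ...) frame, box-plot ready."""
    rows = []
    for r in reports:
        for f, s in r.scores.items():
            rows.append(
                {
                    "subject_id": r.subject_id,
                    "feature": f,
                    "score": s,
                    "score_sum": r.score_sum,
                    "decision": r.decision,
                }
            )
    frame = pd.DataFrame(rows)
    if quartiles is not None and not frame.empty:
        wide = quartiles.pivot(index="feature", columns="group")
        wide.columns = [f"{g.lower()}_{stat}" for stat, g in wide.columns]
        frame = frame.merge(wide, left_on="feature", right_index=True, how="left")
    return frame
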