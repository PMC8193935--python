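"""Isolation-forest outlier scoring with a Tukey-fence cutoff.

Records that are "few and different" — scanner artefacts, segmentation
failures, extreme anatomical variants — are isolated in few random splits,
giving anomaly scores s(x) = 2^(-E[h(x)]/c(psi)) in (0, 1], where h is the
isolation path length (with the standard average-path correction c(m) at
unexpanded nodes) and psi the sub-sampling size.  The cutoff is the Tukey
far-out fence on the *training* scores,

    cutoff = Q3 + 3 * IQR,

and any record scoring strictly above it is flagged.  Both the forest and
the cutoff are fitted on the training partition only and applied unchanged
to test data.

The forest itself is scikit-learn's IsolationForest; the height limit is
tied to the sub-sampling size as l = ceil(log2 psi), so the default
psi = 256 gives l = 8 with t = 100 trees.  Serialization exports the raw
split arrays of every tree, and :meth:`OutlierModel.manual_scores`
recomputes scores from those arrays alone — used both to score a
deserialized model and as an independent path-length trace in tests.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import IsolationForest

from .io_features import FeatureTable


class OutlierError(ValueError):
    pass


def _average_path_length(n_samples: np.ndarray) -> np.ndarray:
    """Expected isolation path length c(m) of an unsuccessful BST search."""
    n = np.asarray(n_samples, dtype=float)
    out = np.zeros_like(n)
    mask_big = n > 2
    out[n == 2] = 1.0
    nb = n[mask_big]
    out[mask_big] = 2.0 * (np.log(nb - 1.0) + np.euler_gamma) - 2.0 * (nb - 1.0) / nb
    return out


@dataclass
class OutlierModel:
    psi: int
    height_limit: int
    n_trees: int
    feature_names: list[str]
    max_samples: int
    cutoff: float | None = None
    forest: IsolationForest | None = None
    trees: list[dict] | None = field(default=None, repr=False)

    def tree_arrays(self) -> list[dict]:
        """Per-tree split structure (children, split feature/value, sizes)."""
        if self.trees is not None:
            return self.trees
        assert self.forest is not None
        arrays = []
        for est in self.forest.estimators_:
            t = est.tree_
            arrays.append(
                {
                    "children_left": t.children_left.tolist(),
                    "children_right": t.children_right.tolist(),
                    "feature": t.feature.tolist(),
                    "threshold": t.threshold.tolist(),
                    "n_node_samples": t.n_node_samples.tolist(),
                }
            )
        return arrays

    def manual_scores(self, X: np.ndarray) -> np.ndarray:
        """Score by explicitly tracing each record through every tree."""
        X = np.asarray(X, dtype=float)
        depths = np.zeros(X.shape[0])
        for tree in self.tree_arrays():
            left = np.asarray(tree["children_left"])
            right = np.asarray(tree["children_right"])
            feat = np.asarray(tree["feature"])
            thr = np.asarray(tree["threshold"])
            sizes = np.asarray(tree["n_node_samples"])
            for i, row in enumerate(X):
                node, edges = 0, 0
                while left[node] != -1:
                    node = left[node] if row[feat[node]] <= thr[node] else right[node]
                    edges += 1
                depths[i] += edges + _average_path_length(
                    np.array([sizes[node]])
                )[0]
        denom = self.n_trees * _average_path_length(np.array([self.max_samples]))[0]
        return np.power(2.0, -depths / denom)

    def to_json(self) -> str:
        return json.dumps(
            {
                "psi": self.psi,
                "height_limit": self.height_limit,
                "n_trees": self.n_trees,
                "max_samples": self.max_samples,
                "feature_names": self.feature_names,
                "cutoff": self.cutoff,
                "trees": self.tree_arrays(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "OutlierModel":
        d = json.loads(text)
        return cls(
            psi=d["psi"],
            height_limit=d["height_limit"],
            n_trees=d["n_trees"],
            feature_names=list(d["feature_names"]),
            max_samples=d["max_samples"],
            cutoff=d["cutoff"],
            forest=None,
            trees=d["trees"],
        )


def fit_iforest(
    train: FeatureTable,
    psi: int = 256,
    height_limit: int | None = None,
    n_trees: int = 100,
    seed: int = 0,
) -> OutlierModel:
    """Fit an isolation forest on the training partition (labels unused).

    Each of the ``n_trees`` trees grows on a uniform subsample of
    min(psi, n) rows with random split features and uniform random split
    values, stopping at height ceil(log2 psi) or at singleton nodes.
    """
    if train.n_subjects < 1:
        raise OutlierError("cannot fit an isolation forest on an empty table")
    if psi < 2:
        raise OutlierError("sub-sampling size psi must be >= 2")
    max_samples = min(psi, train.n_subjects)
    implied_limit = int(math.ceil(math.log2(max(max_samples, 2))))
    if height_limit is not None and height_limit != implied_limit:
        raise OutlierError(
            f"height limit {height_limit} inconsistent with psi={psi} "
            f"(the forest grows to ceil(log2 psi) = {implied_limit})"
        )
    forest = IsolationForest(
        n_estimators=n_trees,
        max_samples=max_samples,
        random_state=seed,
    ).fit(train.features.to_numpy())
    return OutlierModel(
        psi=psi,
        height_limit=implied_limit,
        n_trees=n_trees,
        feature_names=train.feature_names,
        max_samples=int(forest.max_samples_),
        forest=forest,
    )


def score_outliers(model: OutlierModel, table: FeatureTable) -> np.ndarray:
    """Anomaly scores in (0, 1]; higher means more isolated."""
    if table.feature_names != model.feature_names:
        raise OutlierError("feature names do not match the fitted outlier model")
    X = table.features.to_numpy()
    if model.forest is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return -model.forest.score_samples(X)
    return model.manual_scores(X)


def tukey_cutoff(scores) -> float:
    """Far-out Tukey fence Q3 + 3*(Q3 - Q1), linear-interpolation quantiles."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 4:
        raise OutlierError("need at least 4 scores for a quartile-based cutoff")
    q1, q3 = np.quantile(scores, [0.25, 0.75])
    return float(q3 + 3.0 * (q3 - q1))


def filter_outliers(
    table: FeatureTable, scores, threshold: float
) -> tuple[FeatureTable, FeatureTable]:
    """Split into (kept, removed); removed rows score strictly above cutoff."""
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (table.n_subjects,):
        raise OutlierError("scores are not aligned with the table rows")
    removed_mask = scores > threshold
    return table.where(~removed_mask), table.where(removed_mask)


def fit_outlier_stage(
    train: FeatureTable,
    psi: int = 256,
    n_trees: int = 100,
    seed: int = 0,
) -> tuple[OutlierModel, np.ndarray]:
    """Fit forest + Tukey cutoff on training data; returns (model, scores)."""
    model = fit_iforest(train, psi=psi, n_trees=n_trees, seed=seed)
    scores = score_outliers(model, train)
    model.cutoff = tukey_cutoff(scores)
    return model, scores
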