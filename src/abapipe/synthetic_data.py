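"""Synthetic cohorts with the structure the ABA method assumes.

The generator emulates multi-site AD/CN morphometry tables: per-stratum
(gender x cohort x group) subject counts with truncated-normal age
distributions, features that decline linearly with age, AD-accelerated
atrophy concentrated in a small informative subset of regions, pure-noise
features, and optional planted outlier records.

Generative model (linear-Gaussian by design, so that parameter recovery by
the downstream linear pipeline is analyzable):

    effective_age(s) = age(s) + acceleration * 1[group(s) == AD]
    feature_j(s)     = baseline_j - slope_j * effective_age(s) + eps,   eps ~ N(0, noise_sd^2)

Features split into three kinds:

* AD-informative: nonzero ageing slope *and* the AD acceleration applies —
  these are the ground-truth set a biased feature selector should recover;
* age-only: the same ageing slope but no AD acceleration — informative
  about age, useless (given age) for the diagnosis;
* noise: independent of age and diagnosis.

:func:`bayes_reference` computes the exact posterior P(AD | features, age)
under this model, giving an oracle accuracy that upper-bounds any pipeline
run on the generated table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .io_features import FeatureTable, METADATA_COLUMNS


@dataclass(frozen=True)
class Stratum:
    gender: str
    cohort: str
    group: str
    n: int
    age_mean: float
    age_sd: float
    age_min: float
    age_max: float


@dataclass(frozen=True)
class CohortConfig:
    """Full description of one synthetic cohort draw.

    ``slope`` is the decline per year of effective age (units/year) shared
    by the AD-informative and age-only features; ``acceleration`` is the
    extra effective ageing (years) applied to AD subjects on the
    AD-informative features only.  ``n_outliers`` subjects have their whole
    feature vector displaced by ``outlier_magnitude`` noise standard
    deviations per feature.
    """

    strata: tuple[Stratum, ...]
    n_features: int = 100
    ad_informative: int = 5
    age_only: int = 15
    slope: float = 0.03
    acceleration: float = 8.0
    noise_sd: float = 0.21
    baseline_mean: float = 3.0
    baseline_spread: float = 0.5
    n_outliers: int = 0
    outlier_magnitude: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s.n < 0 for s in self.strata):
            raise ValueError("stratum counts must be non-negative")
        if any(s.age_sd <= 0 for s in self.strata):
            raise ValueError("stratum age sd must be positive")
        if any(s.age_min >= s.age_max for s in self.strata):
            raise ValueError("infeasible age truncation bounds")
        if self.ad_informative + self.age_only > self.n_features:
            raise ValueError("informative feature counts exceed n_features")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_outliers > self.n_subjects:
            raise ValueError("more outliers requested than subjects")

    @property
    def n_subjects(self) -> int:
        return sum(s.n for s in self.strata)

    @property
    def ad_fraction(self) -> float:
        n_ad = sum(s.n for s in self.strata if s.group == "AD")
        return n_ad / self.n_subjects


@dataclass(frozen=True)
class GroundTruth:
    """Generator-side truth for parameter-recovery tests."""

    informative_features: tuple[str, ...]
    age_only_features: tuple[str, ...]
    effective_age: pd.Series  # indexed by subject_id
    outlier_ids: tuple[str, ...]

    def to_json(self) -> str:
        return json.dumps(
            {
                "informative_features": list(self.informative_features),
                "age_only_features": list(self.age_only_features),
                "effective_age": {k: float(v) for k, v in self.effective_age.items()},
                "outlier_ids": list(self.outlier_ids),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            informative_features=tuple(d["informative_features"]),
            age_only_features=tuple(d["age_only_features"]),
            effective_age=pd.Series(d["effective_age"], dtype=float),
            outlier_ids=tuple(d["outlier_ids"]),
        )


def feature_names(config: CohortConfig) -> list[str]:
    """Deterministic feature naming; alternating lh_/rh_ hemisphere tags."""
    return [
        f"{'lh' if j % 2 == 0 else 'rh'}_roi_{j:03d}" for j in range(config.n_features)
    ]


def feature_parameters(config: CohortConfig):
    """Reproducible per-feature (baseline, slope, acceleration) arrays.

    Drawn from a dedicated seed-sequence child so that
    :func:`bayes_reference` can re-derive them without the table.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    p = config.n_features
    baselines = config.baseline_mean + config.baseline_spread * rng.uniform(-1, 1, p)
    slopes = np.zeros(p)
    accels = np.zeros(p)
    slopes[: config.ad_informative + config.age_only] = config.slope
    accels[: config.ad_informative] = config.acceleration
    return baselines, slopes, accels


def _truncnorm_ages(stratum: Stratum, rng: np.random.Generator) -> np.ndarray:
    a = (stratum.age_min - stratum.age_mean) / stratum.age_sd
    b = (stratum.age_max - stratum.age_mean) / stratum.age_sd
    return stats.truncnorm.rvs(
        a, b, loc=stratum.age_mean, scale=stratum.age_sd, size=stratum.n,
        random_state=rng,
    )


def generate_cohort(config: CohortConfig) -> tuple[FeatureTable, GroundTruth]:
    """Draw one cohort; identical seeds give byte-identical tables."""
    ss = np.random.SeedSequence([config.seed, 0])
    age_rng, noise_rng, outlier_rng = (
        np.random.default_rng(c) for c in ss.spawn(3)
    )
    baselines, slopes, accels = feature_parameters(config)
    names = feature_names(config)

    meta_rows = []
    ages = []
    for stratum in config.strata:
        stratum_ages = _truncnorm_ages(stratum, age_rng)
        for age in stratum_ages:
            meta_rows.append((stratum.gender, stratum.cohort, stratum.group))
            ages.append(age)
    n = len(ages)
    ages = np.asarray(ages)
    gender, cohort, group = (np.array(col) for col in zip(*meta_rows)) if n else (
        np.array([]), np.array([]), np.array([]))
    subject_ids = np.array([f"SUB-{i:05d}" for i in range(n)])
    is_ad = group == "AD"
    # ground-truth "effective brain age": chronological age plus the planted
    # acceleration for AD subjects (applied per-feature only on AD-informative
    # columns below)
    eff = ages.copy()
    eff[is_ad] += config.acceleration
    X = baselines[None, :] + noise_rng.normal(0.0, config.noise_sd, size=(n, config.n_features))
    per_feature_eff = ages[:, None] + np.outer(is_ad.astype(float), (accels > 0).astype(float)) * config.acceleration
    X -= slopes[None, :] * per_feature_eff

    outlier_ids: tuple[str, ...] = ()
    if config.n_outliers:
        idx = outlier_rng.choice(n, size=config.n_outliers, replace=False)
        signs = outlier_rng.choice([-1.0, 1.0], size=(config.n_outliers, config.n_features))
        X[idx] += signs * config.outlier_magnitude * config.noise_sd
        outlier_ids = tuple(subject_ids[np.sort(idx)])

    meta = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "gender": gender,
            "age": ages,
            "group": group,
            "cohort": cohort,
        },
        columns=list(METADATA_COLUMNS),
    )
    features = pd.DataFrame(X, columns=names)
    table = FeatureTable(meta, features)
    truth = GroundTruth(
        informative_features=tuple(np.array(names)[accels > 0]),
        age_only_features=tuple(
            np.array(names)[(slopes > 0) & (accels == 0)]
        ),
        effective_age=pd.Series(eff, index=subject_ids),
        outlier_ids=outlier_ids,
    )
    return table, truth


# ---------------------------------------------------------------------------
# Bayes reference
# ---------------------------------------------------------------------------

def bayes_reference(config: CohortConfig, table: FeatureTable) -> np.ndarray:
    """Exact posterior P(AD | features, age) under the generative model.

    Only the AD-informative features carry diagnostic evidence given age
    (age-only and noise features have identical class-conditional laws), so
    the log likelihood ratio reduces to a Gaussian mean-shift test on those
    columns.  The class prior is the overall AD fraction of the config;
    gender and cohort tags are deliberately not used as evidence.
    """
    if table.feature_names != feature_names(config):
        raise ValueError("table feature names do not match this config")
    if table.n_subjects != config.n_subjects:
        raise ValueError("table size does not match this config")
    baselines, slopes, accels = feature_parameters(config)
    informative = accels > 0
    x = table.features.to_numpy()[:, informative]
    b = baselines[informative]
    s = slopes[informative]
    a = accels[informative]
    age = table.ages[:, None]
    mu_cn = b[None, :] - s[None, :] * age
    mu_ad = b[None, :] - s[None, :] * (age + a[None, :])
    var = config.noise_sd ** 2
    loglr = ((x - mu_cn) ** 2 - (x - mu_ad) ** 2).sum(axis=1) / (2.0 * var)
    prior = config.ad_fraction
    log_odds = loglr + np.log(prior) - np.log1p(-prior)
    return special.expit(log_odds)


def bayes_closed_form_accuracy(config: CohortConfig) -> float:
    """Closed-form oracle accuracy for the equal-covariance Gaussian model.

    With k AD-informative features of slope s, acceleration A and noise sd
    sigma, the two class-conditional feature laws (given age) are Gaussians
    separated by Mahalanobis distance d = A * s * sqrt(k) / sigma; the
    Bayes rule with prior odds rho = pi_CN / pi_AD then has accuracy
    pi_AD * Phi(d/2 - ln(rho)/d) + pi_CN * Phi(d/2 + ln(rho)/d).
    """
    _, slopes, accels = feature_parameters(config)
    informative = accels > 0
    d = np.sqrt(np.sum((accels[informative] * slopes[informative]) ** 2)) / config.noise_sd
    pi_ad = config.ad_fraction
    if d == 0:
        return max(pi_ad, 1 - pi_ad)
    log_rho = np.log((1 - pi_ad) / pi_ad)
    return float(
        pi_ad * stats.norm.cdf(d / 2 - log_rho / d)
        + (1 - pi_ad) * stats.norm.cdf(d / 2 + log_rho / d)
    )


# ---------------------------------------------------------------------------
# Stock configurations
# ---------------------------------------------------------------------------

_TABLE1_ROWS = [
    # gender, cohort, group, n, mean, sd, min, max
    ("M", "ADNI", "AD", 213, 75.82, 7.86, 55.3, 90.4),
    ("M", "ADNI", "CN", 317, 74.2, 6.36, 56.2, 90.3),
    ("M", "AIBL", "AD", 34, 74.65, 9.07, 58.0, 89.4),
    ("M", "AIBL", "CN", 207, 74.36, 7.83, 54.6, 89.8),
    ("M", "IXI", "CN", 90, 65.5, 7.27, 55.09, 86.2),
    ("F", "ADNI", "AD", 177, 74.29, 8.07, 55.2, 91.0),
    ("F", "ADNI", "CN", 398, 72.1, 6.24, 55.6, 89.9),
    ("F", "AIBL", "AD", 45, 75.27, 7.81, 56.3, 88.4),
    ("F", "AIBL", "CN", 277, 74.44, 7.31, 55.2, 88.0),
    ("F", "IXI", "CN", 143, 65.1, 6.31, 55.22, 86.32),
]

# The 1,000-subject default fixture keeps the demographic proportions of the
# 1,901-subject reference cohort (scaled per stratum, rounded).
_FIXTURE_COUNTS = [112, 167, 18, 109, 47, 93, 209, 24, 146, 75]


def table1_strata() -> tuple[Stratum, ...]:
    """The reference multi-site demographic composition (1,901 subjects)."""
    return tuple(Stratum(*row) for row in _TABLE1_ROWS)


def table1_config(seed: int = 0, **overrides) -> CohortConfig:
    return CohortConfig(strata=table1_strata(), seed=seed, **overrides)


def default_fixture_config(seed: int = 42, **overrides) -> CohortConfig:
    """1,000 subjects, 5 AD-informative + 15 age-only + 80 noise features."""
    strata = tuple(
        Stratum(*row[:3], n, *row[4:])
        for row, n in zip(_TABLE1_ROWS, _FIXTURE_COUNTS)
    )
    params = dict(
        n_features=100,
        ad_informative=5,
        age_only=15,
        slope=0.03,
        acceleration=8.0,
        noise_sd=0.21,
        n_outliers=0,
        seed=seed,
    )
    params.update(overrides)
    return CohortConfig(strata=strata, **params)


def contamination_config(seed: int = 7, **overrides) -> CohortConfig:
    """800 clean records plus 20 planted outliers, for outlier-stage tests."""
    strata = (
        Stratum("M", "synthetic", "AD", 205, 75.0, 7.5, 55.0, 91.0),
        Stratum("M", "synthetic", "CN", 615, 73.5, 7.0, 55.0, 91.0),
    )
    params = dict(
        n_features=100,
        ad_informative=5,
        age_only=15,
        n_outliers=20,
        outlier_magnitude=10.0,
        seed=seed,
    )
    params.update(overrides)
    return CohortConfig(strata=strata, **params)
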