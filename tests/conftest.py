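import numpy as np
import pandas as pd
import pytest

from abapipe import (
    CohortConfig,
    PipelineConfig,
    Stratum,
    bayes_reference,
    contamination_config,
    default_fixture_config,
    generate_cohort,
    repeated_cv,
)
from abapipe.io_features import FeatureTable
from abapipe.outlier_detection import fit_outlier_stage


def make_table(
    n=10,
    p=3,
    seed=0,
    genders=None,
    groups=None,
    ages=None,
    cohort="synthetic",
    feature_values=None,
):
    """Hand-rolled small FeatureTable for unit tests."""
    rng = np.random.default_rng(seed)
    if genders is None:
        genders = ["M" if i % 2 == 0 else "F" for i in range(n)]
    if groups is None:
        groups = ["AD" if i % 3 == 0 else "CN" for i in range(n)]
    if ages is None:
        ages = 60.0 + 25.0 * rng.random(n)
    meta = pd.DataFrame(
        {
            "subject_id": [f"S{i:03d}" for i in range(n)],
            "gender": genders,
            "age": ages,
            "group": groups,
            "cohort": [cohort] * n,
        }
    )
    if feature_values is None:
        feature_values = rng.normal(size=(n, p))
    features = pd.DataFrame(
        np.asarray(feature_values, dtype=float),
        columns=[f"f{j}" for j in range(np.asarray(feature_values).shape[1])],
    )
    return FeatureTable(meta, features)


@pytest.fixture
def toy_table():
    return make_table(n=10, p=3, seed=1)


@pytest.fixture(scope="session")
def fixture_cohort():
    """The default synthetic study cohort: 1,000 subjects, 100 features."""
    cfg = default_fixture_config(seed=42)
    table, truth = generate_cohort(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def small_cohort():
    """A small, strong-effect cohort for fast pipeline tests."""
    strata = (
        Stratum("M", "synthetic", "AD", 40, 75.0, 7.5, 55.0, 91.0),
        Stratum("M", "synthetic", "CN", 80, 73.5, 7.0, 55.0, 91.0),
        Stratum("F", "synthetic", "AD", 40, 74.5, 7.8, 55.0, 91.0),
        Stratum("F", "synthetic", "CN", 80, 73.0, 6.8, 55.0, 91.0),
    )
    cfg = CohortConfig(
        strata=strata,
        n_features=20,
        ad_informative=3,
        age_only=5,
        slope=0.03,
        acceleration=10.0,
        noise_sd=0.2,
        seed=11,
    )
    table, truth = generate_cohort(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def contamination():
    """820 records with 20 planted outliers, plus the fitted outlier stage."""
    cfg = contamination_config(seed=7)
    table, truth = generate_cohort(cfg)
    model, scores = fit_outlier_stage(table, seed=7)
    return cfg, table, truth, model, scores


@pytest.fixture(scope="session")
def cv_runs(fixture_cohort):
    """Scaled-down repeated CV of the full (M6) and no-selection (M5)
    pipeline variants on the default cohort, plus the Bayes yardstick."""
    cfg, table, truth = fixture_cohort
    m6 = repeated_cv(table, PipelineConfig(seed=1), folds=5, repeats=2)
    m5 = repeated_cv(
        table, PipelineConfig(seed=1, use_ffs=False), folds=5, repeats=2
    )
    posterior = bayes_reference(cfg, table)
    bayes_acc = 100.0 * float(
        np.mean((posterior >= 0.5) == (table.labels == 1))
    )
    return {"m6": m6, "m5": m5, "bayes_accuracy": bayes_acc}
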