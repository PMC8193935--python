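"""YAML configuration for pipeline and cohort-generation parameters."""

from __future__ import annotations

from pathlib import Path

import yaml

from .evaluation import PipelineConfig
from .feature_selection import SelectionConfig
from .synthetic_data import CohortConfig, Stratum, default_fixture_config


def pipeline_config_from_yaml(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML mapping.

    Recognised keys mirror the dataclass fields; ``selection`` may be a
    nested mapping with SelectionConfig fields.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sel = SelectionConfig(**raw.pop("selection", {}))
    return PipelineConfig(selection=sel, **raw)


def cohort_config_from_yaml(path) -> CohortConfig:
    """Build a CohortConfig from YAML; ``strata`` is a list of mappings."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    strata = tuple(Stratum(**s) for s in raw.pop("strata"))
    return CohortConfig(strata=strata, **raw)


def cohort_config_to_yaml(config: CohortConfig, path) -> None:
    payload = {
        "strata": [vars(s) for s in config.strata],
        **{
            k: getattr(config, k)
            for k in (
                "n_features", "ad_informative", "age_only", "slope",
                "acceleration", "noise_sd", "baseline_mean", "baseline_spread",
                "n_outliers", "outlier_magnitude", "seed",
            )
        },
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
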