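import numpy as np
import pytest

from burnskin.classify import classify_cohort
from burnskin.pipeline import build_feature_table
from burnskin.synthetic import SyntheticCohortConfig, generate_cohort
from burnskin.univariate import outlier_screen


@pytest.fixture(scope="session")
def small_cohort():
    """Small three-class cohort with its truth table (fast, deterministic)."""
    config = SyntheticCohortConfig(n_per_class=(8, 8, 8), seed=42)
    records, truth = generate_cohort(config)
    return config, records, truth


@pytest.fixture(scope="session")
def null_cohort_reports():
    """Screened feature tables and LOOCV reports for 20 null cohorts.

    The study conditions: rate_effect = 0, n = 95/92/102, quartile-calibrated
    parameter laws, 3% stress noise.  Shared across the acceptance tests
    that look at fit adequacy, accuracy and MCC.
    """
    tables, reports = [], []
    for seed in range(20):
        records, _ = generate_cohort(SyntheticCohortConfig(seed=seed))
        features = build_feature_table(records)
        kept, _ = outlier_screen(features)
        tables.append((features, kept))
        reports.append(classify_cohort(kept))
    return tables, reports


def lognormal_sample(rng: np.random.Generator, loc: float, scale: float, n: int):
    return np.exp(loc + scale * rng.standard_normal(n))
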