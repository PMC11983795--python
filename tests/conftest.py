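import warnings

import numpy as np
import pandas as pd
import pytest

import epiperf as ep
from epiperf.reporting import build_all_analysis_sets


@pytest.fixture(scope="session")
def default_config():
    return ep.SimulationConfig(seed=42)


@pytest.fixture(scope="session")
def default_population(default_config):
    return ep.simulate_population(default_config)


@pytest.fixture(scope="session")
def clean_population(default_population):
    clean, _ = ep.apply_global_qc(default_population)
    return clean


@pytest.fixture(scope="session")
def analysis_sets(clean_population):
    return build_all_analysis_sets(clean_population, ("hannum", "cystatin_c", "lymphocytes"))


def make_clean_config(seed=0, group_sizes=None, predictors=("hannum",), rho=None, bias=None):
    """A defect-free config (no topcoding, mismatches, outliers, or missing)."""
    return ep.SimulationConfig(
        seed=seed,
        group_sizes=group_sizes or {"NH White": 400, "NH Black": 400, "Mexican American": 400},
        n_topcoded=0,
        n_sex_mismatch=0,
        n_outliers={},
        missingness={},
        predictors=predictors,
        target_correlation=rho,
        prediction_bias=bias,
    )


def brute_pearson(x, y):
    """Direct product-moment formula with explicit loops (test oracle)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sxx = syy = 0.0
    for i in range(n):
        sxy += (x[i] - mx) * (y[i] - my)
        sxx += (x[i] - mx) ** 2
        syy += (y[i] - my) ** 2
    return sxy / (sxx * syy) ** 0.5


def brute_median(values):
    """Sort-based median with explicit midpoint rule (test oracle)."""
    s = sorted(values)
    n = len(s)
    if n % 2 == 1:
        return s[n // 2]
    return 0.5 * (s[n // 2 - 1] + s[n // 2])


def make_analysis_set(frame, predictor="hannum"):
    """Wrap a prepared phenotype/prediction frame as an AnalysisSet."""
    from epiperf.qc_conversions import AnalysisSet, QCReport, spec_by_name

    return AnalysisSet(spec=spec_by_name(predictor), frame=frame, report=QCReport())
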