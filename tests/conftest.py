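import warnings

import numpy as np
import pandas as pd
import pytest

import recombage as r

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_cohorts():
    """Scaled-down replica of the default nine-cohort structure."""
    return r.default_cohort_specs(scale=0.15)


@pytest.fixture(scope="session")
def nb_meioses(small_cohorts):
    """Negative-binomial synthetic meioses under the default conditions."""
    params = r.default_generative_params(small_cohorts)
    table, truth = r.simulate_cohorts(small_cohorts, params, seed=20210705)
    return table, truth, params


@pytest.fixture(scope="session")
def normal_meioses(small_cohorts):
    params = r.default_generative_params(small_cohorts, model_family="normal")
    table, truth = r.simulate_cohorts(small_cohorts, params, seed=20210705)
    return table, truth, params


def make_meioses(rows) -> pd.DataFrame:
    """Hand-built meiosis table from (cohort, family, parent, child, sex,
    age, configuration, count) tuples."""
    return pd.DataFrame(rows, columns=[
        "cohort", "family_id", "parent_id", "child_id", "parent_sex",
        "parent_age_years", "configuration", "n_crossovers"])


def make_calls(rows) -> pd.DataFrame:
    """Hand-built call table from (cohort, parent, child, chrom, start, end,
    prob, left_idx, right_idx) tuples."""
    return pd.DataFrame(rows, columns=[
        "cohort", "parent_id", "child_id", "chrom", "start_bp", "end_bp",
        "posterior_prob", "left_snp_index", "right_snp_index"])


@pytest.fixture(scope="session")
def sbc_template():
    """Tiny normal-model template for calibration runs."""
    from recombage.hierarchical import HierarchicalCrossoverModel, ModelSpec

    specs = [r.CohortSpec(f"C{i}", {2: 10, 6: 3}) for i in range(2)]
    params = r.default_generative_params(specs, model_family="normal")
    m, _ = r.simulate_cohorts(specs, params, seed=11)
    return HierarchicalCrossoverModel(m, ModelSpec("M1"))
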