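import warnings

import numpy as np
import pytest

import kitlink as kl

warnings.filterwarnings("ignore", message="dropping zero-variance covariates")


@pytest.fixture(scope="session")
def small_cohort():
    """One modest MRL-calibrated cohort shared across read-only tests."""
    scenario = kl.preset_mrl(n_cells=1500, n_genes=1200, seed=2)
    matrix, hto, contigs, truth = kl.simulate_cohort(scenario)
    return {"scenario": scenario, "matrix": matrix, "hto": hto,
            "contigs": contigs, "truth": truth}


@pytest.fixture(scope="session")
def small_norm(small_cohort):
    """QC-filtered + log-normalized view of the shared cohort."""
    mq, report = kl.qc_filter(small_cohort["matrix"])
    norm = kl.log_normalize(mq)
    return {"matrix": mq, "norm": norm, "qc_report": report,
            "truth": small_cohort["truth"].df.loc[mq.barcodes]}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
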