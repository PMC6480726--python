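import numpy as np
import pytest

from benchnmr import chemometrics as chem
from benchnmr import cohort as coh
from benchnmr import quantify as quant
from benchnmr.preprocess import baseline_correct
from benchnmr.spin import AcquisitionConfig


@pytest.fixture(scope="session")
def config60():
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def noise_free60():
    return AcquisitionConfig(noise_sigma=0.0)


@pytest.fixture(scope="session")
def bucket_table():
    return quant.default_bucket_table()


def _quantified_cohort(seed, bucket_table):
    """One cohort replicate: raw + TSP-normalised matrices and labels."""
    spectra, truth = coh.generate_cohort(seed=seed)
    spectra = [baseline_correct(s) for s in spectra]
    fm = quant.bucket_feature_matrix(spectra, bucket_table)
    tsp = [quant.integrate_bucket(s, *quant.TSP_BUCKET) for s in spectra]
    fm_tsp = quant.tsp_normalize_matrix(fm, tsp)
    groups = np.asarray(fm.attrs["groups"])
    return fm, fm_tsp, groups, truth


@pytest.fixture(scope="session")
def cohort_replicates(bucket_table):
    """Six quantified cohort replicates, shared across the statistics tests."""
    return [_quantified_cohort(seed, bucket_table) for seed in range(6)]


@pytest.fixture(scope="session")
def transformed_replicates(cohort_replicates):
    out = []
    for _fm, fm_tsp, groups, _truth in cohort_replicates:
        tr = chem.pareto_scale(chem.glog_transform(fm_tsp))
        out.append((tr, groups))
    return out
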