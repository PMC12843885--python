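"""Shared fixtures: small synthetic worlds generated at test time."""

import warnings

import numpy as np
import pandas as pd
import pytest

from teametab.binning import FeatureMatrix
from teametab.mzml import CentroidScan
from teametab.synthetic import green_config, simulate_dataset

warnings.filterwarnings("ignore", message="ppm_jitter")


@pytest.fixture(scope="session")
def rules():
    from teametab.formulas import load_adduct_rules

    return load_adduct_rules()


@pytest.fixture(scope="session")
def rule_map(rules):
    return {r.name: r for r in rules}


@pytest.fixture
def tiny_matrix():
    """4 features x 4 samples with hand-set intensities."""
    values = pd.DataFrame(
        {
            "s1": [100.0, 0.0, 5.0, 1.0],
            "s2": [110.0, 0.0, 0.0, 2.0],
            "s3": [90.0, 0.0, 0.0, 3.0],
            "s4": [0.0, 0.0, 6.0, 4.0],
        },
        index=["n100.00", "n200.00", "p300.00", "p400.00"],
    )
    info = pd.DataFrame(
        {
            "polarity": ["negative", "negative", "positive", "positive"],
            "bin_mz": [100.0, 200.0, 300.0, 400.0],
            "accurate_mz": [100.0005, 200.001, 300.0008, 400.0011],
        },
        index=values.index,
    )
    return FeatureMatrix(values=values, feature_info=info, provenance={"filters": []})


@pytest.fixture(scope="session")
def small_dataset():
    """A coherent small green-tea world used by several test modules."""
    cfg = green_config(
        11,
        n_features=150,
        n_informative=30,
        n_trend_clusters=3,
        n_compounds=80,
        noise_sigma=0.1,
        ppm_jitter=0.0,
        trend_amplitude=1.0,
    )
    return simulate_dataset(cfg)


def make_scan(polarity, scan_index, peaks):
    mz = np.array([p[0] for p in peaks], dtype=float)
    inten = np.array([p[1] for p in peaks], dtype=float)
    return CentroidScan(polarity=polarity, scan_index=scan_index, mz=mz, intensity=inten)
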