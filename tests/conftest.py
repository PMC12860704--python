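import warnings

import numpy as np
import pandas as pd
import pytest

from lipidstat.annotation import annotate_panel, parse_lipid_name
from lipidstat.core import AbundanceMatrix
from lipidstat.preprocess import run_preprocessing
from lipidstat.quantify import normalize_matrix, quantify_matrix
from lipidstat.synth import StudyConfig, generate_study


def make_matrix(values, feature_names=None, groups=None, tissue="PMphi", stage="normalized"):
    """Small AbundanceMatrix from a 2-D array for unit tests."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    feature_names = feature_names or [f"PC({30 + 2 * i}:0)" for i in range(n_feat)]
    groups = groups or ["CTL"] * (n_samp // 2) + ["CKD"] * (n_samp - n_samp // 2)
    sids = [f"{g}{i:02d}" for i, g in enumerate(groups)]
    samples = pd.DataFrame(
        {
            "group": groups,
            "tissue": [tissue] * n_samp,
            "protein_mass": [100.0] * n_samp if tissue != "plasma" else [np.nan] * n_samp,
            "volume": [50.0] * n_samp if tissue == "plasma" else [np.nan] * n_samp,
        },
        index=pd.Index(sids, name="sample_id"),
    )
    data = pd.DataFrame(values, index=feature_names, columns=sids)
    return AbundanceMatrix(data=data, samples=samples, stage=stage)


def process_bundle(bundle, tissue="PMphi"):
    """Quantify -> normalise -> full preprocessing for one tissue."""
    td = bundle.tissues[tissue]
    cls = {n: parse_lipid_name(n).class_code for n in td.peaks.feature_names}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        conc = quantify_matrix(td.peaks, td.standards, cls)
        return run_preprocessing(normalize_matrix(conc))


@pytest.fixture(scope="session")
def small_study():
    """A compact two-tissue study with the default programmed structure."""
    cfg = StudyConfig(
        seed=7,
        n_per_group=10,
        panel={"FFA": 16, "PC": 20, "TAG": 30, "DAG": 10, "PG": 8, "PE": 12,
               "SM": 10, "AC": 29},
    )
    return generate_study(cfg)


@pytest.fixture(scope="session")
def small_zscore(small_study):
    return process_bundle(small_study, "PMphi")


@pytest.fixture(scope="session")
def small_annotation(small_zscore):
    return annotate_panel(small_zscore.feature_names)
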