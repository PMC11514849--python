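import numpy as np
import pandas as pd
import pytest

import mgomics as mg


@pytest.fixture(scope="session")
def small_config():
    return mg.CohortConfig(
        n_patients=30,
        n_batches=8,
        n_proteins=80,
        n_phosphosites=40,
        n_genes=40,
        n_hypermutators=2,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return mg.simulate_cohort(small_config)


@pytest.fixture(scope="session")
def cohort_dir(small_bundle, tmp_path_factory):
    d = tmp_path_factory.mktemp("cohort")
    mg.write_cohort(small_bundle, d)
    return d


def clean_batches(paths, kind="protein"):
    mats = []
    for p in sorted(paths):
        t = mg.read_quant_table(p, kind=kind)
        t = mg.filter_features(t)
        t = mg.scale_total_intensity(t)
        mats.append(mg.bridge_to_is(t))
    return mg.combine_batches(mats)


@pytest.fixture(scope="session")
def protein_matrix(cohort_dir):
    m = clean_batches(cohort_dir.glob("proteome_batch*.tsv"), "protein")
    return mg.dual_zscore(mg.filter_missing(m))


@pytest.fixture(scope="session")
def phospho_matrix(cohort_dir):
    m = clean_batches(cohort_dir.glob("phospho_batch*.tsv"), "phospho")
    return mg.dual_zscore(mg.filter_missing(m))


@pytest.fixture(scope="session")
def mg_content(small_bundle):
    c = small_bundle.clinical
    return dict(zip(c["tumor_sample"], c["mg_content"]))


def make_matrix(values: np.ndarray, stage="log2", features=None, samples=None):
    """Hand-built ExpressionMatrix for unit tests."""
    values = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=features, columns=samples)
    return mg.ExpressionMatrix(values=df, stage=stage,
                               batch_map={s: "b1" for s in samples})
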