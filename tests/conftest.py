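import numpy as np
import pytest

from desimilk.annotation import load_marker_table
from desimilk.preprocess import build_feature_matrix, scale_matrix, tic_normalize
from desimilk.simulate import pure_study_config, simulate_study


@pytest.fixture(scope="session")
def marker_table():
    return load_marker_table()


@pytest.fixture(scope="session")
def study():
    """One scaled-down synthetic study shared across the suite."""
    cfg = pure_study_config(seed=11, scale=0.12, mixture_samples_per_level=3)
    records, truth = simulate_study(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def pure_records(study):
    _, records, _ = study
    return [r for r in records if not r.sample_id.startswith("mix_")]


@pytest.fixture(scope="session")
def mixture_records(study):
    _, records, _ = study
    return {
        base: [r for r in records if r.sample_id.startswith(f"mix_{base}_")]
        for base in ("goat", "camel", "oat", "soya")
    }


@pytest.fixture(scope="session")
def species_matrix(pure_records):
    """Per-spectrum classification matrix: TIC-normalised, Pareto-scaled."""
    fm = build_feature_matrix(pure_records, per_spectrum=True)
    return scale_matrix(tic_normalize(fm), "pareto")


@pytest.fixture(scope="session")
def sample_matrix(pure_records):
    """Per-sample marker-selection matrix: raw counts, Pareto-scaled."""
    fm = build_feature_matrix(pure_records, per_spectrum=False)
    return scale_matrix(fm, "pareto")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
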