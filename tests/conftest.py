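import numpy as np
import pytest

from edcscan.synthetic_edc import ClusterConfig, generate_cluster
from edcscan.pipeline import annotate_species, species_input_from_truth


@pytest.fixture(scope="session")
def null_cluster():
    """Intact (lesion-free) synthetic cluster plus its truth table."""
    cfg = ClusterConfig(seed=101, n_sedc=5, n_sftp=2, lce_array_size=6, lesion_rate=0.0)
    scaffold, truth, genealogy = generate_cluster(cfg)
    return cfg, scaffold, truth, genealogy


@pytest.fixture(scope="session")
def lesioned_cluster():
    cfg = ClusterConfig(seed=202, n_sedc=6, n_sftp=2, lce_array_size=6, lesion_rate=0.4)
    scaffold, truth, genealogy = generate_cluster(cfg)
    return cfg, scaffold, truth, genealogy


@pytest.fixture(scope="session")
def null_annotation(null_cluster):
    cfg, scaffold, truth, _ = null_cluster
    inp = species_input_from_truth(scaffold, truth, "self", cfg.anchor_names)
    return annotate_species(inp)


@pytest.fixture(scope="session")
def lesioned_annotation(lesioned_cluster):
    cfg, scaffold, truth, _ = lesioned_cluster
    inp = species_input_from_truth(scaffold, truth, "self", cfg.anchor_names)
    return annotate_species(inp)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
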