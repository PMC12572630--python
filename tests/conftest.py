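import numpy as np
import pytest

from mimiclens.synthetic_wings import TaxonTemplate, generate_dataset
from mimiclens.taxa import designed_pair_templates


def spot_count_templates(jitter: bool = False) -> list[TaxonTemplate]:
    """Five taxa whose only strong differences are spot counts 0-4."""
    var = ({"ground_color": 4.0, "shape": 0.02} if jitter else {})
    return [TaxonTemplate(taxon_id=f"taxon_{k}", group="model",
                          regions={"r"}, n_white_spots=k, variability=var)
            for k in range(5)]


@pytest.fixture(scope="session")
def five_taxon_dataset():
    """30 specimens over the five spot-count taxa (session-cached)."""
    return generate_dataset(spot_count_templates(jitter=True), 6, seed=42)


@pytest.fixture(scope="session")
def designed_dataset():
    """Mimic/model designed-partner fixture, 4 specimens per taxon."""
    return generate_dataset(designed_pair_templates(), 4, seed=7)


def three_cluster_features(seed: int, n_per: int = 20):
    """Three well-separated Gaussian clusters in 3D with labels."""
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0.0, 0.5, (n_per, 3)) + np.eye(3)[i] * 8.0
                   for i in range(3)])
    return X, np.repeat(np.arange(3), n_per)
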