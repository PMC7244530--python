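import numpy as np
import pytest

from patternspectra import inference, synth
from patternspectra.pipeline import (
    DEFAULT_HABITAT_SLOPES,
    DEFAULT_SPECIES_HABITAT,
    DEFAULT_TREE_NEWICK,
)


@pytest.fixture(scope="session")
def default_tree():
    return inference.read_newick(DEFAULT_TREE_NEWICK)


@pytest.fixture(scope="session")
def star_tree_10():
    taxa = sorted(DEFAULT_SPECIES_HABITAT)
    newick = "(" + ",".join(f"{t}:1" for t in taxa) + ");"
    return inference.read_newick(newick)


@pytest.fixture
def study_sim_config():
    def _make(**overrides):
        kwargs = dict(
            habitat_slopes=DEFAULT_HABITAT_SLOPES,
            species_habitat=DEFAULT_SPECIES_HABITAT,
            sites_per_species=2,
            fish_per_site=10,
            seed=0,
        )
        kwargs.update(overrides)
        return synth.StudySimConfig(**kwargs)

    return _make


def recovered_slope(beta: float, seed: int, side: int = 200) -> float:
    """Generator -> full spectral pipeline -> slope, for one seed."""
    from patternspectra import spectra

    img = synth.generate_spectral_noise_image(
        synth.SpectralNoiseConfig(side_px=side, beta=beta, seed=seed)
    )
    return spectra.patch_slope(img.pixels).slope


def mean_recovered_slope(beta: float, n_seeds: int, side: int = 200, seed0: int = 0):
    return float(
        np.mean([recovered_slope(beta, seed0 + s, side) for s in range(n_seeds)])
    )
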