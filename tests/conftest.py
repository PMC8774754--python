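import numpy as np
import pytest

from axosym.synthetic import SceneSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20220106)


def make_well_separated_spec(k_rotated: int, seed: int = 0) -> SceneSpec:
    """Noiseless coordinate regime: zero aligned tilt, zero jitter, rotated
    tilt fixed at 40 degrees (well beyond the kappa=0.5 decision boundary),
    exactly ``k_rotated`` rotated doublets per section."""
    return SceneSpec(
        tilt_deg_rotated=(40.0, 0.0, 40.0, 40.0),
        tilt_deg_aligned_sd=0.0,
        a_center_jitter_sd=0.0,
        doublet_spacing_jitter_deg=0.0,
        n_rotated_dist=tuple(1.0 if i == k_rotated else 0.0 for i in range(10)),
        seed=seed,
    )


@pytest.fixture
def well_separated_spec():
    return make_well_separated_spec
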