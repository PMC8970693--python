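import numpy as np
import pytest

import msfakit as mk


@pytest.fixture(scope="session")
def vis_axis() -> mk.SpectralAxis:
    """Visible-range axis, 2 nm grid (the search grid used throughout)."""
    return mk.SpectralAxis.regular(400, 700, 2)


@pytest.fixture(scope="session")
def toy_axis() -> mk.SpectralAxis:
    """16-band axis for small transcription-oracle scenes."""
    return mk.SpectralAxis.regular(500, 530, 2)


@pytest.fixture(scope="session")
def toy_scene(toy_axis):
    """8x8x16 reflectance scene with ground truth."""
    return mk.synthesize_scene(8, 8, toy_axis, 2, "reflectance", seed=5)


@pytest.fixture(scope="session")
def vis_scene(vis_axis):
    """16x16 visible-range reflectance scene with 3 endmembers."""
    return mk.synthesize_scene(16, 16, vis_axis, 3, "reflectance", seed=1)


@pytest.fixture(scope="session")
def recovery_scene(vis_axis):
    """Noisy scene with two isolated narrowband endmembers at known peaks.

    With zero noise any invertible two-filter design unmixes perfectly and
    the merit landscape is flat at the solver floor; band noise makes
    filter placement matter, so the optimum sits at the endmember peaks.
    """
    wl = vis_axis.wavelengths
    E = np.column_stack(
        [
            np.exp(-0.5 * ((wl - 480) / 17) ** 2),
            np.exp(-0.5 * ((wl - 620) / 17) ** 2),
        ]
    )
    lib = mk.EndmemberLibrary(E, ["green", "red"], vis_axis)
    rng = np.random.default_rng(0)
    amap = mk.AbundanceMap(rng.uniform(0.0, 0.5, size=(8, 8, 2)))
    cube = mk.hypercube_from_abundance(amap, lib, noise_sigma=0.05, seed=42)
    return cube, amap, lib


@pytest.fixture(scope="session")
def rgyb_bank(vis_axis):
    """The bundled 4-channel RGYB reference design's filter bank."""
    return mk.FilterBank.gaussian([455, 575, 520, 640], [47] * 4, vis_axis)


@pytest.fixture
def quad_pattern():
    return mk.MosaicPattern.from_array([[0, 1], [2, 3]])
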