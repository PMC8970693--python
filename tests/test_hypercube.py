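import numpy as np
import pytest

import msfakit as mk
from msfakit.hypercube import save_scene_npz, write_hypercube


def _two_band_library():
    axis = mk.SpectralAxis([500.0, 510.0, 520.0])
    E = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
    return mk.EndmemberLibrary(E, ["a", "b"], axis)


class TestSpectralAxis:
    @pytest.mark.parametrize(
        "wl", [[500.0], [500.0, 500.0], [510.0, 500.0], [500.0, np.inf]]
    )
    def test_rejects_invalid_grids(self, wl):
        with pytest.raises(ValueError):
            mk.SpectralAxis(np.array(wl))

    def test_regular_grid_endpoints(self):
        axis = mk.SpectralAxis.regular(400, 700, 2)
        assert axis.n_bands == 151
        assert axis.range == (400.0, 700.0)


class TestMixingModel:
    def test_pure_pixel_returns_endmember_column(self):
        lib = _two_band_library()
        amap = mk.AbundanceMap(np.array([[[1.0, 0.0]]]))
        cube = mk.hypercube_from_abundance(amap, lib)
        np.testing.assert_array_equal(cube.data[0, 0], lib.E[:, 0])

    def test_zero_abundance_gives_zero_cube(self):
        lib = _two_band_library()
        amap = mk.AbundanceMap(np.zeros((3, 2, 2)))
        cube = mk.hypercube_from_abundance(amap, lib)
        assert not cube.data.any()

    def test_matches_hand_computed_products(self):
        # 2x2 pixels, L=2, Q=3, small integers checked by hand
        lib = _two_band_library()
        A = np.array([[[1.0, 0.0], [0.0, 2.0]], [[1.0, 1.0], [2.0, 3.0]]])
        cube = mk.hypercube_from_abundance(mk.AbundanceMap(A), lib)
        expected = np.array(
            [
                [[1, 3, 5], [4, 8, 12]],
                [[3, 7, 11], [8, 18, 28]],
            ],
            dtype=float,
        )
        np.testing.assert_allclose(cube.data, expected)

    def test_noiseless_model_is_linear_in_abundance(self):
        lib = _two_band_library()
        rng = np.random.default_rng(3)
        A = rng.uniform(0, 1, size=(4, 5, 2))
        c1 = mk.hypercube_from_abundance(mk.AbundanceMap(A), lib)
        c2 = mk.hypercube_from_abundance(mk.AbundanceMap(2.5 * A), lib)
        np.testing.assert_allclose(c2.data, 2.5 * c1.data, rtol=1e-12)

    def test_noise_statistics_and_reproducibility(self):
        lib = _two_band_library()
        # large constant offset keeps clipping inactive for the s.d. check
        amap = mk.AbundanceMap(np.full((60, 60, 2), 10.0))
        c1 = mk.hypercube_from_abundance(amap, lib, noise_sigma=0.5, seed=9)
        c2 = mk.hypercube_from_abundance(amap, lib, noise_sigma=0.5, seed=9)
        np.testing.assert_array_equal(c1.data, c2.data)
        clean = mk.hypercube_from_abundance(amap, lib)
        noise = (c1.data - clean.data).ravel()  # > 10^4 samples
        assert abs(noise.std() - 0.5) < 0.05 * 0.5

    def test_negative_radiance_clipped_unless_disabled(self):
        lib = _two_band_library()
        amap = mk.AbundanceMap(np.zeros((20, 20, 2)))
        clipped = mk.hypercube_from_abundance(amap, lib, noise_sigma=1.0, seed=1)
        assert clipped.data.min() == 0.0
        raw = mk.hypercube_from_abundance(
            amap, lib, noise_sigma=1.0, seed=1, clip_negative=False
        )
        assert raw.data.min() < 0.0

    def test_dimension_and_sigma_validation(self):
        lib = _two_band_library()
        with pytest.raises(ValueError, match="endmembers"):
            mk.hypercube_from_abundance(mk.AbundanceMap(np.zeros((2, 2, 3))), lib)
        with pytest.raises(ValueError, match="noise_sigma"):
            mk.hypercube_from_abundance(
                mk.AbundanceMap(np.zeros((2, 2, 2))), lib, noise_sigma=-1.0
            )


class TestSceneSynthesis:
    def test_deterministic_for_fixed_seed(self, vis_axis):
        a = mk.synthesize_scene(12, 10, vis_axis, 3, "reflectance", seed=11)
        b = mk.synthesize_scene(12, 10, vis_axis, 3, "reflectance", seed=11)
        for x, y in zip(a, b):
            arr_x = x.data if hasattr(x, "data") else getattr(x, "A", getattr(x, "E", None))
            arr_y = y.data if hasattr(y, "data") else getattr(y, "A", getattr(y, "E", None))
            np.testing.assert_array_equal(arr_x, arr_y)

    def test_single_endmember_abundances_in_unit_interval(self, vis_axis):
        _, amap, _ = mk.synthesize_scene(8, 8, vis_axis, 1, "reflectance", seed=2)
        assert amap.A.shape[2] == 1
        assert amap.A.min() >= 0.0 and amap.A.max() <= 1.0

    @pytest.mark.parametrize("kind", ["reflectance", "fluorescence"])
    def test_abundance_sums_bounded(self, vis_axis, kind):
        _, amap, _ = mk.synthesize_scene(16, 16, vis_axis, 4, kind, seed=8)
        assert amap.A.min() >= 0.0
        assert amap.A.sum(axis=-1).max() <= 1.0 + 1e-9

    def test_fluorescence_has_narrow_dyes_and_broad_illumination(self, vis_axis):
        _, _, lib = mk.synthesize_scene(8, 8, vis_axis, 4, "fluorescence", seed=4)
        assert lib.names[-1] == "illumination"
        # each dye is a single narrow peak: above-half-max support < 60 nm
        step = np.diff(vis_axis.wavelengths)[0]
        for i in range(3):
            dye = lib.E[:, i]
            assert (dye > 0.5 * dye.max()).sum() * step < 60
        # illumination spans the window far more broadly than any dye
        ill = lib.E[:, -1]
        assert (ill > 0.1 * ill.max()).sum() > (lib.E[:, 0] > 0.1).sum()

    def test_noiseless_roundtrip_recovers_abundances(self, vis_axis):
        cube, amap, lib = mk.synthesize_scene(6, 6, vis_axis, 3, "reflectance", seed=13)
        result = mk.nnls_unmix(cube.data, lib.E)
        np.testing.assert_allclose(result.abundances.A, amap.A, atol=1e-8)

    def test_excess_endmembers_warn(self):
        axis = mk.SpectralAxis([500.0, 510.0, 520.0])
        with pytest.warns(UserWarning, match="endmembers"):
            mk.synthesize_scene(4, 4, axis, 5, "reflectance", seed=0)


class TestIO:
    @pytest.mark.parametrize("fmt,suffix", [("hdf5", ".h5"), ("npz", ".npz")])
    def test_container_roundtrip(self, tmp_path, toy_scene, fmt, suffix):
        cube = toy_scene[0]
        path = tmp_path / f"cube{suffix}"
        write_hypercube(cube, path)
        back = mk.read_hypercube(path)
        np.testing.assert_array_equal(back.data, cube.data)
        np.testing.assert_array_equal(back.axis.wavelengths, cube.axis.wavelengths)

    @pytest.mark.parametrize("interleave", ["bsq", "bil", "bip"])
    def test_envi_dialects_read_identically(self, tmp_path, toy_scene, interleave):
        cube = toy_scene[0]
        path = tmp_path / f"cube_{interleave}.img"
        write_hypercube(cube, path, interleave=interleave)
        back = mk.read_hypercube(path)
        np.testing.assert_array_equal(back.data, cube.data)
        np.testing.assert_allclose(back.axis.wavelengths, cube.axis.wavelengths)

    def test_missing_wavelengths_raise_named_error(self, tmp_path, toy_scene):
        path = tmp_path / "bad.npz"
        np.savez(path, cube=toy_scene[0].data)
        with pytest.raises(KeyError, match="wavelengths"):
            mk.read_hypercube(path)

    def test_scene_archive_keeps_ground_truth(self, tmp_path, toy_scene):
        cube, amap, lib = toy_scene
        path = tmp_path / "scene.npz"
        save_scene_npz(path, cube, amap, lib)
        with np.load(path) as z:
            np.testing.assert_array_equal(z["abundance"], amap.A)
            np.testing.assert_array_equal(z["endmembers"], lib.E)
            assert list(z["names"]) == list(lib.names)
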