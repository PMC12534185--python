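import json
import math

import numpy as np
import pytest

from dnamoire import fft_recovery as fr
from dnamoire import sublattice as sl
from dnamoire import synthetic_imaging as si
from dnamoire.moire_math import moire_period


def quiet_params(**kw):
    # supersample=1: no anti-alias decimation, so the unit-peak-height spot
    # normalisation is observable exactly
    defaults = dict(
        image_size=256, noise_gaussian_sd=0.0, rng_seed=0, contrast="linear",
        supersample=1,
    )
    defaults.update(kw)
    return si.RenderParams(**defaults)


class TestRenderLayers:
    def test_empty_scene_is_uniform_background(self):
        img = si.render_layers([], quiet_params())
        assert np.allclose(img, 0.0)

    def test_single_point_peaks_at_its_pixel(self):
        ps = sl.PointSet(coords=np.array([[10.0, -5.0]]))
        params = quiet_params()
        img = si.render_layers([ps], params)
        iy, ix = np.unravel_index(np.argmax(img), img.shape)
        n = params.image_size
        assert abs(ix - (10.0 / params.pixel_size_nm + n / 2)) <= 1
        assert abs(iy - (-5.0 / params.pixel_size_nm + n / 2)) <= 1
        assert img.max() == pytest.approx(1.0, rel=0.05)

    def test_linear_contrast_renders_additively(self):
        spec = sl.lattice_spec("square")
        params = quiet_params()
        region = (params.field_nm, params.field_nm)
        a = sl.generate_lattice(spec, region, orientation_deg=0.0)
        b = sl.generate_lattice(spec, region, orientation_deg=5.0)
        together = si.render_layers([a, b], params)
        separate = si.render_layers([a], params) + si.render_layers([b], params)
        assert np.allclose(together, separate, atol=1e-9)

    def test_rendering_is_deterministic_given_seed(self):
        img1, _, _ = si.make_fixture("bilayer", rng_seed=5, image_size=256)
        img2, _, _ = si.make_fixture("bilayer", rng_seed=5, image_size=256)
        assert np.array_equal(img1, img2)

    def test_nyquist_violation_rejected_with_suggestion(self):
        params = si.RenderParams(pixel_size_nm=1.0, image_size=128)
        ps = sl.generate_lattice(sl.lattice_spec("square"), (64, 64))
        with pytest.raises(ValueError, match="pixel_size_nm"):
            si.render_layers([ps], params, finest_a_sub_nm=2.2)

    def test_monolayer_spectrum_peaks_at_reciprocal_prediction(self):
        img, truth, params = si.make_fixture("monolayer", rng_seed=0, image_size=512)
        spec = fr.power_spectrum(img, params.pixel_size_nm)
        plist = fr.detect_peaks(
            spec, min_snr=10, annulus=fr.sublattice_annulus(2.2, "square")
        )
        rb = sl.reciprocal_basis(sl.lattice_spec("square"))
        g_pred = np.hypot(*rb.g_vectors[0])
        top = list(plist)[0]
        assert np.hypot(*top.g) == pytest.approx(g_pred, abs=spec.bin_nm_inv)

    @pytest.mark.parametrize("sym", sl.SYMMETRIES)
    def test_strongest_peaks_sit_on_strongest_predicted_shell(self, sym):
        # the shell with the largest structure factor, weighted by the
        # Gaussian spot envelope, must carry the brightest measured peaks
        img, truth, params = si.make_fixture(
            "monolayer", rng_seed=0, image_size=512, symmetry=sym
        )
        spec = fr.power_spectrum(img, params.pixel_size_nm)
        a = truth.layers[0][1]
        shells = sl.reciprocal_shells(sl.LatticeSpec(sym, a), max_index=3)
        sigma = params.spot_sigma_nm

        def envelope(g):
            return math.exp(-2 * math.pi**2 * sigma**2 * g**2)

        best = max(
            shells, key=lambda s: s[1] * envelope(float(np.hypot(*s[0][0])))
        )
        g_best = float(np.hypot(*best[0][0]))
        plist = fr.detect_peaks(
            spec, min_snr=10, annulus=(2 * spec.bin_nm_inv, float(spec.gx.max()))
        )
        top = list(plist)[0]
        assert np.hypot(*top.g) == pytest.approx(g_best, abs=2 * spec.bin_nm_inv)


class TestFixtures:
    def test_bilayer_truth_matches_closed_form(self):
        _, truth, _ = si.make_fixture("bilayer", rng_seed=0, image_size=256)
        truth.validate()
        assert truth.expected_p_M_nm == pytest.approx(moire_period(2.2, 3.9))

    def test_trilayer_truth_orientations_follow_seed_registry(self):
        _, truth, _ = si.make_fixture("trilayer", rng_seed=0, image_size=256)
        assert [l[2] for l in truth.layers] == pytest.approx([0.0, 3.8, 7.6])

    def test_gradient_truth_period_endpoints(self):
        _, truth, _ = si.make_fixture("gradient", rng_seed=0, image_size=256)
        lo, hi = truth.expected_p_M_range_nm
        assert round(lo, 1) == 9.2
        assert round(hi, 1) == 45.0

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            si.make_fixture("pentalayer")


class TestShrinkage:
    def test_square_cryo_to_dried(self):
        dried = si.shrinkage(sl.lattice_spec("square", "cryo"), "dried")
        assert dried.a_sub_nm == pytest.approx(2.2)

    def test_kagome_cryo_to_dried(self):
        dried = si.shrinkage(sl.lattice_spec("kagome", "cryo"), "dried")
        assert dried.a_sub_nm == pytest.approx(4.4)

    def test_dried_to_dried_is_identity(self):
        spec = sl.lattice_spec("honeycomb", "dried")
        assert si.shrinkage(spec, "dried").a_sub_nm == spec.a_sub_nm

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            si.shrinkage(sl.lattice_spec("square"), "lyophilised")


def test_image_io_roundtrip(tmp_path):
    img, truth, params = si.make_fixture("monolayer", rng_seed=0, image_size=256)
    base = tmp_path / "scene"
    si.write_image(base, img, params, truth)
    assert (tmp_path / "scene.tif").exists()
    assert (tmp_path / "scene.png").exists()
    sidecar = json.loads((tmp_path / "scene.json").read_text())
    assert sidecar["pixel_size_nm"] == params.pixel_size_nm
    back = si.read_image(tmp_path / "scene.tif")
    assert back.shape == img.shape
    # 16-bit quantisation preserves the normalised structure
    norm = (img - img.min()) / (img.max() - img.min())
    assert np.corrcoef(norm.ravel(), back.ravel())[0, 1] > 0.9999
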