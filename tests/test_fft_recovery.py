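import numpy as np
import pytest

from dnamoire import fft_recovery as fr
from dnamoire import synthetic_imaging as si
from dnamoire.moire_math import moire_period


class TestPowerSpectrum:
    def test_uniform_image_has_no_off_dc_energy(self):
        spec = fr.power_spectrum(np.full((128, 128), 3.0), 0.5, window="none")
        centre = (64, 64)
        off_dc = spec.power.copy()
        off_dc[centre] = 0.0
        assert off_dc.max() < 1e-12

    def test_pure_cosine_peaks_at_its_frequency(self):
        n, period_px, px = 256, 10, 0.5
        x = np.arange(n)
        img = np.cos(2 * np.pi * x / period_px)[None, :].repeat(n, axis=0)
        spec = fr.power_spectrum(img, px, window="none")
        iy, ix = np.unravel_index(np.argmax(spec.power), spec.power.shape)
        g = np.hypot(spec.gx[ix], spec.gy[iy])
        assert g == pytest.approx(1.0 / (period_px * px), abs=spec.bin_nm_inv / 2)

    def test_missing_calibration_rejected(self):
        with pytest.raises(ValueError):
            fr.power_spectrum(np.zeros((128, 128)), None)

    def test_small_image_rejected(self):
        with pytest.raises(ValueError):
            fr.power_spectrum(np.zeros((32, 32)), 0.5)


class TestDetectPeaks:
    def test_noise_only_spectrum_with_high_snr_is_empty(self):
        rng = np.random.default_rng(0)
        spec = fr.power_spectrum(rng.normal(size=(256, 256)), 0.5)
        plist = fr.detect_peaks(spec, min_snr=1e4, annulus=(0.1, 0.6))
        assert len(plist) == 0

    def test_square_monolayer_gives_two_families_at_ninety(self, monolayer_fixture):
        image, truth, params = monolayer_fixture
        spec = fr.power_spectrum(image, params.pixel_size_nm)
        plist = fr.detect_peaks(
            spec, min_snr=10, annulus=fr.sublattice_annulus(2.2, "square")
        )
        strong = [p for p in plist if p.magnitude > 0.02 * list(plist)[0].magnitude]
        assert len(strong) == 2
        d_az = abs(strong[0].azimuth_deg - strong[1].azimuth_deg)
        assert d_az == pytest.approx(90.0, abs=0.1)

    def test_bilayer_families_split_by_twist(self, bilayer_spectrum):
        spec, truth = bilayer_spectrum
        plist = fr.detect_peaks(
            spec, min_snr=10, annulus=fr.sublattice_annulus(2.2, "square")
        )
        strong = sorted(
            [p for p in plist if p.magnitude > 0.02 * list(plist)[0].magnitude],
            key=lambda p: p.azimuth_deg,
        )
        assert len(strong) == 4
        folded = np.sort([p.azimuth_deg % 90 for p in strong])
        gaps = np.sort(np.diff(np.concatenate([folded, [folded[0] + 90]])))
        # two tight families (near-zero internal gaps) circularly separated
        # by the 5 deg twist
        assert gaps[:2] == pytest.approx([0.0, 0.0], abs=0.2)
        assert gaps[2] == pytest.approx(5.0, abs=0.2)

    def test_empty_annulus_rejected(self, bilayer_spectrum):
        spec, _ = bilayer_spectrum
        with pytest.raises(ValueError):
            fr.detect_peaks(spec, annulus=(0.6, 0.1))


class TestEstimateLattice:
    def test_bilayer_twist_and_constant(self, bilayer_spectrum):
        spec, truth = bilayer_spectrum
        plist = fr.detect_peaks(
            spec, min_snr=10, annulus=fr.sublattice_annulus(2.2, "square")
        )
        report = fr.estimate_lattice(plist, "square")
        assert not report.monolayer
        assert report.twist_deg == pytest.approx(5.0, abs=0.3)
        for layer in report.layers:
            assert layer.a_sub_nm == pytest.approx(2.2, rel=0.03)

    def test_global_rotation_shifts_orientations_not_twist(self):
        img, _, params = si.make_fixture(
            "bilayer", rng_seed=7, twist_deg=5.0, image_size=512,
            orientations=[7.0, 12.0],
        )
        spec = fr.power_spectrum(img, params.pixel_size_nm)
        plist = fr.detect_peaks(
            spec, min_snr=10, annulus=fr.sublattice_annulus(2.2, "square")
        )
        report = fr.estimate_lattice(plist, "square")
        assert report.twist_deg == pytest.approx(5.0, abs=0.1)
        assert report.layers[0].orientation_deg == pytest.approx(7.0, abs=0.2)

    def test_monolayer_flagged_twist_undefined(self, monolayer_fixture):
        image, truth, params = monolayer_fixture
        spec = fr.power_spectrum(image, params.pixel_size_nm)
        plist = fr.detect_peaks(
            spec, min_snr=10, annulus=fr.sublattice_annulus(2.2, "square")
        )
        report = fr.estimate_lattice(plist, "square")
        assert report.monolayer and report.twist_deg is None


class TestMoirePeriod:
    def test_bilayer_period_close_to_closed_form(self, bilayer_spectrum):
        spec, truth = bilayer_spectrum
        p = fr.estimate_moire_period(spec, "square", expected_a_sub_nm=2.2)
        assert p == pytest.approx(truth.expected_p_M_nm, rel=0.10)

    def test_untwisted_bilayer_returns_sentinel(self):
        img, _, params = si.make_fixture(
            "bilayer", rng_seed=2, twist_deg=0.0, image_size=512
        )
        spec = fr.power_spectrum(img, params.pixel_size_nm)
        assert fr.estimate_moire_period(spec, "square", expected_a_sub_nm=2.2) is None

    def test_duality_with_sublattice_star(self, bilayer_spectrum):
        # 1/p_M must match 2 (1/a) sin(theta/2) for identical square layers
        spec, truth = bilayer_spectrum
        p = fr.estimate_moire_period(spec, "square", expected_a_sub_nm=2.2)
        twist = truth.twist_deg[0]
        g_m = 2.0 * (1.0 / 2.2) * np.sin(np.deg2rad(twist) / 2.0)
        assert 1.0 / p == pytest.approx(g_m, rel=0.10)


class TestOrientationMap:
    def test_uniform_bilayer_gives_constant_field(self):
        img, truth, params = si.make_fixture("bilayer", rng_seed=4, twist_deg=5.0)
        field = fr.orientation_map(
            img, params.pixel_size_nm, "square", expected_a_sub_nm=2.2,
            window_px=256, stride_px=128,
        )
        vals = field.twist_deg[np.isfinite(field.twist_deg)]
        assert len(vals) > 10
        assert vals.max() - vals.min() < 1.0
        assert np.nanmedian(np.abs(vals - 5.0)) < 0.5

    def test_stride_beyond_window_warns(self):
        img = np.zeros((256, 256))
        with pytest.warns(UserWarning):
            fr.orientation_map(
                img, 0.5, "square", expected_a_sub_nm=2.2,
                window_px=64, stride_px=128,
            )

    def test_field_csv_roundtrip(self, tmp_path):
        img, _, params = si.make_fixture("bilayer", rng_seed=4, twist_deg=5.0,
                                         image_size=512)
        field = fr.orientation_map(
            img, params.pixel_size_nm, "square", expected_a_sub_nm=2.2,
            window_px=256, stride_px=256,
        )
        path = tmp_path / "field.csv"
        field.to_csv(path)
        import pandas as pd

        back = pd.read_csv(path)
        assert len(back) == field.twist_deg.size


def test_azimuthal_discontinuity_counter():
    az = np.linspace(0, 360, 36, endpoint=False)
    ramp = np.linspace(3.0, 13.0, 36)  # one wrap-around drop
    assert fr.azimuthal_discontinuities(az, ramp, 3.0) == 1
    assert fr.azimuthal_discontinuities(az, np.full(36, 5.0), 3.0) == 0
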