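import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dnamoire import seed_model as sm


class TestCrossSection:
    @pytest.mark.parametrize(
        "array_type,rim,pore,expected",
        [
            ("square", (8, 8), (4, 4), 48),
            ("honeycomb", (12, 6), (6, 3), 54),
        ],
    )
    def test_helix_counts(self, array_type, rim, pore, expected):
        spec = sm.CrossSectionSpec(array_type, rim[0], rim[1], pore[0], pore[1])
        layout = sm.build_cross_section(spec)
        assert layout.helix_count == expected
        assert not layout.degenerate
        # no duplicate centres
        assert len(np.unique(np.round(layout.centres, 6), axis=0)) == expected

    def test_rim_equals_pore_is_degenerate(self):
        spec = sm.CrossSectionSpec("square", 4, 4, 4, 4)
        layout = sm.build_cross_section(spec)
        assert layout.helix_count == 0 and layout.degenerate

    def test_pore_larger_than_rim_rejected(self):
        with pytest.raises(ValueError):
            sm.CrossSectionSpec("square", 4, 4, 5, 4)

    @given(
        rim_c=st.integers(1, 12),
        rim_r=st.integers(1, 12),
        pore_c=st.integers(0, 12),
        pore_r=st.integers(0, 12),
    )
    @settings(max_examples=40, deadline=None)
    def test_count_is_rim_minus_pore(self, rim_c, rim_r, pore_c, pore_r):
        if pore_c > rim_c or pore_r > rim_r:
            return
        spec = sm.CrossSectionSpec("square", rim_c, rim_r, pore_c, pore_r)
        assert sm.build_cross_section(spec).helix_count == rim_c * rim_r - pore_c * pore_r


class TestSegmentArithmetic:
    @pytest.mark.parametrize(
        "bp,expected_nm",
        [(128, 43.5), (32, 10.9), (36, 12.2), (126, 42.8), (0, 0.0)],
    )
    def test_heights_at_canonical_rise(self, bp, expected_nm):
        assert sm.segment_height(bp, 0.34) == pytest.approx(expected_nm, abs=0.05)

    def test_negative_bp_rejected(self):
        with pytest.raises(ValueError):
            sm.segment_height(-1, 0.34)

    @pytest.mark.parametrize(
        "bp,rate,expected",
        [(32, 3.8 / 32, 3.8), (36, 1.2 / 36, 1.2), (0, 0.5, 0.0)],
    )
    def test_twist_calibration_identities(self, bp, rate, expected):
        assert sm.segment_twist(bp, rate) == pytest.approx(expected)

    @given(a=st.integers(0, 500), b=st.integers(0, 500))
    @settings(max_examples=40, deadline=None)
    def test_height_additivity(self, a, b):
        total = (a + b) * 0.34
        assert sm.segment_height(a, 0.34) + sm.segment_height(b, 0.34) == pytest.approx(
            total, abs=0.11
        )


class TestCompileStack:
    def test_seed_s_trilayer_registry(self):
        stack = sm.compile_stack(sm.seed_preset("seed-S"))
        z = [(l.z_lo_nm, l.z_hi_nm) for l in stack.layers]
        assert np.allclose(z, [(0.0, 43.52), (54.4, 97.92), (108.8, 152.32)], atol=0.01)
        assert stack.orientations_deg == pytest.approx([0.0, 3.8, 7.6])

    def test_seed_h_interlayer_twist(self):
        stack = sm.compile_stack(sm.seed_preset("seed-H"))
        o = stack.orientations_deg
        assert o[1] - o[0] == pytest.approx(1.2)

    def test_empty_design_gives_empty_stack(self):
        seed = sm.SeedDesign(
            "empty", sm.CrossSectionSpec("square", 2, 2, 0, 0), segments=()
        )
        assert sm.compile_stack(seed).layers == ()

    def test_total_height_conserved_and_orientations_monotone(self):
        seed = sm.seed_preset("seed-S")
        stack = sm.compile_stack(seed)
        total = sum(s.bp for s in seed.segments) * seed.rise_nm_per_bp
        assert stack.layers[-1].z_hi_nm == pytest.approx(total)
        o = stack.orientations_deg
        assert all(b >= a for a, b in zip(o, o[1:]))
        # consecutive difference equals the intervening spacer twist exactly
        spacers = [s.twist_deg for s in seed.segments if s.role == sm.SPACER]
        assert np.allclose(np.diff(o), spacers)

    def test_non_alternating_segments_rejected(self):
        cs = sm.CrossSectionSpec("square", 2, 2, 0, 0)
        with pytest.raises(ValueError):
            sm.SeedDesign(
                "bad",
                cs,
                segments=(
                    sm.SeedSegment("Z1", sm.GROWTH, 10),
                    sm.SeedSegment("Z2", sm.SPACER, 10, 1.0),
                ),
            )


class TestGradientFaces:
    def test_gradient_seed_face_twists(self):
        theta_b, theta_a = sm.gradient_face_orientations(sm.seed_preset("seed-SG"))
        assert theta_b == pytest.approx(2.8)
        assert theta_a == pytest.approx(13.7)

    @pytest.mark.parametrize("theta,dtheta", [(0.0, 10.9), (2.8, 0.0)])
    def test_face_twist_additivity(self, theta, dtheta):
        cs = sm.CrossSectionSpec(
            "square", 8, 8, 4, 4, taper=sm.GradientTaper(delta_theta_deg=dtheta)
        )
        seed = sm.SeedDesign(
            "g",
            cs,
            segments=(
                sm.SeedSegment("Z1", sm.GROWTH, 128),
                sm.SeedSegment("Z2", sm.SPACER, 32, theta),
                sm.SeedSegment("Z3", sm.GROWTH, 128),
            ),
        )
        theta_b, theta_a = sm.gradient_face_orientations(seed)
        assert (theta_b, theta_a) == pytest.approx((theta, theta + dtheta))

    def test_taperless_seed_rejected(self):
        with pytest.raises(ValueError):
            sm.gradient_face_orientations(sm.seed_preset("seed-S"))


def test_design_roundtrip_through_yaml(tmp_path):
    seed = sm.seed_preset("seed-S")
    path = tmp_path / "design.yaml"
    import yaml

    path.write_text(
        yaml.safe_dump(
            {
                "name": seed.name,
                "cross_section": {
                    "array_type": "square",
                    "rim_cols": 8,
                    "rim_rows": 8,
                    "pore_cols": 4,
                    "pore_rows": 4,
                },
                "segments": [
                    {"id": s.id, "role": s.role, "bp": s.bp, "twist_deg": s.twist_deg}
                    for s in seed.segments
                ],
            }
        )
    )
    loaded = sm.load_seed_design(path)
    assert sm.compile_stack(loaded).to_json() == sm.compile_stack(seed).to_json()
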