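"""Elliptic Fourier transform: analytic cases, oracles and invariances.

The quadrature oracle integrates the Fourier integrals of the
continuous parametric curve directly (dense trapezoid rule), fully
independent of the piecewise-linear segment formulation under test.
"""

import numpy as np
import pytest

from musselshape.efa import (
    CalibrationError,
    EfaError,
    assemble_shape_matrix,
    calibrate_harmonics,
    coefficient_labels,
    combine_views,
    efa_forward,
    efa_inverse,
    efa_normalize,
    harmonic_power,
)
from musselshape.outline_io import Outline

from .conftest import parametric_outline


def rotate_scale_shift(outline, angle, scale, shift, translation=(0.0, 0.0)):
    R = np.array(
        [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
    )
    pts = outline.points @ R.T * scale + np.asarray(translation)
    return Outline(outline.specimen_id, outline.view, np.roll(pts, shift, axis=0))


class TestForward:
    def test_unit_circle_single_harmonic(self, circle):
        c = efa_forward(circle, 7)
        np.testing.assert_allclose(c.harmonics[0], [1, 0, 0, 1], atol=1e-12)
        assert np.abs(c.harmonics[1:]).max() < 1e-9
        assert np.abs(c.dc).max() < 1e-9

    def test_axis_aligned_ellipse_single_harmonic(self, ellipse):
        c = efa_forward(ellipse, 5)
        np.testing.assert_allclose(c.harmonics[0], [2, 0, 0, 1], atol=1e-12)
        assert np.abs(c.harmonics[1:]).max() < 1e-9

    def test_matches_direct_quadrature_oracle(self, mussel):
        c = efa_forward(mussel, 7)
        # oracle: trapezoid quadrature of the continuous Fourier integrals
        n_fine = 1 << 16
        t = np.linspace(0, 2 * np.pi, n_fine, endpoint=False)
        r = (
            1.0
            + 0.28 * np.cos(t)
            + 0.06 * np.sin(t)
            + 0.10 * np.sin(2 * t)
            + 0.045 * np.cos(3 * t)
            + 0.018 * np.sin(4 * t)
            + 0.008 * np.cos(5 * t)
            + 0.004 * np.sin(6 * t)
        )
        x, y = r * np.cos(t), 0.58 * r * np.sin(t)
        expected = np.empty((7, 4))
        for n in range(1, 8):
            expected[n - 1] = [
                2 * np.mean(x * np.cos(n * t)),
                2 * np.mean(x * np.sin(n * t)),
                2 * np.mean(y * np.cos(n * t)),
                2 * np.mean(y * np.sin(n * t)),
            ]
        np.testing.assert_allclose(c.harmonics, expected, atol=1e-8)

    def test_chord_parameterization_available_and_close(self, circle):
        c = efa_forward(circle, 3, parameterization="chord")
        np.testing.assert_allclose(c.harmonics[0], [1, 0, 0, 1], atol=1e-4)

    def test_too_few_points_named_error(self):
        o = parametric_outline("circle", n=12)
        with pytest.raises(EfaError, match="need >="):
            efa_forward(o, 7)


class TestNormalize:
    def test_scale_invariance(self, mussel):
        a = efa_normalize(efa_forward(mussel, 7))
        scaled = Outline("m", "lateral", mussel.points * 3.7)
        b = efa_normalize(efa_forward(scaled, 7))
        np.testing.assert_allclose(a.harmonics, b.harmonics, atol=1e-10)

    def test_invariance_sweep_rotation_scale_start(self, mussel):
        ref = efa_normalize(efa_forward(mussel, 7))
        rng = np.random.default_rng(42)
        for _ in range(20):
            o = rotate_scale_shift(
                mussel,
                rng.uniform(0, 2 * np.pi),
                rng.uniform(0.3, 4.0),
                int(rng.integers(0, mussel.n_points)),
                rng.normal(0, 10, 2),
            )
            c = efa_normalize(efa_forward(o, 7))
            np.testing.assert_allclose(c.harmonics, ref.harmonics, atol=1e-8)

    def test_idempotent(self, mussel):
        once = efa_normalize(efa_forward(mussel, 7))
        twice = efa_normalize(once)
        np.testing.assert_allclose(twice.harmonics, once.harmonics, atol=1e-12)

    def test_first_harmonic_convention(self, mussel):
        c = efa_normalize(efa_forward(mussel, 7))
        assert c.harmonics[0, 0] == pytest.approx(1.0)
        assert abs(c.harmonics[0, 1]) < 1e-10  # b1 start-phase removed
        assert abs(c.harmonics[0, 2]) < 1e-10
        np.testing.assert_allclose(c.dc, 0.0, atol=1e-15)

    def test_near_circular_tie_break_is_rotation_invariant(self):
        # first ellipse nearly circular: orientation must come from h2
        t = np.linspace(0, 2 * np.pi, 1024, endpoint=False)
        r = 1.0 + 0.08 * np.cos(2 * t) + 0.03 * np.sin(3 * t)
        o = Outline("nc", "lateral", np.column_stack([r * np.cos(t), 0.99 * r * np.sin(t)]))
        ref = efa_normalize(efa_forward(o, 7))
        rng = np.random.default_rng(3)
        for _ in range(10):
            o2 = rotate_scale_shift(
                o, rng.uniform(0, 2 * np.pi), rng.uniform(0.5, 2.0),
                int(rng.integers(0, 1024)),
            )
            c = efa_normalize(efa_forward(o2, 7))
            np.testing.assert_allclose(c.harmonics, ref.harmonics, atol=1e-6)

    def test_degenerate_first_ellipse_rejected(self):
        from musselshape.efa import EFACoefficients

        c = EFACoefficients("lateral", np.zeros((3, 4)) + [[0, 0, 0, 0]] * 3)
        c.harmonics[1] = [1, 0, 0, 1]
        with pytest.raises(EfaError, match="degenerate"):
            efa_normalize(c)


class TestInverse:
    def test_circle_reconstruction_radius(self, circle):
        c = efa_forward(circle, 3)
        rec = efa_inverse(c, 256)
        radii = np.linalg.norm(rec.points, axis=1)
        assert np.abs(radii - 1).max() < 1e-9

    def test_round_trip_on_template_at_512(self, mussel):
        c = efa_normalize(efa_forward(mussel, 7))
        rec = efa_inverse(c, 512)
        back = efa_normalize(efa_forward(rec, 7))
        assert np.abs(back.harmonics - c.harmonics).max() < 1e-6

    def test_truncation_to_one_harmonic_is_ellipse(self, mussel):
        c = efa_forward(mussel, 7)
        from musselshape.efa import EFACoefficients

        trunc = EFACoefficients(c.view, c.harmonics[:1], c.dc)
        rec = efa_inverse(trunc, 512)
        again = efa_forward(rec, 4)
        power, _ = harmonic_power(again)
        assert power[1:].max() < 1e-12


class TestPowerAndCalibration:
    def test_pure_ellipse_power_fraction_one(self, ellipse):
        c = efa_forward(ellipse, 5)
        _, cum = harmonic_power(c)
        assert cum[0] == pytest.approx(1.0, abs=1e-12)

    def test_power_sums_match_brute_force(self, mussel):
        c = efa_forward(mussel, 7)
        power, cum = harmonic_power(c)
        brute = np.array([0.5 * np.sum(row**2) for row in c.harmonics])
        np.testing.assert_allclose(power, brute, atol=1e-12)
        assert np.all(np.diff(cum) >= -1e-15)
        assert cum[-1] == pytest.approx(1.0)

    def test_power_invariant_to_rotation_and_scale(self, mussel):
        base, _ = harmonic_power(efa_normalize(efa_forward(mussel, 7)))
        o = rotate_scale_shift(mussel, 1.1, 2.5, 37)
        other, _ = harmonic_power(efa_normalize(efa_forward(o, 7)))
        np.testing.assert_allclose(base, other, atol=1e-10)

    def test_calibration_matches_exhaustive_scan(self, mussel, small_dataset):
        outlines = [
            views["lateral"] for views in list(small_dataset.outlines.values())[:10]
        ]
        # oracle: brute scan over candidate counts, with the total power
        # evaluated at the same 24-harmonic reference decomposition
        fracs = np.mean(
            [harmonic_power(efa_forward(o, 24))[1] for o in outlines], axis=0
        )
        for threshold in (0.9, 0.99, 0.9999):
            n = calibrate_harmonics(outlines, threshold, max_harmonics=7)
            expected = next(i + 1 for i in range(7) if fracs[i] >= threshold)
            assert n == expected

    def test_ellipse_set_needs_one_harmonic(self, ellipse, circle):
        assert calibrate_harmonics([ellipse, circle], 0.98, 5) == 1

    def test_unreachable_threshold_reports_achieved(self, square):
        with pytest.raises(CalibrationError, match="reaches only") as err:
            calibrate_harmonics([square], 0.9999999999, max_harmonics=2)
        assert 0 < err.value.achieved < 1


class TestCombineViews:
    def test_vector_length_and_labels(self, mussel):
        lat = efa_normalize(efa_forward(mussel, 7))
        ven_outline = parametric_outline("ellipse", view="ventral")
        ven = efa_normalize(efa_forward(ven_outline, 7))
        vec = combine_views(lat, ven)
        assert vec.shape == (56,)
        labels = coefficient_labels(7)
        assert len(labels) == 56
        assert labels[0] == "lateral_h1_a" and labels[28] == "ventral_h1_a"

    def test_swapped_views_rejected(self, mussel):
        lat = efa_normalize(efa_forward(mussel, 7))
        ven = efa_normalize(
            efa_forward(parametric_outline("ellipse", view="ventral"), 7)
        )
        with pytest.raises(ValueError, match="swapped|lateral"):
            combine_views(ven, lat)

    def test_harmonic_mismatch_rejected(self, mussel):
        lat = efa_normalize(efa_forward(mussel, 7))
        ven = efa_normalize(
            efa_forward(parametric_outline("ellipse", view="ventral"), 5)
        )
        with pytest.raises(ValueError, match="mismatch"):
            combine_views(lat, ven)

    def test_specimen_missing_view_excluded(self, mussel, caplog):
        lat = efa_normalize(efa_forward(mussel, 7))
        ven = efa_normalize(
            efa_forward(parametric_outline("ellipse", view="ventral"), 7)
        )
        cmap = {
            "s1": {"lateral": lat, "ventral": ven},
            "s2": {"lateral": lat},  # ventral deleted
        }
        import logging

        with caplog.at_level(logging.WARNING):
            matrix = assemble_shape_matrix(cmap)
        assert matrix.specimen_ids == ["s1"]
        assert any("missing a view" in r.message for r in caplog.records)


class TestFixedPoint:
    def test_forward_of_normalized_reconstruction_is_fixed_point(self, mussel):
        c = efa_normalize(efa_forward(mussel, 7))
        for _ in range(3):
            rec = efa_inverse(c, 1024)
            c2 = efa_normalize(efa_forward(rec, 7))
            assert np.abs(c2.harmonics - c.harmonics).max() < 1e-6
            c = c2
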