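import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gbpct.acquisition import AcquisitionGeometry, SteppingScan, simulate_stepping
from gbpct.phantom import PhantomVolume, make_phantom
from gbpct.retrieval import (
    fit_stepping_curve,
    retrieve,
    retrieve_patchwise,
    wrap_phase,
)


def make_flat_scan(a_sample, a_reference, n_angles=3, n_cols=8, visibility=0.3,
                   phase=0.0):
    """Scan whose every pixel has the given stepping-curve parameters."""
    geo = AcquisitionGeometry(
        n_angles=n_angles, n_steps=5, visibility=visibility,
        flux_per_step=a_reference, reference_exposure_factor=1.0,
    )
    s = np.arange(5)
    ref_curve = a_reference * (1 + visibility * np.cos(2 * np.pi * s / 5))
    sam_curve = a_sample * (1 + visibility * np.cos(2 * np.pi * s / 5 + phase))
    sample = np.tile(sam_curve[None, :, None], (n_angles, 1, n_cols))
    reference = np.tile(ref_curve[:, None], (1, n_cols))
    return SteppingScan(sample=sample, reference=reference, geometry=geo)


class TestFitSteppingCurve:
    def test_flat_curve_has_zero_amplitude_and_masked_phase(self):
        fit = fit_stepping_curve(np.array([100.0] * 5))
        assert fit.mean == pytest.approx(100.0)
        assert fit.amplitude == pytest.approx(0.0, abs=1e-10)
        assert not fit.phase_defined
        assert fit.phase == 0.0

    def test_exact_single_harmonic_recovered_to_machine_precision(self):
        s = np.arange(5)
        counts = 100.0 * (1 + 0.5 * np.cos(2 * np.pi * s / 5))
        fit = fit_stepping_curve(counts)
        assert fit.mean == pytest.approx(100.0, abs=1e-12)
        assert fit.amplitude == pytest.approx(50.0, abs=1e-10)
        assert fit.phase == pytest.approx(0.0, abs=1e-12)

    def test_shift_theorem(self):
        s = np.arange(5)
        counts = 100.0 * (1 + 0.5 * np.cos(2 * np.pi * s / 5 + np.pi / 2))
        fit = fit_stepping_curve(counts)
        assert fit.phase == pytest.approx(np.pi / 2, abs=1e-12)

    @given(
        mean=st.floats(10.0, 1e4),
        rel_amp=st.floats(0.01, 0.99),
        phase=st.floats(-3.1, 3.1),
        n=st.integers(4, 12),
    )
    @settings(max_examples=50, deadline=None)
    def test_fit_inverts_any_exact_sinusoid(self, mean, rel_amp, phase, n):
        s = np.arange(n)
        counts = mean * (1 + rel_amp * np.cos(2 * np.pi * s / n + phase))
        fit = fit_stepping_curve(counts, n)
        assert fit.mean == pytest.approx(mean, rel=1e-9)
        assert fit.amplitude == pytest.approx(mean * rel_amp, rel=1e-9)
        assert wrap_phase(fit.phase - phase) == pytest.approx(0.0, abs=1e-8)

    def test_too_few_steps_rejected(self):
        with pytest.raises(ValueError):
            fit_stepping_curve(np.array([1.0, 2.0, 3.0]))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_stepping_curve(np.array([1.0, -2.0, 3.0, 4.0]))


class TestWrapConvention:
    def test_range_is_left_open_at_minus_pi(self):
        assert wrap_phase(np.pi) == pytest.approx(np.pi)
        assert wrap_phase(-np.pi) == pytest.approx(np.pi)  # tie maps to +pi
        assert wrap_phase(0.0) == pytest.approx(0.0)
        assert wrap_phase(3 * np.pi / 2) == pytest.approx(-np.pi / 2)


class TestRetrieve:
    def test_identical_scans_give_unit_transmission_zero_phase(self):
        scan = make_flat_scan(100.0, 100.0)
        sino = retrieve(scan)
        np.testing.assert_allclose(sino.transmission, 1.0, atol=1e-12)
        np.testing.assert_allclose(sino.dphase, 0.0, atol=1e-12)

    def test_transmission_is_ratio_of_means(self):
        sino = retrieve(make_flat_scan(50.0, 100.0))
        np.testing.assert_allclose(sino.transmission, 0.5, atol=1e-12)

    def test_phase_difference_recovered(self):
        sino = retrieve(make_flat_scan(80.0, 100.0, phase=0.3))
        np.testing.assert_allclose(sino.dphase, 0.3, atol=1e-12)

    def test_noiseless_phantom_round_trip_is_exact(self):
        """Retrieval inverts the forward model to machine precision."""
        from gbpct.acquisition import expected_stepping_curves

        ph = make_phantom((32, 32), seed=2)
        geo = AcquisitionGeometry(n_angles=20)
        scan = simulate_stepping(ph, geo, noise=False)
        _, _, t_true, phi_true = expected_stepping_curves(ph, geo)
        sino = retrieve(scan)
        np.testing.assert_allclose(sino.transmission, t_true, rtol=1e-12)
        np.testing.assert_allclose(sino.dphase, phi_true, atol=1e-12)

    def test_zero_reference_pixel_masked_with_warning(self):
        scan = make_flat_scan(50.0, 100.0)
        scan.reference[:, 3] = 0.0
        with pytest.warns(UserWarning, match="masked"):
            sino = retrieve(scan)
        assert np.all(np.isnan(sino.transmission[:, 3]))
        assert not sino.mask[:, 3].any()
        assert sino.mask[:, 0].all()


class TestPatchwise:
    def test_radius_zero_is_bit_identical_to_pixelwise(self):
        ph = make_phantom((32, 32), seed=3)
        geo = AcquisitionGeometry(n_angles=6, seed=1)
        scan = simulate_stepping(ph, geo, noise=True)
        a = retrieve(scan)
        b = retrieve_patchwise(scan, radius=0)
        np.testing.assert_array_equal(a.transmission, b.transmission)
        np.testing.assert_array_equal(a.dphase, b.dphase)

    def test_homogeneous_noiseless_scan_unchanged_by_pooling(self):
        scan = make_flat_scan(70.0, 100.0, n_cols=16, phase=0.2)
        a = retrieve(scan)
        b = retrieve_patchwise(scan, radius=2)
        interior = slice(2, -2)
        np.testing.assert_allclose(
            b.transmission[:, interior], a.transmission[:, interior], atol=1e-10
        )
        np.testing.assert_allclose(
            b.dphase[:, interior], a.dphase[:, interior], atol=1e-10
        )

    def test_pooled_fit_matches_joint_least_squares_oracle(self):
        """Oracle: explicit least-squares sinusoid fit on the concatenated
        neighborhood series (all pooled pixels share a, b, phi)."""
        rng = np.random.default_rng(0)
        geo = AcquisitionGeometry(
            n_angles=1, n_steps=5, visibility=0.3, flux_per_step=100.0,
            reference_exposure_factor=1.0, seed=0,
        )
        n_cols = 15
        sample = rng.poisson(
            100.0 * (1 + 0.3 * np.cos(2 * np.pi * np.arange(5) / 5))[None, :, None]
            * np.linspace(0.5, 1.0, n_cols)[None, None, :]
        ).astype(float)
        s5 = np.arange(5)
        reference = np.tile(
            (100.0 * (1 + 0.3 * np.cos(2 * np.pi * s5 / 5)))[:, None], (1, n_cols)
        )
        scan = SteppingScan(sample=sample, reference=reference, geometry=geo)
        radius = 2
        sino = retrieve_patchwise(scan, radius=radius)

        col = 7
        pooled = sample[0, :, col - radius : col + radius + 1].sum(axis=1)
        design = np.stack(
            [np.ones(5), np.cos(2 * np.pi * s5 / 5), np.sin(2 * np.pi * s5 / 5)],
            axis=1,
        )
        coef, *_ = np.linalg.lstsq(design, pooled, rcond=None)
        a_fit = coef[0] / (2 * radius + 1)
        phi_fit = np.arctan2(-coef[2], coef[1])
        assert sino.transmission[0, col] == pytest.approx(a_fit / 100.0, rel=1e-9)
        assert sino.dphase[0, col] == pytest.approx(phi_fit, abs=1e-9)

    def test_step_edge_blurs_with_radius(self):
        """Pooling across a transmission edge widens the 10-90% edge width."""
        geo = AcquisitionGeometry(
            n_angles=1, n_steps=5, visibility=0.3, flux_per_step=1000.0,
            reference_exposure_factor=1.0,
        )
        n_cols = 32
        s5 = np.arange(5)
        curve = 1 + 0.3 * np.cos(2 * np.pi * s5 / 5)
        t_profile = np.where(np.arange(n_cols) < n_cols // 2, 1.0, 0.2)
        sample = 1000.0 * t_profile[None, None, :] * curve[None, :, None]
        reference = np.tile(1000.0 * curve[:, None], (1, n_cols))
        scan = SteppingScan(sample=sample, reference=reference, geometry=geo)

        def edge_width(t):
            lo, hi = 0.2 + 0.1 * 0.8, 0.2 + 0.9 * 0.8
            cols = np.arange(n_cols)
            below = cols[t < lo].min()
            above = cols[t > hi].max()
            return below - above

        w0 = edge_width(retrieve(scan).transmission[0])
        w2 = edge_width(retrieve_patchwise(scan, radius=2).transmission[0])
        assert w2 > w0

    def test_variance_decreases_monotonically_with_radius(self):
        geo = AcquisitionGeometry(n_angles=1, flux_per_step=200.0, seed=8)
        ph = PhantomVolume(mu=np.zeros((64, 64)), delta=np.zeros((64, 64)))
        scan = simulate_stepping(ph, geo, noise=True)
        variances = [
            np.var(retrieve_patchwise(scan, r).dphase[:, 8:-8]) for r in (0, 1, 2, 3)
        ]
        assert all(a > b for a, b in zip(variances, variances[1:]))

    def test_too_large_radius_rejected(self):
        scan = make_flat_scan(50.0, 100.0, n_cols=8)
        with pytest.raises(ValueError):
            retrieve_patchwise(scan, radius=5)
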