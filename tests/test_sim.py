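"""Forward-model unit and property tests: Lorentzian line shapes,
Bloch-McConnell oracle agreement, phantom determinism, Rician noise."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import curve_fit

from glucest import (
    AcquisitionSpec,
    PhantomSpec,
    Pool,
    add_noise,
    bloch_mcconnell_z,
    default_pools,
    lorentzian_z,
    make_phantom,
    simulate_phantom,
)
from glucest.quant import mtr_asym_spectrum

OFFSETS = np.linspace(-6.0, 6.0, 25)


class TestLorentzianZ:
    def test_single_centered_pool_is_symmetric(self, water_pool):
        z = lorentzian_z(OFFSETS, [water_pool])
        assert np.allclose(z, z[::-1])

    def test_full_saturation_at_water_center(self):
        pool = Pool(shift=0.0, amplitude=1.0 - 1e-12, width=1.0)
        z = lorentzian_z(np.array([0.0]), [pool])
        assert z[0] == pytest.approx(0.0, abs=1e-9)

    def test_two_pool_asymmetry_matches_scalar_arithmetic(self, water_pool, glu_pool):
        # independent scalar evaluation of the same two-Lorentzian sum
        def scalar_z(x):
            za = 0.9 * (1.5 / 2) ** 2 / ((1.5 / 2) ** 2 + x**2)
            zb = 0.05 * (1.0 / 2) ** 2 / ((1.0 / 2) ** 2 + (x - 3.0) ** 2)
            return 1.0 - za - zb

        z = lorentzian_z(np.array([-3.0, 3.0]), [water_pool, glu_pool])
        expected = (scalar_z(-3.0) - scalar_z(3.0)) / scalar_z(-3.0)
        got = (z[0] - z[1]) / z[0]
        assert got > 0
        assert got == pytest.approx(expected, rel=1e-12)

    def test_b0_shift_translates_spectrum(self, water_pool):
        z0 = lorentzian_z(OFFSETS, [water_pool])
        z1 = lorentzian_z(OFFSETS + 0.5, [water_pool], b0_shift=0.5)
        assert np.allclose(z0, z1)

    def test_rejects_nonpositive_b1(self, water_pool):
        with pytest.raises(ValueError, match="b1_scale"):
            lorentzian_z(OFFSETS, [water_pool], b1_scale=0.0)

    def test_rejects_unphysical_amplitude_sum(self):
        pools = [Pool(0.0, 0.9, 1.5), Pool(0.1, 0.9, 1.5)]
        with pytest.raises(ValueError, match="unphysical"):
            lorentzian_z(np.array([0.05]), pools)

    @given(
        amp=st.floats(0.0, 0.08),
        width=st.floats(0.5, 1.5),
        b1=st.floats(0.5, 1.3),
    )
    @settings(deadline=None, max_examples=50)
    def test_symmetric_pools_have_zero_asymmetry(self, amp, width, b1):
        """Any pool set mirror-symmetric about water gives MTR_asym == 0."""
        pools = [
            Pool(0.0, 0.6, 1.5, "water"),
            Pool(+2.5, amp, width),
            Pool(-2.5, amp, width),
        ]
        z = lorentzian_z(OFFSETS, pools, b1_scale=b1)
        _, asym = mtr_asym_spectrum(z, OFFSETS)
        assert np.allclose(asym, 0.0, atol=1e-10)

    @given(st.lists(st.integers(0, 100), min_size=2, max_size=6, unique=True))
    @settings(deadline=None, max_examples=30)
    def test_glucest_strictly_increasing_in_glu_amplitude(self, milli_amps):
        """The 3 ppm contrast is strictly monotone in the glutamate pool size."""
        def contrast(a):
            z = lorentzian_z(np.array([-3.0, 3.0]), default_pools(a))
            return (z[0] - z[1]) / z[0]

        ordered = [a / 1000.0 for a in sorted(milli_amps)]
        vals = [contrast(a) for a in ordered]
        assert all(v2 > v1 for v1, v2 in zip(vals, vals[1:]))


class TestBlochMcConnell:
    WATER = Pool(0.0, t1=1.5, t2=0.05, label="water")
    NO_SOLUTE = Pool(3.0, fraction=0.0, t1=1.0, t2=0.01)

    def test_no_solute_far_off_resonance_leaves_water_unsaturated(self):
        z = bloch_mcconnell_z(
            np.array([-300.0, 300.0]), self.WATER, self.NO_SOLUTE, 1.0, 1.0
        )
        assert np.all(z > 0.99)

    def test_single_pool_spectrum_is_symmetric(self):
        offs = np.array([-4.0, -2.0, -1.0, 1.0, 2.0, 4.0])
        z = bloch_mcconnell_z(offs, self.WATER, self.NO_SOLUTE, 2.0, 1.0)
        assert np.allclose(z, z[::-1], atol=1e-10)

    def test_slow_exchange_agrees_with_matched_lorentzian(self):
        """Two-pool numerics vs the Lorentzian forward model.

        The solute CEST line extracted from the Bloch-McConnell difference
        spectrum is matched by least squares, fed back into the Lorentzian
        model, and the two MTR asymmetries at 3 ppm must agree within the
        declared 5% relative tolerance.
        """
        solute = Pool(3.0, fraction=0.001, exchange_rate=100.0, t1=1.0, t2=0.01)
        z1 = bloch_mcconnell_z(OFFSETS, self.WATER, self.NO_SOLUTE, 1.0, 1.0)
        z2 = bloch_mcconnell_z(OFFSETS, self.WATER, solute, 1.0, 1.0)
        i3 = np.argmin(np.abs(OFFSETS - 3.0))
        im3 = np.argmin(np.abs(OFFSETS + 3.0))
        mtr_bm = (z2[im3] - z2[i3]) / z2[im3]

        def lor(x, amp, width, center):
            return amp * (width / 2) ** 2 / ((width / 2) ** 2 + (x - center) ** 2)

        pos = OFFSETS > 0.5
        (amp, width, center), _ = curve_fit(
            lor, OFFSETS[pos], (z1 - z2)[pos], p0=[np.max(z1 - z2), 1.0, 3.0]
        )
        (w_amp, w_width), _ = curve_fit(
            lambda x, a, w: 1 - lor(x, a, w, 0.0),
            OFFSETS,
            z1,
            p0=[0.5, 1.5],
            bounds=([0, 0.1], [0.999, 10]),
        )
        zl = lorentzian_z(
            np.array([-3.0, 3.0]),
            [Pool(0.0, w_amp, w_width, "water"), Pool(center, amp, width, "glu")],
        )
        mtr_l = (zl[0] - zl[1]) / zl[0]
        assert np.sign(mtr_l) == np.sign(mtr_bm)
        assert mtr_l == pytest.approx(mtr_bm, rel=0.05)

    def test_requires_solute_fraction(self):
        with pytest.raises(ValueError, match="fraction"):
            bloch_mcconnell_z(OFFSETS, self.WATER, Pool(3.0), 1.0, 1.0)


class TestAddNoise:
    def test_zero_sigma_is_identity(self):
        img = np.linspace(0, 1, 12).reshape(3, 4)
        out = add_noise(img, 0.0, seed=3)
        assert np.array_equal(out, img)

    def test_seeded_reproducibility(self):
        img = np.ones((5, 5))
        a = add_noise(img, 0.05, seed=42)
        b = add_noise(img, 0.05, seed=42)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, add_noise(img, 0.05, seed=43))

    def test_rician_is_unbiased_in_large_signal_limit(self):
        """Rician noise tends to additive zero-mean Gaussian when the
        signal dominates sigma, so the noisy/clean ratio has mean 1."""
        n = 10_000
        img = np.full(n, 100.0)
        sigma = 0.01  # of reference 100 -> SNR 100
        out = add_noise(img, sigma, seed=7, reference=100.0)
        ratio = out / img
        sem = np.std(ratio, ddof=1) / np.sqrt(n)
        assert abs(np.mean(ratio) - 1.0) < 3 * sem + sigma**2 / 2

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            add_noise(np.ones(3), -0.1, seed=0)


class TestSimulatePhantom:
    def test_same_seed_is_bit_identical(self, acq):
        kwargs = dict(matrix=(16, 16), noise_sigma=0.02, b0_max=0.1, seed=5)
        a = simulate_phantom(make_phantom(**kwargs), acq)
        b = simulate_phantom(make_phantom(**kwargs), acq)
        assert np.array_equal(a.cest_stack.data, b.cest_stack.data)
        assert np.array_equal(a.wassr_stack.data, b.wassr_stack.data)
        assert np.array_equal(a.angle_images[0], b.angle_images[0])
        assert np.array_equal(a.angle_images[1], b.angle_images[1])

    def test_three_group_truth_means_are_ordered(self, acq):
        means = []
        for amp in (0.040, 0.046, 0.056):
            ph = make_phantom(matrix=(16, 16), glu_amplitude=amp, seed=1)
            study = simulate_phantom(ph, acq)
            means.append(study.truth_glucest.value[ph.roi_mask].mean())
        assert means[0] < means[1] < means[2]

    def test_geometry_mismatch_rejected(self, acq):
        ph = make_phantom(matrix=(8, 8), seed=1)
        with pytest.raises(ValueError, match="matrix"):
            simulate_phantom(ph, acq)

    def test_b0_exceeding_wassr_span_rejected(self, acq):
        with pytest.raises(ValueError, match="half-span"):
            ph = make_phantom(matrix=(16, 16), b0_max=0.9, seed=1)
            simulate_phantom(ph, acq)


class TestSpecValidation:
    def test_acquisition_grids_must_be_symmetric(self):
        with pytest.raises(ValueError, match="symmetric"):
            AcquisitionSpec(cest_offsets=np.linspace(-6, 5.5, 24))

    def test_flip_angles_must_double(self):
        with pytest.raises(ValueError, match="2\\*alpha"):
            AcquisitionSpec(b1_angles=(30.0, 70.0))

    def test_phantom_requires_positive_b1(self):
        ones = np.ones((4, 4))
        with pytest.raises(ValueError, match="positive"):
            PhantomSpec(
                roi_mask=ones > 0,
                pools_inside=tuple(default_pools()),
                pools_outside=tuple(default_pools()),
                b0_field=np.zeros((4, 4)),
                b1_field=np.zeros((4, 4)),
            )

    def test_pool_invariants(self):
        with pytest.raises(ValueError):
            Pool(shift=3.0, amplitude=-0.1)
        with pytest.raises(ValueError):
            Pool(shift=3.0, width=0.0)
        with pytest.raises(ValueError):
            Pool(shift=3.0, fraction=0.001, exchange_rate=-5.0)
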