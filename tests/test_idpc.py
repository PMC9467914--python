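"""Reconstruction core: DPC vector, integration, filtering, CTF, SNR."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import idpcstem as ix
from idpcstem.phantom import SpecimenPotential
from conftest import ncc


def _gaussian_and_gradient(n, sigma):
    x = np.arange(n) - n / 2
    xx, yy = np.meshgrid(x, x, indexing="xy")
    phi = np.exp(-(xx**2 + yy**2) / (2 * sigma**2))
    k = np.fft.fftfreq(n, d=1.0)
    gx = np.real(np.fft.ifft2(np.fft.fft2(phi) * 2j * np.pi * k[None, :]))
    gy = np.real(np.fft.ifft2(np.fft.fft2(phi) * 2j * np.pi * k[:, None]))
    return phi, gx, gy


def _quad(arrs, pixel=1.0):
    det = ix.DetectorGeometry(6.0, 1.0, 4.0)
    return ix.QuadrantImages(*arrs, pixel, det)


class TestDPCVector:
    def test_equal_quadrants_zero_field(self):
        a = np.full((8, 8), 3.0)
        d = ix.dpc_vector(_quad([a, a.copy(), a.copy(), a.copy()]))
        assert np.all(d.x == 0) and np.all(d.y == 0)

    def test_zero_rotation_pure_subtraction(self):
        rng = np.random.default_rng(0)
        arrs = [rng.uniform(0, 1, (6, 6)) for _ in range(4)]
        d = ix.dpc_vector(_quad(arrs), scan_rotation_deg=0.0)
        a, b, c, dd = arrs
        assert np.allclose(d.x, (a + dd) - (b + c))
        assert np.allclose(d.y, (a + b) - (c + dd))

    def test_rotation_90_swaps_components(self):
        rng = np.random.default_rng(1)
        arrs = [rng.uniform(0, 1, (6, 6)) for _ in range(4)]
        d0 = ix.dpc_vector(_quad(arrs), 0.0)
        d90 = ix.dpc_vector(_quad(arrs), 90.0)
        assert np.allclose(d90.x, d0.y)
        assert np.allclose(d90.y, -d0.x)


class TestIntegration:
    def test_recovers_analytic_potential(self):
        """∇φ of a Gaussian integrates back to φ with <1e-6 relative error."""
        phi, gx, gy = _gaussian_and_gradient(64, 6.0)
        rec = ix.integrate_dpc(ix.DPCField(gx, gy, 1.0, "scan")).values
        ref = phi - phi.mean()
        assert np.linalg.norm(rec - ref) / np.linalg.norm(ref) < 1e-6

    def test_zero_field_zero_image(self):
        z = np.zeros((16, 16))
        assert np.all(ix.integrate_dpc(ix.DPCField(z, z, 1.0, "scan")).values == 0)

    def test_linearity(self):
        _, gx1, gy1 = _gaussian_and_gradient(32, 4.0)
        rng = np.random.default_rng(2)
        gx2, gy2 = rng.normal(size=(2, 32, 32))
        a, b = 2.5, -1.3
        lhs = ix.integrate_dpc(
            ix.DPCField(a * gx1 + b * gx2, a * gy1 + b * gy2, 1.0, "scan")).values
        rhs = a * ix.integrate_dpc(ix.DPCField(gx1, gy1, 1.0, "scan")).values \
            + b * ix.integrate_dpc(ix.DPCField(gx2, gy2, 1.0, "scan")).values
        assert np.abs(lhs - rhs).max() < 1e-10 * np.abs(rhs).max()

    def test_detector_frame_rejected(self):
        z = np.zeros((8, 8))
        with pytest.raises(ValueError):
            ix.integrate_dpc(ix.DPCField(z, z, 1.0, "detector"))

    @settings(max_examples=15, deadline=None)
    @given(sigma=st.floats(3.0, 10.0), amp=st.floats(0.1, 50.0))
    def test_gradient_roundtrip_property(self, sigma, amp):
        # band-limit the field (zero Nyquist) so its spectral gradient is
        # exactly real and the round trip is limited only by float error
        phi, _, _ = _gaussian_and_gradient(48, sigma)
        spec = np.fft.fft2(amp * phi)
        spec[24, :] = 0.0
        spec[:, 24] = 0.0
        phi = np.real(np.fft.ifft2(spec))
        k = np.fft.fftfreq(48, d=1.0)
        gx = np.real(np.fft.ifft2(np.fft.fft2(phi) * 2j * np.pi * k[None, :]))
        gy = np.real(np.fft.ifft2(np.fft.fft2(phi) * 2j * np.pi * k[:, None]))
        rec = ix.integrate_dpc(ix.DPCField(gx, gy, 1.0, "scan")).values
        ref = phi - phi.mean()
        assert np.linalg.norm(rec - ref) / np.linalg.norm(ref) < 1e-6


class TestGaussianHighpass:
    def _sine_image(self, n, cycles, pixel=1.0):
        # integer cycle counts keep the image on a single Fourier mode
        x = np.arange(n)
        img = np.sin(2 * np.pi * cycles * x[None, :] / n) * np.ones((n, 1))
        return ix.IDPCImage(img, pixel)

    def test_constant_removed(self):
        img = ix.IDPCImage(np.full((64, 64), 5.0), 1.0)
        out = ix.gaussian_highpass(img, 40.0)
        assert np.abs(out.values).max() < 1e-10

    def test_high_frequency_passes(self):
        img = self._sine_image(256, 32)  # period 8 Å << 251 Å
        out = ix.gaussian_highpass(img, 251.0)
        sel = np.s_[64:192, 64:192]  # interior, away from the padded edges
        gain = np.linalg.norm(out.values[sel]) / np.linalg.norm(img.values[sel])
        assert gain > 0.99

    def test_gain_squares_on_second_application(self):
        """The filter is multiplicative in the spectrum: applying it twice
        squares the gain (checked without the edge padding, which is a
        boundary treatment, not part of the operator)."""
        img = self._sine_image(256, 1)  # period 256 Å: partially attenuated
        once = ix.gaussian_highpass(img, 120.0, pad=False)
        twice = ix.gaussian_highpass(once, 120.0, pad=False)
        g1 = np.linalg.norm(once.values) / np.linalg.norm(img.values)
        g2 = np.linalg.norm(twice.values) / np.linalg.norm(img.values)
        assert g2 == pytest.approx(g1**2, rel=0.02)

    def test_unresolvable_fwhm_rejected(self):
        with pytest.raises(ValueError):
            ix.gaussian_highpass(ix.IDPCImage(np.zeros((32, 32)), 2.0), 3.0)


def overlap_integral_ctf(beam, det, n, spacing, step=3):
    """Aperture-overlap oracle for the quadrant-iDPC transfer function.

    For a weak phase grating at frequency q, the detector-D signal modulates
    as beta_D(q) = sum_k D(k) A(k) [A(k−q) − A(k+q)]; Fourier integration of
    the two DPC channels gives CTF(q) = (qx βx + qy βy)/(2π|q|²).  Built from
    sharp masks and direct summation — no scan, no propagation, no
    reconstruction operator.
    """
    lam = beam.wavelength_A
    alpha = beam.csa_mrad * 1e-3
    k1 = np.fft.fftfreq(n, d=spacing)
    kx, ky = np.meshgrid(k1, k1, indexing="xy")
    kr = np.hypot(kx, ky)
    A = (kr <= alpha / lam).astype(float)
    A /= n * np.sqrt((A**2).sum() / n**2)  # ortho-spectrum of a unit probe
    th_x, th_y = kx * lam * 1e3, ky * lam * 1e3
    tr = np.hypot(th_x, th_y)
    ann = (tr > det.hole_radius_mrad) & (tr < det.outer_radius_mrad)
    qi = np.floor_divide(np.mod(np.arctan2(th_y, th_x), 2 * np.pi),
                         np.pi / 2).astype(int) % 4
    dx_mask = np.where(ann, np.where((qi == 0) | (qi == 3), 1.0, -1.0), 0.0)
    dy_mask = np.where(ann, np.where((qi == 0) | (qi == 1), 1.0, -1.0), 0.0)
    out = {}
    for i in range(0, n, step):
        for j in range(0, n, step):
            q = np.hypot(kx[i, j], ky[i, j])
            if q == 0:
                continue
            am = np.roll(np.roll(A, i, axis=0), j, axis=1)
            ap = np.roll(np.roll(A, -i, axis=0), -j, axis=1)
            bx = (dx_mask * A * (am - ap)).sum()
            by = (dy_mask * A * (am - ap)).sum()
            out[(i, j)] = (kx[i, j] * bx + ky[i, j] * by) / (2 * np.pi * q**2)
    return out


class TestCTF:
    def test_support_and_positivity(self, ctf_pair):
        quad, _ = ctf_pair
        freqs, rad = quad.radial_profile()
        peak = rad.max()
        beyond = freqs > 1.05 * quad.cutoff
        assert np.abs(rad[beyond]).max() < 1e-6 * peak
        inside = (freqs > 0) & (freqs < 0.95 * quad.cutoff)
        assert rad[inside].min() > -1e-3 * peak

    def test_monotone_decay(self, ctf_pair):
        quad, _ = ctf_pair
        freqs, rad = quad.radial_profile()
        sel = (freqs > 0.2 * quad.cutoff) & (freqs < 0.9 * quad.cutoff)
        assert np.all(np.diff(rad[sel]) < 0)

    def test_fourfold_modulation_only_for_quadrants(self, ctf_pair):
        """4θ azimuthal coefficient: present for quadrants, absent for COM."""
        quad, com_ = ctf_pair

        def c4(profile):
            n = profile.values.shape[0]
            v = np.fft.fftshift(profile.values)
            k = np.fft.fftshift(np.fft.fftfreq(n, d=0.85))
            kx, ky = np.meshgrid(k, k, indexing="xy")
            kr, phi = np.hypot(kx, ky), np.arctan2(ky, kx)
            sel = (kr > 0.2 * profile.cutoff) & (kr < 0.5 * profile.cutoff)
            return float(np.abs(np.mean(v[sel] * np.exp(-4j * phi[sel])))
                         / np.mean(v[sel]))

        assert c4(quad) > 3 * c4(com_)
        assert c4(com_) < 0.02

    def test_matches_overlap_integral_oracle(self, beam4, det4, ctf_pair):
        """Radially averaged pipeline CTF agrees with the analytic
        aperture-overlap route in absolute scale to 10% of peak."""
        quad, _ = ctf_pair
        oracle = overlap_integral_ctf(beam4, det4, 96, 0.85, step=3)
        k1 = np.fft.fftfreq(96, d=0.85)
        kx, ky = np.meshgrid(k1, k1, indexing="xy")
        dk = quad.frequency_spacing
        sums, counts = {}, {}
        for (i, j), val in oracle.items():
            shell = int(round(np.hypot(kx[i, j], ky[i, j]) / dk))
            sums[shell] = sums.get(shell, 0.0) + val
            counts[shell] = counts.get(shell, 0) + 1
        freqs, rad = quad.radial_profile()
        peak = rad.max()
        for shell, total in sums.items():
            f = shell * dk
            if not (0.05 * quad.cutoff < f < 0.9 * quad.cutoff):
                continue
            assert abs(total / counts[shell] - rad[shell]) < 0.10 * peak

    def test_invalid_mode(self, beam4, det4):
        with pytest.raises(ValueError):
            ix.compute_ctf(beam4, det4, 96, 0.85, mode="nonsense")


@pytest.fixture(scope="module")
def thin_weak_setup(beam4, det4):
    n, s = 96, 0.85
    rng = np.random.default_rng(5)
    x = (np.arange(n) - n / 2) * s
    xx, yy = np.meshgrid(x, x, indexing="xy")
    v = np.zeros((n, n))
    for _ in range(12):
        cx, cy = rng.uniform(-30, 30, 2)
        sg = rng.uniform(2, 5)
        v += rng.uniform(5, 15) * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2)
                                         / (2 * sg**2))
    specimen = SpecimenPotential(v[None], s, 10.0)
    scan = ix.ScanGeometry(s, n)
    plan = ix.plan_acquisition(beam4, scan, 35.0)
    q = ix.scan_image(specimen, beam4, scan, det4, plan,
                      ix.SimulationSettings.for_beam(beam4))
    full = ix.integrate_dpc(ix.dpc_vector(q))
    return v, specimen, full


class TestWPOModel:
    def test_matches_full_pipeline(self, thin_weak_setup, ctf_pair):
        v, _, full = thin_weak_setup
        quad, _ = ctf_pair
        wpo = ix.wpo_image(v, quad, ix.interaction_constant(300.0))
        assert ncc(full.values, wpo.values) > 0.98

    def test_protein_renders_white(self, thin_weak_setup):
        v, _, full = thin_weak_setup
        assert np.corrcoef(full.values.ravel(), v.ravel())[0, 1] > 0.9

    def test_zero_potential_zero_image(self, ctf_pair):
        quad, _ = ctf_pair
        out = ix.wpo_image(np.zeros_like(quad.values), quad, 1e-3)
        assert np.all(out.values == 0)

    def test_ctf_deconvolution_roundtrip(self, ctf_pair):
        """Filtering then eps-regularized unfiltering recovers the band-limited
        potential to <1%."""
        quad, _ = ctf_pair
        n = quad.values.shape[0]
        rng = np.random.default_rng(9)
        v = rng.normal(size=(n, n))
        sigma = 1e-3
        img = ix.wpo_image(v, quad, sigma)
        c = quad.values
        support = np.abs(c) > 0.05 * np.abs(c).max()
        rec = np.real(np.fft.ifft2(
            np.where(support, np.fft.fft2(img.values) / (c + 1e-12), 0)))
        ref = np.real(np.fft.ifft2(np.fft.fft2(sigma * v) * support))
        ref -= ref.mean()
        assert np.linalg.norm(rec - ref) / np.linalg.norm(ref) < 0.01

    def test_end_to_end_linearity(self, beam4, det4, thin_weak_setup):
        """Scaling the weak potential scales the noiseless iDPC image."""
        v, specimen, full = thin_weak_setup
        scaled = SpecimenPotential(0.5 * specimen.slices, specimen.voxel_xy_A,
                                   specimen.slice_dz_A)
        scan = ix.ScanGeometry(specimen.voxel_xy_A, 96)
        plan = ix.plan_acquisition(beam4, scan, 35.0)
        q = ix.scan_image(scaled, beam4, scan, det4, plan,
                          ix.SimulationSettings.for_beam(beam4))
        half = ix.integrate_dpc(ix.dpc_vector(q))
        assert np.linalg.norm(half.values - 0.5 * full.values) \
            < 0.01 * np.linalg.norm(0.5 * full.values)


class TestSNR:
    def test_noiseless_uniform_background_infinite(self):
        img = ix.IDPCImage(np.pad(np.ones((4, 4)), 6), 1.0)
        sig = np.pad(np.ones((4, 4), bool), 6)
        bg = ~np.pad(np.ones((8, 8), bool), 4)
        assert ix.snr_of_particle(img, sig, bg) == np.inf

    def test_masks_must_be_disjoint(self):
        img = ix.IDPCImage(np.ones((8, 8)), 1.0)
        m = np.ones((8, 8), bool)
        with pytest.raises(ValueError):
            ix.snr_of_particle(img, m, m)

    def test_snr_decreases_with_csa(self, snr_by_csa):
        """At fixed dose, larger CSA spreads electrons over more solid angle
        and costs particle SNR."""
        vals = {csa: snr for csa, (snr, _) in snr_by_csa.items()}
        assert vals[2.0] > vals[4.5] > vals[10.0] > 0

    def test_snr_scales_with_sqrt_dose(self, snr_by_csa):
        """Doubling the dose improves SNR by about √2 (Poisson statistics)."""
        _, q = snr_by_csa[4.5]
        npx = q.a.shape[0]
        yy, xx = np.meshgrid(np.arange(npx) - (npx - 1) / 2,
                             np.arange(npx) - (npx - 1) / 2, indexing="ij")
        r = np.hypot(xx, yy)
        sig_m, bg_m = r < 10, r > 14
        q2 = ix.QuadrantImages(2 * q.a, 2 * q.b, 2 * q.c, 2 * q.d,
                               q.pixel_size_A, q.detector)
        def mean_snr(qq, n_seeds=24):
            return np.mean([ix.snr_of_particle(
                ix.integrate_dpc(ix.dpc_vector(ix.add_shot_noise(qq, 50 + s))),
                sig_m, bg_m) for s in range(n_seeds)])
        ratio = mean_snr(q2) / mean_snr(q)
        assert ratio == pytest.approx(np.sqrt(2), rel=0.25)
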