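"""iDPC reconstruction: DPC vector field, Fourier integration, filtering, CTF.

The center-of-mass shift of the CBED pattern is, for a thin weak-phase
object, proportional to the gradient of the projected electrostatic
potential.  A four-quadrant detector approximates the two COM components by
opposite-quadrant differences; 2D Fourier integration of that vector field
yields a scalar image proportional to the projected potential itself — the
iDPC image.  The transfer function of the whole chain is positive, decays
roughly linearly and vanishes at 2α/λ; the quadrant approximation adds a
fourfold azimuthal modulation at low frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft

from .optics import BeamParameters, ScanGeometry, ScanPlan, interaction_constant
from .phantom import SpecimenPotential
from .scan_detector import DetectorGeometry, QuadrantImages, SimulationSettings, \
    scan_image

__all__ = [
    "DPCField",
    "IDPCImage",
    "CTFProfile",
    "dpc_vector",
    "integrate_dpc",
    "gaussian_highpass",
    "compute_ctf",
    "wpo_image",
    "snr_of_particle",
]


@dataclass(frozen=True)
class DPCField:
    """Two-component vector image over scan positions.

    ``frame`` records whether the components are still in the detector
    coordinate frame or have been rotated into the scan frame; integration
    requires the scan frame.
    """

    x: np.ndarray
    y: np.ndarray
    pixel_size_A: float
    frame: str  # "detector" | "scan"

    def __post_init__(self) -> None:
        if self.x.shape != self.y.shape:
            raise ValueError("DPC components must have the same shape")
        if self.frame not in ("detector", "scan"):
            raise ValueError("frame must be 'detector' or 'scan'")


@dataclass(frozen=True)
class IDPCImage:
    """Integrated DPC image; mean-zero by the k=0 convention."""

    values: np.ndarray
    pixel_size_A: float


@dataclass(frozen=True)
class CTFProfile:
    """Transfer function on the 2D frequency grid (fft order, unshifted)."""

    values: np.ndarray
    frequency_spacing: float  # 1/Å per sample
    cutoff: float  # 2α/λ in 1/Å

    def radial_profile(self) -> tuple[np.ndarray, np.ndarray]:
        n = self.values.shape[0]
        k = np.fft.fftfreq(n, d=1.0 / (n * self.frequency_spacing))
        kr = np.hypot(*np.meshgrid(k, k, indexing="xy"))
        bins = np.round(kr / self.frequency_spacing).astype(int)
        counts = np.bincount(bins.ravel())
        sums = np.bincount(bins.ravel(), weights=self.values.ravel())
        prof = sums / np.maximum(counts, 1)
        freqs = np.arange(len(prof)) * self.frequency_spacing
        return freqs, prof


def dpc_vector(q: QuadrantImages, scan_rotation_deg: float | None = None) -> DPCField:
    """DPC vector in the scan frame from opposite-quadrant differences.

    Detector-frame components are x: (A+D)−(B+C), y: (A+B)−(C+D) with
    quadrants labeled counterclockwise from the detector +x axis; they are
    then rotated by −scan_rotation into the scan frame.  Only at zero scan
    rotation is the DPC vector a pure subtraction with no mixing.
    """
    if scan_rotation_deg is None:
        scan_rotation_deg = q.scan_rotation_deg
    dx = (q.a + q.d) - (q.b + q.c)
    dy = (q.a + q.b) - (q.c + q.d)
    rot = np.deg2rad(scan_rotation_deg)
    cx = np.cos(rot) * dx + np.sin(rot) * dy
    cy = -np.sin(rot) * dx + np.cos(rot) * dy
    return DPCField(cx, cy, q.pixel_size_A, "scan")


def integrate_dpc(d: DPCField, regularization_eps: float = 0.0) -> IDPCImage:
    """Fourier integration of the DPC vector field to the iDPC image.

    I(k) = (kx·Dx(k) + ky·Dy(k)) / (2πi(|k|² + eps)), with k=0 nulled, so a
    conservative field ∇φ integrates back to φ up to a constant.  A small
    Tikhonov eps (units 1/Å²) damps the noise amplification near k=0.
    """
    if d.frame != "scan":
        raise ValueError("DPC field must be rotated into the scan frame "
                         "before integration")
    if d.pixel_size_A <= 0:
        raise ValueError("pixel size must be set")
    ny, nx = d.x.shape
    kx1 = np.fft.fftfreq(nx, d=d.pixel_size_A)
    ky1 = np.fft.fftfreq(ny, d=d.pixel_size_A)
    kx, ky = np.meshgrid(kx1, ky1, indexing="xy")
    k2 = kx**2 + ky**2 + regularization_eps
    k2[0, 0] = 1.0  # k=0 term nulled below
    num = kx * sfft.fft2(d.x) + ky * sfft.fft2(d.y)
    num[0, 0] = 0.0
    img = np.real(sfft.ifft2(num / (2j * np.pi * k2)))
    return IDPCImage(img - img.mean(), d.pixel_size_A)


def gaussian_highpass(img: IDPCImage, fwhm_A: float = 251.0,
                      reciprocal_fwhm: bool = False,
                      pad: bool = True) -> IDPCImage:
    """Gaussian high-pass preprocessing: multiply the spectrum by 1 − G(k).

    By default the FWHM is that of the complementary low-pass kernel in real
    space (Å); with ``reciprocal_fwhm`` the value is interpreted as the FWHM
    of the Gaussian in reciprocal space (also given in Å as 1/frequency).
    The image is edge-padded by 10% before filtering to suppress wrap-around.
    """
    if fwhm_A <= 2 * img.pixel_size_A:
        raise ValueError("high-pass FWHM is not resolvable on this grid")
    npad = max(2, int(0.1 * max(img.values.shape))) if pad else 0
    v = np.pad(img.values, npad, mode="edge") if pad else img.values
    ny, nx = v.shape
    kx, ky = np.meshgrid(np.fft.fftfreq(nx, d=img.pixel_size_A),
                         np.fft.fftfreq(ny, d=img.pixel_size_A), indexing="xy")
    k2 = kx**2 + ky**2
    if reciprocal_fwhm:
        sigma_k = (1.0 / fwhm_A) / (2 * np.sqrt(2 * np.log(2)))
        low = np.exp(-k2 / (2 * sigma_k**2))
    else:
        sigma_r = fwhm_A / (2 * np.sqrt(2 * np.log(2)))
        low = np.exp(-2 * np.pi**2 * sigma_r**2 * k2)
    out = np.real(sfft.ifft2(sfft.fft2(v) * (1.0 - low)))
    if pad:
        out = out[npad:npad + img.values.shape[0],
                  npad:npad + img.values.shape[1]]
    return IDPCImage(out - out.mean(), img.pixel_size_A)


def _thin_impulse_specimen(n: int, spacing_A: float, v0: float) -> SpecimenPotential:
    slab = np.zeros((1, n, n))
    slab[0, n // 2, n // 2] = v0
    return SpecimenPotential(slab, spacing_A, 1.0)


def compute_ctf(beam: BeamParameters, det: DetectorGeometry, n: int,
                spacing_A: float, mode: str = "quadrant",
                scan_rotation_deg: float = 0.0) -> CTFProfile:
    """Numerical iDPC transfer function of the full imaging chain.

    Measured as the linear (weak-phase) response: the chain — probe, thin
    phase impulse, far field, detector, opposite-quadrant differences,
    Fourier integration — is simulated on an n×n periodic grid with scan
    step equal to the grid step, and the output spectrum is divided by the
    input phase spectrum.  ``mode='com'`` replaces the quadrants with exact
    center-of-mass detection (rotationally symmetric reference CTF).
    """
    if mode not in ("quadrant", "com"):
        raise ValueError("mode must be 'quadrant' or 'com'")
    cutoff = 2 * (beam.csa_mrad * 1e-3) / beam.wavelength_A
    if 1.0 / (2 * spacing_A) < cutoff:
        raise ValueError("frequency grid does not reach the 2α/λ cutoff; "
                         "reduce the grid spacing")
    sigma = interaction_constant(beam.voltage_kv)
    v0 = 1e-3 / sigma  # 1 mrad peak phase: safely in the linear regime
    specimen = _thin_impulse_specimen(n, spacing_A, v0)
    scan = ScanGeometry(spacing_A, n, scan_rotation_deg)
    plan = ScanPlan(dwell_time_us=1.0, frame_time_s=1.0, total_dose=1.0,
                    electrons_per_dwell=1.0, aliased=False)
    q = scan_image(specimen, beam, scan, det, plan,
                   SimulationSettings(sigma), com_mode=(mode == "com"),
                   dtype=np.complex128)
    img = integrate_dpc(dpc_vector(q, scan_rotation_deg))
    phase = sigma * specimen.projected()
    num = sfft.fft2(img.values)
    den = sfft.fft2(phase)
    ctf = np.real(num / den)
    ctf[0, 0] = 0.0
    dk = 1.0 / (n * spacing_A)
    return CTFProfile(ctf, dk, cutoff)


def wpo_image(projected_potential: np.ndarray, ctf: CTFProfile,
              sigma: float) -> IDPCImage:
    """Linear weak-phase forward model: filter σ·V_proj by the CTF.

    A fast surrogate for the full scan simulation on thin weak specimens;
    the potential renders positive (protein white, not inverted).
    """
    if projected_potential.shape != ctf.values.shape:
        raise ValueError("potential and CTF grids do not match")
    spec = sfft.fft2(sigma * projected_potential) * ctf.values
    img = np.real(sfft.ifft2(spec))
    pixel = 1.0 / (ctf.values.shape[0] * ctf.frequency_spacing)
    return IDPCImage(img - img.mean(), pixel)


def snr_of_particle(img: IDPCImage, signal_mask: np.ndarray,
                    background_mask: np.ndarray) -> float:
    """(mean signal − mean background) / background standard deviation.

    Returns inf for a zero-variance background (noiseless image).
    """
    if not signal_mask.any() or not background_mask.any():
        raise ValueError("masks must be non-empty")
    if (signal_mask & background_mask).any():
        raise ValueError("signal and background masks must be disjoint")
    sig = img.values[signal_mask].mean()
    bg = img.values[background_mask]
    if bg.std() == 0:
        return np.inf
    return (sig - bg.mean()) / bg.std()
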