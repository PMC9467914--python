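"""Electron-optical formulas, probe construction and acquisition planning.

All quantities cross the API in the conventional microscopy units: accelerating
voltage in kV, convergence semi-angle (CSA) in mrad, lengths in Å (depth of
focus in nm), beam current in pA, dwell time in µs, dose in e−/Å².

The convergence semi-angle α of the focused probe sets both the
diffraction-limited resolution λ/(2α) and the depth of focus 2λ/α²; the
required scan pixel size for fully sampling that resolution is λ/(4α)
(Nyquist).  These three numbers, as functions of α at fixed voltage, are the
planning table a cryo-STEM operator works from.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import constants as _const

__all__ = [
    "AberrationCoefficients",
    "BeamParameters",
    "ScanGeometry",
    "ScanPlan",
    "ProbeField",
    "electron_wavelength",
    "max_resolution",
    "depth_of_focus",
    "required_pixel_size",
    "plan_acquisition",
    "min_csa_below_thickness",
    "make_probe",
    "propagate",
    "probe_axial_extent",
    "interaction_constant",
    "planner_table",
]

_E_PER_PA = 1e-12 / _const.e  # electrons per second per pA


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic de Broglie wavelength of the beam electrons, in pm.

    λ = h / sqrt(2 m0 e V (1 + eV / (2 m0 c²)));  300 kV → 1.969 pm.
    """
    if voltage_kv <= 0:
        raise ValueError(f"accelerating voltage must be positive, got {voltage_kv} kV")
    v = voltage_kv * 1e3
    ev = _const.e * v
    p = math.sqrt(2 * _const.m_e * ev * (1 + ev / (2 * _const.m_e * _const.c**2)))
    return _const.h / p * 1e12


def interaction_constant(voltage_kv: float) -> float:
    """Relativistic beam-specimen interaction constant σ in rad/(V·Å).

    The phase imprinted by a thin slice of projected potential Vz [V·Å] is
    σ·Vz.  σ = 2π m e λ / h² with the relativistic electron mass;
    ≈ 6.53e-4 rad/(V·Å) at 300 kV.
    """
    v = voltage_kv * 1e3
    gamma = 1 + _const.e * v / (_const.m_e * _const.c**2)
    lam_m = electron_wavelength(voltage_kv) * 1e-12
    sigma_per_vm = 2 * math.pi * gamma * _const.m_e * _const.e * lam_m / _const.h**2
    return sigma_per_vm * 1e-10


@dataclass(frozen=True)
class AberrationCoefficients:
    """Axial aberrations of the probe-forming lens.

    defocus_nm: positive = underfocus (weaker lens; the beam waist sits
    upstream of the nominal specimen plane).  spherical_cs_mm: Cs.
    """

    defocus_nm: float = 0.0
    spherical_cs_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.spherical_cs_mm < 0:
            raise ValueError("spherical aberration Cs must be >= 0")


@dataclass(frozen=True)
class BeamParameters:
    """Optical state of the instrument: voltage, CSA, aberrations, current."""

    voltage_kv: float
    csa_mrad: float
    aberrations: AberrationCoefficients = field(default_factory=AberrationCoefficients)
    current_pa: float = 4.0

    def __post_init__(self) -> None:
        if self.voltage_kv <= 0:
            raise ValueError("voltage must be positive")
        if self.csa_mrad <= 0:
            raise ValueError("convergence semi-angle must be positive")

    @property
    def wavelength_pm(self) -> float:
        return electron_wavelength(self.voltage_kv)

    @property
    def wavelength_A(self) -> float:
        return self.wavelength_pm * 1e-2


@dataclass(frozen=True)
class ScanGeometry:
    """Raster-scan geometry: pixel size (Å), side length in pixels, rotation."""

    pixel_size_A: float
    n_pixels: int
    scan_rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.pixel_size_A <= 0:
            raise ValueError("pixel size must be positive")
        if self.n_pixels < 2:
            raise ValueError("need at least 2 scan pixels per side")

    @property
    def fov_A(self) -> float:
        return self.n_pixels * self.pixel_size_A


@dataclass(frozen=True)
class ScanPlan:
    """Derived acquisition plan: dwell/frame times and per-dwell dose."""

    dwell_time_us: float
    frame_time_s: float
    total_dose: float  # e−/Å²
    electrons_per_dwell: float
    aliased: bool
    flyback_overhead_s: float = 0.0

    @property
    def total_time_s(self) -> float:
        return self.frame_time_s + self.flyback_overhead_s


def max_resolution(beam: BeamParameters) -> float:
    """Diffraction-limited STEM resolution λ/(2α) in Å.

    The conventional "effective probe diameter"; the numerically measured
    Airy intensity FWHM (≈ 0.51 λ/α) is a different, smaller number and is
    available from :func:`make_probe` output, never substituted here.
    """
    alpha = beam.csa_mrad * 1e-3
    return beam.wavelength_A / (2 * alpha)


def depth_of_focus(beam: BeamParameters) -> float:
    """Depth of focus 2λ/α² in nm."""
    alpha = beam.csa_mrad * 1e-3
    return 2 * (beam.wavelength_pm * 1e-3) / alpha**2


def required_pixel_size(beam: BeamParameters) -> float:
    """Scan pixel size λ/(4α) (Å) that Nyquist-samples the λ/(2α) cutoff."""
    return max_resolution(beam) / 2


def _round_half_up(x: float, decimals: int) -> float:
    q = 10.0**decimals
    return math.floor(x * q + 0.5) / q


def planner_table(voltage_kv: float = 300.0,
                  csas_mrad: tuple[float, ...] = (2.0, 3.0, 3.5, 4.0, 4.5)) -> list[dict]:
    """Planning table of (resolution, required pixel, depth of focus) vs CSA.

    Values are computed from the wavelength rounded to 4 significant figures
    and rounded to the table's printed precision (0.1 Å; 1 nm), half-up.
    """
    lam_pm = float(f"{electron_wavelength(voltage_kv):.4g}")
    lam_A = lam_pm * 1e-2
    rows = []
    for csa in csas_mrad:
        alpha = csa * 1e-3
        rows.append({
            "csa_mrad": csa,
            "resolution_A": _round_half_up(lam_A / (2 * alpha), 1),
            "pixel_size_A": _round_half_up(lam_A / (4 * alpha), 1),
            "depth_of_focus_nm": _round_half_up(2 * lam_pm * 1e-3 / alpha**2, 0),
        })
    return rows


def plan_acquisition(beam: BeamParameters, scan: ScanGeometry, total_dose: float,
                     flyback_overhead_s: float = 0.0) -> ScanPlan:
    """Derive dwell and frame times from the total-dose equation.

    TED = I·t_dwell / PS², so t_dwell = TED·PS²/I (with I converted from pA
    to electrons/s) and t_frame = N²·t_dwell.  The aliased flag is set when
    the scan pixel undersamples the optical cutoff (PS > λ/(4α)).
    """
    if total_dose <= 0:
        raise ValueError("total dose must be positive")
    if beam.current_pa <= 0:
        raise ValueError("cannot plan an acquisition with zero beam current")
    rate = beam.current_pa * _E_PER_PA  # e−/s
    electrons_per_dwell = total_dose * scan.pixel_size_A**2
    dwell_s = electrons_per_dwell / rate
    frame_s = scan.n_pixels**2 * dwell_s
    aliased = scan.pixel_size_A > required_pixel_size(beam)
    return ScanPlan(
        dwell_time_us=dwell_s * 1e6,
        frame_time_s=frame_s,
        total_dose=total_dose,
        electrons_per_dwell=electrons_per_dwell,
        aliased=aliased,
        flyback_overhead_s=flyback_overhead_s,
    )


def dose_from_plan(beam: BeamParameters, scan: ScanGeometry, plan: ScanPlan) -> float:
    """Recompute TED = I·t_dwell/PS² from a plan (round-trip check)."""
    rate = beam.current_pa * _E_PER_PA
    return rate * plan.dwell_time_us * 1e-6 / scan.pixel_size_A**2


def min_csa_below_thickness(voltage_kv: float, thickness_nm: float,
                            max_csa_mrad: int = 100) -> int:
    """Smallest integer CSA (mrad) whose depth of focus drops below a thickness.

    For samples thinner than the depth of focus the image is a complete
    projection; the returned α is the first integer CSA for which it is not.
    Returns 1 if even 1 mrad focuses shorter than the sample (never for
    cryo-relevant thicknesses) and raises if no integer up to max_csa_mrad
    qualifies.
    """
    if thickness_nm <= 0:
        raise ValueError("thickness must be positive")
    for csa in range(1, max_csa_mrad + 1):
        beam = BeamParameters(voltage_kv, float(csa))
        if depth_of_focus(beam) < thickness_nm:
            return csa
    return 1  # every CSA keeps the whole thickness in focus


@dataclass(frozen=True)
class ProbeField:
    """Complex probe wavefunction sampled on a square real-space grid.

    amplitude is normalized so that sum(|ψ|²) = 1; grid_spacing in Å;
    plane_z is the axial offset (Å) from the nominal focal plane.
    """

    amplitude: np.ndarray
    grid_spacing_A: float
    plane_z_A: float = 0.0

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.amplitude) ** 2


def aperture_and_phase(beam: BeamParameters, grid_spacing_A: float, grid_size: int):
    """Top-hat aperture A(k) (with anti-aliased rim) and aberration phase χ(k).

    χ(θ) = (2π/λ)(−Δf·θ²/2 + Cs·θ⁴/4) with θ = λ|k|; positive Δf (underfocus)
    pulls the waist upstream of the nominal plane.
    """
    lam = beam.wavelength_A
    alpha = beam.csa_mrad * 1e-3
    k = np.fft.fftfreq(grid_size, d=grid_spacing_A)
    kx, ky = np.meshgrid(k, k, indexing="xy")
    kr = np.hypot(kx, ky)
    kmax = alpha / lam
    dk = 1.0 / (grid_size * grid_spacing_A)
    # linear rim taper over one frequency sample: quantization-robust top hat
    ap = np.clip((kmax - kr) / dk + 0.5, 0.0, 1.0)
    theta2 = (lam * kr) ** 2
    df_A = beam.aberrations.defocus_nm * 10.0
    cs_A = beam.aberrations.spherical_cs_mm * 1e7
    chi = (2 * np.pi / lam) * (-df_A * theta2 / 2 + cs_A * theta2**2 / 4)
    return ap, chi, kr


def make_probe(beam: BeamParameters, grid_spacing_A: float, grid_size: int) -> ProbeField:
    """Focused probe: inverse transform of the aberrated top-hat aperture.

    The grid must resolve the aperture (spacing ≤ λ/(4α)) and be wide enough
    that the probe tails have decayed at the border.
    """
    if grid_spacing_A > required_pixel_size(beam):
        raise ValueError(
            f"grid spacing {grid_spacing_A:.3f} Å undersamples the aperture; "
            f"need <= {required_pixel_size(beam):.3f} Å")
    ap, chi, _ = aperture_and_phase(beam, grid_spacing_A, grid_size)
    psi = np.fft.fftshift(np.fft.ifft2(ap * np.exp(1j * chi)))
    psi /= np.sqrt(np.sum(np.abs(psi) ** 2))
    border = np.max(np.abs(psi[0, :])) ** 2
    peak = np.max(np.abs(psi)) ** 2
    if border > 1e-4 * peak:
        warnings.warn("probe intensity at the grid border exceeds 1e-4 of peak; "
                      "enlarge the grid", stacklevel=2)
    return ProbeField(psi, grid_spacing_A)


def propagate(psi: np.ndarray, dz_A: float, wavelength_A: float, spacing_A: float) -> np.ndarray:
    """Fresnel free-space propagation of a wavefield by dz along the beam."""
    n = psi.shape[-1]
    k = np.fft.fftfreq(n, d=spacing_A)
    kx, ky = np.meshgrid(k, k, indexing="xy")
    kernel = np.exp(-1j * np.pi * wavelength_A * dz_A * (kx**2 + ky**2))
    return np.fft.ifft2(np.fft.fft2(psi) * kernel)


def probe_axial_extent(beam: BeamParameters, grid_spacing_A: float | None = None,
                       grid_size: int = 256, n_z: int = 121,
                       threshold: float = 0.8) -> float:
    """Axial range (nm) over which the probe's peak intensity stays >= 80% of focus.

    Measured by numerically propagating the in-focus probe over z; scales as
    2λ/α² across CSAs (the proportionality constant depends on the threshold).
    """
    if grid_spacing_A is None:
        grid_spacing_A = required_pixel_size(beam) / 2
    probe = make_probe(beam, grid_spacing_A, grid_size)
    dof_A = depth_of_focus(beam) * 10.0
    zs = np.linspace(-1.5 * dof_A, 1.5 * dof_A, n_z)
    peak0 = probe.intensity.max()
    peaks = np.array([
        np.abs(propagate(probe.amplitude, z, beam.wavelength_A, grid_spacing_A)).max() ** 2
        for z in zs
    ])
    ok = peaks >= threshold * peak0
    if not ok.any():
        return 0.0
    idx = np.where(ok)[0]
    return (zs[idx[-1]] - zs[idx[0]]) * 0.1  # Å → nm
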