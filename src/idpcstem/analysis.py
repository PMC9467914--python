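"""Micrograph and map analysis: power spectra, helical layer lines, B factors, FSC.

A helical rod diffracts onto discrete layer lines at multiples of the
reciprocal pitch (1/23 Å⁻¹ for a TMV-like rod; second order at 1/11.5 Å⁻¹).
Summed power spectra of in-plane rotated segments, collapsed orthogonally to
the helical axis, give a 1D layer-line profile from which the pixel size can
be calibrated against the expected comb {n/22.03 Å⁻¹} and peak ratios read.
Guinier and particle-number (Rosenthal–Henderson) B factors and the Fourier
shell correlation complete the map-quality toolbox.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft
from scipy import ndimage

__all__ = [
    "LayerLineProfile",
    "GuinierFit",
    "FSCCurve",
    "power_spectrum",
    "radial_average",
    "extract_segments",
    "layerline_profile",
    "find_layer_peaks",
    "peak_ratio",
    "calibrate_pixel_size",
    "guinier_bfactor",
    "rosenthal_bfactor",
    "fsc",
]


@dataclass
class LayerLineProfile:
    """Collapsed 1D power profile along the meridional (axial) frequency."""

    frequencies: np.ndarray  # 1/Å, strictly increasing, >= 0
    values: np.ndarray
    pixel_size_A: float
    peaks: list = field(default_factory=list)  # (frequency, height, order)

    def __post_init__(self) -> None:
        if (np.diff(self.frequencies) <= 0).any():
            raise ValueError("frequency axis must be strictly increasing")
        if (self.values < 0).any():
            raise ValueError("power values must be nonnegative")


@dataclass(frozen=True)
class GuinierFit:
    """ln F vs k² regression: B = −4·slope (Å²)."""

    b_factor_A2: float
    fit_range: tuple[float, float]
    intercept: float
    residual: float


@dataclass(frozen=True)
class FSCCurve:
    shells: np.ndarray  # 1/Å
    correlation: np.ndarray
    resolution_at_0143_A: float


def power_spectrum(image: np.ndarray) -> np.ndarray:
    """Centered squared-modulus spectrum |F|² (fftshifted)."""
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite values")
    return np.abs(sfft.fftshift(sfft.fft2(image))) ** 2


def radial_average(ps: np.ndarray, pixel_size_A: float = 1.0):
    """Azimuthal average over annuli one frequency sample wide."""
    ny, nx = ps.shape
    ky, kx = np.meshgrid(sfft.fftshift(sfft.fftfreq(ny, d=pixel_size_A)),
                         sfft.fftshift(sfft.fftfreq(nx, d=pixel_size_A)),
                         indexing="ij")
    kr = np.hypot(kx, ky)
    dk = 1.0 / (max(nx, ny) * pixel_size_A)
    bins = np.round(kr / dk).astype(int)
    counts = np.bincount(bins.ravel())
    sums = np.bincount(bins.ravel(), weights=ps.ravel())
    prof = sums / np.maximum(counts, 1)
    return np.arange(len(prof)) * dk, prof


def extract_segments(micrograph: np.ndarray, coordinates, box_px: int,
                     order: int = 3) -> list[np.ndarray]:
    """Boxed segments rotated so the helical axis is vertical.

    ``coordinates`` is a list of (x, y, in-plane angle°); the angle is the
    axis direction measured counterclockwise from vertical, and each segment
    is rotated by −angle (cubic interpolation) before cropping.
    """
    out = []
    ny, nx = micrograph.shape
    half = box_px // 2
    # crop margin so the rotated box stays inside valid data
    margin = int(np.ceil(half * np.sqrt(2))) + 2
    for x, y, angle in coordinates:
        xi, yi = int(round(x)), int(round(y))
        if (xi - margin < 0 or yi - margin < 0
                or xi + margin > nx or yi + margin > ny):
            raise ValueError(f"segment at ({x}, {y}) does not fit the micrograph")
        crop = micrograph[yi - margin:yi + margin, xi - margin:xi + margin]
        if angle != 0:
            crop = ndimage.rotate(crop, -angle, reshape=False, order=order,
                                  mode="grid-wrap")
        c = crop.shape[0] // 2
        out.append(crop[c - half:c + half, c - half:c + half].copy())
    return out


def layerline_profile(segments, pixel_size_A: float,
                      collapse_halfwidth: float = 1.0 / 50.0) -> LayerLineProfile:
    """Sum of segment power spectra collapsed orthogonally to the helical axis.

    The 2D power spectra are summed over segments, then summed over the
    transverse frequency |k_x| ≤ collapse_halfwidth (1/Å), yielding a 1D
    profile along the meridional axis k_y ≥ 0 (both half-axes folded).
    """
    segments = list(segments)
    if not segments:
        raise ValueError("need at least one segment")
    shape = segments[0].shape
    ps = np.zeros(shape)
    for s in segments:
        if s.shape != shape:
            raise ValueError("segments must share one shape")
        ps += power_spectrum(s)
    ny, nx = shape
    kx = sfft.fftshift(sfft.fftfreq(nx, d=pixel_size_A))
    ky = sfft.fftshift(sfft.fftfreq(ny, d=pixel_size_A))
    cols = np.abs(kx) <= collapse_halfwidth
    collapsed = ps[:, cols].sum(axis=1)
    # fold the Hermitian-symmetric negative half-axis onto the positive one
    dk = 1.0 / (ny * pixel_size_A)
    bins = np.round(np.abs(ky) / dk).astype(int)
    sums = np.bincount(bins, weights=collapsed)
    counts = np.bincount(bins)
    prof = sums / np.maximum(counts, 1)
    freqs = np.arange(1, len(prof)) * dk  # drop the k=0 sample
    return LayerLineProfile(freqs, prof[1:], pixel_size_A)


def _local_background(freqs, values, lo, hi):
    """Background through the side-bands just outside [lo, hi].

    Fitted as a line in log(power) vs log(frequency): exact for the
    power-law decay that colors integrated-DPC noise spectra, where a
    straight line in linear coordinates is systematically biased.
    """
    width = hi - lo
    side = ((freqs >= lo - 0.8 * width) & (freqs < lo)) \
        | ((freqs > hi) & (freqs <= hi + 0.8 * width))
    side &= (freqs > 0) & (values > 0)
    if side.sum() < 2:
        return np.zeros_like(values), False
    coef = np.polyfit(np.log(freqs[side]), np.log(values[side]), 1)
    with np.errstate(divide="ignore"):
        bg = np.exp(np.polyval(coef, np.log(np.maximum(freqs, 1e-12))))
    return bg, True


def find_layer_peaks(profile: LayerLineProfile, repeat_A: float,
                     orders=(1, 2), window: float = 0.15) -> list:
    """Locate layer-line peaks near n/repeat by quadratic interpolation.

    Searches ±window (fractional) around each expected comb position; the
    peak height is background-subtracted (local linear fit).  Peaks that do
    not rise above the background are omitted.  Results are stored on the
    profile and returned as (frequency, height, order) tuples.
    """
    f, v = profile.frequencies, profile.values
    peaks = []
    for nth in orders:
        f0 = nth / repeat_A
        lo, hi = f0 * (1 - window), f0 * (1 + window)
        sel = (f >= lo) & (f <= hi)
        if sel.sum() < 3:
            # coarse grids: widen to the three samples nearest the comb position
            near = np.argsort(np.abs(f - f0))[:3]
            sel = np.zeros_like(sel)
            sel[near] = True
            lo, hi = f[sel].min(), f[sel].max()
        if sel.sum() < 3:
            continue
        bg, ok = _local_background(f, v, lo, hi)
        resid = v - bg if ok else v
        idx = np.flatnonzero(sel)
        i = idx[np.argmax(resid[idx])]
        # significance: the apex must rise above the side-band scatter
        width = hi - lo
        side = (((f >= lo - 0.8 * width) & (f < lo))
                | ((f > hi) & (f <= hi + 0.8 * width)))
        floor = 1e-9 * v.max()
        if side.sum() >= 3:
            floor = max(floor, 3.0 * float(np.std(resid[side])))
        if resid[i] <= floor:
            continue
        # quadratic interpolation of the apex on the raw profile
        if 0 < i < len(f) - 1:
            y0, y1, y2 = resid[i - 1], resid[i], resid[i + 1]
            denom = (y0 - 2 * y1 + y2)
            delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
            fpk = f[i] + delta * (f[min(i + 1, len(f) - 1)] - f[i])
            hpk = y1 - 0.25 * (y0 - y2) * delta
        else:
            fpk, hpk = f[i], resid[i]
        peaks.append((float(fpk), float(hpk), nth))
    profile.peaks = peaks
    return peaks


def peak_ratio(profile: LayerLineProfile, repeat_A: float = 23.0) -> float:
    """Background-subtracted height ratio of the second- over first-order peak."""
    peaks = {o: (fq, h) for fq, h, o in
             find_layer_peaks(profile, repeat_A, orders=(1, 2))}
    if 1 not in peaks or 2 not in peaks:
        raise ValueError("both layer-line peaks must be detected above background")
    return peaks[2][1] / peaks[1][1]


def calibrate_pixel_size(profile: LayerLineProfile,
                         reference_spacing_A: float = 22.03,
                         orders=(1, 2)) -> tuple[float, float]:
    """Least-squares scale mapping detected peaks onto the n/reference comb.

    Returns (scale, corrected pixel size): true frequencies are scale times
    the measured ones, so the pixel size used to build the profile divides
    by the scale.
    """
    peaks = find_layer_peaks(profile, reference_spacing_A, orders=orders)
    if not peaks:
        raise ValueError("no layer-line peak detected")
    meas = np.array([p[0] for p in peaks])
    target = np.array([p[2] / reference_spacing_A for p in peaks])
    scale = float(np.dot(meas, target) / np.dot(meas, meas))
    return scale, profile.pixel_size_A / scale


def guinier_bfactor(frequencies: np.ndarray, amplitudes: np.ndarray,
                    fit_range: tuple[float, float]) -> GuinierFit:
    """Guinier analysis: regression of ln F on k²; B = −4·slope.

    Sharpening multiplies amplitudes by exp(+B·k²/4).
    """
    lo, hi = fit_range
    sel = (frequencies >= lo) & (frequencies <= hi)
    if sel.sum() < 5:
        raise ValueError("need at least 5 shells inside the fit range")
    if (amplitudes[sel] <= 0).any():
        raise ValueError("amplitudes must be positive inside the fit range")
    k2 = frequencies[sel] ** 2
    lnf = np.log(amplitudes[sel])
    coef, res = np.polyfit(k2, lnf, 1, full=True)[:2]
    residual = float(res[0]) if len(res) else 0.0
    return GuinierFit(-4.0 * float(coef[0]), fit_range, float(coef[1]), residual)


def sharpen(frequencies: np.ndarray, amplitudes: np.ndarray,
            b_factor_A2: float) -> np.ndarray:
    """Apply exp(+B k²/4) sharpening to a radial amplitude profile."""
    return amplitudes * np.exp(b_factor_A2 * frequencies**2 / 4.0)


def rosenthal_bfactor(points) -> float:
    """Data-quality B factor from particle numbers vs achieved resolution.

    Regression of ln N on 1/d²; B = 2·slope (Å²).  Requires at least three
    points with distinct resolutions.
    """
    pts = [(float(n), float(d)) for n, d in points]
    if len(pts) < 3:
        raise ValueError("need at least three (N, resolution) points")
    x = np.array([1.0 / d**2 for _, d in pts])
    y = np.array([np.log(n) for n, _ in pts])
    if np.ptp(x) == 0:
        raise ValueError("resolutions are degenerate; slope undefined")
    slope = np.polyfit(x, y, 1)[0]
    return 2.0 * float(slope)


def fsc(half_map_1: np.ndarray, half_map_2: np.ndarray,
        voxel_size_A: float = 1.0, threshold: float = 0.143) -> FSCCurve:
    """Fourier shell correlation of two half maps; resolution at 0.143.

    Shells are one frequency sample wide; the threshold crossing is linearly
    interpolated.  Returns inf resolution (in 1/Å terms: crossing at Nyquist)
    as the Nyquist distance if the curve never drops below the threshold.
    """
    if half_map_1.shape != half_map_2.shape:
        raise ValueError("half maps must have the same shape")
    f1 = sfft.fftn(half_map_1)
    f2 = sfft.fftn(half_map_2)
    grids = np.meshgrid(*[sfft.fftfreq(s, d=voxel_size_A) for s in f1.shape],
                        indexing="ij")
    kr = np.sqrt(sum(g**2 for g in grids))
    dk = 1.0 / (max(f1.shape) * voxel_size_A)
    bins = np.round(kr / dk).astype(int)
    nmax = bins.max() + 1
    num = np.bincount(bins.ravel(), weights=np.real(f1 * np.conj(f2)).ravel(),
                      minlength=nmax)
    p1 = np.bincount(bins.ravel(), weights=(np.abs(f1) ** 2).ravel(), minlength=nmax)
    p2 = np.bincount(bins.ravel(), weights=(np.abs(f2) ** 2).ravel(), minlength=nmax)
    denom = np.sqrt(p1 * p2)
    corr = np.where(denom > 0, num / np.maximum(denom, 1e-300), 0.0)
    nyq = int(np.floor((0.5 / voxel_size_A) / dk))
    shells = np.arange(nyq + 1) * dk
    corr = corr[: nyq + 1]
    res = _threshold_crossing(shells, corr, threshold)
    return FSCCurve(shells, corr, res)


def _threshold_crossing(shells, corr, threshold) -> float:
    for i in range(1, len(shells)):
        if corr[i] < threshold <= corr[i - 1]:
            f = shells[i - 1] + (corr[i - 1] - threshold) \
                / (corr[i - 1] - corr[i]) * (shells[i] - shells[i - 1])
            return 1.0 / f if f > 0 else np.inf
    return 1.0 / shells[-1] if shells[-1] > 0 else np.inf
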