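"""Synthetic specimens as sliced electrostatic potentials.

A specimen is a stack of z-slices of *projected* potential (V·Å per slice)
on a square xy grid: the representation the multislice propagator consumes.
Generators cover the objects a cryo-STEM resolution study needs: helical
rods with a tobacco-mosaic-virus-like lattice (layer lines at n/pitch),
a gold-lattice resolution standard, arbitrary atom lists, and an amorphous
ice slab.  All generators are pure functions of their arguments (and seed).

Coordinates are right-handed with z along the beam and the helical axis
along image y; the origin sits at the grid center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpecimenPotential",
    "HelixSpec",
    "helical_phantom",
    "gold_lattice_phantom",
    "atoms_to_potential",
    "ice_layer",
    "compose",
]

# Z^0.8 scattering weight, normalized to carbon; a single-Gaussian stand-in
# for the tabulated atomic potentials (absolute scale is not load-bearing).
_ELEMENT_Z = {
    "H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16, "FE": 26, "AU": 79,
}


@dataclass(frozen=True)
class SpecimenPotential:
    """Sliced 3D potential: slices[iz, iy, ix] in V·Å, with voxel sizes in Å."""

    slices: np.ndarray  # (nz, ny, nx)
    voxel_xy_A: float
    slice_dz_A: float

    def __post_init__(self) -> None:
        if self.slices.ndim != 3:
            raise ValueError("slices must be a (nz, ny, nx) stack")
        if self.voxel_xy_A <= 0 or self.slice_dz_A <= 0:
            raise ValueError("voxel sizes must be positive")
        if not np.isfinite(self.slices).all():
            raise ValueError("potential contains non-finite values")

    @property
    def thickness_A(self) -> float:
        return self.slices.shape[0] * self.slice_dz_A

    @property
    def shape_xy(self) -> tuple[int, int]:
        return self.slices.shape[1:]

    def projected(self) -> np.ndarray:
        """Projected potential along the beam (V·Å)."""
        return self.slices.sum(axis=0)


@dataclass(frozen=True)
class HelixSpec:
    """Helical lattice: subunits_per_repeat blobs over turns_per_repeat turns.

    axial_repeat_A is the helical pitch — the projection of the lattice along
    the beam repeats with this period, so layer lines appear at n/pitch.
    Per-subunit rise = pitch·turns/subunits; twist = 360°·turns/subunits.
    TMV-like defaults: 90 Å outer radius, 23 Å pitch, 49 subunits / 3 turns
    (rise 1.41 Å, twist 22.0°).
    """

    outer_radius_A: float = 90.0
    axial_repeat_A: float = 23.0
    subunits_per_repeat: int = 49
    turns_per_repeat: int = 3
    # blob width: subunits carry near-atomic internal detail, so the effective
    # Gaussian width must not wash out the second-order (11.5 Å) layer line
    subunit_sigma_A: float = 2.5
    # peak projected V·Å per blob, set so the rod's projected contrast is a few
    # hundred V·Å: a ~2-3 V protein-vs-ice inner-potential excess over a
    # ~100-180 Å path
    amplitude: float = 150.0

    def __post_init__(self) -> None:
        if self.axial_repeat_A <= 0:
            raise ValueError("axial repeat must be positive")
        if self.subunits_per_repeat < 1:
            raise ValueError("need at least one subunit per repeat")

    @property
    def rise_A(self) -> float:
        return self.axial_repeat_A * self.turns_per_repeat / self.subunits_per_repeat

    @property
    def twist_deg(self) -> float:
        return 360.0 * self.turns_per_repeat / self.subunits_per_repeat


def _grid_axes(n: int, spacing: float) -> np.ndarray:
    return (np.arange(n) - n / 2) * spacing


def _add_blob(slices: np.ndarray, voxel_xy: float, dz: float,
              x0: float, y0: float, z0: float, sigma: float, amp: float) -> None:
    """Accumulate one blob's projected 2D Gaussian into its nearest z-slice.

    Binning the whole blob to one slice (rather than sampling a 3D Gaussian
    on a coarse z grid) keeps the total projected potential exact — the
    standard atom-to-slice assignment of multislice codes.  Truncated at 4σ.
    """
    nz, ny, nx = slices.shape
    xs = _grid_axes(nx, voxel_xy)
    ys = _grid_axes(ny, voxel_xy)
    zs = _grid_axes(nz, dz)
    iz = int(np.clip(np.argmin(np.abs(zs - z0)), 0, nz - 1))
    cut = 4.0 * sigma
    ix = np.flatnonzero(np.abs(xs - x0) <= cut)
    iy = np.flatnonzero(np.abs(ys - y0) <= cut)
    if ix.size == 0 or iy.size == 0:
        return
    gx = np.exp(-((xs[ix] - x0) ** 2) / (2 * sigma**2))
    gy = np.exp(-((ys[iy] - y0) ** 2) / (2 * sigma**2))
    slices[iz][np.ix_(iy, ix)] += amp * gy[:, None] * gx[None, :]


def helical_phantom(spec: HelixSpec, length_A: float, voxel_xy_A: float = 1.0,
                    slice_dz_A: float = 30.0, n_xy: int | None = None,
                    phase_deg: float = 0.0) -> SpecimenPotential:
    """Helical rod along y: Gaussian subunits on the helical lattice.

    Subunit centers sit at radius outer_radius − 2σ so the density stays
    inside outer_radius.  The rod spans the full y extent of the grid with
    blob phases continued periodically, so the projection is y-periodic with
    the pitch (up to the grid's own periodicity).
    """
    if voxel_xy_A > spec.subunit_sigma_A:
        raise ValueError("voxel must sample the subunit width (voxel <= sigma)")
    if n_xy is None:
        n_xy = int(round(length_A / voxel_xy_A))
    r0 = max(spec.outer_radius_A - 2 * spec.subunit_sigma_A, 0.25 * spec.outer_radius_A)
    nz = max(1, int(np.ceil(2 * (r0 + 2 * spec.subunit_sigma_A) / slice_dz_A)))
    slices = np.zeros((nz, n_xy, n_xy))
    y_extent = n_xy * voxel_xy_A
    n_sub = int(np.ceil(y_extent / spec.rise_A)) + 1
    for j in range(n_sub):
        y = -y_extent / 2 + j * spec.rise_A
        theta = np.deg2rad(phase_deg + j * spec.twist_deg)
        x = r0 * np.cos(theta)
        z = r0 * np.sin(theta)
        _add_blob(slices, voxel_xy_A, slice_dz_A, x, y, z,
                  spec.subunit_sigma_A, spec.amplitude)
    return SpecimenPotential(slices, voxel_xy_A, slice_dz_A)


def gold_lattice_phantom(d_spacing_A: float = 2.35, thickness_A: float = 100.0,
                         voxel_xy_A: float = 0.5, n_xy: int = 256,
                         slice_dz_A: float = 50.0, amplitude: float = 10.0,
                         background_rms: float = 0.5, seed: int = 0) -> SpecimenPotential:
    """Resolution-standard lattice: crossed sinusoids of first-order spacing d.

    A weak amorphous background (seeded Gaussian noise, lightly smoothed)
    emulates the supporting carbon film.
    """
    if voxel_xy_A > d_spacing_A / 4:
        raise ValueError("voxel must be <= d_spacing/4 to resolve the lattice")
    nz = max(1, int(round(thickness_A / slice_dz_A)))
    x = _grid_axes(n_xy, voxel_xy_A)
    xx, yy = np.meshgrid(x, x, indexing="xy")
    g = 2 * np.pi / d_spacing_A
    lattice = amplitude * (np.cos(g * xx) + np.cos(g * yy) + 2.0) / 4.0
    rng = np.random.default_rng(seed)
    bg = rng.normal(0.0, 1.0, (n_xy, n_xy))
    bgf = np.fft.fft2(bg)
    k = np.fft.fftfreq(n_xy, d=voxel_xy_A)
    kr = np.hypot(*np.meshgrid(k, k, indexing="xy"))
    bg = np.real(np.fft.ifft2(bgf * np.exp(-((kr * 3.0) ** 2))))
    if bg.std() > 0:
        bg *= background_rms / bg.std()
    slab = (lattice + bg) / nz
    return SpecimenPotential(np.repeat(slab[None], nz, axis=0), voxel_xy_A, slice_dz_A)


def atoms_to_potential(atoms, voxel_xy_A: float, n_xy: int,
                       slice_dz_A: float, n_z: int,
                       sigma_A: float = 1.0, amplitude_c: float = 8.0) -> SpecimenPotential:
    """Potential from an (element, x, y, z) list: one Gaussian per atom.

    Amplitude scales as Z^0.8 relative to carbon.  Coordinates in Å from the
    grid center.  Deterministic.
    """
    slices = np.zeros((n_z, n_xy, n_xy))
    half_xy = n_xy * voxel_xy_A / 2
    half_z = n_z * slice_dz_A / 2
    for element, x, y, z in atoms:
        key = str(element).upper()
        if key not in _ELEMENT_Z:
            raise KeyError(f"unknown element symbol: {element!r}")
        if abs(x) > half_xy or abs(y) > half_xy or abs(z) > half_z:
            raise ValueError(f"atom at ({x}, {y}, {z}) outside the grid")
        amp = amplitude_c * (_ELEMENT_Z[key] / 6.0) ** 0.8
        _add_blob(slices, voxel_xy_A, slice_dz_A, x, y, z, sigma_A, amp)
    return SpecimenPotential(slices, voxel_xy_A, slice_dz_A)


def ice_layer(thickness_A: float, rms_fluctuation: float, correlation_length_A: float,
              seed: int, voxel_xy_A: float = 1.0, n_xy: int = 128,
              slice_dz_A: float = 30.0, mean_level: float = 1.0) -> SpecimenPotential:
    """Amorphous ice slab: mean potential + band-limited Gaussian fluctuations.

    The fluctuation field has a Gaussian correlation function of the given
    correlation length and the requested per-voxel rms (in projected V·Å per
    slice); reproducible for a fixed seed.
    """
    if thickness_A <= 0:
        raise ValueError("thickness must be positive")
    nz = max(1, int(round(thickness_A / slice_dz_A)))
    rng = np.random.default_rng(seed)
    slices = np.full((nz, n_xy, n_xy), float(mean_level))
    if rms_fluctuation > 0:
        k = np.fft.fftfreq(n_xy, d=voxel_xy_A)
        kx, ky = np.meshgrid(k, k, indexing="xy")
        filt = np.exp(-0.5 * (np.pi * correlation_length_A) ** 2 * (kx**2 + ky**2))
        for iz in range(nz):
            white = rng.normal(0.0, 1.0, (n_xy, n_xy))
            f = np.real(np.fft.ifft2(np.fft.fft2(white) * filt))
            f *= rms_fluctuation / np.sqrt(np.mean(filt**2))
            slices[iz] += f
    return SpecimenPotential(slices, voxel_xy_A, slice_dz_A)


def compose(*specimens: SpecimenPotential) -> SpecimenPotential:
    """Voxelwise superposition of potentials on matching xy grids.

    Stacks with different slice counts are aligned at the center and
    zero-padded in z to the thickest input.
    """
    if not specimens:
        raise ValueError("compose needs at least one specimen")
    first = specimens[0]
    for s in specimens[1:]:
        if s.shape_xy != first.shape_xy or s.voxel_xy_A != first.voxel_xy_A \
                or s.slice_dz_A != first.slice_dz_A:
            raise ValueError("specimen grids do not match")
    nz = max(s.slices.shape[0] for s in specimens)
    out = np.zeros((nz, *first.shape_xy))
    for s in specimens:
        n = s.slices.shape[0]
        lo = (nz - n) // 2
        out[lo:lo + n] += s.slices
    return SpecimenPotential(out, first.voxel_xy_A, first.slice_dz_A)
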