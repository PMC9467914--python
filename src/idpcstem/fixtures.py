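"""Standard synthetic fixtures tying the generators to realistic conditions.

Three named fixtures cover the study's specimen classes:

- ``tmv_raft``: parallel 18-nm helical rods (23 Å pitch) lying side by side
  in an amorphous ice slab — a single-layer raft, 180 Å thick.
- ``gold``: the 2.35 Å lattice resolution standard on an amorphous film.
- ``hemoglobin_like``: a globular atom cluster embedded in ice, for
  SNR-vs-CSA studies.

Every fixture is a pure function of (name, seed) at fixed size parameters.
"""

from __future__ import annotations

import numpy as np

from .optics import AberrationCoefficients, BeamParameters, ScanGeometry
from .phantom import HelixSpec, SpecimenPotential, atoms_to_potential, compose, \
    gold_lattice_phantom, helical_phantom, ice_layer
from .scan_detector import DetectorGeometry, set_camera_length
from .config import RunConfig

__all__ = ["make_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("tmv_raft", "gold", "hemoglobin_like")


def _tmv_raft(seed: int, n_xy: int, voxel: float) -> SpecimenPotential:
    spec = HelixSpec()
    fov = n_xy * voxel
    rods = []
    spacing = 2 * spec.outer_radius_A + 10.0  # rods nearly touching
    n_rods = max(1, int(fov // spacing))
    offsets = (np.arange(n_rods) - (n_rods - 1) / 2) * spacing
    rng = np.random.default_rng(seed)
    base = helical_phantom(spec, fov, voxel_xy_A=voxel, n_xy=n_xy)
    for i, off in enumerate(offsets):
        phase = float(rng.uniform(0, 360))
        rod = helical_phantom(spec, fov, voxel_xy_A=voxel, n_xy=n_xy,
                              phase_deg=phase)
        shift = int(round(off / voxel))
        rod = SpecimenPotential(np.roll(rod.slices, shift, axis=2),
                                voxel, rod.slice_dz_A)
        rods.append(rod)
    ice = ice_layer(thickness_A=base.thickness_A, rms_fluctuation=0.6,
                    correlation_length_A=8.0, seed=seed + 1,
                    voxel_xy_A=voxel, n_xy=n_xy,
                    slice_dz_A=base.slice_dz_A, mean_level=1.0)
    return compose(*rods, ice)


def _hemoglobin_like(seed: int, n_xy: int, voxel: float,
                     n_atoms: int = 600) -> SpecimenPotential:
    """Dense globular atom cluster (~condensed protein interior) in quiet ice.

    600 atoms in a 14 Å sphere give a projected contrast of ~300 V·Å, the
    scale of a small protein against vitreous ice; the ice texture is kept
    weak so particle signal-to-noise is measured against shot noise rather
    than imaged solvent structure.
    """
    rng = np.random.default_rng(seed)
    n_z = 4
    dz = 16.0
    radius = 14.0
    atoms = []
    elements = np.array(["C", "N", "O", "S"])
    probs = np.array([0.62, 0.2, 0.16, 0.02])
    for _ in range(n_atoms):
        while True:
            p = rng.uniform(-radius, radius, 3)
            if np.linalg.norm(p) <= radius:
                break
        atoms.append((rng.choice(elements, p=probs), p[0], p[1], p[2]))
    mol = atoms_to_potential(atoms, voxel, n_xy, dz, n_z,
                             sigma_A=1.5, amplitude_c=10.0)
    ice = ice_layer(thickness_A=n_z * dz, rms_fluctuation=0.02,
                    correlation_length_A=6.0, seed=seed + 1,
                    voxel_xy_A=voxel, n_xy=n_xy, slice_dz_A=dz,
                    mean_level=0.8)
    return compose(mol, ice)


def make_fixture(name: str, seed: int = 0, n_xy: int | None = None,
                 voxel_A: float | None = None) -> tuple[RunConfig, SpecimenPotential]:
    """Deterministic standard phantom plus a matching acquisition config."""
    if name == "tmv_raft":
        n_xy = n_xy or 256
        voxel = voxel_A or 2.0
        specimen = _tmv_raft(seed, n_xy, voxel)
        beam = BeamParameters(300.0, 2.0, AberrationCoefficients(), current_pa=4.0)
        scan = ScanGeometry(pixel_size_A=2.4, n_pixels=max(16, n_xy // 2))
    elif name == "gold":
        n_xy = n_xy or 256
        voxel = voxel_A or 0.5
        specimen = gold_lattice_phantom(voxel_xy_A=voxel, n_xy=n_xy, seed=seed)
        beam = BeamParameters(300.0, 4.5, AberrationCoefficients(), current_pa=4.0)
        scan = ScanGeometry(pixel_size_A=0.76, n_pixels=max(16, n_xy // 2))
    elif name == "hemoglobin_like":
        n_xy = n_xy or 128
        voxel = voxel_A or 0.6
        specimen = _hemoglobin_like(seed, n_xy, voxel)
        beam = BeamParameters(300.0, 4.5, AberrationCoefficients(), current_pa=4.0)
        scan = ScanGeometry(pixel_size_A=1.0, n_pixels=max(16, n_xy // 2))
    else:
        raise KeyError(f"unknown fixture name: {name!r}; "
                       f"choose from {FIXTURE_NAMES}")
    det = set_camera_length(DetectorGeometry.standard(), beam)
    return RunConfig(beam=beam, scan=scan, detector=det, phantom_name=name,
                     phantom_params={"n_xy": n_xy, "voxel_A": voxel},
                     total_dose=35.0, seed=seed,
                     output_prefix=name), specimen
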