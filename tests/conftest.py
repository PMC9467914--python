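"""Shared fixtures: small but realistic simulation runs reused across tests.

The expensive forward simulations are session-scoped; tests assert different
properties of the same run.  Sizes are chosen so the whole suite runs on one
CPU in a few minutes: scan rasters of 32²-100² positions on 96²-160²
simulation grids.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import idpcstem as ix
from idpcstem.fixtures import _hemoglobin_like


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    return float(np.sum(a * b) / np.sqrt(np.sum(a**2) * np.sum(b**2)))


@pytest.fixture(scope="session")
def beam4() -> ix.BeamParameters:
    return ix.BeamParameters(300.0, 4.0)


@pytest.fixture(scope="session")
def det4(beam4) -> ix.DetectorGeometry:
    return ix.set_camera_length(ix.DetectorGeometry.standard(), beam4)


@pytest.fixture(scope="session")
def rod_sim(beam4, det4):
    """Noiseless 4 mrad scan of the TMV-like rod in ice.

    FOV 115 Å = 5 pitches, so the layer-line comb falls on exact frequency
    samples; scan pixel 1.15 Å Nyquist-samples the 2.46 Å optical cutoff.
    """
    vox, ngrid, npix = 1.15, 112, 100
    spec = ix.HelixSpec()
    rod = ix.helical_phantom(spec, ngrid * vox, voxel_xy_A=vox, n_xy=ngrid)
    ice = ix.ice_layer(thickness_A=rod.thickness_A, rms_fluctuation=0.5,
                       correlation_length_A=8.0, seed=1, voxel_xy_A=vox,
                       n_xy=ngrid, slice_dz_A=rod.slice_dz_A)
    specimen = ix.compose(rod, ice)
    scan = ix.ScanGeometry(vox, npix)
    plan = ix.plan_acquisition(beam4, scan, 35.0)
    q = ix.scan_image(specimen, beam4, scan, det4, plan,
                      ix.SimulationSettings.for_beam(beam4))
    img0 = ix.integrate_dpc(ix.dpc_vector(q))
    return {"q": q, "img0": img0, "vox": vox, "scan": scan, "plan": plan,
            "specimen": specimen, "helix": spec}


@pytest.fixture(scope="session")
def ctf_pair(beam4, det4):
    """Quadrant and ideal-COM transfer functions on the same 96² grid."""
    quad = ix.compute_ctf(beam4, det4, 96, 0.85, mode="quadrant")
    com_ = ix.compute_ctf(beam4, det4, 96, 0.85, mode="com")
    return quad, com_


@pytest.fixture(scope="session")
def snr_by_csa():
    """Particle SNR at fixed dose for CSA 2.0, 4.5 and 10 mrad.

    The simulation grid is adapted per CSA (aperture sampling vs detector
    quantization); the scan raster and dose are held fixed.
    """
    grids = {2.0: (1.2, 136), 4.5: (0.75, 96), 10.0: (0.45, 160)}
    npix = 40
    yy, xx = np.meshgrid(np.arange(npix) - (npix - 1) / 2,
                         np.arange(npix) - (npix - 1) / 2, indexing="ij")
    r = np.hypot(xx, yy)
    sig_m, bg_m = r < 10, r > 14
    out = {}
    for csa, (s, ngrid) in grids.items():
        specimen = _hemoglobin_like(3, ngrid, s)
        beam = ix.BeamParameters(300.0, csa)
        det = ix.set_camera_length(ix.DetectorGeometry.standard(), beam)
        scan = ix.ScanGeometry(1.0, npix)
        plan = ix.plan_acquisition(beam, scan, 35.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            q = ix.scan_image(specimen, beam, scan, det, plan,
                              ix.SimulationSettings.for_beam(beam))
        vals = [ix.snr_of_particle(
            ix.integrate_dpc(ix.dpc_vector(ix.add_shot_noise(q, sd))),
            sig_m, bg_m) for sd in range(12)]
        out[csa] = (float(np.mean(vals)), q)
    return out
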