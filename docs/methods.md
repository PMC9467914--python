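# Methods

## Image-formation model

The probe wavefunction is the inverse Fourier transform of a top-hat
aperture of semi-angle α carrying the axial aberration phase
χ(θ) = (2π/λ)(−Δf·θ²/2 + C_s·θ⁴/4), θ = λk. Positive defocus means
underfocus: the beam waist sits upstream of the nominal specimen plane
(tested by the direction of the waist shift under numerical propagation).
The wavelength is relativistic (scipy.constants CODATA values); at 300 kV
λ = 1.9687 pm and the interaction constant σ = 2π·γm₀·e·λ/h² ≈
6.53×10⁻⁴ rad/(V·Å).

Specimens are stacks of z-slices of projected potential (V·Å). The exit
wave at each scan position is computed by the multislice algorithm:
alternately multiply by the phase grating exp(iσV_z) and propagate by the
Fresnel kernel exp(−iπλΔz·k²). Both factors are unitary, so flux is
conserved to rounding error. Probe positioning across the scan raster uses
Fourier-space phase ramps (sub-pixel exact, separable per axis); the
simulation grid is periodic.

The far field is the unitary FFT of the exit wave with angular calibration
θ = λk. Quadrant signals integrate the CBED intensity over four 90°
sectors of the annulus between the central hole and the detector edge,
with radial edges anti-aliased over one angular sample and azimuthal
boundaries resolved by 3×3 subsampling. The camera length is set so the
bright-field disk radius equals 4× the hole radius (hence 2/3 of the outer
radius, with hole = outer/6). Shot noise, when requested, is an
independent Poisson draw per quadrant per dwell with expectation
dose × pixel² × (quadrant fraction).

Reconstruction: detector-frame DPC components x = (A+D)−(B+C),
y = (A+B)−(C+D) (quadrants labeled counterclockwise from the detector +x
axis) are rotated by −(scan rotation) into the scan frame; only at zero
rotation is the DPC vector a pure subtraction. Fourier integration
I(k) = (k_x D_x + k_y D_y)/(2πi(|k|² + ε)) with the k = 0 term nulled gives
the mean-zero iDPC image; ε (default 0) is an optional Tikhonov
regularizer for noisy data. The Gaussian high-pass used for display
("preprocessed" images) multiplies the spectrum by 1 − G(k), where G's
real-space kernel has a 251 Å FWHM by default; the reciprocal-space
reading of the FWHM is selectable. Inputs are edge-padded by 10% before
filtering (disable with `pad=False` for strictly multiplicative spectral
behavior).

## Transfer function

`compute_ctf` measures the transfer function of the whole chain
numerically: a thin weak phase impulse (peak phase 1 mrad — safely linear)
is scanned with step equal to the simulation grid step, the iDPC image is
reconstructed, and the output spectrum is divided by the input phase
spectrum. Because the periodic chain is linear and shift-invariant this
yields the response at every frequency in one scan. An independent
aperture-overlap route — β_D(q) = Σ_k D(k)A(k)[A(k−q) − A(k+q)], combined
as (q_x β_x + q_y β_y)/(2π|q|²) — agrees with the pipeline measurement to
better than 10% of peak (radially averaged) and serves as the cross-check
in the test suite. The aberration-free CTF is positive over its support,
decays monotonically over (0.2, 0.9)×cutoff, vanishes beyond 2α/λ, and
shows a fourfold azimuthal modulation for quadrant detection that is
absent under exact-COM detection. On the affordable test grids the
innermost frequency shells are dominated by square-grid discretization
anisotropy common to both detector models, so the fourfold coefficient is
asserted on the (0.2–0.5)×cutoff ring, where the oracle shows the
quadrant-specific 4θ term most cleanly.

## Synthetic specimens

Helical rod: Gaussian subunits on the tobacco-mosaic-virus lattice —
pitch 23 Å, 49 subunits per 3 turns, hence rise 1.408 Å and twist 22.04°
per subunit, outer radius 90 Å (subunit centers at radius − 2σ). Note the
lattice's exact translational repeat is 3 turns (69 Å); a one-pitch shift
is a screw operation, so the 23 Å periodicity appears as the dominant
layer line (with its second order at 11.5 Å), not as a real-space
translation symmetry. Subunit width defaults to σ = 2.5 Å — subunits carry
near-atomic internal detail, and a broader blob would artificially damp
the second-order line. The blob amplitude (150 V·Å) sets a projected rod
contrast of ~200–300 V·Å, the scale of a 2–3 V protein-vs-ice
inner-potential excess over a 100–180 Å path. Each blob is binned wholly
into its nearest slice (the standard atom-to-slice assignment), keeping
the total projected potential exact.

Gold lattice: crossed sinusoids of 2.35 Å first-order spacing on a weak
smoothed-noise background (the supporting film). Atom lists: one Gaussian
per atom with amplitude ∝ Z^0.8 relative to carbon — a deliberately simple
monotone-in-Z model; no result depends on the absolute potential scale.
Ice: mean slab plus band-limited Gaussian fluctuations of chosen rms and
correlation length, seeded. The hemoglobin-like SNR fixture packs 600
atoms into a 14 Å sphere (condensed protein interior, ~300 V·Å projected
contrast) in deliberately quiet ice, so that particle SNR is measured
against shot noise rather than imaged solvent texture.

What the generators do not emulate: tabulated (Kirkland-type) atomic
scattering factors, solvent/charge models, inelastic scattering, detector
MTF beyond Poisson statistics, stage drift and beam-induced motion, and
radiation damage. Passing tests therefore demonstrate the optics,
detection geometry, reconstruction algebra and estimator correctness — not
quantitative contrast of real micrographs.

## Analysis conventions

Layer-line profiles: segment power spectra are summed, collapsed over the
transverse frequency within ±1/50 Å⁻¹ of the meridian (configurable; the
window covers the near-meridional Bessel maxima for rod radii of 70–90 Å),
and folded onto the positive axis. Peaks are located in ±15% windows
around the expected comb n/repeat (widened to the three nearest samples on
coarse grids) by quadratic apex interpolation over a local background
fitted as a line in log-power vs log-frequency — the correct model for the
power-law coloring that Fourier integration imprints on shot noise — and
must exceed three standard deviations of the side-band residuals.
Pixel-size calibration least-squares-scales detected peaks onto the
n/22.03 Å comb (the reference spacing and the 23 Å generator pitch are
both free parameters; neither is hard-coded). Guinier fits regress ln F on
k² over an explicit range (default 0.1 Å⁻¹ to the cutoff), B = −4·slope;
the particle-number B factor regresses ln N on 1/d², B = 2·slope. FSC uses
shells one frequency sample wide, no masking, and linear interpolation of
the 0.143 crossing.

## Problem sizes and numerics

Test and acceptance simulations use 96²–160² simulation grids and 20²–100²
scan rasters; the rod runs use a 115 Å field of view (five pitches, so the
layer-line comb falls on exact frequency samples) at 1.15 Å scan pixel,
Nyquist-sampling the 4 mrad cutoff. The scan loop runs in single precision
(per-position error ~10⁻⁶, far below shot noise); transfer-function
measurements request double precision. Detector masks require the
bright-field disk to span at least 16 angular samples, which sets the
minimum simulation-grid extent per CSA. Noisy layer-line detection
averages 64 Poisson realizations of one expected scan — emulating the
segment averaging of the real workflow at the experimental 35 e−/Å² dose.
The gold-ring resolution check reads the noiseless power spectrum: a
test-sized raster cannot reproduce the 4096²-pixel averaging that pulls
the ring out of the noise floor experimentally.

Planner tables are computed from the wavelength rounded to 4 significant
figures and reported at 0.1 Å / 1 nm precision (half-up), reproducing the
standard 300 kV planning grid. The frame-time planner reports pure scan
time; per-line flyback overhead is an explicit parameter defaulting to
zero, since vendor overheads are not specified anywhere authoritative.

## Known limitations

The quadrant CTF's absolute scale is defined by the unit-intensity probe
and fraction-of-beam signals; comparisons across detector models (quadrant
vs COM) are shape comparisons. The eight physical detector segments are
modeled directly as four quadrants (the radial split is unused in the
hardware wiring this models). Descan is assumed ideal. 2D correction of
the fourfold CTF pattern is available through `wpo_image`-style
deconvolution but is not applied by default.
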