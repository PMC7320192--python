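# Methods

## Model and conventions

A reconstruction is a real scalar field on a cubic voxel grid (`(x, y, z)`
in memory, MRC column/row/section on disk), with the box and rotation
center at integer index `n//2` on each axis. All Fourier-domain arrays use
the matching centered layout (DC at `n//2`), produced by
`fftshift(fftn(ifftshift(·)))`, so real-space and Fourier-space center
conventions coincide and the data-zone membership indexes the same grid
the restoration iterates on.

The tilt axis is Y and the beam is lab z. Projecting at tilt φ integrates
the map along z after rotating it by −φ about Y (trilinear interpolation,
fixed point at the center voxel); a point at polar position (r, θ) in the
x–z plane lands at frame coordinate r·cos(θ−φ). Reconstruction is direct
Fourier inversion: each frame's centered 2D transform is scattered as a
central slice spanned by (cos φ, 0, sin φ) and k_y, with trilinear
gridding weights, then weight-normalized and inverse-transformed. The
projector, the backprojector and the data-zone mask share this one
geometry; the adjoint-consistency test (correlation > 0.9 between a map
and backproject(project(map)) at ±30°) breaks if any of the three
diverges.

### Discrete data zone

A Fourier voxel is "measured" iff atan2(|k_z|, |k_x|) ≤ tilt_max + δ or it
lies on the tilt-axis line k_x = k_z = 0. δ = atan(1/box) is the angular
half-thickness of a one-voxel slice at the box edge (±0.5 voxel at radius
box/2): it keeps the discrete zone's voxel count within ~1.4 points of the
continuous-limit fraction tilt/90 (measured inside the inscribed Nyquist
cylinder, where angular measure is uniform) while covering the gridded
slices. Trilinear gridding additionally bleeds one voxel past this
geometric zone — near DC those skirt voxels can carry a large share of
total power — so the wedge-emptiness check (<1 % of spectral energy
outside the zone before restoration) excludes a one-voxel dilation of the
zone. The Fourier lock deliberately does *not* include the skirt: its
values are attenuated spill, not measurements.

## The restoration iteration

One iteration applies, in order: the real-space constraints (zero outside
the support mask; inside it, imaginary parts discarded and negative real
parts clamped to zero), a forward FFT, replacement of the data-zone voxels
with F₀ = ℱ[initial map] (computed once per run and never updated), and an
inverse FFT. A round is `n_iter_per_round` iterations (default 1,000)
under a fixed mask; the round output is taken after a final real-space
constraint application, so it satisfies the constraints exactly and
matches F₀ on the zone up to that one application (measured ≲1.5 % on
consistent noise-free fixtures; asserted < 5 %). Later rounds rebuild the
mask from the previous round's output — less elongated, hence a more
accurate support — and continue the iteration from that output, so wedge
data already restored is kept while the lock still refers to the original
measurements. Convergence is reported as the per-iteration relative map
change; by default the iteration runs a fixed count (an optional early
stop at relative change < 1e−6 exists but is off), matching the
fixed-1,000-cycle protocol.

The mask is built by low-pass filtering the source map to
`mask_filter_res` and bisecting the density threshold until the
above-threshold volume equals `volume_factor` × mw × 1.21 Å³/Da within
1 %. The 1.21 Å³/Da conversion is the standard protein partial specific
volume (0.73 cm³/g) and is configurable. The mask is applied as the hard
binary region the constraint equations state; the "softness" of its
boundary comes from thresholding a heavily filtered map, which yields a
smooth isosurface. Degenerate inputs (all-zero initial map, mask target
exceeding the box) raise errors rather than returning silent zeros.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `tilt_max` | — | tilt half-range in degrees; defines the data zone |
| `mw_da` | — | molecular mass in Da; calibrates the mask volume |
| `mask_filter_res` | 40 Å | low-pass applied to the mask source map (useful range 40–80 Å for ~140 Å particles in 256³ boxes; scale with particle size — the 64³ desk experiments use 10 Å, the same particle-diameter/3.5 proportion) |
| `volume_factor` | 3.0 | mask volume as a multiple of the MW-equivalent volume (~1.5–4 useful) |
| `n_iter_per_round` | 1000 | constraint cycles per round |
| `n_rounds` | 5 | rounds, each with a regenerated mask |

Noise is generated per frame as i.i.d. Gaussian with σ = (frame signal
σ)/SNR — at SNR 0.3 the noise σ is ~3.33× the signal's. The measurement
formula SNR = (I_s − I_b)/N_b (means over the particle and background,
s.d. of the background) is implemented separately in `estimate_snr`; the
two definitions agree only approximately on real images, and generation
follows the σ-ratio recipe.

## Phantoms

`atoms_to_map` renders atomic models pdb2mrc-style: each atom's mass is
deposited on its 8 neighbor voxels with trilinear weights and the grid is
convolved once with an isotropic Gaussian of σ = blur_res/(π√2),
blur_res defaulting to 2 voxels (half-max transfer at Nyquist). Atom
weights are atomic masses, matching the molecular-weight bookkeeping used
for mask volumes.

`make_synthetic_phantom` emulates the relevant features of such
crystal-structure maps without any downloaded input: a compact globular
particle (clusters of pseudo-atoms packed in a ball of radius 0.25·box, so
the particle spans about half the box), rendered through the same
deposit-and-blur kernel so it keeps genuine structure out to the Nyquist
shell, with optional exact n-fold symmetry about Z (cluster positions
replicated analytically). Sharpness matters: a smooth, large-σ blob
phantom has no real mid/high-frequency structure, so wedge restoration has
nothing to recover there and volume-calibrated masks fail to wrap its
scattered support — early experiments with such phantoms mischaracterized
the algorithm. What the synthetic phantom does **not** emulate: atomic
electron-scattering contrast, solvent, the CTF, and alignment errors of
real tilt series — passing desk-scale tests therefore demonstrates the
restoration mechanics, not performance on experimental data.

The n-fold symmetry check compares the map against its 360°/n rotation
after a 6 Å band limit: grid-interpolated rotation of a Nyquist-sharp map
carries ~12 % RMS interpolation error that is unrelated to symmetry, while
at the 6 Å band the residual is ~0.6 % (< 2 % asserted). Rotations pivot
on the center voxel `n//2` (not scipy's `(n−1)/2` array center).

## Desk-scale study conditions

The standard characterization (tests and `scripts/acceptance.py`) uses
64³ phantoms at 1 Å/voxel, tilt steps of 1.5°, and 200-iteration rounds —
a scaled-down analogue of the reference 256³/1,000-iteration protocol,
sized so the whole study runs in about a minute:

* **±15°, map-derived mask, 5 rounds** — the multi-round protocol;
  resolution improves in every seed (e.g. 9.6 → 8.5 Å, 22.0 → 5.4 Å) and
  the z/x elongation ratio returns toward 1.
* **±30°, precise mask from the object, 1 round** — the precise-mask
  protocol. At ±30° the initial map's FSC against the object never falls
  below 0.5 (the measured zone holds √(1/3) ≈ 0.58 of each shell's power),
  so its reported resolution is the Nyquist clamp 2·voxel_size; restored
  maps land within ~8 % of that bound (min-shell FSC 0.4–0.5). Restoration
  is judged by CCC (which rises strongly, e.g. 0.72 → 0.84) and elongation
  moving to the object's own z/x ratio.
* **±15°, SNR 0.3** — the noise-limited regime: restoration does not
  improve the resolution, reproducing the qualitative negative result that
  noise overweights the free wedge variables.

Resolution is the linearly interpolated first FSC-0.5 crossing, clamped at
Nyquist and flagged when the curve never crosses; curves that start below
threshold are flagged "no signal". FSC shells are one Fourier voxel wide
(shell = round(|k|)); the low-pass filter is a Gaussian with half-max
transfer at the cutoff. Elongation is the z/x support-extent ratio at half
max after an 8 Å display filter.

## Known limitations

* No CTF simulation or correction, no tilt-geometry refinement, no
  dual-axis schemes, no amplitude sharpening.
* Trilinear gridding (not Kaiser–Bessel) bounds the ideal-reconstruction
  FSC at the outermost shells to ~0.9; sub-Nyquist "resolutions" are never
  reported (clamped, flagged).
* The mask is binary; no apodized-edge variant is provided.
* Full-scale (256³, 5×1,000 iterations) runs take hours on one CPU; the
  desk-scale studies are the tested configuration.
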