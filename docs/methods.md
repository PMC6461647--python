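# Methods

## The problem and the model

A 2D crystal images as a periodic projection whose unit cells deviate from
ideal lattice positions (in-plane disorder) and from the common plane
(out-of-plane disorder: membrane curvature, "bumps").  When the sample is
tilted by an angle `tltang` about an in-image axis at angle `tltaxis`, all
unit cells share one projection direction, and defocus varies linearly
across the image.  `xtal2p` treats each unit cell as a single particle: it
is located by cross-correlation, given the Euler angles implied by the
crystal tilt geometry, assigned the defocus of its own position on the
tilted plane, and exported for single-particle refinement.  The package
implements the stages around that idea — simulation, picking, geometry and
CTF, stack assembly, map postprocessing, ensemble comparison — and leaves
iterative likelihood refinement and classification to the dedicated
refinement packages whose input files it writes.

## Conventions (pinned, enforced by tests)

- **Coordinates.** 0-based pixels; position `(x, y)` maps to `array[y, x]`;
  volumes are `[z, y, x]`.  A box of side `b` around center `x` covers the
  half-open window `[floor(x) − b//2, floor(x) − b//2 + b)`; the sub-pixel
  remainder `x − floor(x)` travels with the particle record and is applied
  as a Fourier phase ramp (exactly invertible), never by real-space
  interpolation.
- **Rotations.** ZYZ intrinsic Euler angles in degrees,
  `matrix(φ,θ,ψ) = Rz(φ)·Ry(θ)·Rz(ψ)` on `(x,y,z)` column vectors, θ in
  [0°, 180°] (the FREALIGN/RELION ordering).  The tilt-geometry matrix is
  `Rz(−tltaxis)·Ry(tltang)·Rz(tltaxis + taxa)`; the conversion is enforced
  against independently composed rotation matrices to 1e−9 over random
  geometries.  In this convention the in-plane rotation of the *object*
  appears in φ: projections of a C4 phantom repeat under φ → φ + 90°.
- **Map center.** Rotation, projection, Fourier-insertion and soft masks
  all use voxel `n//2` as the center.  Phantoms default to odd boxes so
  this coincides with `(n−1)/2`, making C4 symmetrization exact on the
  grid.
- **Defocus.** Underfocus positive, in Å.  The local-defocus offset is
  `dz = tan(tltang)·(−dx·sin(tltaxis) + dy·cos(tltaxis))·pixel`, so points
  with positive perpendicular coordinate relative to the axis get larger
  defocus at positive tilt.  Astigmatism (magnitude and angle) is inherited
  unchanged from the micrograph center — no gradient model for it exists.
- **CTF.** `CTF(s,α) = −[√(1−A²)·sin χ + A·cos χ]` with
  `χ = πλz(α)s² − (π/2)Cs λ³s⁴ + Δφ` and
  `z(α) = ½[df1+df2+(df1−df2)cos 2(α−α_ast)]`; λ is the relativistic
  electron wavelength.  On discrete grids the CTF is averaged with its
  Friedel partner along the folded Nyquist lines, where the sign of the
  frequency direction is ambiguous; this keeps corrected images exactly
  real.  The DC term is treated like any other frequency using
  `CTF(0) = −A`.  Wiener filtering uses `CTF/(CTF² + c)` with `c = 0.1` by
  default (exposed as a parameter).
- **Fourier shells.** Integer-radius bins in voxel frequency units; DC is
  excluded from shell 1; shell `s` of a box-`n` map sits at `s/(n·pixel)`
  1/Å.

## The simulator

`sim.render_crystal` composes the forward model stage by stage:

1. **Phantom.** `n_blobs` Gaussian blobs (default 6, σ = 2.2 px) scattered
   in a soft support, replicated analytically over the `symmetry_order`
   rotations about z (default 4, mimicking a tetrameric channel; box 49,
   1.3 Å/px).  Building the symmetry mates analytically makes the C4
   invariance exact to float precision for orders 1, 2, 4.
2. **Lattice.** The input lattice is the crystal-plane lattice; its image
   appearance is foreshortened by `cos(tltang)` perpendicular to the tilt
   axis with the `a` vector rotated `taxa` from the axis, and returned as
   `GroundTruth.lattice_image` — the quantity unbending would measure on a
   real micrograph and what the picker should be given.
3. **Disorder.** Per cell: Gaussian in-plane jitter (default σ = 2 px) and
   a small out-of-plane orientation wobble (default σ = 2°, random axis)
   composed onto the global tilt.  A smooth sinusoidal height field
   (amplitude in Å, default 50; wavelength 200 px) models membrane bumps
   and is rendered as an extra defocus offset — the dominant imaging effect
   of height variations, at a fraction of the cost of re-rendering in 3D.
   Optional vacancy: cells are occupied with probability `occupancy`.
4. **Imaging.** Each cell's projection is CTF-modulated with its own local
   defocus in a box padded by 64 px — the oscillatory CTF point spread is
   far wider than one unit cell, and modulating in the unpadded box would
   wrap it circularly — then phase-ramped to its sub-pixel position and
   accumulated.  Gaussian noise is added last.  Draw order is documented in
   the module docstring; a seed fully determines the output.

Default magnitudes for the lattice disorder are chosen for testability (a
picker should succeed at 2 px jitter and SNR ≥ 0.5, and fail visibly if
broken), not measured fidelity; the real crystals' disorder magnitude is
not quantified anywhere authoritative.  What the simulator deliberately
omits: dose fractionation and drift, detector MTF, ice-thickness gradients,
structural noise (lipid, solvent).  Passing tests therefore demonstrate
correctness of the geometry, CTF bookkeeping and statistics of the
pipeline — not robustness to every pathology of real micrographs.

## Picking

The CC reference defaults to the average of patches at the predicted
lattice positions, low-pass filtered at a quarter of Nyquist (one unit
cell; a user reference is accepted).  Correlation is locally normalized
(scikit-image `match_template`), making picking invariant to additive
offsets and slowly varying background.  Peaks are refined with a separable
parabolic fit on the 3×3 neighborhood (clamped to ±0.5 px).  The default
threshold is the mean of the found peak values — the vacancy-masking rule —
with ties kept (≥, with a 1e−9 guard so exactly-equal peak sets are not
split by float jitter).  On a fully occupied crystal that rule removes
about half the (equally good) cells by construction, so the demo and the
recall measurements use a fixed threshold of 0 there and reserve the mean
rule for occupancy separation, where it cleanly splits the two CC
populations.

## Stacks and half-sets

Boxes windowed from one crystal overlap, so half-sets are constrained per
crystal: crystals sorted by descending particle count go greedily to the
currently smaller half-set (deterministic, near-balanced; a seeded random
split is trivially layered on top if wanted).  Exports assert that no
crystal appears in both half-sets.  STAR files carry full-precision floats
and round-trip bit-identically; the FREALIGN v9 PAR writer uses the
standard fixed-width 17-column layout (FILM = crystal index) and
round-trips at the format's printed precision (0.01° / 0.1 Å).

Neighbor subtraction projects `map · (1 − mask)` at each particle's
orientation, applies its sub-pixel shift and CTF by multiplication (the
physical forward model — a Wiener filter would not match how the neighbors
were imaged), in the same padded-box scheme as the simulator, and
subtracts.  Its validation scenario uses a finite 3×3 crystal that fits
entirely inside one particle box, the one geometry in which the reference
block can represent every molecule in the data; residual power is then
< 5% of input power, limited by CTF tails clipped at the image border.

## Map postprocessing

The soft spherical mask is 1 out to `radius` and falls as a half-cosine to
0 at `radius + edge` (the radius/width wording is ambiguous about which
side the edge occupies; this convention is pinned and tested).  Volume
correction uses `f·FSC/(1+(f−1)·FSC)` with `f = v_mask/v_particle`;
non-positive shells pass through unchanged because the formula is derived
for genuine shared signal and diverges at `FSC = −1/(f−1)`.  `v_particle`
defaults to the voxel count of the molecular envelope above a caller-chosen
density threshold, with an explicit override.  The half-bit threshold uses
`n_eff = n_voxels·(d/(box·pixel))²/symmetry` (clamped ≥ 1) in
`(0.2071 + 1.9102/√n_eff)/(1.2071 + 0.9102/√n_eff)`; the
diameter-over-box-squared model for the effective voxel count on a cubic
grid is pinned here.  Resolution is the linearly interpolated first
downward crossing; a curve that never crosses reports the Nyquist limit
`2·pixel`.  Sharpening is plain B-factor scaling `exp(−B·s²/4)` with a
cosine-edge low-pass (a cutoff at or beyond Nyquist disables filtering);
auto-sharpening and detector-MTF deconvolution are intentionally out of
scope, as they are not reproducible as closed formulas.  Directional FRC
correlates matching central real-space slices; on anisotropic data the
out-of-plane crossing moves to coarser resolution by a moderate factor —
rings in the xz plane keep their correlated low-`kz` sectors, so the shift
is intrinsically smaller than the anisotropy itself, as observed in real
half-maps.

The projector resamples with trilinear interpolation and sums along z; the
backprojector inserts each image's 2D transform as a central slice with
trilinear spreading and divides by the sampling weight.  Both exist to
validate geometry conventions end-to-end (project → backproject recovers a
low-passed phantom at masked correlation ≥ 0.95 from 60 views), not to
compete with production reconstruction code: there is no CTF weighting and
no gridding kernel correction.

## Ensemble comparison

Superposition is plain Kabsch least squares (proper rotation enforced via
the SVD determinant sign) over the selection — all C-α, all atoms, or a
residue range such as a channel's selectivity filter; no iterative outlier
trimming, so RMSDs can differ slightly from tools that trim pairs.  Atoms
pair strictly by (chain, residue number, atom name); the highest-occupancy
alternate location wins.  Single-linkage clustering is delegated to
scipy's linkage on the condensed matrix and validated against a brute-force
agglomerator; pair ranking breaks ties by label order.

## Demo problem sizes and numerical choices

The end-to-end demo uses two 512² micrographs (one crystal each, tilts
25° and 35°), a 49-voxel phantom, a 52 px square lattice (~80 unit cells
per image), box 48, per-cell SNR 1, and a 16/4-voxel soft mask for the
FSC — sizes chosen so the whole chain, including tests, runs in seconds
while every stage still has enough statistics to fail loudly when broken.
The per-stage random streams are spawned from one `SeedSequence(seed)` in
documented order (phantom; then render and noise streams per crystal).
The CLI exposes the field-standard defaults for real-data work (box 320 at
1.3 Å/px, 104³ crop with +12 z-shift, 42/6-voxel mask, Fourier crop to
2.6 Å, FSC 0.143, half-bit diameter 100 Å, C4).

## Known limitations

- Orientation assignment is purely geometric (global tilt); per-particle
  wobble refinement is the job of the downstream refinement package, so
  demo resolutions saturate at the wobble-induced floor.
- The backprojector's nearest-slice weighting leaves interpolation
  artifacts visible beyond ~3 px resolution; use it for geometry checks.
- The one-lattice rule rejects multi-lattice micrographs outright rather
  than separating lattices.
- The exact frame conventions of legacy 2D-crystal packages (handedness of
  the tilt axis, sign of taxa) are pinned here by internal consistency
  (matrix oracle, simulator round trip); interoperating with files from
  those packages may require a global mirror or in-plane rotation.
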