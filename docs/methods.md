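# Methods

`mtlumen` quantifies globular particles inside the microtubule (MT) lumen of
cryo-electron tomograms: where the particles are, how densely and how
regularly they pack, how their abundance relates to MT curvature and to
lattice defects, and roughly how heavy they are.  Because annotated
tomograms are large and scarce, the package pairs every estimator with a
synthetic-data generator that emulates the relevant statistical structure at
coordinate or voxel level, so the whole pipeline can be verified end-to-end
against known ground truth.

All coordinates are nm, continuous.  Voxel grids are 0-based with the volume
origin at the corner of voxel (0,0,0) and voxel centres at
`origin + (index + 0.5) * voxel_size`.  Every stochastic operation takes an
explicit integer seed; Monte-Carlo envelopes derive child seeds by fixed
increments, so all pipelines are bit-reproducible.

## Geometry model

An MT centerline is an ordered 3D polyline.  `resample_equidistant` walks
the polyline placing each sample at euclidean (chord) distance exactly
`spacing` from the previous one — the usual meaning of "equidistant points"
in filament tracing.  Chord stepping (rather than equal-arclength sampling)
makes consecutive sample distances exactly equal to the spacing and makes
resampling idempotent; for the gentle curvatures of cellular MTs
(persistence lengths of tens of µm against 20 nm steps) the chord/arc
difference is O((spacing/R)^2) and negligible.  The default spacing is
20 nm: fine enough to resolve curvature at the 20–45 µm persistence-length
scale while keeping traces small.

The lumen is a tube of radius 8.5 nm (the ~17 nm channel) around the
centerline, closed with flat caps at both ends so that membership
(`contains`) is consistent with the tube volume `pi r^2 L`.  The boundary is
closed (distance exactly `r` is inside).  The curvature correction to the
volume of a bent tube is O((r/Lp)^2) and ignored.

## Curvature: tangent-correlation length

Curvature is summarised by the apparent persistence length aLp: unit
tangents are taken by central differences along a resampled trace
(one-sided at the ends), tangent dot products are pooled over all filaments
and positions into a correlation curve C(s), and `ln C(s) = -s / aLp` is fit
through the origin by weighted least squares with pair counts as weights.
The 3D worm-like-chain convention `<t(u).t(u+s)> = exp(-s/Lp)` is used
throughout; a 2D-projection variant (factor 2) exists in the literature, so
the convention is stated here rather than silently assumed.  The default fit
window is lags up to 2 µm — tomogram fields of view are ~1–2 µm, the decay
over that range is shallow (C(2 µm) ≈ 0.93 at Lp = 28.4 µm), and pooling
across filaments is therefore essential; single-filament estimates trigger a
warning.  Straight filaments give slope ≈ 0; estimates beyond 10^6 nm are
reported censored at that cap with infinite standard error.

The WLC generator draws per-step deflections from the equilibrium
distribution `p(cos t) ~ exp(kappa cos t)` with kappa solved so that
`E[cos t] = exp(-step/Lp)`; successive deflections are independent, hence
the ensemble tangent correlation is *exactly* `exp(-s/Lp)` at every lag and
the generator doubles as an analytic oracle for the estimator.  Recovery
tests at the literature values (28.4 and 41.6 µm; ensembles of 200 chains of
2 µm) recover the generator value to within a few percent, well inside the
±15 % acceptance band.

## Lumenal point processes

Particles are placed strictly inside the tube by one of four processes:

* **csr** — homogeneous Poisson with a given intensity (nm^-3); the null
  model for all spatial tests.
* **hardcore** — random sequential placement rejecting centres closer than
  the hardcore distance (default 7 nm ≈ particle diameter); retries are
  capped at 100x the target count, after which a packing error names the
  achieved count (deterministic failure instead of a hang).
* **quasi_periodic** — a walk along the centerline with Normal axial gaps
  and small radial jitter (uniform disk, default 2 nm).  Gaps are truncated
  *symmetrically* to `[hardcore, 2*mean - hardcore]`: one-sided truncation
  at the hardcore distance would shift the realised mean (e.g. a nominal
  9.6 ± 3.4 nm gap becomes ~10.9 nm), whereas symmetric truncation preserves
  the nominal mean exactly and only shrinks the sd — the generator then
  actually embodies the mean spacings it is parameterised with.  Optional
  end-zone fields let the gap distribution differ within a given distance
  of an open MT end (tighter packing near freshly polymerized plus ends:
  9.6 ± 3.4 nm within ~100 nm versus 14.3 ± 6.7 nm distally).
* **anchored_cluster** — CSR background plus `intensity x (multiplier - 1)`
  extra CSR intensity within ±`cluster_domain/2` of each anchor (lattice
  breaks or open ends), the generative stand-in for defect-associated
  microclusters.

Dense neuronal packing uses spacing 9 ± 1.5 nm with hardcore 7 nm, which
reproduces the 8–10 nm nearest-neighbour mode.

## Volume rendering

Synthetic tomograms are rendered bright-on-dark: MT walls as soft-edged
hollow cylindrical shells (inner/outer radii 8.5/12.5 nm, erf-profile edges,
sigma 0.75 nm) over a distance field computed by a Euclidean distance
transform of the finely rasterized centerlines; particles as 3D Gaussians
whose width scales as `sigma_ref (m/m_ref)^(1/3)` (default 2.5 nm at
300 kDa, i.e. ~6 nm FWHM), so integrated intensity is proportional to mass
and peak amplitude is mass-independent; ribosome-sized reference blobs
(3200 kDa, sigma ~5.5 nm) outside the MTs with mutual clearance; then
additive white Gaussian noise.  Default particle masses are drawn uniformly
from 200–400 kDa.  No missing-wedge anisotropy or CTF is simulated: the
downstream statistics operate on coordinates, and detection only needs
blob-like maxima.  Consequently, passing tests demonstrate estimator
correctness on well-modelled blob data, not robustness to reconstruction
artifacts of real tomograms.

The "moderate noise" rendering condition is noise sd 0.15 against unit peak
amplitude; after the 0.5 px detection low-pass this leaves a voxel SNR of
~16, optimistic relative to raw cryo-ET but appropriate for data that has
already been denoised/binned as in practice.

## Particle detection

Detection is template-free: Gaussian low-pass at sigma 0.5 px, restriction
to the lumen masks, then topological-persistence simplification of local
maxima.  The masked voxel graph (26-connected) is swept in descending
intensity with a union-find merge tree: each maximum's persistence is its
height minus the saddle at which its superlevel component merges into a
higher one; unmerged maxima persist to the masked minimum.  This coincides
with discrete-Morse persistence on maxima for the purpose of picking blob
centres and is exactly testable against a level-sweep labelling oracle.
Ties are broken by flat voxel index (earlier voxel counts as higher), and
zero-persistence plateau maxima are never reported.  Voxels outside the
mask take no part (peaks cannot merge through the MT wall), and maxima
sitting on the mask surface are discarded: a one-sided maximum cannot be
distinguished from a truncation artifact such as the clipped tail of the
wall density.

The persistence threshold defaults to 3x the robust per-voxel noise SD.
The noise SD is estimated from adjacent masked-voxel *differences* of the
raw volume (1.4826 MAD / sqrt(2)) and scaled analytically through the
Gaussian filter: the value-MAD of masked voxels measures the particles
rather than the noise in a densely decorated lumen and would suppress close
pairs.  Peaks closer than 6 nm (the smallest particle diameter) are greedily
suppressed keeping the higher.  Surviving peaks are refined to sub-voxel
centres by an intensity-weighted centroid over the 3x3x3 neighbourhood
(weights above the neighbourhood minimum), assigned to the MT with the
nearest centerline (ties to the lower mt_id), and given arclength positions
by projection.  On the dense fixture the chain reaches recall/precision
≈ 0.99/1.0 at a 3 nm match radius.

## Spatial statistics in tubes

Per-MT concentrations are reported volumetrically (per µm^3 of lumen) and
linearly (per 100 nm of MT length); the two differ only by the fixed tube
cross-section, and which one a figure axis means is not always stated in the
literature, so both are emitted.  Nearest-neighbour (NN) distances are
always computed within a single MT (the lumen is secluded; cross-MT
neighbours are never counted), histogrammed at 2 nm, with the mode reported
as a bin centre (ties to the smaller bin).

Ripley's K is estimated as
`K(r) = V / (n(n-1)) * sum_{i!=j} 1(d_ij <= r) / w_ij` with the isotropic
boundary correction: `w_ij` is the fraction of the sphere of radius `d_ij`
centred on `i` that lies inside the tube, evaluated from quasi-uniform
Fibonacci surface points (default 256).  Pairs with `w = 0` are dropped and
logged.  L is the cube-root transform `(3K/4pi)^(1/3)` with CSR expectation
`L(r) = r`, so values above a Monte-Carlo CSR envelope mean clustering and
below mean greater-than-random uniformity.  Envelopes are pointwise
[5, 95] % bands over (default) 200 CSR replicates with the observed per-MT
counts, on a default 10–500 nm radius grid for defect analyses.

The bivariate statistic counts particles around fixed anchors (breaks, open
ends) with the same correction.  Because the bivariate correction depends
only on (anchor, distance), it is tabulated per anchor on a distance grid
and shared by the observed curve and all replicates; the table is computed
on the sub-polyline within `r_max + 2r` of the anchor, which is exact.  Two
numerical points matter in thin tubes:

* the sphere-surface fraction falls as `r^2/(2 d^2)` (~4e-4 at 300 nm), so
  with only 256 samples the fraction quantizes to zero beyond ~100 nm and
  silently drops exactly the pairs that carry the cluster signal; the
  defect-analysis fixtures therefore use 4096 samples.  Residual table
  noise is shared by the observed curve and the null, so it cancels in the
  envelope comparison;
* `domain_size` reads the largest radius up to which the observed L exceeds
  the upper envelope contiguously from the smallest radius (0 if not above
  at the first radius).  Under count conservation (the null redistributes
  the *same* total count), an anchored cluster of half-extent `c` on MTs of
  length `L` with excess `E = (m-1) * cluster_domain` crosses the null at
  `r* = (c^3 (m-1) L / E)^(1/3)`-type radii, so the readout depends on the
  unpublished background intensity and traced MT length, not only on the
  cluster extent.  The break fixture (15 MTs, one central break, multiplier
  4, cluster extent 300 nm) uses 3.0 µm MTs at 3e-4 nm^-3 background,
  dimensioned by this power analysis so that the fixture's own readout
  reproduces the ~300 nm cluster domain it embodies; the open-end fixture
  uses short (0.4 µm) freshly polymerized MTs whose weak end-proximal
  enrichment yields a small domain size, below the 200 nm bound.

Group comparisons use Mann-Whitney U (exact null for pooled n <= 12 without
ties, otherwise the normal approximation with tie correction) or Welch's t,
and report the percent change of medians.  No multiple-testing correction is
applied: each comparison mirrors a single-figure contrast.

## Occupancy and end spacing

Occupancy profiles count particles in non-overlapping 100 nm arclength
windows (the near-end zone scale); the last window is truncated and a
normalised per-nm variant is emitted.  End-spacing statistics sort particles
by arclength from the open end and assign each successive gap to the near
(< 100 nm) or distal zone by the gap midpoint — unambiguous for
boundary-spanning gaps.  Gaps are arclength differences by default; a 3D
euclidean variant is exposed as an option (the two differ only by the small
radial jitter).

## Mass calibration

Intensities in a tomogram have no absolute scale, but background-subtracted
integrated density is proportional to molecular mass within one volume.
Ribosomes in the same volume provide the scale (`reference_mass /
mean(reference intensity)`; the 3200 kDa reference mass is a named
configuration constant, not a measurement).  Integration sums
`voxel - background` within a sphere; the default background is the median
of the [r, 1.5r] shell, robust to crowding gradients.  In the verification
pipeline the integration apertures are matched in units of each object's
Gaussian width (2 sigma for both particles and references): the finite-
aperture capture fraction and the shell-tail oversubtraction then cancel
between particle and reference, so no aperture correction is needed and a
300 kDa particle is recovered at ~280 kDa (the residue comes from wall
density entering the particle shell).  Estimates are invariant under global
additive offsets, equivariant under intensity rescaling, and negative
intensities are clipped to zero with a flag.

## Map comparison

Small density maps are compared after Fourier-Gaussian low-pass filtering to
a common resolution (amplitude 0.5 at 1/resolution; default 25 Å) by Pearson
correlation over voxels, and grouped by average-linkage hierarchical
clustering of `1 - CC` cut at `CC > 0.8`.  Maps must be pre-aligned on
identical grids: rigid-body alignment and model fitting are out of scope,
so the module measures similarity of consistently oriented averages only.
Note the filter convention implies a real-space kernel sigma of
`resolution * sqrt(2 ln 2) / (2 pi)` (FWHM ≈ 0.44 resolution), and that a
*larger* resolution value means stronger blurring.

## Problem sizes and defaults used in verification

Curvature: 20 ensembles x 200 chains x 2 µm at 20 nm steps.  Detection
chain: 20 MTs x 1.5 µm at 1 nm voxels, near-straight (a worm-like chain at
28.4 µm persistence sags ~300 nm transversally over 1.5 µm, which only
inflates the rendered box without affecting the packing statistic; a ≤1°
random tilt varies orientation instead).  Defect analyses: 200-replicate
envelopes on a 10–500 nm grid, medians over 20 seeds.  Group comparison:
40 MTs x 2 µm per group at 2e-4 nm^-3 (control).  Mass: one 0.8 µm MT,
~26 particles at 300 kDa, 10 ribosome references, noise sd 0.1.

## Known limitations

* The renderer omits missing wedge, CTF, and neighbouring cellular
  densities; detection performance on real tomograms will be lower than the
  synthetic recall/precision.
* The isotropic Ripley correction is variance-heavy in thin tubes at radii
  much larger than the tube radius (weights grow as `d^2/r^2`); domain-size
  readouts at several hundred nm are meaningful only with adequate surface
  sampling and should be interpreted jointly with the envelope width.
* `domain_size` conflates cluster extent with fixture geometry through the
  count-conservation crossing described above; on real data the analogous
  dependence is on the traced MT length distribution.
* Mass estimates assume a mass-proportional, background-separable density
  integral; aggregation, close packing, or strong gradients violate this.
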