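# mtlumen

Quantitative analysis of **microtubule (MT) lumenal particles** in
cryo-electron tomograms — for structural cell biologists who have traced MT
centerlines and want reproducible numbers for what is inside the lumen.

Neuronal MTs carry globular particles (6–8 nm, ~200–400 kDa) inside their
~17 nm lumen.  `mtlumen` implements the quantitative side of that analysis
as a tested, reusable pipeline:

* **Detection** — template-free particle picking inside lumen masks by
  topological-persistence simplification of local maxima (merge-tree
  persistence on the masked voxel graph, noise-relative threshold).
* **Abundance** — per-MT concentrations (per µm³ of lumen and per 100 nm of
  length) with Mann-Whitney / Welch group comparisons.
* **Order** — within-MT nearest-neighbour (NN) distance histograms, and
  univariate / bivariate Ripley functions confined to the tubular lumen,
  `L(r) = (3K(r)/4π)^{1/3}` with the isotropic sphere-surface-fraction
  volume correction and Monte-Carlo envelopes under complete spatial
  randomness (CSR): `L` above the [5, 95]% envelope ⇒ clustering, below ⇒
  more uniform than random.  Anchored (bivariate) variants measure particle
  clustering around lattice breaks and open MT ends, and `domain_size`
  reads off the cluster extent.
* **Curvature** — the apparent persistence length aLp from the
  tangent-correlation decay `⟨t(u)·t(u+s)⟩ = exp(−s/aLp)`, fit by weighted
  least squares of `ln C(s)` pooled over filaments.
* **Mass** — approximate molecular masses from background-subtracted
  integrated density, calibrated on ribosomes as an internal standard.
* **Map comparison** — pairwise cross-correlation of small density maps
  after low-pass filtering to a common resolution, grouped at `CC > 0.8`.
* **Synthetic data** — a first-class generator (worm-like-chain filaments,
  CSR / hardcore / quasi-periodic / anchored-cluster lumenal point
  processes, volume rendering with walls, mass-proportional blobs, ribosome
  references and noise) that reproduces the statistical structure of the
  real data with full ground truth, so every stage is verifiable without
  any download.

Inputs are either synthetic (generated in-process) or user-supplied: a
density volume (MRC2014), traced centerlines (CSV polylines, nm), and
optionally pre-picked particle tables (CSV).  See `docs/methods.md` for the
models, estimators, defaults and their rationale.

## Worked example

Simulate one neuron-like MT, render it, detect the particles, and measure
packing — all from explicit seeds:

```python
from mtlumen import (ProcessSpec, RenderSpec, build_domain, concentration,
                     detect_particles, draw_masses, nn_distances,
                     place_particles, render_volume, simulate_filament)

# 0.5 µm worm-like-chain centerline at the primary-neuron persistence length
trace = simulate_filament(n_points=26, step=20.0,
                          persistence_length=28_400.0, seed=1)
domain = build_domain(trace, lumen_radius=8.5)

# dense quasi-periodic lumenal packing (axial gaps 9 ± 1.5 nm, hardcore 7 nm)
truth = place_particles(domain, ProcessSpec(kind="quasi_periodic",
                                            spacing_mean=9.0, spacing_sd=1.5,
                                            hardcore_distance=7.0, seed=1))
masses = draw_masses(len(truth), seed=2)          # 200-400 kDa
vol, table = render_volume([trace], truth, masses,
                           RenderSpec(voxel_size=1.0, noise_sd=0.15, seed=3))

detected, report = detect_particles(vol, [domain])
nn = nn_distances(detected)
conc = concentration(detected, domain)
print(f"placed {len(truth)}, detected {len(detected)} "
      f"(persistence threshold {report['threshold_used']:.3f})")
print(f"concentration: {conc.per_um3:,.0f} per um^3 ({conc.per_100nm:.1f} per 100 nm)")
print(f"NN mode bin centre: {nn.mode_bin_center:.0f} nm")
```

prints

```
placed 56, detected 53 (persistence threshold 0.209)
concentration: 467,001 per um^3 (10.6 per 100 nm)
NN mode bin centre: 9 nm
```

53 of the 56 placed particles are recovered (the misses are closest-pair
merges at the hardcore limit); the detection threshold is 3x the estimated
noise SD after filtering; the dense packing gives ~11 particles per 100 nm
of MT (≈ 4.7 x 10^5 per µm³ of lumen) and the characteristic 8–10 nm
nearest-neighbour mode (here the 8–10 nm bin, centre 9 nm).

The same scenarios are scripted in the fixture registry and runnable from
the shell:

```bash
mtlumen run --fixture break_cluster --seed 1 --out out/break
mtlumen curvature --traces traces.csv --out alp.json
mtlumen detect --volume tomo.mrc --traces traces.csv --out particles.csv
```

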