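"""Scenario orchestration: simulate -> detect -> analyze with standard I/O.

Each ``run_*`` function executes one scenario end-to-end from an explicit
seed and returns a plain-dict result bundle; :func:`run_scenario` dispatches
a :class:`~mtlumen.fixtures.PipelineConfig`, writes results (JSON/CSV, MRC
where volumes are produced) into an output directory, and records a manifest
with a hash of the configuration so reruns are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import io as mio
from .detect import detect_particles
from .filaments import build_domain, estimate_alp, tangent_correlation
from .fixtures import PipelineConfig, fixtures
from .mass import calibrate, estimate_mass, integrate_density
from .occupancy import end_spacing_stats
from .particles import ParticleSet
from .simulate import (ProcessSpec, RenderSpec, draw_masses, place_particles,
                       render_volume, simulate_ensemble, simulate_filament)
from .spatial import (DEFAULT_RADII_NM, compare_groups, concentration,
                      domain_size, nn_distances, ripley_L_bivariate)

logger = logging.getLogger(__name__)

__all__ = ["run_scenario", "run_alp_recovery", "run_nn_detection",
           "run_break_cluster", "run_open_end", "run_two_group",
           "run_mass_pipeline"]


# ---------------------------------------------------------------------------
# Scenario implementations
# ---------------------------------------------------------------------------

def run_alp_recovery(persistence_length_nm: float, seed: int,
                     n_chains: int = 200, chain_length_nm: float = 2000.0,
                     step_nm: float = 20.0, n_ensembles: int = 20,
                     fit_max_lag_nm: float = 2000.0, **_ignored) -> dict:
    """Recover the tangent-correlation length from WLC ensembles.

    Simulates ``n_ensembles`` independent ensembles of ``n_chains`` chains,
    pools tangent correlations per ensemble, fits ``ln C(s) = -s / aLp`` and
    reports the per-ensemble estimates and their median.
    """
    n_points = int(round(chain_length_nm / step_nm)) + 1
    estimates, ses = [], []
    for e in range(n_ensembles):
        traces = simulate_ensemble(n_chains, n_points, step_nm,
                                   persistence_length_nm, seed=seed + e)
        curve = tangent_correlation(traces, max_lag=min(fit_max_lag_nm, chain_length_nm))
        alp, se = estimate_alp(curve, fit_max_lag=fit_max_lag_nm)
        estimates.append(alp)
        ses.append(se)
    return {"alp_nm": estimates, "alp_se_nm": ses,
            "median_alp_nm": float(np.median(estimates)),
            "true_persistence_length_nm": persistence_length_nm,
            "n_filaments": n_chains, "n_ensembles": n_ensembles,
            "fit_max_lag_nm": fit_max_lag_nm}


def _tilted_direction(rng, tilt_max_deg: float) -> np.ndarray:
    ang = np.deg2rad(tilt_max_deg)
    d = np.array([1.0, rng.uniform(-ang, ang), rng.uniform(-ang, ang)])
    return d / np.linalg.norm(d)


def run_nn_detection(seed: int, n_mts: int = 20, mt_length_nm: float = 1500.0,
                     lumen_radius_nm: float = 8.5, spacing_mean_nm: float = 9.0,
                     spacing_sd_nm: float = 1.5, hardcore_nm: float = 7.0,
                     radial_jitter_nm: float = 2.0, voxel_size_nm: float = 1.0,
                     noise_sd: float = 0.15, tilt_max_deg: float = 1.0,
                     bin_width_nm: float = 2.0, match_radius_nm: float = 3.0,
                     keep_volumes: bool = False, **_ignored) -> dict:
    """Full chain: quasi-periodic lumenal packing, rendering, template-free
    detection, pooled within-MT nearest-neighbour histogram.

    Each MT is simulated and rendered in its own compact box (MTs are
    near-straight over the 1.5 µm segment; a small random tilt varies the
    orientation).  Returns the NN mode bin centre, detection counts, and
    recall/precision against the rendered ground truth.
    """
    rng = np.random.default_rng(seed)
    detected_sets = []
    n_truth_total = 0
    n_matched_truth = 0
    n_det_total = 0
    n_det_matched = 0
    volumes = []
    for m in range(n_mts):
        step = 20.0
        trace = simulate_filament(int(mt_length_nm / step) + 1, step,
                                  persistence_length=1e9,
                                  seed=seed * 1000 + m,
                                  direction=_tilted_direction(rng, tilt_max_deg),
                                  mt_id=m)
        dom = build_domain(trace, lumen_radius_nm)
        pspec = ProcessSpec(kind="quasi_periodic", spacing_mean=spacing_mean_nm,
                            spacing_sd=spacing_sd_nm, hardcore_distance=hardcore_nm,
                            radial_jitter=radial_jitter_nm, seed=seed * 1000 + 500 + m)
        truth_ps = place_particles(dom, pspec)
        masses = draw_masses(len(truth_ps), seed=seed * 1000 + 700 + m)
        rspec = RenderSpec(voxel_size=voxel_size_nm, noise_sd=noise_sd,
                           seed=seed * 1000 + 900 + m)
        vol, truth = render_volume([trace], truth_ps, masses, rspec)
        det, report = detect_particles(vol, [dom])
        detected_sets.append(det)
        if keep_volumes:
            volumes.append(vol)
        # match detections to ground truth
        tpos = truth[["x_nm", "y_nm", "z_nm"]].to_numpy()
        n_truth_total += tpos.shape[0]
        n_det_total += len(det)
        if len(det) and tpos.shape[0]:
            d, _ = cKDTree(tpos).query(det.positions())
            n_det_matched += int((d <= match_radius_nm).sum())
            d2, _ = cKDTree(det.positions()).query(tpos)
            n_matched_truth += int((d2 <= match_radius_nm).sum())
        logger.info("MT %d: %d truth, %d detected (report %s)", m,
                    tpos.shape[0], len(det), report)
    pooled = ParticleSet.concat(detected_sets)
    nn = nn_distances(pooled, per_mt=True, bin_width=bin_width_nm)
    out = {"mode_bin_center_nm": nn.mode_bin_center,
           "n_detected": len(pooled), "n_truth": n_truth_total,
           "recall": n_matched_truth / n_truth_total if n_truth_total else np.nan,
           "precision": n_det_matched / n_det_total if n_det_total else np.nan,
           "nn_counts": nn.counts.tolist(),
           "nn_bin_edges": nn.bin_edges.tolist(),
           "_particles": pooled}
    if keep_volumes:
        out["_volumes"] = volumes
    return out


def _wlc_domains(n_mts, mt_length_nm, step_nm, persistence_length_nm,
                 lumen_radius_nm, seed, open_start=False, central_break=False):
    n_points = int(round(mt_length_nm / step_nm)) + 1
    traces = simulate_ensemble(n_mts, n_points, step_nm, persistence_length_nm,
                               seed=seed)
    doms = []
    for tr in traces:
        dom = build_domain(tr, lumen_radius_nm)
        if central_break:
            dom = dom.with_defects(break_arclengths=[dom.length / 2])
        if open_start:
            dom = dom.with_defects(open_ends=["start"])
        doms.append(dom)
    return doms


def run_break_cluster(seed: int, n_mts: int = 15, mt_length_nm: float = 3000.0,
                      lumen_radius_nm: float = 8.5, step_nm: float = 20.0,
                      persistence_length_nm: float = 41600.0,
                      intensity_per_nm3: float = 3e-4,
                      cluster_domain_nm: float = 300.0,
                      cluster_multiplier: float = 4.0,
                      radii: np.ndarray | None = None, n_reps: int = 200,
                      n_correction_samples: int = 4096, **_ignored) -> dict:
    """Anchored microclusters at lattice breaks, tested by bivariate L.

    One central break per MT; particle placement is CSR background plus a
    ``cluster_multiplier`` x intensity boost within ±cluster_domain/2 of the
    break.  Returns the enveloped bivariate L curve and its domain size.
    """
    radii = DEFAULT_RADII_NM if radii is None else np.asarray(radii, dtype=float)
    doms = _wlc_domains(n_mts, mt_length_nm, step_nm, persistence_length_nm,
                        lumen_radius_nm, seed, central_break=True)
    sets = []
    for i, dom in enumerate(doms):
        pspec = ProcessSpec(kind="anchored_cluster", intensity=intensity_per_nm3,
                            cluster_domain=cluster_domain_nm,
                            cluster_multiplier=cluster_multiplier,
                            seed=seed * 1000 + i)
        sets.append(place_particles(dom, pspec))
    particles = ParticleSet.concat(sets)
    curve = ripley_L_bivariate(particles, doms, radii=radii, n_reps=n_reps,
                               n_correction_samples=n_correction_samples,
                               seed=seed * 7 + 13)
    return {"domain_size_nm": domain_size(curve), "n_particles": len(particles),
            "n_anchors": curve.meta["n_anchors"], "curve": curve.to_dict(),
            "_curve": curve, "_domains": doms, "_particles": particles}


def run_open_end(seed: int, n_mts: int = 20, mt_length_nm: float = 400.0,
                 lumen_radius_nm: float = 8.5, step_nm: float = 20.0,
                 persistence_length_nm: float = 41600.0,
                 near_zone_nm: float = 100.0,
                 near_spacing_mean_nm: float = 9.6, near_spacing_sd_nm: float = 3.4,
                 distal_spacing_mean_nm: float = 14.3, distal_spacing_sd_nm: float = 6.7,
                 hardcore_nm: float = 7.0, radial_jitter_nm: float = 2.0,
                 radii: np.ndarray | None = None, n_reps: int = 200,
                 n_correction_samples: int = 4096,
                 near_cutoff_nm: float = 100.0, compute_ripley: bool = True,
                 **_ignored) -> dict:
    """Open-end fixture: tighter axial packing near the open end.

    Gap spacing is near-Normal within ``near_zone_nm`` of the open end and
    distal-Normal elsewhere.  Reports pooled near/distal mean spacings and
    the bivariate-L domain size anchored at the open ends.
    """
    radii = DEFAULT_RADII_NM if radii is None else np.asarray(radii, dtype=float)
    doms = _wlc_domains(n_mts, mt_length_nm, step_nm, persistence_length_nm,
                        lumen_radius_nm, seed, open_start=True)
    sets = []
    for i, dom in enumerate(doms):
        pspec = ProcessSpec(kind="quasi_periodic",
                            spacing_mean=distal_spacing_mean_nm,
                            spacing_sd=distal_spacing_sd_nm,
                            hardcore_distance=hardcore_nm,
                            radial_jitter=radial_jitter_nm,
                            end_zone=near_zone_nm,
                            end_spacing_mean=near_spacing_mean_nm,
                            end_spacing_sd=near_spacing_sd_nm,
                            seed=seed * 1000 + i)
        sets.append(place_particles(dom, pspec))
    particles = ParticleSet.concat(sets)
    # pooled near/distal gap means, weighted by gap counts
    tot = {"near": [0.0, 0], "distal": [0.0, 0]}
    for dom in doms:
        st = end_spacing_stats(particles, dom, near_cutoff=near_cutoff_nm)
        for z in ("near", "distal"):
            if st[f"n_{z}"]:
                tot[z][0] += st[f"{z}_mean"] * st[f"n_{z}"]
                tot[z][1] += st[f"n_{z}"]
    near_mean = tot["near"][0] / tot["near"][1] if tot["near"][1] else np.nan
    distal_mean = tot["distal"][0] / tot["distal"][1] if tot["distal"][1] else np.nan
    out = {"near_mean_nm": float(near_mean), "distal_mean_nm": float(distal_mean),
           "n_near": tot["near"][1], "n_distal": tot["distal"][1],
           "n_particles": len(particles),
           "_domains": doms, "_particles": particles}
    if compute_ripley:
        curve = ripley_L_bivariate(particles, doms, radii=radii, n_reps=n_reps,
                                   n_correction_samples=n_correction_samples,
                                   seed=seed * 7 + 13)
        out.update({"domain_size_nm": domain_size(curve),
                    "curve": curve.to_dict(), "_curve": curve})
    return out


def run_two_group(seed: int, n_mts: int = 40, mt_length_nm: float = 2000.0,
                  lumen_radius_nm: float = 8.5, step_nm: float = 20.0,
                  persistence_length_nm: float = 41600.0,
                  intensity_per_nm3: float = 2e-4,
                  concentration_ratio: float = 0.75,
                  test: str = "mann_whitney", **_ignored) -> dict:
    """Control vs treated concentration comparison at a known intensity ratio."""
    groups = {}
    for gi, (label, inten) in enumerate([("control", intensity_per_nm3),
                                         ("treated", intensity_per_nm3 * concentration_ratio)]):
        doms = _wlc_domains(n_mts, mt_length_nm, step_nm, persistence_length_nm,
                            lumen_radius_nm, seed + 7919 * gi)
        conc = []
        for i, dom in enumerate(doms):
            pspec = ProcessSpec(kind="csr", intensity=inten,
                                seed=seed * 1000 + 97 * gi + i)
            ps = place_particles(dom, pspec)
            conc.append(concentration(ps, dom).per_um3)
        groups[label] = conc
    cmp_res = compare_groups(groups["control"], groups["treated"], test=test)
    return {"percent_change": cmp_res.percent_change, "pvalue": cmp_res.pvalue,
            "statistic": cmp_res.statistic, "test": test,
            "median_control_per_um3": float(np.median(groups["control"])),
            "median_treated_per_um3": float(np.median(groups["treated"])),
            "concentrations": groups}


def run_mass_pipeline(seed: int, mt_length_nm: float = 800.0,
                      lumen_radius_nm: float = 8.5,
                      particle_mass_kda: float = 300.0,
                      particle_spacing_nm: float = 30.0,
                      ribosome_mass_kda: float = 3200.0, n_ribosomes: int = 10,
                      voxel_size_nm: float = 1.0, noise_sd: float = 0.1,
                      particle_radius_nm: float = 5.0,
                      ribosome_radius_sigmas: float = 2.0,
                      keep_volume: bool = False, **_ignored) -> dict:
    """Internal-standard mass estimation on a rendered synthetic tomogram.

    Renders lumenal particles of known mass plus ribosome references, then
    integrates densities at the ground-truth positions, calibrates kDa per
    intensity unit on the ribosomes, and estimates each particle's mass.

    Integration apertures are matched in units of each object's Gaussian
    width (default 2 sigma for both particles and references): the finite-
    aperture capture fraction and the shell-background oversubtraction then
    cancel between particle and reference, so no aperture correction is
    needed.
    """
    step = 20.0
    trace = simulate_filament(int(mt_length_nm / step) + 1, step, 1e9,
                              seed=seed, direction=(1.0, 0.0, 0.0))
    dom = build_domain(trace, lumen_radius_nm)
    pspec = ProcessSpec(kind="quasi_periodic", spacing_mean=particle_spacing_nm,
                        spacing_sd=3.0, hardcore_distance=20.0,
                        radial_jitter=2.0, seed=seed + 11)
    ps = place_particles(dom, pspec)
    rspec = RenderSpec(voxel_size=voxel_size_nm, noise_sd=noise_sd,
                       ribosome_mass=ribosome_mass_kda, ribosome_count=n_ribosomes,
                       seed=seed + 23)
    vol, truth = render_volume([trace], ps, particle_mass_kda, rspec)
    sig_ribo = rspec.sigma_for_mass(ribosome_mass_kda)
    ribo = truth[truth["kind"] == "ribosome"]
    ref_int = [integrate_density(vol, r[["x_nm", "y_nm", "z_nm"]].to_numpy(float),
                                 ribosome_radius_sigmas * sig_ribo)
               for _, r in ribo.iterrows()]
    calib = calibrate(ref_int, reference_mass=ribosome_mass_kda)
    lum = truth[truth["kind"] == "lumenal"]
    masses, ses = [], []
    for _, r in lum.iterrows():
        inten = integrate_density(vol, r[["x_nm", "y_nm", "z_nm"]].to_numpy(float),
                                  particle_radius_nm)
        mk, se, _clip = estimate_mass(inten, calib)
        masses.append(mk)
        ses.append(se)
    out = {"median_mass_kda": float(np.median(masses)),
           "masses_kda": masses, "mass_se_kda": ses,
           "scale_kda_per_intensity": calib.scale, "scale_se": calib.scale_se,
           "n_particles": len(masses), "n_references": len(ref_int),
           "true_mass_kda": particle_mass_kda}
    if keep_volume:
        out["_volume"] = vol
        out["_truth"] = truth
    return out


# ---------------------------------------------------------------------------
# Dispatch + persistence
# ---------------------------------------------------------------------------

_DISPATCH = {
    "curvature": lambda cfg: run_alp_recovery(seed=cfg.seed, **cfg.generator,
                                              **cfg.analysis),
    "nn_detection": lambda cfg: run_nn_detection(seed=cfg.seed, **cfg.generator,
                                                 **cfg.analysis),
    "break_cluster": lambda cfg: run_break_cluster(seed=cfg.seed, **_radii_kw(cfg)),
    "open_end": lambda cfg: run_open_end(seed=cfg.seed, **_radii_kw(cfg)),
    "two_group": lambda cfg: run_two_group(seed=cfg.seed, **cfg.generator,
                                           **cfg.analysis),
    "mass_pipeline": lambda cfg: run_mass_pipeline(seed=cfg.seed, **cfg.generator,
                                                   **cfg.analysis),
}


def _radii_kw(cfg: PipelineConfig) -> dict:
    kw = {**cfg.generator, **cfg.analysis}
    if {"radii_start_nm", "radii_stop_nm", "radii_step_nm"} <= kw.keys():
        kw["radii"] = np.arange(kw.pop("radii_start_nm"),
                                kw.pop("radii_stop_nm") + 1e-9,
                                kw.pop("radii_step_nm"))
    return kw


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_scenario(config: PipelineConfig, outdir=None) -> dict:
    """Run one scenario; optionally persist results + manifest to ``outdir``.

    Deterministic given the config seed: rerunning with the same config
    writes byte-identical JSON results.  Any stage error aborts with a
    stage-named diagnostic.
    """
    config.validate()
    try:
        results = _DISPATCH[config.scenario](config)
    except Exception as exc:  # annotate with the failing stage
        raise RuntimeError(f"scenario {config.name!r} ({config.scenario}) failed: {exc}") from exc
    public = {k: v for k, v in results.items() if not k.startswith("_")}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mio.write_json(public, outdir / "results.json")
        if "_particles" in results:
            results["_particles"].to_csv(outdir / "particles.csv")
        if "_volume" in results:
            mio.write_mrc(results["_volume"], outdir / "volume.mrc")
        manifest = {"name": config.name, "scenario": config.scenario,
                    "config": config.to_dict(), "config_sha256": config_hash(config)}
        mio.write_json(manifest, outdir / "manifest.json")
        logger.info("scenario %s written to %s", config.name, outdir)
    return public


def run_fixture(name: str, seed: int = 1, outdir=None) -> dict:
    return run_scenario(fixtures(name, seed=seed), outdir=outdir)
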