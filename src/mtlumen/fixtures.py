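"""Scenario registry: fully seeded configurations of the study conditions.

Each fixture bundles the generator and analysis parameters of one scenario
(cell type, drug treatment, or defect geometry) so that every analysis can be
reproduced end-to-end from a single seed.  Literature-derived defaults live
here, never hard-coded in library code:

* tangent-correlation lengths: primary neurons 28.4 µm, hiPSC-derived
  neurons 21.7 µm, pluripotent P19 41.6 µm, differentiated P19 25.9 µm;
* dense neuronal lumenal packing: quasi-periodic axial spacing 9 +- 1.5 nm
  (hardcore 7 nm), giving the 8-10 nm nearest-neighbour mode;
* Taxol: lumenal particle concentration reduced to 0.75x the control;
* lattice breaks: anchored clusters of ~300 nm axial extent, 15 breakpoints;
* open ends: tighter packing (9.6 +- 3.4 nm gaps) within ~100 nm of the end
  vs 14.3 +- 6.7 nm distally, on short freshly polymerized MTs;
* masses: lumenal particles 200-400 kDa; ribosome reference 3200 kDa.

Background lumenal concentrations are not published as numbers; the CSR
intensity 2e-4 nm^-3 (~1 particle per 22 nm of lumen) is used as a
P19-like reference density, with 1e-4 nm^-3 for sparse conditions.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

__all__ = ["PipelineConfig", "fixtures", "FIXTURE_NAMES"]


@dataclass
class PipelineConfig:
    name: str
    scenario: str           # one of SCENARIO_KINDS
    seed: int
    generator: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)

    def validate(self) -> "PipelineConfig":
        if self.scenario not in SCENARIO_KINDS:
            raise ValueError(f"unknown scenario kind {self.scenario!r}; "
                             f"known: {sorted(SCENARIO_KINDS)}")
        if not isinstance(self.seed, int) or isinstance(self.seed, bool):
            raise ValueError("seed must be an explicit integer")
        for key, val in {**self.generator, **self.analysis}.items():
            if key in _POSITIVE_KEYS and not (isinstance(val, (int, float)) and val > 0):
                raise ValueError(f"parameter {key!r} must be a positive number, got {val!r}")
        return self

    def to_dict(self) -> dict:
        return {"name": self.name, "scenario": self.scenario, "seed": self.seed,
                "generator": copy.deepcopy(self.generator),
                "analysis": copy.deepcopy(self.analysis)}

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(name=d["name"], scenario=d["scenario"], seed=int(d["seed"]),
                   generator=dict(d.get("generator", {})),
                   analysis=dict(d.get("analysis", {}))).validate()


SCENARIO_KINDS = {"curvature", "nn_detection", "break_cluster", "open_end",
                  "two_group", "mass_pipeline"}

_POSITIVE_KEYS = {"persistence_length_nm", "step_nm", "mt_length_nm",
                  "intensity_per_nm3", "spacing_mean_nm", "spacing_sd_nm",
                  "voxel_size_nm", "lumen_radius_nm", "cluster_domain_nm",
                  "cluster_multiplier", "near_cutoff_nm", "particle_mass_kda",
                  "ribosome_mass_kda", "n_mts", "n_chains", "n_ensembles",
                  "n_reps", "concentration_ratio"}

# Reference lumen geometry (nm)
LUMEN_RADIUS_NM = 8.5

_REGISTRY: dict[str, dict] = {
    # Curvature + dense, ordered lumenal packing of primary neurons.
    "primary_neuron": {
        "scenario": "curvature",
        "generator": {
            "persistence_length_nm": 28400.0,
            "n_chains": 200, "chain_length_nm": 2000.0, "step_nm": 20.0,
            "n_ensembles": 20,
            # dense packing parameters consumed by the companion
            # nn_detection scenario of the same cell type
            "spacing_mean_nm": 9.0, "spacing_sd_nm": 1.5, "hardcore_nm": 7.0,
        },
        "analysis": {"fit_max_lag_nm": 2000.0},
    },
    "hipsc": {
        "scenario": "curvature",
        "generator": {
            "persistence_length_nm": 21700.0,
            "n_chains": 200, "chain_length_nm": 2000.0, "step_nm": 20.0,
            "n_ensembles": 20,
            "spacing_mean_nm": 9.0, "spacing_sd_nm": 1.5, "hardcore_nm": 7.0,
        },
        "analysis": {"fit_max_lag_nm": 2000.0},
    },
    "p19_pluripotent": {
        "scenario": "curvature",
        "generator": {
            "persistence_length_nm": 41600.0,
            "n_chains": 200, "chain_length_nm": 2000.0, "step_nm": 20.0,
            "n_ensembles": 20,
            "intensity_per_nm3": 2e-4,
        },
        "analysis": {"fit_max_lag_nm": 2000.0},
    },
    "p19_differentiated": {
        "scenario": "curvature",
        "generator": {
            "persistence_length_nm": 25900.0,
            "n_chains": 200, "chain_length_nm": 2000.0, "step_nm": 20.0,
            "n_ensembles": 20,
            "spacing_mean_nm": 9.0, "spacing_sd_nm": 1.5, "hardcore_nm": 7.0,
        },
        "analysis": {"fit_max_lag_nm": 2000.0},
    },
    # End-to-end simulate -> render -> detect -> NN on dense packing.
    "neuron_dense_packing": {
        "scenario": "nn_detection",
        "generator": {
            "n_mts": 20, "mt_length_nm": 1500.0, "lumen_radius_nm": LUMEN_RADIUS_NM,
            "spacing_mean_nm": 9.0, "spacing_sd_nm": 1.5, "hardcore_nm": 7.0,
            "radial_jitter_nm": 2.0, "voxel_size_nm": 1.0, "noise_sd": 0.15,
            "tilt_max_deg": 1.0,
        },
        "analysis": {"bin_width_nm": 2.0, "match_radius_nm": 3.0},
    },
    # Lattice-break microclusters (15 breakpoints, ~300 nm cluster extent).
    "break_cluster": {
        "scenario": "break_cluster",
        "generator": {
            "n_mts": 15, "mt_length_nm": 3000.0, "lumen_radius_nm": LUMEN_RADIUS_NM,
            "persistence_length_nm": 41600.0, "step_nm": 20.0,
            "intensity_per_nm3": 3e-4,
            "cluster_domain_nm": 300.0, "cluster_multiplier": 4.0,
        },
        "analysis": {"radii_start_nm": 10.0, "radii_stop_nm": 500.0,
                     "radii_step_nm": 10.0, "n_reps": 200,
                     "n_correction_samples": 4096},
    },
    # Freshly polymerized MTs with open ends and end-proximal enrichment.
    "open_end": {
        "scenario": "open_end",
        "generator": {
            "n_mts": 20, "mt_length_nm": 400.0, "lumen_radius_nm": LUMEN_RADIUS_NM,
            "persistence_length_nm": 41600.0, "step_nm": 20.0,
            "near_zone_nm": 100.0,
            "near_spacing_mean_nm": 9.6, "near_spacing_sd_nm": 3.4,
            "distal_spacing_mean_nm": 14.3, "distal_spacing_sd_nm": 6.7,
            "hardcore_nm": 7.0, "radial_jitter_nm": 2.0,
        },
        "analysis": {"radii_start_nm": 10.0, "radii_stop_nm": 500.0,
                     "radii_step_nm": 10.0, "n_reps": 200,
                     "n_correction_samples": 4096, "near_cutoff_nm": 100.0},
    },
    # Taxol-treated vs control concentration comparison.
    "taxol_pair": {
        "scenario": "two_group",
        "generator": {
            "n_mts": 40, "mt_length_nm": 2000.0, "lumen_radius_nm": LUMEN_RADIUS_NM,
            "persistence_length_nm": 41600.0, "step_nm": 20.0,
            "intensity_per_nm3": 2e-4, "concentration_ratio": 0.75,
        },
        "analysis": {"test": "mann_whitney"},
    },
    # Internal-standard mass estimation.
    "mass_calibration": {
        "scenario": "mass_pipeline",
        "generator": {
            "mt_length_nm": 800.0, "lumen_radius_nm": LUMEN_RADIUS_NM,
            "particle_mass_kda": 300.0, "particle_spacing_nm": 30.0,
            "ribosome_mass_kda": 3200.0, "n_ribosomes": 10,
            "voxel_size_nm": 1.0, "noise_sd": 0.1,
        },
        "analysis": {"particle_radius_nm": 5.0, "ribosome_radius_sigmas": 2.0},
    },
}

FIXTURE_NAMES = tuple(sorted(_REGISTRY))


def fixtures(name: str, seed: int = 1) -> PipelineConfig:
    """A fully seeded configuration reproducing one registered scenario."""
    if name not in _REGISTRY:
        raise KeyError(f"unknown fixture {name!r}; registry: {list(FIXTURE_NAMES)}")
    entry = copy.deepcopy(_REGISTRY[name])
    return PipelineConfig(name=name, scenario=entry["scenario"], seed=seed,
                          generator=entry["generator"],
                          analysis=entry["analysis"]).validate()
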