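"""Spatial statistics of lumenal particles confined to MT lumen domains.

Concentrations, nearest-neighbour (NN) distance distributions, univariate and
bivariate (anchor-referenced) Ripley's K/L functions with numerical volume
corrections for the tubular geometry, Monte-Carlo envelopes under complete
spatial randomness (CSR), cluster domain-size estimation, and two-group
comparisons.

Ripley's K is estimated as ``K(r) = V / (n (n-1)) * sum_{i!=j} 1(d_ij <= r) /
w_ij`` with the isotropic correction ``w_ij`` equal to the fraction of the
sphere surface of radius ``d_ij`` centred on ``i`` that lies inside the
domain, evaluated numerically from quasi-uniform (Fibonacci) surface points.
L is the variance-stabilised transform ``L(r) = (3 K(r) / 4 pi)^(1/3)`` whose
CSR expectation is ``L(r) = r``: values above the Monte-Carlo envelope
indicate clustering at that scale, values below indicate a more uniform
arrangement than random.  NN distances are always computed within a single
MT (the lumen is secluded; cross-MT neighbours are never counted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .filaments import LumenDomain
from .particles import ParticleSet
from .simulate import _sample_csr_tube

logger = logging.getLogger(__name__)

__all__ = [
    "StatCurve", "NNResult", "ConcentrationResult", "GroupComparison",
    "concentration", "nn_distances", "csr_envelope", "ripley_L",
    "ripley_L_bivariate", "domain_size", "compare_groups",
    "DEFAULT_RADII_NM",
]

#: default radius grid for break / open-end analyses (nm)
DEFAULT_RADII_NM = np.arange(10.0, 501.0, 10.0)
DEFAULT_N_REPS = 200
DEFAULT_CORRECTION_SAMPLES = 256
NN_BIN_WIDTH_NM = 2.0


@dataclass
class StatCurve:
    """A distance-indexed statistic with pointwise [5, 95]% CSR envelope."""

    radii: np.ndarray
    observed: np.ndarray
    envelope_lo: np.ndarray | None = None
    envelope_hi: np.ndarray | None = None
    n_reps: int = 0
    n_points: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.radii = np.asarray(self.radii, dtype=float)
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be strictly increasing")
        if self.envelope_lo is not None and self.envelope_hi is not None:
            if np.any(np.asarray(self.envelope_lo) > np.asarray(self.envelope_hi) + 1e-12):
                raise ValueError("envelope_lo must be <= envelope_hi")

    def to_dict(self) -> dict:
        d = {"radii_nm": self.radii.tolist(),
             "observed": np.asarray(self.observed).tolist(),
             "n_reps": self.n_reps, "n_points": self.n_points}
        if self.envelope_lo is not None:
            d["envelope_lo"] = np.asarray(self.envelope_lo).tolist()
            d["envelope_hi"] = np.asarray(self.envelope_hi).tolist()
        d.update({k: v for k, v in self.meta.items()
                  if isinstance(v, (int, float, str))})
        return d


@dataclass
class ConcentrationResult:
    count: int
    per_um3: float     # particles per µm^3 of lumen volume
    per_100nm: float   # particles per 100 nm of MT length


def concentration(particles: ParticleSet, domain: LumenDomain) -> ConcentrationResult:
    """Lumenal particle concentration of one MT (volumetric and linear)."""
    if domain.length <= 0:
        raise ValueError("zero-length domain")
    n = len(particles.for_mt(domain.mt_id)) if len(particles) else 0
    return ConcentrationResult(
        count=n,
        per_um3=n / domain.tube_volume() * 1e9,
        per_100nm=n / domain.length * 100.0,
    )


@dataclass
class NNResult:
    distances: np.ndarray       # nm, one per particle included
    bin_edges: np.ndarray
    counts: np.ndarray
    mode_bin_center: float      # nm (tie -> smallest bin)
    n_excluded_mts: int = 0
    envelope_lo: np.ndarray | None = None
    envelope_hi: np.ndarray | None = None


def nn_distances(particles: ParticleSet, per_mt: bool = True,
                 class_filter: str | None = None,
                 bin_width: float = NN_BIN_WIDTH_NM,
                 max_distance: float | None = None) -> NNResult:
    """Nearest-neighbour distances, pooled across MTs.

    With ``per_mt`` (the default) each particle's nearest neighbour is sought
    within the same MT only; MTs with fewer than 2 particles are excluded and
    counted.  ``class_filter`` restricts the analysis to one class label.
    """
    ps = particles.filter_class(class_filter) if class_filter is not None else particles
    groups = ([ps.for_mt(m) for m in np.unique(ps.mt_ids())] if per_mt and len(ps)
              else ([ps] if len(ps) else []))
    dists = []
    n_excluded = 0
    for g in groups:
        if len(g) < 2:
            n_excluded += 1
            continue
        pos = g.positions()
        d, _ = cKDTree(pos).query(pos, k=2)
        dists.append(d[:, 1])
    dists = np.concatenate(dists) if dists else np.empty(0)
    top = max_distance if max_distance is not None else (dists.max() + bin_width if dists.size else bin_width)
    edges = np.arange(0.0, top + bin_width, bin_width)
    counts, edges = np.histogram(dists, bins=edges)
    mode_i = int(np.argmax(counts)) if counts.size else 0
    mode_center = float(0.5 * (edges[mode_i] + edges[mode_i + 1]))
    return NNResult(distances=dists, bin_edges=edges, counts=counts,
                    mode_bin_center=mode_center, n_excluded_mts=n_excluded)


def _csr_replicate(domains: list[LumenDomain], counts: dict, rng_seed: int) -> ParticleSet:
    """CSR pattern with fixed per-domain counts (conditioning on n)."""
    sets = []
    for dom in domains:
        n = counts.get(dom.mt_id, 0)
        rng = np.random.default_rng(rng_seed * 100003 + dom.mt_id)
        pos, s = _sample_csr_tube(dom, n, rng)
        sets.append(ParticleSet.from_arrays(pos, mt_id=dom.mt_id, s_nm=s))
    return ParticleSet.concat(sets)


def csr_envelope(domains: list[LumenDomain] | LumenDomain, n_points,
                 statistic, n_reps: int = DEFAULT_N_REPS, seed: int = 0,
                 lo_pct: float = 5.0, hi_pct: float = 95.0):
    """Pointwise [5, 95]% envelope of a statistic under CSR.

    ``n_points`` is either a total (single domain) or a mapping
    ``mt_id -> count``; each replicate draws that many uniform points in each
    lumen domain and evaluates ``statistic(ParticleSet) -> vector``.
    Child replicate seeds are derived from ``seed`` by fixed increments, so
    envelopes are bit-reproducible.
    """
    if isinstance(domains, LumenDomain):
        domains = [domains]
    if n_reps < 20:
        raise ValueError("n_reps must be >= 20")
    counts = (dict(n_points) if isinstance(n_points, dict)
              else {domains[0].mt_id: int(n_points)})
    reps = []
    for rep in range(n_reps):
        pset = _csr_replicate(domains, counts, seed + rep + 1)
        reps.append(np.asarray(statistic(pset), dtype=float))
    reps = np.vstack(reps)
    return np.percentile(reps, lo_pct, axis=0), np.percentile(reps, hi_pct, axis=0)


# ---------------------------------------------------------------------------
# Ripley's K / L in tubes
# ---------------------------------------------------------------------------

def fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform directions on the unit sphere (Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1 + 5**0.5) * i
    z = 1 - 2 * i / n
    r = np.sqrt(np.maximum(0.0, 1 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _surface_fractions(domain: LumenDomain, centers: np.ndarray,
                       dists: np.ndarray, dirs: np.ndarray,
                       chunk_rows: int = 200) -> np.ndarray:
    """Fraction of each sphere's surface points inside the domain."""
    m = centers.shape[0]
    w = np.empty(m)
    ns = dirs.shape[0]
    for lo in range(0, m, chunk_rows):
        c = centers[lo:lo + chunk_rows]
        d = dists[lo:lo + chunk_rows]
        pts = (c[:, None, :] + d[:, None, None] * dirs[None, :, :]).reshape(-1, 3)
        inside = np.asarray(domain.contains(pts)).reshape(-1, ns)
        w[lo:lo + chunk_rows] = inside.mean(axis=1)
    return w


def _L_from_K(K: np.ndarray) -> np.ndarray:
    return np.cbrt(3.0 * np.maximum(K, 0.0) / (4.0 * np.pi))


def _univariate_K(by_mt: dict, domains_by_id: dict, radii: np.ndarray,
                  V: float, n_total: int, dirs: np.ndarray) -> np.ndarray:
    """Sum over same-MT ordered pairs of 1(d<=r)/w, scaled by V/(n(n-1))."""
    acc = np.zeros(radii.size)
    rmax = radii[-1]
    n_dropped = 0
    for mt_id, pos in by_mt.items():
        if pos.shape[0] < 2:
            continue
        dom = domains_by_id[mt_id]
        iu, ju = np.triu_indices(pos.shape[0], k=1)
        d = np.linalg.norm(pos[iu] - pos[ju], axis=1)
        sel = d <= rmax
        iu, ju, d = iu[sel], ju[sel], d[sel]
        if d.size == 0:
            continue
        # ordered pairs: weight at i for (i,j) and at j for (j,i)
        centers = np.vstack([pos[iu], pos[ju]])
        dd = np.concatenate([d, d])
        w = _surface_fractions(dom, centers, dd, dirs)
        ok = w > 0
        n_dropped += int((~ok).sum())
        contrib = np.zeros_like(dd)
        contrib[ok] = 1.0 / w[ok]
        acc += np.sum((dd[:, None] <= radii[None, :]) * contrib[:, None], axis=0)
    if n_dropped:
        logger.info("ripley_L: dropped %d ordered pairs with zero surface fraction",
                    n_dropped)
    return V / (n_total * (n_total - 1)) * acc


def ripley_L(particles: ParticleSet, domains: list[LumenDomain] | LumenDomain,
             radii: np.ndarray = DEFAULT_RADII_NM,
             n_correction_samples: int = DEFAULT_CORRECTION_SAMPLES,
             n_reps: int = DEFAULT_N_REPS, seed: int = 0) -> StatCurve:
    """Univariate Ripley's L confined to lumen domains, with CSR envelope.

    Pairs are counted within a single MT; the normalising volume is the sum
    of the tube volumes.  Set ``n_reps=0`` to skip the envelope.
    """
    if isinstance(domains, LumenDomain):
        domains = [domains]
    radii = np.asarray(radii, dtype=float)
    domains_by_id = {d.mt_id: d for d in domains}
    n_total = len(particles)
    if n_total < 2:
        raise ValueError("need at least 2 particles")
    V = sum(d.tube_volume() for d in domains)
    dirs = fibonacci_sphere(n_correction_samples)
    by_mt = {m: particles.for_mt(m).positions() for m in np.unique(particles.mt_ids())}
    K_obs = _univariate_K(by_mt, domains_by_id, radii, V, n_total, dirs)
    L_obs = _L_from_K(K_obs)
    lo = hi = None
    if n_reps:
        counts = {m: p.shape[0] for m, p in by_mt.items()}

        def stat(pset: ParticleSet) -> np.ndarray:
            bym = {m: pset.for_mt(m).positions() for m in np.unique(pset.mt_ids())}
            return _L_from_K(_univariate_K(bym, domains_by_id, radii, V, n_total, dirs))

        lo, hi = csr_envelope(domains, counts, stat, n_reps=n_reps, seed=seed)
    return StatCurve(radii=radii, observed=L_obs, envelope_lo=lo, envelope_hi=hi,
                     n_reps=n_reps, n_points=n_total,
                     meta={"statistic": "ripley_L", "V_nm3": V})


def _clip_domain_around(dom: LumenDomain, s_anchor: float, reach: float) -> LumenDomain:
    """Sub-tube containing every centerline point within ``reach`` of the anchor.

    Containment of a point at distance <= rmax from the anchor depends only on
    the centerline within rmax + lumen_radius of the anchor, so clipping the
    polyline with margin ``reach >= rmax + 2 * radius`` is exact and makes the
    surface-fraction tables much cheaper for long filaments.
    """
    spacing = dom.centerline.spacing
    i0 = max(int(np.floor((s_anchor - reach) / spacing)), 0)
    i1 = min(int(np.ceil((s_anchor + reach) / spacing)) + 1,
             dom.centerline.n_points)
    if i1 - i0 >= dom.centerline.n_points:
        return dom
    from .filaments import FilamentTrace
    sub = FilamentTrace(mt_id=dom.mt_id,
                        points=dom.centerline.points[i0:i1],
                        resampled=True, spacing=spacing)
    return LumenDomain(centerline=sub, lumen_radius=dom.lumen_radius)


def _anchor_weight_tables(domains: list[LumenDomain], anchors_by_mt: dict,
                          rmax: float, dirs: np.ndarray,
                          n_grid: int = 48) -> tuple[np.ndarray, dict]:
    """Per-anchor isotropic-correction tables w(d) on a common distance grid.

    The bivariate correction depends only on the (fixed) anchor and the pair
    distance, so it is tabulated once and shared by the observed curve and
    every Monte-Carlo replicate.
    """
    dgrid = np.linspace(rmax / n_grid, rmax, n_grid)
    tables = {}
    for dom in domains:
        anchors = anchors_by_mt.get(dom.mt_id)
        if anchors is None or len(anchors) == 0:
            continue
        per = []
        for a in np.atleast_2d(anchors):
            _, s_a = dom.distance_and_arclength(a)
            sub = _clip_domain_around(dom, float(s_a[0]),
                                      rmax + 2 * dom.lumen_radius + 2.0)
            centers = np.tile(a, (dgrid.size, 1))
            per.append(_surface_fractions(sub, centers, dgrid, dirs))
        tables[dom.mt_id] = np.asarray(per)  # (n_anchors, n_grid)
    return dgrid, tables


def _bivariate_K(by_mt: dict, anchors_by_mt: dict, dgrid: np.ndarray,
                 tables: dict, radii: np.ndarray, V: float,
                 n1: int, n2: int) -> np.ndarray:
    acc = np.zeros(radii.size)
    rmax = radii[-1]
    for mt_id, anchors in anchors_by_mt.items():
        pos = by_mt.get(mt_id)
        if pos is None or pos.shape[0] == 0 or mt_id not in tables:
            continue
        tab = tables[mt_id]
        for ai, a in enumerate(np.atleast_2d(anchors)):
            d = np.linalg.norm(pos - a, axis=1)
            sel = d <= rmax
            d = d[sel]
            if d.size == 0:
                continue
            w = np.interp(d, dgrid, tab[ai])
            ok = w > 0
            contrib = np.zeros_like(d)
            contrib[ok] = 1.0 / w[ok]
            acc += np.sum((d[:, None] <= radii[None, :]) * contrib[:, None], axis=0)
    return V / (n1 * n2) * acc


def ripley_L_bivariate(particles: ParticleSet,
                       domains: list[LumenDomain] | LumenDomain,
                       radii: np.ndarray = DEFAULT_RADII_NM,
                       anchors_by_mt: dict | None = None,
                       n_correction_samples: int = DEFAULT_CORRECTION_SAMPLES,
                       n_reps: int = DEFAULT_N_REPS, seed: int = 0) -> StatCurve:
    """Bivariate (anchor-referenced) Ripley's L with CSR envelopes.

    Anchors default to each domain's annotated defects (lattice breaks and
    open ends).  ``K12(r) = V/(n1 n2) * sum_anchors sum_particles
    1(d <= r)/w`` with the same isotropic volume correction as the univariate
    statistic; the null keeps anchors fixed and redraws particles as CSR with
    the observed per-MT counts.
    """
    if isinstance(domains, LumenDomain):
        domains = [domains]
    radii = np.asarray(radii, dtype=float)
    if anchors_by_mt is None:
        anchors_by_mt = {d.mt_id: d.anchor_points() for d in domains
                         if len(d.anchor_points())}
    n1 = sum(np.atleast_2d(a).shape[0] for a in anchors_by_mt.values())
    n2 = len(particles)
    if n1 < 1 or n2 < 1:
        raise ValueError("need at least 1 anchor and 1 particle")
    V = sum(d.tube_volume() for d in domains)
    dirs = fibonacci_sphere(n_correction_samples)
    dgrid, tables = _anchor_weight_tables(domains, anchors_by_mt, radii[-1], dirs)
    by_mt = {m: particles.for_mt(m).positions() for m in np.unique(particles.mt_ids())}
    K_obs = _bivariate_K(by_mt, anchors_by_mt, dgrid, tables, radii, V, n1, n2)
    L_obs = _L_from_K(K_obs)
    lo = hi = None
    if n_reps:
        counts = {m: p.shape[0] for m, p in by_mt.items()}

        def stat(pset: ParticleSet) -> np.ndarray:
            bym = {m: pset.for_mt(m).positions() for m in np.unique(pset.mt_ids())}
            return _L_from_K(_bivariate_K(bym, anchors_by_mt, dgrid, tables,
                                          radii, V, n1, n2))

        lo, hi = csr_envelope(domains, counts, stat, n_reps=n_reps, seed=seed)
    return StatCurve(radii=radii, observed=L_obs, envelope_lo=lo, envelope_hi=hi,
                     n_reps=n_reps, n_points=n2,
                     meta={"statistic": "ripley_L_bivariate", "n_anchors": n1})


def domain_size(curve: StatCurve) -> float:
    """Cluster domain size from an enveloped L curve (nm).

    The largest radius up to which the observed statistic exceeds the upper
    envelope contiguously from the smallest evaluated radius; 0 when the
    observed curve is not above the envelope at the first radius.
    """
    if curve.envelope_hi is None:
        raise ValueError("curve has no envelope")
    above = np.asarray(curve.observed) > np.asarray(curve.envelope_hi)
    if not above[0]:
        return 0.0
    i = np.argmin(above) if not above.all() else above.size
    return float(curve.radii[i - 1])


@dataclass
class GroupComparison:
    test: str
    statistic: float
    pvalue: float
    percent_change: float  # (median_a - median_b) / median_a * 100


def compare_groups(values_a, values_b, test: str = "mann_whitney") -> GroupComparison:
    """Two-sided group comparison with percent change of medians.

    Mann-Whitney U uses the exact null distribution for pooled n <= 12
    without ties, otherwise the normal approximation with tie correction;
    the t test is Welch's (unequal variances).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if test == "mann_whitney":
        pooled = np.concatenate([a, b])
        exact = a.size + b.size <= 12 and np.unique(pooled).size == pooled.size
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="exact" if exact else "asymptotic")
    elif test == "t_test":
        res = stats.ttest_ind(a, b, equal_var=False)
    else:
        raise ValueError(f"unknown test {test!r}")
    med_a = float(np.median(a))
    pct = (med_a - float(np.median(b))) / med_a * 100.0 if med_a != 0 else np.nan
    return GroupComparison(test=test, statistic=float(res.statistic),
                           pvalue=float(res.pvalue), percent_change=pct)
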