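"""Static and dynamic observables.

Static: polar order Psi, DBSCAN cluster identification on minimum-image
distances, periodic centers of mass, cluster size S_c and system size S,
the gyration-tensor asymmetry A, and the radial orientation order used to
recognize asters.

Dynamic: mean squared displacement and orientation correlation function with
time-origin averaging, their closed-form free-ABP baselines, and neighbor /
leadership turnover inside a cluster.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import DBSCAN

from .params import SimParams
from .state import Trajectory

__all__ = [
    "CurveWithError",
    "ClusterLabeling",
    "polar_order",
    "periodic_com",
    "min_image_displacement",
    "find_clusters",
    "cluster_size",
    "system_size",
    "radial_order",
    "asymmetry",
    "msd",
    "ocf",
    "abp_msd",
    "abp_ocf",
    "abp_baselines",
    "neighbor_turnover",
    "NeighborTurnover",
]


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def min_image_displacement(d: np.ndarray, L: float) -> np.ndarray:
    """Fold displacement components into [-L/2, L/2)."""
    return d - L * np.round(np.asarray(d, dtype=np.float64) / L)


def periodic_com(points: np.ndarray, L: float) -> np.ndarray:
    """Center of mass of points in a periodic box via the circle embedding.

    Each coordinate is mapped to an angle on the unit circle, the embedded
    points are averaged, and the mean angle is mapped back to [0, L).  This
    is exact for compact clusters straddling the boundary.  A mass-balanced
    antipodal configuration leaves the embedded mean at the origin; the
    arithmetic mean is returned with a warning in that degenerate case.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    theta = points * (2.0 * math.pi / L)
    z = np.exp(1j * theta).mean(axis=0)
    com = np.empty(points.shape[1])
    for k in range(points.shape[1]):
        if abs(z[k]) < 1e-9:
            warnings.warn(
                "degenerate periodic center of mass; falling back to the "
                "arithmetic mean", stacklevel=2)
            com[k] = points[:, k].mean() % L
            continue
        ref = np.angle(z[k]) * L / (2.0 * math.pi)
        # refine: arithmetic mean of minimum-image displacements about the
        # circular estimate — exact (equal to the plain mean) for clusters
        # narrower than half the box, wherever they sit
        d = points[:, k] - ref
        d -= L * np.round(d / L)
        com[k] = (ref + d.mean()) % L
    return com


def _min_image_distance_matrix(pos: np.ndarray, L: float) -> np.ndarray:
    d = pos[:, None, :] - pos[None, :, :]
    d -= L * np.round(d / L)
    return np.sqrt((d**2).sum(axis=-1))


# ---------------------------------------------------------------------------
# static observables
# ---------------------------------------------------------------------------

def polar_order(phi: np.ndarray) -> float:
    """Norm of the mean orientation vector, |sum_i u_i| / N, in [0, 1]."""
    phi = np.asarray(phi)
    if phi.size == 0:
        raise ValueError("empty orientation array")
    return float(np.hypot(np.cos(phi).sum(), np.sin(phi).sum())) / phi.size


@dataclass
class ClusterLabeling:
    """Per-particle cluster ids and per-cluster periodic centers of mass."""

    t: float
    labels: np.ndarray  # (N,) dense ids 0..n_clusters-1
    coms: np.ndarray  # (n_clusters, 2) in [0, L)^2
    n_clusters: int

    def members(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.labels == c)


def find_clusters(pos: np.ndarray, L: float, eps: float = 1.5,
                  min_samples: int = 1, t: float = 0.0) -> ClusterLabeling:
    """DBSCAN on the minimum-image distance matrix.

    With ``min_samples=1`` every particle is a core point, so the labeling
    coincides with connected components of the graph whose edges join pairs
    closer than ``eps``; no noise label occurs.
    """
    if eps > L / 2:
        raise ValueError(f"eps {eps} exceeds L/2 = {L / 2}")
    pos = np.asarray(pos, dtype=np.float64) % L
    dist = _min_image_distance_matrix(pos, L)
    labels = DBSCAN(eps=eps, min_samples=min_samples,
                    metric="precomputed").fit_predict(dist)
    # relabel densely in order of first appearance
    _, labels = np.unique(labels, return_inverse=True)
    n_clusters = int(labels.max()) + 1
    coms = np.vstack([periodic_com(pos[labels == c], L)
                      for c in range(n_clusters)])
    return ClusterLabeling(t, labels, coms, n_clusters)


def _cluster_extent(points: np.ndarray, com: np.ndarray, L: float) -> float:
    d = min_image_displacement(points - com, L)
    return float(np.hypot(d[:, 0], d[:, 1]).max())


def cluster_size(labeling: ClusterLabeling, pos: np.ndarray, L: float) -> float:
    """Mean over clusters of the farthest member's distance to the cluster's
    periodic center of mass (the average cluster size S_c)."""
    pos = np.asarray(pos, dtype=np.float64) % L
    extents = [_cluster_extent(pos[labeling.labels == c], labeling.coms[c], L)
               for c in range(labeling.n_clusters)]
    return float(np.mean(extents))


def system_size(pos: np.ndarray, L: float) -> float:
    """Cluster-size-style extent of all N particles about the global periodic
    center of mass (detects the box-spanning line state)."""
    pos = np.asarray(pos, dtype=np.float64) % L
    com = periodic_com(pos, L)
    return _cluster_extent(pos, com, L)


def radial_order(pos: np.ndarray, phi: np.ndarray, labeling: ClusterLabeling,
                 L: float) -> float:
    """Mean of u_i . (r_i - r_CoM)^hat over particles (minimum image).

    Outward orientations give +1; an aster, with every particle pointing at
    its cluster's center, gives values near -1.  Particles sitting exactly
    on their center of mass are excluded.
    """
    pos = np.asarray(pos, dtype=np.float64) % L
    d = min_image_displacement(pos - labeling.coms[labeling.labels], L)
    r = np.hypot(d[:, 0], d[:, 1])
    ok = r > 1e-9
    if not np.any(ok):
        return float("nan")
    ux, uy = np.cos(phi[ok]), np.sin(phi[ok])
    return float(np.mean((ux * d[ok, 0] + uy * d[ok, 1]) / r[ok]))


def asymmetry(points: np.ndarray, L: float) -> float:
    """Gyration-tensor asymmetry A = |I1 - I2| / (I1 + I2) of one cluster.

    I1 >= I2 are the eigenvalues of the 2x2 second-moment tensor of
    minimum-image displacements about the periodic center of mass.  A = 0
    for an isotropic cluster, A = 1 for a collinear one.  Coincident points
    (zero tensor) return NaN, which callers exclude from averages.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if points.shape[0] < 2:
        raise ValueError("asymmetry needs at least two particles")
    com = periodic_com(points % L, L)
    d = min_image_displacement(points % L - com, L)
    gyr = d.T @ d / d.shape[0]
    i2, i1 = np.linalg.eigvalsh(gyr)
    if i1 + i2 <= 0.0:
        return float("nan")
    return float(abs(i1 - i2) / (i1 + i2))


# ---------------------------------------------------------------------------
# dynamic observables
# ---------------------------------------------------------------------------

@dataclass
class CurveWithError:
    """Lag-time curve with per-lag standard errors (over particles)."""

    lags: np.ndarray
    mean: np.ndarray
    stderr: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=np.float64)
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.stderr = np.asarray(self.stderr, dtype=np.float64)
        self.n = np.asarray(self.n)


def _default_lag_frames(n_frames: int, max_lags: int = 80) -> np.ndarray:
    if n_frames <= max_lags:
        return np.arange(n_frames)
    lf = np.unique(np.round(np.logspace(0, math.log10(n_frames - 1),
                                        max_lags - 1)).astype(int))
    return np.concatenate(([0], lf))


def _lag_curve(values_fn, n_frames: int, times: np.ndarray,
               lag_frames: np.ndarray, zero_value: float) -> CurveWithError:
    """Average values_fn(lag) over origins and particles; SE over particles."""
    dtimes = times - times[0]
    lags, means, errs, counts = [], [], [], []
    for lf in lag_frames:
        if lf >= n_frames:
            raise ValueError(f"lag of {lf} frames exceeds trajectory length")
        if lf == 0:
            per_particle = None
        else:
            per_particle = values_fn(lf)  # (N,) origin-averaged
        lags.append(dtimes[lf])
        if per_particle is None:
            means.append(zero_value)
            errs.append(0.0)
            counts.append(n_frames)
        else:
            n = per_particle.size
            means.append(per_particle.mean())
            errs.append(per_particle.std(ddof=1) / math.sqrt(n) if n > 1 else 0.0)
            counts.append(n_frames - lf)
    return CurveWithError(np.array(lags), np.array(means), np.array(errs),
                          np.array(counts))


def msd(traj: Trajectory, lag_frames: np.ndarray | None = None) -> CurveWithError:
    """Mean squared displacement from unwrapped coordinates.

    Averages over all time origins (frame spacing) and all particles; the
    quoted error is the standard error over particles of their
    origin-averaged displacements.  Lag 0 is pinned to 0.
    """
    r = traj.unwrapped
    f = traj.n_frames
    if lag_frames is None:
        lag_frames = _default_lag_frames(f)

    def per_particle(lf: int) -> np.ndarray:
        d = r[lf:] - r[:f - lf]
        return (d**2).sum(axis=-1).mean(axis=0)

    return _lag_curve(per_particle, f, traj.times, np.asarray(lag_frames), 0.0)


def ocf(traj: Trajectory, lag_frames: np.ndarray | None = None) -> CurveWithError:
    """Orientation correlation function <u(t+t0) . u(t0)>; OCF(0) = 1."""
    u = traj.u
    f = traj.n_frames
    if lag_frames is None:
        lag_frames = _default_lag_frames(f)

    def per_particle(lf: int) -> np.ndarray:
        c = (u[lf:] * u[:f - lf]).sum(axis=-1)
        return c.mean(axis=0)

    return _lag_curve(per_particle, f, traj.times, np.asarray(lag_frames), 1.0)


def abp_msd(params: SimParams, t: np.ndarray) -> np.ndarray:
    """Closed-form MSD of an isolated active Brownian particle:
    4 D t + (2 v0^2 / D_R^2)(D_R t - 1 + exp(-D_R t))."""
    t = np.asarray(t, dtype=np.float64)
    return (4.0 * params.D * t
            + 2.0 * params.v0**2 / params.D_R**2
            * (params.D_R * t - 1.0 + np.exp(-params.D_R * t)))


def abp_ocf(params: SimParams, t: np.ndarray) -> np.ndarray:
    """Closed-form OCF of an isolated ABP, exp(-D_R t)."""
    return np.exp(-params.D_R * np.asarray(t, dtype=np.float64))


def abp_baselines(params: SimParams, t: np.ndarray) -> tuple[CurveWithError, CurveWithError]:
    """Analytic free-ABP MSD and OCF packaged as zero-error curves."""
    t = np.asarray(t, dtype=np.float64)
    z = np.zeros_like(t)
    return (CurveWithError(t, abp_msd(params, t), z, np.ones_like(t)),
            CurveWithError(t, abp_ocf(params, t), z, np.ones_like(t)))


# ---------------------------------------------------------------------------
# neighbor / leadership tracking
# ---------------------------------------------------------------------------

@dataclass
class NeighborTurnover:
    """Neighborhood change of one particle between two frames."""

    fraction: float  # fraction of t0-neighbors lost by t1
    n_neighbors_t0: int
    rank_t0: int  # 0 = frontmost along the cluster's mean orientation
    rank_t1: int
    cluster_size_t0: int
    cluster_size_t1: int


def _front_rank(pos: np.ndarray, phi: np.ndarray, i: int, L: float,
                eps: float = 1.5) -> tuple[int, int]:
    lab = find_clusters(pos, L, eps=eps)
    c = lab.labels[i]
    members = lab.members(c)
    d = min_image_displacement(pos[members] % L - lab.coms[c], L)
    mean_u = np.array([np.cos(phi[members]).mean(), np.sin(phi[members]).mean()])
    norm = np.hypot(*mean_u)
    if norm < 1e-12:
        return 0, len(members)
    proj = d @ (mean_u / norm)
    order = np.argsort(-proj, kind="stable")  # descending: front first
    rank = int(np.flatnonzero(members[order] == i)[0])
    return rank, len(members)


def neighbor_turnover(traj: Trajectory, i: int, t0: float, t1: float,
                      R: float | None = None) -> NeighborTurnover:
    """Fraction of particles within R of particle i at time t0 that are no
    longer within R at time t1, plus the particle's front/back rank along
    its cluster's mean orientation at both times."""
    if t1 < t0:
        raise ValueError("t1 must be >= t0")
    L = traj.params.L
    if R is None:
        R = traj.params.R_sigma
    k0 = int(np.argmin(np.abs(traj.times - t0)))
    k1 = int(np.argmin(np.abs(traj.times - t1)))

    def neighbors(k: int) -> set[int]:
        d = min_image_displacement(traj.pos[k] - traj.pos[k][i], L)
        r = np.hypot(d[:, 0], d[:, 1])
        idx = np.flatnonzero(r < R)
        return set(int(x) for x in idx if x != i)

    n0 = neighbors(k0)
    n1 = neighbors(k1)
    frac = (len(n0 - n1) / len(n0)) if n0 else 0.0
    rank0, size0 = _front_rank(traj.pos[k0], traj.phi[k0], i, L)
    rank1, size1 = _front_rank(traj.pos[k1], traj.phi[k1], i, L)
    return NeighborTurnover(frac, len(n0), rank0, rank1, size0, size1)
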