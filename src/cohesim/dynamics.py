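"""Equations of motion: WCA repulsion, alignment and cohesive torques,
Euler--Maruyama integration under periodic boundaries.

The model couples overdamped active Brownian particles through three pair
interactions sharing one geometry:

* a purely repulsive WCA force (steric core of diameter sigma),
* a reciprocal alignment torque ``T_A * sin(phi_j - phi_i)`` inside radius R,
* a non-reciprocal cohesive torque ``-T_C * sin(theta)`` that turns particle
  i toward neighbor j, where theta is the signed angle from u_i to the unit
  separation vector r_ij/|r_ij| with r_ij = r_i - r_j.

The alignment torque obeys Newton's third law pairwise; the cohesive torque
does not, which is the model's source of non-reciprocity.  The Heaviside
support is strict (interaction iff distance < R).

Hot loops are numba-compiled; the integrator uses an internal linked-cell
neighbor search that falls back to an all-pairs scan when the box is too
small for three cells per side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

from .params import SimParams, R_C
from .state import ParticleState, Trajectory

__all__ = [
    "OverlapError",
    "InstabilityError",
    "wca_force",
    "signed_angle",
    "alignment_torque",
    "cohesion_torque",
    "total_torque",
    "PairTable",
    "build_pairs",
    "step",
    "run_simulation",
]

TWO_PI = 2.0 * math.pi


class OverlapError(RuntimeError):
    """Two particles came closer than the minimum allowed separation.

    This indicates the time step is too large for the steric repulsion;
    reduce ``dt``.
    """


class InstabilityError(RuntimeError):
    """Non-finite positions or orientations appeared during integration."""


# ---------------------------------------------------------------------------
# elementary interactions (reference implementations, also used by the
# stability-analysis module)
# ---------------------------------------------------------------------------

def wca_force(r_vec, eps: float, sigma: float = 1.0, min_separation: float = 0.5):
    """WCA force on the particle at +r_vec exerted by a particle at the origin.

    The potential is the Lennard-Jones form truncated and shifted at its
    minimum r_c = 2^(1/6) sigma, so the force is purely repulsive and
    vanishes for |r_vec| > r_c.
    """
    r_vec = np.asarray(r_vec, dtype=np.float64)
    r = float(np.hypot(r_vec[0], r_vec[1]))
    if r == 0.0:
        raise ValueError("zero separation vector")
    if r < min_separation * sigma:
        raise OverlapError(
            f"pair separation {r:.4g} below {min_separation} sigma; reduce dt"
        )
    if r > R_C * sigma:
        return np.zeros(2)
    sr6 = (sigma / r) ** 6
    # -dU/dr = 24 eps (2 (sigma/r)^12 - (sigma/r)^6) / r, along +r_hat
    fmag = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r
    return fmag * r_vec / r


def signed_angle(u, v) -> float:
    """Counterclockwise angle in (-pi, pi] that rotates unit vector u onto v."""
    ux, uy = float(u[0]), float(u[1])
    vx, vy = float(v[0]), float(v[1])
    if (ux == 0.0 and uy == 0.0) or (vx == 0.0 and vy == 0.0):
        raise ValueError("zero vector passed to signed_angle")
    ang = math.atan2(ux * vy - uy * vx, ux * vx + uy * vy)
    if ang <= -math.pi:  # atan2 returns [-pi, pi]; fold -pi onto +pi
        ang = math.pi
    return ang


def alignment_torque(phi_i: float, phi_j: float, dist: float, T_A: float, R: float) -> float:
    """Reciprocal alignment torque on particle i from j (zero for dist >= R)."""
    if dist >= R:
        return 0.0
    return T_A * math.sin(phi_j - phi_i)


def cohesion_torque(u_i, r_ij, T_C: float, R: float) -> float:
    """Non-reciprocal cohesive torque on particle i, turning it toward j.

    ``r_ij = r_i - r_j`` (minimum image).  The torque is
    ``-T_C * sin(theta)`` with theta the signed angle from u_i to r_ij/|r_ij|;
    its fixed point u_i = -r_hat_ij points straight at the neighbor.
    """
    r_ij = np.asarray(r_ij, dtype=np.float64)
    d = float(np.hypot(r_ij[0], r_ij[1]))
    if d == 0.0:
        raise ValueError("coincident particles in cohesion_torque")
    if d >= R:
        return 0.0
    return -T_C * math.sin(signed_angle(u_i, r_ij / d))


# ---------------------------------------------------------------------------
# pair tables
# ---------------------------------------------------------------------------

@dataclass
class PairTable:
    """Ordered pairs (i, j) with minimum-image separation vectors r_i - r_j.

    Contains (i, j) iff it contains (j, i) with negated separation; only
    pairs with distance strictly below the build cutoff are stored.
    """

    i: np.ndarray  # (P,) int
    j: np.ndarray  # (P,) int
    rij: np.ndarray  # (P, 2) minimum-image r_i - r_j
    dist: np.ndarray  # (P,)
    cutoff: float

    def __len__(self) -> int:
        return len(self.i)


def build_pairs(state: ParticleState, cutoff: float, L: float) -> PairTable:
    """All ordered pairs within ``cutoff`` under the minimum-image convention.

    Uses a periodic k-d tree for the candidate search; the strict-inequality
    convention (distance exactly equal to the cutoff excluded) is enforced
    afterwards.
    """
    if cutoff > L / 2:
        raise ValueError(
            f"cutoff {cutoff} exceeds L/2 = {L / 2}; minimum image is ambiguous"
        )
    pos = np.mod(state.pos, L)
    tree = cKDTree(pos, boxsize=L)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs):
        d = pos[pairs[:, 0]] - pos[pairs[:, 1]]
        d -= L * np.round(d / L)
        r = np.hypot(d[:, 0], d[:, 1])
        keep = r < cutoff
        pairs, d, r = pairs[keep], d[keep], r[keep]
    else:
        d = np.zeros((0, 2))
        r = np.zeros(0)
    i = np.concatenate([pairs[:, 0], pairs[:, 1]]) if len(pairs) else np.zeros(0, int)
    j = np.concatenate([pairs[:, 1], pairs[:, 0]]) if len(pairs) else np.zeros(0, int)
    rij = np.concatenate([d, -d]) if len(pairs) else np.zeros((0, 2))
    dist = np.concatenate([r, r]) if len(pairs) else np.zeros(0)
    order = np.lexsort((j, i))
    return PairTable(i[order], j[order], rij[order], dist[order], cutoff)


def total_torque(state: ParticleState, pairs: PairTable, params: SimParams) -> np.ndarray:
    """Per-particle total interaction torque, summed over neighbors within R.

    T_i = sum_j T0 * Theta(R - |r_ij|) * [sin(phi_j - phi_i)
          - (1/ratio) * sin(theta_{u_i, r_hat_ij})].
    """
    torques = np.zeros(state.N)
    if len(pairs) == 0 or params.T0 == 0.0:
        return torques
    inside = pairs.dist < params.R_sigma
    i = pairs.i[inside]
    j = pairs.j[inside]
    rij = pairs.rij[inside]
    d = pairs.dist[inside]
    if np.any(d == 0.0):
        raise ValueError("coincident particles")
    phi = state.phi
    align = np.sin(phi[j] - phi[i])
    ux, uy = np.cos(phi[i]), np.sin(phi[i])
    rhx, rhy = rij[:, 0] / d, rij[:, 1] / d
    sin_theta = ux * rhy - uy * rhx  # cross(u_i, r_hat_ij)
    contrib = params.T0 * (align - sin_theta / params.ratio)
    np.add.at(torques, i, contrib)
    return torques


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _min_image(d, L):
    return d - L * math.floor(d / L + 0.5)


@njit(cache=True)
def _pair_kernel(xi, yi, phii, xj, yj, phij, L, eps, rc2, T0, inv_ratio, R2, min_sep2):
    """Force and torque on particle i from particle j.

    Returns (fx, fy, torque, status); status 1 flags an overlap.
    """
    dx = _min_image(xi - xj, L)
    dy = _min_image(yi - yj, L)
    r2 = dx * dx + dy * dy
    fx = 0.0
    fy = 0.0
    tq = 0.0
    status = 0
    if r2 < min_sep2:
        status = 1
    if r2 < rc2 and r2 > 0.0:
        inv_r2 = 1.0 / r2
        sr6 = inv_r2 * inv_r2 * inv_r2
        fmag_over_r = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) * inv_r2
        fx = fmag_over_r * dx
        fy = fmag_over_r * dy
    if r2 < R2 and r2 > 0.0:
        inv_r = 1.0 / math.sqrt(r2)
        ux = math.cos(phii)
        uy = math.sin(phii)
        sin_theta = (ux * dy - uy * dx) * inv_r
        tq = T0 * (math.sin(phij - phii) - inv_ratio * sin_theta)
    return fx, fy, tq, status


@njit(cache=True)
def _accumulate_brute(pos, phi, L, eps, rc2, T0, inv_ratio, R2, min_sep2, fx, fy, tq):
    n = pos.shape[0]
    status = 0
    for i in range(n):
        fx[i] = 0.0
        fy[i] = 0.0
        tq[i] = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            fxi, fyi, tqi, st = _pair_kernel(
                pos[i, 0], pos[i, 1], phi[i], pos[j, 0], pos[j, 1], phi[j],
                L, eps, rc2, T0, inv_ratio, R2, min_sep2)
            fx[i] += fxi
            fy[i] += fyi
            tq[i] += tqi
            if st != 0:
                status = 1
    return status


@njit(cache=True)
def _accumulate_cells(pos, phi, L, eps, rc2, T0, inv_ratio, R2, min_sep2,
                      fx, fy, tq, ncell, cell_of, count, start, order):
    """Linked-cell accumulation; cell side >= cutoff so 3x3 stencils suffice."""
    n = pos.shape[0]
    nc2 = ncell * ncell
    cell_size = L / ncell
    for i in range(n):
        cx = int(pos[i, 0] / cell_size)
        cy = int(pos[i, 1] / cell_size)
        if cx >= ncell:
            cx = ncell - 1
        if cy >= ncell:
            cy = ncell - 1
        cell_of[i] = cy * ncell + cx
    for c in range(nc2):
        count[c] = 0
    for i in range(n):
        count[cell_of[i]] += 1
    acc = 0
    for c in range(nc2):
        start[c] = acc
        acc += count[c]
    for c in range(nc2):
        count[c] = 0
    for i in range(n):
        c = cell_of[i]
        order[start[c] + count[c]] = i
        count[c] += 1

    status = 0
    for i in range(n):
        fx[i] = 0.0
        fy[i] = 0.0
        tq[i] = 0.0
        ci = cell_of[i]
        cx = ci % ncell
        cy = ci // ncell
        for ox in range(-1, 2):
            for oy in range(-1, 2):
                nx = (cx + ox) % ncell
                ny = (cy + oy) % ncell
                c = ny * ncell + nx
                for k in range(start[c], start[c] + count[c]):
                    j = order[k]
                    if j == i:
                        continue
                    fxi, fyi, tqi, st = _pair_kernel(
                        pos[i, 0], pos[i, 1], phi[i],
                        pos[j, 0], pos[j, 1], phi[j],
                        L, eps, rc2, T0, inv_ratio, R2, min_sep2)
                    fx[i] += fxi
                    fy[i] += fyi
                    tq[i] += tqi
                    if st != 0:
                        status = 1
    return status


@njit(cache=True)
def _wrap_angle(a):
    w = a - TWO_PI * math.floor((a + math.pi) / TWO_PI)
    if w <= -math.pi:  # keep the (-pi, pi] convention at the boundary
        w += TWO_PI
    return w


@njit(cache=True)
def _integrate_chunk(pos, phi, image, L, nsteps, dt, v0, mu, mu_R,
                     amp_t, amp_r, eps, rc2, T0, inv_ratio, R2, min_sep2,
                     noise_xy, noise_phi, ncell,
                     fx, fy, tq, cell_of, count, start, order):
    """Advance nsteps Euler--Maruyama steps in place; returns overlap status."""
    n = pos.shape[0]
    use_cells = ncell >= 3
    for s in range(nsteps):
        if use_cells:
            st = _accumulate_cells(pos, phi, L, eps, rc2, T0, inv_ratio, R2,
                                   min_sep2, fx, fy, tq, ncell, cell_of,
                                   count, start, order)
        else:
            st = _accumulate_brute(pos, phi, L, eps, rc2, T0, inv_ratio, R2,
                                   min_sep2, fx, fy, tq)
        if st != 0:
            return 1
        for i in range(n):
            px = pos[i, 0] + (v0 * math.cos(phi[i]) + mu * fx[i]) * dt \
                + amp_t * noise_xy[s, i, 0]
            py = pos[i, 1] + (v0 * math.sin(phi[i]) + mu * fy[i]) * dt \
                + amp_t * noise_xy[s, i, 1]
            sx = math.floor(px / L)
            sy = math.floor(py / L)
            pos[i, 0] = px - sx * L
            pos[i, 1] = py - sy * L
            image[i, 0] += int(sx)
            image[i, 1] += int(sy)
            phi[i] = _wrap_angle(phi[i] + mu_R * tq[i] * dt + amp_r * noise_phi[s, i])
    return 0


# ---------------------------------------------------------------------------
# integrator driver
# ---------------------------------------------------------------------------

def _kernel_workspace(params: SimParams):
    """Preallocated scratch arrays and the cell-grid size for the kernel."""
    n = params.N
    cutoff = max(params.R_sigma, params.r_c)
    ncell = int(params.L / cutoff)
    # cells only need side >= cutoff; cap the grid so clearing it stays O(N)
    ncell = min(ncell, max(3, 2 * int(math.sqrt(n))))
    if ncell < 3:
        ncell = 0  # brute-force path
    nc2 = max(ncell * ncell, 1)
    return dict(
        ncell=ncell,
        fx=np.zeros(n), fy=np.zeros(n), tq=np.zeros(n),
        cell_of=np.zeros(n, np.int64), count=np.zeros(nc2, np.int64),
        start=np.zeros(nc2, np.int64), order=np.zeros(n, np.int64),
    )


def step(state: ParticleState, params: SimParams, rng: np.random.Generator,
         noise: bool = True) -> ParticleState:
    """One Euler--Maruyama step; returns a new ParticleState.

    With ``noise=False`` the deterministic drift (self-propulsion, steric
    forces, interaction torques) acts alone.
    """
    new = state.copy()
    n = state.N
    if noise:
        noise_xy = rng.standard_normal((1, n, 2))
        noise_phi = rng.standard_normal((1, n))
    else:
        noise_xy = np.zeros((1, n, 2))
        noise_phi = np.zeros((1, n))
    ws = _kernel_workspace(params)
    st = _integrate_chunk(
        new.pos, new.phi, new.image, params.L, 1, params.dt, params.v0,
        params.mu, params.mu_R,
        math.sqrt(2.0 * params.D * params.dt),
        math.sqrt(2.0 * params.D_R * params.dt),
        params.eps, params.r_c**2, params.T0, 1.0 / params.ratio,
        params.R_sigma**2, (params.min_separation * params.sigma) ** 2,
        noise_xy, noise_phi, ws["ncell"],
        ws["fx"], ws["fy"], ws["tq"], ws["cell_of"], ws["count"],
        ws["start"], ws["order"])
    if st != 0:
        raise OverlapError("pair separation below minimum; reduce dt")
    if not (np.all(np.isfinite(new.pos)) and np.all(np.isfinite(new.phi))):
        raise InstabilityError("non-finite state after step; reduce dt")
    new.t = state.t + params.dt
    return new


def run_simulation(params: SimParams, init, progress: bool = False,
                   chunk_steps: int = 20000) -> Trajectory:
    """Equilibrate for t_equil, then collect frames for t_collect.

    ``init`` is either an InitialCondition (see :mod:`cohesim.initializers`)
    or a ready ParticleState.  The master seed is split into independent
    initialization and thermal-noise streams; equilibration and collection
    share the noise stream, so a run is bit-reproducible from (params, init).
    Frames are sampled every ``sample_interval`` from the end of
    equilibration (time origin 0), unwrap bookkeeping included.
    """
    from .initializers import build_initial_state, InitialCondition

    params.validate_timestep()
    ss = np.random.SeedSequence(params.seed)
    init_ss, noise_ss = ss.spawn(2)
    if isinstance(init, ParticleState):
        state = init.copy()
    elif isinstance(init, InitialCondition):
        state = build_initial_state(params, init, np.random.default_rng(init_ss))
    else:
        raise TypeError(f"unsupported initial condition {init!r}")
    noise_rng = np.random.default_rng(noise_ss)

    n = params.N
    dt = params.dt
    steps_sample = max(1, int(round(params.sample_interval / dt)))
    n_equil = int(round(params.t_equil / dt))
    n_collect = int(round(params.t_collect / dt))
    n_frames = n_collect // steps_sample + 1

    ws = _kernel_workspace(params)
    amp_t = math.sqrt(2.0 * params.D * dt)
    amp_r = math.sqrt(2.0 * params.D_R * dt)
    args = (params.L, dt, params.v0, params.mu, params.mu_R, amp_t, amp_r,
            params.eps, params.r_c**2, params.T0, 1.0 / params.ratio,
            params.R_sigma**2, (params.min_separation * params.sigma) ** 2)

    def advance(nsteps: int) -> None:
        done = 0
        while done < nsteps:
            m = min(chunk_steps, nsteps - done)
            nxy = noise_rng.standard_normal((m, n, 2))
            nph = noise_rng.standard_normal((m, n))
            st = _integrate_chunk(state.pos, state.phi, state.image, *args[:1],
                                  m, *args[1:], nxy, nph, ws["ncell"],
                                  ws["fx"], ws["fy"], ws["tq"], ws["cell_of"],
                                  ws["count"], ws["start"], ws["order"])
            if st != 0:
                raise OverlapError(
                    f"overlap at t≈{state.t:.3f} tau_R; reduce dt")
            done += m
            state.t += m * dt
        if not (np.all(np.isfinite(state.pos)) and np.all(np.isfinite(state.phi))):
            raise InstabilityError(
                f"non-finite state at t≈{state.t:.3f} tau_R; reduce dt")

    advance(n_equil)
    # reset unwrap bookkeeping and the time origin at the start of collection
    state.image[:] = 0
    state.t = 0.0

    times = np.empty(n_frames)
    pos = np.empty((n_frames, n, 2))
    images = np.empty((n_frames, n, 2), dtype=np.int64)
    phis = np.empty((n_frames, n))

    def record(k: int) -> None:
        times[k] = state.t
        pos[k] = state.pos
        images[k] = state.image
        phis[k] = state.phi
        if progress:
            psi = float(np.hypot(np.cos(state.phi).sum(),
                                 np.sin(state.phi).sum())) / n
            from .observables import find_clusters
            nc = find_clusters(state.pos, params.L).n_clusters
            print(f"t={state.t:9.2f} tau_R  Psi={psi:.3f}  clusters={nc}",
                  flush=True)

    record(0)
    for k in range(1, n_frames):
        advance(steps_sample)
        record(k)
    return Trajectory(times, pos, images, phis, params)
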