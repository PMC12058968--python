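"""Static and dynamic observables: polar order, periodic centers of mass,
clustering, sizes, asymmetry, MSD/OCF and their free-ABP baselines."""

import math

import numpy as np
import pytest

import cohesim as cs
from cohesim.observables import (
    abp_msd,
    abp_ocf,
    asymmetry,
    cluster_size,
    find_clusters,
    min_image_displacement,
    neighbor_turnover,
    periodic_com,
    polar_order,
    radial_order,
    system_size,
)
from cohesim import SimParams, Trajectory


def connected_components_oracle(pos, L, eps):
    """Union-find on the minimum-image proximity graph."""
    n = len(pos)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            d = pos[i] - pos[j]
            d -= L * np.round(d / L)
            if np.hypot(d[0], d[1]) < eps:
                parent[find(i)] = find(j)
    roots = [find(i) for i in range(n)]
    remap = {}
    return np.array([remap.setdefault(r, len(remap)) for r in roots])


def same_partition(a, b):
    return len(set(zip(a.tolist(), b.tolist()))) == len(set(a.tolist())) == len(set(b.tolist()))


class TestPolarOrder:
    def test_aligned_and_antiparallel(self):
        assert polar_order(np.full(10, 0.73)) == pytest.approx(1.0)
        assert polar_order(np.array([0.2, 0.2 + math.pi])) == pytest.approx(0.0, abs=1e-15)

    def test_random_orientations_scale(self):
        """For uniform random headings the residual order is the 2D
        random-walk result, mean ~ sqrt(pi)/2 * N^(-1/2)."""
        rng = np.random.default_rng(7)
        n = 10000
        vals = [polar_order(rng.uniform(-math.pi, math.pi, n)) for _ in range(60)]
        expected = math.sqrt(math.pi) / 2 / math.sqrt(n)
        assert np.mean(vals) == pytest.approx(expected, rel=0.15)


class TestPeriodicCom:
    def test_identity_and_wrap(self):
        L = 10.0
        p = np.array([[3.3, 7.7]] * 4)
        assert periodic_com(p, L) == pytest.approx([3.3, 7.7])
        two = np.array([[L - 1.0, 5.0], [1.0, 5.0]])
        com = periodic_com(two, L)
        assert min(com[0], L - com[0]) == pytest.approx(0.0, abs=1e-9)

    def test_compact_cluster_matches_arithmetic_mean(self, rng):
        L = 50.0
        pts = rng.uniform(20.0, 24.0, (40, 2))
        assert np.allclose(periodic_com(pts, L), pts.mean(axis=0), atol=1e-9)

    def test_degenerate_antipodal_warns(self):
        L = 10.0
        pts = np.array([[0.0, 1.0], [5.0, 1.0]])
        with pytest.warns(UserWarning, match="degenerate"):
            periodic_com(pts, L)


class TestFindClusters:
    def test_threshold_straddle(self):
        L = 30.0
        near = np.array([[5.0, 5.0], [6.4, 5.0]])
        far = np.array([[5.0, 5.0], [6.6, 5.0]])
        assert find_clusters(near, L).n_clusters == 1
        assert find_clusters(far, L).n_clusters == 2

    def test_chain_across_boundary(self):
        L = 12.0
        xs = np.arange(0, L, 1.0)  # ring of spacing 1 < eps crossing both edges
        pos = np.column_stack([xs, np.full_like(xs, 3.0)])
        lab = find_clusters(pos, L)
        assert lab.n_clusters == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.uniform(0, 40.0, (200, 2))
        lab = find_clusters(pos, 40.0, eps=1.5)
        oracle = connected_components_oracle(pos, 40.0, 1.5)
        assert same_partition(lab.labels, oracle)
        # every particle labeled, ids dense, no noise label
        assert lab.labels.min() == 0
        assert set(lab.labels) == set(range(lab.n_clusters))
        assert np.all((lab.coms >= 0) & (lab.coms < 40.0))

    def test_eps_beyond_half_box_rejected(self):
        with pytest.raises(ValueError):
            find_clusters(np.zeros((3, 2)), 2.0, eps=1.5)


class TestSizes:
    def test_singletons_and_pair(self):
        L = 30.0
        sparse = np.array([[1.0, 1.0], [10.0, 10.0], [20.0, 5.0]])
        lab = find_clusters(sparse, L)
        assert cluster_size(lab, sparse, L) == pytest.approx(0.0)
        pair = np.array([[5.0, 5.0], [6.2, 5.0]])
        lab2 = find_clusters(pair, L)
        assert cluster_size(lab2, pair, L) == pytest.approx(0.6)

    def test_direct_reimplementation_oracle(self, rng):
        L = 25.0
        centers = np.array([[5.0, 5.0], [18.0, 12.0]])
        pos = np.vstack([c + rng.uniform(-1.5, 1.5, (15, 2)) for c in centers]) % L
        lab = find_clusters(pos, L, eps=1.5)
        got = cluster_size(lab, pos, L)
        # naive loop over clusters
        extents = []
        for c in range(lab.n_clusters):
            pts = pos[lab.labels == c]
            com = periodic_com(pts, L)
            d = min_image_displacement(pts - com, L)
            extents.append(np.hypot(d[:, 0], d[:, 1]).max())
        assert got == pytest.approx(np.mean(extents))

    def test_system_size_two_particles(self):
        L = 20.0
        pos = np.array([[5.0, 5.0], [8.0, 9.0]])
        assert system_size(pos, L) == pytest.approx(2.5)  # d/2 with d=5

    def test_system_size_equals_cluster_size_single_cluster(self, rng):
        L = 40.0
        pos = (np.array([20.0, 20.0]) + rng.uniform(-2, 2, (30, 2))) % L
        lab = find_clusters(pos, L)
        assert lab.n_clusters == 1
        assert system_size(pos, L) == pytest.approx(cluster_size(lab, pos, L))


class TestAsymmetry:
    def test_square_is_isotropic(self):
        sq = np.array([[1.0, 1.0], [1.0, 2.0], [2.0, 1.0], [2.0, 2.0]])
        assert asymmetry(sq, 20.0) == pytest.approx(0.0, abs=1e-12)

    def test_collinear_is_one(self):
        line = np.column_stack([np.linspace(2, 6, 9), np.full(9, 3.0)])
        assert asymmetry(line, 20.0) == pytest.approx(1.0)

    def test_coincident_flagged_nan(self):
        assert math.isnan(asymmetry(np.array([[1.0, 1.0]] * 3), 20.0))

    def test_direct_eigendecomposition_oracle(self, rng):
        pts = rng.uniform(3.0, 8.0, (25, 2))
        L = 50.0
        com = pts.mean(axis=0)
        d = pts - com
        gyr = d.T @ d / len(d)
        ev = np.linalg.eigvalsh(gyr)
        expected = abs(ev[1] - ev[0]) / (ev[1] + ev[0])
        assert asymmetry(pts, L) == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_rotation_and_translation(self, rng):
        pts = rng.uniform(0.0, 3.0, (20, 2)) + 10.0
        L = 40.0
        a0 = asymmetry(pts, L)
        ang = 1.1
        rot = np.array([[math.cos(ang), -math.sin(ang)],
                        [math.sin(ang), math.cos(ang)]])
        moved = (pts - pts.mean(0)) @ rot.T + np.array([25.0, 13.0])
        assert asymmetry(moved, L) == pytest.approx(a0, abs=1e-9)
        assert 0.0 <= a0 <= 1.0


def _synthetic_traj(times, unwrapped, phi, params):
    L = params.L
    images = np.floor(unwrapped / L).astype(np.int64)
    pos = unwrapped - images * L
    return Trajectory(times, pos, images, phi, params)


class TestMsdOcf:
    def test_immobile_and_frozen(self):
        p = SimParams(N=3, Phi=0.01, seed=0)
        times = np.linspace(0, 5, 26)
        r = np.broadcast_to(np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
                            (26, 3, 2)).copy()
        phi = np.broadcast_to(np.array([0.1, 0.2, 0.3]), (26, 3)).copy()
        traj = _synthetic_traj(times, r, phi, p)
        m = cs.msd(traj)
        o = cs.ocf(traj)
        assert np.allclose(m.mean, 0.0)
        assert np.allclose(o.mean, 1.0)
        assert m.mean[0] == 0.0 and o.mean[0] == 1.0  # pinned lag-0 values

    def test_ballistic_closed_form(self):
        p = SimParams(N=2, Phi=0.01, seed=0)
        times = np.linspace(0, 8, 33)
        v = 3.0
        r = np.zeros((33, 2, 2))
        r[:, 0, 0] = v * times
        r[:, 1, 1] = v * times
        phi = np.zeros((33, 2))
        traj = _synthetic_traj(times, r, phi, p)
        m = cs.msd(traj)
        assert np.allclose(m.mean, (v * m.lags) ** 2, atol=1e-9)

    def test_uniform_rotation_ocf(self):
        p = SimParams(N=1, Phi=0.01, seed=0)
        omega = 2.0
        times = np.linspace(0, 6, 121)
        phi = (omega * times)[:, None]
        r = np.zeros((121, 1, 2))
        traj = _synthetic_traj(times, r, phi, p)
        o = cs.ocf(traj)
        assert np.allclose(o.mean, np.cos(omega * o.lags), atol=1e-9)

    def test_lag_beyond_length_rejected(self):
        p = SimParams(N=1, Phi=0.01, seed=0)
        traj = _synthetic_traj(np.linspace(0, 1, 6), np.zeros((6, 1, 2)),
                               np.zeros((6, 1)), p)
        with pytest.raises(ValueError):
            cs.msd(traj, np.array([10]))


class TestAbpBaselines:
    def test_small_t_expansion(self):
        """MSD -> 4 D t + v0^2 t^2 for t << tau_R."""
        p = SimParams(Pe=80.0)
        t = np.array([1e-5, 1e-4, 1e-3])
        expected = 4 * p.D * t + p.v0**2 * t**2
        assert np.allclose(abp_msd(p, t), expected, rtol=1e-3)

    def test_long_time_diffusive_slope(self):
        """Effective long-time diffusivity 4 D + 2 v0^2 / D_R."""
        p = SimParams(Pe=80.0)
        t = np.array([500.0, 1000.0])
        slope = np.diff(abp_msd(p, t))[0] / np.diff(t)[0]
        assert slope == pytest.approx(4 * p.D + 2 * p.v0**2 / p.D_R, rel=1e-4)

    def test_ocf_normalization_and_decay(self):
        p = SimParams()
        t = np.array([0.0, 1.0, 2.0])
        o = abp_ocf(p, t)
        assert o[0] == 1.0
        assert np.allclose(o, np.exp(-t))
        msd_curve, ocf_curve = cs.abp_baselines(p, t)
        assert msd_curve.mean[0] == 0.0 and ocf_curve.mean[0] == 1.0


class TestRadialOrder:
    def test_aster_configuration(self):
        L = 40.0
        rng = np.random.default_rng(0)
        center = np.array([20.0, 20.0])
        r = rng.uniform(0.5, 4.0, 40)
        ang = rng.uniform(-math.pi, math.pi, 40)
        pos = center + np.column_stack([r * np.cos(ang), r * np.sin(ang)])
        lab = find_clusters(pos, L, eps=5.0)
        assert lab.n_clusters == 1
        com = lab.coms[0]
        phi_in = np.arctan2(com[1] - pos[:, 1], com[0] - pos[:, 0])
        assert radial_order(pos, phi_in, lab, L) == pytest.approx(-1.0)
        assert radial_order(pos, phi_in + math.pi, lab, L) == pytest.approx(1.0)


class TestNeighborTurnover:
    def test_identity_and_frozen(self):
        p = SimParams(N=5, Phi=0.002, R=2.0, seed=0)
        times = np.linspace(0, 4, 9)
        base = np.array([[5.0, 5.0], [6.0, 5.0], [7.0, 5.0], [5.5, 6.0], [20.0, 20.0]])
        r = np.broadcast_to(base, (9, 5, 2)).copy()
        phi = np.zeros((9, 5))
        traj = _synthetic_traj(times, r, phi, p)
        out = neighbor_turnover(traj, 0, 0.0, 0.0)
        assert out.fraction == 0.0
        frozen = neighbor_turnover(traj, 0, 0.0, 4.0)
        assert frozen.fraction == 0.0
        assert frozen.n_neighbors_t0 == 3

    def test_departing_neighbor(self):
        p = SimParams(N=3, Phi=0.002, R=2.0, seed=0)
        times = np.array([0.0, 1.0])
        r = np.zeros((2, 3, 2))
        r[0] = [[5.0, 5.0], [6.0, 5.0], [6.5, 5.5]]
        r[1] = [[5.0, 5.0], [6.0, 5.0], [15.0, 15.0]]  # particle 2 leaves
        phi = np.zeros((2, 3))
        traj = _synthetic_traj(times, r, phi, p)
        out = neighbor_turnover(traj, 0, 0.0, 1.0)
        assert out.n_neighbors_t0 == 2
        assert out.fraction == pytest.approx(0.5)

    def test_front_rank_ordering(self):
        """Ranks order cluster members along the mean orientation."""
        p = SimParams(N=3, Phi=0.02, R=2.0, seed=0)
        times = np.array([0.0, 1.0])
        base = np.array([[5.0, 5.0], [6.0, 5.0], [7.0, 5.0]])
        r = np.broadcast_to(base, (2, 3, 2)).copy()
        phi = np.zeros((2, 3))  # all heading +x: particle 2 leads
        traj = _synthetic_traj(times, r, phi, p)
        assert neighbor_turnover(traj, 2, 0.0, 1.0).rank_t0 == 0
        assert neighbor_turnover(traj, 0, 0.0, 1.0).rank_t0 == 2
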