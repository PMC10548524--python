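import numpy as np
import pandas as pd
import pytest

from oxytraj.constants import KB_KCAL_MOL_K
from oxytraj.occupancy import (
    DensityGrid,
    FreeEnergyGrid,
    GridSpec,
    accumulate_density,
    barrier_and_ratio,
    boltzmann_invert,
    boltzmann_ratio,
    detect_sites,
    minimax_barrier,
    reweight_biased,
)
from oxytraj.traj_io import Trajectory


def point_trajectory(positions, stride_ps=50.0):
    positions = np.atleast_2d(positions)
    atoms = pd.DataFrame(
        {"name": ["O1"], "resname": ["OXY"], "resnum": [1], "chain": ["A"]}
    )
    return Trajectory(
        times=np.arange(len(positions)) * stride_ps / 1000.0,
        atoms=atoms,
        coords=positions[:, None, :],
    )


def grid_from_counts(counts, origin=(0, 0, 0), spacing=1.0):
    counts = np.asarray(counts, dtype=float)
    return DensityGrid(origin=np.asarray(origin, float), spacing=spacing,
                       counts=counts, n_samples=max(int(counts.sum()), 1),
                       probability=counts / counts.sum())


def fe_from_values(values, spacing=1.0, temperature=300.0):
    values = np.asarray(values, dtype=float)
    mask = ~np.isfinite(values)
    shifted = values - np.nanmin(values)
    return FreeEnergyGrid(origin=np.zeros(3), spacing=spacing, values=shifted,
                          mask=mask, temperature=temperature)


class TestAccumulateDensity:
    def test_all_frames_in_one_voxel(self):
        traj = point_trajectory(np.tile([0.2, 0.2, 0.2], (10, 1)))
        spec = GridSpec(origin=np.zeros(3), spacing=0.5, shape=(2, 2, 2))
        grid = accumulate_density(traj, "O1", spec)
        assert grid.probability[0, 0, 0] == 1.0
        assert grid.probability.sum() == pytest.approx(1.0, abs=1e-12)

    def test_uniform_sampling_within_multinomial_error(self, rng):
        n = 100_000
        pts = rng.uniform(0.0, 4.0, (n, 3))
        traj = point_trajectory(pts)
        spec = GridSpec(origin=np.zeros(3), spacing=1.0, shape=(4, 4, 4))
        grid = accumulate_density(traj, "O1", spec)
        p0 = 1.0 / 64
        se = np.sqrt(p0 * (1 - p0) / n)
        assert np.all(np.abs(grid.probability - p0) < 4 * se)

    def test_sample_stride_takes_every_other_frame(self):
        pts = np.zeros((10, 3))
        pts[1::2] = [3.0, 3.0, 3.0]  # odd frames elsewhere
        traj = point_trajectory(pts, stride_ps=50.0)
        spec = GridSpec(origin=np.full(3, -1.0), spacing=1.0, shape=(6, 6, 6))
        grid = accumulate_density(traj, "O1", spec, sample_stride_ps=100.0)
        assert grid.n_samples == 5
        assert grid.probability[1, 1, 1] == 1.0  # only even frames (origin) counted

    def test_outside_grid_without_clipping_rejected(self):
        traj = point_trajectory([[10.0, 0.0, 0.0]])
        spec = GridSpec(origin=np.zeros(3), spacing=1.0, shape=(2, 2, 2))
        with pytest.raises(ValueError, match="outside"):
            accumulate_density(traj, "O1", spec)


class TestDetectSites:
    def test_two_separated_clouds(self, rng):
        a = rng.normal([2.0, 2.0, 2.0], 0.5, (4000, 3))
        b = rng.normal([10.0, 2.0, 2.0], 0.5, (2000, 3))
        traj = point_trajectory(np.vstack([a, b]))
        spec = GridSpec.from_points(traj.coords[:, 0, :], spacing=0.5)
        grid = accumulate_density(traj, "O1", spec)
        sites = detect_sites(grid, iso_level=0.1 * grid.probability.max(),
                             min_voxels=3)
        assert len(sites) == 2
        assert sites[0].probability_mass > sites[1].probability_mass
        assert np.linalg.norm(sites[0].center - [2, 2, 2]) < 0.5
        assert np.linalg.norm(sites[1].center - [10, 2, 2]) < 0.5
        assert sites[0].label == "I" and sites[1].label == "II"

    def test_iso_above_max_gives_empty_list(self):
        grid = grid_from_counts(np.ones((3, 3, 3)))
        assert detect_sites(grid, iso_level=1.0) == []

    def test_sphere_volume_recovered(self, rng):
        # isotropic Gaussian cloud; choose the iso level whose enclosing
        # region is analytically a sphere of 15 A^3 (r ~ 1.53 A)
        sigma = 1.0
        n = 400_000
        pts = rng.normal(0.0, sigma, (n, 3))
        traj = point_trajectory(pts)
        spacing = 0.5
        spec = GridSpec(origin=np.full(3, -4.0), spacing=spacing,
                        shape=(16, 16, 16), clip=True)
        grid = accumulate_density(traj, "O1", spec)
        target_volume = 15.0
        r = (3 * target_volume / (4 * np.pi)) ** (1 / 3)
        # iso level = Gaussian probability mass of the voxel at radius r
        dens = np.exp(-r**2 / (2 * sigma**2)) / (2 * np.pi * sigma**2) ** 1.5
        iso = dens * spacing**3
        sites = detect_sites(grid, iso_level=iso, min_voxels=1)
        assert len(sites) >= 1
        # exact lattice oracle: voxel centers whose density clears the
        # threshold (the discretized sphere, 17.0 A^3 at this spacing)
        centers = (np.arange(16) + 0.5) * spacing - 4.0
        xx, yy, zz = np.meshgrid(centers, centers, centers, indexing="ij")
        cdens = np.exp(-(xx**2 + yy**2 + zz**2) / (2 * sigma**2))
        cdens /= (2 * np.pi * sigma**2) ** 1.5
        lattice_volume = np.sum(cdens * spacing**3 >= iso) * spacing**3
        assert abs(sites[0].volume - lattice_volume) <= 8 * spacing**3
        # and the discretized sphere sits near the continuum 15 A^3
        assert abs(sites[0].volume - target_volume) <= 3.0

    def test_sorted_output_stable(self, rng):
        counts = rng.integers(0, 5, (6, 6, 6)).astype(float)
        counts[1, 1, 1] = 60
        counts[4, 4, 4] = 40
        grid = grid_from_counts(counts)
        sites = detect_sites(grid, iso_level=30 / grid.n_samples)
        masses = [s.probability_mass for s in sites]
        assert masses == sorted(masses, reverse=True)


class TestBoltzmannInvert:
    def test_uniform_grid_is_flat_zero(self):
        grid = grid_from_counts(np.ones((3, 3, 3)))
        fe = boltzmann_invert(grid, 300.0)
        assert np.allclose(fe.values, 0.0)

    def test_probability_ratio_e_gives_kbt(self):
        counts = np.zeros((2, 1, 1))
        counts[0, 0, 0] = 1000.0 * np.e
        counts[1, 0, 0] = 1000.0
        grid = grid_from_counts(counts)
        fe = boltzmann_invert(grid, 300.0)
        dg = fe.values[1, 0, 0] - fe.values[0, 0, 0]
        assert dg == pytest.approx(KB_KCAL_MOL_K * 300.0, rel=1e-9)
        assert dg == pytest.approx(0.596, abs=5e-4)

    def test_monotone_lower_probability_higher_free_energy(self, rng):
        counts = rng.integers(1, 100, (4, 4, 4)).astype(float)
        grid = grid_from_counts(counts)
        fe = boltzmann_invert(grid, 310.0)
        p = grid.probability.ravel()
        g = fe.values.ravel()
        order = np.argsort(p)
        assert np.all(np.diff(g[order]) <= 1e-12)

    def test_zero_count_voxels_masked(self):
        counts = np.ones((2, 2, 2))
        counts[0, 0, 0] = 0
        fe = boltzmann_invert(grid_from_counts(counts), 300.0)
        assert fe.mask[0, 0, 0] and np.isnan(fe.values[0, 0, 0])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            grid = DensityGrid(origin=np.zeros(3), spacing=1.0,
                               counts=np.zeros((2, 2, 2)), n_samples=1,
                               probability=np.zeros((2, 2, 2)))

    def test_scale_invariance_up_to_shift(self, rng):
        counts = rng.integers(1, 50, (3, 3, 3)).astype(float)
        fe1 = boltzmann_invert(grid_from_counts(counts), 300.0)
        fe2 = boltzmann_invert(grid_from_counts(counts * 7), 300.0)
        assert np.allclose(fe1.values, fe2.values, atol=1e-9)


class TestReweightBiased:
    def test_zero_bias_identical_to_plain_density(self, rng):
        pts = rng.normal(2.0, 0.8, (5000, 3))
        traj = point_trajectory(pts)
        spec = GridSpec.from_points(pts, spacing=0.5)
        plain = accumulate_density(traj, "O1", spec)
        rw = reweight_biased(traj, np.zeros(traj.n_frames), "O1", spec, 300.0)
        assert np.allclose(rw.probability, plain.probability, atol=1e-12)

    def test_constant_bias_cancels(self, rng):
        pts = rng.normal(2.0, 0.8, (5000, 3))
        traj = point_trajectory(pts)
        spec = GridSpec.from_points(pts, spacing=0.5)
        plain = accumulate_density(traj, "O1", spec)
        rw = reweight_biased(traj, np.full(traj.n_frames, 3.7), "O1", spec, 300.0)
        assert np.allclose(rw.probability, plain.probability, atol=1e-12)

    def test_linear_bias_recovers_uniform_density(self, rng):
        # sample a 1-D lattice under P(x) ∝ exp(-V(x)/kT) with linear V;
        # reweighting by exp(+V/kT) must return the uniform law
        temperature = 300.0
        kbt = KB_KCAL_MOL_K * temperature
        nx = 8
        x_sites = np.arange(nx) + 0.5
        v = 0.2 * x_sites  # kcal/mol, linear in x
        p = np.exp(-v / kbt)
        p /= p.sum()
        n = 200_000
        idx = rng.choice(nx, size=n, p=p)
        pts = np.column_stack([x_sites[idx], np.full(n, 0.5), np.full(n, 0.5)])
        traj = point_trajectory(pts)
        spec = GridSpec(origin=np.zeros(3), spacing=1.0, shape=(nx, 1, 1))
        rw = reweight_biased(traj, v[idx], "O1", spec, temperature)
        uniform = 1.0 / nx
        # the statistical error is set by the least-sampled site's counts
        se = uniform / np.sqrt(n * p.min())
        assert np.all(np.abs(rw.probability.ravel() - uniform) < 4 * se)

    def test_length_mismatch_rejected(self, rng):
        traj = point_trajectory(rng.normal(size=(10, 3)))
        spec = GridSpec.from_points(traj.coords[:, 0, :], spacing=1.0)
        with pytest.raises(ValueError, match="length"):
            reweight_biased(traj, np.zeros(5), "O1", spec, 300.0)

    def test_non_finite_bias_rejected(self, rng):
        traj = point_trajectory(rng.normal(size=(10, 3)))
        spec = GridSpec.from_points(traj.coords[:, 0, :], spacing=1.0)
        bias = np.zeros(10)
        bias[3] = np.inf
        with pytest.raises(ValueError, match="finite"):
            reweight_biased(traj, bias, "O1", spec, 300.0)


def brute_force_minimax(values, start, end):
    """Oracle: smallest threshold v such that start and end are 26-connected
    within {voxels <= v}, by explicit threshold sweep + flood fill."""
    from scipy import ndimage

    finite = np.isfinite(values)
    for v in np.sort(np.unique(values[finite])):
        mask = finite & (values <= v)
        labels, _ = ndimage.label(mask, structure=np.ones((3, 3, 3)))
        if labels[start] and labels[start] == labels[end]:
            return float(v)
    raise ValueError("not connected")


def networkx_minimax(values, start, end):
    """Second oracle: minimax path via the minimum spanning tree of the
    voxel graph with edge weight max(endpoint values)."""
    import networkx as nx

    shape = values.shape
    g = nx.Graph()
    idx = [tuple(i) for i in np.argwhere(np.isfinite(values))]
    for v in idx:
        g.add_node(v)
    offs = [
        (i, j, k)
        for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
    for v in idx:
        for o in offs:
            w = (v[0] + o[0], v[1] + o[1], v[2] + o[2])
            if w in g:
                g.add_edge(v, w, weight=max(values[v], values[w]))
    mst = nx.minimum_spanning_tree(g)
    path = nx.shortest_path(mst, start, end)
    return float(max(values[p] for p in path))


class TestMinimaxBarrier:
    def test_flat_landscape_zero_barrier_unit_ratio(self):
        fe = fe_from_values(np.zeros((3, 3, 3)))
        b = minimax_barrier(fe, (0, 0, 0), (2, 2, 2))
        assert b == 0.0
        assert boltzmann_ratio(b, b, 300.0) == 1.0

    def test_1d_double_well_recovers_analytic_barrier(self):
        # G(x) = 2 * sin^2(pi x / L): wells at 0 and L, barrier 2 kcal/mol
        nx_ = 41
        x = np.arange(nx_)
        g = 2.0 * np.sin(np.pi * x / (nx_ - 1)) ** 2
        fe = fe_from_values(g.reshape(nx_, 1, 1))
        b = minimax_barrier(fe, (0, 0, 0), (nx_ - 1, 0, 0))
        # discretization error: one voxel's free-energy step
        step = np.max(np.abs(np.diff(g)))
        assert abs(b - 2.0) <= step

    def test_matches_both_oracles_on_random_small_grids(self, rng):
        for trial in range(25):
            shape = tuple(rng.integers(2, 6, 3))
            values = rng.uniform(0, 5, shape)
            values -= values.min()
            fe = fe_from_values(values)
            start = tuple(int(i) for i in rng.integers(0, shape))
            end = tuple(int(i) for i in rng.integers(0, shape))
            mine = minimax_barrier(fe, start, end)
            assert mine == pytest.approx(brute_force_minimax(fe.values, start, end))
            assert mine == pytest.approx(networkx_minimax(fe.values, start, end))

    def test_disconnected_mask_rejected(self):
        values = np.full((3, 1, 1), np.nan)
        values[0] = 0.0
        values[2] = 1.0
        fe = FreeEnergyGrid(origin=np.zeros(3), spacing=1.0, values=values,
                            mask=~np.isfinite(values), temperature=300.0)
        with pytest.raises(ValueError, match="not connected"):
            minimax_barrier(fe, (0, 0, 0), (2, 0, 0))


class TestBarrierAndRatio:
    def test_reference_ratio_reproduces_boltzmann_factor(self):
        # barriers 4.1 vs 6.5 kcal/mol at 300 K -> ~56-fold in favor of 4.1
        ratio = boltzmann_ratio(4.1, 6.5, 300.0)
        assert ratio == pytest.approx(np.exp(2.4 / (KB_KCAL_MOL_K * 300.0)), rel=1e-12)
        assert ratio == pytest.approx(56.0, rel=0.01)

    def test_site_to_site_barrier_on_double_well(self):
        from oxytraj.occupancy import SiteCluster

        nx_ = 21
        g = 2.0 * np.sin(np.pi * np.arange(nx_) / (nx_ - 1)) ** 2
        fe = fe_from_values(g.reshape(nx_, 1, 1))
        mk = lambda i, lab: SiteCluster(
            voxels=np.array([[i, 0, 0]]), center=np.array([i + 0.5, 0.5, 0.5]),
            volume=1.0, probability_mass=0.1, label=lab,
        )
        barrier, ratio = barrier_and_ratio(fe, mk(0, "I"), mk(nx_ - 1, "II"),
                                           300.0, reference_barrier=2.0)
        assert abs(barrier - 2.0) <= np.max(np.abs(np.diff(g)))
        assert ratio == pytest.approx(
            np.exp(-(barrier - 2.0) / (KB_KCAL_MOL_K * 300.0))
        )
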