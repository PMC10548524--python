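"""Occupancy-density pocket mapping and free-energy reconstruction.

A gas particle's sampled positions are accumulated on a 3-D voxel grid to
give an occupancy probability per voxel; connected high-density regions are
reported as site clusters (pockets); Boltzmann inversion turns the density
into a relative free-energy landscape; and the entry barrier between two
sites is estimated as the bottleneck (minimax) free energy along the best
path on the voxel graph.  Biased (metadynamics-style) sampling is supported
through per-frame exponential reweighting of the bias energy.

Conventions: grid origin is the minimum corner of the box, voxel ``(i,j,k)``
covers ``origin + [i,i+1)·spacing`` per axis and its center is
``origin + (i+½)·spacing``; clustering and paths use 26-neighbor
connectivity; free energies are in kcal/mol with the global minimum at 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .constants import KB_KCAL_MOL_K, PS_PER_NS
from .traj_io import Trajectory

__all__ = [
    "GridSpec",
    "DensityGrid",
    "SiteCluster",
    "FreeEnergyGrid",
    "accumulate_density",
    "detect_sites",
    "boltzmann_invert",
    "reweight_biased",
    "barrier_and_ratio",
    "boltzmann_ratio",
    "minimax_barrier",
]

_CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class GridSpec:
    """Axis-aligned voxel grid: origin (minimum corner, Å), cubic voxel
    spacing (Å) and shape (voxels per axis)."""

    origin: np.ndarray
    spacing: float
    shape: tuple[int, int, int]
    clip: bool = False

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if any(s < 1 for s in self.shape):
            raise ValueError("shape must be >= 1 per axis")

    @classmethod
    def from_points(
        cls, points: np.ndarray, spacing: float = 0.5, padding: float = 1.0
    ) -> "GridSpec":
        """Smallest grid at the given spacing covering all points plus
        padding on every side."""
        points = np.atleast_2d(points)
        lo = points.min(axis=0) - padding
        hi = points.max(axis=0) + padding
        shape = tuple(int(np.ceil((h - l) / spacing)) + 1 for l, h in zip(lo, hi))
        return cls(origin=lo, spacing=spacing, shape=shape)

    def voxel_of(self, points: np.ndarray) -> np.ndarray:
        """Integer voxel indices of the given points (may fall outside)."""
        return np.floor((np.atleast_2d(points) - self.origin) / self.spacing).astype(int)


@dataclass
class DensityGrid:
    """Per-voxel sample counts and normalized occupancy probability."""

    origin: np.ndarray
    spacing: float
    counts: np.ndarray
    n_samples: int
    probability: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if self.probability is None:
            if self.n_samples <= 0:
                raise ValueError("n_samples must be > 0")
            self.probability = self.counts / self.n_samples
        total = float(self.probability.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {total}, expected 1")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.counts.shape

    @property
    def voxel_volume(self) -> float:
        return self.spacing**3

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        return self.origin + (np.atleast_2d(indices) + 0.5) * self.spacing


_ROMAN = [
    (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"), (90, "XC"),
    (50, "L"), (40, "XL"), (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
]


def _roman(n: int) -> str:
    out = []
    for v, s in _ROMAN:
        while n >= v:
            out.append(s)
            n -= v
    return "".join(out)


@dataclass
class SiteCluster:
    """A connected high-occupancy region of the grid."""

    voxels: np.ndarray  # (n_voxels, 3) integer indices
    center: np.ndarray  # probability-weighted center of mass, Å
    volume: float  # Å³ = voxel count × spacing³
    probability_mass: float
    label: str

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("cluster volume must be > 0")
        if self.probability_mass > 1 + 1e-12:
            raise ValueError("probability mass cannot exceed 1")


@dataclass
class FreeEnergyGrid:
    """Relative free energy per voxel (kcal/mol, minimum = 0); voxels with
    zero counts are masked and carry no finite value."""

    origin: np.ndarray
    spacing: float
    values: np.ndarray  # NaN on masked voxels
    mask: np.ndarray  # True where no samples (no finite value)
    temperature: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        finite = self.values[~self.mask]
        if finite.size and abs(finite.min()) > 1e-9:
            raise ValueError("unmasked minimum must be 0 (reference convention)")


def _sampled_positions(
    traj: Trajectory, selection: str | int, sample_stride_ps: float | None
) -> np.ndarray:
    idx = traj.atom_index(selection) if isinstance(selection, str) else int(selection)
    positions = traj.coords[:, idx, :]
    if sample_stride_ps is None or traj.n_frames < 2:
        return positions
    stride_ps = traj.stride_ns * PS_PER_NS
    step = int(round(sample_stride_ps / stride_ps))
    if step < 1 or abs(step * stride_ps - sample_stride_ps) > 1e-6:
        raise ValueError(
            f"sample stride {sample_stride_ps} ps is not a multiple of the "
            f"trajectory stride {stride_ps} ps"
        )
    return positions[::step]


def _bin_positions(
    positions: np.ndarray, spec: GridSpec, weights: np.ndarray | None = None
) -> tuple[np.ndarray, int]:
    vox = spec.voxel_of(positions)
    inside = np.all((vox >= 0) & (vox < np.array(spec.shape)), axis=1)
    if not spec.clip and not inside.all():
        raise ValueError(
            f"{(~inside).sum()} sampled positions fall outside the grid "
            "(enable clipping to drop them)"
        )
    vox = vox[inside]
    w = None if weights is None else np.asarray(weights, dtype=float)[inside]
    flat = np.ravel_multi_index(tuple(vox.T), spec.shape)
    counts = np.bincount(flat, weights=w, minlength=int(np.prod(spec.shape)))
    return counts.reshape(spec.shape), int(inside.sum())


def accumulate_density(
    traj: Trajectory,
    selection: str | int,
    grid: GridSpec,
    sample_stride_ps: float | None = None,
) -> DensityGrid:
    """Accumulate sampled particle positions into an occupancy grid.

    ``selection`` is an atom name or index resolving to the tracked
    particle; ``sample_stride_ps`` (default: every frame) subsamples the
    trajectory, e.g. 100 ps on a 50 ps trajectory counts every other frame.
    Probability per voxel = samples in voxel / total samples.
    """
    positions = _sampled_positions(traj, selection, sample_stride_ps)
    if positions.size == 0:
        raise ValueError("selection resolves to no sampled positions")
    counts, n = _bin_positions(positions, grid)
    if n == 0:
        raise ValueError("no sampled positions inside the grid")
    return DensityGrid(origin=grid.origin, spacing=grid.spacing, counts=counts, n_samples=n)


def detect_sites(
    grid: DensityGrid, iso_level: float, min_voxels: int = 1
) -> list[SiteCluster]:
    """Find pockets as 26-connected components of voxels with probability
    ≥ ``iso_level``, keeping those with at least ``min_voxels`` voxels.

    Clusters are sorted by probability mass (descending) and labelled with
    Roman numerals in that order, so the output is stable under any
    relabeling of voxel iteration order.
    """
    if not iso_level > 0:
        raise ValueError("iso_level must be > 0")
    above = grid.probability >= iso_level
    labelled, n_found = ndimage.label(above, structure=_CONNECTIVITY_26)
    clusters = []
    for lab in range(1, n_found + 1):
        vox = np.argwhere(labelled == lab)
        if vox.shape[0] < min_voxels:
            continue
        p = grid.probability[tuple(vox.T)]
        mass = float(p.sum())
        center = (grid.voxel_centers(vox) * p[:, None]).sum(axis=0) / mass
        clusters.append(
            dict(voxels=vox, center=center, volume=vox.shape[0] * grid.voxel_volume,
                 probability_mass=mass)
        )
    clusters.sort(key=lambda c: -c["probability_mass"])
    return [
        SiteCluster(label=_roman(i + 1), **c) for i, c in enumerate(clusters)
    ]


def boltzmann_invert(grid: DensityGrid, temperature: float) -> FreeEnergyGrid:
    """Free energy from occupancy: G = −k_B·T·ln(p/p_max) per voxel.

    Zero-count voxels are masked (NaN), never imputed; the reference is the
    most-occupied voxel, so the unmasked minimum is 0.
    """
    if not temperature > 0:
        raise ValueError("temperature must be > 0")
    p = grid.probability
    pmax = p.max()
    if pmax <= 0:
        raise ValueError("all-zero density grid")
    mask = p <= 0
    values = np.full(p.shape, np.nan)
    with np.errstate(divide="ignore"):
        values[~mask] = -KB_KCAL_MOL_K * temperature * np.log(p[~mask] / pmax)
    return FreeEnergyGrid(
        origin=grid.origin, spacing=grid.spacing, values=values, mask=mask,
        temperature=temperature,
    )


def reweight_biased(
    traj: Trajectory,
    bias_kcal_mol: np.ndarray,
    selection: str | int,
    grid: GridSpec,
    temperature: float,
    sample_stride_ps: float | None = None,
) -> DensityGrid:
    """Recover the unbiased occupancy from bias-accelerated sampling.

    Each sampled frame is weighted by exp(+V_bias/k_BT) and the weighted
    histogram renormalized — the importance-sampling identity for a
    trajectory generated under an additive bias potential V_bias.  With
    zero (or any constant) bias this reduces to :func:`accumulate_density`.
    """
    bias = np.asarray(bias_kcal_mol, dtype=float)
    if bias.shape != (traj.n_frames,):
        raise ValueError(
            f"bias series length {bias.shape} does not match {traj.n_frames} frames"
        )
    if not np.all(np.isfinite(bias)):
        raise ValueError("bias energies must be finite")
    positions = _sampled_positions(traj, selection, sample_stride_ps)
    if sample_stride_ps is not None and traj.n_frames >= 2:
        stride_ps = traj.stride_ns * PS_PER_NS
        bias = bias[:: int(round(sample_stride_ps / stride_ps))]
    # subtract the max before exponentiating for numerical stability
    w = np.exp((bias - bias.max()) / (KB_KCAL_MOL_K * temperature))
    weighted, n = _bin_positions(positions, grid, weights=w)
    counts, _ = _bin_positions(positions, grid)
    return DensityGrid(
        origin=grid.origin, spacing=grid.spacing, counts=counts, n_samples=n,
        probability=weighted / weighted.sum(),
    )


def _neighbors_26(idx: tuple[int, int, int], shape) -> list[tuple[int, int, int]]:
    out = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if di == dj == dk == 0:
                    continue
                i, j, k = idx[0] + di, idx[1] + dj, idx[2] + dk
                if 0 <= i < shape[0] and 0 <= j < shape[1] and 0 <= k < shape[2]:
                    out.append((i, j, k))
    return out


def minimax_barrier(
    fe: FreeEnergyGrid, start_voxel: np.ndarray, end_voxel: np.ndarray
) -> float:
    """Bottleneck free energy between two voxels: the smallest value ``v``
    such that start and end are 26-connected through voxels with free
    energy ≤ ``v``.

    Implemented by sorted-threshold union-find: voxels are activated in
    order of increasing free energy and merged with active neighbors; the
    activation value at which the endpoints join is the bottleneck.
    Masked voxels never become active; raises if the endpoints are not
    connected through unmasked voxels.
    """
    start = tuple(int(x) for x in start_voxel)
    end = tuple(int(x) for x in end_voxel)
    for p in (start, end):
        if fe.mask[p]:
            raise ValueError(f"endpoint voxel {p} is masked")
    if start == end:
        return float(fe.values[start])
    order = np.argsort(fe.values, axis=None, kind="stable")
    shape = fe.values.shape
    parent: dict[tuple, tuple] = {}

    def find(x):
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    for flat in order:
        idx = np.unravel_index(flat, shape)
        v = fe.values[idx]
        if not np.isfinite(v):
            break  # NaNs sort last; everything finite has been processed
        parent[idx] = idx
        for nb in _neighbors_26(idx, shape):
            if nb in parent:
                ra, rb = find(idx), find(nb)
                if ra != rb:
                    parent[ra] = rb
        if start in parent and end in parent and find(start) == find(end):
            return float(v)
    raise ValueError("endpoints are not connected through unmasked voxels")


def boltzmann_ratio(
    barrier_1: float, barrier_2: float, temperature: float
) -> float:
    """Probability ratio exp(−(b1−b2)/k_BT) implied by two barriers; >1
    favors the first (lower) barrier."""
    if not temperature > 0:
        raise ValueError("temperature must be > 0")
    return float(np.exp(-(barrier_1 - barrier_2) / (KB_KCAL_MOL_K * temperature)))


def barrier_and_ratio(
    fe: FreeEnergyGrid,
    site_a: SiteCluster,
    site_b: SiteCluster,
    temperature: float,
    reference_barrier: float | None = None,
) -> tuple[float, float | None]:
    """Entry barrier from site_a to site_b and its Boltzmann probability
    ratio against a reference barrier.

    The barrier is the bottleneck free energy along the minimax path
    between the sites' lowest-free-energy voxels, minus the free energy at
    site_a's minimum.  The ratio (None when no reference is supplied) is
    ``exp(−(barrier − reference)/k_BT)``.
    """
    def min_voxel(site: SiteCluster) -> np.ndarray:
        vals = fe.values[tuple(site.voxels.T)]
        if not np.any(np.isfinite(vals)):
            raise ValueError(f"site {site.label} has no unmasked voxels")
        return site.voxels[np.nanargmin(vals)]

    va, vb = min_voxel(site_a), min_voxel(site_b)
    bottleneck = minimax_barrier(fe, va, vb)
    barrier = bottleneck - float(fe.values[tuple(va)])
    ratio = (
        None
        if reference_barrier is None
        else boltzmann_ratio(barrier, reference_barrier, temperature)
    )
    return barrier, ratio
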