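"""Synthetic trajectory, escape-event and rotamer-series generators.

These generators emulate the statistical structure of gas-migration MD
output so that every downstream analysis stage can be exercised and
validated without running molecular dynamics:

* a gas particle hopping among discrete pockets — a continuous-time Markov
  chain (CTMC) over site centers with isotropic positional noise, observed
  on a fixed frame grid (microsecond-scale replicas sampled every 50 ps);
* exponential escape times from a reactive site, right-censored at an
  observation cutoff (50 ns in the water runs the defaults mirror);
* a binary side-chain rotamer state (plus ↔ trans) whose switching rates
  may depend on whether the gas occupies a coupled region, emitting χ1
  angles clustered near +60°/180°/−60°;
* small labelled structure fixtures with an exactly constructed ligand–gas
  dihedral Φ and gas-to-ring-plane distance.

All generators take an integer seed and are bit-reproducible; the RNG is
NumPy's PCG64 (``numpy.random.default_rng``), recorded in output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import PS_PER_NS
from .geometry import StructureModel, dihedral
from .traj_io import EventTable, Trajectory

__all__ = [
    "HoppingModel",
    "EscapeModel",
    "RotamerModel",
    "simulate_hopping_trajectory",
    "simulate_escape_events",
    "simulate_rotamer_series",
    "simulate_structure_jitter",
    "make_fixture_complex",
]

_RNG_NAME = "numpy.default_rng(PCG64)"


@dataclass
class HoppingModel:
    """CTMC over discrete pockets with isotropic positional spread.

    Parameters
    ----------
    site_centers : (n_sites, 3) pocket centers, Å.
    rate_matrix : (n_sites, n_sites) inter-site transition rates, ns⁻¹.
        Off-diagonal entries are the i→j rates and must be non-negative;
        the diagonal is ignored.
    noise_sd : isotropic positional spread per site, Å (truncated at
        3·noise_sd so frames remain assignable to their site).
    bulk_site_index : optional index of a designated "solvent" site.
    """

    site_centers: np.ndarray
    rate_matrix: np.ndarray
    noise_sd: float = 0.5
    bulk_site_index: int | None = None

    def __post_init__(self) -> None:
        self.site_centers = np.atleast_2d(np.asarray(self.site_centers, dtype=float))
        self.rate_matrix = np.asarray(self.rate_matrix, dtype=float)
        n = self.site_centers.shape[0]
        if n == 0:
            raise ValueError("at least one site is required")
        if self.rate_matrix.shape != (n, n):
            raise ValueError(
                f"rate matrix shape {self.rate_matrix.shape} does not match "
                f"{n} sites"
            )
        off = self.rate_matrix[~np.eye(n, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_sites(self) -> int:
        return self.site_centers.shape[0]

    def stationary_distribution(self) -> np.ndarray:
        """Analytic stationary distribution of the CTMC (null space of the
        generator matrix)."""
        n = self.n_sites
        q = self.rate_matrix.copy()
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        # solve pi Q = 0 with sum(pi) = 1
        a = np.vstack([q.T, np.ones(n)])
        b = np.zeros(n + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(a, b, rcond=None)
        return pi


@dataclass
class EscapeModel:
    """Exponential escape from a reactive site with right-censoring.

    ``mean_residence`` is the true k_off⁻¹ in ns; runs whose drawn escape
    time reaches ``cutoff`` are recorded as censored at the cutoff
    (``cutoff=inf`` disables censoring; whether real residence runs used a
    cutoff is left to the caller).
    """

    mean_residence: float
    cutoff: float = float("inf")
    n_runs: int = 50

    def __post_init__(self) -> None:
        if not self.mean_residence > 0:
            raise ValueError("mean_residence must be > 0")
        if not self.cutoff > 0:
            raise ValueError("cutoff must be > 0 (use inf for unbounded)")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


@dataclass
class RotamerModel:
    """Two-state (plus ↔ trans) rotamer chain with von Mises χ1 emission.

    ``switch_rates`` are (plus→trans, trans→plus) in ns⁻¹ when the coupled
    region is unoccupied; ``switch_rates_occupied`` apply on frames where
    the gas occupies the region (defaults to the unoccupied rates, i.e. no
    coupling).  ``concentration`` is the von Mises κ of the angular noise
    (default ≈33, giving a mode s.d. of about 10°); ``inf`` emits exact
    mode angles.
    """

    mode_angles: tuple[float, float, float] = (60.0, 180.0, -60.0)
    concentration: float = 33.0
    switch_rates: tuple[float, float] = (1.0, 1.0)
    switch_rates_occupied: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.switch_rates):
            raise ValueError("switch rates must be >= 0")
        if self.switch_rates_occupied is not None and any(
            r < 0 for r in self.switch_rates_occupied
        ):
            raise ValueError("switch rates must be >= 0")
        if not self.concentration > 0:
            raise ValueError("concentration must be > 0")


@dataclass
class RotamerSeries:
    """Per-frame χ1 angles with optional state labels."""

    times: np.ndarray
    chi1: np.ndarray
    labels: np.ndarray | None = None
    replica_id: int = 0
    undefined: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.chi1 = np.asarray(self.chi1, dtype=float)
        if self.times.shape != self.chi1.shape:
            raise ValueError("times and chi1 must have equal length")


def _gas_atoms() -> pd.DataFrame:
    return pd.DataFrame(
        {"name": ["O1"], "resname": ["OXY"], "resnum": [1], "chain": ["A"]}
    )


def _truncated_normal(rng: np.random.Generator, sd: float, size) -> np.ndarray:
    """Isotropic normal noise truncated (by resampling) at ±3 sd."""
    if sd == 0:
        return np.zeros(size)
    x = rng.normal(0.0, sd, size)
    bad = np.abs(x) > 3 * sd
    while np.any(bad):
        x[bad] = rng.normal(0.0, sd, bad.sum())
        bad = np.abs(x) > 3 * sd
    return x


def _ctmc_on_grid(
    rate_matrix: np.ndarray, t_grid: np.ndarray, rng: np.random.Generator, start: int
) -> np.ndarray:
    """Exact Gillespie realization of the CTMC, sampled on the frame grid.

    Event times are simulated exactly and the chain state is read off at
    each grid time, so the frame stride is purely an observation parameter.
    """
    n = rate_matrix.shape[0]
    labels = np.empty(t_grid.size, dtype=int)
    state = start
    t = 0.0
    i = 0
    t_end = t_grid[-1]
    rates = rate_matrix.copy()
    np.fill_diagonal(rates, 0.0)
    totals = rates.sum(axis=1)
    while True:
        total = totals[state]
        t_next = t + (rng.exponential(1.0 / total) if total > 0 else np.inf)
        while i < t_grid.size and t_grid[i] < t_next:
            labels[i] = state
            i += 1
        if i >= t_grid.size or t_next > t_end:
            labels[i:] = state
            break
        t = t_next
        state = rng.choice(n, p=rates[state] / total)
    return labels


def simulate_hopping_trajectory(
    model: HoppingModel,
    duration_ns: float,
    stride_ps: float,
    seed: int,
    start_site: int = 0,
) -> tuple[Trajectory, np.ndarray]:
    """Simulate a gas particle hopping among pockets.

    Returns the observed single-particle :class:`Trajectory` (frame count
    ``floor(duration/stride) + 1``) together with the true per-frame site
    labels.  Each frame's position is the current site center plus
    truncated isotropic noise.
    """
    stride_ns = stride_ps / PS_PER_NS
    if stride_ns <= 0:
        raise ValueError("stride must be > 0")
    if duration_ns < stride_ns:
        raise ValueError("duration must be >= stride")
    rng = np.random.default_rng(seed)
    # tolerance guards against floor(0.9999999) when duration/stride is
    # an exact multiple up to float rounding
    n_frames = int(np.floor(duration_ns / stride_ns + 1e-9)) + 1
    times = np.arange(n_frames) * stride_ns
    labels = _ctmc_on_grid(model.rate_matrix, times, rng, start_site)
    noise = _truncated_normal(rng, model.noise_sd, (n_frames, 3))
    coords = model.site_centers[labels] + noise
    traj = Trajectory(
        times=times,
        atoms=_gas_atoms(),
        coords=coords[:, None, :],
        provenance={
            "generator": "simulate_hopping_trajectory",
            "rng": _RNG_NAME,
            "seed": seed,
            "stride_ps": stride_ps,
            "duration_ns": duration_ns,
            "n_sites": model.n_sites,
        },
    )
    return traj, labels


def simulate_escape_events(model: EscapeModel, seed: int) -> EventTable:
    """Draw one exponential residence time per run, censoring at the cutoff."""
    rng = np.random.default_rng(seed)
    raw = rng.exponential(model.mean_residence, model.n_runs)
    censored = raw >= model.cutoff
    durations = np.where(censored, model.cutoff, raw)
    df = pd.DataFrame(
        {
            "run_id": np.arange(model.n_runs),
            "duration_ns": durations,
            "censored": censored,
        }
    )
    return EventTable(events=df, cutoff_ns=model.cutoff)


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap degrees into (−180, 180]."""
    w = np.mod(a, 360.0)
    w = np.where(w > 180.0, w - 360.0, w)
    return np.where(w == -180.0, 180.0, w)


def simulate_rotamer_series(
    model: RotamerModel,
    occupancy_series: np.ndarray,
    stride_ps: float = 50.0,
    seed: int = 0,
    replica_id: int = 0,
) -> RotamerSeries:
    """Simulate a χ1 series from the hidden two-state plus/trans chain.

    On each frame interval the chain propagates with the switch rates in
    effect for that frame (occupied vs unoccupied), using the exact
    two-state transition probability over the stride.  The emitted χ1 is
    the hidden mode angle plus von Mises noise, wrapped to (−180°, 180°].
    """
    occ = np.asarray(occupancy_series, dtype=bool)
    if occ.size == 0:
        raise ValueError("occupancy series is empty")
    rng = np.random.default_rng(seed)
    dt = stride_ps / PS_PER_NS
    plus_angle, trans_angle, _ = model.mode_angles
    rates_u = model.switch_rates
    rates_o = model.switch_rates_occupied or model.switch_rates

    n = occ.size
    # hidden state: 0 = plus, 1 = trans
    states = np.empty(n, dtype=int)
    # initialize from the stationary law of the first frame's rates
    k_pt, k_tp = rates_o if occ[0] else rates_u
    p_trans0 = k_pt / (k_pt + k_tp) if (k_pt + k_tp) > 0 else 0.5
    states[0] = int(rng.random() < p_trans0)
    u = rng.random(n - 1)
    for i in range(1, n):
        k_pt, k_tp = rates_o if occ[i] else rates_u
        total = k_pt + k_tp
        s = states[i - 1]
        if total == 0:
            states[i] = s
            continue
        # exact 2-state propagator over dt
        relax = 1.0 - np.exp(-total * dt)
        p_switch = (k_pt if s == 0 else k_tp) / total * relax
        states[i] = 1 - s if u[i - 1] < p_switch else s

    modes = np.where(states == 0, plus_angle, trans_angle)
    if np.isinf(model.concentration):
        chi1 = modes.astype(float)
    else:
        noise = np.degrees(rng.vonmises(0.0, model.concentration, n))
        chi1 = _wrap_angle(modes + noise)
    labels = np.where(states == 0, "plus", "trans")
    return RotamerSeries(
        times=np.arange(n) * dt, chi1=chi1, labels=labels, replica_id=replica_id
    )


def simulate_structure_jitter(
    structure: StructureModel,
    n_frames: int,
    jitter_sd: float | np.ndarray,
    stride_ps: float = 50.0,
    seed: int = 0,
    rototranslate: bool = True,
) -> Trajectory:
    """Thermal-jitter trajectory of a fixed structure.

    Each frame is the reference structure plus per-atom isotropic Gaussian
    displacement (``jitter_sd`` scalar or per-atom, Å), optionally followed
    by a random global rotation and translation.  The per-atom fluctuation
    amplitude is the known truth for superposition/RMSF validation.
    """
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    n_atoms = len(structure.names)
    sd = np.broadcast_to(np.asarray(jitter_sd, dtype=float), (n_atoms,))
    # jitter drawn for all frames first, so the per-atom noise realization
    # is identical with and without the global-motion overlay (same seed)
    coords = structure.coords[None] + rng.normal(
        0.0, 1.0, (n_frames, n_atoms, 3)
    ) * sd[None, :, None]
    if rototranslate:
        for f in range(n_frames):
            rot = Rotation.random(random_state=rng)
            frame = coords[f]
            coords[f] = rot.apply(frame - frame.mean(axis=0)) + rng.normal(0, 5.0, 3)
    atoms = pd.DataFrame(
        {
            "name": structure.names,
            "resname": structure.residues or ["UNK"] * n_atoms,
            "resnum": np.arange(1, n_atoms + 1),
            "chain": ["A"] * n_atoms,
        }
    )
    return Trajectory(
        times=np.arange(n_frames) * stride_ps / PS_PER_NS,
        atoms=atoms,
        coords=coords,
        provenance={
            "generator": "simulate_structure_jitter",
            "rng": _RNG_NAME,
            "seed": seed,
        },
    )


def _place_by_torsion(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Place atom d so that |c−d| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = torsion (natural extension reference frame)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = np.radians(angle_deg)
    phi = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_fixture_complex(phi: float, plane_offset: float) -> StructureModel:
    """Construct a ligand-ring + diatomic-gas fixture with exact geometry.

    A planar six-membered ring (atoms C1–C6, 1.40 Å bonds) lies in the
    z = 0 plane.  The gas atom O2 sits at the requested unsigned distance
    ``plane_offset`` below that plane, displaced in-plane away from the
    ring center so the C4–C2–O2 triplet is never colinear.  O1 is then
    placed (1.21 Å O–O bond, 120° bond angle) so that the dihedral
    Φ = (C4–C2–O2–O1) equals ``phi`` exactly.

    The geometry module applied to the fixture recovers ``phi`` within
    1e-6° and ``plane_offset`` within 1e-6 Å by construction.
    """
    if abs(phi) > 180.0:
        raise ValueError("phi must satisfy |phi| <= 180")
    r = 1.40
    ang = np.radians(np.arange(6) * 60.0)
    ring = np.column_stack([r * np.cos(ang), r * np.sin(ang), np.zeros(6)])
    names = [f"C{i + 1}" for i in range(6)]
    c2 = ring[1]
    c4 = ring[3]
    radial_out = c2 / np.linalg.norm(c2)
    o2 = c2 + 0.7 * radial_out + np.array([0.0, 0.0, -float(plane_offset)])
    o1 = _place_by_torsion(c4, c2, o2, bond=1.21, angle_deg=120.0, torsion_deg=phi)
    coords = np.vstack([ring, o2, o1])
    structure = StructureModel(
        names=names + ["O2", "O1"],
        coords=coords,
        residues=["MQO"] * 6 + ["OXY"] * 2,
        elements=["C"] * 6 + ["O"] * 2,
    )
    # construction self-check: the fixture must reproduce the request
    got = dihedral(c4, c2, o2, o1)
    err = (got - phi + 180.0) % 360.0 - 180.0
    assert abs(err) < 1e-6, f"fixture dihedral {got} != requested {phi}"
    return structure
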