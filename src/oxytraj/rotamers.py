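"""Side-chain χ1 rotamer analysis and superposition-based fluctuations.

The serine χ1 torsion (N–CA–CB–OG) clusters at three canonical modes:
plus (+60°), trans (180°) and minus (−60°).  This module computes χ1 per
frame, classifies angles into the three 120° sectors centered on those
modes, builds replica-averaged normalized histograms, conditions rotamer
fractions on a gas-occupancy series, and computes per-atom RMSF after
iterative least-squares superposition onto the mean structure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .synthgen import RotamerSeries, _wrap_angle
from .traj_io import Trajectory

__all__ = [
    "compute_chi1",
    "classify_rotamer",
    "rotamer_distribution",
    "conditional_rotamer_fractions",
    "superpose_and_rmsf",
]

STATES = ("plus", "trans", "minus")
CHI1_ATOMS = ("N", "CA", "CB", "OG")


def _dihedral_frames(p1, p2, p3, p4) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized signed dihedral over frames; returns (angles deg,
    defined mask).  Frames with a colinear triplet are flagged undefined
    rather than raising."""
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    defined = (np.linalg.norm(n1, axis=1) > 1e-12) & (np.linalg.norm(n2, axis=1) > 1e-12)
    b2n = b2 / np.maximum(np.linalg.norm(b2, axis=1, keepdims=True), 1e-300)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b2n)
    ang = np.degrees(np.arctan2(y, x))
    ang = np.where(ang <= -180.0, ang + 360.0, ang)
    return ang, defined


def compute_chi1(
    traj: Trajectory,
    resnum: int,
    chain: str | None = None,
    atom_names: tuple[str, str, str, str] = CHI1_ATOMS,
    replica_id: int = 0,
) -> RotamerSeries:
    """χ1 (N–CA–CB–OG by default) per frame for one residue.

    Returns an unlabelled :class:`RotamerSeries` (use
    :func:`classify_rotamer` on ``.chi1`` for state labels) in the IUPAC
    sign convention, range (−180°, 180°].  Per-frame degenerate geometry
    is flagged in ``.undefined`` with NaN angles.
    """
    sel = traj.atoms["resnum"].to_numpy() == resnum
    if chain is not None:
        sel &= traj.atoms["chain"].to_numpy() == chain
    idx = []
    for name in atom_names:
        hit = np.flatnonzero(sel & (traj.atoms["name"].to_numpy() == name))
        if hit.size == 0:
            raise KeyError(f"atom {name!r} of residue {resnum} not found")
        idx.append(int(hit[0]))
    p = [traj.coords[:, i, :] for i in idx]
    ang, defined = _dihedral_frames(*p)
    ang = np.where(defined, ang, np.nan)
    return RotamerSeries(
        times=traj.times, chi1=ang, labels=None, replica_id=replica_id,
        undefined=~defined,
    )


def classify_rotamer(chi1):
    """Classify χ1 (degrees) into plus / trans / minus.

    The circle is partitioned into three 120° sectors centered on the
    modes, half-open toward increasing angle: plus = [0°, 120°),
    trans = [120°, 240°) ≡ [120°, 180°] ∪ (−180°, −120°),
    minus = [240°, 360°) ≡ [−120°, 0°).  Classification is invariant under
    ±360° shifts.  Scalars in, scalar out; arrays in, array out.
    """
    a = np.asarray(chi1, dtype=float)
    if np.any(~np.isfinite(a)):
        raise ValueError("non-finite angle")
    w = np.mod(a, 360.0)
    out = np.where(w < 120.0, "plus", np.where(w < 240.0, "trans", "minus"))
    return out.item() if np.isscalar(chi1) else out


def rotamer_distribution(
    series_list: list[RotamerSeries], bin_width: float = 5.0
) -> pd.DataFrame:
    """Replica-averaged normalized χ1 histogram.

    Each replica's histogram is normalized to unit mass, then averaged;
    the per-bin spread across replicas is the population s.d. (ddof = 0,
    i.e. s.d. over the replicas actually run).  Both per-bin probability
    mass and probability density (mass / bin width in degrees) are
    reported, since "normalized distribution" can mean either.
    """
    if not series_list:
        raise ValueError("at least one replica series is required")
    if not 360.0 / bin_width == int(360.0 / bin_width):
        raise ValueError("bin width must divide 360")
    edges = np.arange(-180.0, 180.0 + bin_width / 2, bin_width)
    masses = []
    for s in series_list:
        chi = s.chi1[np.isfinite(s.chi1)]
        if chi.size == 0:
            raise ValueError(f"replica {s.replica_id} has no defined angles")
        # 180 is included in the last bin by the (−180, 180] convention
        h, _ = np.histogram(np.clip(chi, -180.0, 180.0 - 1e-12), bins=edges)
        masses.append(h / h.sum())
    m = np.array(masses)
    return pd.DataFrame(
        {
            "bin_left_deg": edges[:-1],
            "bin_right_deg": edges[1:],
            "mean_mass": m.mean(axis=0),
            "sd_mass": m.std(axis=0, ddof=0),
            "mean_density_per_deg": m.mean(axis=0) / bin_width,
            "sd_density_per_deg": m.std(axis=0, ddof=0) / bin_width,
        }
    )


def state_fractions(chi1: np.ndarray) -> dict[str, float]:
    """Fraction of frames in each rotamer state."""
    chi = np.asarray(chi1, dtype=float)
    chi = chi[np.isfinite(chi)]
    if chi.size == 0:
        return {s: float("nan") for s in STATES}
    labels = classify_rotamer(chi)
    return {s: float(np.mean(labels == s)) for s in STATES}


def conditional_rotamer_fractions(
    series: RotamerSeries, occupancy_series: np.ndarray
) -> pd.DataFrame:
    """Rotamer-state fractions conditioned on gas occupancy.

    Rows ``occupied`` / ``unoccupied`` give the plus/trans/minus fractions
    over frames where the gas does / does not occupy the coupled region
    (NaN when a condition has no frames), plus the frame counts.
    """
    occ = np.asarray(occupancy_series, dtype=bool)
    if occ.size != series.chi1.size:
        raise ValueError(
            f"occupancy length {occ.size} does not match series length "
            f"{series.chi1.size}"
        )
    rows = {}
    for name, mask in (("occupied", occ), ("unoccupied", ~occ)):
        fr = state_fractions(series.chi1[mask])
        fr["n_frames"] = int(mask.sum())
        rows[name] = fr
    return pd.DataFrame.from_dict(rows, orient="index")


def superpose_and_rmsf(
    traj: Trajectory,
    selection: np.ndarray | list[int] | None = None,
    max_iter: int = 10,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Per-atom RMSF (Å) after iterative superposition onto the mean.

    Each frame is rigid-body superposed (optimal least-squares rotation +
    translation, Kabsch) onto the mean structure of the selected atoms;
    the mean is recomputed and the procedure iterated until the reference
    shifts by less than ``tol`` Å (at most ``max_iter`` rounds) — the
    self-consistent "average structure".  RMSF is the root-mean-square
    deviation of each selected atom from its mean position.

    ``selection``: atom indices (default: all atoms, e.g. pass the Cα
    indices for a backbone-fluctuation profile).
    """
    if traj.n_frames < 2:
        raise ValueError("at least two frames are required")
    sel = np.arange(traj.n_atoms) if selection is None else np.asarray(selection, int)
    if sel.size < 3:
        raise ValueError("at least three atoms are required for superposition")
    x = traj.coords[:, sel, :].copy()
    spread = np.linalg.norm(x[0] - x[0].mean(axis=0), axis=1)
    if np.count_nonzero(spread > 1e-9) < 2:
        raise ValueError("degenerate (coincident) selection")

    ref = x[0] - x[0].mean(axis=0)
    for _ in range(max_iter):
        aligned = np.empty_like(x)
        for f in range(x.shape[0]):
            frame = x[f] - x[f].mean(axis=0)
            rot, _ = Rotation.align_vectors(ref, frame)
            aligned[f] = rot.apply(frame)
        new_ref = aligned.mean(axis=0)
        shift = float(np.max(np.linalg.norm(new_ref - ref, axis=1)))
        ref = new_ref
        x = aligned
        if shift < tol:
            break

    rmsf = np.sqrt(np.mean(np.sum((x - ref) ** 2, axis=2), axis=0))
    at = traj.atoms.iloc[sel]
    return pd.DataFrame(
        {
            "chain": at["chain"].to_numpy(),
            "resnum": at["resnum"].to_numpy(),
            "name": at["name"].to_numpy(),
            "rmsf_A": rmsf,
        }
    )
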