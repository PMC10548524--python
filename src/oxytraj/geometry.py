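"""Structure-level geometric descriptors.

Signed dihedral angles (crystallographic/IUPAC convention), distances to a
least-squares ring plane, and contact-shell queries around a chosen atom.
These are the primitives used to characterise how a diatomic gas molecule
sits against an aromatic ligand: the orientation dihedral Φ(C4–C2–O2–O1),
the gas-to-ring-plane distance, and the set of protein atoms lining a
hydrophobic pocket within a given distance band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StructureModel",
    "dihedral",
    "plane_distance",
    "contact_shell",
]


@dataclass
class StructureModel:
    """A single-conformer labelled structure.

    Parameters
    ----------
    names : per-atom atom names (unique identifiers within the model).
    coords : (n_atoms, 3) array, Å.
    residues : optional per-atom residue names.
    elements : optional per-atom element symbols.
    """

    names: list[str]
    coords: np.ndarray
    residues: list[str] | None = None
    elements: list[str] | None = None
    occupancies: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.names), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.names)} atom names"
            )
        if len(set(self.names)) != len(self.names):
            raise ValueError("atom names must be unique within a model")

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"no atom named {name!r} in structure") from None


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle p1–p2–p3–p4 in degrees, range (−180, 180].

    IUPAC sign convention: looking down the p2→p3 axis, the angle is
    positive when the far bond (p3→p4) is rotated clockwise from the near
    bond (p2→p1).

    Raises
    ------
    ValueError
        If consecutive points coincide or either bonded triplet is
        colinear (the dihedral is then undefined).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for a, b in ((p1, p2), (p2, p3), (p3, p4)):
        if np.allclose(a, b):
            raise ValueError("consecutive points coincide; dihedral undefined")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise ValueError("colinear triplet; dihedral undefined")
    # atan2 form is numerically stable near 0 and 180 degrees
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def plane_distance(point, ring_atoms) -> float:
    """Unsigned distance (Å) from ``point`` to the least-squares plane of
    ``ring_atoms`` (≥3 non-colinear points).

    The plane is the total-least-squares fit: it passes through the ring
    centroid with normal given by the smallest principal axis of the ring
    coordinates, so puckered rings are handled the way a crystallographic
    "molecular plane" is.
    """
    point = np.asarray(point, dtype=float)
    ring = np.asarray(ring_atoms, dtype=float)
    if ring.ndim != 2 or ring.shape[0] < 3 or ring.shape[1] != 3:
        raise ValueError("ring_atoms must be an (n>=3, 3) array")
    centroid = ring.mean(axis=0)
    centered = ring - centroid
    # normal = singular vector of the smallest singular value
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-10:
        raise ValueError("ring atoms are colinear; plane undefined")
    normal = vt[2]
    return float(abs(np.dot(point - centroid, normal)))


def contact_shell(
    structure: StructureModel,
    center_atom: str,
    r_min: float,
    r_max: float,
) -> list[tuple[str, float]]:
    """Atoms of ``structure`` with r_min ≤ d ≤ r_max from ``center_atom``.

    The center atom itself is excluded. Returns (atom name, distance Å)
    pairs sorted by distance, ties broken by atom name.
    """
    if r_min < 0 or r_max < r_min:
        raise ValueError("require 0 <= r_min <= r_max")
    ci = structure.index_of(center_atom)
    center = structure.coords[ci]
    d = np.linalg.norm(structure.coords - center, axis=1)
    hits = [
        (structure.names[i], float(d[i]))
        for i in range(len(structure.names))
        if i != ci and r_min <= d[i] <= r_max
    ]
    hits.sort(key=lambda t: (t[1], t[0]))
    return hits
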