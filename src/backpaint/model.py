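"""Backbone model representation and derived quantities.

A protein backbone is held as an ordered list of residues, each mapping
atom names (N, CA, C, O, optionally CB plus any passed-through atoms) to
coordinates in Angstrom.  Torsions phi/psi/omega are derived quantities,
computed on demand; entries that are undefined at chain termini are NaN.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
from scipy.spatial import cKDTree

from .geometry import InternalCoordinate, dihedral, nerf

__all__ = [
    "IdealGeometry",
    "Residue",
    "BackboneChain",
    "Contact",
    "extract_torsions",
    "ramachandran_class",
    "environment_distances",
    "RAMACHANDRAN_BOXES",
    "DEFAULT_CONTACT_CUTOFF",
]

BACKBONE_ATOMS = ("N", "CA", "C")


@dataclass(frozen=True)
class IdealGeometry:
    """Ideal covalent backbone geometry (restraint-dictionary standard
    values), used whenever this package builds atoms itself.

    Lengths in Angstrom, angles in degrees.  ``omega`` is the peptide-bond
    torsion enforced between consecutive residues (180 = trans).
    """

    n_ca: float = 1.458
    ca_c: float = 1.525
    c_n: float = 1.329
    c_n_ca: float = 121.7
    n_ca_c: float = 111.2
    ca_c_n: float = 116.2
    omega: float = 180.0
    # carbonyl oxygen, needed for valid PDB output
    c_o: float = 1.231
    ca_c_o: float = 120.8

    def __post_init__(self):
        for name in ("n_ca", "ca_c", "c_n", "c_o"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Residue:
    """One amino-acid residue: sequence id, chain id, 3-letter name and an
    atom-name -> coordinate map.  Must contain at least N, CA and C."""

    seq_id: int
    chain_id: str = "A"
    name: str = "ALA"
    atoms: dict[str, np.ndarray] = field(default_factory=dict)
    elements: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.atoms = {k: np.asarray(v, dtype=float) for k, v in self.atoms.items()}

    def __getitem__(self, atom_name: str) -> np.ndarray:
        return self.atoms[atom_name]

    def has_backbone(self) -> bool:
        return all(a in self.atoms for a in BACKBONE_ATOMS)

    def copy(self) -> "Residue":
        return Residue(
            self.seq_id,
            self.chain_id,
            self.name,
            {k: v.copy() for k, v in self.atoms.items()},
            dict(self.elements),
        )


class Torsions(NamedTuple):
    phi: float
    psi: float
    omega: float


@dataclass
class BackboneChain:
    """An ordered chain of residues with strictly increasing seq_ids."""

    residues: list[Residue] = field(default_factory=list)
    chain_id: str = "A"

    def __post_init__(self):
        ids = [r.seq_id for r in self.residues]
        if any(b <= a for a, b in zip(ids, ids[1:])):
            raise ValueError("residue seq_ids must be strictly increasing")

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, i: int) -> Residue:
        return self.residues[i]

    def __iter__(self):
        return iter(self.residues)

    def ca_positions(self) -> np.ndarray:
        return np.array([r["CA"] for r in self.residues], dtype=float)

    def copy(self) -> "BackboneChain":
        return BackboneChain([r.copy() for r in self.residues], self.chain_id)

    @property
    def torsions(self) -> list[Torsions]:
        return extract_torsions(self)


def extract_torsions(chain: BackboneChain) -> list[Torsions]:
    """Per-residue (phi, psi, omega), NaN where undefined.

    phi_i = dihedral(C_{i-1}, N_i, CA_i, C_i);
    psi_i = dihedral(N_i, CA_i, C_i, N_{i+1});
    omega_i = dihedral(CA_i, C_i, N_{i+1}, CA_{i+1}).
    The first residue has no phi; the last has no psi/omega.
    """
    out = []
    res = chain.residues
    for i, r in enumerate(res):
        phi = psi = omega = float("nan")
        if i > 0 and "C" in res[i - 1].atoms:
            phi = dihedral(res[i - 1]["C"], r["N"], r["CA"], r["C"])
        if i + 1 < len(res) and "N" in res[i + 1].atoms:
            psi = dihedral(r["N"], r["CA"], r["C"], res[i + 1]["N"])
            omega = dihedral(r["CA"], r["C"], res[i + 1]["N"], res[i + 1]["CA"])
        out.append(Torsions(phi, psi, omega))
    return out


# Rectangular Ramachandran regions, (phi_range, psi_range) in degrees.
# Deliberately coarse; swappable for contour tables by editing this map.
RAMACHANDRAN_BOXES: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "alpha": ((-100.0, -30.0), (-80.0, 0.0)),
    "beta": ((-180.0, -60.0), (90.0, 180.0)),
    "left_alpha": ((30.0, 100.0), (0.0, 80.0)),
}


def ramachandran_class(phi: float, psi: float) -> str:
    """Classify a (phi, psi) pair into alpha | beta | left_alpha | other.

    NaN input (undefined torsion, e.g. at a terminus) -> "undefined".
    """
    if phi is None or psi is None or np.isnan(phi) or np.isnan(psi):
        return "undefined"

    def inside(x, lo, hi):
        # angles are periodic: +180 must match a box edge at -180
        return any(lo <= y <= hi for y in (x, x - 360.0, x + 360.0))

    for label, ((p0, p1), (s0, s1)) in RAMACHANDRAN_BOXES.items():
        if inside(phi, p0, p1) and inside(psi, s0, s1):
            return label
    return "other"


class Contact(NamedTuple):
    """A short inter-residue atom-atom distance ("environment distance")."""

    atom_a: tuple[int, str]  # (seq_id, atom name) in the query residue
    atom_b: tuple[int, str]
    distance: float


DEFAULT_CONTACT_CUTOFF = 3.9  # Angstrom


def environment_distances(
    chains: Iterable[BackboneChain],
    residue: tuple[str, int],
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> list[Contact]:
    """All atom pairs within ``cutoff`` linking the query residue to any
    other residue, sorted ascending by distance.

    ``residue`` is a (chain_id, seq_id) pair.  Raises KeyError when the
    residue does not exist.
    """
    chains = list(chains)
    chain_id, seq_id = residue
    query = None
    for ch in chains:
        for r in ch:
            if r.chain_id == chain_id and r.seq_id == seq_id:
                query = r
    if query is None:
        raise KeyError(f"residue {chain_id}/{seq_id} not found")

    other_pos, other_ref = [], []
    for ch in chains:
        for r in ch:
            if r is query:
                continue
            for name, p in r.atoms.items():
                other_pos.append(p)
                other_ref.append((r.seq_id, name))
    if not other_pos:
        return []
    tree = cKDTree(np.asarray(other_pos))
    contacts = []
    for name, p in query.atoms.items():
        for j in tree.query_ball_point(p, cutoff):
            d = float(np.linalg.norm(np.asarray(other_pos[j]) - p))
            contacts.append(Contact((seq_id, name), other_ref[j], d))
    contacts.sort(key=lambda c: (c.distance, c.atom_a, c.atom_b))
    return contacts


# ---------------------------------------------------------------------------
# Residue placement helpers shared by the chain builder and the painter.
# Atom order along the chain is N1 CA1 C1 | N2 CA2 C2 | ...; psi_i places
# N_{i+1}, omega places CA_{i+1}, phi_{i+1} places C_{i+1}, and the carbonyl
# O_i sits in the amide plane trans to N_{i+1} (torsion psi_i + 180).


def wrap_angle(a):
    """Wrap degrees into (-180, 180]."""
    a = np.asarray(a, dtype=float)
    w = -((-a + 180.0) % 360.0 - 180.0)
    w = np.where(w == -180.0, 180.0, w)
    return float(w) if w.ndim == 0 else w


def place_c(ref, n, ca, phi: float, geom: IdealGeometry) -> np.ndarray:
    """Place a residue's carbonyl C from its N, CA and the phi reference
    atom (previous C, or a virtual reference for the first residue)."""
    return nerf(ref, n, ca, geom.ca_c, geom.n_ca_c, phi)


def place_next_n(n, ca, c, psi: float, geom: IdealGeometry) -> np.ndarray:
    return nerf(n, ca, c, geom.c_n, geom.ca_c_n, psi)


def place_next_ca(ca, c, n_next, geom: IdealGeometry) -> np.ndarray:
    return nerf(ca, c, n_next, geom.n_ca, geom.c_n_ca, geom.omega)


def place_o(n, ca, c, psi: float, geom: IdealGeometry) -> np.ndarray:
    return nerf(n, ca, c, geom.c_o, geom.ca_c_o, wrap_angle(psi + 180.0))
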