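"""Geometric selection volumes: spheres, chain ranges, and the clipping
frustum with its linked corner-handle update rules.

The frustum is a truncated square-based pyramid whose apex is the eye;
the truncation (the near plane) is the front clipping plane.  Its four
near-plane corner handles are linked: dragging one corner sideways drags
the vertically adjacent corner with it and mirrors the horizontally
opposite pair, keeping a vertical line of symmetry; dragging towards or
away from the eye translates the whole slab.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple

import numpy as np

from .model import BackboneChain

__all__ = [
    "AtomRef",
    "SphereSelection",
    "ChainRangeSelection",
    "ClipFrustum",
    "select_sphere",
    "select_sphere_residues",
    "select_chain_range",
    "frustum_contains",
    "move_corner",
]

CORNERS = ("TL", "TR", "BL", "BR")
_MIN_NEAR = 1e-6  # Angstrom; the apex itself is never a valid near plane


class AtomRef(NamedTuple):
    chain_id: str
    seq_id: int
    atom_name: str


@dataclass(frozen=True)
class SphereSelection:
    """Closed ball of ``radius`` Angstrom about ``center``."""

    center: np.ndarray
    radius: float

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if not self.radius > 0:
            raise ValueError("radius must be positive")


@dataclass(frozen=True)
class ChainRangeSelection:
    """Inclusive residue interval on one chain, normalized start <= end."""

    chain_id: str
    start_seq_id: int
    end_seq_id: int

    def __post_init__(self):
        if self.start_seq_id > self.end_seq_id:
            object.__setattr__(self, "start_seq_id", self.end_seq_id)
            object.__setattr__(self, "end_seq_id", self.start_seq_id)

    def to_selection_string(self) -> str:
        """Coot-style atom-selection string, e.g. ``//A/5-12``."""
        return f"//{self.chain_id}/{self.start_seq_id}-{self.end_seq_id}"

    @classmethod
    def from_selection_string(cls, s: str) -> "ChainRangeSelection":
        parts = s.strip().lstrip("/").split("/")
        if len(parts) != 2 or "-" not in parts[1]:
            raise ValueError(f"cannot parse selection string {s!r}")
        lo, hi = parts[1].split("-")
        return cls(parts[0], int(lo), int(hi))


def select_sphere(
    chains: Iterable[BackboneChain], sel: SphereSelection
) -> set[AtomRef]:
    """Atoms with |p - center| <= radius (closed ball)."""
    out = set()
    for ch in chains:
        for res in ch:
            for name, p in res.atoms.items():
                if np.linalg.norm(p - sel.center) <= sel.radius:
                    out.add(AtomRef(res.chain_id, res.seq_id, name))
    return out


def select_sphere_residues(
    chains: Iterable[BackboneChain], sel: SphereSelection
) -> set[tuple[str, int]]:
    """Residue-granular variant: residues with >= 1 atom inside."""
    return {(r.chain_id, r.seq_id) for r in _hit_residues(chains, sel)}


def _hit_residues(chains, sel):
    for ch in chains:
        for res in ch:
            if any(
                np.linalg.norm(p - sel.center) <= sel.radius
                for p in res.atoms.values()
            ):
                yield res


def select_chain_range(
    chains: Iterable[BackboneChain], pick_a, pick_b
) -> ChainRangeSelection:
    """Residue interval between the residues whose CA atoms are nearest to
    the two pick points.  Raises when the picks resolve to different
    chains."""
    pick_a = np.asarray(pick_a, dtype=float)
    pick_b = np.asarray(pick_b, dtype=float)

    def nearest(p):
        best = None
        for ch in chains:
            for res in ch:
                d = np.linalg.norm(res["CA"] - p)
                if best is None or d < best[0]:
                    best = (d, res.chain_id, res.seq_id)
        if best is None:
            raise ValueError("no residues to select from")
        return best

    _, ch_a, seq_a = nearest(pick_a)
    _, ch_b, seq_b = nearest(pick_b)
    if ch_a != ch_b:
        raise ValueError(
            f"pick points resolve to different chains ({ch_a!r} vs {ch_b!r})"
        )
    return ChainRangeSelection(ch_a, min(seq_a, seq_b), max(seq_a, seq_b))


@dataclass(frozen=True)
class ClipFrustum:
    """Truncated viewing pyramid.

    ``view`` rows are the (right, up, forward) unit vectors; depths are
    measured from ``eye`` along forward.  ``corners`` maps TL/TR/BL/BR to
    (right, up) offsets of the near-plane rectangle, kept symmetric about
    the vertical axis with horizontal top and bottom edges.
    """

    eye: np.ndarray
    view: np.ndarray
    near_depth: float
    far_depth: float
    corners: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "TL": (-1.0, 1.0),
            "TR": (1.0, 1.0),
            "BL": (-1.0, -1.0),
            "BR": (1.0, -1.0),
        }
    )

    def __post_init__(self):
        object.__setattr__(self, "eye", np.asarray(self.eye, dtype=float))
        V = np.asarray(self.view, dtype=float)
        if V.shape != (3, 3) or np.abs(V @ V.T - np.eye(3)).max() > 1e-9:
            raise ValueError("view must be a 3x3 orthonormal frame")
        object.__setattr__(self, "view", V)
        if not 0 < self.near_depth < self.far_depth:
            raise ValueError("need 0 < near_depth < far_depth")
        c = {k: (float(r), float(u)) for k, (r, u) in self.corners.items()}
        if set(c) != set(CORNERS):
            raise ValueError(f"corners must be exactly {CORNERS}")
        sym = (
            c["TL"][0] == -c["TR"][0]
            and c["BL"][0] == -c["BR"][0]
            and c["TR"][0] == c["BR"][0]
            and c["TL"][1] == c["TR"][1]
            and c["BL"][1] == c["BR"][1]
        )
        if not sym:
            raise ValueError("corner rectangle violates the symmetry invariant")
        if not (c["TR"][0] > 0 and c["BR"][0] > 0 and c["TL"][1] > c["BL"][1]):
            raise ValueError("degenerate near rectangle")
        object.__setattr__(self, "corners", c)

    @property
    def right(self) -> np.ndarray:
        return self.view[0]

    @property
    def up(self) -> np.ndarray:
        return self.view[1]

    @property
    def forward(self) -> np.ndarray:
        return self.view[2]

    def with_thickness(self, thickness: float) -> "ClipFrustum":
        """Explicit slab-thickness setter (far = near + thickness)."""
        if not thickness > 0:
            raise ValueError("thickness must be positive")
        return replace(self, far_depth=self.near_depth + thickness)


def frustum_contains(f: ClipFrustum, points) -> np.ndarray | bool:
    """Closed containment test; accepts one point or an (n, 3) array.

    A point is inside when its depth lies in [near, far] and its lateral
    (right, up) coordinates lie within the near rectangle scaled linearly
    with depth from the apex.
    """
    p = np.asarray(points, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p) - f.eye
    depth = p @ f.forward
    r = p @ f.right
    u = p @ f.up
    w = f.corners["TR"][0]
    u_top = f.corners["TL"][1]
    u_bot = f.corners["BL"][1]
    scale = depth / f.near_depth
    ok = (
        (depth >= f.near_depth)
        & (depth <= f.far_depth)
        & (r >= -w * scale)
        & (r <= w * scale)
        & (u >= u_bot * scale)
        & (u <= u_top * scale)
    )
    return bool(ok[0]) if single else ok


def move_corner(
    f: ClipFrustum, corner_id: str, delta: tuple[float, float, float]
) -> tuple[ClipFrustum, bool]:
    """Drag a corner handle by (right, up, forward) Angstrom.

    Sideways: the vertically adjacent corner follows, the horizontally
    opposite pair mirrors (vertical symmetry is preserved exactly).
    Up/down: the horizontally adjacent corner follows (edges stay
    horizontal).  Forward: the whole slab translates (near and far move
    together); returns (frustum, clamped) where ``clamped`` reports that
    the near plane was limited to stay in front of the eye.
    """
    if corner_id not in CORNERS:
        raise ValueError(f"unknown corner {corner_id!r}")
    dr, du, df = (float(x) for x in delta)
    c = {k: list(v) for k, v in f.corners.items()}
    clamped = False

    col = "L" if corner_id.endswith("L") else "R"
    row = corner_id[0]  # T or B
    # horizontal: grabbed + vertically adjacent take the new right value,
    # the other column mirrors it; a drag past the symmetry axis is
    # clamped so the rectangle never degenerates or flips
    new_r = c[corner_id][0] + dr
    limit = _MIN_NEAR if col == "R" else -_MIN_NEAR
    if (col == "R" and new_r < limit) or (col == "L" and new_r > limit):
        new_r = limit
        clamped = True
    for r_ in ("T", "B"):
        c[r_ + col][0] = new_r
        c[r_ + ("R" if col == "L" else "L")][0] = -new_r
    # vertical: grabbed + horizontally adjacent take the new up value;
    # the top edge may not cross below the bottom edge
    new_u = c[corner_id][1] + du
    if row == "T" and new_u <= c["BL"][1]:
        new_u = c["BL"][1] + _MIN_NEAR
        clamped = True
    elif row == "B" and new_u >= c["TL"][1]:
        new_u = c["TL"][1] - _MIN_NEAR
        clamped = True
    for col_ in ("L", "R"):
        c[row + col_][1] = new_u

    near = f.near_depth + df
    far = f.far_depth + df
    if near < _MIN_NEAR:
        shift = _MIN_NEAR - near
        near += shift
        far += shift
        clamped = True
    corners = {k: (v[0], v[1]) for k, v in c.items()}
    return replace(f, near_depth=near, far_depth=far, corners=corners), clamped
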