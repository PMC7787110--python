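"""Frame and torsion mathematics.

Dihedral angles follow the IUPAC sign convention: looking down the b->c
axis, the torsion is the signed angle from the a-b bond to the c-d bond,
positive clockwise (right-handed about b->c), with cis = 0 deg and
trans = 180 deg.  All public angles are in degrees; radians are used only
inside function bodies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InternalCoordinate",
    "RigidTransform",
    "dihedral",
    "bond_angle",
    "place_atom",
    "nerf",
    "rotation_about_axis",
]

_COLLINEAR_TOL = 1e-12


def _as_vec3(p) -> np.ndarray:
    v = np.asarray(p, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite coordinates")
    return v


def dihedral(a, b, c, d) -> float:
    """Signed torsion angle a-b-c-d about the b->c axis, in (-180, 180].

    Raises ValueError when b == c or either atom triple is collinear
    (the torsion is undefined there, never silently NaN).
    """
    a, b, c, d = (_as_vec3(p) for p in (a, b, c, d))
    b0 = a - b
    b1 = c - b
    b2 = d - c
    nb1 = np.linalg.norm(b1)
    if nb1 < _COLLINEAR_TOL:
        raise ValueError("dihedral undefined: b and c coincide")
    b1 = b1 / nb1
    # components perpendicular to the axis
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    if np.linalg.norm(v) < _COLLINEAR_TOL or np.linalg.norm(w) < _COLLINEAR_TOL:
        raise ValueError("dihedral undefined: collinear atom triple")
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = np.degrees(np.arctan2(y, x))
    # atan2 returns (-180, 180]; map -180 exactly to +180 for the convention
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def bond_angle(a, b, c) -> float:
    """Angle a-b-c at vertex b, degrees in [0, 180]."""
    a, b, c = (_as_vec3(p) for p in (a, b, c))
    u = a - b
    v = c - b
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu < _COLLINEAR_TOL or nv < _COLLINEAR_TOL:
        raise ValueError("bond angle undefined: coincident atoms")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


@dataclass(frozen=True)
class InternalCoordinate:
    """A (bond length, bond angle, torsion) triple for NeRF placement.

    bond_length in Angstrom, bond_angle in degrees in (0, 180),
    torsion in degrees in (-180, 180].
    """

    bond_length: float
    bond_angle: float
    torsion: float

    def __post_init__(self):
        if not self.bond_length > 0:
            raise ValueError("bond_length must be positive")
        if not 0 < self.bond_angle < 180:
            raise ValueError("bond_angle must be in (0, 180) degrees")
        if not -180 < self.torsion <= 180:
            raise ValueError("torsion must be in (-180, 180] degrees")


def nerf(a, b, c, bond_length, bond_angle, torsion):
    """Vectorised internal->Cartesian placement (natural extension
    reference frame).

    Places point(s) d such that |d-c| = bond_length, angle(b,c,d) =
    bond_angle and dihedral(a,b,c,d) = torsion.  Every argument may be a
    single value or a broadcastable array (reference atoms with shape
    (..., 3)); the result has the broadcast shape + (3,).  Angles in
    degrees.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    if a.shape[-1:] != (3,) or b.shape[-1:] != (3,) or c.shape[-1:] != (3,):
        raise ValueError("reference atoms must have trailing dimension 3")
    bc = c - b
    nbc = np.linalg.norm(bc, axis=-1, keepdims=True)
    if np.any(nbc < _COLLINEAR_TOL):
        raise ValueError("placement frame degenerate: b == c")
    bc = bc / nbc
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n, axis=-1, keepdims=True)
    if np.any(nn < _COLLINEAR_TOL):
        raise ValueError("placement frame degenerate: a, b, c collinear")
    n = n / nn
    m = np.cross(n, bc)

    L = np.asarray(bond_length, dtype=float)
    theta = np.radians(np.asarray(bond_angle, dtype=float))
    tau = np.radians(np.asarray(torsion, dtype=float))
    x = -L * np.cos(theta)
    y = L * np.sin(theta) * np.cos(tau)
    z = L * np.sin(theta) * np.sin(tau)
    return (
        c
        + x[..., None] * bc
        + y[..., None] * m
        + z[..., None] * n
    )


def place_atom(a, b, c, ic: InternalCoordinate) -> np.ndarray:
    """Place a fourth atom from three reference atoms and an
    :class:`InternalCoordinate`.  Scalar convenience over :func:`nerf`."""
    return nerf(a, b, c, ic.bond_length, ic.bond_angle, ic.torsion)


def rotation_about_axis(axis, angle_deg) -> np.ndarray:
    """Rodrigues rotation matrix about ``axis`` (need not be unit length)."""
    axis = _as_vec3(axis)
    n = np.linalg.norm(axis)
    if n < _COLLINEAR_TOL:
        raise ValueError("rotation axis has zero length")
    k = axis / n
    t = np.radians(float(angle_deg))
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


@dataclass(frozen=True)
class RigidTransform:
    """Rotation + translation, optionally with a uniform positive scale.

    Acts on points as ``p -> scale * R @ p + t``.  With ``scale == 1`` this
    is a proper rigid motion; the rotation is validated to be orthonormal
    with determinant +1.
    """

    rotation: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: float = 1.0

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be a 3x3 matrix")
        if t.shape != (3,):
            raise ValueError("translation must be a 3-vector")
        if not self.scale > 0:
            raise ValueError("scale must be positive")
        err = np.abs(R @ R.T - np.eye(3)).max()
        if err > 1e-9:
            raise ValueError(f"rotation not orthonormal (max dev {err:.2e})")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has determinant -1 (reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        object.__setattr__(self, "scale", float(self.scale))

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), 1.0)

    @classmethod
    def from_rotation_about(cls, axis, angle_deg, center=None) -> "RigidTransform":
        """Rotation about an axis through ``center`` (origin by default)."""
        R = rotation_about_axis(axis, angle_deg)
        if center is None:
            return cls(R, np.zeros(3))
        c = _as_vec3(center)
        return cls(R, c - R @ c)

    @classmethod
    def scaling_about(cls, center, scale: float) -> "RigidTransform":
        """Pure uniform scaling with ``center`` as fixed point."""
        c = _as_vec3(center)
        return cls(np.eye(3), c - scale * c, scale)

    def apply(self, points) -> np.ndarray:
        """Apply to a point (3,) or point array (..., 3)."""
        p = np.asarray(points, dtype=float)
        return self.scale * (p @ self.rotation.T) + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self.compose(other)).apply(p) ==
        self.apply(other.apply(p))."""
        R = self.rotation @ other.rotation
        # re-orthonormalize to keep long compositions within tolerance
        u, _, vt = np.linalg.svd(R)
        R = u @ vt
        t = self.scale * (self.rotation @ other.translation) + self.translation
        return RigidTransform(R, t, self.scale * other.scale)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        s = 1.0 / self.scale
        return RigidTransform(Rinv, -s * (Rinv @ self.translation), s)
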