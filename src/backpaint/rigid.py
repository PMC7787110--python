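"""Rigid (and grab/scale) motion of atom selections.

The grab algebra: when a hand holding the model moves from pose P_old to
P_new, the model must move by T = P_new . P_old^-1 so that it stays fixed
in the hand's frame.  Two-hand grabbing additionally scales by the ratio
of inter-hand distances, with the right hand as the fixed point of the
scaling; scale acts on the view, never on coordinates written to file.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .geometry import RigidTransform, rotation_about_axis
from .model import BackboneChain
from .selection import (
    AtomRef,
    ChainRangeSelection,
    SphereSelection,
    select_sphere,
)

__all__ = ["HandPose", "apply_rigid", "grab_transform", "two_hand_transform", "resolve_selection"]


@dataclass(frozen=True)
class HandPose:
    """Position + orientation of one hand controller."""

    position: np.ndarray
    orientation: np.ndarray  # 3x3 orthonormal, det +1

    def __post_init__(self):
        p = np.asarray(self.position, dtype=float)
        R = np.asarray(self.orientation, dtype=float)
        if p.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if R.shape != (3, 3) or np.abs(R @ R.T - np.eye(3)).max() > 1e-9:
            raise ValueError("orientation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("orientation must be a proper rotation")
        object.__setattr__(self, "position", p)
        object.__setattr__(self, "orientation", R)

    def as_transform(self) -> RigidTransform:
        return RigidTransform(self.orientation, self.position)


def resolve_selection(
    chains: Iterable[BackboneChain],
    selection,
) -> set[AtomRef]:
    """Expand a selection object into concrete atom references.

    Accepts a :class:`SphereSelection`, a :class:`ChainRangeSelection`,
    or an explicit iterable of :class:`AtomRef`.
    """
    chains = list(chains)
    if isinstance(selection, SphereSelection):
        return select_sphere(chains, selection)
    if isinstance(selection, ChainRangeSelection):
        refs = set()
        for ch in chains:
            for res in ch:
                if (
                    res.chain_id == selection.chain_id
                    and selection.start_seq_id <= res.seq_id <= selection.end_seq_id
                ):
                    refs.update(
                        AtomRef(res.chain_id, res.seq_id, a) for a in res.atoms
                    )
        return refs
    return {AtomRef(*r) for r in selection}


def apply_rigid(
    chains: Iterable[BackboneChain],
    selection,
    t: RigidTransform,
) -> list[BackboneChain]:
    """Transform the selected atoms by ``t``; every other atom is carried
    over bit-identically.  ``t`` must be rigid (scale 1); an empty
    selection is an error."""
    if t.scale != 1.0:
        raise ValueError("apply_rigid requires scale == 1 (coordinates stay in Angstrom)")
    chains = list(chains)
    refs = resolve_selection(chains, selection)
    if not refs:
        raise ValueError("selection resolves to no atoms")
    out = []
    for ch in chains:
        new = ch.copy()
        for res in new:
            for name in res.atoms:
                if AtomRef(res.chain_id, res.seq_id, name) in refs:
                    res.atoms[name] = t.apply(res.atoms[name])
        out.append(new)
    return out


def grab_transform(old: HandPose, new: HandPose) -> RigidTransform:
    """Model transform keeping the model fixed in the moving hand's frame:
    T = pose(new) . pose(old)^-1."""
    return new.as_transform().compose(old.as_transform().inverse())


def _twist_angle(M: np.ndarray, axis: np.ndarray) -> float:
    """Signed rotation angle of M about ``axis`` (the twist component of
    the swing-twist decomposition), degrees."""
    a = axis / np.linalg.norm(axis)
    # any vector perpendicular to the axis
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, a)) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    v = seed - np.dot(seed, a) * a
    v /= np.linalg.norm(v)
    w = M @ v
    w = w - np.dot(w, a) * a
    nw = np.linalg.norm(w)
    if nw < 1e-12:
        return 0.0
    w /= nw
    return float(
        np.degrees(np.arctan2(np.dot(np.cross(v, w), a), np.dot(v, w)))
    )


def _align_rotation(u_old: np.ndarray, u_new: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector u_old to u_new."""
    c = float(np.clip(np.dot(u_old, u_new), -1.0, 1.0))
    axis = np.cross(u_old, u_new)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any perpendicular axis
        seed = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(seed, u_old)) > 0.9:
            seed = np.array([0.0, 1.0, 0.0])
        perp = np.cross(u_old, seed)
        return rotation_about_axis(perp, 180.0)
    return rotation_about_axis(axis, np.degrees(np.arctan2(n, c)))


def two_hand_transform(
    old_left: HandPose,
    old_right: HandPose,
    new_left: HandPose,
    new_right: HandPose,
) -> RigidTransform:
    """Two-hand grab with scale.

    Scale is the ratio of inter-hand distances; the rotation aligns the
    old inter-hand direction with the new one, plus the right hand's
    orientation change projected on the inter-hand axis (the
    bottle-unscrewing twist).  The right-hand position is the fixed point:
    old_right.position maps exactly to new_right.position.
    """
    d_old = old_left.position - old_right.position
    d_new = new_left.position - new_right.position
    n_old = np.linalg.norm(d_old)
    n_new = np.linalg.norm(d_new)
    if n_old < 1e-12 or n_new < 1e-12:
        raise ValueError("coincident hands: inter-hand direction undefined")
    s = n_new / n_old
    u_old = d_old / n_old
    u_new = d_new / n_new
    R_align = _align_rotation(u_old, u_new)
    dR = new_right.orientation @ old_right.orientation.T
    twist = _twist_angle(R_align.T @ dR, u_old)
    R = R_align @ rotation_about_axis(u_old, twist)
    u, _, vt = np.linalg.svd(R)
    R = u @ vt
    translation = new_right.position - s * (R @ old_right.position)
    return RigidTransform(R, translation, s)
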