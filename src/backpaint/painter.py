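"""The protein-painter kernel.

A backbone chain is grown one residue at a time towards a stream of 3D
target points (originally a hand path).  While residue *i* is under
control, the two free parameters are the phi and psi torsions of residue
*i-1*: rotations about the preceding N-CA and CA-C axes.  This is the
unique two-torsion parameterization that moves the controlled CA while
leaving the already-frozen prefix and the peptide planarity (omega)
untouched.  A consequence worth knowing: the carbonyl C/O of the residue
*behind* the controlled one belong to the linking amide plane and keep
moving until the next residue is committed.

The solver minimises |CA(psi_prev, phi_prev) - target| with a coarse
5-degree torus grid followed by Levenberg-Marquardt refinement of the best
grid basins.  All distinct local minima are kept as candidates so the
caller can toggle between near-equidistant solutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import least_squares

from .geometry import RigidTransform, dihedral, nerf
from .model import (
    BackboneChain,
    IdealGeometry,
    Residue,
    place_c,
    place_next_ca,
    place_next_n,
    place_o,
    ramachandran_class,
    wrap_angle,
)

__all__ = [
    "Candidate",
    "PainterState",
    "TraceResult",
    "start_chain",
    "from_chain",
    "solve_closest_ca",
    "toggle_solution",
    "commit_and_extend",
    "undo",
    "trace_path",
    "frame_from_residue",
    "ca_surface",
]

# initial torsions of a freshly created residue: the alpha-helical pair
DEFAULT_PHI = -57.0
DEFAULT_PSI = -47.0


class Candidate(NamedTuple):
    """One local minimum of the CA-to-target distance, (psi_prev,
    phi_prev) in degrees plus the achieved distance in Angstrom."""

    psi: float
    phi: float
    distance: float


@dataclass(frozen=True)
class PainterState:
    """Immutable snapshot of a painting session.

    ``torsions[i]`` holds residue i's working (phi, psi); for the residue
    behind the controlled one these are the free torsions, for earlier
    residues they are frozen, and for the controlled residue they are the
    provisional values its own carbonyl is drawn with.
    """

    chain: BackboneChain
    controlled_index: int
    ref_point: np.ndarray  # virtual phi reference ahead of residue 1
    torsions: tuple[tuple[float, float], ...]
    candidates: tuple[Candidate, ...] = ()
    active_candidate: int = 0
    geometry: IdealGeometry = field(default_factory=IdealGeometry)
    undo_stack: tuple["PainterState", ...] = ()

    @property
    def free_torsions(self) -> tuple[float, float]:
        """(psi_prev, phi_prev) — the pair moving the controlled CA."""
        if self.controlled_index == 0:
            raise ValueError("the first residue has no free torsions")
        phi, psi = self.torsions[self.controlled_index - 1]
        return (psi, phi)

    @property
    def controlled_residue(self) -> Residue:
        return self.chain[self.controlled_index]


class TraceResult(NamedTuple):
    chain: BackboneChain
    distances: np.ndarray  # per-residue achieved |CA - target|, Angstrom
    state: PainterState


def _template_atoms(geom: IdealGeometry):
    """Canonical local pose of a first residue: CA at the origin, N along
    -x, C in the xy-plane at the ideal N-CA-C angle."""
    n = np.array([-geom.n_ca, 0.0, 0.0])
    ca = np.zeros(3)
    ang = np.radians(180.0 - geom.n_ca_c)
    c = geom.ca_c * np.array([np.cos(ang), np.sin(ang), 0.0])
    return n, ca, c


def _virtual_ref(n, ca, c, geom: IdealGeometry) -> np.ndarray:
    """A virtual predecessor carbonyl C bonded to N, placed trans, so the
    first residue's phi is a well-defined dihedral."""
    return nerf(c, ca, n, geom.c_n, geom.c_n_ca, 180.0)


def start_chain(
    first_ca,
    orientation: RigidTransform | None = None,
    geometry: IdealGeometry | None = None,
    chain_id: str = "A",
) -> PainterState:
    """Begin a chain: one residue with CA pinned at ``first_ca`` and N/C
    placed with ideal geometry in the rotated template frame.  Only the
    rotation part of ``orientation`` is used; CA stays at ``first_ca``."""
    geom = geometry or IdealGeometry()
    R = (orientation or RigidTransform.identity()).rotation
    first_ca = np.asarray(first_ca, dtype=float)
    n_loc, ca_loc, c_loc = _template_atoms(geom)
    n = first_ca + R @ n_loc
    ca = first_ca + R @ ca_loc
    c = first_ca + R @ c_loc
    ref = _virtual_ref(n, ca, c, geom)
    o = place_o(n, ca, c, DEFAULT_PSI, geom)
    phi0 = dihedral(ref, n, ca, c)
    res = Residue(1, chain_id, "ALA", {"N": n, "CA": ca, "C": c, "O": o})
    chain = BackboneChain([res], chain_id)
    return PainterState(
        chain=chain,
        controlled_index=0,
        ref_point=ref,
        torsions=((phi0, DEFAULT_PSI),),
        geometry=geom,
    )


def frame_from_residue(residue: Residue, geometry: IdealGeometry | None = None):
    """Recover (first_ca, orientation) such that ``start_chain`` reproduces
    this residue's N and CA exactly (and C too, for ideal geometry)."""
    geom = geometry or IdealGeometry()

    def basis(n, ca, c):
        e1 = n - ca
        e1 = e1 / np.linalg.norm(e1)
        v = c - ca
        e2 = v - np.dot(v, e1) * e1
        e2 = e2 / np.linalg.norm(e2)
        return np.stack([e1, e2, np.cross(e1, e2)], axis=-1)

    n_loc, ca_loc, c_loc = _template_atoms(geom)
    B_loc = basis(n_loc, ca_loc, c_loc)
    B_act = basis(residue["N"], residue["CA"], residue["C"])
    R = B_act @ B_loc.T
    u, _, vt = np.linalg.svd(R)
    return residue["CA"].copy(), RigidTransform(u @ vt)


def from_chain(chain: BackboneChain, geometry: IdealGeometry | None = None) -> PainterState:
    """Adopt an existing chain, taking control of its last residue, so the
    painter can extend it (e.g. from a gap anchor)."""
    geom = geometry or IdealGeometry()
    if len(chain) == 0:
        raise ValueError("cannot adopt an empty chain")
    chain = chain.copy()
    first = chain[0]
    ref = _virtual_ref(first["N"], first["CA"], first["C"], geom)
    torsions = []
    derived = chain.torsions
    for i, t in enumerate(derived):
        phi = t.phi if np.isfinite(t.phi) else dihedral(ref, first["N"], first["CA"], first["C"])
        psi = t.psi if np.isfinite(t.psi) else DEFAULT_PSI
        torsions.append((phi, psi))
    return PainterState(
        chain=chain,
        controlled_index=len(chain) - 1,
        ref_point=ref,
        torsions=tuple(torsions),
        geometry=geom,
    )


def _phi_reference(state: PainterState) -> np.ndarray:
    """The atom defining phi of the residue behind the controlled one."""
    ci = state.controlled_index
    if ci >= 2:
        return state.chain[ci - 2]["C"]
    return state.ref_point


def _rebuild_controlled(state: PainterState, psi_prev: float, phi_prev: float) -> PainterState:
    """Re-place the linking amide plane and the controlled residue for the
    given free torsions; everything before stays bit-identical."""
    ci = state.controlled_index
    geom = state.geometry
    chain = state.chain.copy()
    prev = chain[ci - 1]
    cur = chain[ci]
    ref = _phi_reference(state)
    n_p, ca_p = prev["N"], prev["CA"]
    c_p = place_c(ref, n_p, ca_p, phi_prev, geom)
    prev.atoms["C"] = c_p
    prev.atoms["O"] = place_o(n_p, ca_p, c_p, psi_prev, geom)
    n_i = place_next_n(n_p, ca_p, c_p, psi_prev, geom)
    ca_i = place_next_ca(ca_p, c_p, n_i, geom)
    phi_i, psi_i = state.torsions[ci]
    c_i = place_c(c_p, n_i, ca_i, phi_i, geom)
    cur.atoms["N"] = n_i
    cur.atoms["CA"] = ca_i
    cur.atoms["C"] = c_i
    cur.atoms["O"] = place_o(n_i, ca_i, c_i, psi_i, geom)
    torsions = list(state.torsions)
    torsions[ci - 1] = (wrap_angle(phi_prev), wrap_angle(psi_prev))
    return replace(state, chain=chain, torsions=tuple(torsions))


def ca_surface(ref, n_prev, ca_prev, phis, psis, geometry: IdealGeometry | None = None) -> np.ndarray:
    """Forward kinematics of the controlled CA on a torsion grid.

    Returns an array of shape (len(phis), len(psis), 3): the CA position
    reached for each (phi_prev, psi_prev) pair, with omega held at the
    ideal value.  Used both by the solver's coarse scan and by exhaustive
    grid evaluation.
    """
    geom = geometry or IdealGeometry()
    phis = np.atleast_1d(np.asarray(phis, dtype=float))
    psis = np.atleast_1d(np.asarray(psis, dtype=float))
    c_prev = nerf(ref, n_prev, ca_prev, geom.ca_c, geom.n_ca_c, phis)  # (n,3)
    n_i = nerf(
        n_prev,
        ca_prev,
        c_prev[:, None, :],
        geom.c_n,
        geom.ca_c_n,
        psis[None, :],
    )  # (n,m,3)
    ca_i = nerf(ca_prev, c_prev[:, None, :], n_i, geom.n_ca, geom.c_n_ca, geom.omega)
    return ca_i


def _ca_of(state: PainterState, psi_prev: float, phi_prev: float) -> np.ndarray:
    """Scalar forward kinematics for the controlled CA."""
    ci = state.controlled_index
    geom = state.geometry
    prev = state.chain[ci - 1]
    ref = _phi_reference(state)
    c_p = place_c(ref, prev["N"], prev["CA"], phi_prev, geom)
    n_i = place_next_n(prev["N"], prev["CA"], c_p, psi_prev, geom)
    return place_next_ca(prev["CA"], c_p, n_i, geom)


def _grid_local_minima(dist: np.ndarray) -> list[tuple[int, int]]:
    """Indices of cells not exceeded by any of their 8 torus neighbours."""
    is_min = np.ones_like(dist, dtype=bool)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            is_min &= dist <= np.roll(np.roll(dist, di, axis=0), dj, axis=1)
    idx = np.argwhere(is_min)
    idx = sorted(map(tuple, idx), key=lambda ij: dist[ij])
    return idx


def _torsion_gap(a: float, b: float) -> float:
    return abs(wrap_angle(a - b))


def solve_closest_ca(
    state: PainterState,
    target,
    coarse_step: float = 5.0,
    max_starts: int = 4,
    dedupe_tol: float = 0.5,
) -> PainterState:
    """Set the free torsions so the controlled CA lands as close as
    possible to ``target``; all distinct local minima are retained as
    candidates, sorted by achieved distance (ties broken by psi).
    """
    if state.controlled_index == 0:
        raise ValueError(
            "the first residue has no free torsions; its pose is set by "
            "start_chain's orientation"
        )
    target = np.asarray(target, dtype=float)
    geom = state.geometry
    ci = state.controlled_index
    prev = state.chain[ci - 1]
    ref = _phi_reference(state)

    grid = np.arange(-180.0 + coarse_step / 2.0, 180.0, coarse_step)
    surface = ca_surface(ref, prev["N"], prev["CA"], grid, grid, geom)
    dist = np.linalg.norm(surface - target, axis=-1)

    starts = _grid_local_minima(dist)[:max_starts]

    def residual(x):
        return _ca_of(state, x[1], x[0]) - target

    found: list[Candidate] = []
    for i, j in starts:
        sol = least_squares(
            residual,
            x0=[grid[i], grid[j]],
            method="lm",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        phi, psi = wrap_angle(sol.x[0]), wrap_angle(sol.x[1])
        d = float(np.linalg.norm(sol.fun))
        dup = False
        for k, c in enumerate(found):
            if _torsion_gap(c.phi, phi) < dedupe_tol and _torsion_gap(c.psi, psi) < dedupe_tol:
                dup = True
                if d < c.distance:
                    found[k] = Candidate(psi, phi, d)
                break
        if not dup:
            found.append(Candidate(psi, phi, d))
    # Reachable targets are generically attained by exactly two torsion
    # pairs (phi, psi) and (phi', -psi): |CA - CA_prev| is independent of
    # both torsions, so the reachable set is a doubly-covered sphere zone.
    # Among equal-distance candidates prefer the Ramachandran-favoured
    # branch, then lower psi, for determinism.
    region_rank = {"alpha": 0, "beta": 1, "left_alpha": 2, "other": 3}
    found.sort(
        key=lambda c: (
            round(c.distance / 1e-6),
            region_rank[ramachandran_class(c.phi, c.psi)],
            c.psi,
        )
    )
    best = found[0]
    new = _rebuild_controlled(state, best.psi, best.phi)
    return replace(new, candidates=tuple(found), active_candidate=0)


def toggle_solution(state: PainterState) -> PainterState:
    """Advance cyclically to the next candidate solution and re-pose the
    chain accordingly.  With a single candidate this is a no-op."""
    if not state.candidates:
        raise ValueError("no candidates: run solve_closest_ca first")
    k = (state.active_candidate + 1) % len(state.candidates)
    cand = state.candidates[k]
    new = _rebuild_controlled(state, cand.psi, cand.phi)
    return replace(new, active_candidate=k)


def commit_and_extend(state: PainterState) -> PainterState:
    """Freeze the controlled residue and append a fresh one (initial
    torsions at the alpha default), which takes over control.  The prior
    state is pushed on the undo stack; no existing atom moves."""
    ci = state.controlled_index
    geom = state.geometry
    chain = state.chain.copy()
    cur = chain[ci]
    phi_i, psi_i = state.torsions[ci]
    n_next = place_next_n(cur["N"], cur["CA"], cur["C"], psi_i, geom)
    ca_next = place_next_ca(cur["CA"], cur["C"], n_next, geom)
    c_next = place_c(cur["C"], n_next, ca_next, DEFAULT_PHI, geom)
    o_next = place_o(n_next, ca_next, c_next, DEFAULT_PSI, geom)
    res = Residue(
        cur.seq_id + 1,
        cur.chain_id,
        "ALA",
        {"N": n_next, "CA": ca_next, "C": c_next, "O": o_next},
    )
    chain.residues.append(res)
    return replace(
        state,
        chain=chain,
        controlled_index=ci + 1,
        torsions=state.torsions + ((DEFAULT_PHI, DEFAULT_PSI),),
        candidates=(),
        active_candidate=0,
        undo_stack=state.undo_stack + (state,),
    )


def undo(state: PainterState) -> tuple[PainterState, bool]:
    """Delete the controlled residue and resume control of the previous
    one, restoring the exact pre-commit state.  Returns (state, False)
    unchanged when already at the root."""
    if not state.undo_stack:
        return state, False
    return state.undo_stack[-1], True


def trace_path(
    targets: Sequence,
    orientation: RigidTransform | None = None,
    geometry: IdealGeometry | None = None,
    chain_id: str = "A",
) -> TraceResult:
    """Batch painting: start at ``targets[0]`` and, for every further
    target, extend the chain and solve its CA as close as possible.

    Greedy and best-effort: targets beyond the reachable step are not an
    error, the achieved per-residue |CA - target| distances are reported.
    """
    targets = np.asarray(targets, dtype=float)
    if targets.ndim != 2 or targets.shape[1] != 3 or len(targets) == 0:
        raise ValueError("targets must be a non-empty (n, 3) array")
    state = start_chain(targets[0], orientation, geometry, chain_id)
    dists = [0.0]
    for t in targets[1:]:
        state = commit_and_extend(state)
        state = solve_closest_ca(state, t)
        dists.append(state.candidates[0].distance)
    return TraceResult(state.chain, np.asarray(dists), state)
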