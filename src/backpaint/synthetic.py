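"""Synthetic backbone generators and the gap-rebuilding harness.

``make_chain`` realizes a phi/psi schedule exactly with ideal covalent
geometry, by a direct internal-to-Cartesian walk (no solver involved), so
it serves as ground truth for the painter.  ``make_gap_puzzle`` deletes a
seeded interior run of residues; ``rebuild_gap`` repaints the gap towards
the true CA positions (optionally noise-perturbed, emulating an imprecise
hand path) and scores the result in the shared frame — no superposition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple, Sequence

import numpy as np

from .model import (
    BackboneChain,
    IdealGeometry,
    RAMACHANDRAN_BOXES,
    Residue,
    place_c,
    place_next_ca,
    place_next_n,
    place_o,
)
from .painter import (
    RigidTransform,
    commit_and_extend,
    from_chain,
    solve_closest_ca,
    start_chain,
)

__all__ = [
    "make_chain",
    "make_gap_puzzle",
    "rebuild_gap",
    "GapPuzzle",
    "GapReport",
    "PRESETS",
]

# canonical (phi, psi) pairs for the named presets
ALPHA = (-57.0, -47.0)
BETA = (-120.0, 130.0)


def _preset_schedule(preset: str, n: int, seed: int | None) -> list[tuple[float, float]]:
    if preset == "alpha":
        return [ALPHA] * n
    if preset == "beta":
        return [BETA] * n
    if preset == "mixed":
        # alternating 5-residue helical and extended blocks
        return [ALPHA if (i // 5) % 2 == 0 else BETA for i in range(n)]
    if preset == "random":
        rng = np.random.default_rng(seed)
        out = []
        boxes = [RAMACHANDRAN_BOXES["alpha"], RAMACHANDRAN_BOXES["beta"]]
        for _ in range(n):
            (p0, p1), (s0, s1) = boxes[rng.integers(2)]
            out.append((float(rng.uniform(p0, p1)), float(rng.uniform(s0, s1))))
        return out
    raise ValueError(f"unknown preset {preset!r}")


PRESETS = ("alpha", "beta", "mixed", "random")


def make_chain(
    n: int,
    schedule: str | Sequence[tuple[float, float]] = "alpha",
    seed: int | None = 0,
    geometry: IdealGeometry | None = None,
    orientation: RigidTransform | None = None,
    first_ca=(0.0, 0.0, 0.0),
    chain_id: str = "A",
) -> BackboneChain:
    """Build an ideal-geometry chain realizing a torsion schedule exactly.

    ``schedule`` is a preset name (alpha | beta | mixed | random) or an
    explicit list of per-residue (phi, psi) pairs.  Deterministic for a
    given seed.  The first residue's phi only fixes the (arbitrary)
    azimuth of its carbonyl; the chain frame comes from ``orientation``.
    """
    if n < 1:
        raise ValueError("need at least one residue")
    geom = geometry or IdealGeometry()
    if isinstance(schedule, str):
        sched = _preset_schedule(schedule, n, seed)
    else:
        sched = [(float(p), float(s)) for p, s in schedule]
        if len(sched) != n:
            raise ValueError("schedule length must equal n")

    state = start_chain(first_ca, orientation, geom, chain_id)
    chain = state.chain
    ref = state.ref_point
    for i in range(1, n):
        phi_prev, psi_prev = sched[i - 1]
        prev = chain[i - 1]
        rp = ref if i == 1 else chain[i - 2]["C"]
        c_p = place_c(rp, prev["N"], prev["CA"], phi_prev, geom)
        prev.atoms["C"] = c_p
        prev.atoms["O"] = place_o(prev["N"], prev["CA"], c_p, psi_prev, geom)
        n_i = place_next_n(prev["N"], prev["CA"], c_p, psi_prev, geom)
        ca_i = place_next_ca(prev["CA"], c_p, n_i, geom)
        c_i = place_c(c_p, n_i, ca_i, sched[i][0], geom)
        o_i = place_o(n_i, ca_i, c_i, sched[i][1], geom)
        chain.residues.append(
            Residue(i + 1, chain_id, "ALA", {"N": n_i, "CA": ca_i, "C": c_i, "O": o_i})
        )
    return chain


@dataclass(frozen=True)
class GapPuzzle:
    """A chain with an interior run deleted, plus the ground truth.

    ``gap`` is the inclusive (i, j) range of deleted seq_ids; the anchor
    residues i-1 and j+1 survive with coordinates identical to the truth.
    """

    truth: BackboneChain
    puzzle: BackboneChain
    gap: tuple[int, int]

    @property
    def gap_length(self) -> int:
        return self.gap[1] - self.gap[0] + 1


def make_gap_puzzle(chain: BackboneChain, gap_length: int, seed: int = 0) -> GapPuzzle:
    """Delete a uniformly random interior run of ``gap_length`` residues
    (both terminal residues always survive as anchors)."""
    n = len(chain)
    if gap_length < 0:
        raise ValueError("gap_length must be non-negative")
    if n < gap_length + 2:
        raise ValueError(
            f"chain of {n} residues cannot hold an interior gap of {gap_length}"
        )
    rng = np.random.default_rng(seed)
    if gap_length == 0:
        i = j = 0
        puzzle = chain.copy()
        return GapPuzzle(chain.copy(), puzzle, (0, -1))
    first = chain[0].seq_id
    last = chain[-1].seq_id
    i = int(rng.integers(first + 1, last - gap_length + 1))
    j = i + gap_length - 1
    kept = [r.copy() for r in chain if not i <= r.seq_id <= j]
    return GapPuzzle(chain.copy(), BackboneChain(kept, chain.chain_id), (i, j))


class GapReport(NamedTuple):
    per_residue_distance: np.ndarray  # |CA_rebuilt - CA_truth| over the gap
    ca_rmsd: float  # over the gap residues, shared frame (no superposition)
    closure_distance: float  # |CA_rebuilt - CA_truth| at anchor j+1
    rebuilt: BackboneChain


def rebuild_gap(
    puzzle: GapPuzzle,
    noise_sigma: float = 0.0,
    seed: int = 0,
    geometry: IdealGeometry | None = None,
) -> GapReport:
    """Repaint the gap from the N-side anchor towards the true CA
    positions (the "targets from truth" strategy: the hand path is taken
    to be the true CA trace, optionally blurred by isotropic Gaussian noise
    of ``noise_sigma`` Angstrom per coordinate).

    The painter is anchored on the residues before the gap; it rebuilds
    the gap residues plus one more aimed at the C-side anchor's CA, whose
    miss distance is reported as the closure gap.
    """
    i, j = puzzle.gap
    if puzzle.gap_length == 0:
        return GapReport(np.zeros(0), 0.0, 0.0, puzzle.puzzle.copy())
    geom = geometry or IdealGeometry()
    rng = np.random.default_rng(seed)
    truth_by_id = {r.seq_id: r for r in puzzle.truth}
    prefix = [r.copy() for r in puzzle.puzzle if r.seq_id < i]
    state = from_chain(BackboneChain(prefix, puzzle.puzzle.chain_id), geom)

    target_ids = list(range(i, j + 1)) + [j + 1]
    targets = np.array([truth_by_id[s]["CA"] for s in target_ids])
    if noise_sigma > 0:
        # the closure anchor is a known atom, not a hand guess: keep exact
        targets[:-1] += rng.normal(scale=noise_sigma, size=(len(targets) - 1, 3))

    for t in targets:
        state = commit_and_extend(state)
        state = solve_closest_ca(state, t)

    rebuilt = state.chain
    built_by_id = {r.seq_id: r for r in rebuilt}
    gap_ids = list(range(i, j + 1))
    d = np.array(
        [np.linalg.norm(built_by_id[s]["CA"] - truth_by_id[s]["CA"]) for s in gap_ids]
    )
    closure = float(
        np.linalg.norm(built_by_id[j + 1]["CA"] - truth_by_id[j + 1]["CA"])
    )
    rmsd = float(np.sqrt(np.mean(d**2)))
    return GapReport(d, rmsd, closure, rebuilt)
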