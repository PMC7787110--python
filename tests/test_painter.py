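"""The torsion-space painter: chain starting, CA solving, candidate
toggling, commit/undo, and path tracing."""

import numpy as np
import pytest

from backpaint.geometry import RigidTransform, rotation_about_axis
from backpaint.model import IdealGeometry, extract_torsions
from backpaint.painter import (
    ca_surface,
    commit_and_extend,
    frame_from_residue,
    from_chain,
    solve_closest_ca,
    start_chain,
    toggle_solution,
    trace_path,
    undo,
)
from backpaint.painter import _ca_of, _phi_reference
from backpaint.synthetic import make_chain
from conftest import ca_forward_rodrigues, random_rotation, wrap_diff


def assert_ideal_geometry(chain, geom=None, tol=1e-6):
    """Every painted bond length/angle must equal the ideal constants."""
    from backpaint.geometry import bond_angle

    geom = geom or IdealGeometry()
    res = chain.residues
    for i, r in enumerate(res):
        assert abs(np.linalg.norm(r["N"] - r["CA"]) - geom.n_ca) < tol
        assert abs(np.linalg.norm(r["CA"] - r["C"]) - geom.ca_c) < tol
        assert abs(bond_angle(r["N"], r["CA"], r["C"]) - geom.n_ca_c) < tol
        if i + 1 < len(res):
            nxt = res[i + 1]
            assert abs(np.linalg.norm(r["C"] - nxt["N"]) - geom.c_n) < tol
            assert abs(bond_angle(r["CA"], r["C"], nxt["N"]) - geom.ca_c_n) < tol
            assert abs(bond_angle(r["C"], nxt["N"], nxt["CA"]) - geom.c_n_ca) < tol
    for t in extract_torsions(chain)[:-1]:
        assert wrap_diff(t.omega, geom.omega) < tol


class TestStartChain:
    def test_first_residue_has_ideal_bonds(self, geom):
        st = start_chain([1.0, 2.0, 3.0])
        r = st.chain[0]
        assert np.allclose(r["CA"], [1, 2, 3])
        assert abs(np.linalg.norm(r["N"] - r["CA"]) - geom.n_ca) < 1e-9
        assert abs(np.linalg.norm(r["C"] - r["CA"]) - geom.ca_c) < 1e-9

    def test_orientation_equivariance(self, rng):
        R = RigidTransform(random_rotation(rng))
        st0 = start_chain([0.0, 0.0, 0.0])
        st1 = start_chain([0.0, 0.0, 0.0], orientation=R)
        for name in ("N", "CA", "C"):
            assert np.abs(R.apply(st0.chain[0][name]) - st1.chain[0][name]).max() < 1e-9

    def test_single_residue_torsions_undefined(self):
        st = start_chain([0.0, 0.0, 0.0])
        (t,) = extract_torsions(st.chain)
        assert np.isnan(t.phi) and np.isnan(t.psi)

    def test_solve_on_first_residue_is_an_error(self):
        st = start_chain([0.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="orientation"):
            solve_closest_ca(st, [1.0, 1.0, 1.0])


class TestSolveClosestCa:
    def test_target_at_current_ca_is_a_fixed_point(self):
        st = commit_and_extend(start_chain([0.0, 0.0, 0.0]))
        before = st.free_torsions
        st2 = solve_closest_ca(st, st.controlled_residue["CA"])
        assert st2.candidates[0].distance < 1e-9
        assert wrap_diff(st2.free_torsions[0], before[0]) < 0.5
        assert wrap_diff(st2.free_torsions[1], before[1]) < 0.5

    def test_recovers_known_forward_kinematics(self, rng):
        """Targets generated at a known torsion pair are recovered either
        exactly or by the equal-distance mirror solution."""
        st = commit_and_extend(start_chain([0.0, 0.0, 0.0]))
        st = commit_and_extend(solve_closest_ca(st, [2.0, 2.0, 0.5]))
        for _ in range(10):
            phi, psi = rng.uniform(-170, 170, size=2)
            target = ca_forward_rodrigues(st, phi, psi)
            sol = solve_closest_ca(st, target)
            assert sol.candidates[0].distance < 1e-4
            hit = any(
                wrap_diff(c.phi, phi) < 0.5 and wrap_diff(c.psi, psi) < 0.5
                for c in sol.candidates
                if c.distance < 1e-4
            )
            assert hit

    def test_never_worse_than_one_degree_grid(self, rng):
        """The refined solver must beat the exhaustive 1-degree grid."""
        st = commit_and_extend(start_chain([0.0, 0.0, 0.0]))
        prev = st.chain[0]
        g = np.arange(-179.5, 180.0, 1.0)
        surf = ca_surface(_phi_reference(st), prev["N"], prev["CA"], g, g)
        for _ in range(15):
            target = st.chain[0]["CA"] + rng.normal(size=3) * 3.0
            grid_min = np.linalg.norm(surf - target, axis=-1).min()
            sol = solve_closest_ca(st, target)
            assert sol.candidates[0].distance <= grid_min + 1e-9

    def test_geometry_invariants_preserved_after_solve(self, rng):
        st = commit_and_extend(start_chain([0.0, 0.0, 0.0]))
        for _ in range(3):
            st = solve_closest_ca(st, rng.normal(size=3) * 4)
            st = commit_and_extend(st)
        assert_ideal_geometry(st.chain)


class TestCandidateToggle:
    def test_reachable_target_has_two_equal_candidates(self):
        """|CA - CA_prev| is torsion-independent, so reachable targets
        are hit by exactly two torsion pairs: equal distances."""
        st = commit_and_extend(start_chain([0.0, 0.0, 0.0]))
        st = commit_and_extend(solve_closest_ca(st, [2.5, 2.0, 1.0]))
        target = ca_forward_rodrigues(st, -75.0, -30.0)
        sol = solve_closest_ca(st, target)
        assert len(sol.candidates) >= 2
        d0, d1 = sol.candidates[0].distance, sol.candidates[1].distance
        assert abs(d0 - d1) < 1e-6
        # mirror structure: psi of the partner is -psi
        assert wrap_diff(sol.candidates[1].psi, -sol.candidates[0].psi) < 0.5

    def test_toggle_changes_coordinates_and_cycles(self):
        st = commit_and_extend(start_chain([0.0, 0.0, 0.0]))
        st = commit_and_extend(solve_closest_ca(st, [2.5, 2.0, 1.0]))
        sol = solve_closest_ca(st, ca_forward_rodrigues(st, -80.0, -20.0))
        n = len(sol.candidates)
        t1 = toggle_solution(sol)
        assert t1.active_candidate == 1 % n
        if n > 1:
            moved = np.abs(
                t1.chain[t1.controlled_index - 1]["C"]
                - sol.chain[sol.controlled_index - 1]["C"]
            ).max()
            assert moved > 1e-3
        back = sol
        for _ in range(n):
            back = toggle_solution(back)
        assert back.active_candidate == 0
        assert np.abs(back.controlled_residue["CA"] - sol.controlled_residue["CA"]).max() < 1e-9

    def test_generic_candidates_sorted_by_distance(self, rng):
        st = commit_and_extend(start_chain([0.0, 0.0, 0.0]))
        sol = solve_closest_ca(st, rng.normal(size=3) * 5)
        d = [c.distance for c in sol.candidates]
        assert d == sorted(d)


class TestCommitUndo:
    def test_commit_appends_with_ideal_peptide(self, geom):
        st = commit_and_extend(start_chain([0.0, 0.0, 0.0]))
        st = solve_closest_ca(st, [3.0, 1.0, 0.5])
        st2 = commit_and_extend(st)
        assert len(st2.chain) == len(st.chain) + 1
        c_prev = st2.chain[-2]["C"]
        n_new = st2.chain[-1]["N"]
        assert abs(np.linalg.norm(c_prev - n_new) - geom.c_n) < 1e-6
        tors = extract_torsions(st2.chain)
        assert wrap_diff(tors[-2].omega, 180.0) < 1e-6

    def test_commit_leaves_existing_atoms_bit_identical(self):
        st = commit_and_extend(start_chain([0.0, 0.0, 0.0]))
        st = solve_closest_ca(st, [3.0, 1.0, 0.5])
        st2 = commit_and_extend(st)
        for r_old, r_new in zip(st.chain, st2.chain):
            for name in r_old.atoms:
                assert (r_old.atoms[name] == r_new.atoms[name]).all()

    def test_committed_torsions_show_up_in_extraction(self):
        st = commit_and_extend(start_chain([0.0, 0.0, 0.0]))
        st = solve_closest_ca(st, [3.0, 1.5, 1.0])
        psi_prev, phi_prev = st.free_torsions
        st = commit_and_extend(st)
        st = solve_closest_ca(st, [5.5, 3.0, 1.0])
        st = commit_and_extend(st)
        tors = extract_torsions(st.chain)
        assert wrap_diff(tors[0].psi, psi_prev) < 1e-6

    def test_undo_restores_state_field_for_field(self):
        st = commit_and_extend(start_chain([0.0, 0.0, 0.0]))
        st = solve_closest_ca(st, [2.0, 2.0, 1.0])
        st2 = commit_and_extend(st)
        st3, ok = undo(st2)
        assert ok
        assert st3 is st
        st4, ok = undo(solve_closest_ca(st2, [4.0, 1.0, 0.0]))
        assert ok and st4 is st

    def test_two_commits_two_undos_returns_to_start(self):
        root = start_chain([0.0, 0.0, 0.0])
        a = commit_and_extend(root)
        b = commit_and_extend(a)
        back1, _ = undo(b)
        back2, _ = undo(back1)
        assert back2 is root

    def test_undo_at_root_is_noop_with_signal(self):
        root = start_chain([0.0, 0.0, 0.0])
        same, ok = undo(root)
        assert same is root and not ok


class TestTracePath:
    def test_single_target_single_residue(self):
        res = trace_path([[1.0, 2.0, 3.0]])
        assert len(res.chain) == 1
        assert np.allclose(res.chain[0]["CA"], [1, 2, 3])

    def test_empty_targets_error(self):
        with pytest.raises(ValueError):
            trace_path(np.zeros((0, 3)))

    def test_helix_ca_roundtrip(self):
        truth = make_chain(15, "alpha")
        cas = truth.ca_positions()
        _, orient = frame_from_residue(truth[0])
        res = trace_path(cas, orient)
        assert res.distances.max() < 1e-4
        rmsd = np.sqrt(((res.chain.ca_positions() - cas) ** 2).sum(axis=1).mean())
        assert rmsd < 0.01

    def test_unreachable_spacing_reports_distances_without_raising(self):
        targets = np.array([[0.0, 0, 0], [10.0, 0, 0], [20.0, 0, 0]])
        res = trace_path(targets)
        assert len(res.chain) == 3
        assert res.distances[1] > 5.0  # max CA-CA step is ~3.8 A

    def test_equivariance_under_rigid_motion(self, rng):
        targets = make_chain(8, "mixed").ca_positions()
        R = RigidTransform(random_rotation(rng), rng.normal(size=3) * 5)
        base = trace_path(targets)
        _, orient0 = frame_from_residue(base.chain[0])
        moved = trace_path(R.apply(targets), RigidTransform(R.rotation @ orient0.rotation))
        for r0, r1 in zip(base.chain, moved.chain):
            for name in ("N", "CA", "C"):
                assert np.abs(R.apply(r0[name]) - r1[name]).max() < 1e-6


class TestFromChain:
    def test_adopted_chain_extends_with_ideal_geometry(self):
        truth = make_chain(10, "mixed")
        st = from_chain(truth)
        st = commit_and_extend(st)
        st = solve_closest_ca(st, truth[-1]["CA"] + np.array([3.0, 1.0, 0.0]))
        assert len(st.chain) == 11
        assert st.chain[-1].seq_id == 11
        assert_ideal_geometry(st.chain)

    def test_adoption_preserves_coordinates(self):
        truth = make_chain(6, "alpha")
        st = from_chain(truth)
        for r0, r1 in zip(truth, st.chain):
            for name in r0.atoms:
                assert (r0.atoms[name] == r1.atoms[name]).all()


def test_ca_surface_matches_rodrigues_oracle(rng):
    """The vectorized torsion-grid kinematics agrees with an independent
    rotation-matrix formulation."""
    st = commit_and_extend(start_chain([0.0, 0.0, 0.0]))
    st = commit_and_extend(solve_closest_ca(st, [2.0, 2.0, 0.0]))
    prev = st.chain[st.controlled_index - 1]
    phis = rng.uniform(-180, 180, size=6)
    psis = rng.uniform(-180, 180, size=5)
    surf = ca_surface(_phi_reference(st), prev["N"], prev["CA"], phis, psis)
    for i, phi in enumerate(phis):
        for j, psi in enumerate(psis):
            expect = ca_forward_rodrigues(st, phi, psi)
            assert np.abs(surf[i, j] - expect).max() < 1e-9


def test_reachable_surface_is_sphere_zone(rng):
    """Both free-torsion axes pass through the preceding CA, so every
    reachable CA position is equidistant from it."""
    st = commit_and_extend(start_chain([0.0, 0.0, 0.0]))
    prev = st.chain[0]
    g = rng.uniform(-180, 180, size=(2, 30))
    surf = ca_surface(_phi_reference(st), prev["N"], prev["CA"], g[0], g[1])
    radii = np.linalg.norm(surf - prev["CA"], axis=-1)
    assert radii.std() < 1e-9
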