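"""Bend/twist/flip movements and hydrogen-bond network topology."""

import itertools

import numpy as np
import pytest

from macroconf import chemgraph, fixtures, moves
from macroconf.ffmin import Conformer, ForceFieldEngine
from macroconf.geometry import kabsch_rmsd
from macroconf.search import memory_free_start


def brute_force_bend_pairs(graph, system):
    """Independent oracle: apply the three textual eligibility rules by brute
    force over all atom pairs of the ring system."""
    import networkx as nx

    mol = graph.mol
    special = system.fusion_atoms | system.bridge_atoms
    sub = graph.to_networkx().subgraph(system.atoms)
    out = set()
    for a, b in itertools.combinations(sorted(system.atoms), 2):
        if mol.GetBondBetweenAtoms(a, b) is not None:
            continue  # not-connected rule
        if not (
            {a, b} & system.nonplanar_ring_atoms
        ):
            continue  # non-planarity rule: neither atom is in a non-planar ring
        work = sub.copy()
        work.remove_nodes_from([a, b])
        comps = list(nx.connected_components(work))
        if len(comps) != 2:
            continue
        if all(special & c for c in comps):
            continue  # crossing rule: junction atoms split onto both sides
        out.add((a, b))
    return out


class TestBendEnumeration:
    def test_benzene_has_no_bends(self, benzene):
        system = chemgraph.perceive_ring_systems(benzene)[0]
        assert moves.enumerate_bends(benzene, system) == []

    def test_cyclohexane_has_all_nine_nonadjacent_pairs(self, cyclohexane):
        system = chemgraph.perceive_ring_systems(cyclohexane)[0]
        bends = moves.enumerate_bends(cyclohexane, system)
        assert len(bends) == 9
        assert {b.axis for b in bends} == brute_force_bend_pairs(cyclohexane, system)

    def test_decalin_pairs_spanning_fusion_excluded(self, decalin):
        system = chemgraph.perceive_ring_systems(decalin)[0]
        bends = moves.enumerate_bends(decalin, system)
        assert {b.axis for b in bends} == brute_force_bend_pairs(decalin, system)
        fusion = system.fusion_atoms
        for b in bends:
            # the cut never separates the fusion atoms onto both sides
            sides = [set(b.lhs), set(b.rhs)]
            assert not all(fusion & s for s in sides)

    def test_rhs_is_smaller_side(self, cyclohexane):
        system = chemgraph.perceive_ring_systems(cyclohexane)[0]
        for b in moves.enumerate_bends(cyclohexane, system):
            assert len(b.rhs) <= len(b.lhs)


class TestBendApplication:
    def test_bend_moves_between_chair_and_boat_families(
        self, cyclohexane, cyclohexane_engine
    ):
        system = chemgraph.perceive_ring_systems(cyclohexane)[0]
        start = cyclohexane_engine.minimize(
            memory_free_start(cyclohexane, seed=1)
        ).conformer
        energies = set()
        for bend in moves.enumerate_bends(cyclohexane, system):
            cand = moves.apply_bend(cyclohexane_engine, start, bend, system)
            if cand is not None:
                energies.add(round(cand.energy, 2))
        # at least one bend lands in the other ring family
        assert any(abs(e - round(start.energy, 2)) > 1.0 for e in energies)

    def test_double_bend_is_approximate_involution(
        self, cyclohexane, cyclohexane_engine
    ):
        system = chemgraph.perceive_ring_systems(cyclohexane)[0]
        start = cyclohexane_engine.minimize(
            memory_free_start(cyclohexane, seed=1)
        ).conformer
        bend = moves.enumerate_bends(cyclohexane, system)[0]
        once = moves.apply_bend(cyclohexane_engine, start, bend, system)
        twice = moves.apply_bend(cyclohexane_engine, once, bend, system)
        ring = sorted(system.atoms)
        assert kabsch_rmsd(twice.coords[ring], start.coords[ring]) < 0.3

    def test_lhs_and_axis_atoms_unmoved_by_rotation_step(self, cyclohexane):
        # re-derive the pure rotation: axis and LHS substituent positions fixed
        from macroconf.ffmin import dihedral_deg
        import math

        start = memory_free_start(cyclohexane, seed=1)
        system = chemgraph.perceive_ring_systems(cyclohexane)[0]
        bend = moves.enumerate_bends(cyclohexane, system)[0]
        coords = start.coords.copy()
        a1, a2 = bend.axis
        c_rhs = coords[list(bend.rhs)].mean(axis=0)
        c_lhs = coords[list(bend.lhs)].mean(axis=0)
        tau = dihedral_deg(c_rhs, coords[a1], coords[a2], c_lhs)
        axis = coords[a2] - coords[a1]
        moving = tuple(bend.rhs) + bend.rhs_pendants
        moves._rotate_about_axis(
            coords, moving, coords[a1], axis / np.linalg.norm(axis),
            math.radians(-2.0 * tau),
        )
        static = [
            i for i in range(len(coords)) if i not in set(moving)
        ]
        assert np.array_equal(coords[static], start.coords[static])
        # torsion negated by the rotation
        c_rhs2 = coords[list(bend.rhs)].mean(axis=0)
        assert dihedral_deg(c_rhs2, coords[a1], coords[a2], c_lhs) == pytest.approx(
            -tau, abs=1e-6
        )


class TestTwists:
    def test_cyclodecane_has_twenty_twists(self, cyclodecane):
        macro = chemgraph.perceive_macrocycles(cyclodecane)[0]
        twists = moves.enumerate_twists(cyclodecane, macro)
        assert len(twists) == 20
        # every ring bond twisted from both ends
        bonds = {tuple(sorted(t.atoms[1:3])) for t in twists}
        assert len(bonds) == 10

    def test_cyclohexane_has_none(self, cyclohexane):
        assert chemgraph.perceive_macrocycles(cyclohexane) == []

    def test_hexapeptide_excludes_amide_bonds(self, hexapeptide):
        """18-ring with 6 amide bonds: 12 twistable bonds, two ends each."""
        macro = chemgraph.perceive_macrocycles(hexapeptide)[0]
        twists = moves.enumerate_twists(hexapeptide, macro)
        assert len(twists) == 24
        amide_bonds = {
            tuple(sorted((b.GetBeginAtomIdx(), b.GetEndAtomIdx())))
            for b in hexapeptide.mol.GetBonds()
            if chemgraph._is_amide_bond(b) and b.IsInRing()
        }
        assert len(amide_bonds) == 6
        for t in twists:
            assert tuple(sorted(t.atoms[1:3])) not in amide_bonds

    def test_zero_twist_is_identity_and_redundant(
        self, cyclodecane, cyclodecane_engine, cyclodecane_start
    ):
        macro = chemgraph.perceive_macrocycles(cyclodecane)[0]
        start = cyclodecane_engine.minimize(cyclodecane_start).conformer
        twist = moves.enumerate_twists(cyclodecane, macro)[0]
        cand = moves.apply_twist(cyclodecane_engine, start, twist, angles=(0.0,))[0]
        assert kabsch_rmsd(cand.coords, start.coords) < 0.05

    def test_pinned_atoms_barely_move_during_pinned_phase(
        self, cyclodecane, cyclodecane_engine, cyclodecane_start
    ):
        from macroconf.ffmin import Pin, RestraintSet

        start = cyclodecane_engine.minimize(cyclodecane_start).conformer
        pins = RestraintSet(pins=[Pin(i, None) for i in (0, 1, 2)])
        res = cyclodecane_engine.minimize(start.copy(), pins)
        assert np.abs(res.conformer.coords[[0, 1, 2]] - start.coords[[0, 1, 2]]).max() < 0.1


class TestFlips:
    def test_enumeration_obeys_distance_and_dot_gates(self, cyclodecane):
        conf = memory_free_start(cyclodecane, seed=2)
        macro = chemgraph.perceive_macrocycles(cyclodecane)[0]
        for f in moves.enumerate_flips(cyclodecane, conf, macro):
            assert f.midpoint_distance >= moves.FLIP_MIN_MIDPOINT_DISTANCE
            assert f.min_dot > moves.FLIP_MIN_DOT

    def test_synthetic_gate_cases(self):
        """Constructed geometry: parallel bonds 5 A apart with the midpoint
        vector parallel to both pass; 3.9 A midpoints or dot products at the
        0.3 boundary are excluded."""
        d = moves.FLIP_MIN_MIDPOINT_DISTANCE

        def gate(m_dist, min_dot):
            return m_dist >= d and min_dot > moves.FLIP_MIN_DOT

        assert gate(5.0, 1.0)  # parallel bonds, V3 parallel: all dots ~ 1
        assert not gate(3.9, 1.0)  # too close
        assert not gate(5.0, 0.3)  # strict inequality at the dot threshold

    def test_flip_rotation_is_exact_isometry_and_involution(self, cyclodecane):
        conf = memory_free_start(cyclodecane, seed=2)
        macro = chemgraph.perceive_macrocycles(cyclodecane)[0]
        cycle = macro.main_cycle
        # construct a flip across the ring regardless of the geometric gates
        bonds = [(cycle[i], cycle[(i + 1) % 10]) for i in range(10)]
        flip = moves.Flip(
            lhs_bond=bonds[0], rhs_bond=bonds[5],
            arc=tuple(cycle[1:6]), min_dot=1.0, midpoint_distance=5.0,
        )
        once = moves.flip_rotation(conf, flip, cyclodecane)
        # isometry: all pairwise distances among moved atoms preserved
        moved = list(flip.arc)
        d0 = np.linalg.norm(
            conf.coords[moved][:, None] - conf.coords[moved][None], axis=-1
        )
        d1 = np.linalg.norm(once[moved][:, None] - once[moved][None], axis=-1)
        assert np.allclose(d0, d1, atol=1e-10)
        # distance of each moved atom to the flip axis preserved
        m1 = 0.5 * (conf.coords[flip.lhs_bond[0]] + conf.coords[flip.lhs_bond[1]])
        m2 = 0.5 * (conf.coords[flip.rhs_bond[0]] + conf.coords[flip.rhs_bond[1]])
        axis = (m2 - m1) / np.linalg.norm(m2 - m1)

        def axis_dist(pts):
            rel = pts - m1
            return np.linalg.norm(rel - np.outer(rel @ axis, axis), axis=1)

        assert np.allclose(axis_dist(conf.coords[moved]), axis_dist(once[moved]),
                           atol=1e-10)
        # involution: exact return to the original coordinates
        twice = moves.flip_rotation(Conformer(coords=once), flip, cyclodecane)
        assert np.allclose(twice, conf.coords, atol=1e-10)

    def test_arc_never_crosses_bridge_attachment(self, sfti_like):
        conf = memory_free_start(sfti_like, seed=0)
        macro = chemgraph.perceive_macrocycles(sfti_like)[0]
        attach = {p[0] for p in macro.bridges} | {p[-1] for p in macro.bridges}
        for f in moves.enumerate_flips(sfti_like, conf, macro):
            assert not set(f.arc) & attach


class TestBridgeFlip:
    def test_bridge_free_macrocycle_is_noop(self, cyclodecane):
        macro = chemgraph.perceive_macrocycles(cyclodecane)[0]
        assert macro.bridges == []

    def test_disulfide_bridge_flip_preserves_chirality(self, sfti_like):
        from macroconf.ffmin import check_chirality

        engine = ForceFieldEngine(sfti_like)
        start = memory_free_start(sfti_like, seed=0, engine=engine)
        macro = chemgraph.perceive_macrocycles(sfti_like)[0]
        cand = moves.apply_bridge_flip(engine, start, macro.bridges[0], macro)
        if cand is not None:  # retention rule may reject the candidate
            ok, bad = check_chirality(sfti_like, cand)
            assert ok and bad == []
            # signed-volume oracle over every recorded center
            from macroconf.ffmin import signed_volume

            for rec in sfti_like.stereo_records:
                if rec.kind != "tetrahedral":
                    continue
                center = rec.atoms[0]
                nbrs = [
                    n.GetIdx()
                    for n in sfti_like.mol.GetAtomWithIdx(center).GetNeighbors()
                ][:3]
                v_ref = signed_volume(start.coords, center, nbrs)
                v_new = signed_volume(cand.coords, center, nbrs)
                assert v_ref * v_new > 0


class TestHBondTopology:
    def test_cyclodecane_has_no_pairs(self, cyclodecane):
        macro = chemgraph.perceive_macrocycles(cyclodecane)[0]
        assert moves.enumerate_hbond_pairs(cyclodecane, macro) == []

    def test_minimum_turn_distance(self, sfti_like):
        macro = chemgraph.perceive_macrocycles(sfti_like)[0]
        for p in moves.enumerate_hbond_pairs(sfti_like, macro):
            assert p.path_length >= moves.HBOND_MIN_PATH

    def test_pairs_never_cross_a_bridge(self, sfti_like):
        macro = chemgraph.perceive_macrocycles(sfti_like)[0]
        cycle = macro.main_cycle
        n = len(cycle)
        pos = {a: i for i, a in enumerate(cycle)}
        attach = {p[0] for p in macro.bridges} | {p[-1] for p in macro.bridges}
        for p in moves.enumerate_hbond_pairs(sfti_like, macro):
            i, j = pos[p.donor_anchor], pos[p.acceptor_anchor]
            fwd, bwd = (j - i) % n, (i - j) % n
            k, step = (fwd, 1) if fwd <= bwd else (bwd, -1)
            walk = {cycle[(i + step * t) % n] for t in range(k + 1)}
            assert not (walk - {cycle[i], cycle[j]}) & attach

    def test_triplets_match_bruteforce_scan(self, sfti_like, aba_like, hexapeptide):
        """Enumeration equals a brute-force scan of all C(n,3) subsets with
        an independently coded compatibility predicate."""
        for graph in (sfti_like, aba_like, hexapeptide):
            macros = chemgraph.perceive_macrocycles(graph)
            if not macros:
                continue
            macro = macros[0]
            pairs = moves.enumerate_hbond_pairs(graph, macro)
            got = moves.enumerate_hbond_triplets(pairs, macro)
            n = macro.ring_size
            pos = {a: i for i, a in enumerate(macro.main_cycle)}

            def wrap(d):
                d %= n
                return d - n if d > n / 2 else d

            expected = 0
            for trio in itertools.combinations(pairs, 3):
                if len({p.donor_h for p in trio}) < 3:
                    continue
                if len({p.acceptor for p in trio}) < 3:
                    continue
                o = sorted(trio, key=lambda p: pos[p.donor_anchor])
                dp = [wrap(pos[o[k + 1].donor_anchor] - pos[o[k].donor_anchor]) for k in (0, 1)]
                da = [wrap(pos[o[k + 1].acceptor_anchor] - pos[o[k].acceptor_anchor]) for k in (0, 1)]
                if 0 in dp or 0 in da:
                    continue
                if da[0] == -dp[0] and da[1] == -dp[1]:
                    expected += 1
            assert len(got) == expected

    def test_same_direction_deltas_rejected(self, sfti_like):
        macro = chemgraph.perceive_macrocycles(sfti_like)[0]
        pairs = moves.enumerate_hbond_pairs(sfti_like, macro)
        for t in moves.enumerate_hbond_triplets(pairs, macro):
            assert tuple(-d for d in t.deltas_donor) == t.deltas_acceptor

    def test_fewer_than_three_pairs_gives_no_triplets(self, sfti_like):
        macro = chemgraph.perceive_macrocycles(sfti_like)[0]
        pairs = moves.enumerate_hbond_pairs(sfti_like, macro)[:2]
        assert moves.enumerate_hbond_triplets(pairs, macro) == []

    def test_enumeration_is_deterministic(self, sfti_like):
        macro = chemgraph.perceive_macrocycles(sfti_like)[0]
        a = moves.enumerate_hbond_pairs(sfti_like, macro)
        b = moves.enumerate_hbond_pairs(sfti_like, macro)
        assert a == b


@pytest.fixture(scope="module")
def setup(sfti_like):
    engine = ForceFieldEngine(sfti_like)
    base = memory_free_start(sfti_like, seed=0, engine=engine)
    macro = chemgraph.perceive_macrocycles(sfti_like)[0]
    pairs = moves.enumerate_hbond_pairs(sfti_like, macro)
    triplets = moves.enumerate_hbond_triplets(pairs, macro)
    return engine, base, triplets


class TestConstrainedStarts:
    def test_top_eight_plus_agnostic(self, sfti_like, setup):
        engine, base, triplets = setup
        assert len(triplets) > moves.TRIPLET_STARTS_KEPT
        embeds = []

        def embed(rs):
            embeds.append(rs)
            return memory_free_start(sfti_like, seed=0, restraints=rs, engine=engine)

        starts = moves.build_constrained_starts(
            sfti_like, triplets[:12], base, engine, embed
        )
        assert len(starts) == moves.TRIPLET_STARTS_KEPT + 1
        assert starts[-1][1] is None  # agnostic start appended last

    def test_fewer_triplets_all_kept(self, sfti_like, setup):
        engine, base, triplets = setup

        def embed(rs):
            return memory_free_start(sfti_like, seed=0, restraints=rs, engine=engine)

        starts = moves.build_constrained_starts(
            sfti_like, triplets[:2], base, engine, embed
        )
        assert len(starts) == 3

    def test_no_triplets_agnostic_only(self, sfti_like, setup):
        engine, base, _ = setup
        starts = moves.build_constrained_starts(sfti_like, [], base, engine,
                                                embed=lambda rs: base)
        assert len(starts) == 1 and starts[0][1] is None
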