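"""Search orchestration: starts, ring search, elaboration, ensemble assembly."""

import numpy as np
import pytest

from macroconf import chemgraph, fixtures
from macroconf.chemgraph import MolecularGraph
from macroconf.ffmin import Conformer, check_chirality
from macroconf.geometry import kabsch_rmsd
from macroconf.search import (
    ConformerEnsemble,
    SearchConfig,
    assemble_ensemble,
    exocyclic_elaboration,
    generate_conformers,
    hbond_network_search,
    memory_free_start,
    ring_search,
)


class TestSearchConfig:
    def test_mode_caps(self, benzene, hexapeptide):
        assert SearchConfig.from_mode("pfastf").resolve_cap(benzene) == 50
        assert SearchConfig.from_mode("pgeom").resolve_cap(benzene) == 250
        assert SearchConfig.from_mode("pquant").resolve_cap(benzene) == 1000
        # pscreen: flexibility-dependent 50 / 120 switch
        assert SearchConfig.from_mode("pscreen").resolve_cap(benzene) == 50
        assert chemgraph.total_flexibility(hexapeptide) > 8
        assert SearchConfig.from_mode("pscreen").resolve_cap(hexapeptide) == 120

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            SearchConfig.from_mode("pbogus")


class TestMemoryFreeStart:
    def test_input_coordinates_are_never_read(self, cyclohexane):
        """Scrambling any conformer attached to the input changes nothing."""
        from rdkit import Chem
        from rdkit.Geometry import Point3D

        ref = memory_free_start(cyclohexane, seed=3)
        poisoned = MolecularGraph(
            mol=Chem.Mol(cyclohexane.mol),
            stereo_records=list(cyclohexane.stereo_records),
        )
        conf = Chem.Conformer(poisoned.mol.GetNumAtoms())
        rng = np.random.default_rng(0)
        for i in range(poisoned.mol.GetNumAtoms()):
            x, y, z = rng.normal(0, 50, 3)
            conf.SetAtomPosition(i, Point3D(x, y, z))
        poisoned.mol.RemoveAllConformers()
        poisoned.mol.AddConformer(conf, assignId=True)
        again = memory_free_start(poisoned, seed=3)
        assert np.array_equal(ref.coords, again.coords)

    def test_stereocenter_configuration_matches_record(self):
        graph = MolecularGraph.from_smiles("C[C@H](N)C(=O)O")
        for seed in range(4):
            conf = memory_free_start(graph, seed=seed)
            ok, bad = check_chirality(graph, conf)
            assert ok, bad

    def test_start_is_far_from_any_particular_reference(self):
        """Over seeds, starts for a toy cyclic peptide typically land > 1 A
        ring RMSD away from an independently generated reference."""
        graph = fixtures.simple_peptide(5)
        macro = chemgraph.perceive_macrocycles(graph)[0]
        ring = sorted(macro.atoms)
        ref = memory_free_start(graph, seed=100)
        dists = [
            kabsch_rmsd(
                memory_free_start(graph, seed=s).coords[ring], ref.coords[ring]
            )
            for s in range(5)
        ]
        assert float(np.median(dists)) > 0.5
        assert max(dists) > 1.0


class TestRingSearch:
    def test_benzene_is_rigid(self, benzene):
        start = memory_free_start(benzene, seed=1)
        pool = ring_search(benzene, start, SearchConfig.from_mode("pgeomf"))
        assert len(pool) == 1

    def test_cyclohexane_recovers_chair_and_boat_families(
        self, cyclohexane, cyclohexane_start
    ):
        pool = ring_search(
            cyclohexane, cyclohexane_start, SearchConfig.from_mode("pgeom", max_rounds=6)
        )
        energies = sorted({round(c.energy, 1) for c in pool})
        assert len(pool) >= 2
        # chair family clearly below the twist-boat family
        assert energies[-1] - energies[0] > 4.0

    def test_energies_windowed_and_sorted(self, cyclohexane, cyclohexane_start):
        cfg = SearchConfig.from_mode("pgeom", max_rounds=4)
        pool = ring_search(cyclohexane, cyclohexane_start, cfg)
        es = [c.energy for c in pool]
        assert es == sorted(es)
        assert max(es) - min(es) <= cfg.final_window


class TestHBondNetworkSearch:
    def test_no_donors_equals_plain_ring_search(self, cyclodecane, cyclodecane_start):
        cfg = SearchConfig.from_mode("pgeom", max_rounds=1, max_conformers=20)
        plain = ring_search(cyclodecane, cyclodecane_start, cfg)
        networked = hbond_network_search(
            cyclodecane, cfg, start=cyclodecane_start
        )
        assert len(plain) == len(networked)
        for a, b in zip(plain, networked):
            assert np.array_equal(a.coords, b.coords)

    def test_triplet_capable_peptide_forms_hbonds(self):
        """The merged pool contains conformers with three simultaneous
        hydrogen bonds at short range."""
        peptide = fixtures.simple_peptide(7)
        cfg = SearchConfig.from_mode(
            "pgeom", max_rounds=1, max_conformers=4, use_flips=False,
            twist_angles=(120.0,), seed=0,
        )
        pool = hbond_network_search(peptide, cfg)
        assert pool
        from macroconf import moves

        macro = chemgraph.perceive_macrocycles(peptide)[0]
        pairs = moves.enumerate_hbond_pairs(peptide, macro)
        triplets = moves.enumerate_hbond_triplets(pairs, macro)
        best = 99.0
        for conf in pool:
            for t in triplets:
                d = max(
                    np.linalg.norm(conf.coords[p.donor_h] - conf.coords[p.acceptor])
                    for p in t.pairs
                )
                best = min(best, d)
        assert best <= 2.5


class TestExocyclicElaboration:
    def test_no_rotatables_is_identity(self, cyclohexane, cyclohexane_start):
        cfg = SearchConfig.from_mode("pgeomf")
        out = exocyclic_elaboration(cyclohexane, [cyclohexane_start], cfg)
        assert out == [cyclohexane_start]

    def test_pendant_chain_gets_multiple_rotamers(self):
        graph = MolecularGraph.from_smiles(fixtures.ETHYLBENZENE_SMILES)
        start = memory_free_start(graph, seed=1)
        cfg = SearchConfig.from_mode("pgeomf", max_rounds=2)
        out = exocyclic_elaboration(graph, [start], cfg)
        assert len(out) >= 2

    def test_cap_respected(self):
        graph = MolecularGraph.from_smiles("CCCCCC")  # flexible chain
        start = memory_free_start(graph, seed=1)
        cfg = SearchConfig.from_mode("pgeomf", max_conformers=5)
        out = exocyclic_elaboration(graph, [start], cfg)
        assert 1 <= len(out) <= 5


def _fake_conformers(n, energy_fn, spread=50.0, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n):
        coords = rng.uniform(-spread, spread, (6, 3)) + 100.0 * k
        out.append(Conformer(coords=coords, energy=float(energy_fn(k))))
    return out


class TestAssembleEnsemble:
    def test_window_rule(self, cyclohexane):
        confs = _fake_conformers(5, lambda k: 0.0 if k == 0 else 50.0 + k)
        cfg = SearchConfig.from_mode("pgeom")
        ens = assemble_ensemble(cyclohexane, confs, cfg)
        assert len(ens) == 1

    def test_duplicates_collapse_to_one(self, cyclohexane, cyclohexane_start):
        confs = [cyclohexane_start.copy() for _ in range(6)]
        for c in confs:
            c.energy = cyclohexane_start.energy
        ens = assemble_ensemble(cyclohexane, confs, SearchConfig.from_mode("pgeom"))
        assert len(ens) == 1

    def test_cap_with_lowest_always_included(self, cyclohexane):
        confs = _fake_conformers(300, lambda k: 0.01 * k)
        cfg = SearchConfig.from_mode("pgeom", max_conformers=100, search_window=10.0)
        ens = assemble_ensemble(cyclohexane, confs, cfg)
        assert len(ens) == 100
        assert ens.conformers[0].energy == min(c.energy for c in confs)
        rel = ens.relative_energies()
        assert (np.diff(rel) >= 0).all()


class TestGenerateConformers:
    def test_rigid_benzene_gives_one_conformer(self, benzene):
        for mode in ("pfastf", "pgeom"):
            ens = generate_conformers(benzene, SearchConfig.from_mode(mode))
            assert len(ens) == 1

    def test_deterministic_and_thread_independent(self, cyclohexane):
        cfgs = [
            SearchConfig.from_mode("pgeom", max_rounds=3, seed=7, threads=t)
            for t in (1, 3)
        ]
        ensembles = [generate_conformers(cyclohexane, c) for c in cfgs]
        assert len(ensembles[0]) == len(ensembles[1])
        for a, b in zip(*[e.conformers for e in ensembles]):
            assert np.array_equal(a.coords, b.coords)
            assert a.energy == b.energy

    def test_output_invariants(self, hexapeptide):
        """Window, cap, pairwise redundancy and chirality hold on output."""
        cfg = SearchConfig.from_mode(
            "pfast", max_rounds=1, max_conformers=12, seed=1
        )
        ens = generate_conformers(hexapeptide, cfg)
        assert 1 <= len(ens) <= 12
        rel = ens.relative_energies()
        assert rel.max() <= cfg.final_window + 1e-9
        heavy = hexapeptide.heavy_atoms()
        for i in range(len(ens)):
            ok, bad = check_chirality(hexapeptide, ens.conformers[i])
            assert ok, bad
            for j in range(i + 1, len(ens)):
                assert (
                    kabsch_rmsd(
                        ens.conformers[i].coords[heavy], ens.conformers[j].coords[heavy]
                    )
                    >= cfg.redundancy_heavy - 1e-9
                )

    def test_sdf_roundtrip_preserves_energies(self, tmp_path, cyclohexane):
        cfg = SearchConfig.from_mode("pgeomf", max_rounds=3)
        ens = generate_conformers(cyclohexane, cfg)
        path = tmp_path / "out.sdf"
        ens.write_sdf(path)
        back = ConformerEnsemble.from_sdf(path)
        assert len(back) == len(ens)
        for a, b in zip(ens, back):
            assert b.energy == pytest.approx(a.energy, abs=1e-5)
            assert kabsch_rmsd(a.coords, b.coords) < 1e-3
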