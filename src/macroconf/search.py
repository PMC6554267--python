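"""Search orchestration: memory-free starts, iterative ring search over all
movements, hydrogen-bond-network exploration, exocyclic torsional elaboration
and energy-windowed ensemble assembly.

The search is deterministic: move enumeration is a pure function of the graph
and conformer, candidates are processed in enumeration order, and parallel
move application merges results in task order, so the output is independent
of the thread count.
"""

from __future__ import annotations

import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Geometry import Point3D

from macroconf import chemgraph, moves
from macroconf.chemgraph import MolecularGraph
from macroconf.ffmin import Conformer, ForceFieldEngine, RestraintSet, check_chirality
from macroconf.geometry import kabsch_rmsd

#: per-mode defaults: (max conformers, max rounds, flips, hbond exploration)
MODE_TABLE = {
    "pfastf": dict(cap=50, rounds=2, flips=False, hbond=False),
    "pscreen": dict(cap=None, rounds=3, flips=False, hbond=False),  # 50 or 120
    "pfast": dict(cap=50, rounds=3, flips=False, hbond=False),
    "pgeomf": dict(cap=250, rounds=4, flips=True, hbond=False),
    "pgeom": dict(cap=250, rounds=25, flips=True, hbond=True),
    "pquantf": dict(cap=1000, rounds=25, flips=True, hbond=False),
    "pquant": dict(cap=1000, rounds=50, flips=True, hbond=True),
}
#: pscreen keeps 50 conformers unless the ligand is flexible (then 120)
PSCREEN_FLEX_THRESHOLD = 8


class StartGenerationError(RuntimeError):
    """3D structure generation kept inverting a recorded configuration."""


@dataclass
class SearchConfig:
    """Knobs of the conformational search.

    Energy windows are kcal/mol relative to the running minimum of the
    combined objective (force-field + violation energy): the ring phase
    retains and expands inside ``final_window``; ``search_window`` is the
    final ensemble window for non-macrocycles.  Redundancy thresholds are
    RMSD in Angstrom under fixed atom labeling.
    """

    mode: str = "pgeomf"
    max_conformers: int | None = None
    search_window: float = 10.0
    final_window: float = 20.0
    max_rounds: int | None = None
    redundancy_ring: float = 0.3
    redundancy_heavy: float = 0.3
    twist_angles: tuple = moves.DEFAULT_TWIST_ANGLES
    use_flips: bool | None = None
    hbond_exploration: bool | None = None
    threads: int = 1
    seed: int = 0

    @classmethod
    def from_mode(cls, mode: str, **overrides) -> "SearchConfig":
        if mode not in MODE_TABLE:
            raise ValueError(f"unknown search mode {mode!r}")
        return cls(mode=mode, **overrides)

    def resolve_cap(self, graph: MolecularGraph) -> int:
        if self.max_conformers is not None:
            return self.max_conformers
        cap = MODE_TABLE[self.mode]["cap"]
        if cap is None:  # pscreen: flexibility-dependent
            flex = chemgraph.total_flexibility(graph)
            cap = 120 if flex > PSCREEN_FLEX_THRESHOLD else 50
        return cap

    def resolve_rounds(self) -> int:
        return self.max_rounds if self.max_rounds is not None else MODE_TABLE[self.mode]["rounds"]

    def resolve_flips(self) -> bool:
        return MODE_TABLE[self.mode]["flips"] if self.use_flips is None else self.use_flips

    def resolve_hbond(self) -> bool:
        return (
            MODE_TABLE[self.mode]["hbond"]
            if self.hbond_exploration is None
            else self.hbond_exploration
        )


@dataclass
class ConformerEnsemble:
    """Energy-sorted, windowed, redundancy-pruned conformer pool."""

    graph: MolecularGraph
    conformers: list
    metadata: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.conformers)

    def __iter__(self):
        return iter(self.conformers)

    @property
    def min_energy(self) -> float:
        return min(c.energy for c in self.conformers)

    def relative_energies(self) -> np.ndarray:
        e0 = self.min_energy
        return np.array([c.energy - e0 for c in self.conformers])

    def write_sdf(self, path: str):
        mol = Chem.Mol(self.graph.mol)
        mol.RemoveAllConformers()
        writer = Chem.SDWriter(str(path))
        try:
            e0 = self.min_energy
            for k, c in enumerate(self.conformers):
                conf = Chem.Conformer(mol.GetNumAtoms())
                for i, (x, y, z) in enumerate(c.coords):
                    conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
                m = Chem.Mol(mol)
                m.AddConformer(conf, assignId=True)
                m.SetProp("_Name", f"conformer_{k}")
                m.SetProp("energy_kcal_mol", f"{c.energy:.6f}")
                m.SetProp("relative_energy_kcal_mol", f"{c.energy - e0:.6f}")
                m.SetProp("violation_energy_kcal_mol", f"{c.violation_energy:.6f}")
                m.SetProp("provenance", ";".join(c.provenance) or "start")
                writer.write(m)
        finally:
            writer.close()

    @classmethod
    def from_sdf(cls, path: str) -> "ConformerEnsemble":
        mols = [m for m in Chem.SDMolSupplier(str(path), removeHs=False) if m is not None]
        if not mols:
            raise ValueError(f"no molecules in {path}")
        graph = MolecularGraph.from_rdkit(mols[0], "sdf")
        engine = ForceFieldEngine(graph)
        confs = []
        for m in mols:
            coords = np.array(m.GetConformer().GetPositions(), dtype=float)
            if m.HasProp("energy_kcal_mol"):
                e = float(m.GetProp("energy_kcal_mol"))
            else:
                e = engine.energy(coords)
            prov = m.GetProp("provenance").split(";") if m.HasProp("provenance") else []
            viol = float(m.GetProp("violation_energy_kcal_mol")) if m.HasProp(
                "violation_energy_kcal_mol") else 0.0
            confs.append(Conformer(coords=coords, energy=e, violation_energy=viol,
                                   provenance=prov))
        return cls(graph=graph, conformers=confs)


# ---------------------------------------------------------------------------
# memory-free 3D starts


def memory_free_start(
    graph: MolecularGraph,
    seed: int = 0,
    restraints: RestraintSet | None = None,
    engine: ForceFieldEngine | None = None,
    max_retries: int = 20,
) -> Conformer:
    """A 3D structure generated from topology and recorded stereo only.

    Any coordinates on the input are ignored (the generation path reads only
    the bond graph and stereo records, emulating coordinate zeroing).  The
    result is minimized (restraints active, if given) and its chirality
    verified against the records; generation retries with perturbed seeds and
    raises :class:`StartGenerationError` if every retry inverts a center.
    """
    engine = engine or ForceFieldEngine(graph)
    mol = Chem.Mol(graph.mol)
    mol.RemoveAllConformers()
    last_violation = None
    for attempt in range(max_retries):
        params = AllChem.ETKDGv3()
        params.randomSeed = (seed * 101 + attempt * 7919 + 1) % (2**31 - 1)
        params.useRandomCoords = attempt >= max_retries // 2
        ok = AllChem.EmbedMolecule(mol, params)
        if ok != 0:
            continue
        coords = np.array(mol.GetConformer().GetPositions(), dtype=float)
        cand = Conformer(coords=coords, provenance=["start"])
        res = engine.minimize(cand, restraints)
        good, bad = check_chirality(graph, res.conformer)
        if good:
            return res.conformer
        last_violation = bad
    raise StartGenerationError(
        f"3D generation failed to preserve recorded configurations: {last_violation}"
    )


# ---------------------------------------------------------------------------
# redundancy


def _ring_atoms(graph: MolecularGraph) -> list:
    atoms = [a.GetIdx() for a in graph.mol.GetAtoms() if a.IsInRing()]
    return atoms or graph.heavy_atoms()


def combined_score(c) -> float:
    """Search objective: force-field energy plus restraint violation energy
    (the violation term is zero for unconstrained searches)."""
    return c.energy + c.violation_energy


def is_redundant(
    candidate: Conformer,
    pool: list,
    atom_ids: list,
    threshold: float,
    energy_prefilter: float = 1.0,
) -> bool:
    """Fixed-labeling RMSD duplicate test against a pool, restricted to
    conformers of similar energy (duplicate minima have matching energies)."""
    sel = list(atom_ids)
    p = candidate.coords[sel]
    for other in pool:
        if (
            candidate.energy is not None
            and other.energy is not None
            and abs(combined_score(candidate) - combined_score(other)) > energy_prefilter
        ):
            continue
        if kabsch_rmsd(p, other.coords[sel]) < threshold:
            return True
    return False


# ---------------------------------------------------------------------------
# ring search


def _move_tasks(engine, graph, conformer, config, restraints, systems, macros):
    """Deterministically ordered move applications for one conformer."""
    tasks = []
    for system in systems:
        for bend in moves.enumerate_bends(graph, system):
            tasks.append(
                lambda eng, c=conformer, b=bend, s=system: [
                    x for x in [moves.apply_bend(eng, c, b, s, restraints)] if x
                ]
            )
    for macro in macros:
        for twist in moves.enumerate_twists(graph, macro):
            tasks.append(
                lambda eng, c=conformer, t=twist: moves.apply_twist(
                    eng, c, t, config.twist_angles, restraints
                )
            )
        if config.resolve_flips():
            for flip in moves.enumerate_flips(graph, conformer, macro):
                tasks.append(
                    lambda eng, c=conformer, f=flip: [
                        x for x in [moves.apply_flip(eng, c, f, restraints)] if x
                    ]
                )
            for bridge in macro.bridges:
                if len(bridge) > 2:
                    tasks.append(
                        lambda eng, c=conformer, br=bridge, m=macro: [
                            x
                            for x in [moves.apply_bridge_flip(eng, c, br, m, restraints)]
                            if x
                        ]
                    )
    return tasks


def _run_tasks(tasks, engines):
    """Run move tasks across engines; results concatenated in task order."""
    if len(engines) == 1 or len(tasks) <= 1:
        out = []
        for t in tasks:
            out.extend(t(engines[0]))
        return out
    results = [None] * len(tasks)

    def run_chunk(eng_idx):
        eng = engines[eng_idx]
        for i in range(eng_idx, len(tasks), len(engines)):
            results[i] = tasks[i](eng)

    with ThreadPoolExecutor(max_workers=len(engines)) as pool:
        list(pool.map(run_chunk, range(len(engines))))
    out = []
    for r in results:
        out.extend(r or [])
    return out


def ring_search(
    graph: MolecularGraph,
    start: Conformer,
    config: SearchConfig,
    restraints: RestraintSet | None = None,
    engine: ForceFieldEngine | None = None,
) -> list:
    """Fixed-point iteration of all ring movements over an evolving pool.

    Every candidate is minimized (restraints active), checked for chirality
    and the energy window, and added when non-redundant by ring-atom RMSD.
    Iteration stops when a round finds nothing new, the round cap is reached,
    or the pool hits the mode's conformer cap.
    """
    engine = engine or ForceFieldEngine(graph)
    engines = [engine] + [
        ForceFieldEngine(graph) for _ in range(max(0, config.threads - 1))
    ]
    macros = chemgraph.perceive_macrocycles(graph)
    systems = chemgraph.small_ring_components(graph)
    ring_ids = _ring_atoms(graph)
    res = engine.minimize(start, restraints)
    pool = [res.conformer]
    cap = config.resolve_cap(graph)
    frontier = [res.conformer]
    for _round in range(config.resolve_rounds()):
        if not frontier or len(pool) >= cap:
            break
        next_frontier = []
        e_min = min(combined_score(c) for c in pool)
        for conf in frontier:
            if combined_score(conf) > e_min + config.final_window:
                continue
            tasks = _move_tasks(engine, graph, conf, config, restraints, systems, macros)
            for cand in _run_tasks(tasks, engines):
                if len(pool) >= cap:
                    break
                if cand.energy is None or not math.isfinite(cand.energy):
                    continue
                e_min = min(e_min, combined_score(cand))
                if combined_score(cand) > e_min + config.final_window:
                    continue
                ok, _bad = check_chirality(graph, cand)
                if not ok:
                    continue
                if is_redundant(cand, pool, ring_ids, config.redundancy_ring):
                    continue
                pool.append(cand)
                next_frontier.append(cand)
            if len(pool) >= cap:
                break
        frontier = next_frontier
    e_min = min(combined_score(c) for c in pool)
    pool = [c for c in pool if combined_score(c) <= e_min + config.final_window]
    pool.sort(key=combined_score)
    return pool


def hbond_network_search(
    graph: MolecularGraph,
    config: SearchConfig,
    restraints: RestraintSet | None = None,
    engine: ForceFieldEngine | None = None,
    start: Conformer | None = None,
) -> list:
    """Ring search from each hydrogen-bond-triplet constrained start plus the
    agnostic start, merged by energy with redundancy pruning."""
    engine = engine or ForceFieldEngine(graph)
    base = start if start is not None else memory_free_start(
        graph, config.seed, restraints, engine
    )
    macros = chemgraph.perceive_macrocycles(graph)
    triplets = []
    for macro in macros:
        pairs = moves.enumerate_hbond_pairs(graph, macro)
        triplets.extend(moves.enumerate_hbond_triplets(pairs, macro))
    if not triplets:
        return ring_search(graph, base, config, restraints, engine)
    starts = moves.build_constrained_starts(
        graph,
        triplets,
        base,
        engine,
        embed=lambda rs: memory_free_start(
            graph, config.seed, rs.merged_with(restraints), engine
        ),
        restraints=restraints,
    )
    merged = []
    ring_ids = _ring_atoms(graph)
    for start_conf, triplet_rs in starts:
        rs = triplet_rs.merged_with(restraints) if triplet_rs else restraints
        merged.extend(ring_search(graph, start_conf, config, rs, engine))
    # the triplet wells are search scaffolding: re-score each conformer
    # against the data restraints only before merging by energy
    for c in merged:
        c.violation_energy = restraints.violation_energy(c.coords) if restraints else 0.0
    merged.sort(key=combined_score)
    out = []
    for cand in merged:
        if not is_redundant(cand, out, ring_ids, config.redundancy_ring):
            out.append(cand)
    e_min = min(combined_score(c) for c in out)
    out = [c for c in out if combined_score(c) <= e_min + config.final_window]
    return out[: config.resolve_cap(graph)]


# ---------------------------------------------------------------------------
# exocyclic elaboration


#: strict rotatable bond: non-ring single bond between non-terminal heavy
#: atoms, amide-like C-N bonds excluded
_ROTATABLE_SMARTS = Chem.MolFromSmarts(
    "[!$(*#*)&!D1&!$([CX3](=[OX1])[NX3])&!$([NX3][CX3]=[OX1])]-&!@"
    "[!$(*#*)&!D1&!$([CX3](=[OX1])[NX3])&!$([NX3][CX3]=[OX1])]"
)


def _exocyclic_rotatable_bonds(graph: MolecularGraph) -> list:
    mol = graph.mol
    out = set()
    for i, j in mol.GetSubstructMatches(_ROTATABLE_SMARTS):
        bond = mol.GetBondBetweenAtoms(i, j)
        if bond.IsInRing():
            continue
        out.add(tuple(sorted((i, j))))
    return sorted(out)


def _moving_side(graph: MolecularGraph, i: int, j: int) -> list:
    """Atoms on the j side of bond i-j (the side that rotates), j included."""
    import networkx as nx

    g = graph.to_networkx()
    g.remove_edge(i, j)
    return sorted(nx.node_connected_component(g, j))


def _set_dihedral(coords, graph, a, b, c, d, value_deg):
    import math as _m

    cur = moves.dihedral_deg(coords[a], coords[b], coords[c], coords[d])
    delta = value_deg - cur
    axis = coords[c] - coords[b]
    n = np.linalg.norm(axis)
    if n < 1e-9:
        return
    side = _moving_side(graph, b, c)
    moves._rotate_about_axis(coords, side, coords[b], axis / n, _m.radians(delta))


def exocyclic_elaboration(
    graph: MolecularGraph,
    ring_conformers: list,
    config: SearchConfig,
    restraints: RestraintSet | None = None,
    engine: ForceFieldEngine | None = None,
) -> list:
    """Greedy torsion driving of exocyclic rotatable bonds.

    For each rotatable bond in turn, each pool member is branched over a
    staggered (sp3: +-60/180) or planar (conjugated: 0/180) target set, each
    branch minimized, and the pool deduplicated by heavy-atom RMSD, windowed
    and capped.  With no exocyclic rotatables the input pool is returned
    unchanged.
    """
    bonds = _exocyclic_rotatable_bonds(graph)
    if not bonds:
        return list(ring_conformers)
    engine = engine or ForceFieldEngine(graph)
    heavy = graph.heavy_atoms()
    cap = config.resolve_cap(graph)
    mol = graph.mol
    pool = list(ring_conformers)
    for i, j in bonds:
        heavy_nb_i = sorted(
            n.GetIdx() for n in mol.GetAtomWithIdx(i).GetNeighbors()
            if n.GetAtomicNum() > 1 and n.GetIdx() != j
        )
        heavy_nb_j = sorted(
            n.GetIdx() for n in mol.GetAtomWithIdx(j).GetNeighbors()
            if n.GetAtomicNum() > 1 and n.GetIdx() != i
        )
        if not heavy_nb_i or not heavy_nb_j:
            continue
        a, d = heavy_nb_i[0], heavy_nb_j[0]
        conjugated = any(
            mol.GetAtomWithIdx(k).GetIsAromatic()
            or mol.GetAtomWithIdx(k).GetHybridization() == Chem.HybridizationType.SP2
            for k in (i, j)
        )
        values = (0.0, 180.0) if conjugated else (60.0, -60.0, 180.0)
        out = []
        for conf in pool:
            out.append(conf)
            for v in values:
                coords = conf.coords.copy()
                _set_dihedral(coords, graph, a, i, j, d, v)
                cand = Conformer(
                    coords=coords, provenance=conf.provenance + [f"tors({i}-{j})={v:+.0f}"]
                )
                try:
                    res = engine.minimize(cand, restraints)
                except Exception:
                    continue
                c = res.conformer
                if c.energy is None or not math.isfinite(c.energy):
                    continue
                ok, _bad = check_chirality(graph, c)
                if not ok:
                    continue
                if not is_redundant(c, out, heavy, config.redundancy_heavy):
                    out.append(c)
        out.sort(key=combined_score)
        e_min = combined_score(out[0])
        pool = [c for c in out if combined_score(c) <= e_min + config.final_window][: max(cap, 1)]
    return pool


# ---------------------------------------------------------------------------
# assembly and pipeline


def assemble_ensemble(
    graph: MolecularGraph, conformers: list, config: SearchConfig
) -> ConformerEnsemble:
    """Sort by energy, apply the final window, prune redundant conformers by
    heavy-atom RMSD (keeping the lowest-energy exemplar of each cluster) and
    truncate to the mode cap."""
    if not conformers:
        raise ValueError("no conformers to assemble")
    is_macro = bool(chemgraph.perceive_macrocycles(graph))
    window = config.final_window if is_macro else config.search_window
    heavy = graph.heavy_atoms()
    ordered = sorted(conformers, key=combined_score)
    e_min = combined_score(ordered[0])
    kept = []
    cap = config.resolve_cap(graph)
    for cand in ordered:
        if combined_score(cand) > e_min + window:
            break
        if is_redundant(cand, kept, heavy, config.redundancy_heavy):
            continue
        kept.append(cand)
        if len(kept) >= cap:
            break
    meta = {
        "mode": config.mode,
        "force_field": "MMFF94s",
        "final_window_kcal_mol": window,
        "cap": cap,
        "n_input": len(conformers),
        "macrocyclic": is_macro,
    }
    return ConformerEnsemble(graph=graph, conformers=kept, metadata=meta)


def generate_conformers(
    graph: MolecularGraph,
    config: SearchConfig | None = None,
    constraints=None,
) -> ConformerEnsemble:
    """Full pipeline: memory-free start -> ring search (with hydrogen-bond
    network exploration when enabled and applicable) -> exocyclic torsional
    elaboration -> windowed, capped ensemble.  NMR constraints, when given,
    are active during start generation and every minimization."""
    config = config or SearchConfig()
    engine = ForceFieldEngine(graph)
    restraints = None
    if constraints is not None:
        restraints = (
            constraints.to_restraints(graph)
            if hasattr(constraints, "to_restraints")
            else constraints
        )
    macros = chemgraph.perceive_macrocycles(graph)
    donors, _acc = chemgraph.find_donors_acceptors(graph)
    start = memory_free_start(graph, config.seed, restraints, engine)
    if config.resolve_hbond() and macros and donors:
        ring_pool = hbond_network_search(graph, config, restraints, engine, start=start)
    else:
        ring_pool = ring_search(graph, start, config, restraints, engine)
    full_pool = exocyclic_elaboration(graph, ring_pool, config, restraints, engine)
    ensemble = assemble_ensemble(graph, full_pool, config)
    ensemble.metadata["n_ring_conformers"] = len(ring_pool)
    ensemble.metadata["seed"] = config.seed
    return ensemble
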