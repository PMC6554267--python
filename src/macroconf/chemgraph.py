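"""Molecular graph perception.

This module wraps an RDKit molecule in a light :class:`MolecularGraph` and
derives the structural annotations that drive conformational search:

* small-ring systems (every internal bond belongs to a ring of size 3-8),
* macrocyclic systems (ring systems containing a cycle of nine or more atoms),
  including their bridges (e.g. disulfides) and a canonical numbering of the
  main cycle,
* hydrogen-bond donors and acceptors,
* the total-flexibility descriptor (exocyclic rotatable bonds plus non-amide
  macrocyclic single bonds).

A ring bond is *macrocyclic* iff its smallest enclosing ring has at least
:data:`MACROCYCLE_THRESHOLD` atoms; this single definition is used everywhere.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

MACROCYCLE_THRESHOLD = 9

#: Elements with MMFF parameters; anything else is rejected on import.
SUPPORTED_ELEMENTS = frozenset("H C N O P S F Cl Br I".split())


class PerceptionError(ValueError):
    """Raised when a molecule cannot be interpreted."""


@dataclass(frozen=True)
class StereoRecord:
    """A stereocenter noted on input, checked after every move.

    ``kind`` is ``"tetrahedral"`` or ``"double_bond"``; ``atoms`` are the
    center atom (tetrahedral) or the two doubly-bonded atoms; ``label`` is the
    recorded configuration (CIP code or RDKit stereo tag name).
    """

    kind: str
    atoms: tuple
    label: str


@dataclass
class RingSystem:
    """A connected system of small rings (every bond in a ring of size 3-8).

    ``planar_atoms`` flags individual atoms (aromatic or sp2/sp);
    ``nonplanar_ring_atoms`` holds every atom belonging to at least one
    non-planar ring (a ring with at least one non-planar atom) — the bend
    eligibility rule is expressed at the ring level.
    """

    atoms: frozenset
    bonds: frozenset
    planar_atoms: frozenset
    nonplanar_ring_atoms: frozenset
    fusion_atoms: frozenset
    bridge_atoms: frozenset
    is_macrocyclic: bool = False


@dataclass
class MacrocycleSystem:
    """A ring system containing at least one macrocyclic bond.

    ``main_cycle`` is the ordered atom list of the macrocyclic ring with
    bridges excised; its length is ``ring_size``.  ``bridges`` are shortest
    paths (inclusive of their endpoint attachment atoms, which lie on the main
    cycle) that shortcut the main cycle.
    """

    system_id: int
    atoms: frozenset
    bonds: frozenset
    macro_bonds: frozenset
    main_cycle: list
    bridges: list = field(default_factory=list)
    small_ring_systems: list = field(default_factory=list)

    @property
    def ring_size(self) -> int:
        return len(self.main_cycle)

    @property
    def bridge_atoms(self) -> frozenset:
        """Internal atoms of all bridges (attachment atoms excluded)."""
        out = set()
        for path in self.bridges:
            out.update(path[1:-1])
        return frozenset(out)

    def position(self, atom: int) -> int:
        """Index of ``atom`` along the main cycle."""
        return self.main_cycle.index(atom)


@dataclass
class MolecularGraph:
    """A molecule with explicit hydrogens and recorded stereochemistry."""

    mol: Chem.Mol
    stereo_records: list
    source_format: str = "smiles"

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, source_format: str = "smiles") -> "MolecularGraph":
        if mol is None:
            raise PerceptionError("molecule could not be parsed")
        mol = Chem.AddHs(Chem.Mol(mol), addCoords=mol.GetNumConformers() > 0)
        Chem.SanitizeMol(mol)
        Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
        bad = [
            (a.GetIdx(), a.GetSymbol())
            for a in mol.GetAtoms()
            if a.GetSymbol() not in SUPPORTED_ELEMENTS
        ]
        if bad:
            raise PerceptionError(
                "unsupported elements (no MMFF parameters): "
                + ", ".join(f"{s}@{i}" for i, s in bad)
            )
        return cls(mol=mol, stereo_records=_note_stereo(mol), source_format=source_format)

    @classmethod
    def from_smiles(cls, smiles: str) -> "MolecularGraph":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise PerceptionError(f"bad SMILES: {smiles!r}")
        return cls.from_rdkit(mol, "smiles")

    @classmethod
    def from_sdf(cls, path: str) -> list:
        """All molecules of an SDF (V2000) file."""
        out = []
        for mol in Chem.SDMolSupplier(str(path), removeHs=False):
            if mol is not None:
                out.append(cls.from_rdkit(mol, "sdf"))
        return out

    @classmethod
    def from_mol2(cls, path: str) -> "MolecularGraph":
        mol = Chem.MolFromMol2File(str(path), removeHs=False)
        if mol is None:
            raise PerceptionError(f"could not parse mol2 file {path}")
        return cls.from_rdkit(mol, "mol2")

    @classmethod
    def from_file(cls, path: str):
        p = str(path)
        if p.endswith(".sdf") or p.endswith(".mol"):
            return cls.from_sdf(p)
        if p.endswith(".mol2"):
            return [cls.from_mol2(p)]
        # anything else: SMILES file, one molecule per line
        out = []
        with open(p) as fh:
            for line in fh:
                line = line.split()
                if line:
                    out.append(cls.from_smiles(line[0]))
        return out

    # -- basic views ------------------------------------------------------

    @property
    def num_atoms(self) -> int:
        return self.mol.GetNumAtoms()

    def heavy_atoms(self) -> list:
        return [a.GetIdx() for a in self.mol.GetAtoms() if a.GetAtomicNum() > 1]

    def to_networkx(self, ring_bonds_only: bool = False) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.mol.GetNumAtoms()))
        for b in self.mol.GetBonds():
            if ring_bonds_only and not b.IsInRing():
                continue
            g.add_edge(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), idx=b.GetIdx())
        return g


def _note_stereo(mol: Chem.Mol) -> list:
    records = []
    for atom, code in Chem.FindMolChiralCenters(
        mol, includeUnassigned=False, useLegacyImplementation=False
    ):
        records.append(StereoRecord("tetrahedral", (atom,), code))
    for bond in mol.GetBonds():
        st = bond.GetStereo()
        if st in (Chem.BondStereo.STEREOE, Chem.BondStereo.STEREOZ,
                  Chem.BondStereo.STEREOCIS, Chem.BondStereo.STEREOTRANS):
            label = {Chem.BondStereo.STEREOE: "E", Chem.BondStereo.STEREOZ: "Z",
                     Chem.BondStereo.STEREOCIS: "Z", Chem.BondStereo.STEREOTRANS: "E"}[st]
            records.append(
                StereoRecord("double_bond", (bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()), label)
            )
    return records


# ---------------------------------------------------------------------------
# ring-size bookkeeping


def smallest_enclosing_ring_size(graph: MolecularGraph, bond: Chem.Bond) -> int:
    """Atom count of the smallest ring containing ``bond`` (0 if acyclic bond)."""
    if not bond.IsInRing():
        return 0
    g = graph.to_networkx()
    u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
    g.remove_edge(u, v)
    return nx.shortest_path_length(g, u, v) + 1


def _bond_ring_sizes(graph: MolecularGraph) -> dict:
    """bond idx -> smallest enclosing ring size, for every ring bond."""
    g = graph.to_networkx()
    sizes = {}
    for b in graph.mol.GetBonds():
        if not b.IsInRing():
            continue
        u, v = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        g.remove_edge(u, v)
        sizes[b.GetIdx()] = nx.shortest_path_length(g, u, v) + 1
        g.add_edge(u, v)
    return sizes


def macrocyclic_bond_indices(graph: MolecularGraph) -> frozenset:
    """Ring bonds whose smallest enclosing ring has >= 9 atoms."""
    return frozenset(
        i for i, s in _bond_ring_sizes(graph).items() if s >= MACROCYCLE_THRESHOLD
    )


def _is_planar(atom: Chem.Atom) -> bool:
    return atom.GetIsAromatic() or atom.GetHybridization() in (
        Chem.HybridizationType.SP2,
        Chem.HybridizationType.SP,
    )


def _ring_bond_components(graph: MolecularGraph, bond_ids):
    """Connected components (atom sets) of the given ring bonds."""
    g = nx.Graph()
    mol = graph.mol
    for bid in bond_ids:
        b = mol.GetBondWithIdx(bid)
        g.add_edge(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), idx=bid)
    return [g.subgraph(c).copy() for c in nx.connected_components(g)]


def _make_ring_system(graph: MolecularGraph, sub: nx.Graph, is_macro=False) -> RingSystem:
    mol = graph.mol
    atoms = frozenset(sub.nodes)
    bonds = frozenset(d["idx"] for _, _, d in sub.edges(data=True))
    planar = frozenset(a for a in atoms if _is_planar(mol.GetAtomWithIdx(a)))
    ri = mol.GetRingInfo()
    rings = [set(r) for r in ri.AtomRings() if set(r) <= atoms]
    nonplanar_ring = set()
    for r in rings:
        if not r <= planar:
            nonplanar_ring |= r
    fusion, bridgehead = set(), set()
    for r1, r2 in itertools.combinations(rings, 2):
        shared = r1 & r2
        if len(shared) == 2:
            fusion.update(shared)
        elif len(shared) > 2:
            # bridged bicyclic: the shared path's endpoints are bridgeheads
            bridgehead.update(a for a in shared if sub.degree(a) >= 3)
    return RingSystem(
        atoms=atoms,
        bonds=bonds,
        planar_atoms=planar,
        nonplanar_ring_atoms=frozenset(nonplanar_ring),
        fusion_atoms=frozenset(fusion),
        bridge_atoms=frozenset(bridgehead),
        is_macrocyclic=is_macro,
    )


def perceive_ring_systems(graph: MolecularGraph) -> list:
    """Small-ring systems: components of ring bonds whose smallest enclosing
    ring has 3-8 atoms, excluding systems attached to a macrocyclic component.

    Small-ring systems fused *into* a macrocyclic system are reported on the
    corresponding :class:`MacrocycleSystem` instead.
    """
    sizes = _bond_ring_sizes(graph)
    small = [i for i, s in sizes.items() if s < MACROCYCLE_THRESHOLD]
    macro_atoms = set()
    for m in perceive_macrocycles(graph):
        macro_atoms |= m.atoms
    out = []
    for sub in _ring_bond_components(graph, small):
        if set(sub.nodes) & macro_atoms:
            continue
        out.append(_make_ring_system(graph, sub))
    out.sort(key=lambda s: min(s.atoms))
    return out


def small_ring_components(graph: MolecularGraph) -> list:
    """All small-ring systems, including those inside macrocyclic systems
    (these are the units that ring bending operates on)."""
    sizes = _bond_ring_sizes(graph)
    small = [i for i, s in sizes.items() if s < MACROCYCLE_THRESHOLD]
    out = [_make_ring_system(graph, sub) for sub in _ring_bond_components(graph, small)]
    out.sort(key=lambda s: min(s.atoms))
    return out


def _segments(g: nx.Graph):
    """Maximal chains between junction nodes (degree >= 3) whose internal
    nodes all have degree 2, as ordered node lists (canonical orientation)."""
    junctions = sorted(n for n in g if g.degree(n) >= 3)
    segs = set()
    for u in junctions:
        for first in sorted(g.neighbors(u)):
            path = [u, first]
            prev, cur = u, first
            while g.degree(cur) == 2 and cur not in junctions:
                nxt = next(n for n in g.neighbors(cur) if n != prev)
                path.append(nxt)
                prev, cur = cur, nxt
            if path[-1] in junctions and path[-1] != u or (path[-1] == u and len(path) > 3):
                key = tuple(path) if path[0] <= path[-1] else tuple(reversed(path))
                segs.add(key)
    return sorted(segs, key=lambda s: (len(s), s))


def _extract_bridges(sub: nx.Graph, macro_edges: set):
    """Strip bridges, then trace the main macrocyclic cycle.

    A junction-pair path qualifies as a bridge only when its removal leaves
    at least two internally disjoint paths made purely of macrocyclic bonds
    (the two arcs of the main cycle).  A fused small ring (e.g. proline)
    offers only one all-macrocyclic path between its junctions, so it is
    never treated as a bridge.  Returns (main_cycle, bridges).
    """

    work = sub.copy()
    bridges = []
    for _ in range(64):  # safety bound
        candidates = []
        for seg in _segments(work):
            u, v = seg[0], seg[-1]
            probe = work.copy()
            if len(seg) == 2:
                probe.remove_edge(u, v)
            else:
                probe.remove_nodes_from(seg[1:-1])
            try:
                alt = nx.shortest_path_length(probe, u, v)
            except (nx.NetworkXNoPath, nx.NodeNotFound):
                continue
            # (a) the smallest cycle through the segment is macrocyclic
            if len(seg) - 1 + alt < MACROCYCLE_THRESHOLD:
                continue
            # (b) the segment is strictly the shortest connection (the
            # convention: the shortest path between attachments is the bridge)
            if alt <= len(seg) - 1:
                continue
            # (c) removal leaves the main cycle intact through both ends
            try:
                n_disjoint = len(list(nx.node_disjoint_paths(probe, u, v)))
            except (nx.NetworkXNoPath, nx.NetworkXError):
                continue
            if n_disjoint < 2:
                continue
            candidates.append(seg)
        if not candidates:
            break
        bridge = min(candidates, key=lambda s: (len(s), s))
        bridges.append(list(bridge))
        if len(bridge) == 2:
            work.remove_edge(bridge[0], bridge[1])
        else:
            work.remove_nodes_from(bridge[1:-1])
    # main cycle: close the smallest-indexed macrocyclic bond that survived
    # bridge removal by the shortest remaining path between its atoms
    surviving = sorted(
        e for e in macro_edges if work.has_edge(*e)
    )
    main = None
    for u, v in surviving:
        work.remove_edge(u, v)
        try:
            path = nx.shortest_path(work, u, v)
        except nx.NetworkXNoPath:
            path = None
        work.add_edge(u, v)
        if path is not None:
            main = path
            break
    if main is None:
        cycles = nx.cycle_basis(work)
        if not cycles:
            raise PerceptionError("macrocyclic system decomposition failed")
        main = max(cycles, key=len)
    # canonical orientation: start at smallest atom index, walk toward the
    # smaller of its two neighbours
    i = main.index(min(main))
    main = main[i:] + main[:i]
    if main[-1] < main[1]:
        main = [main[0]] + main[1:][::-1]
    return main, bridges


def perceive_macrocycles(graph: MolecularGraph) -> list:
    """Macrocyclic ring systems with bridges and a numbered main cycle."""
    sizes = _bond_ring_sizes(graph)
    macro_bonds = {i for i, s in sizes.items() if s >= MACROCYCLE_THRESHOLD}
    if not macro_bonds:
        return []
    out = []
    for sid, sub in enumerate(_ring_bond_components(graph, sizes.keys())):
        bond_ids = frozenset(d["idx"] for _, _, d in sub.edges(data=True))
        sys_macro = bond_ids & macro_bonds
        if not sys_macro:
            continue
        mol = graph.mol
        macro_edges = set()
        for bid in sys_macro:
            b = mol.GetBondWithIdx(bid)
            u, v = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            macro_edges.add((min(u, v), max(u, v)))
        main, bridges = _extract_bridges(sub, macro_edges)
        small_ids = [i for i in bond_ids if sizes[i] < MACROCYCLE_THRESHOLD]
        small_systems = [
            _make_ring_system(graph, s) for s in _ring_bond_components(graph, small_ids)
        ]
        small_systems.sort(key=lambda s: min(s.atoms))
        out.append(
            MacrocycleSystem(
                system_id=sid,
                atoms=frozenset(sub.nodes),
                bonds=bond_ids,
                macro_bonds=frozenset(sys_macro),
                main_cycle=main,
                bridges=bridges,
                small_ring_systems=small_systems,
            )
        )
    out.sort(key=lambda m: min(m.atoms))
    return out


def macrocycle_size(graph: MolecularGraph) -> int:
    """Molecule-level macrocycle size: the largest system's ring size (0 if none)."""
    systems = perceive_macrocycles(graph)
    return max((m.ring_size for m in systems), default=0)


# ---------------------------------------------------------------------------
# descriptors


def _is_amide_bond(bond: Chem.Bond) -> bool:
    """C-N single bond where the carbon bears a doubly-bonded O (amide C-N)."""
    a, b = bond.GetBeginAtom(), bond.GetEndAtom()
    for c, n in ((a, b), (b, a)):
        if c.GetSymbol() == "C" and n.GetSymbol() == "N":
            for nb in c.GetBonds():
                if (
                    nb.GetBondType() == Chem.BondType.DOUBLE
                    and nb.GetOtherAtom(c).GetSymbol() == "O"
                ):
                    return True
    return False


def total_flexibility(graph: MolecularGraph) -> int:
    """Exocyclic rotatable bonds plus macrocyclic single bonds that are not
    amide C-N bonds.  The exocyclic count uses the standard strict rotatable
    bond definition (non-ring single bond between non-terminal heavy atoms,
    amide-like bonds excluded)."""
    mol = Chem.RemoveHs(Chem.Mol(graph.mol))
    exo = rdMolDescriptors.CalcNumRotatableBonds(
        mol, rdMolDescriptors.NumRotatableBondsOptions.Strict
    )
    sizes = _bond_ring_sizes(graph)
    ring = 0
    for bid, size in sizes.items():
        if size < MACROCYCLE_THRESHOLD:
            continue
        bond = graph.mol.GetBondWithIdx(bid)
        if bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        if _is_amide_bond(bond):
            continue
        ring += 1
    return exo + ring


def find_donors_acceptors(graph: MolecularGraph):
    """Hydrogen-bond donors and acceptors.

    Donors are polar hydrogens (H on N, O or S); an N-methylated ring nitrogen
    carries no H and therefore yields no donor.  Acceptors are oxygens
    (uncharged or anionic) and nitrogens with an available lone pair — amide
    nitrogens, positively charged nitrogens and three-coordinate aromatic
    nitrogens are excluded.
    """
    mol = graph.mol
    donors, acceptors = [], []
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym == "H":
            heavy = atom.GetNeighbors()
            if heavy and heavy[0].GetSymbol() in ("N", "O", "S"):
                donors.append(atom.GetIdx())
        elif sym == "O":
            if atom.GetFormalCharge() <= 0:
                acceptors.append(atom.GetIdx())
        elif sym == "N":
            if atom.GetFormalCharge() > 0 or atom.GetDegree() >= 4:
                continue
            if atom.GetIsAromatic() and atom.GetDegree() == 3:
                continue
            is_amide = any(
                _is_amide_bond(b) for b in atom.GetBonds()
            )
            if is_amide:
                continue
            acceptors.append(atom.GetIdx())
    return donors, acceptors
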