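"""Physical ring movements and hydrogen-bond network topology.

Four movements drive ring conformer search:

* **bend** — negate the cross-ring torsion defined by the two side centroids
  about a non-bonded ring atom pair (the classic chair -> boat manipulation);
* **twist** — force one end atom of a macrocyclic single bond around the bond
  axis while the other three torsion atoms are pinned;
* **flip** — rotate a macrocycle arc 180 degrees about the axis between the
  midpoints of two distant, directionally compatible ring bonds;
* **bridge flip** — mirror a bridge (e.g. a disulfide) to the opposite face of
  the macrocycle under chirality-enforcing restraints.

Alongside these, trans-annular hydrogen-bond pairs and topologically
compatible triplets are enumerated purely from the graph, and constrained
starting structures are built for the most promising triplets.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from macroconf import chemgraph
from macroconf.chemgraph import MacrocycleSystem, MolecularGraph, RingSystem
from macroconf.ffmin import (
    Conformer,
    DistanceWell,
    ForceFieldEngine,
    Pin,
    RestraintSet,
    check_chirality,
    chirality_restraint_records,
    dihedral_deg,
)

FLIP_MIN_MIDPOINT_DISTANCE = 4.0  # Angstrom
FLIP_MIN_DOT = 0.3  # directional compatibility; ~70 degrees max deviation
HBOND_MIN_PATH = 8  # atoms, inclusive, donor..acceptor anchor
HBOND_TARGET_DISTANCE = 2.0  # Angstrom, H...acceptor upper bound
HBOND_PENALTY = 20.0  # kcal/mol/A^2
TRIPLET_STARTS_KEPT = 8
DEFAULT_TWIST_ANGLES = (60.0, -60.0, 120.0, -120.0, 180.0)


# ---------------------------------------------------------------------------
# move descriptors


@dataclass(frozen=True)
class Bend:
    axis: tuple  # two non-bonded ring atoms
    lhs: tuple  # larger side (ring-system atoms)
    rhs: tuple  # smaller side; these atoms (and pendants) rotate
    rhs_pendants: tuple

    @property
    def label(self) -> str:
        return f"bend({self.axis[0]}-{self.axis[1]})"


@dataclass(frozen=True)
class Twist:
    atoms: tuple  # (a1, a2, a3, a4) along the macrocycle; bond a2-a3 twists
    moving_end: int  # index of the atom that is pushed around the axis

    @property
    def label(self) -> str:
        return f"twist({self.atoms[1]}-{self.atoms[2]};move {self.moving_end})"


@dataclass(frozen=True)
class Flip:
    lhs_bond: tuple
    rhs_bond: tuple
    arc: tuple  # main-cycle atoms rotated (between the two bonds, inclusive)
    min_dot: float
    midpoint_distance: float

    @property
    def label(self) -> str:
        return f"flip({self.lhs_bond}->{self.rhs_bond})"


@dataclass(frozen=True)
class HBondPair:
    donor_h: int
    donor_anchor: int  # main-cycle atom bearing (or nearest to) the donor H
    acceptor: int
    acceptor_anchor: int
    path_length: int  # shortest non-bridging path, atoms, inclusive


@dataclass(frozen=True)
class HBondTriplet:
    pairs: tuple  # three HBondPairs, ordered by donor position
    deltas_donor: tuple
    deltas_acceptor: tuple
    mean_distance: float = float("nan")  # set after constrained minimization


# ---------------------------------------------------------------------------
# pendant bookkeeping


def pendant_map(graph: MolecularGraph, core_atoms) -> dict:
    """core atom -> tuple of non-core atoms hanging off it (substituent trees,
    reached without passing through another core atom)."""
    core = set(core_atoms)
    g = graph.to_networkx()
    g.remove_nodes_from(core)
    comp_of = {}
    for comp in nx.connected_components(g):
        for a in comp:
            comp_of[a] = frozenset(comp)
    out = {a: [] for a in core}
    mol = graph.mol
    seen = {a: set() for a in core}
    for a in core:
        for nb in mol.GetAtomWithIdx(a).GetNeighbors():
            i = nb.GetIdx()
            if i in core:
                continue
            comp = comp_of[i]
            if comp not in seen[a]:
                seen[a].add(comp)
                out[a].extend(sorted(comp))
    return {a: tuple(sorted(set(v))) for a, v in out.items()}


def _rotate_about_axis(coords, atom_ids, p0, axis_unit, angle_rad):
    """Rotate the given atoms about the line through p0 with direction axis_unit."""
    if not atom_ids:
        return
    k = axis_unit
    pts = coords[list(atom_ids)] - p0
    cos, sin = math.cos(angle_rad), math.sin(angle_rad)
    rotated = (
        pts * cos
        + np.cross(k, pts) * sin
        + np.outer(pts @ k, k) * (1.0 - cos)
    )
    coords[list(atom_ids)] = rotated + p0


# ---------------------------------------------------------------------------
# bends


def enumerate_bends(graph: MolecularGraph, system: RingSystem) -> list:
    """All eligible bend axes of a small-ring system.

    Eligibility: the pair is not directly bonded; at least one pair atom
    belongs to a non-planar ring; the pair does not cross a fused or bridged
    junction — removing the two atoms must split the ring system into exactly
    two sides, and fusion/bridgehead atoms may appear on at most one side
    (axis atoms themselves may be junction atoms: bending an arc about the
    fusion axis is a legitimate movement).
    """
    import networkx as nx

    mol = graph.mol
    atoms = sorted(system.atoms)
    special = system.fusion_atoms | system.bridge_atoms
    sub = graph.to_networkx(ring_bonds_only=False).subgraph(system.atoms)
    pend = pendant_map(graph, system.atoms)
    out = []
    for a, b in itertools.combinations(atoms, 2):
        if mol.GetBondBetweenAtoms(a, b) is not None:
            continue
        if (
            a not in system.nonplanar_ring_atoms
            and b not in system.nonplanar_ring_atoms
        ):
            continue
        work = sub.copy()
        work.remove_nodes_from([a, b])
        comps = sorted(nx.connected_components(work), key=lambda c: (len(c), sorted(c)))
        if len(comps) != 2:
            continue
        if all(special & c for c in comps):
            continue  # the cut separates the fused/bridged junction
        rhs, lhs = comps  # smaller side is the RHS
        rhs_pend = tuple(
            sorted(itertools.chain.from_iterable(pend[i] for i in rhs))
        )
        out.append(
            Bend(
                axis=(a, b),
                lhs=tuple(sorted(lhs)),
                rhs=tuple(sorted(rhs)),
                rhs_pendants=rhs_pend,
            )
        )
    return out


def apply_bend(
    engine: ForceFieldEngine,
    conformer: Conformer,
    bend: Bend,
    system: RingSystem,
    restraints: RestraintSet | None = None,
) -> Conformer | None:
    """Negate the cross-ring torsion about the bend axis, then relax.

    The RHS atoms and their pendants rotate so that the torsion (RHS centroid,
    axis, LHS centroid) goes to its negative; ring-system atoms are then
    pinned and the conformer minimized, and finally minimized unpinned.
    """
    coords = conformer.coords.copy()
    a1, a2 = bend.axis
    c_rhs = coords[list(bend.rhs)].mean(axis=0)
    c_lhs = coords[list(bend.lhs)].mean(axis=0)
    tau = dihedral_deg(c_rhs, coords[a1], coords[a2], c_lhs)
    axis = coords[a2] - coords[a1]
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        return None
    moving = tuple(bend.rhs) + bend.rhs_pendants
    # rotating the RHS by +delta about a1->a2 shifts the torsion
    # (rhs, a1, a2, lhs) by +delta; to send tau -> -tau rotate by -2*tau
    _rotate_about_axis(coords, moving, coords[a1], axis / norm, math.radians(-2.0 * tau))
    return _relax_two_stage(
        engine, conformer, coords, sorted(system.atoms), restraints, bend.label
    )


def _relax_two_stage(engine, parent, coords, pin_atoms, restraints, label):
    pinned = RestraintSet(pins=[Pin(a, None) for a in pin_atoms]).merged_with(restraints)
    cand = Conformer(coords=coords, provenance=parent.provenance + [label])
    try:
        stage1 = engine.minimize(cand, pinned)
        stage2 = engine.minimize(stage1.conformer, restraints)
    except Exception:
        return None
    out = stage2.conformer
    if out.energy is None or not math.isfinite(out.energy):
        return None
    return out


# ---------------------------------------------------------------------------
# twists


def _is_twistable_bond(graph, bond, sizes):
    from rdkit import Chem

    if sizes.get(bond.GetIdx(), 0) < chemgraph.MACROCYCLE_THRESHOLD:
        return False
    if bond.GetBondType() != Chem.BondType.SINGLE:
        return False
    if chemgraph._is_amide_bond(bond):
        return False  # amide C-N has partial double-bond character
    return True


def enumerate_twists(graph: MolecularGraph, macro: MacrocycleSystem) -> list:
    """One twist per eligible macrocyclic single bond and moving end."""
    mol = graph.mol
    sizes = chemgraph._bond_ring_sizes(graph)
    cycle = macro.main_cycle
    n = len(cycle)
    pos = {a: i for i, a in enumerate(cycle)}
    out = []
    for i, a2 in enumerate(cycle):
        a3 = cycle[(i + 1) % n]
        bond = mol.GetBondBetweenAtoms(a2, a3)
        if bond is None or not _is_twistable_bond(graph, bond, sizes):
            continue
        a1 = cycle[(i - 1) % n]
        a4 = cycle[(i + 2) % n]
        out.append(Twist(atoms=(a1, a2, a3, a4), moving_end=a4))
        out.append(Twist(atoms=(a4, a3, a2, a1), moving_end=a1))
    out.sort(key=lambda t: (t.atoms, t.moving_end))
    _ = pos
    return out


def apply_twist(
    engine: ForceFieldEngine,
    conformer: Conformer,
    twist: Twist,
    angles=DEFAULT_TWIST_ANGLES,
    restraints: RestraintSet | None = None,
) -> list:
    """Push the moving end atom around the central bond axis.

    Atoms 1-3 of the torsion window are pinned; the moving atom is placed at
    each target rotation and pinned there; the conformer is minimized pinned,
    then minimized free.  One candidate per target angle.
    """
    a1, a2, a3, a4 = twist.atoms
    out = []
    for delta in angles:
        coords = conformer.coords.copy()
        axis = coords[a3] - coords[a2]
        norm = np.linalg.norm(axis)
        if norm < 1e-9:
            continue
        _rotate_about_axis(coords, (a4,), coords[a2], axis / norm, math.radians(delta))
        cand = _relax_two_stage(
            engine,
            conformer,
            coords,
            [a1, a2, a3, a4],
            restraints,
            f"{twist.label};{delta:+.0f}",
        )
        if cand is not None:
            out.append(cand)
    return out


# ---------------------------------------------------------------------------
# flips


def _cycle_bonds(macro: MacrocycleSystem):
    cycle = macro.main_cycle
    n = len(cycle)
    return [(cycle[i], cycle[(i + 1) % n]) for i in range(n)]


def _arc_between(cycle, i, j):
    """Main-cycle atoms strictly after bond i and up to/including the start of
    bond j, walking forward; bond i is (cycle[i], cycle[i+1])."""
    n = len(cycle)
    out = []
    k = (i + 1) % n
    while True:
        out.append(cycle[k])
        if k == j:
            break
        k = (k + 1) % n
    return tuple(out)


def enumerate_flips(
    graph: MolecularGraph, conformer: Conformer, macro: MacrocycleSystem
) -> list:
    """Geometrically eligible sub-cycle flips for the current conformer.

    For each pair of rotatable main-cycle bonds, both arcs between them are
    candidates; an arc is emitted when the bond midpoints are at least 4.0 A
    apart, the arc carries no bridge attachment, and the two bond vectors
    (oriented along the walk) and the midpoint vector are mutually compatible:
    min of the three pairwise dot products > 0.3.
    """
    from rdkit import Chem

    mol = graph.mol
    sizes = chemgraph._bond_ring_sizes(graph)
    coords = conformer.coords
    cycle = macro.main_cycle
    n = len(cycle)
    bonds = _cycle_bonds(macro)
    attach = {p[0] for p in macro.bridges} | {p[-1] for p in macro.bridges}
    rotatable = []
    for i, (u, v) in enumerate(bonds):
        b = mol.GetBondBetweenAtoms(u, v)
        if b is not None and b.GetBondType() == Chem.BondType.SINGLE and not chemgraph._is_amide_bond(b):
            rotatable.append(i)
    out = []
    for i, j in itertools.combinations(rotatable, 2):
        (u1, v1), (u2, v2) = bonds[i], bonds[j]
        m1 = 0.5 * (coords[u1] + coords[v1])
        m2 = 0.5 * (coords[u2] + coords[v2])
        dist = float(np.linalg.norm(m2 - m1))
        if dist < FLIP_MIN_MIDPOINT_DISTANCE:
            continue
        for first, second in ((i, j), (j, i)):
            bu, bv = bonds[first]
            cu, cv = bonds[second]
            arc = _arc_between(cycle, first, _index_of(cycle, cu))
            if set(arc) & attach:
                continue
            ma = 0.5 * (coords[bu] + coords[bv])
            mb = 0.5 * (coords[cu] + coords[cv])
            v1_vec = _unit(coords[bv] - coords[bu])
            v2_vec = _unit(coords[cv] - coords[cu])
            v3_vec = _unit(mb - ma)
            min_dot = min(
                float(v1_vec @ v2_vec), float(v1_vec @ v3_vec), float(v2_vec @ v3_vec)
            )
            if min_dot > FLIP_MIN_DOT:
                out.append(
                    Flip(
                        lhs_bond=(bu, bv),
                        rhs_bond=(cu, cv),
                        arc=arc,
                        min_dot=min_dot,
                        midpoint_distance=dist,
                    )
                )
    out.sort(key=lambda f: (f.lhs_bond, f.rhs_bond))
    return out


def _index_of(cycle, atom):
    return cycle.index(atom)


def _unit(v):
    return v / np.linalg.norm(v)


def flip_rotation(conformer: Conformer, flip: Flip, graph: MolecularGraph) -> np.ndarray:
    """Coordinates after the exact 180-degree rotation of the flipped arc
    (and its pendants) about the midpoint axis — no minimization."""
    coords = conformer.coords.copy()
    u1, v1 = flip.lhs_bond
    u2, v2 = flip.rhs_bond
    m1 = 0.5 * (coords[u1] + coords[v1])
    m2 = 0.5 * (coords[u2] + coords[v2])
    axis = _unit(m2 - m1)
    pend = pendant_map(graph, flip.arc)
    moving = list(flip.arc) + sorted(
        itertools.chain.from_iterable(pend[a] for a in flip.arc)
    )
    _rotate_about_axis(coords, moving, m1, axis, math.pi)
    return coords


def apply_flip(
    engine: ForceFieldEngine,
    conformer: Conformer,
    flip: Flip,
    restraints: RestraintSet | None = None,
) -> Conformer | None:
    """180-degree arc rotation, end atoms pinned, minimize, release, minimize."""
    coords = flip_rotation(conformer, flip, engine.graph)
    ends = sorted({*flip.lhs_bond, *flip.rhs_bond})
    return _relax_two_stage(engine, conformer, coords, ends, restraints, flip.label)


def apply_bridge_flip(
    engine: ForceFieldEngine,
    conformer: Conformer,
    bridge: list,
    macro: MacrocycleSystem,
    restraints: RestraintSet | None = None,
) -> Conformer | None:
    """Mirror the bridge across the local macrocycle plane and relax with
    chirality-enforcing signed-volume terms active, then without."""
    graph = engine.graph
    coords = conformer.coords.copy()
    ring_pts = coords[list(macro.main_cycle)]
    centroid = ring_pts.mean(axis=0)
    # least-squares macrocycle plane
    _, _, vt = np.linalg.svd(ring_pts - centroid)
    normal = vt[2]
    internal = list(bridge[1:-1])
    pend = pendant_map(graph, set(macro.main_cycle) | set(internal))
    moving = internal + sorted(itertools.chain.from_iterable(pend[a] for a in internal))
    if not moving:
        return None
    pts = coords[moving] - centroid
    coords[moving] = pts - 2.0 * np.outer(pts @ normal, normal) + centroid
    chir = RestraintSet(
        chirality_records=chirality_restraint_records(graph, conformer.coords)
    ).merged_with(restraints)
    cand = Conformer(
        coords=coords, provenance=conformer.provenance + [f"bridge_flip({bridge[0]}-{bridge[-1]})"]
    )
    try:
        stage1 = engine.minimize(cand, chir)
        stage2 = engine.minimize(stage1.conformer, restraints)
    except Exception:
        return None
    out = stage2.conformer
    ok, _ = check_chirality(graph, out)
    if not ok:
        return None
    return out


# ---------------------------------------------------------------------------
# hydrogen-bond topology


def _nearest_cycle_anchor(graph: MolecularGraph, macro: MacrocycleSystem, atom: int):
    """Main-cycle atom closest (bond-topologically) to ``atom``."""
    import networkx as nx

    if atom in macro.main_cycle:
        return atom
    g = graph.to_networkx()
    lengths = nx.single_source_shortest_path_length(g, atom, cutoff=4)
    on_cycle = [(d, a) for a, d in lengths.items() if a in set(macro.main_cycle)]
    if not on_cycle:
        return None
    return min(on_cycle)[1]


def enumerate_hbond_pairs(graph: MolecularGraph, macro: MacrocycleSystem) -> list:
    """Donor/acceptor pairs of one macrocyclic system whose shortest
    non-bridging main-cycle path (inclusive) has at least 8 atoms."""
    donors, acceptors = chemgraph.find_donors_acceptors(graph)
    cycle = macro.main_cycle
    n = len(cycle)
    pos = {a: i for i, a in enumerate(cycle)}
    sys_atoms = set(macro.atoms)
    out = []
    for h in donors:
        heavy = graph.mol.GetAtomWithIdx(h).GetNeighbors()[0].GetIdx()
        if heavy not in sys_atoms and not _touches(graph, heavy, sys_atoms):
            continue
        d_anchor = _nearest_cycle_anchor(graph, macro, heavy)
        if d_anchor is None:
            continue
        for acc in acceptors:
            if acc == heavy:
                continue
            if acc not in sys_atoms and not _touches(graph, acc, sys_atoms):
                continue
            a_anchor = _nearest_cycle_anchor(graph, macro, acc)
            if a_anchor is None or a_anchor == d_anchor:
                continue
            i, j = pos[d_anchor], pos[a_anchor]
            fwd = (j - i) % n
            bwd = (i - j) % n
            # the two main-cycle paths between the anchors (atom counts incl ends)
            path_len = min(fwd, bwd) + 1
            if path_len < HBOND_MIN_PATH:
                continue
            # neither direction may matter for bridge crossing: the *shortest*
            # path must avoid bridge attachments (paths through a bridge are
            # shorter than main-cycle paths when a bridge shortcuts them)
            if _bridged_shortcut(macro, i, j, n):
                continue
            out.append(
                HBondPair(
                    donor_h=h,
                    donor_anchor=d_anchor,
                    acceptor=acc,
                    acceptor_anchor=a_anchor,
                    path_length=path_len,
                )
            )
    out.sort(key=lambda p: (p.donor_anchor, p.acceptor_anchor, p.donor_h, p.acceptor))
    return out


def _touches(graph, atom, sys_atoms):
    return any(nb.GetIdx() in sys_atoms for nb in graph.mol.GetAtomWithIdx(atom).GetNeighbors())


def _bridged_shortcut(macro: MacrocycleSystem, i: int, j: int, n: int) -> bool:
    """True when the shortest non-bridging main-cycle walk between positions
    i and j passes a bridge attachment atom, i.e. a bridge shortcuts it."""
    if not macro.bridges:
        return False
    cycle = macro.main_cycle
    fwd = (j - i) % n
    bwd = (i - j) % n
    k, step = (fwd, 1) if fwd <= bwd else (bwd, -1)
    walk = {cycle[(i + step * t) % n] for t in range(k + 1)}
    attach = {p[0] for p in macro.bridges} | {p[-1] for p in macro.bridges}
    interior = walk - {cycle[i], cycle[j]}
    return bool(interior & attach)


def enumerate_hbond_triplets(
    pairs: list, macro: MacrocycleSystem
) -> list:
    """All 3-subsets of hydrogen-bond pairs able to form simultaneously:
    walking across the triplet, donor-side ring indices advance by exactly the
    amounts the acceptor-side indices retreat (modulo ring wrap)."""
    cycle = macro.main_cycle
    n = len(cycle)
    pos = {a: i for i, a in enumerate(cycle)}

    def signed_mod(d):
        d %= n
        return d - n if d > n / 2 else d

    out = []
    for trio in itertools.combinations(pairs, 3):
        if len({p.donor_h for p in trio}) < 3 or len({p.acceptor for p in trio}) < 3:
            continue
        ordered = sorted(trio, key=lambda p: pos[p.donor_anchor])
        dp = [signed_mod(pos[ordered[k + 1].donor_anchor] - pos[ordered[k].donor_anchor]) for k in range(2)]
        da = [signed_mod(pos[ordered[k + 1].acceptor_anchor] - pos[ordered[k].acceptor_anchor]) for k in range(2)]
        if dp[0] == 0 or dp[1] == 0 or da[0] == 0 or da[1] == 0:
            continue
        if da[0] == -dp[0] and da[1] == -dp[1]:
            out.append(
                HBondTriplet(pairs=tuple(ordered), deltas_donor=tuple(dp), deltas_acceptor=tuple(da))
            )
    return out


def triplet_restraints(triplet: HBondTriplet) -> RestraintSet:
    """Square wells holding each H...acceptor distance at 2.0 A or less
    (zero penalty anywhere below the target)."""
    wells = [
        DistanceWell(
            group_a=(p.donor_h,),
            group_b=(p.acceptor,),
            dist=HBOND_TARGET_DISTANCE / 2.0,
            wiggle=HBOND_TARGET_DISTANCE / 2.0,
            penalty=HBOND_PENALTY,
            label=f"hbond({p.donor_h}->{p.acceptor})",
        )
        for p in triplet.pairs
    ]
    return RestraintSet(distance_wells=wells)


def mean_triplet_distance(coords: np.ndarray, triplet: HBondTriplet) -> float:
    return float(
        np.mean(
            [np.linalg.norm(coords[p.donor_h] - coords[p.acceptor]) for p in triplet.pairs]
        )
    )


def build_constrained_starts(
    graph: MolecularGraph,
    triplets: list,
    base: Conformer,
    engine: ForceFieldEngine,
    embed,
    keep: int = TRIPLET_STARTS_KEPT,
    restraints: RestraintSet | None = None,
) -> list:
    """Constrained starting structures for the most promising triplets.

    Each triplet is minimized (from ``base``) under its three hydrogen-bond
    wells; triplets are ranked by the resulting mean H...acceptor distance and
    the top ``keep`` kept.  For each survivor, ``embed(restraint_set)`` must
    generate a fresh structure from zeroed coordinates under those wells.  The
    restraint-free agnostic start (``base``, None) is always appended last.
    """
    scored = []
    for t in triplets:
        rs = triplet_restraints(t).merged_with(restraints)
        try:
            res = engine.minimize(base.copy(), rs)
        except Exception:
            continue
        d = mean_triplet_distance(res.conformer.coords, t)
        scored.append((d, t))
    scored.sort(key=lambda x: x[0])
    out = []
    for d, t in scored[:keep]:
        rs = triplet_restraints(t).merged_with(restraints)
        try:
            start = embed(rs)
        except Exception:
            continue
        out.append((start, triplet_restraints(t)))
    out.append((base.copy(), None))
    return out
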