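"""Synthetic molecules and data so every search stage is testable offline.

Provides cycloalkanes, well-known ring-system drugs as SMILES constants, toy
head-to-tail cyclic peptides with controllable N-methylation / proline /
ester / disulfide patterns (a minimal sidechain alphabet — enough chemistry
to exercise donor/acceptor, bridge and flexibility logic without force-field
edge cases), and synthetic NOE-like distance constraints and RDC tables with
known generating parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from macroconf.chemgraph import MolecularGraph, PerceptionError
from macroconf.ffmin import Conformer
from macroconf.nmr import Constraint, ConstraintSet, RDCRecord

# public-knowledge structures used as perception fixtures
BENZENE_SMILES = "c1ccccc1"
CYCLOHEXANE_SMILES = "C1CCCCC1"
DECALIN_SMILES = "C1CCC2CCCCC2C1"
TETRACYCLINE_SMILES = (
    "CC1(C2CC3C(C(=O)C(=C(C3(C(=O)C2=C(C4=C1C=CC=C4O)O)O)O)C(=O)N)N(C)C)O"
)
ETHYLBENZENE_SMILES = "CCc1ccccc1"


def make_cycloalkane(n: int) -> MolecularGraph:
    """CnH2n single-ring cycloalkane, 3 <= n <= 60."""
    if not 3 <= n <= 60:
        raise ValueError(f"ring size {n} outside 3..60")
    return MolecularGraph.from_smiles("C1" + "C" * (n - 1) + "1")


# ---------------------------------------------------------------------------
# toy cyclic peptides

SIDECHAINS = ("H", "methyl", "hydroxyl", "aromatic", "thiol")


@dataclass(frozen=True)
class ResidueSpec:
    sidechain: str = "H"  # one of SIDECHAINS
    n_methyl: bool = False
    proline: bool = False


@dataclass
class PeptideSpec:
    """A head-to-tail cyclic peptide: per-residue decorations, optional
    disulfide bridge between two thiol sidechains, optional ester linkages
    (the backbone nitrogen of the listed residues becomes an oxygen,
    depsipeptide style)."""

    residues: list
    disulfide: tuple | None = None
    esters: tuple = ()

    def __post_init__(self):
        if len(self.residues) < 3:
            raise ValueError("need at least 3 residues")
        if self.disulfide is not None:
            i, j = self.disulfide
            if i == j:
                raise ValueError("disulfide endpoints must differ")
            for k in (i, j):
                if self.residues[k].sidechain != "thiol":
                    raise ValueError(f"disulfide residue {k} must have a thiol sidechain")
        for k in self.esters:
            if self.residues[k].proline:
                raise ValueError(f"residue {k} cannot be both proline and ester")
            if self.residues[k].n_methyl:
                raise ValueError(f"ester residue {k} has no N to methylate")


def make_cyclic_peptide(spec: PeptideSpec) -> MolecularGraph:
    """Build the macrocycle: per residue the ring contributes N (or ester O),
    CA and carbonyl C — so an n-residue peptide has a 3n-atom main ring."""
    rw = Chem.RWMol()
    n_res = len(spec.residues)
    backbone = []  # (n_or_o, ca, c) per residue
    sulfurs = {}
    for ri, res in enumerate(spec.residues):
        if ri in spec.esters:
            head = rw.AddAtom(Chem.Atom("O"))
        else:
            head = rw.AddAtom(Chem.Atom("N"))
        ca = rw.AddAtom(Chem.Atom("C"))
        c = rw.AddAtom(Chem.Atom("C"))
        o = rw.AddAtom(Chem.Atom("O"))
        rw.AddBond(head, ca, Chem.BondType.SINGLE)
        rw.AddBond(ca, c, Chem.BondType.SINGLE)
        rw.AddBond(c, o, Chem.BondType.DOUBLE)
        backbone.append((head, ca, c))
        if res.n_methyl:
            if ri in spec.esters:
                raise ValueError("cannot N-methylate an ester linkage")
            me = rw.AddAtom(Chem.Atom("C"))
            rw.AddBond(head, me, Chem.BondType.SINGLE)
        sc = res.sidechain
        if res.proline:
            if ri in spec.esters:
                raise ValueError("proline cannot carry an ester linkage")
            cb = rw.AddAtom(Chem.Atom("C"))
            cg = rw.AddAtom(Chem.Atom("C"))
            cd = rw.AddAtom(Chem.Atom("C"))
            rw.AddBond(ca, cb, Chem.BondType.SINGLE)
            rw.AddBond(cb, cg, Chem.BondType.SINGLE)
            rw.AddBond(cg, cd, Chem.BondType.SINGLE)
            rw.AddBond(cd, head, Chem.BondType.SINGLE)
        elif sc == "methyl":
            cb = rw.AddAtom(Chem.Atom("C"))
            rw.AddBond(ca, cb, Chem.BondType.SINGLE)
        elif sc == "hydroxyl":
            cb = rw.AddAtom(Chem.Atom("C"))
            og = rw.AddAtom(Chem.Atom("O"))
            rw.AddBond(ca, cb, Chem.BondType.SINGLE)
            rw.AddBond(cb, og, Chem.BondType.SINGLE)
        elif sc == "aromatic":
            cb = rw.AddAtom(Chem.Atom("C"))
            rw.AddBond(ca, cb, Chem.BondType.SINGLE)
            ring = []
            for _ in range(6):
                ar = Chem.Atom("C")
                ar.SetIsAromatic(True)
                ring.append(rw.AddAtom(ar))
            for k in range(6):
                b = rw.AddBond(ring[k], ring[(k + 1) % 6], Chem.BondType.AROMATIC)
                _ = b
            rw.AddBond(cb, ring[0], Chem.BondType.SINGLE)
        elif sc == "thiol":
            cb = rw.AddAtom(Chem.Atom("C"))
            sg = rw.AddAtom(Chem.Atom("S"))
            rw.AddBond(ca, cb, Chem.BondType.SINGLE)
            rw.AddBond(cb, sg, Chem.BondType.SINGLE)
            if spec.disulfide and ri in spec.disulfide:
                sulfurs[ri] = sg
        elif sc != "H":
            raise ValueError(f"unknown sidechain class {sc!r}")
    # close the backbone head-to-tail
    for ri in range(n_res):
        c_prev = backbone[ri][2]
        head_next = backbone[(ri + 1) % n_res][0]
        rw.AddBond(c_prev, head_next, Chem.BondType.SINGLE)
    if spec.disulfide is not None:
        i, j = spec.disulfide
        rw.AddBond(sulfurs[i], sulfurs[j], Chem.BondType.SINGLE)
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:
        raise PerceptionError(f"invalid peptide spec: {exc}") from exc
    return MolecularGraph.from_rdkit(mol, "smiles")


def simple_peptide(
    n_res: int,
    n_methylated: tuple = (),
    prolines: tuple = (),
    esters: tuple = (),
    disulfide: tuple | None = None,
    sidechains: dict | None = None,
) -> MolecularGraph:
    """Convenience wrapper around :func:`make_cyclic_peptide`."""
    sidechains = sidechains or {}
    residues = []
    for i in range(n_res):
        sc = sidechains.get(i, "H")
        if disulfide and i in disulfide:
            sc = "thiol"
        residues.append(
            ResidueSpec(
                sidechain=sc,
                n_methyl=i in n_methylated,
                proline=i in prolines,
            )
        )
    return make_cyclic_peptide(
        PeptideSpec(residues=residues, disulfide=disulfide, esters=tuple(esters))
    )


def aba_like_peptide() -> MolecularGraph:
    """A 9-residue depsipeptide topology: one ester linkage, one proline,
    four N-methylated amides — leaving three backbone N-H donors, like the
    aureobasidin scaffold."""
    return simple_peptide(
        9,
        n_methylated=(2, 4, 6, 8),
        prolines=(1,),
        esters=(0,),
        sidechains={3: "methyl", 5: "hydroxyl", 7: "methyl"},
    )


def trypsin_inhibitor_like_peptide() -> MolecularGraph:
    """A 14-residue cyclic peptide with a disulfide bridge (42-atom main
    ring), echoing the sunflower trypsin inhibitor topology."""
    return simple_peptide(
        14,
        disulfide=(2, 11),
        prolines=(7,),
        sidechains={4: "methyl", 9: "hydroxyl"},
    )


# ---------------------------------------------------------------------------
# synthetic constraint and RDC generators


def _noe_candidate_pairs(graph: MolecularGraph, coords: np.ndarray,
                         max_dist=5.0, min_path=6):
    """Candidate fold-defining atom pairs for synthetic NOE-like restraints.

    Real NOE sets constrain the fold through *long-range* contacts (e.g.
    trans-annular donor-to-acceptor distances), so candidates are polar-H ->
    acceptor pairs plus H-H pairs at least ``min_path`` bonds apart, all
    within ``max_dist`` Angstrom in the reference conformer.  Sequential
    short-range pairs carry no fold information and are excluded.
    """
    import networkx as nx

    from macroconf import chemgraph

    mol = graph.mol
    g = graph.to_networkx()
    donors, acceptors = chemgraph.find_donors_acceptors(graph)
    hs = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 1]
    pairs = []
    seen = set()
    for h in donors:
        lengths = nx.single_source_shortest_path_length(g, h)
        for acc in acceptors:
            if lengths.get(acc, 99) < min_path:
                continue
            d = float(np.linalg.norm(coords[h] - coords[acc]))
            if d <= max_dist:
                key = tuple(sorted((h, acc)))
                if key not in seen:
                    seen.add(key)
                    pairs.append((h, acc, d))
    for x in range(len(hs)):
        lengths = nx.single_source_shortest_path_length(g, hs[x])
        for y in range(x + 1, len(hs)):
            i, j = hs[x], hs[y]
            if lengths.get(j, 99) < min_path:
                continue
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if d <= max_dist:
                key = tuple(sorted((i, j)))
                if key not in seen:
                    seen.add(key)
                    pairs.append((i, j, d))
    return pairs


def make_synthetic_constraints(
    graph: MolecularGraph,
    reference: Conformer,
    k: int = 20,
    noise: float = 0.0,
    seed: int = 0,
    wiggle: float = 0.5,
    penalty: float = 10.0,
) -> ConstraintSet:
    """NOE-like distance constraints sampled from a reference conformer.

    ``k`` proton-proton distances are drawn (seeded, deterministic), the
    target distance perturbed by Gaussian noise of the given scale, and
    emitted as square wells with the standard +-0.5 A allowance.  With zero
    noise the reference itself has zero violation energy by construction.
    """
    import warnings

    rng = np.random.default_rng(seed)
    pairs = _noe_candidate_pairs(graph, np.asarray(reference.coords, float))
    if not pairs:
        raise ValueError("no candidate proton pairs within range")
    if k > len(pairs):
        warnings.warn(f"only {len(pairs)} candidate pairs available; capping k={k}")
        k = len(pairs)
    idx = rng.choice(len(pairs), size=k, replace=False)
    out = []
    for n, sel in enumerate(sorted(idx)):
        i, j, d = pairs[sel]
        target = d + (rng.normal(0.0, noise) if noise > 0 else 0.0)
        out.append(
            Constraint(
                kind="nmr", atoms_a=(i,), atoms_b=(j,),
                dist=float(max(0.5, target)), wiggle=wiggle, penalty=penalty,
                label=f"noe_{n}",
            )
        )
    return ConstraintSet(constraints=out)


def saupe_from_elements(elements) -> np.ndarray:
    sxx, syy, sxy, sxz, syz = (float(x) for x in elements)
    return np.array([[sxx, sxy, sxz], [sxy, syy, syz], [sxz, syz, -sxx - syy]])


def make_synthetic_rdcs(
    graph: MolecularGraph,
    conformer: Conformer,
    tensor_elements=(3e-4, -1e-4, 2e-4, 1e-4, -2e-4),
    noise: float = 0.0,
    seed: int = 0,
    scale: float = 10000.0,
) -> list:
    """Forward-calculated RDCs for every C-H and N-H bond, from a known
    alignment tensor, with optional multiplicative Gaussian noise.

    ``scale`` converts reduced couplings to convenient magnitudes (the fit is
    scale-invariant for the Q-factor)."""
    from macroconf.nmr import forward_couplings

    rng = np.random.default_rng(seed)
    mol = graph.mol
    vec_pairs = []
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if {a.GetAtomicNum(), b.GetAtomicNum()} in ({1, 6}, {1, 7}):
            heavy, h = (a, b) if a.GetAtomicNum() > 1 else (b, a)
            vec_pairs.append((heavy.GetIdx(), h.GetIdx()))
    if len(vec_pairs) < 5:
        raise ValueError("fewer than 5 C-H/N-H bond vectors available")
    S = saupe_from_elements(tensor_elements) * scale
    records = [RDCRecord(i, j, 0.0) for i, j in vec_pairs]
    d = forward_couplings(np.asarray(conformer.coords, float), records, S)
    out = []
    for (i, j), val in zip(vec_pairs, d):
        if noise > 0:
            val = val * (1.0 + rng.normal(0.0, noise))
        out.append(RDCRecord(i, j, float(val)))
    return out
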