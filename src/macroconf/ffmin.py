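"""MMFF94s energies and restrained minimization.

Restraints are square wells: free movement inside the well, a quadratic
penalty outside.  The closed forms are

* distance:  ``penalty * max(0, |d - dist| - wiggle)**2``       [kcal/mol]
* torsion:   ``penalty * (periodic distance to nearest bound)**2``
* pin:       ``k * |r - target|**2``
* chirality: ``k * max(0, margin - sign * V)**2`` on the signed tetrahedral
  volume ``V`` of a stereocenter, pushing ``V`` to the recorded sign.

Minimization uses RDKit's native conjugate-gradient minimizer whenever every
restraint maps onto a native contrib (pins at current coordinates, atom-atom
distance wells, torsion wells); centroid (group) distance wells and
chirality-enforcing terms fall back to an L-BFGS-B loop over the force-field
energy and gradient plus the custom terms.  RDKit's contribs are rescaled so
the energies reported here always equal the closed forms above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Geometry import Point3D
from scipy.optimize import minimize as _scipy_minimize

from macroconf.chemgraph import MolecularGraph, StereoRecord

#: default force constant for positional pins, kcal/mol/A^2
PIN_FORCE_CONSTANT = 100.0
#: gradient-norm convergence tolerance, kcal/mol/A
GRADIENT_TOL = 1e-4
MAX_ITERATIONS = 2000
#: margin for the chirality-enforcing signed-volume term, A^3
CHIRALITY_MARGIN = 0.25


class ParameterizationError(ValueError):
    """An atom has no MMFF parameters."""


@dataclass
class Conformer:
    """One coordinate set with its energies and move provenance."""

    coords: np.ndarray
    energy: float | None = None
    violation_energy: float = 0.0
    provenance: list = field(default_factory=list)

    def copy(self) -> "Conformer":
        return replace(self, coords=self.coords.copy(), provenance=list(self.provenance))


@dataclass
class DistanceWell:
    """Square-well distance restraint between two atom groups.

    Groups with more than one atom are measured from their centroid (the
    convention for degenerate proton groups).
    """

    group_a: tuple
    group_b: tuple
    dist: float
    wiggle: float
    penalty: float
    label: str = ""

    def measure(self, coords: np.ndarray) -> float:
        ca = coords[list(self.group_a)].mean(axis=0)
        cb = coords[list(self.group_b)].mean(axis=0)
        return float(np.linalg.norm(ca - cb))

    @property
    def is_atom_pair(self) -> bool:
        return len(self.group_a) == 1 and len(self.group_b) == 1


@dataclass
class TorsionWell:
    """Square-well torsion restraint; bounds in degrees, normalized (-180, 180]."""

    atoms: tuple
    lo: float
    hi: float
    penalty: float
    label: str = ""

    def measure(self, coords: np.ndarray) -> float:
        return dihedral_deg(*(coords[i] for i in self.atoms))


@dataclass
class Pin:
    atom: int
    target: np.ndarray | None  # None -> pin at current position
    k: float = PIN_FORCE_CONSTANT


@dataclass
class RestraintSet:
    pins: list = field(default_factory=list)
    distance_wells: list = field(default_factory=list)
    torsion_wells: list = field(default_factory=list)
    chirality_records: list = field(default_factory=list)
    chirality_k: float = 50.0

    def __post_init__(self):
        for w in self.distance_wells:
            if w.wiggle < 0 or w.penalty < 0:
                raise ValueError("wiggle and penalty must be non-negative")
        for w in self.torsion_wells:
            if w.penalty < 0:
                raise ValueError("penalty must be non-negative")

    def __bool__(self):
        return bool(
            self.pins or self.distance_wells or self.torsion_wells or self.chirality_records
        )

    def merged_with(self, other: "RestraintSet | None") -> "RestraintSet":
        if not other:
            return self
        return RestraintSet(
            pins=self.pins + other.pins,
            distance_wells=self.distance_wells + other.distance_wells,
            torsion_wells=self.torsion_wells + other.torsion_wells,
            chirality_records=self.chirality_records + other.chirality_records,
            chirality_k=max(self.chirality_k, other.chirality_k),
        )

    # -- energies ---------------------------------------------------------

    def violation_energy(self, coords: np.ndarray) -> float:
        """Sum of the distance- and torsion-well penalties (the quantity the
        profiler reports; pins and chirality terms are search scaffolding)."""
        e = 0.0
        for w in self.distance_wells:
            e += square_well_distance_penalty(w.measure(coords), w.dist, w.wiggle, w.penalty)
        for w in self.torsion_wells:
            e += square_well_torsion_penalty(w.measure(coords), w.lo, w.hi, w.penalty)
        return e

    def energy(self, coords: np.ndarray) -> float:
        e = self.violation_energy(coords)
        for pin in self.pins:
            if pin.target is not None:
                e += pin.k * float(np.sum((coords[pin.atom] - pin.target) ** 2))
        for rec in self.chirality_records:
            e += _chirality_energy(coords, rec, self.chirality_k)[0]
        return e


# ---------------------------------------------------------------------------
# penalty closed forms


def square_well_distance_penalty(d: float, dist: float, wiggle: float, penalty: float) -> float:
    """penalty * max(0, |d - dist| - wiggle)**2 — continuous and once
    differentiable everywhere, flat inside [dist - wiggle, dist + wiggle]."""
    excess = abs(d - dist) - wiggle
    return penalty * excess * excess if excess > 0 else 0.0


def _angular_distance(a: float, b: float) -> float:
    """Minimal absolute separation of two angles in degrees, in [0, 180]."""
    d = (a - b) % 360.0
    return min(d, 360.0 - d)


def angle_in_well(angle: float, lo: float, hi: float) -> bool:
    """Whether ``angle`` lies on the arc from ``lo`` counter-clockwise to ``hi``."""
    return (angle - lo) % 360.0 <= (hi - lo) % 360.0


def square_well_torsion_penalty(angle: float, lo: float, hi: float, penalty: float) -> float:
    """Zero inside [lo, hi]; outside, penalty times the squared periodic
    angular distance (degrees) to the nearest bound."""
    if angle_in_well(angle, lo, hi):
        return 0.0
    d = min(_angular_distance(angle, lo), _angular_distance(angle, hi))
    return penalty * d * d


def dihedral_deg(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees, in (-180, 180]."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b0, b1), np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x, y = float(np.dot(n1, n2)), float(np.dot(m1, n2))
    return math.degrees(math.atan2(y, x))


def signed_volume(coords: np.ndarray, center: int, neighbors) -> float:
    """Signed volume of the tetrahedron spanned by three neighbor vectors."""
    c = coords[center]
    v = [coords[n] - c for n in neighbors[:3]]
    return float(np.dot(v[0], np.cross(v[1], v[2]))) / 6.0


def _chirality_energy(coords, rec, k):
    """(energy, gradient contributions) for a chirality-enforcing term."""
    center, neighbors, sign = rec
    v = signed_volume(coords, center, neighbors)
    gap = CHIRALITY_MARGIN - sign * v
    if gap <= 0:
        return 0.0, None
    return k * gap * gap, (v, gap)


# ---------------------------------------------------------------------------
# engine


@dataclass
class MinimizationResult:
    conformer: Conformer
    converged: bool
    iterations: int
    gradient_norm: float


class ForceFieldEngine:
    """MMFF94s energies and restrained minimization for one molecule."""

    def __init__(self, graph: MolecularGraph, variant: str = "MMFF94s"):
        self.graph = graph
        self.variant = variant
        self.mol = Chem.Mol(graph.mol)
        if self.mol.GetNumConformers() == 0:
            conf = Chem.Conformer(self.mol.GetNumAtoms())
            self.mol.AddConformer(conf, assignId=True)
        if not AllChem.MMFFHasAllMoleculeParams(self.mol):
            bad = [
                f"{a.GetSymbol()}@{a.GetIdx()}"
                for a in self.mol.GetAtoms()
                if a.GetSymbol() not in ("H", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I")
            ]
            raise ParameterizationError(
                f"molecule not parameterizable with {variant}"
                + (f"; offending atoms: {', '.join(bad)}" if bad else "")
            )
        self._props = AllChem.MMFFGetMoleculeProperties(self.mol, mmffVariant=variant)
        if self._props is None:
            raise ParameterizationError(f"molecule not parameterizable with {variant}")

    # -- helpers ----------------------------------------------------------

    def _set_coords(self, coords: np.ndarray):
        conf = self.mol.GetConformer()
        for i, (x, y, z) in enumerate(np.asarray(coords, dtype=float)):
            conf.SetAtomPosition(i, Point3D(x, y, z))

    def _get_coords(self) -> np.ndarray:
        return np.array(self.mol.GetConformer().GetPositions(), dtype=float)

    def _build_ff(self, restraints: "RestraintSet | None", native: bool):
        ff = AllChem.MMFFGetMoleculeForceField(self.mol, self._props)
        if restraints is None:
            return ff
        for w in restraints.torsion_wells:
            a, b, c, d = w.atoms
            # RDKit torsion contrib is penalty * (deg past bound)^2 already
            ff.MMFFAddTorsionConstraint(a, b, c, d, False, w.lo, w.hi, w.penalty)
        if native:
            for pin in restraints.pins:
                # pins are added after coordinates have been placed at the
                # target, so restraining to the current position is exact;
                # RDKit's contrib is 0.5*k*x^2, ours k*x^2
                ff.MMFFAddPositionConstraint(pin.atom, 0.0, 2.0 * pin.k)
            for w in restraints.distance_wells:
                i, j = w.group_a[0], w.group_b[0]
                ff.AddDistanceConstraint(
                    i, j, max(0.0, w.dist - w.wiggle), w.dist + w.wiggle, 2.0 * w.penalty
                )
        return ff

    @staticmethod
    def _needs_numeric(coords, restraints: "RestraintSet | None") -> bool:
        if restraints is None:
            return False
        if restraints.chirality_records:
            return True
        if any(not w.is_atom_pair for w in restraints.distance_wells):
            return True
        for pin in restraints.pins:
            if pin.target is not None and np.max(np.abs(coords[pin.atom] - pin.target)) > 1e-9:
                return True
        return False

    # -- public API -------------------------------------------------------

    def energy(self, conformer: "Conformer | np.ndarray") -> float:
        """Pure force-field energy (no restraint terms), kcal/mol."""
        coords = conformer.coords if isinstance(conformer, Conformer) else conformer
        self._set_coords(coords)
        return float(self._build_ff(None, native=True).CalcEnergy())

    def gradient(self, coords: np.ndarray) -> np.ndarray:
        self._set_coords(coords)
        ff = self._build_ff(None, native=True)
        return np.array(ff.CalcGrad(), dtype=float).reshape(-1, 3)

    def minimize(
        self,
        conformer: Conformer,
        restraints: "RestraintSet | None" = None,
        max_iterations: int = MAX_ITERATIONS,
        force_tol: float = GRADIENT_TOL,
    ) -> MinimizationResult:
        coords = np.asarray(conformer.coords, dtype=float)
        if self._needs_numeric(coords, restraints):
            return self._minimize_numeric(conformer, restraints, max_iterations, force_tol)
        return self._minimize_native(conformer, restraints, max_iterations, force_tol)

    def _minimize_native(self, conformer, restraints, max_iterations, force_tol):
        self._set_coords(conformer.coords)
        ff = self._build_ff(restraints, native=True)
        ret = ff.Minimize(maxIts=max_iterations, forceTol=force_tol, energyTol=1e-10)
        coords = self._get_coords()
        grad = np.array(ff.CalcGrad(), dtype=float)
        energy = self.energy(coords)
        out = Conformer(
            coords=coords,
            energy=energy,
            violation_energy=restraints.violation_energy(coords) if restraints else 0.0,
            provenance=list(conformer.provenance),
        )
        return MinimizationResult(
            conformer=out,
            converged=(ret == 0),
            iterations=max_iterations if ret != 0 else -1,
            gradient_norm=float(np.linalg.norm(grad)),
        )

    def _minimize_numeric(self, conformer, restraints, max_iterations, force_tol):
        n = self.mol.GetNumAtoms()
        ff = self._build_ff(restraints, native=False)  # torsion wells included
        x0 = np.asarray(conformer.coords, float)
        pins = [
            Pin(p.atom, (p.target if p.target is not None else x0[p.atom].copy()), p.k)
            for p in restraints.pins
        ]
        wells = list(restraints.distance_wells)
        chir = list(restraints.chirality_records)
        k_chir = restraints.chirality_k
        best = {"e": math.inf, "x": np.asarray(conformer.coords, float).ravel().copy()}

        def fun(x):
            coords = x.reshape(n, 3)
            try:
                e = float(ff.CalcEnergy(x.tolist()))
                g = np.array(ff.CalcGrad(x.tolist()), dtype=float)
            except Exception:
                return 1e10, np.zeros_like(x)
            if not math.isfinite(e):
                return 1e10, np.zeros_like(x)
            g = g.reshape(n, 3)
            for p in pins:
                dv = coords[p.atom] - p.target
                e += p.k * float(np.sum(dv * dv))
                g[p.atom] += 2.0 * p.k * dv
            for w in wells:
                ia, ib = list(w.group_a), list(w.group_b)
                ca, cb = coords[ia].mean(axis=0), coords[ib].mean(axis=0)
                dv = ca - cb
                d = float(np.linalg.norm(dv))
                excess = abs(d - w.dist) - w.wiggle
                if excess > 0 and d > 1e-12:
                    e += w.penalty * excess * excess
                    dEdd = 2.0 * w.penalty * excess * math.copysign(1.0, d - w.dist)
                    u = dv / d
                    g[ia] += dEdd * u / len(ia)
                    g[ib] -= dEdd * u / len(ib)
            for rec in chir:
                center, neighbors, sign = rec
                term, info = _chirality_energy(coords, rec, k_chir)
                if info is not None:
                    _, gap = info
                    c = coords[center]
                    v1, v2, v3 = (coords[nb] - c for nb in neighbors[:3])
                    dV = {
                        neighbors[0]: np.cross(v2, v3) / 6.0,
                        neighbors[1]: np.cross(v3, v1) / 6.0,
                        neighbors[2]: np.cross(v1, v2) / 6.0,
                    }
                    dV[center] = -sum(dV.values())
                    coef = -2.0 * k_chir * gap * sign
                    for idx, dv in dV.items():
                        g[idx] += coef * dv
                    e += term
            if e < best["e"]:
                best["e"], best["x"] = e, x.copy()
            return e, g.ravel()

        res = _scipy_minimize(
            fun,
            np.asarray(conformer.coords, float).ravel(),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iterations, "gtol": force_tol},
        )
        x = res.x if math.isfinite(res.fun) and res.fun <= best["e"] + 1e-9 else best["x"]
        coords = x.reshape(n, 3)
        energy = self.energy(coords)
        out = Conformer(
            coords=coords,
            energy=energy,
            violation_energy=restraints.violation_energy(coords),
            provenance=list(conformer.provenance),
        )
        _, g = fun(x)
        return MinimizationResult(
            conformer=out,
            converged=bool(res.success),
            iterations=int(res.nit),
            gradient_norm=float(np.linalg.norm(g)),
        )


# ---------------------------------------------------------------------------
# chirality verification


def check_chirality(graph: MolecularGraph, conformer: Conformer):
    """Re-perceive stereo from coordinates and compare with the records.

    Returns ``(ok, violations)`` where ``violations`` lists every
    :class:`StereoRecord` whose configuration has inverted.
    """
    mol = Chem.Mol(graph.mol)
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, (x, y, z) in enumerate(np.asarray(conformer.coords, float)):
        conf.SetAtomPosition(i, Point3D(x, y, z))
    mol.RemoveAllConformers()
    mol.AddConformer(conf, assignId=True)
    Chem.AssignStereochemistryFrom3D(mol)
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    current = {}
    for atom, code in Chem.FindMolChiralCenters(
        mol, includeUnassigned=True, useLegacyImplementation=False
    ):
        current[("tetrahedral", (atom,))] = code
    for bond in mol.GetBonds():
        st = bond.GetStereo()
        if st in (Chem.BondStereo.STEREOE, Chem.BondStereo.STEREOZ,
                  Chem.BondStereo.STEREOCIS, Chem.BondStereo.STEREOTRANS):
            label = {Chem.BondStereo.STEREOE: "E", Chem.BondStereo.STEREOZ: "Z",
                     Chem.BondStereo.STEREOCIS: "Z", Chem.BondStereo.STEREOTRANS: "E"}[st]
            key = ("double_bond", (bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
            current[key] = label
    violations = []
    for rec in graph.stereo_records:
        seen = current.get((rec.kind, rec.atoms))
        if rec.kind == "double_bond" and seen is None:
            seen = current.get((rec.kind, (rec.atoms[1], rec.atoms[0])))
        if seen is not None and seen != rec.label:
            violations.append(rec)
    return (not violations), violations


def chirality_restraint_records(graph: MolecularGraph, coords: np.ndarray):
    """(center, neighbors, sign) terms reproducing the current signed volumes
    of all recorded tetrahedral centers — used to enforce configurations
    during bridge flips."""
    out = []
    for rec in graph.stereo_records:
        if rec.kind != "tetrahedral":
            continue
        center = rec.atoms[0]
        neighbors = tuple(
            n.GetIdx() for n in graph.mol.GetAtomWithIdx(center).GetNeighbors()
        )[:3]
        v = signed_volume(np.asarray(coords, float), center, neighbors)
        if abs(v) > 1e-6:
            out.append((center, neighbors, 1.0 if v > 0 else -1.0))
    return out
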