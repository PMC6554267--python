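"""NMR constraint files, ensemble/constraint profiling, and RDC validation.

Constraint file dialect (whitespace-separated, ``#`` comments, 1-based atom
indices in input-file atom order)::

    nmr 12 47 dist=2.8 wiggle=0.5 penalty=10
    qnmr 21,22,23 35 dist=3.5 wiggle=0.5 penalty=10
    torsion 4 5 6 7 lo=-80 hi=-40 penalty=0.01

``nmr`` restrains a proton-proton (or any atom-atom) distance; ``qnmr``
restrains the distance measured from the centroid of a symmetry-degenerate
proton group; ``torsion`` restrains a dihedral to the band [lo, hi] degrees.
All are square wells: flat inside the allowance, quadratic outside.

RDC validation fits the five independent Saupe alignment-tensor elements by
SVD least squares from reduced dipolar couplings ``D_i = b_i^T S b_i`` (unit
prefactor convention) and reports the Q-factor
``rms(D_obs - D_calc) / rms(D_obs)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from macroconf.chemgraph import MolecularGraph
from macroconf.evalstats import automorph_rmsd_single
from macroconf.ffmin import (
    Conformer,
    DistanceWell,
    RestraintSet,
    TorsionWell,
    square_well_distance_penalty,
    square_well_torsion_penalty,
)

#: discrete violation-count thresholds
DISTANCE_THRESHOLDS = (0.2, 0.5)  # Angstrom beyond the well edge
TORSION_THRESHOLDS = (5.0, 15.0)  # degrees beyond the bound
DEFAULT_PENALTY = 10.0  # kcal/mol/A^2
DEFAULT_TORSION_PENALTY = 0.01  # kcal/mol/deg^2


class ConstraintParseError(ValueError):
    pass


@dataclass(frozen=True)
class Constraint:
    """One NMR restraint record (atom indices 0-based internally)."""

    kind: str  # nmr | qnmr | torsion
    atoms_a: tuple
    atoms_b: tuple  # torsion: atoms_a holds all four atoms, atoms_b empty
    dist: float = 0.0
    wiggle: float = 0.0
    lo: float = 0.0
    hi: float = 0.0
    penalty: float = DEFAULT_PENALTY
    label: str = ""

    def measure(self, coords: np.ndarray) -> float:
        if self.kind == "torsion":
            from macroconf.ffmin import dihedral_deg

            return dihedral_deg(*(coords[i] for i in self.atoms_a))
        ca = coords[list(self.atoms_a)].mean(axis=0)
        cb = coords[list(self.atoms_b)].mean(axis=0)
        return float(np.linalg.norm(ca - cb))

    def violation_energy(self, coords: np.ndarray) -> float:
        m = self.measure(coords)
        if self.kind == "torsion":
            return square_well_torsion_penalty(m, self.lo, self.hi, self.penalty)
        return square_well_distance_penalty(m, self.dist, self.wiggle, self.penalty)

    def violation_magnitude(self, coords: np.ndarray) -> float:
        """Distance (A) or angle (deg) beyond the well edge; 0 if satisfied."""
        m = self.measure(coords)
        if self.kind == "torsion":
            from macroconf.ffmin import angle_in_well, _angular_distance

            if angle_in_well(m, self.lo, self.hi):
                return 0.0
            return min(_angular_distance(m, self.lo), _angular_distance(m, self.hi))
        return max(0.0, abs(m - self.dist) - self.wiggle)


@dataclass
class ConstraintSet:
    constraints: list = field(default_factory=list)

    def __len__(self):
        return len(self.constraints)

    def __iter__(self):
        return iter(self.constraints)

    def to_restraints(self, graph: MolecularGraph | None = None) -> RestraintSet:
        """The equivalent square-well restraints for minimization.  The
        penalty forms are identical, so the violation energy the profiler
        reports equals the restraint energy the minimizer saw."""
        dists, tors = [], []
        for c in self.constraints:
            if c.kind == "torsion":
                tors.append(
                    TorsionWell(atoms=c.atoms_a, lo=c.lo, hi=c.hi, penalty=c.penalty,
                                label=c.label)
                )
            else:
                dists.append(
                    DistanceWell(
                        group_a=c.atoms_a, group_b=c.atoms_b, dist=c.dist,
                        wiggle=c.wiggle, penalty=c.penalty, label=c.label,
                    )
                )
        return RestraintSet(distance_wells=dists, torsion_wells=tors)

    def violation_energy(self, coords: np.ndarray) -> float:
        return sum(c.violation_energy(coords) for c in self.constraints)

    def serialize(self) -> str:
        lines = []
        for c in self.constraints:
            if c.kind == "torsion":
                a = " ".join(str(i + 1) for i in c.atoms_a)
                lines.append(f"torsion {a} lo={c.lo:.10g} hi={c.hi:.10g} penalty={c.penalty:.10g}")
            else:
                a = ",".join(str(i + 1) for i in c.atoms_a)
                b = ",".join(str(i + 1) for i in c.atoms_b)
                lines.append(
                    f"{c.kind} {a} {b} dist={c.dist:.10g} wiggle={c.wiggle:.10g} "
                    f"penalty={c.penalty:.10g}"
                )
        return "\n".join(lines) + "\n"

    def write(self, path: str):
        with open(path, "w") as fh:
            fh.write(self.serialize())


def _parse_kv(tokens, line_no):
    out = {}
    for tok in tokens:
        if "=" not in tok:
            raise ConstraintParseError(f"line {line_no}: expected key=value, got {tok!r}")
        k, v = tok.split("=", 1)
        try:
            out[k] = float(v)
        except ValueError as exc:
            raise ConstraintParseError(f"line {line_no}: bad number {v!r}") from exc
    return out


def _parse_group(tok, line_no, n_atoms):
    try:
        idx = tuple(int(t) - 1 for t in tok.split(","))
    except ValueError as exc:
        raise ConstraintParseError(f"line {line_no}: bad atom index {tok!r}") from exc
    for i in idx:
        if not (0 <= i < n_atoms):
            raise ConstraintParseError(
                f"line {line_no}: atom index {i + 1} out of range (1..{n_atoms})"
            )
    if not idx:
        raise ConstraintParseError(f"line {line_no}: empty atom group")
    return idx


def parse_constraints(text: str, graph: MolecularGraph) -> ConstraintSet:
    n = graph.num_atoms
    out = []
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#")[0].strip()
        if not line:
            continue
        tokens = line.split()
        kind = tokens[0].lower()
        if kind in ("nmr", "qnmr"):
            if len(tokens) < 3:
                raise ConstraintParseError(f"line {line_no}: too few fields")
            a = _parse_group(tokens[1], line_no, n)
            b = _parse_group(tokens[2], line_no, n)
            if kind == "nmr" and (len(a) != 1 or len(b) != 1):
                raise ConstraintParseError(
                    f"line {line_no}: 'nmr' takes single atoms; use 'qnmr' for groups"
                )
            kv = _parse_kv(tokens[3:], line_no)
            dist = kv.get("dist")
            if dist is None:
                raise ConstraintParseError(f"line {line_no}: missing dist=")
            wiggle = kv.get("wiggle", 0.5)
            penalty = kv.get("penalty", DEFAULT_PENALTY)
            if wiggle < 0:
                raise ConstraintParseError(f"line {line_no}: negative wiggle")
            if penalty < 0:
                raise ConstraintParseError(f"line {line_no}: negative penalty")
            out.append(
                Constraint(kind=kind, atoms_a=a, atoms_b=b, dist=dist, wiggle=wiggle,
                           penalty=penalty, label=f"{kind}@{line_no}")
            )
        elif kind == "torsion":
            if len(tokens) < 5:
                raise ConstraintParseError(f"line {line_no}: torsion needs 4 atoms")
            atoms = tuple(
                _parse_group(t, line_no, n)[0] for t in tokens[1:5]
            )
            # the four atoms must form a connected path
            mol = graph.mol
            for x, y in zip(atoms, atoms[1:]):
                if mol.GetBondBetweenAtoms(x, y) is None:
                    raise ConstraintParseError(
                        f"line {line_no}: torsion atoms {x + 1}-{y + 1} not bonded"
                    )
            kv = _parse_kv(tokens[5:], line_no)
            if "lo" not in kv or "hi" not in kv:
                raise ConstraintParseError(f"line {line_no}: missing lo=/hi=")
            penalty = kv.get("penalty", DEFAULT_TORSION_PENALTY)
            if penalty < 0:
                raise ConstraintParseError(f"line {line_no}: negative penalty")
            out.append(
                Constraint(kind="torsion", atoms_a=atoms, atoms_b=(),
                           lo=kv["lo"], hi=kv["hi"], penalty=penalty,
                           label=f"torsion@{line_no}")
            )
        else:
            raise ConstraintParseError(f"line {line_no}: unknown record kind {kind!r}")
    return ConstraintSet(constraints=out)


def parse_constraint_file(path: str, graph: MolecularGraph) -> ConstraintSet:
    with open(path) as fh:
        return parse_constraints(fh.read(), graph)


# ---------------------------------------------------------------------------
# profiling


def profile_ensemble(
    ensemble,
    constraints: ConstraintSet,
    reference: Conformer | None = None,
):
    """Profile an ensemble against a constraint set.

    Returns ``(conformer_profile, constraint_profile)`` DataFrames.  The
    conformer profile lists force-field energy, violation energy and discrete
    violation counts per threshold (plus automorphism-corrected RMSD to the
    reference when one is given); the constraint profile lists, for each
    restraint, how often and how badly it is violated across the ensemble.
    """
    rows = []
    mags = np.zeros((len(ensemble.conformers), len(constraints)))
    for ci, conf in enumerate(ensemble.conformers):
        viol = 0.0
        for ki, c in enumerate(constraints):
            mags[ci, ki] = c.violation_magnitude(conf.coords)
            viol += c.violation_energy(conf.coords)
        row = {
            "conformer": ci,
            "energy_kcal_mol": conf.energy,
            "violation_energy_kcal_mol": viol,
        }
        for thr in DISTANCE_THRESHOLDS:
            row[f"n_dist_viol_gt_{thr:g}A"] = int(
                sum(
                    1
                    for ki, c in enumerate(constraints)
                    if c.kind != "torsion" and mags[ci, ki] > thr
                )
            )
        for thr in TORSION_THRESHOLDS:
            row[f"n_tors_viol_gt_{thr:g}deg"] = int(
                sum(
                    1
                    for ki, c in enumerate(constraints)
                    if c.kind == "torsion" and mags[ci, ki] > thr
                )
            )
        if reference is not None:
            row["rmsd_to_reference_A"] = automorph_rmsd_single(
                ensemble.graph, conf.coords, reference.coords
            )
        rows.append(row)
    conf_df = pd.DataFrame(rows)
    crows = []
    for ki, c in enumerate(constraints):
        col = mags[:, ki]
        violated = col > 1e-9
        crows.append(
            {
                "constraint": c.label or f"{c.kind}_{ki}",
                "kind": c.kind,
                "frequency": float(np.mean(violated)) if len(col) else 0.0,
                "mean_magnitude": float(col[violated].mean()) if violated.any() else 0.0,
                "max_magnitude": float(col.max()) if len(col) else 0.0,
            }
        )
    return conf_df, pd.DataFrame(crows)


def write_profiles(conf_df: pd.DataFrame, cons_df: pd.DataFrame, prefix: str):
    """Tab-delimited profile outputs ``<prefix>-conformers.tsv`` and
    ``<prefix>-constraints.tsv``."""
    conf_df.to_csv(f"{prefix}-conformers.tsv", sep="\t", index=False)
    cons_df.to_csv(f"{prefix}-constraints.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# residual dipolar couplings


@dataclass(frozen=True)
class RDCRecord:
    atom_i: int
    atom_j: int
    observed: float  # coupling (Hz, or reduced units)


@dataclass
class AlignmentTensor:
    """Saupe order matrix fitted to RDCs, with back-calculation and Q-factor."""

    saupe: np.ndarray  # 3x3 symmetric traceless
    back_calculated: np.ndarray
    observed: np.ndarray
    q_factor: float

    @property
    def elements(self) -> np.ndarray:
        """The five independent elements (Szz', Sxx'-Syy' basis is not used;
        this is [Sxx, Syy, Sxy, Sxz, Syz])."""
        S = self.saupe
        return np.array([S[0, 0], S[1, 1], S[0, 1], S[0, 2], S[1, 2]])


class RDCFitError(ValueError):
    pass


def _direction_cosines(coords: np.ndarray, rdcs) -> np.ndarray:
    B = np.zeros((len(rdcs), 3))
    for k, r in enumerate(rdcs):
        v = coords[r.atom_j] - coords[r.atom_i]
        n = np.linalg.norm(v)
        if n < 1e-9:
            raise RDCFitError(f"degenerate bond vector for RDC {r}")
        B[k] = v / n
    return B


def saupe_design_matrix(B: np.ndarray) -> np.ndarray:
    """Rows [bx^2-bz^2, by^2-bz^2, 2bxby, 2bxbz, 2bybz] so that
    D = A @ [Sxx, Syy, Sxy, Sxz, Syz] with Szz = -Sxx-Syy."""
    bx, by, bz = B[:, 0], B[:, 1], B[:, 2]
    return np.column_stack(
        [bx * bx - bz * bz, by * by - bz * bz, 2 * bx * by, 2 * bx * bz, 2 * by * bz]
    )


def forward_couplings(coords: np.ndarray, rdcs, saupe: np.ndarray) -> np.ndarray:
    B = _direction_cosines(coords, rdcs)
    return np.einsum("ki,ij,kj->k", B, saupe, B)


def fit_alignment_tensor(conformer: Conformer, rdcs: list) -> AlignmentTensor:
    """Least-squares Saupe tensor by SVD of the direction-cosine design
    matrix; requires at least five RDCs with non-degenerate directions."""
    if len(rdcs) < 5:
        raise RDCFitError("at least 5 RDCs are required to fit an alignment tensor")
    coords = np.asarray(conformer.coords, float)
    B = _direction_cosines(coords, rdcs)
    A = saupe_design_matrix(B)
    obs = np.array([r.observed for r in rdcs], float)
    rank = np.linalg.matrix_rank(A, tol=1e-8)
    if rank < 5:
        raise RDCFitError(
            "rank-deficient design matrix (bond directions too degenerate); "
            "add RDCs with more diverse orientations"
        )
    x, *_ = np.linalg.lstsq(A, obs, rcond=None)
    sxx, syy, sxy, sxz, syz = x
    S = np.array([[sxx, sxy, sxz], [sxy, syy, syz], [sxz, syz, -sxx - syy]])
    calc = np.einsum("ki,ij,kj->k", B, S, B)
    denom = float(np.sqrt(np.mean(obs**2)))
    if denom < 1e-12:
        q = 0.0
    else:
        q = float(np.sqrt(np.mean((obs - calc) ** 2)) / denom)
    return AlignmentTensor(saupe=S, back_calculated=calc, observed=obs, q_factor=q)


def read_rdc_table(path: str) -> list:
    """RDC input as TSV with columns atom_i, atom_j (1-based), D_obs."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = list(df.columns[:3])
    return [
        RDCRecord(int(r[cols[0]]) - 1, int(r[cols[1]]) - 1, float(r[cols[2]]))
        for _, r in df.iterrows()
    ]
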