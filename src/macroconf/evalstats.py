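"""Evaluation statistics: automorphism-corrected RMSD, ensemble success
metrics, and the significance machinery used for benchmark comparisons
(two-sample Kolmogorov-Smirnov critical differences and paired t-tests).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from scipy import stats

from macroconf.chemgraph import MolecularGraph
from macroconf.geometry import kabsch_rmsd

AUTOMORPHISM_CAP = 10000

#: asymptotic two-sample KS coefficients c(alpha) = sqrt(-ln(alpha/2)/2)
def ks_coefficient(alpha: float) -> float:
    return math.sqrt(-math.log(alpha / 2.0) / 2.0)


@dataclass
class RMSDResult:
    rmsd: float  # heavy-atom RMSD, Angstrom
    ring_rmsd: float | None  # macrocyclic ring atoms only, same mapping
    conformer_index: int
    automorphism: tuple


def heavy_atom_automorphisms(graph: MolecularGraph, cap: int = AUTOMORPHISM_CAP):
    """Symmetry self-maps of the heavy-atom bond graph (element and bond-order
    colored), as tuples mapping heavy-position -> heavy-position.

    Enumeration is capped; if the cap is hit a warning is emitted and the
    identity-containing partial set is used (symmetry correction then only
    improves, never degrades, the RMSD).
    """
    import warnings

    mol = Chem.RemoveHs(Chem.Mol(graph.mol))
    matches = mol.GetSubstructMatches(mol, uniquify=False, maxMatches=cap, useChirality=False)
    if len(matches) >= cap:
        warnings.warn(
            f"automorphism enumeration capped at {cap}; RMSD correction may be partial"
        )
    if not matches:
        matches = (tuple(range(mol.GetNumAtoms())),)
    return matches


def automorph_rmsd_single(
    graph: MolecularGraph, coords: np.ndarray, ref_coords: np.ndarray,
    automorphisms=None,
) -> float:
    """Minimum heavy-atom RMSD of one conformer against a reference over all
    molecular symmetries, with optimal rigid superposition for each."""
    heavy = graph.heavy_atoms()
    if automorphisms is None:
        automorphisms = heavy_atom_automorphisms(graph)
    P = np.asarray(coords, float)[heavy]
    Q = np.asarray(ref_coords, float)[heavy]
    best = math.inf
    for perm in automorphisms:
        # perm maps heavy position k -> heavy position perm[k]
        best = min(best, kabsch_rmsd(P[list(perm)], Q))
    return best


def automorph_rmsd(graph: MolecularGraph, ensemble, reference) -> RMSDResult:
    """Best automorphism-corrected heavy-atom RMSD over an ensemble, with the
    macrocyclic ring RMSD computed under the same best mapping."""
    from macroconf import chemgraph

    ref_coords = reference.coords if hasattr(reference, "coords") else np.asarray(reference)
    conformers = ensemble.conformers if hasattr(ensemble, "conformers") else list(ensemble)
    heavy = graph.heavy_atoms()
    heavy_pos = {a: k for k, a in enumerate(heavy)}
    autos = heavy_atom_automorphisms(graph)
    macros = chemgraph.perceive_macrocycles(graph)
    ring_atoms = sorted(set().union(*(m.atoms for m in macros))) if macros else None
    best = (math.inf, None, None)
    Q = np.asarray(ref_coords, float)[heavy]
    for ci, conf in enumerate(conformers):
        P = np.asarray(conf.coords, float)[heavy]
        for perm in autos:
            r = kabsch_rmsd(P[list(perm)], Q)
            if r < best[0]:
                best = (r, ci, perm)
    rmsd, ci, perm = best
    ring_rmsd = None
    if ring_atoms is not None:
        # align the full heavy-atom sets, then measure ring atoms under the
        # same mapping and transform
        from macroconf.geometry import kabsch_rotation

        P = np.asarray(conformers[ci].coords, float)[heavy][list(perm)]
        cp, cq = P.mean(axis=0), Q.mean(axis=0)
        R = kabsch_rotation(P - cp, Q - cq)
        moved = (P - cp) @ R.T + cq
        # ring atom at heavy position heavy_pos[a]; under perm the conformer
        # atom matched to reference heavy position k is perm[k]
        ring_pos = [heavy_pos[a] for a in ring_atoms]
        diff = moved[ring_pos] - Q[ring_pos]
        ring_rmsd = float(np.sqrt((diff * diff).sum() / len(ring_pos)))
    return RMSDResult(rmsd=rmsd, ring_rmsd=ring_rmsd, conformer_index=ci,
                      automorphism=perm)


# ---------------------------------------------------------------------------
# success metrics


def success_curve(rmsds, thresholds):
    """Fraction of cases at or below each RMSD threshold."""
    r = np.asarray(list(rmsds), float)
    if r.size == 0:
        raise ValueError("empty RMSD list")
    return np.array([float(np.mean(r <= t)) for t in thresholds])


def rmsd95(rmsds) -> float:
    """95th percentile RMSD (linear interpolation)."""
    return float(np.percentile(np.asarray(list(rmsds), float), 95))


# ---------------------------------------------------------------------------
# significance machinery


def ks_critical_difference(n: int, m: int, alpha: float = 0.05) -> float:
    """Asymptotic two-sample KS critical maximal CDF difference:
    c(alpha) * sqrt((n + m) / (n * m))."""
    if n < 1 or m < 1:
        raise ValueError("sample sizes must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return ks_coefficient(alpha) * math.sqrt((n + m) / (n * m))


def paired_t(pairs):
    """Two-sided paired t-test on (a, b) pairs; returns (t, p).

    With zero variance of the differences the t statistic degenerates: p = 1
    for identical columns and p -> 0 for a constant nonzero difference (a
    warning is emitted in the latter case).
    """
    import warnings

    arr = np.asarray(list(pairs), float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 (a, b) pairs")
    d = arr[:, 0] - arr[:, 1]
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0
        warnings.warn("zero variance of nonzero differences; p from degenerate limit")
        return math.copysign(math.inf, d.mean()), 0.0
    t, p = stats.ttest_rel(arr[:, 0], arr[:, 1])
    return float(t), float(p)


# ---------------------------------------------------------------------------
# benchmark summaries


@dataclass
class BenchmarkSummary:
    results: list  # (name, RMSDResult)
    thresholds: tuple = (0.5, 1.0, 1.5, 2.0)

    @property
    def rmsds(self):
        return [r.rmsd for _, r in self.results]

    def to_frame(self):
        import pandas as pd

        rows = [
            {"molecule": name, "rmsd_A": r.rmsd, "ring_rmsd_A": r.ring_rmsd,
             "best_conformer": r.conformer_index}
            for name, r in self.results
        ]
        return pd.DataFrame(rows)

    def summary(self):
        import pandas as pd

        r = self.rmsds
        succ = success_curve(r, self.thresholds)
        data = {
            "n": len(r),
            "mean_rmsd_A": float(np.mean(r)),
            "median_rmsd_A": float(np.median(r)),
            "rmsd95_A": rmsd95(r),
        }
        for t, s in zip(self.thresholds, succ):
            data[f"success_at_{t:g}A"] = s
        return pd.Series(data)
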