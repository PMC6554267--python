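"""Rigid-body superposition helpers (Kabsch alignment)."""

from __future__ import annotations

import numpy as np


def kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Optimal proper rotation aligning centered P onto centered Q."""
    H = P.T @ Q
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def kabsch_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Minimal RMSD of P onto Q over proper rigid motions (no reflection)."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    R = kabsch_rotation(Pc, Qc)
    diff = Pc @ R.T - Qc
    return float(np.sqrt((diff * diff).sum() / len(P)))


def superpose(P: np.ndarray, Q: np.ndarray):
    """(rmsd, transformed P) after optimal superposition of P onto Q."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    R = kabsch_rotation(P - cp, Q - cq)
    moved = (P - cp) @ R.T + cq
    diff = moved - Q
    return float(np.sqrt((diff * diff).sum() / len(P))), moved
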