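"""Reconstruction quality metrics.

Three complementary views of agreement between a reconstruction and its
reference:

* **RMSD** after least-squares superposition (Kabsch).  Reflection is
  allowed by default because pairwise distances cannot determine
  chirality — a perfect reconstruction may be the mirror image of the
  truth.  Uniform scale matching is off by default (the frequency-to-
  distance power law fixes absolute scale) but available for comparing
  methods whose output scale is arbitrary.
* **Distance PCC** — Pearson correlation between the upper-triangle
  pairwise-distance vectors of the two structures; invariant to rigid
  motion, reflection and uniform scaling, so it isolates shape agreement.
* **Recovered-frequency SCC** — Spearman correlation between the input
  contact frequencies and frequencies back-computed from the
  reconstructed geometry (``F' = d**(-1/alpha)``), over pairs with
  positive input frequency; used when no ground-truth structure exists.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr, spearmanr

from ._types import ContactMatrix, Structure
from .errors import (
    DegenerateAlignmentError,
    ParameterError,
    UndefinedCorrelationError,
    ValidationError,
)

__all__ = [
    "AlignmentResult",
    "superpose",
    "rmsd",
    "distance_pcc",
    "recovered_scc",
]


@dataclass
class AlignmentResult:
    """Optimal transform of B onto A and the residual RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    scale: float
    reflection_used: bool
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Map coordinates from B's frame into A's frame."""
        return self.scale * coords @ self.rotation.T + self.translation


def _coords(X: Structure | np.ndarray) -> np.ndarray:
    if isinstance(X, Structure):
        return X.coords
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValidationError(f"expected (n, 3) coordinates, got {X.shape}")
    return X


def superpose(
    A: Structure | np.ndarray,
    B: Structure | np.ndarray,
    allow_reflection: bool = True,
    allow_scale: bool = False,
) -> AlignmentResult:
    """Least-squares superposition of B onto A (Kabsch, via SVD).

    With ``allow_reflection`` the optimum is taken over all orthogonal
    transforms (det ±1); otherwise over proper rotations only.  With
    ``allow_scale`` a uniform positive scale is fitted as well.
    """
    Pa, Pb = _coords(A), _coords(B)
    if Pa.shape != Pb.shape:
        raise ValidationError(f"size mismatch: {Pa.shape} vs {Pb.shape}")
    n = Pa.shape[0]
    ca, cb = Pa.mean(axis=0), Pb.mean(axis=0)
    Ac, Bc = Pa - ca, Pb - cb
    if allow_scale and (n < 3 or np.linalg.matrix_rank(Bc, tol=1e-9) < 2):
        raise DegenerateAlignmentError(
            "scale fitting needs at least 3 non-collinear points"
        )
    H = Ac.T @ Bc
    U, sv, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    if allow_reflection:
        signs = np.ones(3)
    else:
        signs = np.array([1.0, 1.0, d])  # flip the weakest axis if improper
    R = U @ np.diag(signs) @ Vt
    traced = float((sv * signs).sum())
    if allow_scale:
        denom = float((Bc**2).sum())
        if denom == 0.0:
            raise DegenerateAlignmentError("cannot scale a zero-extent structure")
        scale = traced / denom
    else:
        scale = 1.0
    Bfit = scale * Bc @ R.T
    res = float(np.sqrt(((Ac - Bfit) ** 2).sum() / n))
    return AlignmentResult(
        rotation=R,
        translation=ca - scale * R @ cb,
        scale=scale,
        reflection_used=bool(np.linalg.det(R) < 0),
        rmsd=res,
    )


def rmsd(
    A: Structure | np.ndarray,
    B: Structure | np.ndarray,
    allow_reflection: bool = True,
    allow_scale: bool = False,
) -> float:
    """Post-superposition RMSD, in the reference structure's length units."""
    return superpose(A, B, allow_reflection=allow_reflection, allow_scale=allow_scale).rmsd


def distance_pcc(A: Structure | np.ndarray, B: Structure | np.ndarray) -> float:
    """Pearson correlation between the two structures' pairwise-distance vectors."""
    Pa, Pb = _coords(A), _coords(B)
    if Pa.shape != Pb.shape:
        raise ValidationError(f"size mismatch: {Pa.shape} vs {Pb.shape}")
    if Pa.shape[0] < 3:
        raise ValidationError("distance PCC needs at least 3 points")
    da, db = pdist(Pa), pdist(Pb)
    if np.ptp(da) == 0.0 or np.ptp(db) == 0.0:
        raise UndefinedCorrelationError("constant distance vector: PCC undefined")
    return float(pearsonr(da, db).statistic)


def recovered_scc(C_input: ContactMatrix, S: Structure, alpha: float = 0.5) -> float:
    """Spearman correlation between input and geometry-recovered frequencies.

    Recovered frequencies invert the distance power law: ``F' =
    d**(-1/alpha)`` with d the reconstructed Euclidean distances.  Only
    pairs with positive input frequency enter (zero frequency maps to
    infinite distance and has no recoverable rank); rank ties average.
    """
    if not alpha > 0:
        raise ParameterError("alpha must be positive")
    if C_input.n_bins != S.n_bins:
        raise ValidationError("matrix and structure sizes differ")
    iu = np.triu_indices(C_input.n_bins, 1)
    f_in = C_input.F[iu]
    pos = f_in > 0
    if not pos.any():
        raise UndefinedCorrelationError("no positive input frequencies")
    d = pdist(S.coords)[pos]
    f_rec = d ** (-1.0 / alpha)
    res = spearmanr(f_in[pos], f_rec)
    return float(res.statistic)
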