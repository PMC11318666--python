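"""Shared plain-data containers.

These dataclasses are re-exported by the user-facing modules
(:mod:`evrc.matrices_io`, :mod:`evrc.coclustering`, :mod:`evrc.reconstruct`);
they live here only to avoid import cycles between those modules.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = [
    "ContactMatrix",
    "DistanceMatrix",
    "BinIndexMap",
    "Structure",
    "CoCCMatrix",
]


def _check_square(M: np.ndarray, what: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValidationError(f"{what} must be a square 2-D array, got shape {M.shape}")
    return M


@dataclass
class ContactMatrix:
    """Symmetric non-negative interaction frequencies over N genomic bins.

    The diagonal carries no information (a bin's contact with itself) and is
    forced to zero on construction; downstream code never reads it.
    """

    F: np.ndarray
    chain_label: str = "chr"

    def __post_init__(self) -> None:
        F = _check_square(self.F, "contact matrix")
        if not np.all(np.isfinite(F)):
            raise ValidationError("contact matrix contains non-finite entries")
        if np.any(F < 0):
            raise ValidationError("contact matrix contains negative frequencies")
        if not np.allclose(F, F.T, rtol=0, atol=1e-9):
            raise ValidationError(
                "contact matrix is asymmetric; symmetrize before constructing"
            )
        F = (F + F.T) / 2.0  # remove residual float asymmetry
        np.fill_diagonal(F, 0.0)
        self.F = F

    @property
    def n_bins(self) -> int:
        return self.F.shape[0]


@dataclass
class DistanceMatrix:
    """Target spatial distances; ``inf`` marks pairs with no observed contact."""

    D: np.ndarray
    alpha_used: float

    def __post_init__(self) -> None:
        D = _check_square(self.D, "distance matrix")
        off = ~np.eye(D.shape[0], dtype=bool)
        finite = np.isfinite(D) & off
        if np.any(D[finite] <= 0):
            raise ValidationError("finite target distances must be positive")
        if not np.array_equal(np.isinf(D) & off, np.isinf(D.T) & off) or not np.allclose(
            np.where(finite, D, 0.0), np.where(finite.T, D.T, 0.0), rtol=0, atol=1e-12
        ):
            raise ValidationError("distance matrix must be symmetric")
        self.D = D

    @property
    def n_bins(self) -> int:
        return self.D.shape[0]

    def finite_mask(self) -> np.ndarray:
        """Boolean off-diagonal mask of usable (finite) pair constraints."""
        m = np.isfinite(self.D)
        np.fill_diagonal(m, False)
        return m


@dataclass
class BinIndexMap:
    """Bookkeeping between original (chain, local bin) labels and matrix rows.

    ``kept`` lists, in row order, the (chain, local_bin, global_row) triples
    present in the current matrix/structure; ``dropped`` lists bins that were
    removed (e.g. for having no finite contacts) and are reported as NaN rows
    on output.
    """

    kept: list[tuple[str, int, int]]
    dropped: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        globals_ = [g for (_, _, g) in self.kept]
        if globals_ != list(range(len(globals_))):
            raise ValidationError("global indices must be contiguous from 0")
        seen = {(c, b) for (c, b, _) in self.kept} | set(self.dropped)
        if len(seen) != len(self.kept) + len(self.dropped):
            raise ValidationError("kept and dropped bins must not overlap")

    @classmethod
    def identity(cls, n: int, chain: str = "chr") -> "BinIndexMap":
        return cls(kept=[(chain, i, i) for i in range(n)])

    @property
    def n_kept(self) -> int:
        return len(self.kept)


@dataclass
class Structure:
    """Ordered 3-D coordinates, one point per kept bin, with chain labels."""

    coords: np.ndarray
    chains: np.ndarray | list[str] | None = None
    index_map: BinIndexMap | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValidationError(f"coordinates must be (n, 3), got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValidationError("structure coordinates must be finite")
        self.coords = coords
        n = coords.shape[0]
        if self.chains is None:
            self.chains = np.full(n, "chr", dtype=object)
        else:
            chains = np.asarray(self.chains, dtype=object)
            if chains.shape != (n,):
                raise ValidationError("one chain label per bin is required")
            self.chains = chains
        if self.index_map is None:
            self.index_map = BinIndexMap(
                kept=[(str(c), i, i) for i, c in enumerate(self.chains)]
            )

    @property
    def n_bins(self) -> int:
        return self.coords.shape[0]

    def chain_names(self) -> list[str]:
        """Distinct chain labels in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chains:
            seen.setdefault(str(c), None)
        return list(seen)


@dataclass
class CoCCMatrix:
    """Symmetric co-clustering coefficients in [0, 1]; diagonal unused."""

    values: np.ndarray

    def __post_init__(self) -> None:
        V = _check_square(self.values, "coCC matrix")
        off = ~np.eye(V.shape[0], dtype=bool)
        if np.any((V[off] < 0) | (V[off] > 1)):
            raise ValidationError("co-clustering coefficients must lie in [0, 1]")
        if not np.allclose(V, V.T, rtol=0, atol=1e-12):
            raise ValidationError("coCC matrix must be symmetric")
        np.fill_diagonal(V, 0.0)
        self.values = V

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]
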