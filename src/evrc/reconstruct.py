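"""Iterative error-vector-resultant optimizer.

Each bin ``j`` holds a position ``P_j``.  For every pair with a finite
target distance the *error vector*

    E_ij = unit(P_i - P_j) * (|P_i - P_j| - D_ij)

points from ``j`` toward ``i`` when the pair is too far apart and away
when too close; its magnitude is the signed violation.  A bin's update is
the co-clustering-weighted resultant of its error vectors,

    E_j = sum_i  coCC_ij / (S_j * (N - 1)**beta) * E_ij,
    S_j = sum_i coCC_ij            (finite pairs only),

i.e. a weighted *average* of the per-pair error vectors further damped by
``(N - 1)**beta``.  The normalization by ``S_j`` keeps every step a convex
combination of error vectors regardless of how many constraints a bin has,
which is what makes the synchronous update stable at any matrix density;
``beta`` (default 0.1) only tunes speed — larger values converge more
slowly.  All bins move simultaneously (``P_j += E_j``), the objective is

    F = sum_j |E_j|,

and iteration stops when the change ``dF = |F_t - F_{t-1}|`` drops below
``tol`` (default 1e-6) or ``max_iter`` (default 20000) is reached.
Optimization is over relative geometry only: the update commutes with
rigid motions, so absolute placement/orientation is fixed later by
superposition during evaluation.

Gaussian smoothing of the final curve is available for visualization only;
quality metrics are always computed on unsmoothed coordinates.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from ._types import BinIndexMap, CoCCMatrix, DistanceMatrix, Structure
from .errors import DivergenceError, ParameterError, ValidationError

__all__ = [
    "Structure",
    "OptimizerConfig",
    "OptimizerTrace",
    "init_coords",
    "error_vector",
    "resultant",
    "objective",
    "step",
    "run",
    "smooth",
]

_COINCIDENT = 1e-12  # below this separation the unit vector is undefined
_DIVERGENCE_PATIENCE = 100  # consecutive objective increases before giving up


@dataclass
class OptimizerConfig:
    """Tunables; defaults follow the method's published settings."""

    alpha: float = 0.5
    beta: float = 0.1
    tol: float = 1e-6
    max_iter: int = 20000
    seed: int | None = None
    init_scale: float = 1.0

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ParameterError("alpha must be positive")
        if self.beta < 0:
            raise ParameterError("beta must be non-negative")
        if not self.tol > 0:
            raise ParameterError("tol must be positive")
        if self.max_iter < 1:
            raise ParameterError("max_iter must be at least 1")
        if not self.init_scale > 0:
            raise ParameterError("init_scale must be positive")


@dataclass
class OptimizerTrace:
    F_values: np.ndarray
    iterations_run: int
    converged: bool
    final_dF: float
    stop_reason: str = ""

    def __post_init__(self) -> None:
        self.F_values = np.asarray(self.F_values, dtype=float)
        if len(self.F_values) != self.iterations_run:
            raise ValidationError("trace length must equal iterations_run")


def init_coords(n: int, config: OptimizerConfig, D: DistanceMatrix) -> Structure:
    """Random initial coordinates in a cube scaled to the data's distance scale."""
    if n < 2:
        raise ValidationError("need at least 2 bins to embed")
    if D.n_bins != n:
        raise ValidationError("distance matrix size does not match n")
    finite = D.D[D.finite_mask()]
    side = config.init_scale * (float(finite.mean()) if finite.size else 1.0)
    rng = np.random.default_rng(config.seed)
    for _ in range(100):
        P = rng.uniform(0.0, side, size=(n, 3))
        diffs = P[:, None, :] - P[None, :, :]
        d2 = np.einsum("ijk,ijk->ij", diffs, diffs)
        np.fill_diagonal(d2, np.inf)
        if d2.min() > _COINCIDENT**2:
            return Structure(coords=P)
    raise DivergenceError("could not draw non-coincident initial coordinates")


def error_vector(
    P_i: np.ndarray, P_j: np.ndarray, D_ij: float, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Signed violation of one pair constraint, directed along P_i - P_j.

    At (numerically) zero separation the direction is undefined; a random
    unit direction of magnitude ``D_ij`` is returned instead, so coincident
    points are pushed apart (pass ``rng`` for reproducibility).
    """
    P_i = np.asarray(P_i, dtype=float)
    P_j = np.asarray(P_j, dtype=float)
    if not (np.all(np.isfinite(P_i)) and np.all(np.isfinite(P_j)) and np.isfinite(D_ij)):
        raise ValidationError("error_vector requires finite inputs")
    if not D_ij > 0:
        raise ValidationError("target distance must be positive and finite")
    diff = P_i - P_j
    d = float(np.linalg.norm(diff))
    if d < _COINCIDENT:
        rng = np.random.default_rng() if rng is None else rng
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        return v * D_ij
    return diff / d * (d - D_ij)


def _pair_weights(D: DistanceMatrix, W: CoCCMatrix, beta: float) -> np.ndarray:
    """Normalized weights w_ij = coCC_ij / (S_j (N-1)^beta) as a (j, i) matrix."""
    mask = D.finite_mask()
    N = D.n_bins
    raw = np.where(mask, W.values, 0.0)
    S = raw.sum(axis=1)
    damp = (N - 1) ** beta
    with np.errstate(invalid="ignore", divide="ignore"):
        w = raw / (S[:, None] * damp)
    w[S == 0.0, :] = 0.0
    return w


def _resultants_all(
    P: np.ndarray,
    D: DistanceMatrix,
    W: CoCCMatrix,
    beta: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Resultant E_j for every bin, vectorized over pairs."""
    mask = D.finite_mask()
    diff = P[:, None, :] - P[None, :, :]  # [j, i] = P_j - P_i
    d = np.sqrt(np.einsum("jik,jik->ji", diff, diff))
    coincident = mask & (d < _COINCIDENT)
    np.fill_diagonal(d, 1.0)
    d = np.where(d < _COINCIDENT, 1.0, d)
    unit = -diff / d[..., None]  # unit(P_i - P_j)
    if coincident.any():
        rng = np.random.default_rng() if rng is None else rng
        ju, iu = np.where(np.triu(coincident, 1))
        dirs = rng.normal(size=(len(ju), 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        unit[ju, iu] = dirs
        unit[iu, ju] = -dirs
        d[ju, iu] = d[iu, ju] = 0.0
    mag = np.where(mask, d - np.where(mask, D.D, 0.0), 0.0)
    w = _pair_weights(D, W, beta)
    return np.einsum("ji,jik->jk", w * mag, unit)


def resultant(
    j: int,
    S: Structure,
    D: DistanceMatrix,
    W: CoCCMatrix,
    beta: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Weighted-average resultant error vector of one bin (reference path)."""
    n = S.n_bins
    if not (0 <= j < n):
        raise IndexError(f"bin {j} outside 0..{n - 1}")
    mask = D.finite_mask()[j]
    idx = np.flatnonzero(mask)
    weights = W.values[j, idx]
    total_w = weights.sum()
    if idx.size == 0 or total_w == 0.0:
        return np.zeros(3)
    damp = (n - 1) ** beta
    out = np.zeros(3)
    for i, w in zip(idx, weights):
        out += w * error_vector(S.coords[i], S.coords[j], D.D[j, i], rng=rng)
    return out / (total_w * damp)


def objective(S: Structure, D: DistanceMatrix, W: CoCCMatrix, beta: float) -> float:
    """F = sum of resultant magnitudes; zero iff every resultant vanishes."""
    E = _resultants_all(S.coords, D, W, beta)
    return float(np.linalg.norm(E, axis=1).sum())


def step(
    S: Structure,
    D: DistanceMatrix,
    W: CoCCMatrix,
    beta: float,
    rng: np.random.Generator | None = None,
) -> tuple[Structure, float]:
    """One synchronous update: move every bin by its resultant.

    Returns the updated structure and the objective F evaluated on the
    pre-update coordinates.
    """
    E = _resultants_all(S.coords, D, W, beta, rng=rng)
    F = float(np.linalg.norm(E, axis=1).sum())
    P_new = S.coords + E
    if not np.all(np.isfinite(P_new)):
        raise DivergenceError("non-finite coordinates produced by update step")
    return Structure(coords=P_new, chains=S.chains, index_map=S.index_map), F


def run(
    D: DistanceMatrix,
    W: CoCCMatrix,
    config: OptimizerConfig | None = None,
    chains: np.ndarray | list[str] | None = None,
    index_map: BinIndexMap | None = None,
) -> tuple[Structure, OptimizerTrace]:
    """Optimize until ``|F_t - F_{t-1}| < tol`` or ``max_iter``; reproducible by seed."""
    config = OptimizerConfig() if config is None else config
    n = D.n_bins
    if W.n_bins != n:
        raise ValidationError("coCC matrix size does not match distance matrix")
    rng = np.random.default_rng(config.seed)
    S = init_coords(n, config, D)
    P = S.coords
    mask = D.finite_mask()
    w = _pair_weights(D, W, config.beta)
    Dfin = np.where(mask, D.D, 0.0)

    F_values: list[float] = []
    F_prev: float | None = None
    converged = False
    final_dF = np.inf
    rising = 0
    streak_start_F = np.inf
    stop_reason = "max_iter reached"
    for it in range(config.max_iter):
        diff = P[:, None, :] - P[None, :, :]
        d = np.sqrt(np.einsum("jik,jik->ji", diff, diff))
        if (mask & (d < _COINCIDENT)).any():
            E = _resultants_all(P, D, W, config.beta, rng=rng)
        else:
            dsafe = np.where(d < _COINCIDENT, 1.0, d)
            unit = -diff / dsafe[..., None]
            mag = np.where(mask, d - Dfin, 0.0)
            E = np.einsum("ji,jik->jk", w * mag, unit)
        F = float(np.linalg.norm(E, axis=1).sum())
        F_values.append(F)
        P = P + E
        if not np.all(np.isfinite(P)):
            raise DivergenceError(
                f"non-finite coordinates at iteration {it}; try a larger beta",
                iteration=it,
            )
        if F_prev is not None:
            final_dF = abs(F - F_prev)
            if final_dF < config.tol:
                converged = True
                stop_reason = f"dF < {config.tol:g}"
                F_prev = F
                break
            if F > F_prev:
                if rising == 0:
                    streak_start_F = F_prev
                rising += 1
            else:
                rising = 0
            # genuine divergence grows geometrically; a long slow creep at
            # the noise floor of an inconsistent instance is not divergence
            if rising >= _DIVERGENCE_PATIENCE and F > 10.0 * streak_start_F:
                raise DivergenceError(
                    f"objective grew for {_DIVERGENCE_PATIENCE} consecutive "
                    f"iterations (at iteration {it}); try a larger beta",
                    iteration=it,
                )
        F_prev = F
    trace = OptimizerTrace(
        F_values=np.array(F_values),
        iterations_run=len(F_values),
        converged=converged,
        final_dF=float(final_dF),
        stop_reason=stop_reason,
    )
    out = Structure(coords=P, chains=chains, index_map=index_map)
    return out, trace


def smooth(S: Structure, sigma: float | str = "auto") -> Structure:
    """Gaussian-filter each coordinate axis along the bin order, per chain.

    ``sigma="auto"`` (the default) means no smoothing and returns the input
    unchanged.  Chains are filtered independently so no positional
    information bleeds across chromosome boundaries.  For visualization
    only — evaluation always uses unsmoothed coordinates.
    """
    if isinstance(sigma, str):
        if sigma == "auto":
            return Structure(coords=S.coords.copy(), chains=S.chains, index_map=S.index_map)
        raise ParameterError(f"sigma must be positive or 'auto', got {sigma!r}")
    if not sigma > 0:
        raise ParameterError("smoothing sigma must be positive")
    coords = S.coords.copy()
    chains = np.asarray(S.chains, dtype=object)
    for name in S.chain_names():
        sel = np.flatnonzero(chains == name)
        coords[sel] = gaussian_filter1d(
            S.coords[sel], sigma=float(sigma), axis=0, mode="nearest"
        )
    return Structure(coords=coords, chains=S.chains, index_map=S.index_map)
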