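"""Synthetic benchmark structures, contact generation, and distance noise.

Six deterministic curve models of increasing complexity serve as ground
truth: three single-chain curves (circle, open spiral, closed circular
spiral) and three double-chain ones (replication fork, double helix,
double spherical helix), the latter emulating a genome with two
chromosomes whose intra- and inter-chain contacts are both observed.
Each structure defaults to 500 points in total; double-chain models split
them evenly across the two chains.

Contacts follow the reciprocal-distance convention: ``F_ij = 1 / |P_i -
P_j|`` for every pair (intra and inter chain), so the frequency-to-
distance power law with exponent alpha = 1 inverts the construction
exactly and a perfect optimizer can recover the curve up to rigid motion.

Noise is multiplicative on distances, applied *before* conversion to
frequencies: each pairwise distance is scaled by ``(1 + r*s)`` with ``r``
uniform on [-1, 1] drawn once per unordered pair (symmetry preserved) and
``s`` in [0, 1] the noise level.  At ``s = 1`` a distance can shrink to
zero; a floor of 1e-9 times the original value keeps frequencies finite.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial.distance import pdist, squareform

from ._types import ContactMatrix, DistanceMatrix, Structure
from .errors import DegenerateStructureError, ParameterError

__all__ = [
    "MODEL_NAMES",
    "ModelSpec",
    "NoiseSpec",
    "generate_model",
    "structure_distances",
    "contacts_from_structure",
    "add_noise",
    "noisy_contacts",
]

MODEL_NAMES = (
    "circle",
    "spiral",
    "circular_spiral",
    "replication_fork",
    "double_helix",
    "double_spherical_helix",
)

_GEOMETRY_DEFAULTS: dict[str, dict[str, float]] = {
    "circle": {"radius": 1.0},
    "spiral": {"radius": 1.0, "turns": 4.0, "height": 4.0},
    "circular_spiral": {"major_radius": 3.0, "minor_radius": 1.0, "windings": 16.0},
    "replication_fork": {"length": 4.0, "fork_at": 0.4, "spread": 1.0, "strand_gap": 0.02},
    "double_helix": {"radius": 1.0, "turns": 4.0, "height": 4.0},
    "double_spherical_helix": {"sphere_radius": 1.0, "windings": 8.0},
}


@dataclass
class ModelSpec:
    """Which benchmark curve to generate and at what size.

    ``geometry`` overrides the model's canonical parameters (radii, turns,
    ...); unspecified keys keep their defaults.
    """

    name: str
    n_points: int = 500
    geometry: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ParameterError(
                f"unknown model {self.name!r}; choose from {', '.join(MODEL_NAMES)}"
            )
        if self.n_points < 4:
            raise ParameterError("n_points must be at least 4")
        unknown = set(self.geometry) - set(_GEOMETRY_DEFAULTS[self.name])
        if unknown:
            raise ParameterError(f"unknown geometry keys for {self.name}: {sorted(unknown)}")

    @property
    def params(self) -> dict[str, float]:
        return {**_GEOMETRY_DEFAULTS[self.name], **self.geometry}

    @property
    def double_chain(self) -> bool:
        return self.name in ("replication_fork", "double_helix", "double_spherical_helix")


@dataclass
class NoiseSpec:
    """Multiplicative distance-noise level ``s`` in [0, 1] and its seed."""

    s: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.s <= 1.0:
            raise ParameterError(f"noise level s must lie in [0, 1], got {self.s}")


def _circle(n: int, p: dict) -> np.ndarray:
    t = 2 * np.pi * np.arange(n) / n
    r = p["radius"]
    return np.column_stack([r * np.cos(t), r * np.sin(t), np.zeros(n)])


def _spiral(n: int, p: dict) -> np.ndarray:
    t = np.linspace(0.0, 2 * np.pi * p["turns"], n)
    return np.column_stack(
        [p["radius"] * np.cos(t), p["radius"] * np.sin(t), p["height"] * t / t[-1]]
    )


def _circular_spiral(n: int, p: dict) -> np.ndarray:
    # Helix wound around a torus and closed end-to-end.
    theta = 2 * np.pi * np.arange(n) / n
    phi = p["windings"] * theta
    R, r = p["major_radius"], p["minor_radius"]
    return np.column_stack(
        [
            (R + r * np.cos(phi)) * np.cos(theta),
            (R + r * np.cos(phi)) * np.sin(theta),
            r * np.sin(phi),
        ]
    )


def _fork_chain(n: int, p: dict, sign: float) -> np.ndarray:
    # Both strands run along x, parallel at a small gap before the fork
    # point, then diverge quadratically (C1-smooth) in +/- y.
    t = np.linspace(0.0, 1.0, n)
    x = p["length"] * t
    ramp = np.maximum(0.0, t - p["fork_at"]) ** 2
    y = sign * (p["strand_gap"] / 2.0 + p["spread"] * ramp / (1.0 - p["fork_at"]) ** 2)
    return np.column_stack([x, y, np.zeros(n)])


def _helix_chain(n: int, p: dict, phase: float) -> np.ndarray:
    t = np.linspace(0.0, 2 * np.pi * p["turns"], n)
    return np.column_stack(
        [
            p["radius"] * np.cos(t + phase),
            p["radius"] * np.sin(t + phase),
            p["height"] * t / t[-1],
        ]
    )


def _spherical_helix_chain(n: int, p: dict, phase: float) -> np.ndarray:
    # Latitude-sweeping spiral on a sphere; half-step inset at the poles
    # keeps the two phase-shifted chains from meeting there.
    theta = np.pi * (np.arange(n) + 0.5) / n
    phi = 2.0 * p["windings"] * theta + phase
    r = p["sphere_radius"]
    return np.column_stack(
        [
            r * np.sin(theta) * np.cos(phi),
            r * np.sin(theta) * np.sin(phi),
            r * np.cos(theta),
        ]
    )


def generate_model(spec: ModelSpec) -> Structure:
    """Deterministic ground-truth coordinates for one benchmark model.

    Single-chain models carry chain label ``A``; double-chain models split
    ``n_points`` evenly into chains ``A`` and ``B``.
    """
    p = spec.params
    n = spec.n_points
    single: dict[str, Callable[[int, dict], np.ndarray]] = {
        "circle": _circle,
        "spiral": _spiral,
        "circular_spiral": _circular_spiral,
    }
    if spec.name in single:
        coords = single[spec.name](n, p)
        chains = np.full(n, "A", dtype=object)
        return Structure(coords=coords, chains=chains)
    nA = n // 2
    nB = n - nA
    if spec.name == "replication_fork":
        a, b = _fork_chain(nA, p, +1.0), _fork_chain(nB, p, -1.0)
    elif spec.name == "double_helix":
        a, b = _helix_chain(nA, p, 0.0), _helix_chain(nB, p, np.pi)
    else:
        a, b = _spherical_helix_chain(nA, p, 0.0), _spherical_helix_chain(nB, p, np.pi)
    coords = np.vstack([a, b])
    chains = np.array(["A"] * nA + ["B"] * nB, dtype=object)
    return Structure(coords=coords, chains=chains)


def structure_distances(S: Structure) -> DistanceMatrix:
    """All-pairs Euclidean distances of a structure (alpha bookkeeping = 1)."""
    D = squareform(pdist(S.coords))
    if D[~np.eye(S.n_bins, dtype=bool)].min() <= 1e-12:
        raise DegenerateStructureError("structure contains coincident points")
    np.fill_diagonal(D, np.inf)
    return DistanceMatrix(D=D, alpha_used=1.0)


def contacts_from_structure(S: Structure) -> ContactMatrix:
    """Reciprocal-distance contacts: F_ij = 1 / |P_i - P_j|, diagonal 0."""
    D = structure_distances(S)
    with np.errstate(divide="ignore"):
        F = np.where(np.isfinite(D.D), 1.0 / D.D, 0.0)
    np.fill_diagonal(F, 0.0)
    return ContactMatrix(F=F, chain_label="+".join(S.chain_names()))


def add_noise(D: DistanceMatrix, noise: NoiseSpec) -> DistanceMatrix:
    """Multiply each finite distance by (1 + r*s), one r ~ U[-1, 1] per pair.

    Symmetry is preserved by drawing per unordered pair; results are floored
    at 1e-9 of the original value; infinite entries pass through untouched.
    """
    rng = np.random.default_rng(noise.seed)
    n = D.n_bins
    iu = np.triu_indices(n, 1)
    r = rng.uniform(-1.0, 1.0, size=len(iu[0]))
    out = D.D.copy()
    orig = D.D[iu]
    finite = np.isfinite(orig)
    scaled = np.where(finite, orig * (1.0 + r * noise.s), orig)
    scaled = np.where(finite, np.maximum(scaled, 1e-9 * orig), scaled)
    out[iu] = scaled
    out[(iu[1], iu[0])] = scaled
    return DistanceMatrix(D=out, alpha_used=D.alpha_used)


def noisy_contacts(spec: ModelSpec, noise: NoiseSpec) -> tuple[Structure, ContactMatrix]:
    """Ground truth plus its noisy contact matrix.

    Pipeline: generate the model, perturb pairwise distances, then set
    frequencies to reciprocal noisy distance — noise enters *before* the
    distance-to-frequency transformation.
    """
    S = generate_model(spec)
    D = structure_distances(S)
    Dn = add_noise(D, noise)
    with np.errstate(divide="ignore"):
        F = np.where(np.isfinite(Dn.D), 1.0 / Dn.D, 0.0)
    np.fill_diagonal(F, 0.0)
    return S, ContactMatrix(F=F, chain_label="+".join(S.chain_names()))
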