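"""Reading/writing contact matrices and structures.

File dialects are deliberately plain text:

* dense matrix — an N x N whitespace/tab-separated numeric grid;
* sparse triplet — lines ``i<TAB>j<TAB>value`` with 0-based bin indices,
  unlisted pairs are zero, duplicates are summed;
* multi-chromosome manifest — a small key-value file (see
  :func:`read_manifest`) naming per-chain intra matrices and pairwise
  inter matrices;
* structure — TSV with columns ``chain  bin  x  y  z`` (NaN rows mark bins
  dropped for having no contacts) or a minimal PDB with one pseudo-atom per
  bin and one chain ID per chromosome.

Frequencies are converted to target distances with the power law
``D_ij = F_ij**(-alpha)`` (``inf`` where ``F_ij = 0``); alpha defaults to
0.5 for real Hi-C data, while simulated inputs built from reciprocal
distances invert exactly at alpha = 1.
"""
from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._types import BinIndexMap, ContactMatrix, DistanceMatrix, Structure
from .errors import (
    FormatError,
    ParameterError,
    UnrecoverableInputError,
    ValidationError,
)

__all__ = [
    "ContactMatrix",
    "DistanceMatrix",
    "BinIndexMap",
    "MultiChromManifest",
    "read_dense_matrix",
    "write_dense_matrix",
    "read_sparse_triplet",
    "write_sparse_triplet",
    "read_manifest",
    "write_manifest",
    "assemble_multichrom",
    "freq_to_dist",
    "drop_isolated_bins",
    "write_structure",
    "read_structure_tsv",
]

_ASYM_TOL = 1e-9


def _load_grid(path: str | Path) -> np.ndarray:
    try:
        M = np.loadtxt(path, dtype=float, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: not a numeric grid ({exc})") from exc
    return M


def read_dense_matrix(path: str | Path, chain_label: str = "chr") -> ContactMatrix:
    """Read an N x N whitespace-separated frequency grid.

    Inputs asymmetric beyond 1e-9 are symmetrized by averaging with a
    warning (raw Hi-C dumps often carry float asymmetry); negative entries
    are rejected.
    """
    M = _load_grid(path)
    if M.shape[0] != M.shape[1]:
        raise FormatError(f"{path}: expected a square grid, got {M.shape[0]}x{M.shape[1]}")
    if np.any(M < 0):
        raise ValidationError(f"{path}: negative interaction frequencies")
    if not np.allclose(M, M.T, rtol=0, atol=_ASYM_TOL):
        warnings.warn(f"{path}: asymmetric input symmetrized by averaging", stacklevel=2)
    M = (M + M.T) / 2.0
    return ContactMatrix(F=M, chain_label=chain_label)


def write_dense_matrix(M: np.ndarray | ContactMatrix, path: str | Path) -> None:
    """Write a dense matrix as a tab-separated grid (the input dialect)."""
    A = M.F if isinstance(M, ContactMatrix) else np.asarray(M, dtype=float)
    np.savetxt(path, A, delimiter="\t", fmt="%.17g")


def read_sparse_triplet(path: str | Path, n_bins: int, chain_label: str = "chr") -> ContactMatrix:
    """Read ``i j value`` triplet lines into a dense symmetric matrix.

    Duplicate pairs (in either orientation) are summed; unlisted pairs are 0.
    """
    if n_bins < 1:
        raise ParameterError("n_bins must be positive")
    F = np.zeros((n_bins, n_bins))
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 'i j value', got {line!r}")
            try:
                i, j, v = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if not (0 <= i < n_bins and 0 <= j < n_bins):
                raise FormatError(
                    f"{path}:{lineno}: bin index out of range for n_bins={n_bins}"
                )
            if v < 0:
                raise ValidationError(f"{path}:{lineno}: negative frequency {v}")
            a, b = min(i, j), max(i, j)
            F[a, b] += v
    F = F + np.triu(F, 1).T  # mirror the (canonical) upper triangle
    return ContactMatrix(F=F, chain_label=chain_label)


def write_sparse_triplet(M: ContactMatrix, path: str | Path) -> None:
    """Write the non-zero upper triangle as triplet lines (pairs with F = 0 omitted)."""
    iu = np.triu_indices(M.n_bins, 1)
    with open(path, "w") as fh:
        for i, j in zip(*iu):
            v = M.F[i, j]
            if v > 0:
                fh.write(f"{i}\t{j}\t{v:.10g}\n")


@dataclass
class MultiChromManifest:
    """Chain names/sizes plus file references for intra- and inter-chain matrices.

    ``inter`` keys are (first, second) chain-name tuples in file order: the
    referenced matrix has rows for the first chain and columns for the second.
    Missing pairs mean a zero inter block (no observed trans contacts).
    """

    chains: list[tuple[str, int]]
    intra: dict[str, Path]
    inter: dict[tuple[str, str], Path] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chains]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate chain names in manifest")
        for name, n in self.chains:
            if n < 1:
                raise ValidationError(f"chain {name}: non-positive bin count")
            if name not in self.intra:
                raise ValidationError(f"chain {name}: missing intra matrix entry")
        for a, b in self.inter:
            if a not in names or b not in names or a == b:
                raise ValidationError(f"inter entry ({a},{b}) does not name two distinct chains")


def read_manifest(path: str | Path) -> MultiChromManifest:
    """Parse a manifest file.

    Format (paths resolved relative to the manifest's directory)::

        # comment
        chain  <name>  <n_bins>  <intra_matrix_file>
        inter  <name1> <name2>   <inter_matrix_file>
    """
    path = Path(path)
    chains: list[tuple[str, int]] = []
    intra: dict[str, Path] = {}
    inter: dict[tuple[str, str], Path] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            kind = parts[0].lower()
            if kind == "chain" and len(parts) == 4:
                try:
                    n = int(parts[2])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad bin count {parts[2]!r}") from exc
                chains.append((parts[1], n))
                intra[parts[1]] = path.parent / parts[3]
            elif kind == "inter" and len(parts) == 4:
                inter[(parts[1], parts[2])] = path.parent / parts[3]
            else:
                raise FormatError(f"{path}:{lineno}: unrecognized manifest line {line!r}")
    if not chains:
        raise FormatError(f"{path}: manifest declares no chains")
    return MultiChromManifest(chains=chains, intra=intra, inter=inter)


def write_manifest(manifest: MultiChromManifest, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# evrc multi-chromosome manifest\n")
        for name, n in manifest.chains:
            rel = Path(manifest.intra[name]).name
            fh.write(f"chain\t{name}\t{n}\t{rel}\n")
        for (a, b), p in manifest.inter.items():
            fh.write(f"inter\t{a}\t{b}\t{Path(p).name}\n")


def assemble_multichrom(manifest: MultiChromManifest) -> tuple[ContactMatrix, BinIndexMap]:
    """Assemble per-chain blocks into one global symmetric contact matrix.

    Intra matrices become diagonal blocks; each inter matrix fills the
    (first, second) off-diagonal block with its transpose mirrored into the
    lower triangle.
    """
    sizes = dict(manifest.chains)
    order = [name for name, _ in manifest.chains]
    offs: dict[str, int] = {}
    total = 0
    for name in order:
        offs[name] = total
        total += sizes[name]
    G = np.zeros((total, total))
    for name in order:
        C = read_dense_matrix(manifest.intra[name], chain_label=name)
        if C.n_bins != sizes[name]:
            raise ValidationError(
                f"chain {name}: intra matrix is {C.n_bins} bins, manifest says {sizes[name]}"
            )
        o = offs[name]
        G[o : o + sizes[name], o : o + sizes[name]] = C.F
    for (a, b), p in manifest.inter.items():
        M = _load_grid(p)
        if M.shape != (sizes[a], sizes[b]):
            raise ValidationError(
                f"inter block ({a},{b}): shape {M.shape} does not match chain sizes "
                f"({sizes[a]}, {sizes[b]})"
            )
        if np.any(M < 0):
            raise ValidationError(f"inter block ({a},{b}): negative frequencies")
        oa, ob = offs[a], offs[b]
        G[oa : oa + sizes[a], ob : ob + sizes[b]] = M
        G[ob : ob + sizes[b], oa : oa + sizes[a]] = M.T
    kept = []
    g = 0
    for name in order:
        for local in range(sizes[name]):
            kept.append((name, local, g))
            g += 1
    label = "+".join(order)
    return ContactMatrix(F=G, chain_label=label), BinIndexMap(kept=kept)


def freq_to_dist(C: ContactMatrix, alpha: float = 0.5) -> DistanceMatrix:
    """Convert frequencies to target distances: ``D = F**(-alpha)``, inf where F = 0."""
    if not alpha > 0:
        raise ParameterError(f"alpha must be positive, got {alpha}")
    with np.errstate(divide="ignore"):
        D = np.where(C.F > 0, C.F ** (-float(alpha)), np.inf)
    np.fill_diagonal(D, np.inf)  # diagonal carries no constraint
    return DistanceMatrix(D=D, alpha_used=float(alpha))


def drop_isolated_bins(
    D: DistanceMatrix, index_map: BinIndexMap | None = None, chain_label: str = "chr"
) -> tuple[DistanceMatrix, BinIndexMap]:
    """Remove bins whose entire off-diagonal row is inf (no usable constraint).

    The returned map records original (chain, local bin) labels for both kept
    and dropped bins so output coordinates can be reported against the
    original numbering with dropped bins flagged as NaN.
    """
    n = D.n_bins
    if index_map is None:
        index_map = BinIndexMap.identity(n, chain=chain_label)
    if index_map.n_kept != n:
        raise ValidationError("index map size does not match matrix")
    has_contact = D.finite_mask().any(axis=1)
    if not has_contact.any():
        raise UnrecoverableInputError("every bin is isolated: no finite distances at all")
    keep_idx = np.flatnonzero(has_contact)
    sub = DistanceMatrix(D=D.D[np.ix_(keep_idx, keep_idx)], alpha_used=D.alpha_used)
    kept = [
        (index_map.kept[old][0], index_map.kept[old][1], new)
        for new, old in enumerate(keep_idx)
    ]
    dropped = list(index_map.dropped) + [
        (index_map.kept[old][0], index_map.kept[old][1])
        for old in np.flatnonzero(~has_contact)
    ]
    return sub, BinIndexMap(kept=kept, dropped=dropped)


def _structure_table(S: Structure) -> pd.DataFrame:
    """Rows in original bin order (chains in structure order), NaN rows for dropped bins."""
    imap = S.index_map
    by_chain: dict[str, list[tuple[int, int | None]]] = {}
    for chain, local, g in imap.kept:
        by_chain.setdefault(chain, []).append((local, g))
    for chain, local in imap.dropped:
        by_chain.setdefault(chain, []).append((local, None))
    rows = []
    for chain, entries in by_chain.items():
        for local, g in sorted(entries):
            if g is None:
                rows.append((chain, local, np.nan, np.nan, np.nan))
            else:
                x, y, z = S.coords[g]
                rows.append((chain, local, x, y, z))
    return pd.DataFrame(rows, columns=["chain", "bin", "x", "y", "z"])


def _write_pdb(S: Structure, path: str | Path) -> None:
    # One CA pseudo-atom per bin, one chain ID per chromosome; coordinates
    # uniformly rescaled so they always fit the fixed-width %8.3f columns.
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    coords = S.coords
    max_abs = float(np.abs(coords).max())
    scale = 99.0 / max_abs if max_abs > 0 else 1.0
    chain_ids = {name: string.ascii_uppercase[i % 26] for i, name in enumerate(S.chain_names())}
    n = S.n_bins
    atoms = struc.AtomArray(n)
    atoms.coord = coords * scale
    atoms.chain_id = np.array([chain_ids[str(c)] for c in S.chains])
    atoms.res_id = np.concatenate(
        [np.arange(1, int(np.sum(np.asarray(S.chains, dtype=object) == c)) + 1)
         for c in S.chain_names()]
    )
    atoms.res_name = np.full(n, "BIN")
    atoms.atom_name = np.full(n, "CA")
    atoms.element = np.full(n, "C")
    atoms.hetero = np.full(n, True)
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def write_structure(S: Structure, path: str | Path, format: str = "tsv") -> None:
    """Write a structure as TSV (``chain bin x y z``) or minimal PDB."""
    if format == "tsv":
        _structure_table(S).to_csv(path, sep="\t", index=False, float_format="%.17g")
    elif format == "pdb":
        _write_pdb(S, path)
    else:
        raise ParameterError(f"unknown structure format {format!r}")


def read_structure_tsv(path: str | Path) -> Structure:
    """Read a structure TSV written by :func:`write_structure` (NaN rows → dropped)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"chain", "bin", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: structure TSV needs columns {sorted(required)}")
    ok = df[["x", "y", "z"]].notna().all(axis=1)
    kept_rows = df[ok]
    coords = kept_rows[["x", "y", "z"]].to_numpy(dtype=float)
    chains = kept_rows["chain"].astype(str).to_numpy(dtype=object)
    kept = [
        (str(c), int(b), g)
        for g, (c, b) in enumerate(zip(kept_rows["chain"], kept_rows["bin"]))
    ]
    dropped = [(str(c), int(b)) for c, b in zip(df.loc[~ok, "chain"], df.loc[~ok, "bin"])]
    return Structure(coords=coords, chains=chains, index_map=BinIndexMap(kept, dropped))
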