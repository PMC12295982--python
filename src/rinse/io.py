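"""Ingestion of per-frame pairwise interaction-energy tables.

Residue interaction networks are built from pairwise nonbonded energy
decompositions of an MD trajectory: for every sampled frame, a symmetric
residue-by-residue matrix of interaction energies (electrostatic and van der
Waals, kcal/mol).  This module reads those tables, aggregates atom-resolution
matrices to residue resolution, strips excluded residues, and subsamples
frames, producing the :class:`ConstructEnsemble` containers consumed by the
rest of the pipeline.

Two plain-text dialects are supported:

``long``
    rows of ``frame res_i res_j E_elec E_vdw``, whitespace- or
    comma-delimited, optional header line;

``matrix``
    one square matrix per frame, frames concatenated in a single stream and
    separated by ``# frame <id>`` comment lines.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ResidueIndexMap",
    "InteractionFrame",
    "ConstructEnsemble",
    "sample_frames",
    "read_energy_table",
    "write_energy_table",
    "aggregate_atoms_to_residues",
    "strip_residues",
]

#: tolerance (kcal/mol) beyond which an (i,j)/(j,i) duplicate pair triggers a warning
ASYMMETRY_TOL = 1e-6


class EnergyTableParseError(ValueError):
    """Raised when an input table cannot be interpreted."""


def _check_symmetric(m: np.ndarray, tol: float = 1e-8) -> None:
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"matrix must be square, got shape {m.shape}")
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix contains non-finite entries")
    if not np.allclose(m, m.T, atol=tol, rtol=0):
        raise ValueError("matrix is not symmetric within tolerance")


@dataclass(frozen=True)
class ResidueIndexMap:
    """Author-numbered residue labels and their dense 0-based indexing.

    Parameters
    ----------
    labels : sequence of int
        Residue identifiers in author numbering (e.g. 96..290 for the p53
        DNA-binding domain), strictly increasing, after any exclusion.
    excluded : frozenset of int
        Residue identifiers removed before analysis (e.g. {182, 220}: the
        PK11000-modified C182 and the mutation site itself).
    """

    labels: tuple[int, ...]
    excluded: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        labels = tuple(int(x) for x in self.labels)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "excluded", frozenset(int(x) for x in self.excluded))
        if any(b <= a for a, b in zip(labels, labels[1:])):
            raise ValueError("residue labels must be strictly increasing")
        if set(labels) & self.excluded:
            raise ValueError("excluded residues still present in labels")

    @classmethod
    def from_range(
        cls, start: int, stop: int, excluded: Iterable[int] = ()
    ) -> "ResidueIndexMap":
        """Inclusive author-numbered range ``start..stop`` minus ``excluded``."""
        excluded = frozenset(int(x) for x in excluded)
        bad = excluded - set(range(start, stop + 1))
        if bad:
            raise ValueError(f"excluded residues {sorted(bad)} outside {start}..{stop}")
        labels = tuple(r for r in range(start, stop + 1) if r not in excluded)
        return cls(labels, excluded)

    @property
    def size(self) -> int:
        return len(self.labels)

    def index_of(self, label: int) -> int:
        """Dense 0-based index of an author-numbered residue."""
        try:
            return self._lookup[label]
        except AttributeError:
            object.__setattr__(
                self, "_lookup", {lab: i for i, lab in enumerate(self.labels)}
            )
            return self._lookup[label]
        except KeyError:
            raise KeyError(f"residue label {label} not in index map") from None


def default_index_map() -> ResidueIndexMap:
    """p53-DBD default: residues 96-290 with C182/C220 stripped (193 nodes)."""
    return ResidueIndexMap.from_range(96, 290, excluded=(182, 220))


@dataclass
class InteractionFrame:
    """One sampled frame's symmetric residue-pair energy matrices (kcal/mol)."""

    frame_id: int
    elec: np.ndarray
    vdw: np.ndarray | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.elec = np.asarray(self.elec, dtype=float)
        _check_symmetric(self.elec)
        if np.any(np.diag(self.elec) != 0):
            raise ValueError("interaction matrix must have a zero diagonal")
        if self.vdw is not None:
            self.vdw = np.asarray(self.vdw, dtype=float)
            _check_symmetric(self.vdw)
            if self.vdw.shape != self.elec.shape:
                raise ValueError("elec/vdw shape mismatch")

    @property
    def size(self) -> int:
        return self.elec.shape[0]


@dataclass
class ConstructEnsemble:
    """Ordered interaction frames for one labelled construct (WT, Y220C-22, ...)."""

    label: str
    frames: list[InteractionFrame]
    index_map: ResidueIndexMap
    #: global normalization constant applied to edge weights (1.0 if raw)
    scale: float = 1.0

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("ensemble needs at least one frame")
        n = self.index_map.size
        for f in self.frames:
            if f.size != n:
                raise ValueError(
                    f"frame {f.frame_id} has size {f.size}, index map has {n}"
                )
        ids = [f.frame_id for f in self.frames]
        if any(b <= a for a, b in zip(ids, ids[1:])):
            raise ValueError("frame_ids must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def normalized(self) -> bool:
        return all(f.normalized for f in self.frames)

    def stack(self, channel: str = "elec") -> np.ndarray:
        """Frames as a (T, n, n) array for the requested energy channel."""
        if channel == "elec":
            return np.stack([f.elec for f in self.frames])
        if channel == "vdw":
            if any(f.vdw is None for f in self.frames):
                raise ValueError("ensemble has no van der Waals channel")
            return np.stack([f.vdw for f in self.frames])
        raise ValueError(f"unknown channel {channel!r}")


def sample_frames(n_total: int, stride: int = 66, offset: int = 0) -> list[int]:
    """Regular trajectory subsampling: indices ``offset, offset+stride, ...``.

    With the production defaults (10,000-frame, 1 microsecond trajectory,
    stride 66) this yields 152 frames.

    Returns ``ceil((n_total - offset) / stride)`` indices.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if stride < 1 or stride > n_total:
        raise ValueError(f"stride must be in 1..{n_total}, got {stride}")
    if not (0 <= offset < stride):
        raise ValueError(f"offset must be in 0..{stride - 1}, got {offset}")
    idx = list(range(offset, n_total, stride))
    assert len(idx) == math.ceil((n_total - offset) / stride)
    return idx


def aggregate_atoms_to_residues(
    atom_matrix: np.ndarray, atom_to_res: Sequence[int] | dict[int, int]
) -> np.ndarray:
    """Sum an atom-resolution energy matrix into residue resolution.

    ``atom_to_res`` maps each atom index (0-based row of ``atom_matrix``) to a
    dense 0-based residue index.  Off-diagonal residue entry (R, S) is the sum
    of all atom-pair energies with one atom in R and the other in S; the
    diagonal (intra-residue energy) is forced to zero.
    """
    atom_matrix = np.asarray(atom_matrix, dtype=float)
    _check_symmetric(atom_matrix)
    n_atoms = atom_matrix.shape[0]
    if isinstance(atom_to_res, dict):
        missing = [a for a in range(n_atoms) if a not in atom_to_res]
        if missing:
            raise ValueError(f"unmapped atom index {missing[0]}")
        mapping = np.array([atom_to_res[a] for a in range(n_atoms)], dtype=int)
    else:
        mapping = np.asarray(atom_to_res, dtype=int)
        if mapping.shape != (n_atoms,):
            raise ValueError(
                f"atom_to_res must map all {n_atoms} atoms, got {mapping.shape}"
            )
    n_res = int(mapping.max()) + 1
    # residue indicator matrix: S[a, r] = 1 iff atom a belongs to residue r
    S = np.zeros((n_atoms, n_res))
    S[np.arange(n_atoms), mapping] = 1.0
    res = S.T @ atom_matrix @ S
    np.fill_diagonal(res, 0.0)
    return 0.5 * (res + res.T)  # exact symmetry against float round-off


def strip_residues(
    ensemble: ConstructEnsemble, excluded: Iterable[int]
) -> ConstructEnsemble:
    """Remove residues (author numbering) from every frame of an ensemble."""
    excluded = set(int(x) for x in excluded)
    if not excluded:
        return ensemble
    present = set(ensemble.index_map.labels)
    absent = excluded - present
    if absent:
        raise ValueError(f"residues {sorted(absent)} not present in ensemble")
    keep = [i for i, lab in enumerate(ensemble.index_map.labels) if lab not in excluded]
    keep_idx = np.asarray(keep, dtype=int)
    new_map = ResidueIndexMap(
        tuple(ensemble.index_map.labels[i] for i in keep),
        ensemble.index_map.excluded | frozenset(excluded),
    )
    new_frames = [
        InteractionFrame(
            f.frame_id,
            f.elec[np.ix_(keep_idx, keep_idx)],
            None if f.vdw is None else f.vdw[np.ix_(keep_idx, keep_idx)],
            f.normalized,
        )
        for f in ensemble.frames
    ]
    return ConstructEnsemble(ensemble.label, new_frames, new_map, ensemble.scale)


# ---------------------------------------------------------------------------
# plain-text dialects


def _split_row(line: str) -> list[str]:
    return line.replace(",", " ").split()


def read_energy_table(
    path: str | Path,
    dialect: str = "long",
    index_map: ResidueIndexMap | None = None,
    label: str = "construct",
) -> ConstructEnsemble:
    """Read a per-frame pairwise energy table into a :class:`ConstructEnsemble`.

    Missing pairs are zero.  If a file lists both (i, j) and (j, i) with
    values differing by more than ``ASYMMETRY_TOL`` the two are averaged and a
    warning is issued.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "long":
        return _read_long(path, index_map, label)
    if dialect == "matrix":
        return _read_matrix(path, index_map, label)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_long(
    path: Path, index_map: ResidueIndexMap | None, label: str
) -> ConstructEnsemble:
    rows: list[tuple[int, int, int, float, float]] = []
    labels_seen: set[int] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = _split_row(line)
            if lineno == 1 and not parts[0].lstrip("+-").isdigit():
                continue  # header
            if len(parts) not in (4, 5):
                raise EnergyTableParseError(
                    f"{path}:{lineno}: expected 4-5 columns, got {len(parts)}"
                )
            try:
                f, i, j = int(parts[0]), int(parts[1]), int(parts[2])
                e = float(parts[3])
                v = float(parts[4]) if len(parts) == 5 else 0.0
            except ValueError as exc:
                raise EnergyTableParseError(f"{path}:{lineno}: {exc}") from None
            if index_map is not None:
                for lab in (i, j):
                    if lab not in index_map._labels_set():
                        raise EnergyTableParseError(
                            f"{path}:{lineno}: unknown residue label {lab}"
                        )
            labels_seen.update((i, j))
            rows.append((f, i, j, e, v))
    if not rows:
        raise EnergyTableParseError(f"{path}: no data rows")
    if index_map is None:
        index_map = ResidueIndexMap(tuple(sorted(labels_seen)))
    n = index_map.size
    frames: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for f, i, j, e, v in rows:
        if f not in frames:
            frames[f] = (np.zeros((n, n)), np.zeros((n, n)), np.zeros((n, n), dtype=int))
        elec, vdw, count = frames[f]
        a, b = index_map.index_of(i), index_map.index_of(j)
        if a == b:
            continue  # self-energies are not edges
        if count[a, b] or count[b, a]:
            prev = elec[a, b] / max(count[a, b] + count[b, a], 1)
            if abs(prev - e) > ASYMMETRY_TOL:
                warnings.warn(
                    f"{path}: asymmetric duplicate for frame {f} pair "
                    f"({i},{j}): {prev:g} vs {e:g}; averaging",
                    stacklevel=3,
                )
        elec[a, b] += e
        elec[b, a] += e
        vdw[a, b] += v
        vdw[b, a] += v
        count[a, b] += 1
        count[b, a] += 1
    out = []
    for fid in sorted(frames):
        elec, vdw, count = frames[fid]
        cnt = np.maximum(count, 1)
        out.append(InteractionFrame(fid, elec / cnt, vdw / cnt))
    return ConstructEnsemble(label, out, index_map)


def _read_matrix(
    path: Path, index_map: ResidueIndexMap | None, label: str
) -> ConstructEnsemble:
    frames: list[InteractionFrame] = []
    current: list[list[float]] = []
    fid: int | None = None
    n_expect = index_map.size if index_map is not None else None

    def flush() -> None:
        nonlocal current, fid
        if fid is None:
            return
        m = np.asarray(current, dtype=float)
        if n_expect is not None and m.shape != (n_expect, n_expect):
            raise EnergyTableParseError(
                f"{path}: frame {fid} has shape {m.shape}, expected square {n_expect}"
            )
        m = 0.5 * (m + m.T)
        np.fill_diagonal(m, 0.0)
        frames.append(InteractionFrame(fid, m))
        current = []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("# frame"):
                flush()
                fid = int(line.split()[-1])
            elif line:
                current.append([float(x) for x in _split_row(line)])
    flush()
    if not frames:
        raise EnergyTableParseError(f"{path}: no frames found")
    if index_map is None:
        n = frames[0].size
        index_map = ResidueIndexMap(tuple(range(n)))
    return ConstructEnsemble(label, frames, index_map)


def write_energy_table(
    ensemble: ConstructEnsemble, path: str | Path, dialect: str = "long"
) -> None:
    """Write an ensemble in one of the plain-text dialects (round-trip safe)."""
    path = Path(path)
    if dialect == "long":
        with open(path, "w") as fh:
            fh.write("frame res_i res_j elec vdw\n")
            labels = ensemble.index_map.labels
            for f in ensemble.frames:
                vdw = f.vdw if f.vdw is not None else np.zeros_like(f.elec)
                ii, jj = np.nonzero(np.triu(np.abs(f.elec) + np.abs(vdw), k=1))
                for a, b in zip(ii, jj):
                    fh.write(
                        f"{f.frame_id} {labels[a]} {labels[b]} "
                        f"{float(f.elec[a, b])!r} {float(vdw[a, b])!r}\n"
                    )
    elif dialect == "matrix":
        with open(path, "w") as fh:
            for f in ensemble.frames:
                fh.write(f"# frame {f.frame_id}\n")
                for row in f.elec:
                    fh.write(" ".join(repr(float(x)) for x in row) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _labels_set(self: ResidueIndexMap) -> set:
    try:
        return self._labels_cache
    except AttributeError:
        object.__setattr__(self, "_labels_cache", set(self.labels))
        return self._labels_cache


ResidueIndexMap._labels_set = _labels_set
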