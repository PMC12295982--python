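"""Projection of frame heat kernels into a shared 3-component latent space.

The mean kernel of a construct (conventionally the wild type, so all
constructs share one geometry) is eigendecomposed; its three leading
eigenvectors (PC1-PC3) span the latent space.  Every frame kernel's rows,
centered by the corresponding rows of the mean kernel, are projected onto
that basis, giving each residue one 3-vector per frame — for the p53-DBD
system, 193 residues x 152 frames = 29,336 embedded points per construct.

Residues whose kernel connectivity along PC1 is high act as hubs of the
energetic network; low-connectivity residues are peripheral.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ResidueIndexMap
from .kernel import HeatKernel, MeanKernel, _sign_normalize

__all__ = [
    "PCBasis",
    "EmbeddingCloud",
    "HubClassification",
    "pca_basis",
    "project_frames",
    "classify_hubs",
    "HUB_THRESHOLD",
    "PERIPHERAL_THRESHOLD",
]

#: default PC1 connectivity cutoff at/above which a residue is hub-like
HUB_THRESHOLD = 0.0105
#: default cutoff at/below which a residue is peripheral
PERIPHERAL_THRESHOLD = 0.0095


@dataclass
class PCBasis:
    """Leading-k orthonormal eigenvectors of a mean kernel (columns)."""

    vectors: np.ndarray  # (n, k)
    eigenvalues: np.ndarray  # descending, length k
    source: str = ""

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.vectors.ndim != 2:
            raise ValueError("basis vectors must be a 2-D column matrix")
        g = self.vectors.T @ self.vectors
        if not np.allclose(g, np.eye(self.vectors.shape[1]), atol=1e-8):
            raise ValueError("basis columns must be orthonormal")
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("basis eigenvalues must be descending")

    @property
    def n_components(self) -> int:
        return self.vectors.shape[1]


@dataclass
class EmbeddingCloud:
    """Per-residue, per-frame latent coordinates: shape (n_residues, T, k)."""

    coords: np.ndarray
    construct: str
    index_map: ResidueIndexMap
    centered: bool = True
    basis_source: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3:
            raise ValueError("coords must have shape (n_residues, T, k)")
        if self.coords.shape[0] != self.index_map.size:
            raise ValueError("coords/index_map residue count mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")

    @property
    def n_points(self) -> int:
        """Total embedded points = n_residues x T."""
        return self.coords.shape[0] * self.coords.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: construct, residue, frame, pc1..pck."""
        n, t, k = self.coords.shape
        labels = np.repeat(self.index_map.labels, t)
        frames = np.tile(np.arange(t), n)
        data = {
            "construct": self.construct,
            "residue": labels,
            "frame": frames,
        }
        flat = self.coords.reshape(n * t, k)
        for j in range(k):
            data[f"pc{j + 1}"] = flat[:, j]
        return pd.DataFrame(data)


@dataclass
class HubClassification:
    """Residues partitioned by PC1 kernel connectivity."""

    hubs: tuple[int, ...]
    peripherals: tuple[int, ...]
    statistic: dict[int, float] = field(default_factory=dict, repr=False)
    hub_threshold: float = HUB_THRESHOLD
    peripheral_threshold: float = PERIPHERAL_THRESHOLD


def pca_basis(mean: MeanKernel | np.ndarray, k: int = 3, source: str = "") -> PCBasis:
    """Top-k eigenvectors of a (mean) kernel matrix, sign-normalized.

    The kernel is symmetric PSD, so its eigenvectors are the principal axes
    of the kernel rows; degenerate eigenvalues are resolved deterministically
    by ascending-solver index order plus the largest-|component|-positive
    sign convention.
    """
    m = mean.matrix if isinstance(mean, MeanKernel) else np.asarray(mean, float)
    if k > m.shape[0]:
        raise ValueError(f"k={k} exceeds matrix size {m.shape[0]}")
    lam, phi = np.linalg.eigh(m)
    order = np.argsort(lam, kind="stable")[::-1][:k]
    return PCBasis(_sign_normalize(phi[:, order]), lam[order], source)


def project_frames(
    kernels: list[HeatKernel],
    basis: PCBasis,
    mean: MeanKernel | np.ndarray | None = None,
    center: bool = True,
    construct: str = "",
    index_map: ResidueIndexMap | None = None,
) -> EmbeddingCloud:
    """Project every frame kernel's rows onto the latent basis.

    ``coords[i, f, :] = basis^T (h_t^f[i, :] - mean[i, :])`` when ``center``
    is true; without centering the raw kernel rows are projected.
    """
    if not kernels:
        raise ValueError("need at least one kernel")
    n = kernels[0].matrix.shape[0]
    if basis.vectors.shape[0] != n:
        raise ValueError(
            f"basis dimension {basis.vectors.shape[0]} != kernel size {n}"
        )
    if center:
        if mean is None:
            raise ValueError("centering requires the mean kernel")
        m = mean.matrix if isinstance(mean, MeanKernel) else np.asarray(mean, float)
        if m.shape != (n, n):
            raise ValueError("mean kernel shape mismatch")
    stack = np.stack([k.matrix for k in kernels])  # (T, n, n)
    if center:
        stack = stack - m[None, :, :]
    coords = np.einsum("tij,jk->itk", stack, basis.vectors)
    if index_map is None:
        index_map = ResidueIndexMap(tuple(range(n)))
    return EmbeddingCloud(coords, construct, index_map, center, basis.source)


def classify_hubs(
    source: EmbeddingCloud | MeanKernel | np.ndarray,
    basis: PCBasis | None = None,
    hub_threshold: float = HUB_THRESHOLD,
    peripheral_threshold: float = PERIPHERAL_THRESHOLD,
    mode: str = "pc1",
    index_map: ResidueIndexMap | None = None,
) -> HubClassification:
    """Partition residues into hubs / peripherals by kernel connectivity.

    The per-residue statistic is, under ``mode='pc1'`` (default), the PC1
    projection of the residue's *uncentered* mean-kernel row (for an
    :class:`EmbeddingCloud` input the cloud must itself be uncentered, and
    the frame-mean PC1 coordinate is used); under ``mode='kernel'`` it is the
    residue's mean kernel row sum — raw heat-kernel connectivity.
    Residues at/above ``hub_threshold`` are hubs, at/below
    ``peripheral_threshold`` peripheral, the rest unlabeled.
    """
    if hub_threshold <= peripheral_threshold:
        raise ValueError("hub_threshold must exceed peripheral_threshold")
    if isinstance(source, EmbeddingCloud):
        if source.centered:
            raise ValueError(
                "hub statistic needs uncentered coordinates; "
                "project with center=False or pass the mean kernel"
            )
        stat = source.coords[:, :, 0].mean(axis=1)
        index_map = source.index_map
    else:
        m = source.matrix if isinstance(source, MeanKernel) else np.asarray(source, float)
        if mode == "pc1":
            if basis is None:
                basis = pca_basis(m, k=1)
            stat = m @ basis.vectors[:, 0]
        elif mode == "kernel":
            stat = m.sum(axis=1)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if index_map is None:
            index_map = ResidueIndexMap(tuple(range(m.shape[0])))
    labels = index_map.labels
    hubs = tuple(lab for lab, s in zip(labels, stat) if s >= hub_threshold)
    peris = tuple(lab for lab, s in zip(labels, stat) if s <= peripheral_threshold)
    return HubClassification(
        hubs, peris, dict(zip(labels, map(float, stat))), hub_threshold, peripheral_threshold
    )
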