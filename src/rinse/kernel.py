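"""Graph heat kernels from normalized-Laplacian spectra.

The heat kernel ``h_t = Phi exp(-t Lambda) Phi^T`` is the diffusion operator
of the network at time ``t``: entry (i, j) measures how much heat injected at
node i has reached node j, summarizing connectivity at a scale set by ``t``
(small t: local structure; large t: global, dominated by the low end of the
spectrum).  One kernel is computed per sampled trajectory frame; their
elementwise average over the T frames is the mean kernel used to define the
shared latent space.

The diffusion time is chosen by a scree/knee analysis of the kernel spectrum
``{exp(-t * lambda_i)}``: the knee is the point of maximum curvature, located
Kneedle-style as the point of maximum perpendicular distance to the chord of
the normalized scree curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .network import NormalizedLaplacian

__all__ = [
    "SpectralDecomposition",
    "HeatKernel",
    "MeanKernel",
    "spectral_decomposition",
    "heat_kernel",
    "mean_kernel",
    "knee_index",
    "select_diffusion_time",
    "DEFAULT_T",
    "DEFAULT_T_GRID",
]

#: production default diffusion parameter
DEFAULT_T = 6.0
#: default candidate grid for knee-point selection
DEFAULT_T_GRID = tuple(float(t) for t in range(1, 21))


@dataclass
class SpectralDecomposition:
    """Ascending eigenvalues and orthonormal eigenvectors of a symmetric L."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        if np.any(np.diff(self.eigenvalues) < -1e-10):
            raise ValueError("eigenvalues must be ascending")


@dataclass
class HeatKernel:
    """Symmetric PSD kernel matrix at diffusion time t."""

    matrix: np.ndarray
    t: float


@dataclass
class MeanKernel:
    """Elementwise mean of T frame kernels sharing one diffusion time."""

    matrix: np.ndarray
    t: float
    n_frames: int


def _sign_normalize(vectors: np.ndarray) -> np.ndarray:
    """Fix eigenvector signs: the largest-|component| entry is made positive."""
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def spectral_decomposition(
    laplacian: NormalizedLaplacian | np.ndarray,
) -> SpectralDecomposition:
    """Symmetric eigendecomposition with the package's sign convention."""
    L = laplacian.L if isinstance(laplacian, NormalizedLaplacian) else np.asarray(laplacian, float)
    lam, phi = np.linalg.eigh(L)
    return SpectralDecomposition(lam, _sign_normalize(phi))


def heat_kernel(decomposition: SpectralDecomposition, t: float) -> HeatKernel:
    """h_t = Phi exp(-t Lambda) Phi^T; symmetric positive semidefinite."""
    if t < 0:
        raise ValueError(f"diffusion time must be >= 0, got {t}")
    phi = decomposition.eigenvectors
    decay = np.exp(-t * decomposition.eigenvalues)
    h = (phi * decay) @ phi.T
    return HeatKernel(0.5 * (h + h.T), float(t))


def mean_kernel(kernels: list[HeatKernel]) -> MeanKernel:
    """Elementwise average of frame kernels; all must share t and shape."""
    if not kernels:
        raise ValueError("need at least one kernel")
    t = kernels[0].t
    shape = kernels[0].matrix.shape
    for k in kernels:
        if k.t != t:
            raise ValueError(f"mixed diffusion times: {k.t} vs {t}")
        if k.matrix.shape != shape:
            raise ValueError("kernel shape mismatch")
    mean = np.mean([k.matrix for k in kernels], axis=0)
    return MeanKernel(mean, t, len(kernels))


def knee_index(scree: np.ndarray, flat_tol: float = 1e-3) -> int | None:
    """Maximum-curvature index of a descending scree curve.

    Both axes are normalized to [0, 1] and the knee is the point with maximum
    perpendicular distance to the chord joining the first and last points.
    Returns ``None`` when the curve is flat or effectively linear (maximum
    chord distance below ``flat_tol``), i.e. there is no knee.
    """
    y = np.asarray(scree, dtype=float)
    if y.ndim != 1 or y.size < 3:
        return None
    span = y[0] - y[-1]
    if span <= 0:
        return None
    x = np.linspace(0.0, 1.0, y.size)
    yn = (y - y[-1]) / span
    # chord from (0, yn[0]=1) to (1, yn[-1]=0): x + y - 1 = 0
    dist = np.abs(x + yn - 1.0) / np.sqrt(2.0)
    k = int(np.argmax(dist))
    if dist[k] < flat_tol or k in (0, y.size - 1):
        return None
    return k


def select_diffusion_time(
    decomposition: SpectralDecomposition,
    t_grid: tuple[float, ...] | list[float] = DEFAULT_T_GRID,
    n_components: int = 3,
    variance_target: float = 0.90,
    default_t: float = DEFAULT_T,
) -> float:
    """Choose the diffusion time by knee-point analysis of the kernel spectrum.

    For each candidate t the kernel spectrum ``{exp(-t * lambda_i)}`` is sorted
    descending into a scree curve.  The selected t is the smallest grid value
    whose scree knee falls within the leading ``n_components`` dimensions and
    whose leading ``n_components`` capture at least ``variance_target`` of the
    total spectral mass.  Degenerate flat screes (no knee anywhere on the
    grid) fall back to ``default_t`` with a warning.
    """
    t_grid = tuple(float(t) for t in t_grid)
    if not t_grid:
        raise ValueError("t_grid must be nonempty")
    if any(b <= a for a, b in zip(t_grid, t_grid[1:])):
        raise ValueError("t_grid must be strictly ascending")
    lam = decomposition.eigenvalues
    any_knee = False
    for t in t_grid:
        scree = np.sort(np.exp(-t * lam))[::-1]
        k = knee_index(scree)
        if k is None:
            continue
        any_knee = True
        frac = scree[:n_components].sum() / scree.sum()
        if k <= n_components and frac >= variance_target:
            return t
    if not any_knee:
        warnings.warn(
            "flat spectrum: no knee found on the t grid; "
            f"falling back to default t = {default_t}",
            stacklevel=2,
        )
        return float(default_t)
    warnings.warn(
        "no candidate t met the knee/variance criterion; "
        f"falling back to default t = {default_t}",
        stacklevel=2,
    )
    return float(default_t)
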