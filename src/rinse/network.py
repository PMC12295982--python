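"""Weighted-network construction from interaction-energy frames.

Signed pairwise energies are turned into nonnegative edge weights (spectral
graph theory needs a nonnegative weight matrix), normalized to [0, 1], and
sparsified by a *local* threshold: an edge survives if it is strong relative
to the weight distribution at either of its endpoints.  A per-endpoint rule
keeps hub neighbourhoods dense while still pruning weak background edges of
peripheral residues, which a single global cutoff would either drown or
over-prune.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ThresholdConfig",
    "WeightedNetwork",
    "NormalizedLaplacian",
    "apply_sign_policy",
    "normalize_weights",
    "local_threshold",
    "normalized_laplacian",
]

SIGN_POLICIES = ("magnitude", "negative-only", "positive-only")
NORMALIZATIONS = ("global-max-abs", "per-frame-max-abs", "none")


@dataclass(frozen=True)
class ThresholdConfig:
    """Network construction settings.

    q : local quantile in [0, 1]; an edge (i, j) is kept iff its weight is at
        or above the q-quantile of the nonzero weights incident to i *or* to
        j (union rule, so the result stays symmetric).  q = 0 keeps
        everything, q = 1 keeps only per-node maxima.
    normalization : how edge weights are scaled to [0, 1].  The default,
        ``global-max-abs``, divides every frame by the single largest
        magnitude across the whole ensemble so frames stay comparable in
        time.
    sign_policy : how signed energies become nonnegative weights.
        ``magnitude`` (default) uses |E|; ``negative-only`` keeps only
        attractive (negative) energies as |E|; ``positive-only`` the reverse.
    """

    q: float = 0.9
    normalization: str = "global-max-abs"
    sign_policy: str = "magnitude"

    def __post_init__(self) -> None:
        if not 0.0 <= self.q <= 1.0:
            raise ValueError(f"q must be in [0, 1], got {self.q}")
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"normalization must be one of {NORMALIZATIONS}")
        if self.sign_policy not in SIGN_POLICIES:
            raise ValueError(f"sign_policy must be one of {SIGN_POLICIES}")


@dataclass
class WeightedNetwork:
    """Symmetric nonnegative weight matrix in [0, 1] after thresholding."""

    weights: np.ndarray
    retained_fraction: float = 1.0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T, atol=1e-12, rtol=0):
            raise ValueError("weights must be symmetric")
        if w.min() < 0 or w.max() > 1 + 1e-12:
            raise ValueError("weights must lie in [0, 1]")
        np.fill_diagonal(w, 0.0)
        self.weights = w


@dataclass
class NormalizedLaplacian:
    """L = I - D^{-1/2} W D^{-1/2}; isolated nodes carry zero rows/columns."""

    L: np.ndarray
    degrees: np.ndarray


def apply_sign_policy(energies: np.ndarray, sign_policy: str = "magnitude") -> np.ndarray:
    """Map signed interaction energies to nonnegative edge weights."""
    e = np.asarray(energies, dtype=float)
    if sign_policy == "magnitude":
        return np.abs(e)
    if sign_policy == "negative-only":
        return np.where(e < 0, -e, 0.0)
    if sign_policy == "positive-only":
        return np.where(e > 0, e, 0.0)
    raise ValueError(f"unknown sign_policy {sign_policy!r}")


def normalize_weights(
    stack: np.ndarray, config: ThresholdConfig | None = None
) -> tuple[np.ndarray, float]:
    """Normalize a (T, n, n) stack of energies to nonnegative weights in [0, 1].

    Returns ``(weights, scale)`` where ``scale`` is the normalization constant
    (the global max magnitude under the default mode; 1.0 under ``none``).
    Under ``per-frame-max-abs`` the returned scale is the largest of the
    per-frame constants, each frame having been divided by its own.
    """
    config = config or ThresholdConfig()
    w = apply_sign_policy(stack, config.sign_policy)
    if config.normalization == "none":
        if w.max() > 1 + 1e-12:
            raise ValueError("weights exceed 1 but normalization is 'none'")
        return w, 1.0
    if config.normalization == "global-max-abs":
        scale = float(w.max())
        if scale == 0.0:
            raise ValueError("all-zero ensemble: no normalization scale")
        return w / scale, scale
    # per-frame-max-abs
    maxima = w.reshape(w.shape[0], -1).max(axis=1)
    if np.any(maxima == 0.0):
        raise ValueError("a frame is all zeros: no per-frame scale")
    return w / maxima[:, None, None], float(maxima.max())


def _local_quantiles(w: np.ndarray, q: float) -> np.ndarray:
    """Per-node q-quantile of nonzero incident weights; NaN for isolated nodes."""
    masked = np.where(w > 0, w, np.nan)
    with np.errstate(all="ignore"):
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore", category=RuntimeWarning)
            return np.nanquantile(masked, q, axis=1)


def local_threshold(weights: np.ndarray, q: float) -> WeightedNetwork:
    """Sparsify a symmetric weight matrix by the per-endpoint quantile rule.

    Edge (i, j) is retained iff ``w[i, j] >= Q_i`` or ``w[i, j] >= Q_j``,
    where ``Q_i`` is the q-quantile of the nonzero weights incident to node
    i.  Isolated nodes have no defined quantile and cast no retention votes.
    Thresholding never creates edges and never breaks symmetry.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must be in [0, 1], got {q}")
    w = np.asarray(weights, dtype=float)
    if not np.allclose(w, w.T, atol=1e-12, rtol=0):
        raise ValueError("weights must be symmetric")
    if w.min() < 0:
        raise ValueError("weights must be nonnegative (apply a sign policy first)")
    n_nonzero = int(np.count_nonzero(np.triu(w, k=1)))
    if n_nonzero == 0:
        return WeightedNetwork(np.zeros_like(w), 0.0)
    thr = _local_quantiles(w, q)
    thr_safe = np.where(np.isnan(thr), np.inf, thr)
    keep = (w >= thr_safe[:, None]) | (w >= thr_safe[None, :])
    out = np.where(keep & (w > 0), w, 0.0)
    out = 0.5 * (out + out.T)  # retention rule is symmetric; guard round-off
    retained = int(np.count_nonzero(np.triu(out, k=1))) / n_nonzero
    return WeightedNetwork(out, retained)


def normalized_laplacian(network: WeightedNetwork | np.ndarray) -> NormalizedLaplacian:
    """Symmetric normalized graph Laplacian with eigenvalues in [0, 2].

    Isolated nodes (zero weighted degree) get all-zero rows and columns,
    contributing an eigenvalue 0 rather than an undefined division.
    """
    w = network.weights if isinstance(network, WeightedNetwork) else np.asarray(network, float)
    if w.min() < 0:
        raise ValueError("negative weight: apply a sign policy first")
    if not np.allclose(w, w.T, atol=1e-12, rtol=0):
        raise ValueError("weights must be symmetric")
    d = w.sum(axis=1)
    n = w.shape[0]
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
    L = -inv_sqrt[:, None] * w * inv_sqrt[None, :]
    diag = np.where(d > 0, 1.0, 0.0)
    L[np.arange(n), np.arange(n)] = diag
    L = 0.5 * (L + L.T)
    return NormalizedLaplacian(L, d)
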