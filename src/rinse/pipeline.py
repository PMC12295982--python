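"""End-to-end pipeline: frame energies -> networks -> kernels -> latent clouds.

:class:`HeatKernelEmbedding` is a scikit-learn-style transformer.  Fitting on
a reference construct (conventionally the wild type) learns the shared latent
geometry — the diffusion time, the reference mean kernel, and its three
leading eigenvectors; transforming any construct then embeds its frames into
that space, which is what makes cross-construct Wasserstein comparisons
geometrically meaningful.  A ``basis='per-construct'`` mode re-derives the
basis from each construct's own mean kernel instead.

:func:`embed_constructs` and :func:`analyze_rescue` wrap the estimator into
the full comparative workflow (EE, EED, MinEEa/MaxEEa, regional summaries).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .embedding import EmbeddingCloud, PCBasis, pca_basis, project_frames
from .io import ConstructEnsemble, ResidueIndexMap
from .kernel import (
    DEFAULT_T,
    DEFAULT_T_GRID,
    HeatKernel,
    MeanKernel,
    heat_kernel,
    mean_kernel,
    select_diffusion_time,
    spectral_decomposition,
)
from .network import ThresholdConfig, local_threshold, normalize_weights, normalized_laplacian
from .stats import (
    DEFAULT_EED_CUTOFFS,
    DEFAULT_REGIONS,
    EEDDistribution,
    EEDistribution,
    eed,
    ee_distribution,
    max_ee_analysis,
    min_ee_analysis,
    regional_summary,
)

__all__ = ["HeatKernelEmbedding", "embed_constructs", "RescueAnalysis", "analyze_rescue"]


class HeatKernelEmbedding(TransformerMixin, BaseEstimator):
    """Heat-kernel latent-space embedding of interaction-energy frame stacks.

    Parameters
    ----------
    t : float or "auto", default 6.0
        Diffusion time of the heat kernel.  ``"auto"`` selects it on the
        fitted (reference) construct by knee-point analysis of the kernel
        spectrum over ``t_grid``.
    q : float, default 0.9
        Local-threshold quantile for network sparsification.
    n_components : int, default 3
        Latent dimensions (leading mean-kernel eigenvectors).
    normalization, sign_policy : str
        Edge-weight construction; see :class:`~rinse.network.ThresholdConfig`.
        Normalization is per construct (each construct is scaled by its own
        global max magnitude) so frames stay comparable within a trajectory.
    center : bool, default True
        Center frame-kernel rows by the fitted mean kernel before projection.
    t_grid : sequence of float, optional
        Candidate grid for ``t="auto"`` (default: integers 1..20).
    variance_target : float, default 0.90
        Spectral-mass fraction the leading components must capture in auto
        selection.

    Attributes
    ----------
    t_ : float — diffusion time actually used.
    scale_ : float — normalization constant of the fitted construct.
    mean_kernel_ : MeanKernel — reference mean kernel h̄_t.
    basis_ : PCBasis — leading eigenvectors of the reference mean kernel.
    components_ : ndarray (n_components, n) — basis vectors as rows.
    index_map_ : ResidueIndexMap of the fitted construct.
    retained_fraction_ : mean fraction of edges kept by thresholding.
    """

    def __init__(
        self,
        t: float | str = DEFAULT_T,
        q: float = 0.9,
        n_components: int = 3,
        normalization: str = "global-max-abs",
        sign_policy: str = "magnitude",
        center: bool = True,
        t_grid: tuple[float, ...] | None = None,
        variance_target: float = 0.90,
        channel: str = "elec",
    ) -> None:
        self.t = t
        self.q = q
        self.n_components = n_components
        self.normalization = normalization
        self.sign_policy = sign_policy
        self.center = center
        self.t_grid = t_grid
        self.variance_target = variance_target
        self.channel = channel

    # -- internals ---------------------------------------------------------

    def _as_stack(self, X) -> tuple[np.ndarray, ResidueIndexMap, str]:
        if isinstance(X, ConstructEnsemble):
            return X.stack(self.channel), X.index_map, X.label
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 3 or arr.shape[1] != arr.shape[2]:
            raise ValueError(
                "X must be a ConstructEnsemble or a (T, n, n) array of "
                f"symmetric energy matrices, got shape {arr.shape}"
            )
        return arr, ResidueIndexMap(tuple(range(arr.shape[1]))), ""

    def _config(self) -> ThresholdConfig:
        return ThresholdConfig(self.q, self.normalization, self.sign_policy)

    def _networks(self, stack: np.ndarray) -> tuple[list[np.ndarray], float, float]:
        weights, scale = normalize_weights(stack, self._config())
        nets = [local_threshold(w, self.q) for w in weights]
        retained = float(np.mean([n.retained_fraction for n in nets]))
        return [n.weights for n in nets], scale, retained

    def _frame_kernels(self, nets: list[np.ndarray], t: float) -> list[HeatKernel]:
        return [
            heat_kernel(spectral_decomposition(normalized_laplacian(w)), t)
            for w in nets
        ]

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y=None) -> "HeatKernelEmbedding":
        """Learn the shared latent geometry from the reference construct."""
        stack, index_map, label = self._as_stack(X)
        if not (isinstance(self.t, (int, float)) or self.t == "auto"):
            raise ValueError("t must be a nonnegative number or 'auto'")
        nets, scale, retained = self._networks(stack)
        if self.t == "auto":
            mean_net = np.mean(nets, axis=0)
            decomp = spectral_decomposition(normalized_laplacian(mean_net))
            grid = tuple(self.t_grid) if self.t_grid is not None else DEFAULT_T_GRID
            t_star = select_diffusion_time(
                decomp, grid, self.n_components, self.variance_target
            )
        else:
            t_star = float(self.t)
            if t_star < 0:
                raise ValueError("t must be >= 0")
        kernels = self._frame_kernels(nets, t_star)
        mk = mean_kernel(kernels)
        basis = pca_basis(mk, k=self.n_components, source=label or "fit")
        self.t_ = t_star
        self.scale_ = scale
        self.retained_fraction_ = retained
        self.mean_kernel_ = mk
        self.basis_ = basis
        self.components_ = basis.vectors.T
        self.eigenvalues_ = basis.eigenvalues
        self.index_map_ = index_map
        self.n_features_in_ = stack.shape[1]
        return self

    def transform_cloud(self, X) -> EmbeddingCloud:
        """Embed a construct into the fitted latent space as a cloud."""
        self._check_fitted()
        stack, index_map, label = self._as_stack(X)
        if stack.shape[1] != self.n_features_in_:
            raise ValueError(
                f"construct has {stack.shape[1]} residues, "
                f"fitted space has {self.n_features_in_}"
            )
        nets, _, _ = self._networks(stack)
        kernels = self._frame_kernels(nets, self.t_)
        return project_frames(
            kernels,
            self.basis_,
            self.mean_kernel_,
            center=self.center,
            construct=label,
            index_map=index_map,
        )

    def transform(self, X) -> np.ndarray:
        """Flat (n_residues * T, n_components) coordinate array."""
        cloud = self.transform_cloud(X)
        n, t, k = cloud.coords.shape
        return cloud.coords.reshape(n * t, k)

    def _check_fitted(self) -> None:
        if not hasattr(self, "basis_"):
            raise RuntimeError("HeatKernelEmbedding is not fitted yet")


def embed_constructs(
    ensembles: dict[str, ConstructEnsemble],
    reference: str | None = None,
    basis: str = "reference",
    **params,
) -> dict[str, EmbeddingCloud]:
    """Embed several constructs into a latent space.

    ``basis='reference'`` (default) fits one :class:`HeatKernelEmbedding` on
    the reference construct and reuses its geometry for every construct;
    ``basis='per-construct'`` fits each construct on itself (embeddings then
    live in construct-specific spaces and carry their own basis provenance).
    """
    if not ensembles:
        raise ValueError("no ensembles supplied")
    if basis == "reference":
        if reference is None:
            reference = next(iter(ensembles))
        if reference not in ensembles:
            raise KeyError(f"reference construct {reference!r} not supplied")
        est = HeatKernelEmbedding(**params).fit(ensembles[reference])
        return {name: est.transform_cloud(ens) for name, ens in ensembles.items()}
    if basis == "per-construct":
        out = {}
        for name, ens in ensembles.items():
            est = HeatKernelEmbedding(**params).fit(ens)
            out[name] = est.transform_cloud(ens)
        return out
    raise ValueError("basis must be 'reference' or 'per-construct'")


@dataclass
class RescueAnalysis:
    """Comparative statistics for a wild-type / mutant / drug-bound panel."""

    clouds: dict[str, EmbeddingCloud]
    ee_wt: dict[str, EEDistribution]  # WT vs every other construct
    ee_mut: dict[str, EEDistribution]  # unbound mutant vs every drug-bound
    eed: dict[str, EEDDistribution]  # per drug
    min_ee: pd.Series
    min_source: pd.Series
    min_prc: pd.Series
    max_ee: pd.Series | None
    max_source: pd.Series | None
    max_prc: pd.Series | None
    regional_percentages: pd.DataFrame
    regional_mean_eed: pd.DataFrame


def analyze_rescue(
    ensembles: dict[str, ConstructEnsemble],
    wt: str,
    mutant: str,
    drugs: list[str],
    regions: dict[str, tuple[int, int]] | None = None,
    cutoffs: tuple[float, ...] = DEFAULT_EED_CUTOFFS,
    basis: str = "reference",
    aggregate: str = "sum",
    **params,
) -> RescueAnalysis:
    """Full comparative workflow over a panel of constructs.

    Computes, in the shared latent space anchored on ``wt``: EE
    distributions of the wild type against the mutant and each drug-bound
    construct, EE of the unbound mutant against each drug-bound construct,
    per-drug EED, MinEEa over the wild-type comparisons, MaxEEa over the
    mutant comparisons (when >= 2 drugs), and the regional EED summary.
    """
    for name in [wt, mutant, *drugs]:
        if name not in ensembles:
            raise KeyError(f"construct {name!r} not supplied")
    clouds = embed_constructs(ensembles, reference=wt, basis=basis, **params)
    others = [mutant] + list(drugs)
    ee_wt = {c: ee_distribution(clouds[wt], clouds[c], aggregate) for c in others}
    ee_mut = {d: ee_distribution(clouds[mutant], clouds[d], aggregate) for d in drugs}
    eeds = {d: eed(ee_mut[d], ee_wt[d], drug=d) for d in drugs}
    min_ee, min_src, min_prc = min_ee_analysis([ee_wt[c] for c in others])
    if len(drugs) >= 2:
        max_ee, max_src, max_prc = max_ee_analysis([ee_mut[d] for d in drugs])
    else:
        max_ee = max_src = max_prc = None
    pct, mean_eed = regional_summary(
        list(eeds.values()), regions=regions or _regions_for(clouds[wt]), cutoffs=cutoffs
    )
    return RescueAnalysis(
        clouds, ee_wt, ee_mut, eeds, min_ee, min_src, min_prc,
        max_ee, max_src, max_prc, pct, mean_eed,
    )


def _regions_for(cloud: EmbeddingCloud) -> dict[str, tuple[int, int]]:
    """Default motif regions when they fit the residue range, else quartiles."""
    labels = cloud.index_map.labels
    lo, hi = labels[0], labels[-1]
    if all(lo <= a and b <= hi for a, b in DEFAULT_REGIONS.values()):
        return DEFAULT_REGIONS
    # fall back to four equal sequence quarters for non-p53-shaped systems
    qs = np.array_split(np.asarray(labels), 4)
    return {f"Q{i + 1}": (int(part[0]), int(part[-1])) for i, part in enumerate(qs)}
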