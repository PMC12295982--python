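"""Wasserstein embedding-error statistics between construct clouds.

A residue's embedding error (EE) between two constructs U and V is the cost
of transporting its frame-wise latent-coordinate distribution in U onto the
one in V — the first Wasserstein distance, computed per latent axis and
summed over the three components.  The EE difference (EED) for a drug-bound
mutant construct d is, per residue i,

    v_i = EE(mutant, mutant+d)_i - EE(wild-type, mutant+d)_i

so positive values mean drug binding moved the residue's network dynamics
toward the wild type, negative values toward the unbound mutant.

MinEEa / MaxEEa attribute each residue to the comparison yielding its
smallest / largest EE value, summarized as percent residue composition
(PRC).  Regional summaries tabulate, for functionally relevant sequence
motifs, the percentage of residues whose EED clears increasing cutoffs and
the per-drug mean EED.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import wasserstein_distance

from .embedding import EmbeddingCloud

__all__ = [
    "EEDistribution",
    "EEDDistribution",
    "RegionDefinition",
    "DEFAULT_REGIONS",
    "DEFAULT_EED_CUTOFFS",
    "wasserstein_1d",
    "embedding_error",
    "ee_distribution",
    "eed",
    "min_ee_analysis",
    "max_ee_analysis",
    "regional_summary",
]

#: p53-DBD loop/helix motifs implicated in DNA binding and allosteric signaling
DEFAULT_REGIONS: dict[str, tuple[int, int]] = {
    "L1": (113, 121),
    "L2": (164, 177),
    "H1": (178, 180),
    "S6-S7": (207, 213),
    "L6": (221, 230),
    "L3": (239, 252),
    "H2": (281, 290),
}

#: default EED cutoffs for regional percentage tabulation
DEFAULT_EED_CUTOFFS = (0.0002, 0.0003, 0.0004, 0.0005, 0.001, 0.002)


@dataclass(frozen=True)
class RegionDefinition:
    """A named inclusive author-numbered residue range."""

    name: str
    start: int
    stop: int

    def __post_init__(self) -> None:
        if self.stop < self.start:
            raise ValueError(f"region {self.name}: stop < start")

    def members(self, labels: tuple[int, ...]) -> list[int]:
        return [r for r in labels if self.start <= r <= self.stop]


@dataclass
class EEDistribution:
    """Per-residue EE values between constructs U and V, written U_V."""

    pair: tuple[str, str]
    values: pd.Series  # index = author residue numbers

    def __post_init__(self) -> None:
        v = self.values.astype(float)
        if not np.all(np.isfinite(v.to_numpy())):
            raise ValueError("EE values must be finite")
        if (v < 0).any():
            raise ValueError("EE values must be nonnegative")
        self.values = v

    @property
    def name(self) -> str:
        return f"{self.pair[0]}_{self.pair[1]}"


@dataclass
class EEDDistribution:
    """Signed per-residue EED values for one drug-bound construct."""

    drug: str
    values: pd.Series


def wasserstein_1d(sample_a, sample_b) -> float:
    """First Wasserstein distance between two empirical 1-D distributions.

    For equal-size samples this equals the mean absolute difference of the
    sorted values.
    """
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be nonempty")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")
    return float(wasserstein_distance(a, b))


AGGREGATIONS = ("sum", "mean", "pc1")


def _check_comparable(u: EmbeddingCloud, v: EmbeddingCloud) -> None:
    if u.coords.shape[0] != v.coords.shape[0]:
        raise ValueError("clouds cover different residue counts")
    if u.index_map.labels != v.index_map.labels:
        raise ValueError("clouds cover different residues")
    if u.basis_source != v.basis_source or u.centered != v.centered:
        raise ValueError(
            "clouds were embedded with different bases/centering; "
            "EE across bases is undefined"
        )


def embedding_error(
    cloud_u: EmbeddingCloud,
    cloud_v: EmbeddingCloud,
    residue: int,
    aggregate: str = "sum",
) -> float:
    """EE of one residue between two clouds sharing a basis.

    Per latent axis the 1-D Wasserstein distance between the residue's
    frame-coordinate samples is computed; axes are combined per
    ``aggregate`` ('sum' over the three components by default, 'mean', or
    'pc1' only).
    """
    _check_comparable(cloud_u, cloud_v)
    if aggregate not in AGGREGATIONS:
        raise ValueError(f"aggregate must be one of {AGGREGATIONS}")
    i = cloud_u.index_map.index_of(residue)
    k = cloud_u.coords.shape[2] if aggregate != "pc1" else 1
    dists = [
        wasserstein_1d(cloud_u.coords[i, :, ax], cloud_v.coords[i, :, ax])
        for ax in range(k)
    ]
    return float(np.mean(dists)) if aggregate == "mean" else float(np.sum(dists))


def ee_distribution(
    cloud_u: EmbeddingCloud, cloud_v: EmbeddingCloud, aggregate: str = "sum"
) -> EEDistribution:
    """Per-residue EE vector between two clouds, author-number-indexed."""
    _check_comparable(cloud_u, cloud_v)
    labels = cloud_u.index_map.labels
    vals = [
        embedding_error(cloud_u, cloud_v, lab, aggregate=aggregate) for lab in labels
    ]
    series = pd.Series(vals, index=list(labels), name=f"{cloud_u.construct}_{cloud_v.construct}")
    return EEDistribution((cloud_u.construct, cloud_v.construct), series)


def eed(ee_mut_drug: EEDistribution, ee_wt_drug: EEDistribution, drug: str | None = None) -> EEDDistribution:
    """EED = EE(mutant, drug-bound) - EE(wild type, drug-bound), per residue."""
    a, b = ee_mut_drug.values, ee_wt_drug.values
    if not a.index.equals(b.index):
        raise ValueError("EE distributions cover different residue sets")
    if drug is None:
        drug = ee_mut_drug.pair[1]
    return EEDDistribution(drug, (a - b).rename(drug))


def _extreme_ee_analysis(
    distributions: list[EEDistribution], which: str
) -> tuple[pd.Series, pd.Series, pd.Series]:
    if len(distributions) < 2:
        raise ValueError("need at least two EE distributions")
    index = distributions[0].values.index
    for d in distributions[1:]:
        if not d.values.index.equals(index):
            raise ValueError("EE distributions cover different residue sets")
    mat = np.column_stack([d.values.to_numpy() for d in distributions])
    pick = np.argmin(mat, axis=1) if which == "min" else np.argmax(mat, axis=1)
    # np.argmin/argmax return the first (earliest-input) index on ties
    values = mat[np.arange(mat.shape[0]), pick]
    names = [d.name for d in distributions]
    source = pd.Series([names[j] for j in pick], index=index, name="source")
    counts = pd.Series(0.0, index=names, name="prc")
    for j in pick:
        counts.iloc[j] += 1
    prc = counts / mat.shape[0] * 100.0
    return pd.Series(values, index=index, name=f"{which}_ee"), source, prc


def min_ee_analysis(
    distributions: list[EEDistribution],
) -> tuple[pd.Series, pd.Series, pd.Series]:
    """MinEEa: per-residue minimum EE, its source distribution, and the PRC.

    PRC (percent residue composition) gives, per distribution, the
    percentage of residues attributing their minimal EE to it; ties go to
    the earliest distribution in input order.  PRC sums to 100%.
    """
    return _extreme_ee_analysis(distributions, "min")


def max_ee_analysis(
    distributions: list[EEDistribution],
) -> tuple[pd.Series, pd.Series, pd.Series]:
    """MaxEEa: mirror of :func:`min_ee_analysis` with the per-residue maximum."""
    return _extreme_ee_analysis(distributions, "max")


def regional_summary(
    eed_distributions: list[EEDDistribution],
    regions: dict[str, tuple[int, int]] | list[RegionDefinition] | None = None,
    cutoffs: tuple[float, ...] = DEFAULT_EED_CUTOFFS,
    mode: str = "any",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Regional EED tabulation.

    Returns ``(percentages, mean_eed)``:

    * ``percentages`` — rows = regions, columns = cutoffs; each cell is
      ``100 * #{region residues with EED >= cutoff} / #region residues``.
      Under ``mode='any'`` (default) a residue counts if *any* of the
      supplied EED distributions clears the cutoff; ``mode='per-drug'``
      returns a row per (region, drug) instead.
    * ``mean_eed`` — rows = regions, columns = drugs; mean EED over region
      residues.
    """
    if not eed_distributions:
        raise ValueError("need at least one EED distribution")
    if list(cutoffs) != sorted(cutoffs):
        raise ValueError("cutoffs must be ascending")
    if regions is None:
        regions = DEFAULT_REGIONS
    if isinstance(regions, dict):
        regions = [RegionDefinition(k, a, b) for k, (a, b) in regions.items()]
    index = eed_distributions[0].values.index
    for d in eed_distributions[1:]:
        if not d.values.index.equals(index):
            raise ValueError("EED distributions cover different residue sets")
    labels = tuple(int(x) for x in index)
    lo, hi = min(labels), max(labels)
    for reg in regions:
        if reg.stop < lo or reg.start > hi:
            raise ValueError(f"region {reg.name} outside residue range {lo}..{hi}")
    mat = pd.DataFrame({d.drug: d.values for d in eed_distributions})
    mean_rows = {}
    pct_rows = {}
    for reg in regions:
        members = reg.members(labels)
        if not members:
            raise ValueError(f"region {reg.name} contains no analyzed residues")
        sub = mat.loc[members]
        mean_rows[reg.name] = sub.mean(axis=0)
        if mode == "any":
            best = sub.max(axis=1)
            pct_rows[reg.name] = pd.Series(
                {c: float((best >= c).mean() * 100.0) for c in cutoffs}
            )
        elif mode == "per-drug":
            for drug in mat.columns:
                pct_rows[(reg.name, drug)] = pd.Series(
                    {c: float((sub[drug] >= c).mean() * 100.0) for c in cutoffs}
                )
        else:
            raise ValueError(f"unknown mode {mode!r}")
    percentages = pd.DataFrame(pct_rows).T
    mean_eed = pd.DataFrame(mean_rows).T
    return percentages, mean_eed
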