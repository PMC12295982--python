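"""Seeded synthetic interaction-energy ensembles with plantable perturbations.

The generator emulates the statistical shape of per-frame residue-pair
electrostatic energy matrices from an MD trajectory: a fixed underlying
contact topology in which a few hub residues (charged side chains in a real
protein) carry dense, strong edges over a sparse weak background, with
per-frame multiplicative jitter standing in for thermal fluctuation.
Perturbing the edges incident to chosen residues emulates a destabilizing
mutation; interpolating those edges back toward the reference emulates
partial allosteric drug rescue.  Energies are in kcal/mol and mostly
negative (attractive), like real electrostatic decompositions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import ConstructEnsemble, InteractionFrame, ResidueIndexMap, default_index_map

__all__ = [
    "SyntheticSpec",
    "PerturbationSpec",
    "generate_ensemble",
    "hub_residues",
    "perturb_construct",
    "planted_targets",
    "make_rescue_triplet",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic construct generator.

    Defaults are sized to the p53-DBD system: 193 residues (author numbering
    96-290 minus the stripped pair), 152 sampled frames.  Hub edges have
    salt-bridge-scale magnitudes (~10 kcal/mol); background edges are weak
    (~0.5 kcal/mol) and sparse.
    """

    n_residues: int = 193
    n_frames: int = 152
    n_hubs: int = 12
    hub_strength: float = 10.0
    hub_density: float = 0.4
    background_strength: float = 0.5
    background_density: float = 0.05
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 2 or self.n_frames < 2:
            raise ValueError("need at least 2 residues and 2 frames")
        if not (0 <= self.n_hubs <= self.n_residues):
            raise ValueError("n_hubs out of range")
        for name in ("hub_density", "background_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.hub_strength <= 0 or self.background_strength <= 0:
            raise ValueError("edge strengths must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def index_map(self) -> ResidueIndexMap:
        if self.n_residues == 193:
            return default_index_map()
        return ResidueIndexMap(tuple(range(1, self.n_residues + 1)))


@dataclass(frozen=True)
class PerturbationSpec:
    """A planted residue-level perturbation.

    mode 'weaken'/'strengthen' multiplies every edge incident to a target
    residue by ``magnitude`` (< 1 weakens, > 1 strengthens); 'rewire'
    permutes the target-incident edge energies among their positions with a
    seeded shuffle, preserving the weight multiset but scrambling topology.
    """

    target_residues: frozenset = field(default_factory=frozenset)
    mode: str = "weaken"
    magnitude: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "target_residues", frozenset(int(x) for x in self.target_residues)
        )
        if self.mode not in ("weaken", "strengthen", "rewire"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.magnitude <= 0:
            raise ValueError("magnitude must be > 0")


def _layout(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Seeded base energy matrix and the hub node indices (0-based)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    hubs = np.sort(rng.choice(n, size=spec.n_hubs, replace=False))
    base = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    # sparse weak background
    bg_mask = rng.random(iu.size) < spec.background_density
    mag = np.abs(rng.normal(spec.background_strength, spec.background_strength / 3, iu.size))
    sign = np.where(rng.random(iu.size) < 0.8, -1.0, 1.0)  # mostly attractive
    base[iu[bg_mask], ju[bg_mask]] = (sign * mag)[bg_mask]
    # dense strong hub edges
    hub_set = set(int(h) for h in hubs)
    touches_hub = np.array([i in hub_set or j in hub_set for i, j in zip(iu, ju)])
    hub_mask = touches_hub & (rng.random(iu.size) < spec.hub_density)
    hmag = np.abs(rng.normal(spec.hub_strength, spec.hub_strength / 4, iu.size))
    hsign = np.where(rng.random(iu.size) < 0.8, -1.0, 1.0)
    base[iu[hub_mask], ju[hub_mask]] = (hsign * hmag)[hub_mask]
    # backbone chain: sequence neighbours always interact (peptide-bond
    # dipoles), which keeps the network connected and no residue isolated
    cmag = np.abs(rng.normal(spec.background_strength, spec.background_strength / 3, n - 1))
    chain = np.arange(n - 1)
    empty = base[chain, chain + 1] == 0
    base[chain[empty], chain[empty] + 1] = -cmag[empty]
    base = base + base.T
    return base, hubs


def hub_residues(spec: SyntheticSpec) -> tuple[int, ...]:
    """Author-numbered labels of the seeded hub residues for this spec."""
    _, hubs = _layout(spec)
    labels = spec.index_map().labels
    return tuple(labels[h] for h in hubs)


def generate_ensemble(spec: SyntheticSpec, label: str = "synthetic") -> ConstructEnsemble:
    """Generate a seeded frame-wise ensemble; identical for identical specs.

    Per-frame edge energies are ``base * (1 + eps)`` with
    ``eps ~ Normal(0, noise_sd)`` drawn independently per edge per frame.
    A weak near-zero van der Waals channel is included so both channels of
    the ingestion contract are exercised.
    """
    base, _ = _layout(spec)
    rng = np.random.default_rng(spec.seed + 1)  # jitter stream, layout-independent
    n, T = spec.n_residues, spec.n_frames
    iu, ju = np.triu_indices(n, k=1)
    support = base[iu, ju] != 0
    si, sj = iu[support], ju[support]
    vals = base[si, sj]
    index_map = spec.index_map()
    frames = []
    for f in range(T):
        jitter = rng.normal(0.0, spec.noise_sd, si.size) if spec.noise_sd else 0.0
        e = np.zeros((n, n))
        e[si, sj] = vals * (1.0 + jitter)
        e = e + e.T
        v = np.zeros((n, n))
        v[si, sj] = rng.normal(0.0, 0.02, si.size)
        v = v + v.T
        frames.append(InteractionFrame(f, e, v))
    return ConstructEnsemble(label, frames, index_map)


def _target_indices(
    ensemble: ConstructEnsemble, targets: frozenset
) -> np.ndarray:
    missing = [t for t in targets if t not in set(ensemble.index_map.labels)]
    if missing:
        raise ValueError(f"target residues {sorted(missing)} not in ensemble")
    return np.array(sorted(ensemble.index_map.index_of(t) for t in targets), dtype=int)


def perturb_construct(
    ensemble: ConstructEnsemble, perturbation: PerturbationSpec, label: str | None = None
) -> ConstructEnsemble:
    """Apply a planted perturbation; non-target entries are bit-identical."""
    if not perturbation.target_residues:
        raise ValueError("perturbation target set is empty")
    tidx = _target_indices(ensemble, perturbation.target_residues)
    n = ensemble.index_map.size
    incident = np.zeros((n, n), dtype=bool)
    incident[tidx, :] = True
    incident[:, tidx] = True
    np.fill_diagonal(incident, False)
    if label is None:
        label = f"{ensemble.label}-perturbed"
    frames = []
    if perturbation.mode in ("weaken", "strengthen"):
        factor = np.where(incident, perturbation.magnitude, 1.0)
        for f in ensemble.frames:
            frames.append(
                InteractionFrame(f.frame_id, f.elec * factor, f.vdw, f.normalized)
            )
    else:  # rewire: one seeded permutation of target-incident upper-tri slots
        iu, ju = np.triu_indices(n, k=1)
        slot = incident[iu, ju]
        pi, pj = iu[slot], ju[slot]
        perm = np.random.default_rng(perturbation.seed).permutation(pi.size)
        for f in ensemble.frames:
            e = f.elec.copy()
            vals = e[pi, pj]
            e[pi, pj] = vals[perm]
            e[pj, pi] = vals[perm]
            frames.append(InteractionFrame(f.frame_id, e, f.vdw, f.normalized))
    return ConstructEnsemble(label, frames, ensemble.index_map, ensemble.scale)


def planted_targets(spec: SyntheticSpec, n_targets: int = 5) -> frozenset:
    """Default perturbation targets: seeded choice of non-hub residues."""
    labels = spec.index_map().labels
    hubs = set(hub_residues(spec))
    candidates = [lab for lab in labels if lab not in hubs]
    rng = np.random.default_rng(spec.seed + 2)
    picks = rng.choice(len(candidates), size=n_targets, replace=False)
    return frozenset(candidates[i] for i in picks)


def make_rescue_triplet(
    spec: SyntheticSpec,
    perturbation: PerturbationSpec | None = None,
    rescue_fraction: float = 0.5,
    seed: int | None = None,
    n_targets: int = 5,
) -> tuple[ConstructEnsemble, ConstructEnsemble, ConstructEnsemble]:
    """Reference / perturbed / partially rescued ensembles (WT-like triad).

    ``rescued`` equals ``perturbed`` with every target-incident edge moved a
    fraction ``rescue_fraction`` back toward the reference value (0 leaves
    the perturbation in place, 1 restores the reference exactly).  When no
    explicit perturbation is supplied, ``n_targets`` non-hub residues are
    chosen with the seeded default weakening.
    """
    if not 0.0 <= rescue_fraction <= 1.0:
        raise ValueError("rescue_fraction must be in [0, 1]")
    if seed is not None:
        spec = replace(spec, seed=int(seed))
    if perturbation is None:
        perturbation = PerturbationSpec(planted_targets(spec, n_targets), seed=spec.seed)
    reference = generate_ensemble(spec, label="WT")
    perturbed = perturb_construct(reference, perturbation, label="MUT-ub")
    frames = []
    for ref_f, per_f in zip(reference.frames, perturbed.frames):
        e = per_f.elec + rescue_fraction * (ref_f.elec - per_f.elec)
        frames.append(InteractionFrame(per_f.frame_id, e, per_f.vdw, per_f.normalized))
    rescued = ConstructEnsemble("MUT-drug", frames, reference.index_map, reference.scale)
    return reference, perturbed, rescued
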