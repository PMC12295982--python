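# Methods

`rinse` quantifies how point mutations and allosterically bound small
molecules reorganize the long-range electrostatic interaction network of a
protein domain, using per-frame residue-pair interaction energies from
molecular-dynamics ensembles. The reference system is the p53 DNA-binding
domain (DBD, residues 96–290): a wild-type construct, a destabilized
Y220C-like mutant, and mutant constructs bound to candidate rescue
compounds. The pipeline makes no use of coordinates — only pairwise
energies — so any per-frame symmetric energy decomposition can be analyzed.

## Pipeline

1. **Ingestion.** Per-frame symmetric residue×residue energy matrices
   (electrostatic, optionally van der Waals; kcal/mol), read from a
   long-format text table or per-frame matrices. Atom-resolution matrices
   are reduced by summing all atom-pair energies between residue pairs
   (e.g. 2999 atoms → 193 residues). Trajectories are subsampled with a
   regular stride; the production convention is stride 66 over a
   10,000-frame, 1 µs trajectory, which yields 152 frames. For the p53-DBD
   system residues 182 and 220 are stripped (covalent drug modification and
   the mutation site respectively), leaving 193 analyzed residues.
2. **Network construction.** Signed energies become nonnegative edge
   weights via a sign policy (default: magnitude |E|; negative-only and
   positive-only are available), normalized to [0, 1] by the single largest
   magnitude across all frames of a construct so frames remain comparable
   over time. Each frame's network is then sparsified by a *local*
   threshold: edge (i, j) survives iff its weight reaches the q-quantile
   (default q = 0.9) of the nonzero weights incident to i **or** to j.
   The union rule preserves symmetry; per-endpoint quantiles keep hub
   neighbourhoods dense while pruning the weak background of peripheral
   residues. Isolated nodes have no defined quantile and cast no votes.
3. **Heat kernel.** For each frame, the symmetric normalized Laplacian
   L = I − D^{−1/2} W D^{−1/2} (isolated nodes get zero rows, eigenvalue 0)
   is eigendecomposed and the heat kernel h_t = Φ e^{−tΛ} Φᵀ computed at a
   single diffusion time t shared by all constructs (default t = 6). The
   construct's mean kernel h̄_t is the elementwise average over its T
   frames.
4. **Latent space.** The three leading eigenvectors of the reference
   construct's mean kernel (PC1–PC3, sign-fixed so the largest-magnitude
   component is positive) span a shared ℝ³ space. Every frame kernel's
   rows, centered by the corresponding rows of the reference mean kernel,
   are projected onto this basis: 193 residues × 152 frames = 29,336
   embedded points per construct.
5. **Embedding error.** A residue's EE between constructs U and V is the
   first Wasserstein distance between its frame-coordinate samples,
   computed per axis (SciPy's implementation) and summed over the three
   components. EED for a drug-bound construct is
   EE(mutant, drug-bound) − EE(wild type, drug-bound) per residue: positive
   values mean drug binding moved that residue toward wild-type-like
   dynamics. MinEEa/MaxEEa attribute each residue to the comparison with
   the smallest/largest EE (ties to the earliest input) and report percent
   residue composition; regional summaries tabulate the percentage of
   motif residues clearing EED cutoffs
   (0.0002, 0.0003, 0.0004, 0.0005, 0.001, 0.002) and per-drug mean EED
   over the canonical DBD motifs L1 (113–121), L2 (164–177), H1 (178–180),
   S6-S7 (207–213), L6 (221–230), L3 (239–252), H2 (281–290).

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `q` | 0.9 | local-threshold quantile; 0 keeps all edges, 1 keeps per-node maxima |
| `t` | 6 | diffusion time; `"auto"` triggers knee-point selection |
| `n_components` | 3 | latent dimensions |
| `sign_policy` | magnitude | how signed energies become weights |
| `normalization` | global-max-abs | per-construct scaling of weights to [0, 1] |
| hub / peripheral cutoffs | 0.0105 / 0.0095 | PC1 kernel-connectivity classification |

**Diffusion-time selection.** Under `t="auto"` the kernel spectrum
{e^{−tλ_i}} of the time-averaged thresholded network is sorted into a scree
curve for each candidate t (integer grid 1–20); the knee is the point of
maximum perpendicular distance to the chord of the normalized curve
(Kneedle-style). The smallest t whose knee falls within the leading three
dimensions and whose leading three spectral masses reach 90% of the total
is selected; a flat or kneeless scree falls back to t = 6 with a warning.
The variance target and grid are package choices; t is selected once on the
reference construct and reused everywhere.

**Basis sharing.** Cross-construct Wasserstein comparisons are only
geometrically meaningful when all clouds share one basis, so the default
mode anchors the basis and centering on the reference (wild-type)
construct. A `per-construct` mode derives each construct's basis from its
own mean kernel; clouds carry basis provenance, and EE between clouds with
different provenance is refused rather than silently computed.

**EE axis aggregation.** The 1-D Wasserstein distances of the three
components are summed by default (mean and PC1-only are selectable and
recorded); the sum is itself a metric on the product space, preserving
nonnegativity, symmetry and the triangle inequality.

## Synthetic data

No public trajectories exist for the reference system, so the generator
emulates the statistical shape of the real inputs: a fixed contact topology
with `n_hubs` hub residues (charged side chains) carrying dense strong
edges (mean |E| 10 kcal/mol, salt-bridge scale, ~40% partner density) over
a sparse weak background (density 0.05, mean |E| 0.5 kcal/mol), a
guaranteed sequence-neighbour backbone edge per residue (peptide-bond
dipoles — this also keeps the network connected; without it, isolated
residues create an exact stationary kernel subspace that absorbs the PCA
basis and nulls all dynamics), mostly negative (attractive) energies, and
multiplicative per-edge per-frame jitter (sd 0.1) standing in for thermal
fluctuation. Defaults are sized to the production system (193 × 152).
A mutation is emulated by multiplying all edges incident to target
residues by 0.1 (loss of a charged contact); drug rescue by interpolating
those edges a fraction of the way back toward the reference.

What the generator does **not** emulate: force-field physics, correlated
conformational transitions (frames are exchangeable, with no slow modes),
distance-dependent interaction decay, or cooperative multi-residue
rearrangements. Passing recovery tests therefore demonstrates that the
pipeline detects and signs localized energetic perturbations under
realistic noise — not that it reproduces any specific biological result.

## Numerical choices

- Eigendecompositions use the symmetric solver (ascending eigenvalues,
  orthonormal columns); eigenvector signs are fixed by making the
  largest-|component| entry positive, so runs are reproducible across
  solvers. Degenerate eigenvalues are resolved by solver index order.
- Duplicate (i, j)/(j, i) table entries are averaged; a discrepancy above
  1e-6 kcal/mol warns. Matrices are symmetrized by ½(M + Mᵀ) after every
  construction step to suppress round-off drift.
- All-zero ensembles (no normalization scale), empty Wasserstein samples,
  mixed diffusion times, and basis/kernel dimension mismatches raise
  errors rather than propagating NaNs.
- Ties in MinEEa/MaxEEa go to the earliest distribution in input order
  (the CLI orders alphabetically unless overridden).
- No significance testing is applied to EE/EED; they are descriptive
  statistics reported against fixed cutoffs.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data:
structural counts and planted-recovery runs at the production scale
(193 residues × 152 frames; 20 seeded rescue triplets), oracle comparisons
on small random graphs (10 nodes, 50 draws) and small samples (≤ 6 points,
200 draws), and unit/property tests on 24–40-residue systems.

## Known limitations

- The local-threshold rule and the normalization are this package's
  concretization of "normalized and locally thresholded" network
  construction; both are configurable, and alternative published rules can
  be slotted in via `ThresholdConfig`.
- The PC1 hub statistic can be dominated by small disconnected components
  when aggressive thresholding fragments a sparse graph (their stationary
  vectors carry kernel eigenvalue exactly 1); `classify_hubs(mode="kernel")`
  (mean-kernel row sums) is the robust alternative and is what the hub
  recovery test uses.
- EE compares marginal per-axis distributions; joint 3-D transport is not
  computed (the summed 1-D form follows the production protocol and is far
  cheaper, but ignores cross-axis correlation).
- With `rescue_fraction = 0.5` the rescued construct sits midway between
  reference and mutant in *weight* space; its positive EED reflects the
  concavity of the kernel map in edge weight, and very small planted
  perturbations can fall below jitter noise.
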