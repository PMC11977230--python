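# Methods

This package re-implements, as a tested pipeline, the computational route
from a GAF-domain family alignment to a cluster of coevolving residues, and
from coordinate trajectories and plate-reader tables to the
structural-dynamics and biosensor statistics used to dissect GAF-domain
allostery. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic benchmarks do and do not
demonstrate.

## Statistical coupling analysis (SCA)

**Model.** For a filtered alignment of length L, sequence weights
`w_s = 1 / #{t : identity(s,t) >= 0.8}` damp phylogenetic redundancy
(`Meff = sum w_s`). Regularized weighted frequencies are

    f_i^a  = (1 - λ) <count>_w + λ q^a                (single site)
    f_ij^ab = (1 - λ) <joint count>_w + λ q^a q^b     (site pair)

with pseudocount weight λ = 0.03 and background q^a uniform (1/20) by
default; a database background can be supplied. Gaps carry no residue
mass: frequencies are over the 20 amino acids only, with the gap fraction
left as residual probability (there is no 21st state). Diagonal pair
blocks are forced to `f_ii^ab = δ_ab f_i^a` so marginalization is exact.

The positional conservation weight is the derivative of the relative
entropy of `f` against `q`,

    φ_i^a = ln[ f_i^a (1 - q^a) / ((1 - f_i^a) q^a) ],

clipped to ±50 to guard overflow when f approaches 0/1 under tiny λ. The
coupling score is the Frobenius norm of the φ-weighted covariance tensor,

    C_ij = || φ_i^a φ_j^b (f_ij^ab - f_i^a f_j^b) ||_F  over (a, b),

with zero diagonal and exact symmetrization. This positional-weight /
Frobenius-norm formulation is the widely published form of SCA; the
original analyses of GAF domains used unpublished scripts, so the precise
variant is the one genuinely irreproducible choice in the sequence stage —
results that depend on the variant (absolute score scales in particular)
should be compared only within one formulation. Both raw and max-normalized
scores are exposed for this reason.

**Identity definition.** Sequence identity (for both the 95% redundancy
filter and the 80% weighting cutoff) counts matching, mutually non-gap
columns over columns where at least one sequence is non-gap; columns gapped
in both are ignored. The redundancy filter is a greedy scan in file order
(first of a redundant group is kept), so results are deterministic given
input order. Filters run redundancy-first, then gap columns (unweighted
counts, strict `> 0.20`).

**Clustering and the cut.** Distances are `d_ij = 1 - C_ij / max(C)` (max
over off-diagonal scores), clustered by average linkage. The default cut is
placed in the middle of the **largest gap between consecutive dendrogram
merge heights**: a genuinely coevolving block merges at low heights while
uncoupled positions merge near the maximum distance, so the widest gap
separates signal from noise. We chose this over growing a cluster count
until the best cluster's score stops improving, because on planted
benchmarks the best-score-versus-k profile is flat while background
singletons peel off, which makes any stopping rule on it either stall
immediately or over-split; the largest-gap cut recovers the planted sector
in 10/10 seeded benchmarks. An explicit `n_clusters` remains available.
Note one degenerate regime: on an exactly block-constant matrix with a
zero background, background–background and background–block distances tie
exactly, and no fixed-k cut can isolate the block — the gap cut handles
this case too. The *top cluster* is the cluster (size ≥ 2) with maximal
mean off-diagonal intra-cluster coupling.

## Structures and binding-site mapping

PDB parsing is delegated to Bio.PDB (altloc conflicts resolve to highest
occupancy, ties toward 'A'; first NMR model by default). "Heavy atom"
means element other than H/D, with the element taken from columns 77–78
and an atom-name fallback. Binding-site residues are protein residues with
at least one heavy atom within 5.0 Å (inclusive) of any ligand heavy atom.
Residue-pair distances support three modes: mass-weighted center of mass
over all heavy atoms (masses C 12.011, N 14.007, O 15.999, S 32.06, ...),
Cα–Cα, and minimum heavy-atom distance. Whole-residue COM was chosen for
the COM mode (side-chain-only is exposed as a selection rule) because the
underlying experimental convention is ambiguous. Numbering translation
between reference (e.g. human PDE5A1) and template numbering is an
explicit integer offset; unmapped positions are reported, never dropped.

## Trajectory statistics

Trajectories are multi-model PDB (DCD through an optional mdtraj adapter);
frame stride and equilibration discard are config (defaults 1 and 0).

* **Superposition** — closed-form least-squares rigid fit (Kabsch / SVD)
  with the determinant correction, so a proper rotation (det = +1) is
  always returned; mirror images are fitted, not reflected. Vectorized
  over frames via batched 3×3 SVD.
* **RMSD** — per frame after superposition on the selection (default Cα).
* **RMSF** — about the iteratively refined mean structure (two passes),
  reported per residue. The rigid-body fit absorbs roughly `2/N` of
  isotropic fluctuation variance for N fitted atoms, so quantitative
  recovery benchmarks use chains of ≥ ~100 residues; a separate
  `fit_selection` lets callers pin the fit to a rigid core.
* **Rg** — mass-weighted by default, over protein heavy atoms.
* **Group distances** — frame-internal (no superposition), hence exactly
  invariant under per-frame rigid motion.
* **Ligand SASA** — Shrake–Rupley with 960 golden-spiral sphere points,
  probe 1.4 Å, vdW radii C 1.70 / N 1.55 / O 1.52 / S 1.80 / P 1.80 Å,
  hydrogens excluded; a test point is buried only if strictly inside
  another expanded sphere (boundary counts as exposed). Context is all
  heavy atoms of protein + ligand. Cross-checked against a Monte-Carlo
  point-sampling oracle (≤1% discrepancy on toys) and the closed-form
  isolated sphere (≤0.5% at 960 points).
* **H-bonds** — ligand/protein N/O pairs at ≤ 3.5 Å; when the topology
  carries hydrogens, a donor hydrogen with D–H...A angle ≥ 150° is also
  required (hydrogens are attached to their nearest polar heavy atom at
  ≤ 1.2 Å). Without hydrogens the criterion is distance-only and a notice
  is logged. Both cutoffs are config; 3.5 Å / 150° is a conventional
  middle ground among MD-analysis tools.
* **DCC** — normalized covariance of positional deviations from the time
  mean after superposition, clipped to [−1, 1]; zero-variance atoms yield
  zero rows with a warning rather than NaNs. Replicates pool by frame
  concatenation (order-free).
* **Distance landscape** — per frame, Cα-centroid distances for two
  element pairs (binding-site "lid": β3–α4; terminal helices: α2–α5),
  pooled over replicates, then a 2D Gaussian KDE (Scott's rule per axis)
  evaluated on a 0.1 Å grid padded by 4 bandwidths. Modes are strict
  8-neighbor local maxima above 10% of the global maximum, sorted by
  density. If all frames coincide the density is a delta and the code
  returns a flagged degenerate result instead of a singular KDE.

**Element ranges are explicit config.** The β3/α4/α2/α5 residue ranges are
never hard-coded: `coev.metrics.load_elements()` reads a YAML map, and the
shipped default for the human PDE5A1 GAFa domain
(`src/coev/data/pde5_gafa_elements.yaml`) contains *estimates* obtained by
partitioning the domain span according to its known element order
(α α β β β α β α β β α); they must be verified against the structure under
analysis.

## Biosensor curve models

* BRET ratio = acceptor / donor emission; percentage change in BRET is
  `100 · (BRET_ligand − BRET_basal) / BRET_basal`.
* Spectra: sum of 1 or 2 Gaussians `A exp(−(λ−μ)²/2σ²)`, bounded
  least squares (A ≥ 0, σ > 0, μ inside the measured window), components
  reported sorted by center.
* Dose–response: 4-parameter logistic, variable slope,
  `y = bottom + (top − bottom)/(1 + 10^((logEC50 − log c)·h))`, fitted in
  log10 molar with unconstrained plateaus (the variable-slope,
  unconstrained choice mirrors common plate-reader practice; the original
  software settings are unknown). Zero-concentration points are excluded
  from the fit (a display position 3 decades below the lowest dose is
  provided). If the top plateau is not approached within the measured
  range the fit is flagged under-determined and EC50 is a lower bound.
* Melt: Boltzmann sigmoid `y = bottom + (top − bottom)/(1 + exp((Tm−T)/slope))`
  over the 15-temperature ladder 30.0–80.0 °C; Tm is exactly the
  half-plateau crossing of the fitted curve, and a negative slope denotes
  signal decreasing with temperature.

All fits use bounded nonlinear least squares with 5 deterministic
initializations (plateau quartiles of the response range; the midpoint
parameter seeded at the observed half-max crossing); the lowest-cost
solution wins. Parameter SEs come from the Jacobian at the optimum.

## Synthetic data: what it emulates, what it does not

* **Planted-coupling MSA** — hidden-class model: each sequence draws a
  class (2 by default, equal probability); planted positions emit their
  class residue with fidelity p (default 0.9), other positions are i.i.d.
  uniform. The GAF-family-style variant adds ~5% near-duplicate sequences
  (98% identity) and 10 columns with 30% gaps so the redundancy and
  gap-column filters do real work, and plants a nine-position sector to
  match the scale of a GAF coevolving cluster. It does **not** model
  phylogeny: real alignments have tree-structured correlations that
  inflate background coupling, which is why Meff-weighting exists. Passing
  the planted benchmarks shows the machinery is correct, not that a given
  Pfam release will yield the same sector.
* **Gaussian trajectories** — one Cα pseudo-atom per residue (mass 12.011,
  radius 1.7 Å) on a 3.8 Å-spaced chain, with fluctuations drawn per
  Cartesian axis from N(0, Σ), Σ_ij = ρ_ij σ_i σ_j (axes independent, so
  the expected DCC of a pair equals its ρ). The correlation matrix is
  validated PSD. Optional per-frame random rigid contamination exercises
  the superposition. A separate layout generates four 3-residue element
  blocks whose (β3–α4, α2–α5) distance pair follows a prescribed Gaussian
  mixture, for landscape-mode recovery. These trajectories have no
  anharmonicity, no solvent, and no real kinetics — they validate the
  estimators, not the physics.
* **Curve tables** — exact model values plus i.i.d. Gaussian noise on the
  standard grids (half-decade concentration ladder; the 15-temperature
  melt ladder; 385–665 nm at 15 nm steps).

All generators take a single seed and are byte-deterministic.

## Benchmark problem sizes

Recovery benchmarks run at: 10 alignments of 1000 sequences × 100 columns
(SCA sector recovery); 20000 frames × 150 residues (RMSF within 2% of
σ√3, DCC within 0.05 of ρ); 6000 frames (landscape modes within one KDE
bandwidth); oracle equivalence at L ≤ 4 / 3-letter alphabet (coupling),
50 frames × 6 residues (DCC), and 10⁵ Monte-Carlo points (SASA). These
sizes give comfortable statistical margins for the stated tolerances while
keeping the full suite fast.

## Known limitations

* The SCA variant is fixed by construction (see above); scores are not
  comparable across SCA formulations, and the 0.25 sparsity threshold is
  meaningful only on this score scale.
* No mmCIF, no assembly expansion, no structure repair; PDB only.
* Binding-site classification implements only the 5 Å rule; a looser
  "near the site" category is not formalized.
* MD itself, force-field energies, MM-PBSA free energies, homology
  modelling and ICA-based sector decomposition are out of scope.
* The landscape element ranges shipped as defaults are estimates (see
  above) and the spectral/dose/melt fits assume homoscedastic noise.
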