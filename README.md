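# coev

Coevolution and structural-dynamics analysis for GAF-domain allostery
studies.

GAF domains are small-molecule-binding regulatory modules (the
cGMP-sensing GAFa domain of phosphodiesterase 5 is the archetype) that
allosterically control attached catalytic domains. A productive way to
dissect that allostery combines three computational stages, and this
package implements all of them as one tested pipeline:

1. **Statistical coupling analysis (SCA)** of a family alignment — score
   how the amino-acid distribution at one position covaries with another,
   via conservation-weighted covariance
   `C_ij = ‖ φ_i^a φ_j^b (f_ij^ab − f_i^a f_j^b) ‖_F`, then extract the
   cluster of mutually coupled ("coevolving") positions by hierarchical
   clustering of the coupling matrix.
2. **Trajectory statistics** over MD-style coordinate trajectories —
   Kabsch superposition, RMSD, per-residue RMSF, radius of gyration,
   residue-pair distances, ligand SASA (Shrake–Rupley), hydrogen-bond
   counts, dynamic cross-correlation (DCC), and a 2D kernel-density
   *conformational landscape* over two element distances (binding-site
   "lid" β3–α4 vs terminal helices α2–α5) with mode extraction.
3. **Biosensor curve models** — BRET ratios, two-Gaussian emission
   spectra, variable-slope logistic dose–response (EC50), and Boltzmann
   thermal melts (Tm, slope).

Synthetic-data generators with planted ground truth (coupled alignments,
Gaussian trajectories with planted σ/ρ/landscape modes, noisy curve
tables) make the whole pipeline testable without downloads; recovery of
the planted parameters is the package's primary validation surface.

## Layout

```
src/coev/        library: msa, sca, structure, traj, metrics, curves,
                 synth, pipeline, cli
analysis/        numbered drivers reproducing the full analysis sequence
scripts/         acceptance.py (see below)
tests/           pytest suite, including end-to-end acceptance tests
```

A `coev` umbrella CLI wraps the library
(`coev msa-filter | sca | mapstruct | traj | curves | simulate | run`).

## Worked example

Generate a GAF-family-style alignment with a planted nine-position
coevolving sector plus redundant sequences and gappy columns, then run
the full sequence path:

```sh
python analysis/01_simulate_inputs.py
python analysis/02_sca_coevolution.py
```

prints:

```
sequences: 840 -> 800 after 95% redundancy
columns: 100 -> 90 (10 dropped at >20% gaps)
pairs with coupling score > 0.25: 0.90% of off-diagonal pairs (a sparse coupling matrix)
top coevolving cluster (9 positions): [9, 21, 33, 42, 55, 63, 71, 84, 93]
planted sector recovered exactly
```

Reading: the redundancy filter removed the 40 near-duplicate sequences,
the gap filter removed the 10 gap-heavy columns, the coupling matrix is
sparse (under 1% of position pairs score above 0.25), and the
hierarchical-clustering top cluster is exactly the planted nine-position
sector. The remaining drivers map a binding site at the 5 Å rule
(`03`), recover planted trajectory statistics — RMSF ≈ σ√3, DCC ≈ planted
ρ (`04`) — locate landscape density modes for apo-like (≈ 11, 13 Å) and
holo-like (≈ 10, 9 Å) states (`05`), and fit the biosensor curves,
recovering EC50 ≈ 19 nM and Tm ≈ 65.2 °C from the generated tables
(`06`).

In Python:

```python
from coev import msa, sca

aln = msa.read_alignment("family.fasta")
aln = msa.filter_redundant(aln, 0.95)
aln, dropped = msa.filter_gap_columns(aln, 0.20)
w, meff = sca.sequence_weights(aln)
cm = sca.coupling_matrix(sca.weighted_frequencies(aln, w))
cluster = sca.cluster_coupling_matrix(cm)
print(cluster.top_cluster, cluster.top_cluster_score)
```

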