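#!/usr/bin/env python
"""Generate every synthetic input the downstream analyses consume.

Writes, under results/inputs/:
  * a GAF-family-style alignment with a planted nine-position coevolving
    sector, near-duplicate sequences and gap-heavy columns (FASTA),
  * three replicate Gaussian-fluctuation trajectories with a planted
    cross-correlated residue pair (multi-model PDB),
  * apo-like and holo-like element-distance trajectories for the
    conformational landscape,
  * noiseless and noisy biosensor curve tables (dose-response, thermal
    melt, emission spectrum; TSV),
each with a ground-truth JSON sidecar.
"""

import sys
from pathlib import Path

import numpy as np

from coev import msa, synth
from coev.traj import write_trajectory_pdb

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"
OUT.mkdir(parents=True, exist_ok=True)


def main() -> None:
    aln, truth = synth.make_gaf_like_msa(seed=SEED)
    msa.write_alignment(aln, OUT / "gaf_like_msa.fasta")
    synth.write_truth_sidecar(
        {k: truth[k] for k in ("planted", "p", "gappy_columns", "seed")},
        OUT / "gaf_like_msa.truth.json")
    print(f"alignment: {aln.n_seqs} sequences x {aln.length} columns, "
          f"planted sector {truth['planted']}")

    for rep in range(3):
        spec = synth.GaussianTrajSpec(
            n_residues=60, n_frames=300, sigma=0.5, rho={(20, 40): 0.5},
            seed=SEED + 10 + rep)
        traj, ttruth = synth.make_gaussian_trajectory(spec)
        traj.replicate_id = f"rep{rep + 1}"
        write_trajectory_pdb(traj, OUT / f"traj_rep{rep + 1}.pdb")
    synth.write_truth_sidecar(
        {"sigma": 0.5, "rho": {"20,40": 0.5}, "n_frames": 300,
         "replicates": 3}, OUT / "traj.truth.json")
    print("trajectories: 3 replicates, 60 residues x 300 frames, "
          "planted rho=0.5 at pair (20, 40)")

    for label, modes in (("apo", [(11.0, 13.0, 1.0, 0.3)]),
                         ("holo", [(10.0, 9.0, 1.0, 0.3)])):
        spec = synth.GaussianTrajSpec(
            n_frames=4000, landscape_modes=modes, seed=SEED + 20)
        traj, ltruth = synth.make_gaussian_trajectory(spec)
        write_trajectory_pdb(traj, OUT / f"landscape_{label}.pdb")
        synth.write_truth_sidecar(ltruth, OUT / f"landscape_{label}.truth.json")
    print("landscape trajectories: apo-like mode (11, 13) A, "
          "holo-like mode (10, 9) A")

    wt_log_ec50 = float(np.log10(19e-9))
    df, dtruth = synth.make_dose_response_data(
        log_ec50=wt_log_ec50, noise_sd=2.0, n_replicates=3, seed=SEED)
    df.to_csv(OUT / "dose_response.tsv", sep="\t", index=False)
    synth.write_truth_sidecar(dtruth, OUT / "dose_response.truth.json")

    dfm, mtruth = synth.make_melt_data(
        tm=65.23, slope=-2.64, noise_sd=0.01, n_replicates=3, seed=SEED)
    dfm.to_csv(OUT / "melt.tsv", sep="\t", index=False)
    synth.write_truth_sidecar(mtruth, OUT / "melt.truth.json")

    dfs, struth = synth.make_spectrum_data(noise_sd=0.01, seed=SEED)
    dfs.to_csv(OUT / "spectrum.tsv", sep="\t", index=False)
    synth.write_truth_sidecar(struth, OUT / "spectrum.truth.json")
    print("curve tables: dose-response (EC50 19 nM), melt "
          "(Tm 65.23 C, slope -2.64), two-component spectrum")


if __name__ == "__main__":
    main()
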