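"""Synthetic-data generators with planted ground truth.

Every stage of the pipeline gets an input generator whose statistical
structure matches what the stage assumes, so recovery of the planted
parameters is a testable end-to-end property:

* :func:`make_coupled_msa` — an alignment with a planted set of covarying
  positions against an i.i.d. background (ground truth for SCA cluster
  recovery).
* :func:`make_gaussian_trajectory` — Gaussian fluctuations around a linear
  Cα chain with planted per-residue sigma and residue-residue
  cross-correlations, optional rigid-body contamination, and an optional
  element-distance mixture mode (ground truth for RMSF / DCC / landscape).
* :func:`make_dose_response_data` / :func:`make_melt_data` /
  :func:`make_spectrum_data` — noisy curve tables on realistic grids.

All generators draw from one seeded ``numpy`` Generator per call and are
byte-deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .msa import AMINO_ACIDS, GAP, Alignment
from .metrics import ElementDef
from .structure import Structure
from .traj import Trajectory

N_AA = len(AMINO_ACIDS)

#: thermal-melt temperature grid (deg C) used by the plate assay emulated here
MELT_TEMPERATURES_C = [
    30.0, 31.4, 34.3, 38.9, 44.5, 49.3, 52.4, 60.0,
    61.4, 63.9, 67.8, 72.3, 76.1, 78.8, 80.0,
]

#: bioluminescence spectra window: 385-665 nm read at 15 nm steps
SPECTRUM_WAVELENGTHS_NM = np.arange(385.0, 665.0 + 1e-9, 15.0)


# ---------------------------------------------------------------------------
# planted-coupling MSA

@dataclass
class CoupledMsaSpec:
    """Specification of an alignment with planted covarying positions.

    Sequences fall into ``n_classes`` hidden classes; at each planted
    position a sequence emits its class-specific residue with probability
    ``p`` (else uniform over the other 19); all other positions are i.i.d.
    background. ``p = 1`` gives perfect covariation, ``p = 1/20`` none.
    """

    n_seq: int = 1000
    L: int = 100
    planted: tuple = (10, 30, 50, 70, 90)
    n_classes: int = 2
    class_prob: tuple | None = None
    p: float = 0.9
    background: str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.planted) > self.L:
            raise ValueError("more planted positions than columns")
        if any(not (0 <= s < self.L) for s in self.planted):
            raise ValueError("planted positions out of range")
        if not (1.0 / N_AA <= self.p <= 1.0):
            raise ValueError("emission fidelity p must be in [1/20, 1]")
        if self.class_prob is None:
            self.class_prob = tuple([1.0 / self.n_classes] * self.n_classes)
        if abs(sum(self.class_prob) - 1.0) > 1e-9:
            raise ValueError("class probabilities must sum to 1")


def make_coupled_msa(spec: CoupledMsaSpec) -> tuple[Alignment, dict]:
    """Generate the planted-coupling alignment and its ground-truth record."""
    rng = np.random.default_rng(spec.seed)
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    planted = np.asarray(sorted(spec.planted), dtype=int)
    # class-specific residues, distinct across classes at each planted column
    class_residue = np.empty((spec.n_classes, len(planted)), dtype=int)
    for c, _ in enumerate(planted):
        class_residue[:, c] = rng.choice(N_AA, size=spec.n_classes,
                                         replace=False)
    classes = rng.choice(spec.n_classes, size=spec.n_seq, p=spec.class_prob)
    arr = rng.integers(0, N_AA, size=(spec.n_seq, spec.L))
    for c, col in enumerate(planted):
        target = class_residue[classes, c]
        faithful = rng.random(spec.n_seq) < spec.p
        # unfaithful emissions are uniform over the other 19 residues
        other = (target + rng.integers(1, N_AA, size=spec.n_seq)) % N_AA
        arr[:, col] = np.where(faithful, target, other)
    seqs = ["".join(chr(aa[a]) for a in row) for row in arr]
    ids = [f"seq{i + 1:05d}" for i in range(spec.n_seq)]
    truth = {
        "planted": planted.tolist(),
        "classes": classes.tolist(),
        "class_residue": class_residue.tolist(),
        "p": spec.p,
        "seed": spec.seed,
    }
    return Alignment(ids=ids, seqs=seqs), truth


# ---------------------------------------------------------------------------
# Gaussian trajectories

@dataclass
class GaussianTrajSpec:
    """Gaussian-fluctuation trajectory around a linear Cα chain.

    ``sigma`` is the per-residue fluctuation SD per Cartesian axis (Å);
    ``rho`` maps residue-index pairs (0-based) to planted cross-correlation;
    axes are independent so the expected DCC of a pair equals its rho.
    ``landscape_modes`` switches to the element-distance mixture layout
    (see :func:`make_gaussian_trajectory`).
    """

    n_residues: int = 50
    n_frames: int = 1000
    sigma: float | np.ndarray = 0.5
    rho: dict = field(default_factory=dict)
    spacing: float = 3.8
    rigid_contamination: bool = False
    landscape_modes: list | None = None   # [(x, y, weight, sigma), ...]
    seed: int = 0


def _chain_topology(n_residues: int) -> Structure:
    """One Cα pseudo-atom (C, mass 12.011, radius 1.7) per residue."""
    n = n_residues
    return Structure(
        names=np.array(["CA"] * n),
        elements=np.array(["C"] * n),
        coords=np.zeros((n, 3)),
        resnums=np.arange(1, n + 1),
        resnames=np.array(["ALA"] * n),
        chains=np.array(["A"] * n),
        is_het=np.zeros(n, dtype=bool),
    )


def _random_rigid(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A uniformly random proper rotation and a translation."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.uniform(-20, 20, size=3)
    return Q, t


def make_gaussian_trajectory(spec: GaussianTrajSpec) -> tuple[Trajectory, dict]:
    """Generate the Gaussian trajectory and its ground-truth record.

    Frames are ``x_i(t) = mu_i + eps_i(t)`` with ``eps`` drawn independently
    per Cartesian axis from ``N(0, Sigma)``, ``Sigma_ij = rho_ij s_i s_j``.
    With ``rigid_contamination`` a random rigid transform is applied per
    frame (the clean twin is kept in the ground-truth record). With
    ``landscape_modes`` the generator instead builds four three-residue
    element blocks (beta3, alpha4, alpha2, alpha5) whose Cα-COM distance
    pair (beta3-alpha4, alpha2-alpha5) follows the given Gaussian mixture.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.landscape_modes is not None:
        return _make_landscape_trajectory(spec, rng)
    n = spec.n_residues
    sigma = np.broadcast_to(np.asarray(spec.sigma, dtype=float), (n,)).copy()
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    corr = np.eye(n)
    for (i, j), r in spec.rho.items():
        corr[i, j] = corr[j, i] = r
    eig = np.linalg.eigvalsh(corr)
    if eig[0] < -1e-10:
        raise ValueError(
            f"correlation matrix not positive semi-definite "
            f"(smallest eigenvalue {eig[0]:.3e})"
        )
    cov = corr * np.outer(sigma, sigma)
    # eigendecomposition handles the PSD-but-singular case
    w, V = np.linalg.eigh(cov)
    w = np.clip(w, 0, None)
    A = V * np.sqrt(w)[None, :]
    mu = np.zeros((n, 3))
    mu[:, 0] = np.arange(n) * spec.spacing
    eps = rng.normal(size=(spec.n_frames, 3, n)) @ A.T   # (T, 3, n)
    frames = mu[None] + eps.transpose(0, 2, 1)
    top = _chain_topology(n)
    top.coords = mu.copy()
    clean = Trajectory(topology=top, frames=frames.copy())
    truth = {
        "sigma": sigma.tolist(),
        "rho": {f"{i},{j}": r for (i, j), r in spec.rho.items()},
        "seed": spec.seed,
        "rigid_contamination": spec.rigid_contamination,
    }
    if spec.rigid_contamination:
        for t in range(spec.n_frames):
            Q, tr = _random_rigid(rng)
            frames[t] = frames[t] @ Q.T + tr
        truth["clean_trajectory"] = clean
        return Trajectory(topology=top, frames=frames), truth
    return clean, truth


#: element layout used by the landscape-mixture generator
LANDSCAPE_ELEMENTS = ElementDef(ranges={
    "beta3": (1, 3), "alpha4": (4, 6), "alpha2": (7, 9), "alpha5": (10, 12),
})


def _make_landscape_trajectory(
    spec: GaussianTrajSpec, rng: np.random.Generator
) -> tuple[Trajectory, dict]:
    modes = spec.landscape_modes
    weights = np.array([m[2] for m in modes], dtype=float)
    weights = weights / weights.sum()
    comp = rng.choice(len(modes), size=spec.n_frames, p=weights)
    xs = np.empty(spec.n_frames)
    ys = np.empty(spec.n_frames)
    for k, (mx, my, _, s) in enumerate(modes):
        sel = comp == k
        xs[sel] = rng.normal(mx, s, size=sel.sum())
        ys[sel] = rng.normal(my, s, size=sel.sum())
    n = 12
    top = _chain_topology(n)
    frames = np.zeros((spec.n_frames, n, 3))
    # symmetric +/- z offsets keep each block's COM exactly at its center
    offs = np.array([[0.0, 0.0, -1.0], [0.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    centers = np.zeros((spec.n_frames, 4, 3))
    centers[:, 1, 0] = xs                 # alpha4 at (x, 0, 0)
    centers[:, 2, 1] = 50.0               # alpha2 at (0, 50, 0)
    centers[:, 3, 1] = 50.0 + ys          # alpha5 at (0, 50 + y, 0)
    for b in range(4):
        frames[:, 3 * b: 3 * b + 3, :] = centers[:, b][:, None, :] + offs[None]
    top.coords = frames[0].copy()
    truth = {
        "modes": [list(m) for m in modes],
        "elements": LANDSCAPE_ELEMENTS.ranges,
        "seed": spec.seed,
    }
    return Trajectory(topology=top, frames=frames), truth


# ---------------------------------------------------------------------------
# curve tables

def _curve_table(x, xname, model_vals, noise_sd, n_replicates, rng):
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rows = []
    for rep in range(1, n_replicates + 1):
        noise = rng.normal(0, noise_sd, size=len(x)) if noise_sd > 0 else 0.0
        y = model_vals + noise
        for xi, yi in zip(x, np.atleast_1d(y)):
            rows.append({xname: xi, "y": yi, "replicate": rep})
    return pd.DataFrame(rows)


def make_dose_response_data(
    log_ec50: float = -7.72,
    hill: float = 1.0,
    bottom: float = 0.0,
    top: float = 100.0,
    conc: np.ndarray | None = None,
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Noisy 4PL dose-response table (conc in molar, response in % BRET).

    Defaults reproduce a WT-like curve with EC50 ≈ 19 nM over a half-decade
    concentration ladder spanning 0.1 nM - 100 uM.
    """
    if conc is None:
        conc = 10.0 ** np.arange(-10, -3.9, 0.5)
    conc = np.asarray(conc, dtype=float)
    logc = np.log10(conc)
    vals = bottom + (top - bottom) / (1 + 10 ** ((log_ec50 - logc) * hill))
    rng = np.random.default_rng(seed)
    df = _curve_table(conc, "concentration_M", vals, noise_sd, n_replicates, rng)
    truth = {"log_ec50": log_ec50, "hill": hill, "bottom": bottom,
             "top": top, "seed": seed, "noise_sd": noise_sd}
    return df, truth


def make_melt_data(
    tm: float = 65.23,
    slope: float = -2.64,
    bottom: float = 0.0,
    top: float = 1.0,
    temperatures: list | None = None,
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Noisy Boltzmann melt table on the standard 15-temperature grid."""
    T = np.asarray(temperatures if temperatures is not None
                   else MELT_TEMPERATURES_C, dtype=float)
    vals = bottom + (top - bottom) / (1 + np.exp((tm - T) / slope))
    rng = np.random.default_rng(seed)
    df = _curve_table(T, "temperature_C", vals, noise_sd, n_replicates, rng)
    truth = {"tm": tm, "slope": slope, "bottom": bottom, "top": top,
             "seed": seed, "noise_sd": noise_sd}
    return df, truth


def make_spectrum_data(
    components=((1.0, 410.0, 30.0), (0.6, 510.0, 25.0)),
    wavelengths: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Noisy Gaussian-mixture bioluminescence spectrum (385-665 nm)."""
    lam = np.asarray(wavelengths if wavelengths is not None
                     else SPECTRUM_WAVELENGTHS_NM, dtype=float)
    vals = np.zeros_like(lam)
    for A, mu, sig in components:
        vals += A * np.exp(-((lam - mu) ** 2) / (2 * sig ** 2))
    rng = np.random.default_rng(seed)
    df = _curve_table(lam, "wavelength_nm", vals, noise_sd, 1, rng)
    truth = {"components": [list(c) for c in components], "seed": seed,
             "noise_sd": noise_sd}
    return df, truth


def make_gaf_like_msa(
    seed: int = 0,
    n_seq: int = 800,
    L: int = 100,
    planted: tuple = (9, 21, 33, 42, 55, 63, 71, 84, 93),
    p: float = 0.9,
    n_redundant: int = 40,
    n_gappy_columns: int = 10,
) -> tuple[Alignment, dict]:
    """Synthetic stand-in for a Pfam-style GAF family alignment.

    A planted-coupling alignment (nine covarying positions, mirroring the
    size of a coevolving GAF sector) augmented with near-duplicate
    sequences (~98% identity, to exercise the 95% redundancy filter) and
    gap-heavy columns (~30% gaps, to exercise the 20% gap-column filter).
    Purely synthetic: it emulates the filtering workload, not real
    phylogeny.
    """
    rng = np.random.default_rng(seed)
    aln, truth = make_coupled_msa(CoupledMsaSpec(
        n_seq=n_seq, L=L, planted=planted, p=p, seed=seed))
    arr = aln.to_array().astype(int)  # gap encodes as 20
    GAP_CODE = N_AA
    # gap-heavy background columns (30% gaps) that the filter must drop
    candidates = [c for c in range(L) if c not in set(planted)]
    gappy = rng.choice(candidates, size=n_gappy_columns, replace=False)
    for c in gappy:
        rows = rng.choice(n_seq, size=int(0.3 * n_seq), replace=False)
        arr[rows, c] = GAP_CODE
    # near-duplicates of the first sequences (gap pattern shared, 2% point
    # mutations at non-gap positions -> ~98% identity, above the 95% rule)
    dup_rows = []
    for k in range(n_redundant):
        row = arr[k].copy()
        n_mut = max(1, int(0.02 * L))
        nongap = np.flatnonzero(row != GAP_CODE)
        cols = rng.choice(nongap, size=n_mut, replace=False)
        row[cols] = rng.integers(0, N_AA, size=n_mut)
        dup_rows.append(row)
    arr = np.vstack([arr, dup_rows])
    alphabet = AMINO_ACIDS + GAP
    seqs = ["".join(alphabet[v] for v in row) for row in arr]
    ids = [f"seq{i + 1:05d}" for i in range(len(seqs))]
    truth = dict(truth)
    truth.update({
        "gappy_columns": sorted(int(c) for c in gappy),
        "n_redundant_added": n_redundant,
    })
    return Alignment(ids=ids, seqs=seqs), truth


# ---------------------------------------------------------------------------
# synthetic GAF-like structure (stand-in; not a deposited PDB entry)

def make_synthetic_gaf_structure(
    binding_site_resnums=(220, 256, 273, 275),
    n_residues: int = 149,
    first_resnum: int = 154,
    seed: int = 0,
) -> Structure:
    """A synthetic GAF-like structure with a cGMP-like hetero ligand.

    Purely synthetic stand-in used to exercise ligand-proximity detection
    and numbering translation offline: a compact pseudo-Cα fold spanning
    residues ``first_resnum .. first_resnum + n_residues - 1`` with a
    multi-atom ligand (resname CGP) placed so that exactly the
    ``binding_site_resnums`` residues (template numbering) have heavy atoms
    within 5 Å of it.
    """
    rng = np.random.default_rng(seed)
    resnums = np.arange(first_resnum, first_resnum + n_residues)
    # compact globule: random walk re-scaled into a ball of radius ~18 A
    steps = rng.normal(size=(n_residues, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    coords = np.cumsum(steps * 3.8, axis=0)
    coords -= coords.mean(axis=0)
    coords *= 18.0 / np.abs(np.linalg.norm(coords, axis=1)).max()
    # push every residue at least 9 A from the origin (the ligand site) ...
    r = np.linalg.norm(coords, axis=1)
    coords[r < 9.0] *= (9.0 / np.clip(r[r < 9.0], 1e-6, None))[:, None]
    # ... then pull the designated binding-site residues within 5 A
    for k, resnum in enumerate(binding_site_resnums):
        i = int(resnum - first_resnum)
        u = coords[i] / np.linalg.norm(coords[i])
        coords[i] = u * (3.0 + 0.4 * k)
    lig_coords = np.array([
        [0.0, 0.0, 0.0], [1.3, 0.2, 0.0], [-1.1, 0.8, 0.4],
        [0.3, -1.2, 0.6], [-0.4, 0.3, -1.2],
    ])
    n_lig = len(lig_coords)
    return Structure(
        names=np.array(["CA"] * n_residues
                       + [f"C{i + 1}" for i in range(n_lig)]),
        elements=np.array(["C"] * n_residues + ["C", "N", "O", "C", "N"]),
        coords=np.vstack([coords, lig_coords]),
        resnums=np.concatenate([resnums, [900] * n_lig]),
        resnames=np.array(["ALA"] * n_residues + ["CGP"] * n_lig),
        chains=np.array(["A"] * (n_residues + n_lig)),
        is_het=np.concatenate([np.zeros(n_residues, bool),
                               np.ones(n_lig, bool)]),
    )


def write_truth_sidecar(truth: dict, path) -> None:
    """Ground-truth JSON sidecar accompanying every generated artifact."""
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Trajectory):
            return f"<trajectory {o.n_frames}x{o.n_atoms}>"
        return str(o)

    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, default=default)
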