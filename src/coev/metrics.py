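"""Trajectory statistics: RMSD, RMSF, Rg, group distances, SASA, H-bonds,
dynamic cross-correlation, and the 2D conformational distance landscape.

All superposition-based metrics use least-squares (Kabsch) rigid fitting
with a proper rotation enforced. Frame-internal metrics (Rg, distances,
SASA, H-bonds) need no superposition and are rigid-motion invariant by
construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

from .structure import (
    HYDROGEN_ELEMENTS,
    ResidueSelection,
    StructureError,
    group_distance,
)
from .traj import Trajectory, concatenate

logger = logging.getLogger(__name__)


class MetricError(ValueError):
    pass


@dataclass
class TimeSeries:
    """One scalar per frame, plus units and replicate provenance."""

    name: str
    values: np.ndarray
    units: str = ""
    replicate_id: str = "run1"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def summary(self) -> tuple[float, float]:
        """(mean, SD) over frames — the conventional ``value ± SD`` summary."""
        return float(self.values.mean()), float(self.values.std(ddof=0))

    def to_tsv(self, path, times_ns=None) -> None:
        with open(path, "w") as fh:
            fh.write("frame\ttime_ns\tvalue\n")
            for t, v in enumerate(self.values):
                time = "" if times_ns is None else f"{times_ns[t]:.4f}"
                fh.write(f"{t}\t{time}\t{v:.6f}\n")


def pooled_summary(series: list[TimeSeries]) -> tuple[float, float]:
    """Mean ± SD over the concatenated frames of all replicates."""
    allv = np.concatenate([s.values for s in series])
    return float(allv.mean()), float(allv.std(ddof=0))


# ---------------------------------------------------------------------------
# superposition

def kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ||P R^T - Q|| for centered point sets.

    Rows are points; apply as ``P @ R.T``. det(R) = +1 always (mirror images
    are fit by the best proper rotation, never a reflection).
    """
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def superpose(
    frame: np.ndarray, ref: np.ndarray, fit_idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``frame`` onto ``ref``.

    The transform is fitted on ``fit_idx`` atoms and applied to every atom.
    Returns (transformed frame, rotation matrix, RMSD of the fit atoms).
    """
    fit_idx = np.asarray(fit_idx, dtype=int)
    if len(fit_idx) < 3:
        raise MetricError("superposition needs at least 3 fit atoms")
    P = frame[fit_idx]
    Q = ref[fit_idx]
    Pc = P - P.mean(axis=0)
    if np.linalg.matrix_rank(Pc, tol=1e-8) < 2:
        raise MetricError("degenerate (collinear) superposition selection")
    R = kabsch_rotation(Pc, Q - Q.mean(axis=0))
    moved = (frame - P.mean(axis=0)) @ R.T + Q.mean(axis=0)
    rmsd = float(np.sqrt(((moved[fit_idx] - Q) ** 2).sum(axis=1).mean()))
    return moved, R, rmsd


def _batch_superpose(
    frames: np.ndarray, ref: np.ndarray, fit_idx: np.ndarray
) -> np.ndarray:
    """Superpose every frame onto ``ref`` (vectorized Kabsch over frames)."""
    fit_idx = np.asarray(fit_idx, dtype=int)
    P = frames[:, fit_idx]                      # (T, m, 3)
    Q = ref[fit_idx]
    pmean = P.mean(axis=1, keepdims=True)
    qmean = Q.mean(axis=0)
    Pc = P - pmean
    Qc = Q - qmean
    H = np.einsum("tmi,mj->tij", Pc, Qc)        # (T, 3, 3)
    U, S, Vt = np.linalg.svd(H)
    det = np.linalg.det(np.einsum("tji,tkj->tik", Vt, U))  # det(V @ U^T)
    D = np.repeat(np.eye(3)[None], len(frames), axis=0)
    D[:, 2, 2] = np.sign(det)
    R = np.einsum("tji,tjk,tkl->til", Vt, D, U.transpose(0, 2, 1))
    # R[t] = V D U^T ; apply as x @ R^T
    return np.einsum("tni,tji->tnj", frames - pmean, R) + qmean


# ---------------------------------------------------------------------------
# superposition-based metrics

def rmsd_series(
    traj: Trajectory,
    ref: np.ndarray | None = None,
    selection: np.ndarray | None = None,
) -> TimeSeries:
    """Per-frame RMSD (Å) to a reference after Kabsch fitting.

    ``selection`` (atom indices, default all Cα) is used both for the fit
    and the deviation; ``ref`` defaults to the topology coordinates.
    """
    sel = _default_selection(traj, selection)
    refc = traj.topology.coords if ref is None else np.asarray(ref, dtype=float)
    moved = _batch_superpose(traj.frames, refc, sel)
    dev = moved[:, sel] - refc[sel]
    vals = np.sqrt((dev ** 2).sum(axis=2).mean(axis=1))
    return TimeSeries("rmsd", vals, units="A", replicate_id=traj.replicate_id)


def _default_selection(traj: Trajectory, selection) -> np.ndarray:
    if selection is not None:
        return np.asarray(selection, dtype=int)
    sel = traj.topology.atom_indices(subset="ca", hetero=False)
    if len(sel) == 0:  # pseudo-atom toys may label atoms differently
        sel = np.flatnonzero(traj.topology.heavy & ~traj.topology.is_het)
    return sel


def _iterated_mean(
    frames: np.ndarray, sel: np.ndarray, n_iter: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Mean structure refined by repeated superposition (returns
    (superposed frames, mean coordinates over all atoms))."""
    ref = frames[0]
    moved = frames
    for _ in range(n_iter):
        moved = _batch_superpose(frames, ref, sel)
        ref = moved.mean(axis=0)
    return moved, ref


def rmsf_profile(
    traj: Trajectory,
    selection: np.ndarray | None = None,
    fit_selection: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue RMSF (Å) about the iteratively refined mean structure.

    Returns (residue numbers, RMSF values). With the default Cα selection
    there is one value per residue; otherwise atom values are averaged per
    residue. ``fit_selection`` optionally restricts the superposition fit
    to a different atom set (e.g. a rigid core) than the one reported.
    """
    if traj.n_frames < 2:
        raise MetricError("RMSF undefined for a single frame")
    sel = _default_selection(traj, selection)
    fit = sel if fit_selection is None else np.asarray(fit_selection, int)
    moved, mean = _iterated_mean(traj.frames, fit)
    dev = moved[:, sel] - mean[sel]
    per_atom = np.sqrt((dev ** 2).sum(axis=2).mean(axis=0))
    resnums = traj.topology.resnums[sel]
    uniq = np.unique(resnums)
    vals = np.array([per_atom[resnums == r].mean() for r in uniq])
    return uniq, vals


def dcc_matrix(
    traj: Trajectory,
    selection: np.ndarray | None = None,
    fit_selection: np.ndarray | None = None,
) -> np.ndarray:
    """Dynamic cross-correlation of positional fluctuations, in [-1, 1].

    Frames are first superposed onto the iterated mean structure; then
    ``DCC_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2><|dr_j|^2>)`` with ``dr`` the
    deviation from the time-mean position. ``fit_selection`` optionally
    restricts the superposition to a rigid core. Zero-variance atoms get
    zero rows/columns (with unit diagonal left at 0) and a warning.
    """
    if traj.n_frames < 2:
        raise MetricError("DCC needs at least 2 frames")
    sel = _default_selection(traj, selection)
    fit = sel if fit_selection is None else np.asarray(fit_selection, int)
    moved, mean = _iterated_mean(traj.frames, fit)
    dev = moved[:, sel] - mean[sel]                 # (T, m, 3)
    inner = np.einsum("tix,tjx->ij", dev, dev) / traj.n_frames
    var = np.diag(inner).copy()
    zero = var <= 1e-300
    if zero.any():
        logger.warning("%d zero-variance atoms in DCC; rows zeroed", zero.sum())
        var[zero] = 1.0
    dcc = inner / np.sqrt(var[:, None] * var[None, :])
    dcc[zero, :] = 0.0
    dcc[:, zero] = 0.0
    return np.clip(dcc, -1.0, 1.0)


def dcc_matrix_bruteforce(
    traj: Trajectory, selection: np.ndarray | None = None
) -> np.ndarray:
    """Naive two-pass loop oracle for :func:`dcc_matrix` (tests only)."""
    sel = _default_selection(traj, selection)
    moved, mean = _iterated_mean(traj.frames, sel)
    dev = moved[:, sel] - mean[sel]
    m = dev.shape[1]
    out = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            num = np.mean([dev[t, i] @ dev[t, j] for t in range(len(dev))])
            vi = np.mean([dev[t, i] @ dev[t, i] for t in range(len(dev))])
            vj = np.mean([dev[t, j] @ dev[t, j] for t in range(len(dev))])
            if vi <= 1e-300 or vj <= 1e-300:
                out[i, j] = 0.0
            else:
                out[i, j] = num / np.sqrt(vi * vj)
    return out


def dcc_row(
    dcc: np.ndarray, resnums: np.ndarray, residue: int
) -> np.ndarray:
    """Extract one residue's DCC row (e.g. to profile a mutated position
    against the rest of the domain)."""
    hits = np.flatnonzero(resnums == residue)
    if len(hits) == 0:
        raise MetricError(f"residue {residue} not in DCC selection")
    return dcc[hits[0]]


# ---------------------------------------------------------------------------
# frame-internal metrics

def rg_series(
    traj: Trajectory,
    selection: np.ndarray | None = None,
    mass_weighted: bool = True,
) -> TimeSeries:
    """Radius of gyration per frame (Å), default all heavy protein atoms."""
    if selection is None:
        selection = np.flatnonzero(traj.topology.heavy & ~traj.topology.is_het)
    sel = np.asarray(selection, dtype=int)
    if len(sel) == 0:
        raise MetricError("empty Rg selection")
    m = traj.topology.masses[sel] if mass_weighted else np.ones(len(sel))
    if m.sum() <= 0:
        raise MetricError("zero total mass in Rg selection")
    x = traj.frames[:, sel]
    com = (x * m[None, :, None]).sum(axis=1) / m.sum()
    sq = ((x - com[:, None, :]) ** 2).sum(axis=2)
    vals = np.sqrt((sq * m[None, :]).sum(axis=1) / m.sum())
    return TimeSeries("rg", vals, units="A", replicate_id=traj.replicate_id)


def group_distance_series(
    traj: Trajectory,
    a: ResidueSelection,
    b: ResidueSelection,
    mode: str = "com",
) -> TimeSeries:
    """Per-frame distance between two residue selections (no superposition)."""
    from .structure import _subset_for_mode

    subset = _subset_for_mode(mode)
    idx_a = a.atom_indices(traj.topology, subset=subset)
    idx_b = b.atom_indices(traj.topology, subset=subset)
    masses = traj.topology.masses
    vals = np.array([
        group_distance(traj.frames[t], masses, idx_a, idx_b, mode=mode)
        for t in range(traj.n_frames)
    ])
    return TimeSeries("group_distance", vals, units="A",
                      replicate_id=traj.replicate_id)


# ---------------------------------------------------------------------------
# solvent-accessible surface area (Shrake-Rupley)

def golden_spiral_points(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points via the golden-angle spiral."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5 ** 0.5) * k
    return np.column_stack([
        np.sin(phi) * np.cos(theta),
        np.sin(phi) * np.sin(theta),
        np.cos(phi),
    ])


def shrake_rupley_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    target_idx: np.ndarray,
    probe: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom SASA (Å²) of ``target_idx`` atoms in the given context.

    For each target atom, test points on the expanded sphere of radius
    ``r + probe``; a point counts as exposed unless it lies strictly inside
    another atom's expanded sphere (boundary points are exposed). Atoms with
    radius 0 (hydrogens) are excluded from the context.
    """
    sphere = golden_spiral_points(n_points)
    heavy = np.flatnonzero(radii > 0)
    out = np.zeros(len(target_idx))
    for t, i in enumerate(target_idx):
        ri = radii[i] + probe
        pts = coords[i] + sphere * ri
        exposed = np.ones(n_points, dtype=bool)
        for j in heavy:
            if j == i:
                continue
            rj = radii[j] + probe
            if np.linalg.norm(coords[j] - coords[i]) >= ri + rj:
                continue
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            exposed &= d2 >= rj * rj  # strict inside buries; boundary exposed
        out[t] = exposed.mean() * 4 * np.pi * ri * ri
    return out


def ligand_sasa_series(
    traj: Trajectory,
    ligand: str,
    probe: float = 1.4,
    n_points: int = 960,
) -> TimeSeries:
    """Total SASA of the ligand's heavy atoms per frame (Å²).

    The occlusion context is all heavy atoms of protein plus ligand.
    """
    top = traj.topology
    radii = top.radii()
    lig_idx = np.flatnonzero(top.is_het & (top.resnames == ligand) & top.heavy)
    if len(lig_idx) == 0:
        raise StructureError(f"ligand {ligand!r} not in topology")
    vals = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        vals[t] = shrake_rupley_sasa(
            traj.frames[t], radii, lig_idx, probe=probe, n_points=n_points
        ).sum()
    return TimeSeries("ligand_sasa", vals, units="A^2",
                      replicate_id=traj.replicate_id)


def sasa_histogram(
    series: list[TimeSeries], bins: int = 30
) -> tuple[np.ndarray, np.ndarray]:
    """Frequency distribution of SASA across pooled frames."""
    allv = np.concatenate([s.values for s in series])
    counts, edges = np.histogram(allv, bins=bins)
    return counts, edges


def sasa_montecarlo(
    coords: np.ndarray,
    radii: np.ndarray,
    target_idx: np.ndarray,
    probe: float = 1.4,
    n_points: int = 100_000,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo point-sampling SASA oracle (tests only)."""
    rng = np.random.default_rng(seed)
    out = np.zeros(len(target_idx))
    heavy = np.flatnonzero(radii > 0)
    for t, i in enumerate(target_idx):
        ri = radii[i] + probe
        z = rng.normal(size=(n_points, 3))
        z /= np.linalg.norm(z, axis=1, keepdims=True)
        pts = coords[i] + z * ri
        exposed = np.ones(n_points, dtype=bool)
        for j in heavy:
            if j == i:
                continue
            rj = radii[j] + probe
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            exposed &= d2 >= rj * rj
        out[t] = exposed.mean() * 4 * np.pi * ri * ri
    return out


# ---------------------------------------------------------------------------
# hydrogen bonds

def hbond_count_series(
    traj: Trajectory,
    ligand: str,
    d_cut: float = 3.5,
    angle_cut: float = 150.0,
) -> TimeSeries:
    """Ligand-protein hydrogen-bond count per frame.

    Candidate pairs are N/O heavy atoms, one on the ligand and one on the
    protein, at heavy-atom distance <= ``d_cut``. When the topology carries
    hydrogens, the pair additionally needs a donor hydrogen with a D-H...A
    angle >= ``angle_cut`` degrees; without hydrogens the distance rule
    alone is applied (logged once).
    """
    top = traj.topology
    polar = np.isin(top.elements, ["N", "O"])
    lig = np.flatnonzero(top.is_het & (top.resnames == ligand) & polar)
    prot = np.flatnonzero(~top.is_het & polar)
    if len(lig) == 0 or len(prot) == 0:
        return TimeSeries("hbonds", np.zeros(traj.n_frames), units="count",
                          replicate_id=traj.replicate_id)
    hyd = np.flatnonzero(np.isin(top.elements, list(HYDROGEN_ELEMENTS)))
    have_h = len(hyd) > 0
    if not have_h:
        logger.info("no hydrogens in topology; H-bond criterion is distance-only")
    # attach hydrogens to their nearest polar heavy atom (first frame, <=1.2 A)
    attached: dict[int, list[int]] = {}
    if have_h:
        donors = np.concatenate([lig, prot])
        for h in hyd:
            d = np.linalg.norm(traj.frames[0, donors] - traj.frames[0, h], axis=1)
            k = int(np.argmin(d))
            if d[k] <= 1.2:
                attached.setdefault(int(donors[k]), []).append(int(h))
    cos_cut = np.cos(np.deg2rad(angle_cut))
    vals = np.zeros(traj.n_frames)
    for t in range(traj.n_frames):
        x = traj.frames[t]
        d = np.linalg.norm(x[lig][:, None, :] - x[prot][None, :, :], axis=-1)
        pairs = np.argwhere(d <= d_cut)
        count = 0
        for li, pi in pairs:
            a1, a2 = int(lig[li]), int(prot[pi])
            if not have_h:
                count += 1
                continue
            ok = False
            for donor, acceptor in ((a1, a2), (a2, a1)):
                for h in attached.get(donor, []):
                    v1 = x[donor] - x[h]
                    v2 = x[acceptor] - x[h]
                    c = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    # D-H...A angle >= cut  <=>  cos(angle) <= cos(cut)
                    if c <= cos_cut:
                        ok = True
            if ok:
                count += 1
        vals[t] = count
    return TimeSeries("hbonds", vals, units="count",
                      replicate_id=traj.replicate_id)


# ---------------------------------------------------------------------------
# conformational distance landscape

@dataclass
class ElementDef:
    """Named secondary-structure elements as residue-number ranges.

    ``ranges`` maps element names (e.g. 'beta3', 'alpha4') to inclusive
    (start, end) residue-number tuples; distances use the Cα atoms.
    """

    ranges: dict[str, tuple[int, int]]
    subset: str = "ca"

    def selection(self, name: str, chain: str | None = None) -> ResidueSelection:
        start, end = self.ranges[name]
        if end < start:
            raise ValueError(f"empty range for element {name!r}")
        chain = chain or "A"
        return ResidueSelection(
            residues={(chain, r) for r in range(start, end + 1)},
            subset=self.subset,
        )


def load_elements(path=None) -> ElementDef:
    """Load element residue ranges from YAML (name -> [start, end]).

    Without a path, returns the shipped default ranges for the human PDE5A1
    GAFa domain — estimates derived from the domain's element order, meant
    to be verified against the structure under analysis.
    """
    import yaml

    if path is None:
        from importlib import resources

        ref = resources.files("coev").joinpath("data/pde5_gafa_elements.yaml")
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return ElementDef(ranges={str(k): (int(v[0]), int(v[1]))
                              for k, v in raw.items()})


@dataclass
class LandscapeDensity:
    """2D gridded probability density of an element-distance pair."""

    x: np.ndarray                 # grid axis (Å), e.g. β3-α4 distance
    y: np.ndarray                 # grid axis (Å), e.g. α2-α5 distance
    density: np.ndarray           # (len(y), len(x)), integrates to ~1
    bandwidths: tuple[float, float]
    modes: list[tuple[float, float, float]] = field(default_factory=list)
    degenerate: bool = False

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("x\ty\tdensity\n")
            for iy, yv in enumerate(self.y):
                for ix, xv in enumerate(self.x):
                    fh.write(f"{xv:.3f}\t{yv:.3f}\t{self.density[iy, ix]:.6g}\n")


def element_distance_pair(
    traj: Trajectory,
    elements: ElementDef,
    pair_x: tuple[str, str] = ("beta3", "alpha4"),
    pair_y: tuple[str, str] = ("alpha2", "alpha5"),
    chain: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame (x, y) distances between the two element pairs (Cα-COM)."""
    chain = chain or str(traj.topology.chains[0])
    xs = group_distance_series(
        traj, elements.selection(pair_x[0], chain),
        elements.selection(pair_x[1], chain), mode="ca",
    ).values
    ys = group_distance_series(
        traj, elements.selection(pair_y[0], chain),
        elements.selection(pair_y[1], chain), mode="ca",
    ).values
    return xs, ys


def distance_landscape(
    trajs: list[Trajectory],
    elements: ElementDef,
    pair_x: tuple[str, str] = ("beta3", "alpha4"),
    pair_y: tuple[str, str] = ("alpha2", "alpha5"),
    grid_step: float = 0.1,
    mode_floor: float = 0.10,
) -> LandscapeDensity:
    """Pooled 2D Gaussian-KDE landscape of the two element distances.

    Frames are pooled over replicates, the KDE uses Scott's bandwidth rule,
    and modes are strict local maxima above ``mode_floor`` of the global
    maximum, sorted by density (highest first).
    """
    xs, ys = [], []
    for tr in trajs:
        x, y = element_distance_pair(tr, elements, pair_x, pair_y)
        xs.append(x)
        ys.append(y)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if len(x) < 2:
        raise MetricError("landscape needs at least 2 pooled frames")
    if x.std() < 1e-9 and y.std() < 1e-9:
        logger.warning("degenerate landscape: all frames identical")
        gx = np.array([x[0]])
        gy = np.array([y[0]])
        return LandscapeDensity(
            x=gx, y=gy, density=np.array([[1.0]]), bandwidths=(0.0, 0.0),
            modes=[(float(x[0]), float(y[0]), 1.0)], degenerate=True,
        )
    kde = gaussian_kde(np.vstack([x, y]), bw_method="scott")
    hx = float(np.sqrt(kde.covariance[0, 0]))
    hy = float(np.sqrt(kde.covariance[1, 1]))
    pad_x, pad_y = 4 * hx, 4 * hy
    gx = np.arange(x.min() - pad_x, x.max() + pad_x + grid_step, grid_step)
    gy = np.arange(y.min() - pad_y, y.max() + pad_y + grid_step, grid_step)
    XX, YY = np.meshgrid(gx, gy)
    dens = kde(np.vstack([XX.ravel(), YY.ravel()])).reshape(XX.shape)
    modes = _find_modes(gx, gy, dens, floor=mode_floor)
    return LandscapeDensity(
        x=gx, y=gy, density=dens, bandwidths=(hx, hy), modes=modes
    )


def _find_modes(
    gx: np.ndarray, gy: np.ndarray, dens: np.ndarray, floor: float = 0.10
) -> list[tuple[float, float, float]]:
    """Strict 8-neighbor local maxima above ``floor`` of the global max."""
    peak = dens.max()
    modes = []
    ny, nx = dens.shape
    for iy in range(1, ny - 1):
        for ix in range(1, nx - 1):
            v = dens[iy, ix]
            if v < floor * peak:
                continue
            nbhd = dens[iy - 1: iy + 2, ix - 1: ix + 2]
            if (nbhd < v).sum() == 8:  # all 8 neighbors strictly below
                modes.append((float(gx[ix]), float(gy[iy]), float(v)))
    modes.sort(key=lambda m: -m[2])
    return modes


def pooled_dcc(trajs: list[Trajectory], selection=None) -> np.ndarray:
    """DCC over the concatenated frames of all replicates."""
    return dcc_matrix(concatenate(trajs), selection=selection)
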