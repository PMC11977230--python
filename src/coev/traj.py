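"""Coordinate trajectories: container, multi-model PDB I/O, DCD adapter.

A :class:`Trajectory` is a topology (a :class:`coev.structure.Structure`
atom table) plus an ``(n_frames, n_atoms, 3)`` coordinate stack. Multi-model
PDB is the required interchange format; DCD reading is an optional adapter
through mdtraj when that library is importable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from Bio.PDB import PDBParser
import warnings

from .structure import Structure, StructureError, _model_to_structure


@dataclass
class Trajectory:
    """An ordered stack of coordinate frames over a fixed topology."""

    topology: Structure
    frames: np.ndarray                 # (n_frames, n_atoms, 3), Angstrom
    frame_times: np.ndarray | None = None  # ns
    replicate_id: str = "run1"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise StructureError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise StructureError(
                "frame atom count does not match topology "
                f"({self.frames.shape[1]} vs {self.topology.n_atoms})"
            )
        if self.frames.shape[0] < 1:
            raise StructureError("trajectory needs at least one frame")
        if not np.all(np.isfinite(self.frames)):
            raise StructureError("non-finite coordinates in trajectory")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def frame_structure(self, t: int) -> Structure:
        """The topology materialized at frame ``t``."""
        s = self.topology
        return Structure(
            names=s.names, elements=s.elements, coords=self.frames[t].copy(),
            resnums=s.resnums, resnames=s.resnames, chains=s.chains,
            is_het=s.is_het, model_id=t,
        )

    def with_stride(self, stride: int = 1, discard: int = 0) -> "Trajectory":
        """Equilibration-discard and stride (defaults keep everything)."""
        fr = self.frames[discard::stride]
        times = None if self.frame_times is None else self.frame_times[discard::stride]
        return replace(self, frames=fr, frame_times=times)


def concatenate(trajs: list[Trajectory]) -> Trajectory:
    """Pool replicate trajectories over a shared topology."""
    if not trajs:
        raise StructureError("no trajectories to concatenate")
    n0 = trajs[0].n_atoms
    for t in trajs[1:]:
        if t.n_atoms != n0:
            raise StructureError("replicates differ in atom count")
    return Trajectory(
        topology=trajs[0].topology,
        frames=np.concatenate([t.frames for t in trajs], axis=0),
        replicate_id="pooled",
    )


def read_trajectory_pdb(path) -> Trajectory:
    """Read a multi-model PDB file as a trajectory.

    Every MODEL must carry the same atoms in the same order.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("t", str(path))
    models = list(structure)
    if not models:
        raise StructureError(f"no models in {path}")
    top = _model_to_structure(models[0], model_id=0)
    frames = np.empty((len(models), top.n_atoms, 3))
    frames[0] = top.coords
    for t, model in enumerate(models[1:], start=1):
        s = _model_to_structure(model, model_id=t)
        if s.n_atoms != top.n_atoms:
            raise StructureError(
                f"model {t} has {s.n_atoms} atoms, expected {top.n_atoms}"
            )
        frames[t] = s.coords
    return Trajectory(topology=top, frames=frames)


def write_trajectory_pdb(traj: Trajectory, path) -> None:
    """Write a trajectory as a multi-model PDB file."""
    s = traj.topology
    with open(path, "w") as fh:
        for t in range(traj.n_frames):
            fh.write(f"MODEL     {t + 1:4d}\n")
            serial = 1
            for k in range(s.n_atoms):
                record = "HETATM" if s.is_het[k] else "ATOM  "
                name = str(s.names[k])
                pname = f" {name:<3s}" if len(name) < 4 else name[:4]
                x, y, z = traj.frames[t, k]
                el = str(s.elements[k])[:2].rjust(2)
                fh.write(
                    f"{record}{serial:5d} {pname} {str(s.resnames[k])[:3]:>3s} "
                    f"{str(s.chains[k])[:1]}{int(s.resnums[k]):4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {el}\n"
                )
                serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_trajectory_dcd(dcd_path, topology_pdb_path) -> Trajectory:
    """Optional DCD adapter (requires mdtraj); coordinates converted to Å."""
    try:
        import mdtraj
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "DCD reading requires the optional mdtraj dependency"
        ) from exc
    from .structure import read_structure

    top = read_structure(topology_pdb_path)
    mt = mdtraj.load_dcd(str(dcd_path), top=str(topology_pdb_path))
    frames = np.asarray(mt.xyz, dtype=float) * 10.0  # nm -> Angstrom
    return Trajectory(topology=top, frames=frames)
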