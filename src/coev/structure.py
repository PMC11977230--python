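"""Protein structures: PDB parsing, ligand-site detection, static distances.

Wraps Bio.PDB behind flat numpy arrays so the trajectory metrics can reuse
the same atom table. Ligand-binding-site residues are defined by the
conventional minimum heavy-atom distance rule (default cutoff 5 A).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from Bio.PDB import PDBParser

logger = logging.getLogger(__name__)

#: standard atomic masses (amu) for common protein/ligand elements
ATOMIC_MASSES = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "SE": 78.971, "F": 18.998, "CL": 35.45,
    "BR": 79.904, "I": 126.904, "FE": 55.845, "ZN": 65.38, "MG": 24.305,
    "CA": 40.078, "NA": 22.990, "K": 39.098,
}

#: van der Waals radii (A) used for solvent-accessible surface area
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}

HYDROGEN_ELEMENTS = {"H", "D"}


class StructureError(ValueError):
    """Raised for parse failures and selection contract violations."""


def _infer_element(atom_name: str, element: str | None) -> str:
    if element:
        el = element.strip().upper()
        if el:
            return el
    # heuristic fallback from the atom name (PDB v2-style files)
    name = atom_name.strip()
    if name[:1].isdigit():
        name = name.lstrip("0123456789")
    if name[:2].upper() in ATOMIC_MASSES and len(name) > 1 and name[1].islower():
        return name[:2].upper()
    return name[:1].upper()


@dataclass
class Structure:
    """Flat atom table for one model of a structure.

    Arrays are index-aligned: ``coords[k]`` belongs to atom ``names[k]`` of
    residue ``(chains[k], resnums[k], resnames[k])``; ``is_het[k]`` flags
    HETATM records (ligands, ions, waters).
    """

    names: np.ndarray          # atom names
    elements: np.ndarray       # element symbols, upper case
    coords: np.ndarray         # (n_atoms, 3) in Angstrom
    resnums: np.ndarray        # residue sequence numbers
    resnames: np.ndarray
    chains: np.ndarray
    is_het: np.ndarray         # bool
    model_id: int = 0

    def __post_init__(self) -> None:
        if len(self.coords) == 0:
            raise StructureError("structure has no atoms")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES.get(e, 12.011) for e in self.elements])

    @property
    def heavy(self) -> np.ndarray:
        """Boolean mask of non-hydrogen atoms."""
        return np.array([e not in HYDROGEN_ELEMENTS for e in self.elements])

    def radii(self, table: dict | None = None) -> np.ndarray:
        table = table or VDW_RADII
        out = np.empty(self.n_atoms)
        for k, e in enumerate(self.elements):
            if e in HYDROGEN_ELEMENTS:
                out[k] = 0.0
            elif e in table:
                out[k] = table[e]
            else:
                raise StructureError(f"no van der Waals radius for element {e!r}")
        return out

    def ligand_residues(self) -> list[tuple[str, int, str]]:
        """Distinct hetero residues as (chain, resnum, resname)."""
        seen: dict[tuple[str, int, str], None] = {}
        for k in np.flatnonzero(self.is_het):
            seen[(str(self.chains[k]), int(self.resnums[k]),
                  str(self.resnames[k]))] = None
        return list(seen)

    def atom_indices(
        self,
        residues=None,
        chain: str | None = None,
        subset: str = "all_heavy",
        hetero: bool | None = None,
    ) -> np.ndarray:
        """Atom indices for a residue selection.

        subset: 'all' (every atom), 'all_heavy', 'sidechain_heavy', or 'ca'.
        """
        mask = np.ones(self.n_atoms, dtype=bool)
        if residues is not None:
            residues = {int(r) for r in residues}
            mask &= np.isin(self.resnums, list(residues))
        if chain is not None:
            mask &= self.chains == chain
        if hetero is not None:
            mask &= self.is_het == hetero
        if subset == "ca":
            mask &= self.names == "CA"
        elif subset == "all_heavy":
            mask &= self.heavy
        elif subset == "sidechain_heavy":
            backbone = np.isin(self.names, ["N", "CA", "C", "O", "OXT"])
            mask &= self.heavy & ~backbone
        elif subset != "all":
            raise ValueError(f"unknown atom subset {subset!r}")
        return np.flatnonzero(mask)


@dataclass
class ResidueSelection:
    """A set of residues plus the atom-subset rule used in distance modes."""

    residues: set[tuple[str, int]]  # (chain, resnum)
    subset: str = "all_heavy"

    def __post_init__(self) -> None:
        self.residues = {(str(c), int(r)) for c, r in self.residues}

    @property
    def resnums(self) -> list[int]:
        return sorted(r for _, r in self.residues)

    def atom_indices(self, s: Structure, subset: str | None = None) -> np.ndarray:
        subset = subset or self.subset
        idx = []
        for c, r in sorted(self.residues):
            sel = s.atom_indices(residues=[r], chain=c, subset=subset)
            idx.extend(sel.tolist())
        return np.array(sorted(set(idx)), dtype=int)


def read_structure(path, model: int = 0) -> Structure:
    """Read one model of a PDB file into a :class:`Structure`.

    Altloc conflicts are resolved by Bio.PDB's convention (highest occupancy,
    ties broken toward altloc 'A'). NMR multi-model files are allowed;
    ``model`` selects by position in file order.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            structure = parser.get_structure("s", str(path))
        except Exception as exc:
            raise StructureError(f"could not parse PDB file {path}: {exc}") from exc
    models = list(structure)
    if not models:
        raise StructureError(f"no ATOM records in {path}")
    if model >= len(models):
        raise StructureError(
            f"model {model} requested but file has {len(models)} model(s)"
        )
    return _model_to_structure(models[model], model_id=model)


def _model_to_structure(model, model_id: int = 0) -> Structure:
    names, elements, coords = [], [], []
    resnums, resnames, chains, is_het = [], [], [], []
    for chain in model:
        for residue in chain:
            hetflag = residue.id[0].strip() != ""
            for atom in residue:
                names.append(atom.get_name())
                elements.append(_infer_element(atom.get_name(), atom.element))
                coords.append(atom.get_coord())
                resnums.append(residue.id[1])
                resnames.append(residue.get_resname())
                chains.append(chain.id)
                is_het.append(hetflag)
    if not names:
        raise StructureError("model contains no atoms")
    return Structure(
        names=np.array(names),
        elements=np.array(elements),
        coords=np.array(coords, dtype=float),
        resnums=np.array(resnums, dtype=int),
        resnames=np.array(resnames),
        chains=np.array(chains),
        is_het=np.array(is_het, dtype=bool),
        model_id=model_id,
    )


def ligand_proximal_residues(
    s: Structure, ligand: str, cutoff: float = 5.0
) -> ResidueSelection:
    """Protein residues with a heavy atom within ``cutoff`` of the ligand.

    A residue is included when the minimum heavy-atom distance between any
    of its atoms and any heavy atom of the named hetero residue is <= cutoff
    (hydrogens excluded on both sides). This is the standard binding-site
    definition at the conventional 5 A cutoff.
    """
    lig_mask = s.is_het & (s.resnames == ligand) & s.heavy
    if not lig_mask.any():
        available = sorted({str(r) for r in s.resnames[s.is_het]})
        raise StructureError(
            f"ligand {ligand!r} not found; hetero residues present: {available}"
        )
    prot_mask = ~s.is_het & s.heavy
    lig_xyz = s.coords[lig_mask]
    prot_idx = np.flatnonzero(prot_mask)
    d = np.linalg.norm(
        s.coords[prot_idx][:, None, :] - lig_xyz[None, :, :], axis=-1
    ).min(axis=1)
    close = prot_idx[d <= cutoff]
    residues = {(str(s.chains[k]), int(s.resnums[k])) for k in close}
    return ResidueSelection(residues=residues)


def map_positions_to_structure(
    positions, s: Structure, offset: int = 0, chain: str | None = None
) -> tuple[ResidueSelection, list[int]]:
    """Translate reference residue numbers into structure numbering.

    ``structure_number = reference_number + offset`` (e.g. human PDE5A1 267
    with offset -10 lands on residue 257 of a mouse-numbered template).
    Residues absent from the structure are returned in the unmapped list,
    never silently dropped.
    """
    present = set()
    prot = ~s.is_het
    for k in np.flatnonzero(prot):
        if chain is None or s.chains[k] == chain:
            present.add((str(s.chains[k]), int(s.resnums[k])))
    found, unmapped = set(), []
    for p in positions:
        target = int(p) + offset
        hits = [(c, r) for c, r in present if r == target]
        if hits:
            found.update(hits)
        else:
            unmapped.append(int(p))
    if unmapped:
        logger.info("positions not found in structure: %s", unmapped)
    return ResidueSelection(residues=found), unmapped


def _subset_for_mode(mode: str) -> str:
    return {"com": "all_heavy", "ca": "ca", "min_heavy": "all_heavy"}[mode]


def group_distance(
    coords: np.ndarray,
    masses: np.ndarray,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    mode: str = "com",
) -> float:
    """Distance between two atom groups in a single coordinate set.

    mode 'com': mass-weighted centroid distance; 'ca': centroid of the
    (already Cα-restricted) selections; 'min_heavy': minimum pair distance.
    """
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise StructureError("selection resolves to zero atoms under this mode")
    if mode == "min_heavy":
        d = np.linalg.norm(
            coords[idx_a][:, None, :] - coords[idx_b][None, :, :], axis=-1
        )
        return float(d.min())
    if mode == "com":
        wa, wb = masses[idx_a], masses[idx_b]
    elif mode == "ca":
        wa = np.ones(len(idx_a))
        wb = np.ones(len(idx_b))
    else:
        raise ValueError(f"unknown distance mode {mode!r}")
    ca_ = (coords[idx_a] * wa[:, None]).sum(0) / wa.sum()
    cb_ = (coords[idx_b] * wb[:, None]).sum(0) / wb.sum()
    return float(np.linalg.norm(ca_ - cb_))


def residue_group_distance(
    s: Structure, a: ResidueSelection, b: ResidueSelection, mode: str = "com"
) -> float:
    """Static inter-group distance (Å) between two residue selections."""
    subset = _subset_for_mode(mode)
    idx_a = a.atom_indices(s, subset=subset)
    idx_b = b.atom_indices(s, subset=subset)
    return group_distance(s.coords, s.masses, idx_a, idx_b, mode=mode)


def write_selection_report(
    s: Structure, sel: ResidueSelection, ligand: str, path
) -> None:
    """TSV report: chain, resnum, resname, min heavy-atom distance to ligand."""
    lig_mask = s.is_het & (s.resnames == ligand) & s.heavy
    lig_xyz = s.coords[lig_mask]
    with open(path, "w") as fh:
        fh.write("chain\tresnum\tresname\tmin_dist_to_ligand\n")
        for c, r in sorted(sel.residues):
            idx = s.atom_indices(residues=[r], chain=c, subset="all_heavy")
            idx = idx[~s.is_het[idx]]
            if len(idx) == 0:
                continue
            d = np.linalg.norm(
                s.coords[idx][:, None, :] - lig_xyz[None, :, :], axis=-1
            ).min()
            name = s.resnames[idx[0]]
            fh.write(f"{c}\t{r}\t{name}\t{d:.3f}\n")
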