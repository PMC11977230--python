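"""Multiple-sequence-alignment handling for coupling analysis.

Reads FASTA/Stockholm alignments, applies the redundancy and gap-column
filters conventionally used before statistical coupling analysis, and keeps
track of how filtered columns map back to residue numbers of a chosen
reference sequence (e.g. human PDE5A1 numbering).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import AlignIO

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
ALPHABET = AMINO_ACIDS + GAP
#: non-standard residue codes collapsed to gap (SCA runs on the 20-state alphabet)
NONSTANDARD = set("BZXUOJ.")

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_AA_INDEX[GAP] = len(AMINO_ACIDS)


class AlignmentError(ValueError):
    """Raised for malformed or contract-violating alignments."""


def sanitize_sequence(seq: str) -> str:
    """Uppercase and map non-standard characters to gap.

    Characters outside the 20 amino acids that are not already gaps
    (B, Z, X, U, O, J, '.') carry no information for the 20-state coupling
    model and are replaced by ``'-'``.
    """
    seq = seq.upper()
    out = []
    warned = False
    for ch in seq:
        if ch in _AA_INDEX:
            out.append(ch)
        else:
            if not warned and ch in NONSTANDARD:
                logger.warning("non-standard residue %r mapped to gap", ch)
                warned = True
            elif ch not in NONSTANDARD:
                logger.warning("unknown character %r mapped to gap", ch)
            out.append(GAP)
    return "".join(out)


@dataclass
class Alignment:
    """An aligned set of protein sequences over the 20-aa + gap alphabet.

    Attributes
    ----------
    ids : list of str
        Sequence identifiers, order preserved from the source file.
    seqs : list of str
        Equal-length aligned sequences.
    weights : ndarray
        Per-sequence non-negative weights (default 1.0 each).
    column_labels : ndarray of int
        Original column indices retained after filtering; strictly
        increasing. Fresh alignments carry ``0..L-1``.
    """

    ids: list[str]
    seqs: list[str]
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]
    column_labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.seqs) == 0:
            raise AlignmentError("alignment has no sequences")
        L = len(self.seqs[0])
        if L < 1:
            raise AlignmentError("alignment length must be >= 1")
        for sid, s in zip(self.ids, self.seqs):
            if len(s) != L:
                raise AlignmentError(
                    f"ragged alignment: sequence {sid!r} has length {len(s)}, expected {L}"
                )
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and seqs differ in length")
        if self.weights is None:
            self.weights = np.ones(len(self.seqs))
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.seqs):
            raise AlignmentError("weights and seqs differ in length")
        if np.any(self.weights < 0):
            raise AlignmentError("weights must be non-negative")
        if self.column_labels is None:
            self.column_labels = np.arange(L)
        self.column_labels = np.asarray(self.column_labels, dtype=int)
        if len(self.column_labels) != L:
            raise AlignmentError("column_labels length mismatch")
        if L > 1 and np.any(np.diff(self.column_labels) <= 0):
            raise AlignmentError("column_labels must be strictly increasing")

    @property
    def n_seqs(self) -> int:
        return len(self.seqs)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def to_array(self) -> np.ndarray:
        """Integer-encoded alignment, shape (n_seqs, L); gap encodes as 20."""
        flat = np.frombuffer("".join(self.seqs).encode("ascii"), dtype=np.uint8)
        arr = flat.reshape(self.n_seqs, self.length)
        lut = np.full(128, _AA_INDEX[GAP], dtype=np.int8)
        for ch, idx in _AA_INDEX.items():
            lut[ord(ch)] = idx
        return lut[arr]


@dataclass
class PositionMap:
    """Map between alignment columns and reference residue numbers.

    ``pairs`` holds (original column label, reference residue number) tuples,
    injective both ways, residue numbers strictly increasing along columns.
    """

    pairs: list[tuple[int, int]]
    ref_id: str
    numbering_start: int

    def __post_init__(self) -> None:
        cols = [c for c, _ in self.pairs]
        nums = [r for _, r in self.pairs]
        if len(set(cols)) != len(cols) or len(set(nums)) != len(nums):
            raise AlignmentError("position map must be injective both ways")
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise AlignmentError("residue numbers must increase along columns")

    def column_to_residue(self) -> dict[int, int]:
        return dict(self.pairs)

    def residue_to_column(self) -> dict[int, int]:
        return {r: c for c, r in self.pairs}

    def residues_for_columns(self, columns) -> list[int | None]:
        c2r = self.column_to_residue()
        return [c2r.get(int(c)) for c in columns]


def read_alignment(path, fmt: str = "fasta") -> Alignment:
    """Read an alignment file into an :class:`Alignment` with unit weights.

    Parameters
    ----------
    path : path-like
    fmt : {"fasta", "stockholm"}
    """
    if fmt not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported alignment format: {fmt!r}")
    try:
        records = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise AlignmentError(f"could not parse {path} as {fmt}: {exc}") from exc
    ids = [rec.id for rec in records]
    seqs = [sanitize_sequence(str(rec.seq)) for rec in records]
    return Alignment(ids=ids, seqs=seqs)


def write_alignment(aln: Alignment, path) -> None:
    """Write an alignment as FASTA (ids and sequences round-trip exactly)."""
    with open(path, "w") as fh:
        for sid, seq in zip(aln.ids, aln.seqs):
            fh.write(f">{sid}\n{seq}\n")


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical, mutually non-gap columns.

    The denominator counts columns where at least one sequence is non-gap;
    columns gapped in both are ignored. An all-gap pair returns 0.
    """
    if len(a) != len(b):
        raise AlignmentError("sequences must have equal length")
    aa = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    bb = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    gap = ord(GAP)
    nongap = (aa != gap) | (bb != gap)
    denom = int(nongap.sum())
    if denom == 0:
        return 0.0
    match = (aa == bb) & (aa != gap) & (bb != gap)
    return float(match.sum()) / denom


def filter_redundant(aln: Alignment, threshold: float = 0.95) -> Alignment:
    """Remove phylogenetically redundant sequences (greedy, input order).

    A sequence is dropped when its identity to any already-retained sequence
    is strictly greater than ``threshold`` (the 95% redundancy rule). The
    scan is greedy in file order, so the first of a redundant group wins;
    the result is deterministic given input order.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    kept: list[int] = []
    for i, seq in enumerate(aln.seqs):
        redundant = any(
            pairwise_identity(seq, aln.seqs[j]) > threshold for j in kept
        )
        if not redundant:
            kept.append(i)
    return Alignment(
        ids=[aln.ids[i] for i in kept],
        seqs=[aln.seqs[i] for i in kept],
        weights=aln.weights[kept],
        column_labels=aln.column_labels.copy(),
    )


def filter_gap_columns(
    aln: Alignment, max_gap_frac: float = 0.20
) -> tuple[Alignment, list[int]]:
    """Drop columns with more than ``max_gap_frac`` gaps (strict ``>``).

    Gap fractions are unweighted raw counts over sequences. Returns the
    filtered alignment and the list of dropped original column labels.
    """
    if not (0 <= max_gap_frac <= 1):
        raise ValueError("max_gap_frac must be in [0, 1]")
    arr = aln.to_array()
    gap_frac = (arr == _AA_INDEX[GAP]).mean(axis=0)
    keep = gap_frac <= max_gap_frac
    if not keep.any():
        raise AlignmentError("empty alignment after gap-column filtering")
    dropped = [int(c) for c in aln.column_labels[~keep]]
    kept_idx = np.flatnonzero(keep)
    return (
        Alignment(
            ids=list(aln.ids),
            seqs=["".join(s[i] for i in kept_idx) for s in aln.seqs],
            weights=aln.weights.copy(),
            column_labels=aln.column_labels[keep],
        ),
        dropped,
    )


def map_to_reference(
    aln: Alignment, ref_id: str, numbering_start: int = 1
) -> PositionMap:
    """Build the column -> reference-residue-number map.

    Columns where the reference sequence is non-gap receive consecutive
    residue numbers starting at ``numbering_start`` (e.g. 164 for the human
    PDE5A1 GAFa domain). Keys are original column labels, so the mapping of
    a retained column is stable under unrelated column filtering.
    """
    try:
        ridx = aln.ids.index(ref_id)
    except ValueError as exc:
        raise KeyError(f"reference id {ref_id!r} not in alignment") from exc
    ref = aln.seqs[ridx]
    pairs: list[tuple[int, int]] = []
    resnum = numbering_start
    for col_label, ch in zip(aln.column_labels, ref):
        if ch != GAP:
            pairs.append((int(col_label), resnum))
            resnum += 1
    if not pairs:
        logger.warning("reference sequence %r is all gaps; empty map", ref_id)
    return PositionMap(pairs=pairs, ref_id=ref_id, numbering_start=numbering_start)


def write_column_map(posmap: PositionMap, aln: Alignment, path) -> None:
    """Write a TSV of (original_column, kept_column, reference_residue_number)."""
    c2r = posmap.column_to_residue()
    with open(path, "w") as fh:
        fh.write("original_column\tkept_column\treference_residue_number\n")
        for kept, orig in enumerate(aln.column_labels):
            res = c2r.get(int(orig), "")
            fh.write(f"{int(orig)}\t{kept}\t{res}\n")


def subset_columns(aln: Alignment, keep_idx) -> Alignment:
    """Return the alignment restricted to the given current column indices."""
    keep_idx = np.asarray(keep_idx, dtype=int)
    return replace(
        aln,
        seqs=["".join(s[i] for i in keep_idx) for s in aln.seqs],
        column_labels=aln.column_labels[keep_idx],
    )
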