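"""Statistical coupling analysis (SCA).

SCA scores how strongly the amino-acid distribution at one alignment
position covaries with another, up-weighted by positional conservation.
This module implements the positional-weight / Frobenius-norm formulation:

* regularized weighted frequencies
  ``f_i^a = (1-lambda) * <count>_w + lambda * q^a``
* conservation weight
  ``phi_i^a = ln[ f_i^a (1 - q^a) / ((1 - f_i^a) q^a) ]``
  (the derivative of the relative entropy of f w.r.t. the background q)
* coupling tensor
  ``Ct_ij^ab = phi_i^a phi_j^b (f_ij^ab - f_i^a f_j^b)``
* positional coupling score ``Ct_ij = || Ct_ij^(..) ||_F`` (Frobenius norm
  over the 20x20 residue pairs), diagonal set to zero.

The coevolving "sector" is then extracted by average-linkage hierarchical
clustering of the coupling matrix.

Gaps carry no residue mass: frequencies are computed over the 20 amino
acids only, with the gap fraction left as residual probability mass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .msa import AMINO_ACIDS, Alignment, PositionMap

N_AA = len(AMINO_ACIDS)
PHI_CLIP = 50.0  # |phi| bound; guards overflow for f near 0/1 under tiny lambda


class ScaError(ValueError):
    """Raised for contract violations in the SCA computation."""


def sequence_weights(
    aln: Alignment, identity_cutoff: float = 0.8
) -> tuple[np.ndarray, float]:
    """Down-weight near-duplicate sequences.

    The weight of sequence ``s`` is ``1 / #{t : identity(s, t) >= cutoff}``
    (the count includes ``s`` itself); ``Meff = sum of weights`` is the
    effective number of independent sequences.

    Identity here is the same measure as :func:`coev.msa.pairwise_identity`:
    matches over columns where at least one sequence is non-gap.
    """
    arr = aln.to_array()
    n, L = arr.shape
    gap_code = N_AA
    nongap = (arr != gap_code).astype(np.float64)
    # columns gapped in both sequences are excluded from the denominator
    both_gap = (1.0 - nongap) @ (1.0 - nongap).T
    denom = L - both_gap
    matches = np.zeros((n, n))
    for a in range(N_AA):
        X = (arr == a).astype(np.float64)
        matches += X @ X.T
    with np.errstate(invalid="ignore", divide="ignore"):
        ident = np.where(denom > 0, matches / denom, 0.0)
    neighbors = (ident >= identity_cutoff).sum(axis=1)
    weights = 1.0 / neighbors
    return weights, float(weights.sum())


@dataclass
class FrequencyModel:
    """Regularized weighted single- and pairwise-site frequencies."""

    f1: np.ndarray           # (L, 20)
    f2: np.ndarray           # (L, L, 20, 20)
    q: np.ndarray            # (20,) background frequencies
    lam: float               # pseudocount weight
    seq_weights: np.ndarray
    meff: float
    column_labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def length(self) -> int:
        return self.f1.shape[0]


def _background(background, n_aa: int = N_AA) -> np.ndarray:
    if isinstance(background, str):
        if background != "uniform":
            raise ValueError(f"unknown background {background!r}")
        return np.full(n_aa, 1.0 / n_aa)
    q = np.asarray(background, dtype=float)
    if q.shape != (n_aa,) or np.any(q <= 0):
        raise ValueError("background must be 20 positive frequencies")
    return q / q.sum()


def weighted_frequencies(
    aln: Alignment,
    weights: np.ndarray | None = None,
    lam: float = 0.03,
    background="uniform",
) -> FrequencyModel:
    """Compute the regularized frequency model.

    ``f_i^a = (1-lam) * (sum_s w_s [seq_s[i]==a]) / W + lam * q^a`` and the
    pairwise analogue with pseudocount ``lam * q^a q^b``. Gap characters
    contribute no residue counts; the per-position residue mass therefore
    sums to ``(1-lam) * (non-gap fraction) + lam``, with the gap fraction as
    residual.
    """
    if weights is None:
        weights = aln.weights
    weights = np.asarray(weights, dtype=float)
    if len(weights) != aln.n_seqs:
        raise ScaError("weights length does not match alignment")
    if not (0 <= lam < 1):
        raise ScaError("lambda must be in [0, 1)")
    q = _background(background)
    arr = aln.to_array()
    n, L = arr.shape
    W = weights.sum()
    # one-hot over the 20 residues only (gaps contribute no counts)
    X = np.zeros((n, L, N_AA))
    s_idx, p_idx = np.nonzero(arr < N_AA)
    X[s_idx, p_idx, arr[s_idx, p_idx]] = 1.0
    X = X.reshape(n, L * N_AA)
    raw1 = (weights @ X).reshape(L, N_AA) / W
    raw2 = ((weights[:, None] * X).T @ X).reshape(L, N_AA, L, N_AA) / W
    raw2 = raw2.transpose(0, 2, 1, 3)  # (L, L, 20, 20)
    f1 = (1 - lam) * raw1 + lam * q[None, :]
    f2 = (1 - lam) * raw2 + lam * (q[:, None] * q[None, :])[None, None, :, :]
    # diagonal blocks must marginalize like f1: f_ii^ab = delta_ab * f_i^a
    ii = np.arange(L)
    f2[ii, ii] = 0.0
    f2[ii[:, None], ii[:, None], np.arange(N_AA)[None, :],
       np.arange(N_AA)[None, :]] = f1
    if lam == 0.0 and (np.any(raw1 >= 1.0 - 1e-12) or np.any(raw1 == 0.0)):
        # permitted, but phi is undefined downstream
        pass
    return FrequencyModel(
        f1=f1, f2=f2, q=q, lam=lam, seq_weights=weights, meff=float(W),
        column_labels=aln.column_labels.copy(),
    )


@dataclass
class CouplingMatrix:
    """Symmetric L x L non-negative positional coupling scores."""

    scores: np.ndarray
    column_labels: np.ndarray
    phi: np.ndarray  # (L, 20) positional weights used

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def normalized(self) -> np.ndarray:
        """Scores divided by the off-diagonal maximum."""
        m = self.scores.max()
        if m == 0:
            raise ScaError("no coupling signal (all scores zero)")
        return self.scores / m

    def to_tsv(self, path, posmap: PositionMap | None = None) -> None:
        labels = self.column_labels
        if posmap is not None:
            c2r = posmap.column_to_residue()
            labels = [c2r.get(int(c), f"col{c}") for c in labels]
        with open(path, "w") as fh:
            fh.write("pos\t" + "\t".join(str(l) for l in labels) + "\n")
            for lab, row in zip(labels, self.scores):
                fh.write(str(lab) + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")

    def to_edge_list(self, path, threshold: float = 0.0) -> None:
        with open(path, "w") as fh:
            fh.write("pos_i\tpos_j\tscore\n")
            L = self.length
            for i in range(L):
                for j in range(i + 1, L):
                    if self.scores[i, j] > threshold:
                        fh.write(
                            f"{self.column_labels[i]}\t{self.column_labels[j]}"
                            f"\t{self.scores[i, j]:.6g}\n"
                        )


def positional_weights(f1: np.ndarray, q: np.ndarray) -> np.ndarray:
    """phi_i^a = ln[f(1-q) / ((1-f)q)], clipped to +/-PHI_CLIP."""
    if np.any((f1 <= 0) | (f1 >= 1)):
        raise ScaError(
            "frequencies at 0 or 1 make phi undefined; use lambda > 0"
        )
    phi = np.log(f1 * (1 - q[None, :]) / ((1 - f1) * q[None, :]))
    return np.clip(phi, -PHI_CLIP, PHI_CLIP)


def coupling_matrix(freqs: FrequencyModel) -> CouplingMatrix:
    """Positional coupling scores from the frequency model.

    ``Ct_ij = || phi_i^a phi_j^b (f_ij^ab - f_i^a f_j^b) ||_F`` over the
    20 x 20 residue pairs, with the diagonal set to zero by convention.
    """
    if freqs.lam <= 0:
        raise ScaError("coupling_matrix requires lambda > 0 so phi is finite")
    phi = positional_weights(freqs.f1, freqs.q)
    cov = freqs.f2 - freqs.f1[:, None, :, None] * freqs.f1[None, :, None, :]
    weighted = phi[:, None, :, None] * phi[None, :, None, :] * cov
    scores = np.sqrt((weighted ** 2).sum(axis=(2, 3)))
    np.fill_diagonal(scores, 0.0)
    scores = 0.5 * (scores + scores.T)  # exact symmetry
    return CouplingMatrix(
        scores=scores, column_labels=freqs.column_labels, phi=phi
    )


def fraction_above(cm: CouplingMatrix, threshold: float) -> float:
    """Fraction of unordered off-diagonal pairs with score strictly above
    ``threshold`` (the sparsity statistic of the coupling matrix)."""
    L = cm.length
    if L < 2:
        raise ScaError("need L >= 2")
    iu = np.triu_indices(L, k=1)
    vals = cm.scores[iu]
    return float((vals > threshold).sum()) / len(vals)


@dataclass
class ClusterResult:
    """Hierarchical clustering of the coupling matrix."""

    linkage: np.ndarray
    labels: np.ndarray            # cluster id per position (1..k)
    n_clusters: int
    top_cluster: list[int]        # positions (residue numbers if posmap given)
    top_cluster_members: np.ndarray  # positional indices into the matrix
    top_cluster_score: float

    def to_json(self, path) -> None:
        payload = {
            "n_clusters": int(self.n_clusters),
            "top_cluster": [int(p) for p in self.top_cluster],
            "top_cluster_score": self.top_cluster_score,
            "cluster_sizes": np.bincount(self.labels)[1:].tolist(),
            "dendrogram_heights": self.linkage[:, 2].tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _mean_intra_coupling(scores: np.ndarray, members: np.ndarray) -> float:
    if len(members) < 2:
        return 0.0
    sub = scores[np.ix_(members, members)]
    iu = np.triu_indices(len(members), k=1)
    return float(sub[iu].mean())


def cluster_coupling_matrix(
    cm: CouplingMatrix,
    n_clusters: int | None = None,
    min_size: int = 2,
    max_clusters: int = 20,
    posmap: PositionMap | None = None,
) -> ClusterResult:
    """Average-linkage clustering of ``1 - Ct/max(Ct)`` distances.

    When ``n_clusters`` is None the dendrogram is cut in the middle of the
    largest gap between consecutive merge heights — a tight coevolving
    block merges at low heights while the uncoupled background merges near
    the maximum distance, so the widest gap separates signal from noise.
    The ``top_cluster`` is the cluster of size >= ``min_size`` with the
    maximal mean off-diagonal intra-cluster coupling; its positions are
    reported as reference residue numbers when a position map is supplied.
    """
    L = cm.length
    if L < 2:
        raise ScaError("need L >= 2 to cluster")
    norm = cm.normalized()  # raises on all-zero matrix
    dist = 1.0 - norm
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")

    def best_cluster(labels: np.ndarray) -> tuple[float, np.ndarray]:
        best_members, best_score = None, -np.inf
        for cid in range(1, labels.max() + 1):
            members = np.flatnonzero(labels == cid)
            if len(members) < min_size:
                continue
            s = _mean_intra_coupling(cm.scores, members)
            if s > best_score:
                best_score, best_members = s, members
        if best_members is None:  # every cluster below min_size
            best_members = np.arange(L)
            best_score = _mean_intra_coupling(cm.scores, best_members)
        return best_score, best_members

    if n_clusters is not None:
        labels = hierarchy.fcluster(Z, t=int(n_clusters), criterion="maxclust")
    else:
        heights = Z[:, 2]
        if len(heights) < 2:
            labels = np.ones(L, dtype=int)
        else:
            gaps = np.diff(heights)
            i = int(np.argmax(gaps))
            cut = 0.5 * (heights[i] + heights[i + 1])
            labels = hierarchy.fcluster(Z, t=cut, criterion="distance")
    k = int(labels.max())
    score, members = best_cluster(labels)

    positions = [int(cm.column_labels[m]) for m in members]
    if posmap is not None:
        c2r = posmap.column_to_residue()
        positions = [c2r.get(p, p) for p in positions]
    return ClusterResult(
        linkage=Z,
        labels=labels,
        n_clusters=k,
        top_cluster=sorted(positions),
        top_cluster_members=members,
        top_cluster_score=score,
    )


def coupling_matrix_bruteforce(freqs: FrequencyModel) -> np.ndarray:
    """Naive quadruple-loop reference for the coupling score (tests only).

    Independent oracle for :func:`coupling_matrix` on small alignments.
    """
    L = freqs.length
    phi = positional_weights(freqs.f1, freqs.q)
    out = np.zeros((L, L))
    for i in range(L):
        for j in range(L):
            if i == j:
                continue
            acc = 0.0
            for a in range(N_AA):
                for b in range(N_AA):
                    cov = freqs.f2[i, j, a, b] - freqs.f1[i, a] * freqs.f1[j, b]
                    acc += (phi[i, a] * phi[j, b] * cov) ** 2
            out[i, j] = np.sqrt(acc)
    return out
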