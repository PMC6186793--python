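"""k-mer sparse-matrix encoding of ncRNA sequences and SVD summarization.

An ncRNA sequence over {A, C, G, U} of length L is traversed one
nucleotide at a time, giving L-k+1 overlapping k-mer windows. Stacking the
one-hot indicators of those windows yields a sparse (L-k+1) x 4^k matrix Q
that preserves both position and frequency information: its column means
are exactly the normalized k-mer frequency vector. Q is then compressed to
a single 1 x 4^k descriptor via its singular value decomposition
Q = U S V^T — the leading right-singular vector (the dominant k-mer
direction) scaled by sigma_1 / sum(sigma_i), i.e. the fraction of spectral
mass it carries. The default word size is k = 4 (256 columns).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

NUCLEOTIDES = "ACGU"
_NT_INDEX = {nt: i for i, nt in enumerate(NUCLEOTIDES)}


@dataclass(frozen=True)
class KmerMatrix:
    """One-hot window matrix: row w indicates the k-mer starting at w."""

    occupancy: sp.csr_matrix
    k: int
    rna_id: str | None = None

    def __post_init__(self) -> None:
        if self.occupancy.shape[1] != 4 ** self.k:
            raise ValueError(
                f"expected {4 ** self.k} columns for k={self.k}, "
                f"got {self.occupancy.shape[1]}"
            )


@dataclass(frozen=True)
class RnaFeatureVector:
    values: np.ndarray
    k: int
    provenance: str  # "svd", "frequency" or "concat"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float).ravel()
        expected = 2 * 4 ** self.k if self.provenance == "concat" else 4 ** self.k
        if values.size != expected:
            raise ValueError(
                f"expected length {expected} for k={self.k} "
                f"({self.provenance}), got {values.size}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("feature values must be finite")
        object.__setattr__(self, "values", values)


def kmer_index(kmer: str) -> int:
    """Lexicographic rank of a k-mer: base-4 with A=0, C=1, G=2, U=3.

    'AAAA' -> 0, 'AAAC' -> 1, ..., 'UUUU' -> 255 for k=4.
    """
    if not kmer:
        raise ValueError("empty k-mer")
    index = 0
    for ch in kmer:
        try:
            index = index * 4 + _NT_INDEX[ch]
        except KeyError:
            raise ValueError(f"illegal nucleotide {ch!r} in k-mer {kmer!r}") from None
    return index


def index_to_kmer(index: int, k: int) -> str:
    """Inverse of :func:`kmer_index` for a given word size."""
    if not 0 <= index < 4 ** k:
        raise ValueError(f"index {index} out of range for k={k}")
    out = []
    for _ in range(k):
        out.append(NUCLEOTIDES[index % 4])
        index //= 4
    return "".join(reversed(out))


def _window_indices(sequence: str, k: int) -> np.ndarray:
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(sequence) < k:
        raise ValueError(
            f"sequence length {len(sequence)} shorter than k={k}"
        )
    codes = np.array([_NT_INDEX.get(ch, -1) for ch in sequence])
    if np.any(codes < 0):
        bad = sorted(set(sequence) - set(NUCLEOTIDES))
        raise ValueError(f"illegal characters {bad} in RNA sequence")
    n = len(sequence) - k + 1
    idx = np.zeros(n, dtype=np.int64)
    for offset in range(k):
        idx = idx * 4 + codes[offset:offset + n]
    return idx


def kmer_frequency_vector(seq, k: int = 4) -> RnaFeatureVector:
    """Normalized k-mer frequencies: counts over the L-k+1 windows / (L-k+1)."""
    sequence = getattr(seq, "sequence", seq)
    idx = _window_indices(sequence, k)
    counts = np.bincount(idx, minlength=4 ** k).astype(float)
    return RnaFeatureVector(counts / idx.size, k, "frequency")


def kmer_sparse_matrix(seq, k: int = 4) -> KmerMatrix:
    """One-hot (L-k+1) x 4^k occupancy matrix, windows ordered by start."""
    sequence = getattr(seq, "sequence", seq)
    rna_id = getattr(seq, "id", None)
    idx = _window_indices(sequence, k)
    n = idx.size
    matrix = sp.csr_matrix(
        (np.ones(n), (np.arange(n), idx)), shape=(n, 4 ** k)
    )
    return KmerMatrix(matrix, k, rna_id)


def svd_feature(matrix) -> RnaFeatureVector:
    """Leading right-singular direction of Q, scaled by sigma_1 / sum(sigma).

    Accepts a :class:`KmerMatrix` or any 2-D array / sparse matrix. The
    decomposition runs on the Gram matrix Q^T Q (4^k x 4^k symmetric
    eigenproblem), which for the one-hot window matrix is simply the
    diagonal of k-mer counts. The sign is fixed so the entry of largest
    magnitude is positive, making the feature deterministic.
    """
    if isinstance(matrix, KmerMatrix):
        k = matrix.k
        q = matrix.occupancy
    else:
        q = matrix
        cols = q.shape[1]
        k = round(np.log(cols) / np.log(4)) if cols > 0 else 0
        if cols == 0 or 4 ** k != cols:
            raise ValueError("column count must be a power of 4")
    q = sp.csr_matrix(q) if not sp.issparse(q) else q
    if q.shape[0] == 0 or q.nnz == 0:
        raise ValueError("cannot decompose an empty or all-zero matrix")

    gram = np.asarray((q.T @ q).todense(), dtype=float)
    eigvals, eigvecs = np.linalg.eigh(gram)
    eigvals = np.clip(eigvals, 0.0, None)
    sigmas = np.sqrt(eigvals)
    lead = eigvecs[:, -1]
    scale = sigmas[-1] / sigmas.sum()
    pivot = int(np.argmax(np.abs(lead)))
    if lead[pivot] < 0:
        lead = -lead
    return RnaFeatureVector(lead * scale, k, "svd")


def rna_feature(seq, k: int = 4, mode: str = "svd") -> RnaFeatureVector:
    """Dispatch over the RNA representations: svd, frequency, or both stacked."""
    if mode == "svd":
        return svd_feature(kmer_sparse_matrix(seq, k))
    if mode == "frequency":
        return kmer_frequency_vector(seq, k)
    if mode == "concat":
        svd = svd_feature(kmer_sparse_matrix(seq, k))
        freq = kmer_frequency_vector(seq, k)
        return RnaFeatureVector(
            np.concatenate([svd.values, freq.values]), k, "concat"
        )
    raise ValueError(f"unknown mode {mode!r} (expected svd, frequency or concat)")
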