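"""Heterogeneous-graph construction.

Drug-drug edges come from chemical (Tanimoto) similarity of circular
fingerprints, target-target edges from normalized Smith-Waterman local
alignment of protein sequences.  Similarity matrices are thresholded into
binary adjacencies, edge types are aggregated with nonnegative weights, and
the blocks are assembled into one unified adjacency over drugs + targets.
Rows are normalized by a masked softmax over the structural support, so each
connected node distributes unit attention over its neighbours while isolated
nodes keep an all-zero row.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

__all__ = [
    "Fingerprint", "SimilarityMatrix", "EdgeTypeSet", "UnifiedGraph",
    "circular_fingerprint", "kmer_fingerprint", "tanimoto", "smith_waterman",
    "normalized_seq_similarity", "build_similarity_matrix",
    "threshold_adjacency", "aggregate_edge_types", "assemble_unified",
    "row_softmax_normalize",
]


@dataclass
class Fingerprint:
    """Hashed substructure fingerprint as a set of set-bit positions."""

    bits: frozenset
    nbits: int

    def __post_init__(self):
        if self.bits and (min(self.bits) < 0 or max(self.bits) >= self.nbits):
            raise ValueError("bit positions outside [0, nbits)")

    def to_vector(self) -> np.ndarray:
        v = np.zeros(self.nbits)
        v[list(self.bits)] = 1.0
        return v


@dataclass
class SimilarityMatrix:
    values: np.ndarray
    measure: str = "custom"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        self.values = v


@dataclass
class EdgeTypeSet:
    """Binary adjacencies of one class with per-type aggregation weights."""

    adjacencies: list[np.ndarray]
    weights: list[float] | None = None
    klass: str = "drug-drug"  # drug-drug | target-target | drug-target

    def resolved_weights(self) -> np.ndarray:
        if self.weights is None:
            k = len(self.adjacencies)
            return np.full(k, 1.0 / k)
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("edge-type weights must be nonnegative")
        return w


@dataclass
class UnifiedGraph:
    """Block adjacency over m drugs and n targets with normalized blocks."""

    A_DD: np.ndarray
    A_TT: np.ndarray
    A_DT: np.ndarray
    N_DD: np.ndarray = field(init=False)
    N_TT: np.ndarray = field(init=False)
    N_DT: np.ndarray = field(init=False)
    N_TD: np.ndarray = field(init=False)

    def __post_init__(self):
        m, n = self.A_DT.shape
        if self.A_DD.shape != (m, m) or self.A_TT.shape != (n, n):
            raise ValueError("inconsistent block dimensions")
        self.N_DD = row_softmax_normalize(self.A_DD, self.support("DD"))
        self.N_TT = row_softmax_normalize(self.A_TT, self.support("TT"))
        self.N_DT = row_softmax_normalize(self.A_DT, self.support("DT"))
        self.N_TD = row_softmax_normalize(self.A_TD, self.support("TD"))

    @property
    def A_TD(self) -> np.ndarray:
        return self.A_DT.T

    @property
    def m(self) -> int:
        return self.A_DD.shape[0]

    @property
    def n(self) -> int:
        return self.A_TT.shape[0]

    def support(self, block: str) -> np.ndarray:
        A = {"DD": self.A_DD, "TT": self.A_TT,
             "DT": self.A_DT, "TD": self.A_TD}[block]
        return A != 0

    def full_matrix(self) -> np.ndarray:
        top = np.hstack([self.A_DD, self.A_DT])
        bottom = np.hstack([self.A_TD, self.A_TT])
        return np.vstack([top, bottom])


# ---------------------------------------------------------------------------
# fingerprints and chemical similarity
# ---------------------------------------------------------------------------

def circular_fingerprint(smiles: str, radius: int = 2,
                         nbits: int = 2048) -> Fingerprint:
    """Hashed circular (atom-environment) fingerprint of a molecule.

    Uses RDKit's Morgan generator when available; raises a ValueError carrying
    the offending SMILES when it cannot be parsed.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius,
                                                    fpSize=nbits)
    fp = gen.GetFingerprint(mol)
    return Fingerprint(bits=frozenset(fp.GetOnBits()), nbits=nbits)


def kmer_fingerprint(text: str, k: int = 3, nbits: int = 2048) -> Fingerprint:
    """Hashed k-mer fingerprint over a raw string.

    A chemistry-free fingerprint: every length-k substring of the input is
    hashed into [0, nbits).  Deterministic across processes (md5-based).
    """
    bits = set()
    padded = text if len(text) >= k else text + "_" * (k - len(text))
    for i in range(len(padded) - k + 1):
        h = hashlib.md5(padded[i:i + k].encode()).digest()
        bits.add(int.from_bytes(h[:4], "little") % nbits)
    return Fingerprint(bits=frozenset(bits), nbits=nbits)


def tanimoto(fp_a: Fingerprint, fp_b: Fingerprint) -> float:
    """Tanimoto coefficient |A∩B|/|A∪B|; two empty fingerprints give 0."""
    if fp_a.nbits != fp_b.nbits:
        raise ValueError("fingerprints have mismatched nbits")
    union = len(fp_a.bits | fp_b.bits)
    if union == 0:
        return 0.0
    return len(fp_a.bits & fp_b.bits) / union


# ---------------------------------------------------------------------------
# sequence similarity
# ---------------------------------------------------------------------------

def _make_aligner(substitution, gap_open: float, gap_extend: float):
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if isinstance(substitution, str):
        aligner.substitution_matrix = substitution_matrices.load(
            substitution.upper())
    else:  # (match, mismatch) pair for toy/nucleotide scoring
        match, mismatch = substitution
        aligner.match_score = match
        aligner.mismatch_score = mismatch
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def smith_waterman(seq_a: str, seq_b: str, substitution="BLOSUM62",
                   gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Optimal local-alignment score with affine gaps (score floor 0).

    `substitution` is either a substitution-matrix name ("BLOSUM62") or a
    (match, mismatch) pair; gap penalties are passed as positive magnitudes.
    """
    if not seq_a or not seq_b:
        logger.warning("empty sequence in alignment; score 0")
        return 0.0
    aligner = _make_aligner(substitution, gap_open, gap_extend)
    return max(float(aligner.score(seq_a, seq_b)), 0.0)


def normalized_seq_similarity(seq_a: str, seq_b: str,
                              substitution="BLOSUM62",
                              gap_open: float = 11.0,
                              gap_extend: float = 1.0) -> float:
    """SW(a,b) / min(SW(a,a), SW(b,b)), clipped to [0,1].

    Normalizing by the smaller self-alignment score bounds the ratio by 1 and
    makes self-similarity exactly 1.
    """
    cross = smith_waterman(seq_a, seq_b, substitution, gap_open, gap_extend)
    self_a = smith_waterman(seq_a, seq_a, substitution, gap_open, gap_extend)
    self_b = smith_waterman(seq_b, seq_b, substitution, gap_open, gap_extend)
    sw_max = min(self_a, self_b)
    if sw_max <= 0:
        return 0.0
    return float(np.clip(cross / sw_max, 0.0, 1.0))


# ---------------------------------------------------------------------------
# matrix assembly
# ---------------------------------------------------------------------------

def build_similarity_matrix(entities, pairwise_measure,
                            measure: str = "custom") -> SimilarityMatrix:
    """Symmetric unit-diagonal similarity matrix over one entity class."""
    n = len(entities)
    if n < 1:
        raise ValueError("need at least one entity")
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                s = float(pairwise_measure(entities[i], entities[j]))
            except Exception as exc:
                raise ValueError(
                    f"similarity failed for pair ({i}, {j}): {exc}") from exc
            S[i, j] = S[j, i] = s
    return SimilarityMatrix(values=S, measure=measure)


def threshold_adjacency(S: SimilarityMatrix | np.ndarray,
                        threshold: float) -> np.ndarray:
    """Binary adjacency a_ij = 1 iff S_ij >= threshold, self-loops removed."""
    values = S.values if isinstance(S, SimilarityMatrix) else np.asarray(S)
    A = (values >= threshold).astype(float)
    np.fill_diagonal(A, 0.0)
    return A


def aggregate_edge_types(edge_type_set: EdgeTypeSet) -> np.ndarray:
    """Weighted sum of the binary adjacencies of one edge-type class."""
    adjs = edge_type_set.adjacencies
    shapes = {a.shape for a in adjs}
    if len(shapes) != 1:
        raise ValueError(f"edge-type shape mismatch: {shapes}")
    w = edge_type_set.resolved_weights()
    if len(w) != len(adjs):
        raise ValueError("one weight per edge type required")
    out = np.zeros(adjs[0].shape)
    for wk, Ak in zip(w, adjs):
        out += wk * Ak
    return out


def assemble_unified(A_DD: np.ndarray, A_TT: np.ndarray,
                     A_DT: np.ndarray) -> UnifiedGraph:
    """Unified block adjacency [[A_DD, A_DT], [A_DT^T, A_TT]].

    The drug-target block is the (training) interaction matrix Y; the
    target-drug block is always its transpose.
    """
    m, n = A_DT.shape
    if A_DD.shape != (m, m) or A_TT.shape != (n, n):
        raise ValueError(
            f"dimension mismatch: A_DD {A_DD.shape}, A_TT {A_TT.shape}, "
            f"A_DT {A_DT.shape}")
    return UnifiedGraph(A_DD=np.asarray(A_DD, float),
                        A_TT=np.asarray(A_TT, float),
                        A_DT=np.asarray(A_DT, float))


def row_softmax_normalize(block: np.ndarray,
                          support_mask: np.ndarray) -> np.ndarray:
    """Row softmax over supported entries only.

    Unsupported entries stay exactly 0; rows with nonempty support sum to 1;
    rows with empty support are all zero (isolated nodes pass no message and
    keep only their bias term in the encoder).
    """
    block = np.asarray(block, dtype=float)
    support = np.asarray(support_mask, dtype=bool)
    out = np.zeros_like(block)
    for i in range(block.shape[0]):
        idx = np.nonzero(support[i])[0]
        if idx.size == 0:
            continue
        row = block[i, idx]
        row = row - row.max()  # shift for numerical stability
        e = np.exp(row)
        out[i, idx] = e / e.sum()
    return out
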