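"""Raw input feature vectors for drugs and targets.

Drugs use their fingerprint bit vector.  Targets use amino-acid composition
concatenated with 2-mer frequencies, a standard alignment-free sequence
representation; both are what the encoder's input projection consumes.
"""

from __future__ import annotations

import numpy as np

from .graph import Fingerprint
from .io import AMINO_ACIDS

__all__ = ["drug_feature_matrix", "target_feature_vector",
           "target_feature_matrix"]

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def drug_feature_matrix(fingerprints: list[Fingerprint]) -> np.ndarray:
    return np.vstack([fp.to_vector() for fp in fingerprints])


def target_feature_vector(sequence: str, k: int = 2) -> np.ndarray:
    """Amino-acid composition (20) + k-mer frequencies (20^k); residues
    outside the 20-letter alphabet (e.g. X) are skipped."""
    comp = np.zeros(20)
    kmer = np.zeros(20**k)
    valid = [_AA_INDEX[ch] for ch in sequence if ch in _AA_INDEX]
    for idx in valid:
        comp[idx] += 1
    if valid:
        comp /= len(valid)
    n_kmers = 0
    for i in range(len(valid) - k + 1):
        code = 0
        for j in range(k):
            code = code * 20 + valid[i + j]
        kmer[code] += 1
        n_kmers += 1
    if n_kmers:
        kmer /= n_kmers
    return np.concatenate([comp, kmer])


def target_feature_matrix(sequences: list[str], k: int = 2) -> np.ndarray:
    return np.vstack([target_feature_vector(s, k=k) for s in sequences])
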