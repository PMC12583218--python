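"""Synthetic DTI datasets with planted low-rank + cluster structure.

The generator emulates the statistical structure the method exploits:

* drug and target latent factors drawn around cluster centroids, so entities
  form families;
* an interaction matrix Y marking the top-`density` fraction of the latent
  inner products as positives, with a configurable fraction of labels flipped
  as noise;
* cluster-prototype fingerprints with per-drug bit flips (Tanimoto within a
  cluster exceeds Tanimoto between clusters);
* family-prototype protein sequences with point mutations (normalized local
  alignment within a family exceeds between families);
* auxiliary drug-drug / target-target edges from cluster co-membership with
  edge noise;
* a small ontology tree whose leaves are the cluster labels, with is_a edges
  up the tree and member_of triples from entities to their cluster term.

Everything is reproducible from (config, seed) and writes to the exact
on-disk formats the I/O module reads.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import io as hio
from .graph import Fingerprint

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate", "write_fixture"]


@dataclass
class SyntheticConfig:
    """Standard fixture: 60 x 50 entities, rank 8, 5 clusters per side,
    15% interaction density, 5% label noise."""

    m: int = 60
    n: int = 50
    rank: int = 8
    density: float = 0.15
    noise: float = 0.05
    n_drug_clusters: int = 5
    n_target_families: int = 5
    nbits: int = 128
    fp_density: float = 0.25       # fraction of prototype bits set
    fp_flip_rate: float = 0.05     # per-bit flip probability per drug
    seq_length_range: tuple = (80, 120)
    seq_mutation_rate: float = 0.10
    cluster_spread: float = 0.4    # latent-factor noise around centroids
    edge_noise: float = 0.05       # aux-edge flip probability
    ontology_depth: int = 2


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    seed: int
    drugs: list
    targets: list
    fingerprints: list
    Y: np.ndarray                 # observed (noisy) interaction matrix
    Y_clean: np.ndarray           # pre-noise planted labels
    U: np.ndarray
    V: np.ndarray
    drug_clusters: np.ndarray
    target_families: np.ndarray
    A_DD_aux: np.ndarray
    A_TT_aux: np.ndarray
    kg: hio.KnowledgeGraph

    @property
    def interactions(self) -> hio.InteractionTable:
        table = hio.InteractionTable()
        for i, j in zip(*np.nonzero(self.Y == 1)):
            table.pairs.append((self.drugs[i].id, self.targets[j].id, 1))
        return table


def _cluster_assignments(n_items: int, n_clusters: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Deterministic near-balanced assignment, shuffled."""
    labels = np.arange(n_items) % n_clusters
    rng.shuffle(labels)
    return labels


def _planted_interactions(U, V, density, noise, rng):
    scores = U @ V.T
    m, n = scores.shape
    n_pos = int(round(density * m * n))
    if n_pos < 1:
        raise ValueError("density * m * n must be at least 1")
    flat = scores.ravel()
    cutoff = np.partition(flat, -n_pos)[-n_pos]
    Y_clean = (scores >= cutoff).astype(float)
    # keep exactly n_pos in case of ties at the cutoff
    if Y_clean.sum() > n_pos:
        extra = np.argwhere((scores == cutoff) & (Y_clean == 1))
        drop = extra[: int(Y_clean.sum()) - n_pos]
        Y_clean[tuple(drop.T)] = 0.0
    Y = Y_clean.copy()
    n_flip = int(round(noise * n_pos))
    if n_flip:
        pos_idx = np.argwhere(Y == 1)
        neg_idx = np.argwhere(Y == 0)
        off = pos_idx[rng.choice(len(pos_idx), n_flip, replace=False)]
        on = neg_idx[rng.choice(len(neg_idx), n_flip, replace=False)]
        Y[tuple(off.T)] = 0.0
        Y[tuple(on.T)] = 1.0
    return Y, Y_clean


def _cluster_fingerprints(labels, cfg: SyntheticConfig, rng):
    prototypes = rng.random((labels.max() + 1, cfg.nbits)) < cfg.fp_density
    fps = []
    for lab in labels:
        bits = prototypes[lab].copy()
        flips = rng.random(cfg.nbits) < cfg.fp_flip_rate
        bits ^= flips
        fps.append(Fingerprint(bits=frozenset(np.nonzero(bits)[0].tolist()),
                               nbits=cfg.nbits))
    return fps


def _family_sequences(labels, cfg: SyntheticConfig, rng):
    aa = np.array(list(hio.AMINO_ACIDS))
    lo, hi = cfg.seq_length_range
    protos = {}
    for fam in np.unique(labels):
        length = int(rng.integers(lo, hi + 1))
        protos[fam] = rng.integers(0, 20, size=length)
    seqs = []
    for lab in labels:
        codes = protos[lab].copy()
        mutate = rng.random(len(codes)) < cfg.seq_mutation_rate
        codes[mutate] = rng.integers(0, 20, size=int(mutate.sum()))
        seqs.append("".join(aa[codes]))
    return seqs


def _comembership_edges(labels, edge_noise, rng):
    n = len(labels)
    same = labels[:, None] == labels[None, :]
    flip = rng.random((n, n)) < edge_noise
    flip = np.triu(flip, 1)
    flip = flip | flip.T
    A = (same ^ flip).astype(float)
    np.fill_diagonal(A, 0.0)
    return A


def _ontology(drug_ids, target_ids, drug_clusters, target_families,
              depth: int) -> hio.KnowledgeGraph:
    """Tree of is_a edges over cluster terms plus member_of triples."""
    triples = []
    for prefix, labels, ids in (("DC", drug_clusters, drug_ids),
                                ("TF", target_families, target_ids)):
        root = f"{prefix}:root"
        leaves = [f"{prefix}:{c}" for c in range(labels.max() + 1)]
        parents = leaves
        for level in range(depth - 1, 0, -1):
            groups = max(1, len(parents) // 2)
            new_parents = [f"{prefix}:L{level}_{g}" for g in range(groups)]
            for i, node in enumerate(parents):
                triples.append((node, "is_a", new_parents[i % groups]))
            parents = new_parents
        for node in parents:
            triples.append((node, "is_a", root))
        for entity, lab in zip(ids, labels):
            triples.append((entity, "member_of", f"{prefix}:{lab}"))
    return hio.KnowledgeGraph.from_triples(triples)


def generate(config: SyntheticConfig | None = None,
             seed: int = 7) -> SyntheticDataset:
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    drug_clusters = _cluster_assignments(cfg.m, cfg.n_drug_clusters, rng)
    target_families = _cluster_assignments(cfg.n, cfg.n_target_families, rng)

    centroids_D = rng.normal(size=(cfg.n_drug_clusters, cfg.rank))
    centroids_T = rng.normal(size=(cfg.n_target_families, cfg.rank))
    U = (centroids_D[drug_clusters]
         + cfg.cluster_spread * rng.normal(size=(cfg.m, cfg.rank)))
    V = (centroids_T[target_families]
         + cfg.cluster_spread * rng.normal(size=(cfg.n, cfg.rank)))

    Y, Y_clean = _planted_interactions(U, V, cfg.density, cfg.noise, rng)
    fingerprints = _cluster_fingerprints(drug_clusters, cfg, rng)
    sequences = _family_sequences(target_families, cfg, rng)

    drugs = [hio.Drug(id=f"D{i:03d}", features=fp.to_vector(), index=i)
             for i, fp in enumerate(fingerprints)]
    targets = [hio.Target(id=f"T{j:03d}", sequence=s, index=j)
               for j, s in enumerate(sequences)]

    A_DD_aux = _comembership_edges(drug_clusters, cfg.edge_noise, rng)
    A_TT_aux = _comembership_edges(target_families, cfg.edge_noise, rng)
    kg = _ontology([d.id for d in drugs], [t.id for t in targets],
                   drug_clusters, target_families, cfg.ontology_depth)

    return SyntheticDataset(
        config=cfg, seed=seed, drugs=drugs, targets=targets,
        fingerprints=fingerprints, Y=Y, Y_clean=Y_clean, U=U, V=V,
        drug_clusters=drug_clusters, target_families=target_families,
        A_DD_aux=A_DD_aux, A_TT_aux=A_TT_aux, kg=kg)


def write_fixture(dataset: SyntheticDataset, directory) -> dict:
    """Emit the fixture in the formats the I/O module reads; returns paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "drugs": directory / "drugs.tsv",
        "targets": directory / "targets.fasta",
        "interactions": directory / "interactions.tsv",
        "triples": directory / "triples.tsv",
        "truth": directory / "truth.json",
    }
    hio.write_drug_table(dataset.drugs, paths["drugs"])
    hio.write_fasta(dataset.targets, paths["targets"])
    hio.write_interactions(dataset.interactions, paths["interactions"])
    hio.write_kg_triples(dataset.kg, paths["triples"])
    truth = {
        "seed": dataset.seed,
        "config": asdict(dataset.config),
        "U": dataset.U.tolist(),
        "V": dataset.V.tolist(),
        "clean_positives": [
            [int(i), int(j)] for i, j in zip(*np.nonzero(dataset.Y_clean))
        ],
        "drug_clusters": dataset.drug_clusters.tolist(),
        "target_families": dataset.target_families.tolist(),
    }
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    return paths
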