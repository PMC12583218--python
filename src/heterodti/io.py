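"""Readers and writers for the on-disk artifacts of a DTI study.

Drug tables, interaction edge lists and knowledge-graph triples are TSV with a
header row; protein sequences are FASTA.  Entity ordering is file order and is
what gives every downstream matrix its row/column meaning, so it is preserved
exactly and recorded by index on each entity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field


import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = set(AMINO_ACIDS) | {"X"}


@dataclass
class Drug:
    """A small molecule: identifier, optional SMILES, optional feature vector."""

    id: str
    smiles: str | None = None
    features: np.ndarray | None = None
    index: int = -1


@dataclass
class Target:
    """A protein target: identifier, optional sequence, optional features."""

    id: str
    sequence: str | None = None
    features: np.ndarray | None = None
    index: int = -1


@dataclass
class InteractionTable:
    """Labeled (drug, target) pairs; label 1 = observed interaction.

    The optional per-pair confidence is parsed and stored for audit but is not
    consumed by any loss term.
    """

    pairs: list[tuple[str, str, int]] = field(default_factory=list)
    confidence: dict[tuple[str, str], float] = field(default_factory=dict)

    def to_matrix(self, drugs: list[Drug], targets: list[Target]) -> np.ndarray:
        """Dense 0/1 interaction matrix Y (m x n) in entity-index order."""
        d_idx = {d.id: d.index for d in drugs}
        t_idx = {t.id: t.index for t in targets}
        Y = np.zeros((len(drugs), len(targets)))
        for did, tid, label in self.pairs:
            Y[d_idx[did], t_idx[tid]] = label
        return Y


@dataclass
class KnowledgeGraph:
    """Deduplicated (head, relation, tail) triples plus entity/relation maps."""

    triples: list[tuple[str, str, str]] = field(default_factory=list)
    entity_index: dict[str, int] = field(default_factory=dict)
    relations: list[str] = field(default_factory=list)

    @classmethod
    def from_triples(cls, triples) -> "KnowledgeGraph":
        seen = set()
        unique = []
        for t in triples:
            if t not in seen:
                seen.add(t)
                unique.append(t)
        entity_index: dict[str, int] = {}
        relations: list[str] = []
        for h, r, t in unique:
            for e in (h, t):
                if e not in entity_index:
                    entity_index[e] = len(entity_index)
            if r not in relations:
                relations.append(r)
        return cls(unique, entity_index, relations)


def read_drug_table(path) -> list[Drug]:
    """Read a TSV drug table with columns `id`, optionally `smiles` and/or
    feature columns (any column named `f*` or numeric)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if "id" not in df.columns:
        raise ValueError(f"{path}: drug table needs an 'id' column")
    dup = df["id"][df["id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate drug id {dup.iloc[0]!r}")
    feature_cols = [c for c in df.columns if c not in ("id", "smiles")]
    drugs = []
    for i, row in enumerate(df.itertuples(index=False)):
        smiles = getattr(row, "smiles", None)
        if isinstance(smiles, float) and np.isnan(smiles):
            smiles = None
        feats = None
        if feature_cols:
            feats = np.asarray(
                [getattr(row, c) for c in feature_cols], dtype=float
            )
            if not np.all(np.isfinite(feats)):
                raise ValueError(f"{path}: non-finite features for drug {row.id}")
        drugs.append(Drug(id=str(row.id), smiles=smiles, features=feats, index=i))
    return drugs


def read_fasta(path) -> list[Target]:
    """Read targets from FASTA; record id = first header token, sequences
    uppercased, characters outside the amino-acid alphabet logged and kept
    as 'X'."""
    targets = []
    for i, record in enumerate(SeqIO.parse(str(path), "fasta")):
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"{path}: empty sequence for record {record.id!r}")
        cleaned = []
        for ch in seq:
            if ch not in _AA_SET:
                logger.warning("record %s: illegal residue %r kept as 'X'",
                               record.id, ch)
                ch = "X"
            cleaned.append(ch)
        targets.append(Target(id=record.id, sequence="".join(cleaned), index=i))
    return targets


def read_interactions(path, drugs: list[Drug],
                      targets: list[Target]) -> InteractionTable:
    """Read a (drug_id, target_id[, label][, confidence]) TSV.

    A missing label column means every listed pair is a positive; everything
    unlisted is unlabeled (positive-unlabeled framing).
    """
    df = pd.read_csv(path, sep="\t", dtype={"drug_id": str, "target_id": str})
    for col in ("drug_id", "target_id"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    drug_ids = {d.id for d in drugs}
    target_ids = {t.id for t in targets}
    table = InteractionTable()
    seen: dict[tuple[str, str], int] = {}
    for rownum, row in enumerate(df.itertuples(index=False), start=2):
        did, tid = str(row.drug_id), str(row.target_id)
        if did not in drug_ids:
            raise ValueError(f"{path} row {rownum}: unknown drug id {did!r}")
        if tid not in target_ids:
            raise ValueError(f"{path} row {rownum}: unknown target id {tid!r}")
        label = int(getattr(row, "label", 1))
        if label not in (0, 1):
            raise ValueError(f"{path} row {rownum}: label must be 0 or 1")
        key = (did, tid)
        if key in seen:
            if seen[key] != label:
                raise ValueError(
                    f"{path} row {rownum}: pair {key} has conflicting labels")
            continue
        seen[key] = label
        table.pairs.append((did, tid, label))
        conf = getattr(row, "confidence", None)
        if conf is not None and np.isfinite(conf):
            table.confidence[key] = float(conf)
    return table


def read_kg_triples(path) -> KnowledgeGraph:
    """Read (head, relation, tail) TSV into a deduplicated knowledge graph."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("head", "relation", "tail"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    triples = []
    for rownum, row in enumerate(df.itertuples(index=False), start=2):
        vals = (row.head, row.relation, row.tail)
        if any(v is None or (isinstance(v, float) and np.isnan(v)) or
               str(v).strip() == "" for v in vals):
            raise ValueError(f"{path} row {rownum}: blank field in triple")
        triples.append(tuple(str(v) for v in vals))
    return KnowledgeGraph.from_triples(triples)


def write_interactions(table: InteractionTable, path) -> None:
    rows = [{"drug_id": d, "target_id": t, "label": y} for d, t, y in table.pairs]
    df = pd.DataFrame(rows, columns=["drug_id", "target_id", "label"])
    if table.confidence:
        df["confidence"] = [
            table.confidence.get((d, t), np.nan) for d, t, _ in table.pairs
        ]
    df.to_csv(path, sep="\t", index=False)


def write_predictions(scored_pairs, path) -> None:
    """Write (drug_id, target_id, score) rows sorted by descending score;
    ties broken lexicographically by (drug_id, target_id)."""
    for did, tid, score in scored_pairs:
        if not np.isfinite(score):
            raise ValueError(f"non-finite score for pair ({did}, {tid})")
    ordered = sorted(scored_pairs, key=lambda p: (-p[2], p[0], p[1]))
    df = pd.DataFrame(ordered, columns=["drug_id", "target_id", "score"])
    df.to_csv(path, sep="\t", index=False)


def write_fasta(targets: list[Target], path) -> None:
    with open(path, "w") as fh:
        for t in targets:
            fh.write(f">{t.id}\n{t.sequence}\n")


def write_drug_table(drugs: list[Drug], path) -> None:
    rows = []
    for d in drugs:
        row = {"id": d.id}
        if d.smiles is not None:
            row["smiles"] = d.smiles
        if d.features is not None:
            for k, v in enumerate(d.features):
                row[f"f{k}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_kg_triples(kg: KnowledgeGraph, path) -> None:
    pd.DataFrame(kg.triples, columns=["head", "relation", "tail"]).to_csv(
        path, sep="\t", index=False)


def read_similarity_tsv(path, entity_ids: list[str]) -> np.ndarray:
    """Read a precomputed similarity matrix (first column = row id, header =
    column ids) and align it to the given entity ordering."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    missing = [e for e in entity_ids if e not in df.index
               or e not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing entities {missing[:5]}")
    S = df.loc[entity_ids, entity_ids].to_numpy(dtype=float)
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError(f"{path}: similarity matrix is not symmetric")
    return S


def write_similarity_tsv(S: np.ndarray, entity_ids: list[str], path) -> None:
    pd.DataFrame(S, index=entity_ids, columns=entity_ids).to_csv(
        path, sep="\t")


def write_negative_set(negative_set, drugs: list[Drug],
                       targets: list[Target], path) -> None:
    """Audit export of a negative sample set: one row per pair with its
    reliability, importance weight and refinement generation."""
    rows = [{
        "drug_id": drugs[i].id, "target_id": targets[j].id,
        "reliability": r, "weight": w,
        "generation": negative_set.generation,
    } for (i, j), r, w in zip(negative_set.pairs, negative_set.reliability,
                              negative_set.weight)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
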