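"""The DTI prediction estimator.

`DTIPredictor` is a scikit-learn-style estimator: `fit(X, y, data=...)` takes
(drug index, target index) pairs with 0/1 labels plus a `DTIData` bundle of
entity features, similarity networks and an optional knowledge graph;
`decision_function` / `predict_proba` score arbitrary pairs, including cold
entities, from the embeddings the heterogeneous-graph encoder computed over
the full entity set.

Training minimizes

    L = L_weighted + lambda_rec * L_rec + lambda_kg * L_kg (+ gamma_reg * L_reg)

with the adaptive-moment optimizer: the importance-weighted interaction loss
over positives and reliability-sampled negatives, the feature reconstruction
loss of the encoder, the margin ranking loss over knowledge-graph triples,
and (when dataset adaptation is enabled) the Frobenius divergence of the
adapted networks from the global ones.  Negatives are refreshed every
`refresh_interval` epochs once model predictions can veto unreliable ones;
early stopping tracks validation AUPR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator

from . import adaptation as adapt_mod
from . import encoder as enc
from . import knowledge as kg_mod
from . import metrics as metrics_mod
from . import sampling
from .autodiff import Adam, Tensor, concat_rows
from .graph import (UnifiedGraph, assemble_unified, aggregate_edge_types,
                    EdgeTypeSet, threshold_adjacency, normalized_seq_similarity,
                    tanimoto)
from .io import KnowledgeGraph

logger = logging.getLogger(__name__)

__all__ = ["DTIData", "DTIPredictor", "total_loss", "predict_scores",
           "chemical_similarity_matrix", "sequence_similarity_matrix"]


def chemical_similarity_matrix(fingerprints) -> np.ndarray:
    """Pairwise Tanimoto similarity over a fingerprint list."""
    n = len(fingerprints)
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = tanimoto(fingerprints[i], fingerprints[j])
    return S


def sequence_similarity_matrix(sequences, substitution="BLOSUM62",
                               gap_open=11.0, gap_extend=1.0) -> np.ndarray:
    """Pairwise normalized Smith-Waterman similarity (self scores cached)."""
    from .graph import smith_waterman

    n = len(sequences)
    self_scores = np.array([
        smith_waterman(s, s, substitution, gap_open, gap_extend)
        for s in sequences
    ])
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            cross = smith_waterman(sequences[i], sequences[j], substitution,
                                   gap_open, gap_extend)
            denom = min(self_scores[i], self_scores[j])
            S[i, j] = S[j, i] = (np.clip(cross / denom, 0.0, 1.0)
                                 if denom > 0 else 0.0)
    return S


@dataclass
class DTIData:
    """Everything about the entities that is independent of the split:
    raw features, similarity networks, auxiliary adjacencies, and the
    knowledge graph."""

    X_D: np.ndarray
    X_T: np.ndarray
    S_chem: np.ndarray
    S_seq: np.ndarray
    aux_DD: list = field(default_factory=list)
    aux_TT: list = field(default_factory=list)
    kg: KnowledgeGraph | None = None
    drug_ids: list | None = None
    target_ids: list | None = None

    @property
    def m(self) -> int:
        return self.X_D.shape[0]

    @property
    def n(self) -> int:
        return self.X_T.shape[0]

    @classmethod
    def from_synthetic(cls, dataset, seq_scoring=(2, -1), gap_open=1.0,
                       gap_extend=1.0) -> "DTIData":
        """Bundle a synthetic dataset; toy match/mismatch alignment scoring
        keeps the similarity matrix fast to build."""
        from .features import target_feature_matrix

        return cls(
            X_D=np.vstack([d.features for d in dataset.drugs]),
            X_T=target_feature_matrix(
                [t.sequence for t in dataset.targets]),
            S_chem=chemical_similarity_matrix(dataset.fingerprints),
            S_seq=sequence_similarity_matrix(
                [t.sequence for t in dataset.targets], seq_scoring,
                gap_open, gap_extend),
            aux_DD=[dataset.A_DD_aux],
            aux_TT=[dataset.A_TT_aux],
            kg=dataset.kg,
            drug_ids=[d.id for d in dataset.drugs],
            target_ids=[t.id for t in dataset.targets],
        )


def predict_scores(Z_D: np.ndarray, Z_T: np.ndarray, pairs: np.ndarray,
                   bias: float = 0.0) -> np.ndarray:
    """Raw interaction scores z_Di . z_Tj (+ fitted score bias) per pair."""
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    return np.einsum("ij,ij->i", Z_D[pairs[:, 0]], Z_T[pairs[:, 1]]) + bias


def total_loss(components: dict, lambda_rec: float, lambda_kg: float,
               gamma_reg: float = 0.0) -> float:
    """Combine independently computed loss components into the objective."""
    for name, value in components.items():
        if not np.isfinite(value):
            raise FloatingPointError(f"non-finite loss component {name!r}")
    return (components.get("interaction", 0.0)
            + lambda_rec * components.get("reconstruction", 0.0)
            + lambda_kg * components.get("kg", 0.0)
            + gamma_reg * components.get("adaptation", 0.0))


class DTIPredictor(BaseEstimator):
    """Heterogeneous-graph DTI predictor with KG regularization.

    Parameters mirror the framework's hyperparameters: embedding width and
    depth of the encoder, attention on/off, the reliability-based negative
    sampler, the knowledge-graph ranking regularizer and the optional
    dataset adaptation stage.  `random_state` seeds every stream (parameter
    init, negative sampling, corruption, validation sampling) through
    independent substreams, so fits are reproducible.
    """

    def __init__(self, embedding_dim=64, n_layers=2, use_attention=True,
                 renormalize_attention=True, similarity_threshold=0.5,
                 use_kg=True, lambda_kg=0.1, margin=1.0,
                 corruptions_per_triple=1, kg_scoring="bilinear",
                 lambda_rec=0.01, learning_rate=0.005, weight_decay=0.0005,
                 max_epochs=300, patience=80, negative_sampling="combined",
                 sampler_alpha=0.5, sampler_beta=0.5, sampler_gamma=4.0,
                 theta_neg=0.5, theta_rel=0.5, refresh_interval=50,
                 negative_ratio=5.0, negative_term_scale="balanced",
                 adapt_networks=False, gamma_reg=0.1,
                 validation_fraction=0.1, val_negative_ratio=5.0,
                 random_state=0):
        self.embedding_dim = embedding_dim
        self.n_layers = n_layers
        self.use_attention = use_attention
        self.renormalize_attention = renormalize_attention
        self.similarity_threshold = similarity_threshold
        self.use_kg = use_kg
        self.lambda_kg = lambda_kg
        self.margin = margin
        self.corruptions_per_triple = corruptions_per_triple
        self.kg_scoring = kg_scoring
        self.lambda_rec = lambda_rec
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.max_epochs = max_epochs
        self.patience = patience
        self.negative_sampling = negative_sampling
        self.sampler_alpha = sampler_alpha
        self.sampler_beta = sampler_beta
        self.sampler_gamma = sampler_gamma
        self.theta_neg = theta_neg
        self.theta_rel = theta_rel
        self.refresh_interval = refresh_interval
        self.negative_ratio = negative_ratio
        self.negative_term_scale = negative_term_scale
        self.adapt_networks = adapt_networks
        self.gamma_reg = gamma_reg
        self.validation_fraction = validation_fraction
        self.val_negative_ratio = val_negative_ratio
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _sampler_config(self) -> sampling.SamplerConfig:
        return sampling.SamplerConfig(
            alpha=self.sampler_alpha, beta=self.sampler_beta,
            gamma_temp=self.sampler_gamma, theta_neg=self.theta_neg,
            theta_rel=self.theta_rel, refresh_interval=self.refresh_interval,
            ratio=self.negative_ratio)

    def _build_graph(self, data: DTIData,
                     Y_train: np.ndarray) -> tuple[UnifiedGraph, dict]:
        nets_DD = [threshold_adjacency(data.S_chem,
                                       self.similarity_threshold)]
        nets_DD += [np.asarray(A, float) for A in data.aux_DD]
        nets_TT = [threshold_adjacency(data.S_seq, self.similarity_threshold)]
        nets_TT += [np.asarray(A, float) for A in data.aux_TT]
        info: dict = {"adapted": False}

        if self.adapt_networks and (len(nets_DD) + len(nets_TT)) > 2:
            info.update(self._adapt(nets_DD, nets_TT, Y_train))
            A_DD = adapt_mod.adapt_adjacency(nets_DD, info["lambda_DD"])
            A_TT = adapt_mod.adapt_adjacency(nets_TT, info["lambda_TT"])
        else:
            A_DD = aggregate_edge_types(EdgeTypeSet(nets_DD,
                                                    klass="drug-drug"))
            A_TT = aggregate_edge_types(EdgeTypeSet(nets_TT,
                                                    klass="target-target"))
        graph = assemble_unified(A_DD, A_TT, Y_train)
        info["n_edges_DD"] = int(np.count_nonzero(A_DD))
        info["n_edges_TT"] = int(np.count_nonzero(A_TT))
        return graph, info

    def _adapt(self, nets_DD, nets_TT, Y_train) -> dict:
        """Two-stage adaptation: learn combination weights on a propagation
        objective over the training interactions, then freeze them."""
        networks = nets_DD + nets_TT
        n_dd = len(nets_DD)
        pos = np.argwhere(Y_train == 1)
        neg_mask = Y_train == 0
        neg = np.argwhere(neg_mask)
        labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
        pairs = np.vstack([pos, neg])

        def objective(lam):
            A_DD = adapt_mod.adapt_adjacency(nets_DD, lam[:n_dd])
            A_TT = adapt_mod.adapt_adjacency(nets_TT, lam[n_dd:])
            row_D = A_DD.sum(axis=1, keepdims=True)
            row_T = A_TT.sum(axis=1, keepdims=True)
            P = (np.divide(A_DD, row_D, out=np.zeros_like(A_DD),
                           where=row_D > 0) @ Y_train
                 + Y_train @ np.divide(A_TT, row_T, out=np.zeros_like(A_TT),
                                       where=row_T > 0).T)
            scores = P[pairs[:, 0], pairs[:, 1]]
            return 1.0 - metrics_mod.aupr(labels, scores)

        lam, trace = adapt_mod.learn_combination_weights(
            networks, objective, adapt_mod.MetaConfig(max_iter=100))
        alphas = adapt_mod.alpha_coefficients(networks)
        adapted = ([adapt_mod.adapt_adjacency([A], lam[k:k + 1])
                    for k, A in enumerate(nets_DD)]
                   + [adapt_mod.adapt_adjacency([A], lam[n_dd + k:n_dd + k + 1])
                      for k, A in enumerate(nets_TT)])
        L_reg = adapt_mod.adaptation_regularizer(adapted, networks, alphas)
        return {"adapted": True, "lambda_DD": lam[:n_dd],
                "lambda_TT": lam[n_dd:], "alphas": alphas,
                "adaptation_loss": float(L_reg),
                "meta_trace_length": len(trace)}

    # ------------------------------------------------------------------
    def fit(self, X, y, data: DTIData = None, val_X=None, val_y=None):
        if data is None:
            raise ValueError("fit requires the data= bundle of entity "
                             "features and networks")
        X = np.asarray(X, dtype=int).reshape(-1, 2)
        y = np.asarray(y, dtype=int).ravel()
        if len(X) != len(y):
            raise ValueError("X and y must align")
        m, n = data.m, data.n
        h = self.embedding_dim

        seeds = np.random.SeedSequence(self.random_state).spawn(5)
        rng_init, rng_sampler, rng_corrupt, rng_val, rng_meta = (
            np.random.default_rng(s) for s in seeds)

        # -- positives, validation carve-out, interaction matrix ---------
        pos_pairs = X[y == 1]
        if val_X is None:
            n_val = max(1, int(round(self.validation_fraction
                                     * len(pos_pairs))))
            perm = rng_val.permutation(len(pos_pairs))
            val_pos = pos_pairs[perm[:n_val]]
            train_pos = pos_pairs[perm[n_val:]]
        else:
            val_X = np.asarray(val_X, dtype=int).reshape(-1, 2)
            val_y = np.asarray(val_y, dtype=int).ravel()
            val_pos = val_X[val_y == 1]
            train_pos = pos_pairs
        Y_train = np.zeros((m, n))
        Y_train[train_pos[:, 0], train_pos[:, 1]] = 1.0

        graph, graph_info = self._build_graph(data, Y_train)
        self.graph_ = graph
        self.graph_info_ = graph_info

        # -- unlabeled universe and reliability ---------------------------
        sampler_cfg = self._sampler_config()
        unl_mask = Y_train == 0
        if len(val_pos):  # validation positives are never negative candidates
            unl_mask[val_pos[:, 0], val_pos[:, 1]] = False
        rel = sampling.reliability_matrix(Y_train, data.S_chem, data.S_seq,
                                          sampler_cfg)
        unlabeled = np.argwhere(unl_mask)
        unl_rel = rel[unl_mask]

        if self.negative_sampling == "random":
            k = min(int(round(sampler_cfg.ratio * len(train_pos))),
                    len(unlabeled))
            chosen = rng_sampler.choice(len(unlabeled), size=k, replace=False)
            neg_set = sampling.NegativeSampleSet(
                pairs=unlabeled[chosen], reliability=unl_rel[chosen],
                weight=np.full(k, 1.0 / k), generation=0)
        else:
            neg_set = sampling.initial_negative_set(
                unlabeled, unl_rel, len(train_pos), sampler_cfg, rng_sampler)

        # -- validation pairs for early stopping --------------------------
        if val_X is not None:
            # caller supplies labeled validation pairs (e.g. a CV fold)
            val_pairs, val_labels = val_X, val_y
        else:
            n_val_neg = min(int(round(self.val_negative_ratio
                                      * len(val_pos))), len(unlabeled))
            val_neg = unlabeled[rng_val.choice(len(unlabeled),
                                               size=n_val_neg, replace=False)]
            val_pairs = np.vstack([val_pos, val_neg])
            val_labels = np.concatenate([np.ones(len(val_pos)),
                                         np.zeros(len(val_neg))])

        # -- parameters ----------------------------------------------------
        d, t = data.X_D.shape[1], data.X_T.shape[1]
        params = enc.init_encoder_params(d, t, h, self.n_layers, rng_init)
        score_bias = Tensor(np.zeros(()), requires_grad=True)
        trainables = params.parameters() + [score_bias]

        kg_state = None
        if self.use_kg and data.kg is not None and data.kg.triples:
            kg_state = self._prepare_kg(data, h, rng_init)
            trainables += [kg_state["free"], kg_state["R"]]

        lambda_rec = (1.0 / (m * d + n * t) if self.lambda_rec == "auto"
                      else float(self.lambda_rec))
        gamma_reg = self.gamma_reg if graph_info.get("adapted") else 0.0
        reg_const = graph_info.get("adaptation_loss", 0.0)

        optimizer = Adam(trainables, lr=self.learning_rate,
                         weight_decay=self.weight_decay)

        history: list[dict] = []
        best = {"aupr": -np.inf, "epoch": -1, "state": None}
        neg_scale = (len(train_pos) if self.negative_term_scale == "balanced"
                     else 1.0)

        for epoch in range(self.max_epochs):
            # periodic negative refinement (combined strategy only)
            if (self.negative_sampling == "combined" and epoch > 0
                    and epoch % sampler_cfg.refresh_interval == 0):
                with np.errstate(over="ignore"):
                    preds = predict_scores(self._Z_D_np, self._Z_T_np,
                                           unlabeled, self._bias_np)
                neg_set = sampling.refine_negatives(
                    unlabeled, preds, unl_rel, sampler_cfg, neg_set)

            optimizer.zero_grad()
            Z_D, Z_T = enc.encode(data.X_D, data.X_T, graph, params,
                                  use_attention=self.use_attention,
                                  renormalize=self.renormalize_attention)

            all_pairs = np.vstack([train_pos, neg_set.pairs])
            scores = (Z_D.take_rows(all_pairs[:, 0])
                      * Z_T.take_rows(all_pairs[:, 1])).sum(axis=1) + score_bias
            n_pos = len(train_pos)
            pos_scores = scores.take_rows(np.arange(n_pos))
            neg_scores = scores.take_rows(np.arange(n_pos, len(all_pairs)))
            w = Tensor(neg_set.weight * neg_scale)
            L_int = (-pos_scores.log_sigmoid().sum()
                     - (w * (-neg_scores).log_sigmoid()).sum())

            L_rec = enc.reconstruction_loss(Z_D, Z_T, data.X_D, data.X_T,
                                            params)
            loss = L_int + lambda_rec * L_rec
            L_kg_val = 0.0
            if kg_state is not None:
                L_kg = self._kg_loss(Z_D, Z_T, kg_state, rng_corrupt)
                loss = loss + self.lambda_kg * L_kg
                L_kg_val = float(L_kg.data)
            loss.backward()
            optimizer.step()

            self._Z_D_np, self._Z_T_np = Z_D.data, Z_T.data
            self._bias_np = float(score_bias.data)
            total = total_loss(
                {"interaction": float(L_int.data),
                 "reconstruction": float(L_rec.data),
                 "kg": L_kg_val, "adaptation": reg_const},
                lambda_rec, self.lambda_kg if kg_state else 0.0, gamma_reg)

            val_scores = predict_scores(self._Z_D_np, self._Z_T_np,
                                        val_pairs, self._bias_np)
            val_aupr = metrics_mod.aupr(val_labels, val_scores)
            history.append({
                "epoch": epoch, "loss_total": total,
                "loss_interaction": float(L_int.data),
                "loss_reconstruction": float(L_rec.data),
                "loss_kg": L_kg_val, "loss_adaptation": reg_const,
                "val_aupr": float(val_aupr),
                "n_negatives": len(neg_set),
                "negative_generation": neg_set.generation,
            })
            if not np.isfinite(total):
                logger.error("divergence at epoch %d; stopping on last "
                             "good checkpoint", epoch)
                break
            if val_aupr > best["aupr"]:
                best = {"aupr": val_aupr, "epoch": epoch,
                        "state": ([p.data.copy() for p in trainables])}
            elif epoch - best["epoch"] >= self.patience:
                break

        if best["state"] is not None:
            for p, saved in zip(trainables, best["state"]):
                p.data = saved
        Z_D, Z_T = enc.encode(data.X_D, data.X_T, graph, params,
                              use_attention=self.use_attention,
                              renormalize=self.renormalize_attention)
        self.Z_drug_ = Z_D.data
        self.Z_target_ = Z_T.data
        self.score_bias_ = float(score_bias.data)
        self.params_ = params
        self.kg_state_ = kg_state
        self.history_ = history
        self.best_epoch_ = best["epoch"]
        self.best_val_aupr_ = float(best["aupr"])
        self.negative_set_ = neg_set
        self.n_features_in_ = 2
        return self

    def _prepare_kg(self, data: DTIData, h: int,
                    rng: np.random.Generator) -> dict:
        """Index KG entities: drugs/targets share encoder embeddings, pure
        ontology terms get free vectors trained only by the ranking loss."""
        m, n = data.m, data.n
        entity_index: dict[str, int] = {}
        for i, did in enumerate(data.drug_ids or []):
            entity_index[did] = i
        for j, tid in enumerate(data.target_ids or []):
            entity_index[tid] = m + j
        free_terms = [e for e in data.kg.entity_index
                      if e not in entity_index]
        for k, term in enumerate(free_terms):
            entity_index[term] = m + n + k
        limit = np.sqrt(6.0 / (2 * h))
        free = Tensor(rng.uniform(-limit, limit, size=(len(free_terms), h)),
                      requires_grad=True)
        R = Tensor(rng.uniform(-limit, limit,
                               size=(len(data.kg.relations), h)),
                   requires_grad=True)
        triples = kg_mod.triples_to_indices(data.kg, entity_index)
        known = {tuple(row) for row in triples}
        return {"free": free, "R": R, "triples": triples, "known": known,
                "entity_index": entity_index, "n_entities": m + n
                + len(free_terms)}

    def _kg_loss(self, Z_D: Tensor, Z_T: Tensor, kg_state: dict,
                 rng: np.random.Generator) -> Tensor:
        triples = kg_state["triples"]
        corr = kg_mod.corrupt(triples, kg_state["n_entities"],
                              self.corruptions_per_triple,
                              kg_state["known"], rng)
        Z_all = concat_rows([Z_D, Z_T, kg_state["free"]])
        rel_true = kg_state["R"].take_rows(triples[:, 1])
        rel_corr = kg_state["R"].take_rows(corr[:, 1])
        f_true = kg_mod.score_triples(Z_all, triples[:, 0], rel_true,
                                      triples[:, 2], self.kg_scoring)
        f_corr = kg_mod.score_triples(Z_all, corr[:, 0], rel_corr,
                                      corr[:, 2], self.kg_scoring)
        return kg_mod.kg_ranking_loss(f_true, f_corr, self.margin,
                                      self.corruptions_per_triple)

    # ------------------------------------------------------------------
    def decision_function(self, X) -> np.ndarray:
        self._check_fitted()
        return predict_scores(self.Z_drug_, self.Z_target_, X,
                              self.score_bias_)

    def predict_proba(self, X) -> np.ndarray:
        p = expit(self.decision_function(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= 0.0).astype(int)

    def score(self, X, y) -> float:
        """Validation-style score: AUPR over the given labeled pairs."""
        return metrics_mod.aupr(np.asarray(y), self.decision_function(X))

    def _check_fitted(self):
        if not hasattr(self, "Z_drug_"):
            raise RuntimeError("estimator is not fitted")
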