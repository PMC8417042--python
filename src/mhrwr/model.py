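"""Scikit-learn-style estimator wrapping the full pipeline.

:class:`MHRWRLDA` takes a binary association matrix (plus, optionally, a
disease ontology and disease-to-term mapping and/or precomputed layers),
builds the similarity layers and the global transition matrix at fit time,
and ranks candidates per query at predict time.  It is a transductive link
ranker: ``fit`` fixes the node universe and ``predict_for_disease`` /
``predict_for_lncrna`` score the held-out bipartite edges.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from . import rwr, similarity
from .containers import (
    AssociationMatrix,
    OntologyDAG,
    RankedPredictions,
    RWRParams,
    SimilarityMatrix,
)

logger = logging.getLogger(__name__)

__all__ = ["MHRWRLDA", "compute_layers"]


def compute_layers(
    ld: AssociationMatrix,
    ontology: OntologyDAG | None = None,
    term_map: Mapping[str, str] | None = None,
    *,
    semantic_decay: float = 0.5,
    gamma_prime: float = 1.0,
    use_semantic: bool = True,
    use_functional: bool = True,
    use_lncrna_gip: bool = True,
    use_disease_gip: bool = True,
    precomputed_dss: SimilarityMatrix | None = None,
    extra_lncrna_layers: Sequence[SimilarityMatrix] = (),
    extra_disease_layers: Sequence[SimilarityMatrix] = (),
) -> tuple[list[SimilarityMatrix], list[SimilarityMatrix], SimilarityMatrix | None]:
    """Assemble the similarity layers of both multiplexes.

    Returns ``(lncrna_layers, disease_layers, dss)``.  The semantic layer
    (and the functional layer derived from it) requires an ontology with a
    disease-to-term mapping, or a precomputed semantic similarity matrix;
    without one, those layers are skipped and only the GIP layers remain.
    """
    dss = precomputed_dss
    if dss is None and ontology is not None and term_map is not None:
        mapped = {d: t for d, t in term_map.items() if d in set(ld.disease_ids)}
        unmapped = [d for d in ld.disease_ids if d not in mapped]
        if unmapped:
            logger.warning(
                "%d/%d diseases have no ontology mapping; their semantic "
                "similarity is 0 off-diagonal", len(unmapped), ld.n_diseases,
            )
        dss = similarity.disease_semantic_similarity(
            ontology, ld.disease_ids, mapped, semantic_decay
        )

    disease_layers: list[SimilarityMatrix] = []
    if use_semantic and dss is not None:
        disease_layers.append(dss)
    if use_disease_gip:
        disease_layers.append(similarity.gip_similarity(ld, "disease", gamma_prime))
    disease_layers.extend(extra_disease_layers)

    lncrna_layers: list[SimilarityMatrix] = []
    if use_functional and dss is not None:
        lncrna_layers.append(similarity.lncrna_functional_similarity(ld, dss))
    if use_lncrna_gip:
        lncrna_layers.append(similarity.gip_similarity(ld, "lncrna", gamma_prime))
    lncrna_layers.extend(extra_lncrna_layers)

    if not lncrna_layers or not disease_layers:
        raise ValueError("at least one layer per side must be enabled")
    return lncrna_layers, disease_layers, dss


class MHRWRLDA(BaseEstimator):
    """Multiplex-heterogeneous random walk with restart for association ranking.

    Parameters
    ----------
    gamma : float, default 0.9
        Restart probability.
    lambda_ : float, default 0.9
        Cross-network jump probability through known associations.
    eta : float, default 0.9
        Restart weight of the query's own side.
    delta : float, default 0.5
        Inter-layer jump probability within each multiplex.
    semantic_decay : float, default 0.5
        Per-edge decay of ontology semantic contributions.
    gamma_prime : float, default 1.0
        GIP bandwidth numerator.
    tol, max_iter
        Power-iteration convergence control.
    use_semantic, use_functional, use_lncrna_gip, use_disease_gip : bool
        Layer-selection flags.

    Attributes
    ----------
    ld_ : AssociationMatrix
        The fitted association matrix.
    lncrna_layers_, disease_layers_ : list of SimilarityMatrix
        The assembled multiplex layers.
    dss_ : SimilarityMatrix or None
        Disease semantic similarity, if an ontology was supplied.
    transition_ : TransitionMatrix
        The global row-stochastic transition matrix H.
    """

    def __init__(
        self,
        gamma: float = 0.9,
        lambda_: float = 0.9,
        eta: float = 0.9,
        delta: float = 0.5,
        semantic_decay: float = 0.5,
        gamma_prime: float = 1.0,
        tol: float = 1e-10,
        max_iter: int = 10000,
        use_semantic: bool = True,
        use_functional: bool = True,
        use_lncrna_gip: bool = True,
        use_disease_gip: bool = True,
    ) -> None:
        self.gamma = gamma
        self.lambda_ = lambda_
        self.eta = eta
        self.delta = delta
        self.semantic_decay = semantic_decay
        self.gamma_prime = gamma_prime
        self.tol = tol
        self.max_iter = max_iter
        self.use_semantic = use_semantic
        self.use_functional = use_functional
        self.use_lncrna_gip = use_lncrna_gip
        self.use_disease_gip = use_disease_gip

    @property
    def params_(self) -> RWRParams:
        return RWRParams(
            gamma=self.gamma,
            lambda_=self.lambda_,
            eta=self.eta,
            delta=self.delta,
            tol=self.tol,
            max_iter=self.max_iter,
        )

    def fit(
        self,
        X: AssociationMatrix,
        y: None = None,
        *,
        ontology: OntologyDAG | None = None,
        term_map: Mapping[str, str] | None = None,
        precomputed_dss: SimilarityMatrix | None = None,
        extra_lncrna_layers: Sequence[SimilarityMatrix] = (),
        extra_disease_layers: Sequence[SimilarityMatrix] = (),
    ) -> "MHRWRLDA":
        """Build similarity layers and the global transition matrix."""
        params = self.params_  # validates the walk parameters
        self.ld_ = X
        self.lncrna_layers_, self.disease_layers_, self.dss_ = compute_layers(
            X,
            ontology,
            term_map,
            semantic_decay=self.semantic_decay,
            gamma_prime=self.gamma_prime,
            use_semantic=self.use_semantic,
            use_functional=self.use_functional,
            use_lncrna_gip=self.use_lncrna_gip,
            use_disease_gip=self.use_disease_gip,
            precomputed_dss=precomputed_dss,
            extra_lncrna_layers=extra_lncrna_layers,
            extra_disease_layers=extra_disease_layers,
        )
        from .multiplex import build_supra_adjacency, build_transition_matrix

        self.supra_lncrna_ = build_supra_adjacency(self.lncrna_layers_, params.delta)
        self.supra_disease_ = build_supra_adjacency(self.disease_layers_, params.delta)
        self.transition_ = build_transition_matrix(
            self.supra_lncrna_, self.supra_disease_, X, params.lambda_
        )
        logger.info(
            "fitted: %d lncRNAs x %d layers, %d diseases x %d layers, "
            "%d known associations",
            X.n_lncrnas, len(self.lncrna_layers_),
            X.n_diseases, len(self.disease_layers_),
            int(X.values.sum()),
        )
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "transition_"):
            raise RuntimeError("estimator is not fitted; call fit() first")

    def _query(self, query: str, side: str) -> RankedPredictions:
        self._check_fitted()
        ld = self.ld_
        params = self.params_
        if side == "disease":
            j = ld.disease_index(query)
            seeds = ld.lncrnas_of(query)
            seed_idx = [ld.lncrna_index(l) for l in seeds]
        else:
            j = ld.lncrna_index(query)
            seeds = ld.diseases_of(query)
            seed_idx = [ld.disease_index(d) for d in seeds]
        h = self.transition_
        p_rs = rwr.build_restart_vector(
            j, seed_idx, params.eta, ld.n_lncrnas, ld.n_diseases,
            h.n_lncrna_layers, h.n_disease_layers, query_side=side,
        )
        p_inf, self.n_iter_ = rwr.rwr_iterate(
            h, p_rs, params.gamma, params.tol, params.max_iter
        )
        score_side = "lncrna" if side == "disease" else "disease"
        scores = rwr.aggregate_scores(
            p_inf, ld.n_lncrnas, ld.n_diseases,
            h.n_lncrna_layers, h.n_disease_layers, score_side,
        )
        ids = ld.lncrna_ids if score_side == "lncrna" else ld.disease_ids
        return RankedPredictions(
            query=query,
            ranking=rwr._rank(ids, scores, set(seeds)),
            excluded=list(seeds),
        )

    def predict_for_disease(self, disease_id: str) -> RankedPredictions:
        """Rank candidate lncRNAs for a disease (seed lncRNAs removed)."""
        return self._query(disease_id, "disease")

    def predict_for_lncrna(self, lncrna_id: str) -> RankedPredictions:
        """Rank candidate diseases for an lncRNA (seed diseases removed)."""
        return self._query(lncrna_id, "lncrna")
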