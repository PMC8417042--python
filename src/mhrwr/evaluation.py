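"""Leave-one-out cross-validation with ROC/AUC and PR/AUPR.

Each known association (l, d) is masked in turn; the walk is re-run for
disease d on the masked matrix (by default with the GIP and functional
layers recomputed from the masked matrix, so the held-out edge cannot leak
through them) and the held-out lncRNA's score is compared with the scores
of d's candidate lncRNAs (those with no known association to d after
masking).

*Global* mode pools all held-out scores against the union of candidate
scores across folds.  *Local* mode pools within each disease and averages
the per-disease AUC/AUPR (weighted by fold count); with a single disease
the two modes coincide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_curve

from .containers import AssociationMatrix, OntologyDAG, RWRParams, SimilarityMatrix
from .model import compute_layers
from .rwr import predict_for_disease

logger = logging.getLogger(__name__)

__all__ = ["FoldRecord", "EvaluationResult", "roc_auc", "pr_aupr", "loocv"]


@dataclass
class FoldRecord:
    """One LOOCV fold: the held-out pair, its score, and the candidates' scores."""

    lncrna: str
    disease: str
    positive_score: float
    candidate_scores: np.ndarray  # scores of non-associated lncRNAs, positive excluded


@dataclass
class EvaluationResult:
    mode: str
    auc: float
    aupr: float
    roc: pd.DataFrame  # columns fpr, tpr, threshold
    pr: pd.DataFrame  # columns recall, precision, threshold
    fold_records: list[FoldRecord] = field(default_factory=list)

    @property
    def n_folds(self) -> int:
        return len(self.fold_records)


def _scores_labels(
    positive_scores: Sequence[float], candidate_scores: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(candidate_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("positive and candidate score lists must be nonempty")
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    return scores, labels


def roc_auc(
    positive_scores: Sequence[float], candidate_scores: Sequence[float]
) -> tuple[pd.DataFrame, float]:
    """ROC curve over the pooled score thresholds and trapezoidal AUC.

    Ties between a positive and a candidate contribute half credit, so the
    AUC equals the normalised Mann-Whitney U statistic.
    """
    scores, labels = _scores_labels(positive_scores, candidate_scores)
    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return curve, auc


def pr_aupr(
    positive_scores: Sequence[float], candidate_scores: Sequence[float]
) -> tuple[pd.DataFrame, float]:
    """Precision-recall curve and step-wise (non-interpolated) area.

    The area is average precision, sum over ranks of precision times the
    recall increment — no linear interpolation between PR points.
    """
    scores, labels = _scores_labels(positive_scores, candidate_scores)
    precision, recall, thresholds = precision_recall_curve(labels, scores)
    aupr = float(average_precision_score(labels, scores))
    curve = pd.DataFrame(
        {
            "recall": recall[:-1][::-1],
            "precision": precision[:-1][::-1],
            "threshold": thresholds[::-1],
        }
    )
    return curve, aupr


def _run_folds(
    ld: AssociationMatrix,
    params: RWRParams,
    recompute_similarity: bool,
    ontology: OntologyDAG | None,
    term_map: Mapping[str, str] | None,
    semantic_decay: float,
    gamma_prime: float,
    use_semantic: bool,
    use_functional: bool,
) -> list[FoldRecord]:
    pairs = [
        (ld.lncrna_ids[i], ld.disease_ids[j])
        for i, j in np.argwhere(ld.values == 1.0)
    ]
    if len(pairs) < 2:
        raise ValueError("LOOCV needs at least 2 known associations")

    layer_kwargs = dict(
        semantic_decay=semantic_decay,
        gamma_prime=gamma_prime,
        use_semantic=use_semantic,
        use_functional=use_functional,
    )
    # the semantic layer does not depend on LD: compute once and reuse per fold
    _, _, dss = compute_layers(ld, ontology, term_map, **layer_kwargs)
    if not recompute_similarity:
        full_lnc, full_dis, _ = compute_layers(
            ld, ontology, term_map, precomputed_dss=dss, **layer_kwargs
        )

    records: list[FoldRecord] = []
    for l, d in pairs:
        masked = ld.masked(l, d)
        if recompute_similarity:
            lnc_layers, dis_layers, _ = compute_layers(
                masked, ontology, term_map, precomputed_dss=dss, **layer_kwargs
            )
        else:
            lnc_layers, dis_layers = full_lnc, full_dis
        if not masked.lncrnas_of(d):
            logger.debug("fold (%s, %s): disease left with no seed lncRNAs", l, d)
        ranking = predict_for_disease(masked, lnc_layers, dis_layers, params, d)
        scores = ranking.scores()
        positive = scores.pop(l)
        records.append(
            FoldRecord(l, d, positive, np.asarray(list(scores.values())))
        )
    return records


def _fpr_grid_curve(curves: list[pd.DataFrame], weights: np.ndarray) -> pd.DataFrame:
    grid = np.linspace(0.0, 1.0, 101)
    tprs = [
        np.interp(grid, c["fpr"].to_numpy(), c["tpr"].to_numpy()) for c in curves
    ]
    tpr = np.average(np.vstack(tprs), axis=0, weights=weights)
    return pd.DataFrame({"fpr": grid, "tpr": tpr, "threshold": np.nan})


def loocv(
    ld: AssociationMatrix,
    *,
    params: RWRParams | None = None,
    mode: str = "global",
    recompute_similarity: bool = True,
    ontology: OntologyDAG | None = None,
    term_map: Mapping[str, str] | None = None,
    semantic_decay: float = 0.5,
    gamma_prime: float = 1.0,
    use_semantic: bool = True,
    use_functional: bool = True,
) -> EvaluationResult:
    """Leave-one-out cross-validation over all known associations.

    Parameters
    ----------
    ld : AssociationMatrix
    params : RWRParams, optional
        Walk parameters (defaults gamma = lambda = eta = 0.9, delta = 0.5).
    mode : {'global', 'local'}
        Pool scores across all diseases, or within each disease.
    recompute_similarity : bool
        Rebuild the GIP and functional layers from each fold's masked
        matrix (default); if False, the layers computed once from the full
        matrix are reused (cheaper, but the held-out edge leaks into them).
    ontology, term_map
        Optional disease-ontology inputs enabling the semantic and
        functional layers.
    """
    if mode not in ("global", "local"):
        raise ValueError(f"mode must be 'global' or 'local'; got {mode!r}")
    params = params or RWRParams()
    records = _run_folds(
        ld, params, recompute_similarity, ontology, term_map,
        semantic_decay, gamma_prime, use_semantic, use_functional,
    )

    if mode == "global":
        pos = [r.positive_score for r in records]
        neg = np.concatenate([r.candidate_scores for r in records])
        roc, auc = roc_auc(pos, neg)
        pr, aupr = pr_aupr(pos, neg)
        return EvaluationResult("global", auc, aupr, roc, pr, records)

    by_disease: dict[str, list[FoldRecord]] = {}
    for r in records:
        by_disease.setdefault(r.disease, []).append(r)
    curves, aucs, auprs, weights = [], [], [], []
    for d, recs in by_disease.items():
        pos = [r.positive_score for r in recs]
        neg = np.concatenate([r.candidate_scores for r in recs])
        roc_d, auc_d = roc_auc(pos, neg)
        _, aupr_d = pr_aupr(pos, neg)
        curves.append(roc_d)
        aucs.append(auc_d)
        auprs.append(aupr_d)
        weights.append(len(recs))
    w = np.asarray(weights, dtype=float)
    auc = float(np.average(aucs, weights=w))
    aupr = float(np.average(auprs, weights=w))
    roc = _fpr_grid_curve(curves, w)
    pr = pd.DataFrame(columns=["recall", "precision", "threshold"])
    return EvaluationResult("local", auc, aupr, roc, pr, records)
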