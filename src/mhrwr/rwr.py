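"""Random walk with restart on the assembled multiplex/heterogeneous network.

The walk iterates ``P_{t+1} = (1 - gamma) H^T P_t + gamma P_RS`` from
``P_0 = P_RS`` until the L1 change drops below ``tol``.  The restart vector
places weight ``eta`` on the query node's copies and ``1 - eta`` on the seed
nodes of the opposite side; stationary copy probabilities are summed per
entity to score and rank candidates.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

from .containers import AssociationMatrix, RankedPredictions, RWRParams, SimilarityMatrix
from .multiplex import TransitionMatrix, build_supra_adjacency, build_transition_matrix

__all__ = [
    "ConvergenceError",
    "build_restart_vector",
    "rwr_iterate",
    "aggregate_scores",
    "predict_for_disease",
    "predict_for_lncrna",
]


class ConvergenceError(RuntimeError):
    """Power iteration failed to reach tol within max_iter."""

    def __init__(self, residual: float, max_iter: int) -> None:
        super().__init__(
            f"no convergence after {max_iter} iterations (L1 residual {residual:.3e})"
        )
        self.residual = residual
        self.max_iter = max_iter


def build_restart_vector(
    query_index: int,
    seed_indices: list[int] | np.ndarray,
    eta: float,
    n: int,
    m: int,
    n_lncrna_layers: int,
    n_disease_layers: int,
    query_side: str = "disease",
) -> np.ndarray:
    """Restart distribution over all nL + mK node copies.

    The query entity receives total mass ``eta`` split equally over its
    copies; the seed entities on the opposite side share ``1 - eta``
    uniformly, again split over copies.  With no seeds, the full mass goes
    to the query side so the result is still a probability distribution.
    """
    nl = n * n_lncrna_layers
    mk = m * n_disease_layers
    p = np.zeros(nl + mk)
    seed_indices = np.asarray(seed_indices, dtype=int)
    query_mass = eta if seed_indices.size else 1.0
    if query_side == "disease":
        if not 0 <= query_index < m:
            raise IndexError(f"disease index {query_index} out of range")
        for beta in range(n_disease_layers):
            p[nl + beta * m + query_index] = query_mass / n_disease_layers
        if seed_indices.size:
            w = (1.0 - eta) / (seed_indices.size * n_lncrna_layers)
            for alpha in range(n_lncrna_layers):
                p[alpha * n + seed_indices] += w
    elif query_side == "lncrna":
        if not 0 <= query_index < n:
            raise IndexError(f"lncRNA index {query_index} out of range")
        for alpha in range(n_lncrna_layers):
            p[alpha * n + query_index] = query_mass / n_lncrna_layers
        if seed_indices.size:
            w = (1.0 - eta) / (seed_indices.size * n_disease_layers)
            for beta in range(n_disease_layers):
                p[nl + beta * m + seed_indices] += w
    else:
        raise ValueError(f"query_side must be 'disease' or 'lncrna'; got {query_side!r}")
    return p


def rwr_iterate(
    h: TransitionMatrix | sparse.spmatrix,
    p_rs: np.ndarray,
    gamma: float,
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> tuple[np.ndarray, int]:
    """Power-iterate the restart walk to its fixed point.

    Returns ``(P_inf, iterations)``; raises :class:`ConvergenceError` if the
    L1 residual is still above ``tol`` after ``max_iter`` iterations.
    """
    matrix = h.matrix if isinstance(h, TransitionMatrix) else h
    ht = matrix.T.tocsr()
    p = np.asarray(p_rs, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("restart vector must sum to 1")
    restart = gamma * p
    for it in range(1, max_iter + 1):
        p_next = (1.0 - gamma) * (ht @ p) + restart
        residual = float(np.abs(p_next - p).sum())
        p = p_next
        if residual < tol:
            return p, it
    raise ConvergenceError(residual, max_iter)


def aggregate_scores(
    p: np.ndarray,
    n: int,
    m: int,
    n_lncrna_layers: int,
    n_disease_layers: int,
    side: str,
) -> np.ndarray:
    """Sum copy probabilities per entity for one side of the network."""
    nl = n * n_lncrna_layers
    if side == "lncrna":
        return p[:nl].reshape(n_lncrna_layers, n).sum(axis=0)
    if side == "disease":
        return p[nl:].reshape(n_disease_layers, m).sum(axis=0)
    raise ValueError(f"side must be 'lncrna' or 'disease'; got {side!r}")


def _rank(ids: list[str], scores: np.ndarray, exclude: set[str]) -> list[tuple[str, float]]:
    pairs = [(i, float(s)) for i, s in zip(ids, scores) if i not in exclude]
    pairs.sort(key=lambda kv: (-kv[1], kv[0]))
    return pairs


def _walk(
    ld: AssociationMatrix,
    lncrna_layers: list[SimilarityMatrix],
    disease_layers: list[SimilarityMatrix],
    params: RWRParams,
    p_rs: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    a_rm = build_supra_adjacency(lncrna_layers, params.delta)
    a_dm = build_supra_adjacency(disease_layers, params.delta)
    h = build_transition_matrix(a_rm, a_dm, ld, params.lambda_)
    p_inf, _ = rwr_iterate(h, p_rs, params.gamma, params.tol, params.max_iter)
    n, m = ld.n_lncrnas, ld.n_diseases
    args = (n, m, a_rm.n_layers, a_dm.n_layers)
    return aggregate_scores(p_inf, *args, "lncrna"), aggregate_scores(p_inf, *args, "disease")


def predict_for_disease(
    ld: AssociationMatrix,
    lncrna_layers: list[SimilarityMatrix],
    disease_layers: list[SimilarityMatrix],
    params: RWRParams,
    query_disease: str,
) -> RankedPredictions:
    """Rank candidate lncRNAs for one disease.

    Seeds are the disease itself (query side) and its known lncRNAs;
    the seed lncRNAs are removed from the returned ranking.
    """
    j = ld.disease_index(query_disease)
    seeds = ld.lncrnas_of(query_disease)
    seed_idx = [ld.lncrna_index(l) for l in seeds]
    n_layers_l, n_layers_d = len(lncrna_layers), len(disease_layers)
    p_rs = build_restart_vector(
        j, seed_idx, params.eta, ld.n_lncrnas, ld.n_diseases,
        n_layers_l, n_layers_d, query_side="disease",
    )
    lnc_scores, _ = _walk(ld, lncrna_layers, disease_layers, params, p_rs)
    return RankedPredictions(
        query=query_disease,
        ranking=_rank(ld.lncrna_ids, lnc_scores, set(seeds)),
        excluded=list(seeds),
    )


def predict_for_lncrna(
    ld: AssociationMatrix,
    lncrna_layers: list[SimilarityMatrix],
    disease_layers: list[SimilarityMatrix],
    params: RWRParams,
    query_lncrna: str,
) -> RankedPredictions:
    """Rank candidate diseases for one lncRNA (mirror of the disease query)."""
    i = ld.lncrna_index(query_lncrna)
    seeds = ld.diseases_of(query_lncrna)
    seed_idx = [ld.disease_index(d) for d in seeds]
    n_layers_l, n_layers_d = len(lncrna_layers), len(disease_layers)
    p_rs = build_restart_vector(
        i, seed_idx, params.eta, ld.n_lncrnas, ld.n_diseases,
        n_layers_l, n_layers_d, query_side="lncrna",
    )
    _, dis_scores = _walk(ld, lncrna_layers, disease_layers, params, p_rs)
    return RankedPredictions(
        query=query_lncrna,
        ranking=_rank(ld.disease_ids, dis_scores, set(seeds)),
        excluded=list(seeds),
    )
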