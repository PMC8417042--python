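"""Similarity layers of the multiplex network.

Four square similarity matrices are built from two data sources:

* the disease-ontology DAG gives *disease semantic similarity* (shared-ancestor
  semantic contributions decaying with depth, Wang-style) and, through the
  association matrix, *lncRNA functional similarity* (best-match average of
  the semantic similarities between the two lncRNAs' disease sets);
* the binary association matrix gives Gaussian interaction-profile (GIP)
  kernel similarity for both sides, ``exp(-gamma * ||IP_i - IP_j||^2)`` with
  the bandwidth normalised by the mean squared profile norm.
"""

from __future__ import annotations

import graphlib
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .containers import AssociationMatrix, OntologyDAG, SimilarityMatrix

__all__ = [
    "semantic_contributions",
    "disease_semantic_similarity",
    "gip_bandwidth",
    "gip_similarity",
    "lncrna_set_similarity",
    "lncrna_functional_similarity",
]


def semantic_contributions(
    dag: OntologyDAG, term: str, decay: float = 0.5
) -> dict[str, float]:
    """Semantic contribution of each ancestor of ``term`` to ``term``.

    The term itself contributes 1; an ancestor ``k`` contributes
    ``max(decay * contribution(k'))`` over its children ``k'`` inside the
    ancestor closure of ``term``, evaluated by dynamic programming in
    reverse topological order (children before parents).

    Parameters
    ----------
    dag : OntologyDAG
    term : str
        Target term; must be in the ontology.
    decay : float
        Per-edge decay factor in (0, 1); 0.5 by convention.

    Returns
    -------
    dict mapping each term of the ancestor closure (including ``term``)
    to its contribution in (0, 1].
    """
    if term not in dag:
        raise KeyError(f"term not in ontology: {term!r}")
    if not 0 < decay < 1:
        raise ValueError(f"decay must be in (0, 1); got {decay}")
    closure = set(dag.ancestors(term)) | {term}
    children_in: dict[str, list[str]] = {k: [] for k in closure}
    for child in closure:
        for parent in dag.parents[child]:
            if parent in closure:
                children_in[parent].append(child)
    order = graphlib.TopologicalSorter(
        {k: set(children_in[k]) for k in closure}
    ).static_order()
    contrib: dict[str, float] = {}
    for k in order:
        if k == term:
            contrib[k] = 1.0
        else:
            contrib[k] = max(decay * contrib[c] for c in children_in[k])
    return contrib


def disease_semantic_similarity(
    dag: OntologyDAG,
    disease_ids: Sequence[str],
    term_of: Mapping[str, str],
    decay: float = 0.5,
) -> SimilarityMatrix:
    """Pairwise semantic similarity between diseases mapped to ontology terms.

    For two mapped diseases the similarity is the summed contribution of the
    shared terms of their two contribution maps, normalised by the total
    semantic value of each map.  Diseases without an ontology mapping get
    similarity 0 to every other disease and 1 to themselves (the GIP layer
    still covers them).
    """
    if len(disease_ids) == 0:
        raise ValueError("empty disease list")
    for d, t in term_of.items():
        if t not in dag:
            raise KeyError(f"term not in ontology: {t!r} (mapped from {d!r})")

    term_cache: dict[str, dict[str, float]] = {}

    def contrib_for(d: str) -> dict[str, float] | None:
        t = term_of.get(d)
        if t is None:
            return None
        if t not in term_cache:
            term_cache[t] = semantic_contributions(dag, t, decay)
        return term_cache[t]

    maps = [contrib_for(d) for d in disease_ids]
    totals = [sum(m.values()) if m is not None else 0.0 for m in maps]
    k = len(disease_ids)
    values = np.eye(k)
    for i in range(k):
        mi = maps[i]
        if mi is None:
            continue
        for j in range(i + 1, k):
            mj = maps[j]
            if mj is None:
                continue
            shared = mi.keys() & mj.keys()
            if not shared:
                continue
            num = sum(mi[t] + mj[t] for t in shared)
            values[i, j] = values[j, i] = num / (totals[i] + totals[j])
    return SimilarityMatrix(list(disease_ids), values)


def gip_bandwidth(profiles: np.ndarray, gamma_prime: float = 1.0) -> float:
    """Kernel bandwidth gamma = gamma' / mean squared profile norm.

    ``profiles`` is an (n, d) array of binary interaction profiles (one row
    per entity).  Raises if every profile is all-zero, since the bandwidth is
    then undefined.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[0] < 1:
        raise ValueError("profiles must be a nonempty 2-D array")
    if gamma_prime <= 0:
        raise ValueError(f"gamma_prime must be positive; got {gamma_prime}")
    mean_sq = float(np.mean((profiles**2).sum(axis=1)))
    if mean_sq == 0.0:
        raise ValueError("degenerate profiles: bandwidth undefined")
    return gamma_prime / mean_sq


def gip_similarity(
    ld: AssociationMatrix, side: str, gamma_prime: float = 1.0
) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel similarity for one side.

    ``side='lncrna'`` uses the rows of LD as profiles, ``side='disease'``
    the columns.  Entry (i, j) is ``exp(-gamma * ||IP_i - IP_j||^2)``.
    """
    if side == "lncrna":
        profiles, ids = ld.values, ld.lncrna_ids
    elif side == "disease":
        profiles, ids = ld.values.T, ld.disease_ids
    else:
        raise ValueError(f"side must be 'lncrna' or 'disease'; got {side!r}")
    gamma = gip_bandwidth(profiles, gamma_prime)
    if len(ids) == 1:
        return SimilarityMatrix(list(ids), np.ones((1, 1)))
    sq_dists = squareform(pdist(profiles, metric="sqeuclidean"))
    return SimilarityMatrix(list(ids), np.exp(-gamma * sq_dists))


def lncrna_set_similarity(
    d: str, disease_set: Sequence[str], dss: SimilarityMatrix
) -> float:
    """Best-match similarity of disease ``d`` to a disease set: max over members.

    Returns 0 for an empty set (no evidence, no similarity).
    """
    i = dss.index(d)
    if len(disease_set) == 0:
        return 0.0
    idx = [dss.index(x) for x in disease_set]
    return float(dss.values[i, idx].max())


def lncrna_functional_similarity(
    ld: AssociationMatrix, dss: SimilarityMatrix
) -> SimilarityMatrix:
    """Functional similarity between lncRNAs from their associated-disease sets.

    For disease sets ``D_i`` (size m) and ``D_j`` (size n) the similarity is
    the best-match average
    ``(sum_a SS(a, D_j) + sum_b SS(b, D_i)) / (m + n)``;
    it is 0 whenever either set is empty, and 1 on the diagonal.
    """
    d_idx = [dss.index(d) for d in ld.disease_ids]
    sub = dss.values[np.ix_(d_idx, d_idx)]
    sets = [np.flatnonzero(row) for row in ld.values]
    n = ld.n_lncrnas
    values = np.eye(n)
    for i in range(n):
        di = sets[i]
        if di.size == 0:
            continue
        for j in range(i + 1, n):
            dj = sets[j]
            if dj.size == 0:
                continue
            block = sub[np.ix_(di, dj)]
            score = (block.max(axis=1).sum() + block.max(axis=0).sum()) / (
                di.size + dj.size
            )
            values[i, j] = values[j, i] = score
    return SimilarityMatrix(list(ld.lncrna_ids), values)
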