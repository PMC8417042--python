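"""Synthetic fixtures: random ontologies and cluster-structured associations.

The generators make every test and benchmark runnable without external
downloads.  `generate_associations` plants co-cluster structure in the
bipartite matrix (dense blocks on a sparse background), which is the signal
the walk should recover; `benchmark_recovery` runs global LOOCV on such a
matrix and returns the AUC.  All generators are pure functions of their
spec and seed (numpy PCG64 via ``default_rng``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .containers import AssociationMatrix, OntologyDAG, RWRParams

__all__ = [
    "SyntheticSpec",
    "generate_dag",
    "generate_term_map",
    "generate_associations",
    "benchmark_recovery",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions of a synthetic benchmark.

    Defaults are the planted-recovery benchmark: 3 co-clusters over
    30 lncRNAs x 30 diseases, within-cluster association density 0.6
    against a 0.02 background, with a 60-term ontology.
    """

    n_lncrnas: int = 30
    m_diseases: int = 30
    n_terms: int = 60
    n_clusters: int = 3
    within_cluster_density: float = 0.6
    cross_cluster_density: float = 0.02
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("within_cluster_density", "cross_cluster_density"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]; got {v}")
        if self.n_clusters < 1 or self.n_terms < 1:
            raise ValueError("n_clusters and n_terms must be >= 1")
        if self.within_cluster_density < self.cross_cluster_density:
            raise ValueError(
                "within_cluster_density must be >= cross_cluster_density"
            )

    def structureless(self) -> "SyntheticSpec":
        """Control with the same expected density but no planted structure."""
        n_cl = self.n_clusters
        nl, m = self.n_lncrnas, self.m_diseases
        within_pairs = sum(
            len(_partition(nl, n_cl)[c]) * len(_partition(m, n_cl)[c])
            for c in range(n_cl)
        )
        total = nl * m
        density = (
            self.within_cluster_density * within_pairs
            + self.cross_cluster_density * (total - within_pairs)
        ) / total
        return replace(
            self,
            within_cluster_density=density,
            cross_cluster_density=density,
        )


def _partition(count: int, n_clusters: int) -> list[np.ndarray]:
    return np.array_split(np.arange(count), n_clusters)


def generate_dag(spec: SyntheticSpec) -> OntologyDAG:
    """Random rooted DAG: term k > 0 picks 1-2 parents among terms 0..k-1."""
    rng = np.random.default_rng(spec.rng_seed)
    terms = [f"T{k:04d}" for k in range(spec.n_terms)]
    edges: dict[str, set[str]] = {}
    for k in range(1, spec.n_terms):
        n_parents = int(rng.integers(1, min(2, k) + 1))
        parents = rng.choice(k, size=n_parents, replace=False)
        edges[terms[k]] = {terms[p] for p in parents}
    return OntologyDAG(edges, extra_terms=[terms[0]])


def generate_term_map(spec: SyntheticSpec) -> dict[str, str]:
    """Map each disease to a uniformly random ontology term.

    Diseases of the same co-cluster draw from the same contiguous slice of
    terms, so semantic similarity carries (weak) cluster signal too.
    """
    rng = np.random.default_rng(spec.rng_seed + 1)
    terms = [f"T{k:04d}" for k in range(spec.n_terms)]
    diseases = [f"D{j:03d}" for j in range(spec.m_diseases)]
    term_slices = _partition(spec.n_terms, spec.n_clusters)
    mapping: dict[str, str] = {}
    for c, d_idx in enumerate(_partition(spec.m_diseases, spec.n_clusters)):
        pool = term_slices[c] if len(term_slices[c]) else np.arange(spec.n_terms)
        for j in d_idx:
            mapping[diseases[j]] = terms[int(rng.choice(pool))]
    return mapping


def generate_associations(
    spec: SyntheticSpec, max_resample: int = 1000
) -> AssociationMatrix:
    """Cluster-structured bipartite matrix with no empty rows or columns.

    LncRNAs and diseases are split into ``n_clusters`` co-clusters; each
    pair is associated with probability ``within_cluster_density`` inside a
    co-cluster and ``cross_cluster_density`` outside.  Rows and columns left
    empty are redrawn (bounded), so every GIP profile is nonzero.
    """
    rng = np.random.default_rng(spec.rng_seed)
    nl, m = spec.n_lncrnas, spec.m_diseases
    prob = np.full((nl, m), spec.cross_cluster_density)
    l_parts = _partition(nl, spec.n_clusters)
    d_parts = _partition(m, spec.n_clusters)
    for l_idx, d_idx in zip(l_parts, d_parts):
        prob[np.ix_(l_idx, d_idx)] = spec.within_cluster_density

    values = (rng.random((nl, m)) < prob).astype(float)
    for _ in range(max_resample):
        empty_rows = np.flatnonzero(values.sum(axis=1) == 0)
        empty_cols = np.flatnonzero(values.sum(axis=0) == 0)
        if empty_rows.size == 0 and empty_cols.size == 0:
            break
        for i in empty_rows:
            values[i] = rng.random(m) < prob[i]
        for j in empty_cols:
            if values[:, j].sum() == 0:
                values[:, j] = rng.random(nl) < prob[:, j]
    else:
        raise RuntimeError(
            "could not produce a matrix without empty profiles; "
            "densities too low for this size"
        )
    lnc = [f"L{i:03d}" for i in range(nl)]
    dis = [f"D{j:03d}" for j in range(m)]
    return AssociationMatrix(lnc, dis, values)


def benchmark_recovery(
    spec: SyntheticSpec,
    params: RWRParams | None = None,
    *,
    mode: str = "global",
    recompute_similarity: bool = True,
):
    """Global LOOCV on a generated planted-structure benchmark.

    Returns the full :class:`~mhrwr.evaluation.EvaluationResult`; its
    ``auc`` is the recovery statistic.
    """
    from .evaluation import loocv

    ld = generate_associations(spec)
    dag = generate_dag(spec)
    term_map = generate_term_map(spec)
    return loocv(
        ld,
        params=params,
        mode=mode,
        recompute_similarity=recompute_similarity,
        ontology=dag,
        term_map=term_map,
    )
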