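"""Core in-memory containers: ontology DAG, association matrix, similarity matrix.

These are deliberately small, validating wrappers around plain numpy arrays
and dicts; all heavy numerics live in :mod:`mhrwr.similarity`,
:mod:`mhrwr.multiplex` and :mod:`mhrwr.rwr`.
"""

from __future__ import annotations

import graphlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "OntologyDAG",
    "AssociationMatrix",
    "SimilarityMatrix",
    "RWRParams",
    "RankedPredictions",
]

_SYM_TOL = 1e-12


class OntologyDAG:
    """A rooted DAG of ontology terms with child -> parent edges.

    Parameters
    ----------
    parent_edges
        Mapping from a child term to an iterable of its parent terms.
        Terms that appear only as parents are added automatically.
    extra_terms
        Terms with no edges at all (isolated roots).

    Raises
    ------
    ValueError
        If the edge set contains a cycle.
    """

    def __init__(
        self,
        parent_edges: Mapping[str, Iterable[str]],
        extra_terms: Iterable[str] = (),
    ) -> None:
        parents: dict[str, frozenset[str]] = {}
        terms: set[str] = set(extra_terms)
        for child, ps in parent_edges.items():
            ps = frozenset(ps)
            parents[child] = ps
            terms.add(child)
            terms.update(ps)
        for t in terms:
            parents.setdefault(t, frozenset())
        try:
            # dependency graph: a term depends on its parents
            tuple(graphlib.TopologicalSorter(parents).static_order())
        except graphlib.CycleError as exc:
            cycle = exc.args[1] if len(exc.args) > 1 else []
            member = cycle[0] if cycle else "?"
            raise ValueError(
                f"ontology contains a cycle involving term {member!r}"
            ) from exc
        self.terms: frozenset[str] = frozenset(terms)
        self.parents: dict[str, frozenset[str]] = parents
        self.roots: frozenset[str] = frozenset(
            t for t in terms if not parents[t]
        )
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    def ancestors(self, term: str) -> frozenset[str]:
        """All strict ancestors of ``term`` (excluding ``term`` itself)."""
        if term not in self.terms:
            raise KeyError(f"term not in ontology: {term!r}")
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        out: set[str] = set()
        stack = list(self.parents[term])
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.parents[t])
        result = frozenset(out)
        self._ancestor_cache[term] = result
        return result

    def __contains__(self, term: object) -> bool:
        return term in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"OntologyDAG({len(self.terms)} terms, {len(self.roots)} roots)"


@dataclass
class AssociationMatrix:
    """Binary bipartite lncRNA x disease association matrix LD.

    Row ``i`` is the interaction profile of lncRNA ``i``; column ``j`` the
    interaction profile of disease ``j``.
    """

    lncrna_ids: list[str]
    disease_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = len(self.lncrna_ids), len(self.disease_ids)
        if self.values.shape != (n, m):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{n} lncRNAs x {m} diseases"
            )
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("association matrix entries must be 0 or 1")
        if len(set(self.lncrna_ids)) != n or len(set(self.disease_ids)) != m:
            raise ValueError("duplicate identifiers")
        self._l_index = {l: i for i, l in enumerate(self.lncrna_ids)}
        self._d_index = {d: j for j, d in enumerate(self.disease_ids)}

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "AssociationMatrix":
        """Build from (lncRNA, disease) pairs; ids ordered by first appearance."""
        lnc: list[str] = []
        dis: list[str] = []
        li: dict[str, int] = {}
        di: dict[str, int] = {}
        pairs: list[tuple[int, int]] = []
        for l, d in edges:
            if l not in li:
                li[l] = len(lnc)
                lnc.append(l)
            if d not in di:
                di[d] = len(dis)
                dis.append(d)
            pairs.append((li[l], di[d]))
        values = np.zeros((len(lnc), len(dis)))
        for i, j in pairs:
            values[i, j] = 1.0
        return cls(lnc, dis, values)

    @property
    def n_lncrnas(self) -> int:
        return len(self.lncrna_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    def lncrna_index(self, lncrna_id: str) -> int:
        return self._l_index[lncrna_id]

    def disease_index(self, disease_id: str) -> int:
        return self._d_index[disease_id]

    def diseases_of(self, lncrna_id: str) -> list[str]:
        row = self.values[self._l_index[lncrna_id]]
        return [d for d, v in zip(self.disease_ids, row) if v]

    def lncrnas_of(self, disease_id: str) -> list[str]:
        col = self.values[:, self._d_index[disease_id]]
        return [l for l, v in zip(self.lncrna_ids, col) if v]

    def masked(self, lncrna_id: str, disease_id: str) -> "AssociationMatrix":
        """Copy with the (lncRNA, disease) entry set to 0 (LOOCV fold)."""
        values = self.values.copy()
        values[self._l_index[lncrna_id], self._d_index[disease_id]] = 0.0
        return AssociationMatrix(list(self.lncrna_ids), list(self.disease_ids), values)

    def transposed(self) -> "AssociationMatrix":
        """Swap the two sides (diseases become rows)."""
        return AssociationMatrix(
            list(self.disease_ids), list(self.lncrna_ids), self.values.T.copy()
        )


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix over an ordered id list, values in [0, 1]."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.ids)
        if self.values.shape != (k, k):
            raise ValueError(f"shape {self.values.shape} does not match {k} ids")
        if not np.allclose(self.values, self.values.T, atol=_SYM_TOL, rtol=0):
            raise ValueError("similarity matrix is not symmetric")
        if self.values.min() < -_SYM_TOL or self.values.max() > 1 + _SYM_TOL:
            raise ValueError("similarity values outside [0, 1]")
        self._index = {x: i for i, x in enumerate(self.ids)}

    def index(self, node_id: str) -> int:
        return self._index[node_id]

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values[self._index[a], self._index[b]])


@dataclass(frozen=True)
class RWRParams:
    """Parameters of the restart walk.

    gamma
        Restart probability in (0, 1]; each step the walker teleports back to
        the restart distribution with probability gamma.
    lambda_
        Probability of jumping between the lncRNA and disease networks
        through a known association, in (0, 1).
    eta
        Restart weight of the query's own side, in (0, 1); the complement
        1 - eta restarts on the seed nodes of the opposite side.
    delta
        Inter-layer jump probability within a multiplex, in [0, 1).
    tol
        L1 convergence threshold for the power iteration.
    max_iter
        Iteration cap.
    """

    gamma: float = 0.9
    lambda_: float = 0.9
    eta: float = 0.9
    delta: float = 0.5
    tol: float = 1e-10
    max_iter: int = 10000

    def __post_init__(self) -> None:
        if not 0 < self.gamma <= 1:
            raise ValueError(f"gamma must be in (0, 1]; got {self.gamma}")
        if not 0 < self.lambda_ < 1:
            raise ValueError(f"lambda must be in (0, 1); got {self.lambda_}")
        if not 0 < self.eta < 1:
            raise ValueError(f"eta must be in (0, 1); got {self.eta}")
        if not 0 <= self.delta < 1:
            raise ValueError(f"delta must be in [0, 1); got {self.delta}")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tol must be positive and max_iter >= 1")


@dataclass
class RankedPredictions:
    """Descending score ranking of candidate entities for one query."""

    query: str
    ranking: list[tuple[str, float]]
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        scores = [s for _, s in self.ranking]
        if any(b > a for a, b in zip(scores, scores[1:])):
            raise ValueError("ranking scores must be non-increasing")
        present = {c for c, _ in self.ranking}
        if present & set(self.excluded):
            raise ValueError("excluded ids must not appear in the ranking")

    def scores(self) -> dict[str, float]:
        return dict(self.ranking)

    def __len__(self) -> int:
        return len(self.ranking)
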