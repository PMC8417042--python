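"""Multiplex / heterogeneous network assembly.

Each side (lncRNA, disease) is a *multiplex*: several similarity layers over
the same node set, coupled by inter-layer jumps between copies of the same
node.  The two multiplexes are joined by the bipartite association matrix,
replicated so every copy of an lncRNA is adjacent to every copy of each
associated disease.  The result is one global row-stochastic transition
matrix H over all nL + mK node copies.

Copy indexing is layer-major: copy ``alpha * n + i`` is node ``i`` on layer
``alpha``.  This layout is internal; all outputs aggregate over copies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import sparse

from .containers import AssociationMatrix, SimilarityMatrix

__all__ = [
    "normalize_layer",
    "build_supra_adjacency",
    "build_transition_matrix",
    "SupraAdjacency",
    "TransitionMatrix",
]

_ROW_TOL = 1e-12


def normalize_layer(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-normalise a similarity matrix after removing self-loops.

    Returns ``(P, isolated)`` where P is the row-stochastic walk matrix and
    ``isolated`` flags nodes whose row is all-zero after the diagonal is
    removed (their rows are left at zero; the supra-adjacency gives them a
    self-loop fallback).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("layer must be a square matrix")
    if values.min() < 0:
        raise ValueError("layer has negative entries")
    off = values.copy()
    np.fill_diagonal(off, 0.0)
    row_sums = off.sum(axis=1)
    isolated = row_sums == 0.0
    safe = np.where(isolated, 1.0, row_sums)
    return off / safe[:, None], isolated


@dataclass
class SupraAdjacency:
    """Row-stochastic supra-adjacency of one multiplex (size n_nodes * n_layers)."""

    matrix: sparse.csr_matrix
    node_ids: list[str]
    n_layers: int

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def size(self) -> int:
        return self.n_nodes * self.n_layers


def build_supra_adjacency(
    layers: Sequence[SimilarityMatrix], delta: float = 0.5
) -> SupraAdjacency:
    """Couple L normalised similarity layers into one supra-adjacency matrix.

    Diagonal blocks carry ``(1 - delta)`` times the row-normalised layer
    (isolated-in-layer nodes keep that mass on their own copy); off-diagonal
    blocks are ``delta / (L - 1)`` times the identity, so a walker jumps to a
    uniformly chosen copy of its current node with total probability delta.
    With a single layer delta is forced to 0 and the supra-adjacency is just
    the normalised layer.
    """
    if len(layers) == 0:
        raise ValueError("at least one layer required")
    ids = layers[0].ids
    for layer in layers[1:]:
        if layer.ids != ids:
            raise ValueError("all layers must share the same id ordering")
    n_layers = len(layers)
    if n_layers == 1:
        delta = 0.0
    if not 0 <= delta < 1:
        raise ValueError(f"delta must be in [0, 1); got {delta}")

    diag_blocks = []
    for layer in layers:
        p, isolated = normalize_layer(layer.values)
        block = (1.0 - delta) * p
        if isolated.any():
            # self-loop fallback keeps the chain stochastic
            block = block + np.diag(np.where(isolated, 1.0 - delta, 0.0))
        diag_blocks.append(sparse.csr_matrix(block))

    if n_layers == 1:
        matrix = diag_blocks[0]
    else:
        jump = sparse.identity(len(ids), format="csr") * (delta / (n_layers - 1))
        blocks = [
            [diag_blocks[a] if a == b else jump for b in range(n_layers)]
            for a in range(n_layers)
        ]
        matrix = sparse.bmat(blocks, format="csr")
    return SupraAdjacency(matrix, list(ids), n_layers)


@dataclass
class TransitionMatrix:
    """Global row-stochastic transition matrix over all node copies.

    The first ``n * L`` indices are lncRNA copies (layer-major), the last
    ``m * K`` disease copies.
    """

    matrix: sparse.csr_matrix
    lncrna_ids: list[str]
    disease_ids: list[str]
    n_lncrna_layers: int
    n_disease_layers: int

    @property
    def n_lncrna_copies(self) -> int:
        return len(self.lncrna_ids) * self.n_lncrna_layers

    @property
    def n_disease_copies(self) -> int:
        return len(self.disease_ids) * self.n_disease_layers

    @property
    def size(self) -> int:
        return self.n_lncrna_copies + self.n_disease_copies


def build_transition_matrix(
    a_rm: SupraAdjacency,
    a_dm: SupraAdjacency,
    ld: AssociationMatrix,
    lambda_: float,
) -> TransitionMatrix:
    """Join the two supra-adjacencies through the replicated association matrix.

    A copy of lncRNA ``i`` with at least one association keeps probability
    ``1 - lambda_`` on its intra-multiplex row and sends ``lambda_``,
    proportionally to its association profile, to the disease side — split
    equally (1/K) over the K copies of each associated disease.  A copy with
    no associations keeps its intra-multiplex row unchanged.  The disease
    side is symmetric with columns of LD and a 1/L split.
    """
    if not 0 < lambda_ < 1:
        raise ValueError(f"lambda must be in (0, 1); got {lambda_}")
    if a_rm.node_ids != ld.lncrna_ids or a_dm.node_ids != ld.disease_ids:
        raise ValueError("supra-adjacency ids do not match the association matrix")
    b = ld.values
    n, m = b.shape
    n_layers_l, n_layers_d = a_rm.n_layers, a_dm.n_layers
    row_deg = b.sum(axis=1)
    col_deg = b.sum(axis=0)

    # cross blocks: per-node bipartite rows, replicated over layer pairs
    w_rd = np.zeros((n, m))
    has_row = row_deg > 0
    w_rd[has_row] = lambda_ * b[has_row] / row_deg[has_row, None] / n_layers_d
    w_dr = np.zeros((m, n))
    has_col = col_deg > 0
    bt = b.T
    w_dr[has_col] = lambda_ * bt[has_col] / col_deg[has_col, None] / n_layers_l

    ones_rd = np.ones((n_layers_l, n_layers_d))
    h_rd = sparse.kron(ones_rd, sparse.csr_matrix(w_rd), format="csr")
    h_dr = sparse.kron(ones_rd.T, sparse.csr_matrix(w_dr), format="csr")

    # intra blocks: scale rows of associated nodes by (1 - lambda)
    scale_l = np.where(has_row, 1.0 - lambda_, 1.0)
    scale_d = np.where(has_col, 1.0 - lambda_, 1.0)
    h_rr = sparse.diags(np.tile(scale_l, n_layers_l)) @ a_rm.matrix
    h_dd = sparse.diags(np.tile(scale_d, n_layers_d)) @ a_dm.matrix

    matrix = sparse.bmat([[h_rr, h_rd], [h_dr, h_dd]], format="csr")
    row_sums = np.asarray(matrix.sum(axis=1)).ravel()
    if np.abs(row_sums - 1.0).max() > 1e-9:
        raise AssertionError("transition matrix is not row-stochastic")
    return TransitionMatrix(
        matrix, list(ld.lncrna_ids), list(ld.disease_ids), n_layers_l, n_layers_d
    )
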