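"""Readers and writers for the plain-text interchange formats.

Associations, ontology edges and disease-term mappings are 2-column TSV;
ontologies may also be OBO (``is_a`` edges only, parsed with obonet);
similarity matrices are square TSV with an id header row and column;
predictions are rank/candidate/score TSV.  Identifier matching is
exact-string and case-sensitive throughout.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AssociationMatrix, OntologyDAG, RankedPredictions, SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_associations",
    "write_associations",
    "read_ontology",
    "write_ontology",
    "read_term_map",
    "write_term_map",
    "read_similarity",
    "write_similarity",
    "write_predictions",
    "write_evaluation",
]

_HEADER_HINTS = {"lncrna", "lncrna_id", "disease", "disease_id", "child", "parent", "term", "term_id"}


def _read_two_columns(path: str | Path) -> list[tuple[str, str]]:
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, got {line!r}"
                )
            a, b = fields[0].strip(), fields[1].strip()
            if lineno == 1 and (a.lower() in _HEADER_HINTS or b.lower() in _HEADER_HINTS):
                continue  # optional header line
            rows.append((a, b))
    return rows


def read_associations(path: str | Path) -> AssociationMatrix:
    """Read a 2-column (lncRNA, disease) TSV; duplicates logged and kept once."""
    rows = _read_two_columns(path)
    seen: set[tuple[str, str]] = set()
    edges: list[tuple[str, str]] = []
    for edge in rows:
        if edge in seen:
            logger.warning("duplicate association %s ignored", edge)
            continue
        seen.add(edge)
        edges.append(edge)
    if not edges:
        raise ValueError(f"{path}: no associations found")
    return AssociationMatrix.from_edges(edges)


def write_associations(ld: AssociationMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("lncrna_id\tdisease_id\n")
        for i, j in np.argwhere(ld.values == 1.0):
            fh.write(f"{ld.lncrna_ids[i]}\t{ld.disease_ids[j]}\n")


def read_ontology(path: str | Path, format: str | None = None) -> OntologyDAG:
    """Read an ontology from OBO (``is_a`` edges only) or child/parent TSV.

    The format is inferred from the extension unless given explicitly.
    Cyclic inputs are rejected.
    """
    path = Path(path)
    if format is None:
        format = "obo" if path.suffix.lower() == ".obo" else "tsv"
    if format == "tsv":
        edges: dict[str, set[str]] = {}
        for child, parent in _read_two_columns(path):
            edges.setdefault(child, set()).add(parent)
        return OntologyDAG(edges)
    if format == "obo":
        import obonet

        graph = obonet.read_obo(path)
        edges = {}
        ignored = 0
        for child, parent, key in graph.edges(keys=True):
            if key == "is_a":
                edges.setdefault(child, set()).add(parent)
            else:
                ignored += 1
        if ignored:
            logger.warning("ignored %d non-is_a ontology relations", ignored)
        return OntologyDAG(edges, extra_terms=list(graph.nodes))
    raise ValueError(f"unknown ontology format: {format!r}")


def write_ontology(dag: OntologyDAG, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("child\tparent\n")
        for child in sorted(dag.parents):
            for parent in sorted(dag.parents[child]):
                fh.write(f"{child}\t{parent}\n")


def read_term_map(path: str | Path) -> dict[str, str]:
    """Read a disease -> ontology-term 2-column TSV."""
    return dict(_read_two_columns(path))


def write_term_map(term_map: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("disease_id\tterm_id\n")
        for d, t in term_map.items():
            fh.write(f"{d}\t{t}\n")


def read_similarity(path: str | Path) -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column ids differ")
    return SimilarityMatrix([str(x) for x in df.index], df.to_numpy(dtype=float))


def write_similarity(sim: SimilarityMatrix, path: str | Path) -> None:
    """Write a square TSV with id header row/column at full double precision."""
    with open(path, "w") as fh:
        fh.write("\t".join(["id", *sim.ids]) + "\n")
        for i, row_id in enumerate(sim.ids):
            cells = "\t".join(repr(float(v)) for v in sim.values[i])
            fh.write(f"{row_id}\t{cells}\n")


def write_predictions(ranking: RankedPredictions, path: str | Path) -> None:
    """Write rank/candidate/score TSV, rank starting at 1, full precision."""
    with open(path, "w") as fh:
        fh.write("rank\tcandidate\tscore\n")
        for rank, (candidate, score) in enumerate(ranking.ranking, start=1):
            fh.write(f"{rank}\t{candidate}\t{score!r}\n")


def write_evaluation(result, path: str | Path, curves_path: str | Path | None = None) -> None:
    """Write an EvaluationResult as JSON (and optionally its curves as TSV)."""
    payload = {
        "mode": result.mode,
        "auc": result.auc,
        "aupr": result.aupr,
        "n_folds": result.n_folds,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
    if curves_path is not None:
        result.roc.assign(curve="roc").to_csv(curves_path, sep="\t", index=False)
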