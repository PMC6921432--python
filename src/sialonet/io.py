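"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices and sample annotations travel as TSV, gene sets as GMT,
networks as two-column edge-list TSV, and the synthetic ground-truth
manifest as JSON.  Every reader enforces the corresponding data contract
(unique identifiers, complete annotation, well-formed rows) and raises
:class:`~sialonet.errors.ValidationError` with file/line context on
malformed input.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from sialonet.errors import ValidationError

GENE_INDEX_NAME = "gene_id"
SAMPLE_ID_COLUMN = "sample_id"


# ---------------------------------------------------------------------------
# expression matrix


def validate_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check an expression matrix (genes x samples) against its contract."""
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValidationError("expression matrix is empty")
    if matrix.index.duplicated().any():
        dup = matrix.index[matrix.index.duplicated()][0]
        raise ValidationError(f"duplicated gene id: {dup!r}")
    if matrix.columns.duplicated().any():
        dup = matrix.columns[matrix.columns.duplicated()][0]
        raise ValidationError(f"duplicated sample id: {dup!r}")
    values = matrix.to_numpy()
    if not pd.api.types.is_numeric_dtype(values):
        raise ValidationError("expression matrix contains non-numeric values")
    if not pd.DataFrame(values).notna().all().all():
        raise ValidationError("expression matrix contains missing values")
    return matrix


def read_matrix(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValidationError(f"{path}: empty file")
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dup = next(h for h in header if header.count(h) > 1)
        raise ValidationError(f"duplicated sample id: {dup!r}")
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    matrix.index = matrix.index.astype(str)
    matrix.index.name = GENE_INDEX_NAME
    matrix.columns = matrix.columns.astype(str)
    return validate_matrix(matrix)


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    out = matrix.copy()
    out.index.name = GENE_INDEX_NAME
    out.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# sample annotation


def validate_annotation(
    annotation: pd.DataFrame, matrix: pd.DataFrame | None = None
) -> pd.DataFrame:
    for col in (SAMPLE_ID_COLUMN, "batch", "group"):
        if col not in annotation.columns:
            raise ValidationError(f"annotation is missing column {col!r}")
    if annotation[SAMPLE_ID_COLUMN].duplicated().any():
        raise ValidationError("annotation has duplicated sample ids")
    if matrix is not None:
        missing = set(matrix.columns) - set(annotation[SAMPLE_ID_COLUMN])
        if missing:
            raise ValidationError(
                f"samples missing from annotation: {sorted(missing)[:5]}"
            )
    return annotation


def read_annotation(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValidationError(f"{path}: empty file")
    annotation = pd.read_csv(path, sep="\t", dtype={SAMPLE_ID_COLUMN: str})
    return validate_annotation(annotation)


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def align_annotation(annotation: pd.DataFrame, matrix: pd.DataFrame) -> pd.DataFrame:
    """Return annotation rows reordered to match the matrix columns."""
    validate_annotation(annotation, matrix)
    indexed = annotation.set_index(SAMPLE_ID_COLUMN, drop=False)
    return indexed.loc[list(matrix.columns)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> "GeneSetCollection":
    from sialonet.enrich import GeneSetCollection

    path = Path(path)
    if path.stat().st_size == 0:
        raise ValidationError(f"{path}: empty file")
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            name, description, *genes = fields
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = [g.upper() for g in genes if g]
            if not genes:
                raise ValidationError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = set(genes)
            descriptions[name] = description
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: "GeneSetCollection", path: str | Path) -> None:
    with open(path, "w") as handle:
        for name in collection.names():
            genes = sorted(collection.sets[name])
            description = collection.descriptions.get(name, "na")
            handle.write("\t".join([name, description, *genes]) + "\n")


# ---------------------------------------------------------------------------
# edge lists


def read_edge_list(path: str | Path, directed: bool = False) -> nx.Graph | nx.DiGraph:
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValidationError(f"{path}: empty file")
    graph: nx.Graph | nx.DiGraph = nx.DiGraph() if directed else nx.Graph()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValidationError(
                    f"{path}:{lineno}: edge line has {len(fields)} fields, need 2"
                )
            a, b = fields[0], fields[1]
            if lineno == 1 and {a, b} == {"source", "target"}:
                continue  # header
            if a == b:
                raise ValidationError(f"{path}:{lineno}: self-loop {a!r}")
            graph.add_edge(a, b)
    return graph


def write_edge_list(graph: nx.Graph | nx.DiGraph, path: str | Path) -> None:
    directed = graph.is_directed()
    with open(path, "w") as handle:
        handle.write("source\ttarget\n")
        if directed:
            edges = sorted(graph.edges())
        else:
            edges = sorted(tuple(sorted(e)) for e in graph.edges())
        for a, b in edges:
            handle.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# generic JSON helpers (manifest, models, run metadata)


def read_json(path: str | Path) -> dict:
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValidationError(f"{path}: empty file")
    with open(path) as handle:
        return json.load(handle)


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as handle:
        json.dump(obj, handle, indent=2, sort_keys=True)
        handle.write("\n")


def read_gene_list(path: str | Path) -> list[str]:
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValidationError(f"{path}: empty file")
    with open(path) as handle:
        return [line.strip() for line in handle if line.strip()]


def write_gene_list(genes, path: str | Path) -> None:
    with open(path, "w") as handle:
        for gene in genes:
            handle.write(f"{gene}\n")
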