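"""Reading and writing the three input kinds of the pipeline.

The pipeline consumes (1) knowledge-graph triples as 3-column text,
(2) square similarity matrices with identifier headers (drug-drug chemical
similarity and target-target sequence similarity, both in [0, 1]), and
(3) binary drug-by-target interaction matrices, either as a full matrix or
as a 2-column edge list.  All loaders validate their domain invariants on
entry so downstream numerics never see malformed data, and every container
carries its identifier lists so entity <-> index maps stay consistent
across modules.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Triple",
    "SimilarityMatrix",
    "InteractionMatrix",
    "load_triples",
    "write_triples",
    "load_matrix",
    "write_matrix",
    "edges_to_matrix",
    "matrix_to_edges",
    "load_edge_list",
    "write_edge_list",
]

#: asymmetry below this is treated as float round-trip noise and averaged out
SYMMETRY_REPAIR_TOL = 1e-6
#: asymmetry the containers must satisfy after construction
SYMMETRY_TOL = 1e-8


class Triple(NamedTuple):
    """One (head, relation, tail) knowledge-graph fact."""

    head: str
    relation: str
    tail: str


def _validate_triple(t: Triple) -> None:
    if not (t.head and t.relation and t.tail):
        raise ValueError(f"triple fields must be non-empty strings: {t!r}")


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric square matrix of pairwise similarities in [0, 1], diagonal 1."""

    values: np.ndarray
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError(f"similarity matrix must be square, got shape {values.shape}")
        if values.shape[0] != len(self.ids):
            raise ValueError("id list length does not match matrix size")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("similarity matrix ids must be unique")
        asym = np.abs(values - values.T).max(initial=0.0)
        if asym > SYMMETRY_REPAIR_TOL:
            raise ValueError(f"similarity matrix asymmetry {asym:.3g} exceeds {SYMMETRY_REPAIR_TOL:g}")
        if asym > 0:
            values = (values + values.T) / 2.0
        if values.size and (values.min() < 0.0 or values.max() > 1.0):
            raise ValueError("similarity entries must lie in [0, 1]")
        if values.size and not np.allclose(np.diag(values), 1.0, atol=SYMMETRY_TOL):
            raise ValueError("similarity diagonal must equal 1")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "ids", tuple(self.ids))

    @property
    def n(self) -> int:
        return len(self.ids)

    def index(self) -> dict[str, int]:
        return {eid: i for i, eid in enumerate(self.ids)}


@dataclass(frozen=True)
class InteractionMatrix:
    """Binary M x N drug-by-target adjacency."""

    values: np.ndarray
    drug_ids: tuple[str, ...]
    target_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise ValueError("interaction matrix must be 2-D")
        if values.shape != (len(self.drug_ids), len(self.target_ids)):
            raise ValueError("id list lengths do not match matrix shape")
        if len(set(self.drug_ids)) != len(self.drug_ids) or len(set(self.target_ids)) != len(self.target_ids):
            raise ValueError("interaction matrix ids must be unique")
        if values.size and not np.isin(values, (0, 1)).all():
            bad = values[~np.isin(values, (0, 1))][:5]
            raise ValueError(f"interaction entries must be 0 or 1, found {bad.tolist()}")
        object.__setattr__(self, "values", values.astype(np.int8))
        object.__setattr__(self, "drug_ids", tuple(self.drug_ids))
        object.__setattr__(self, "target_ids", tuple(self.target_ids))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def density(self) -> float:
        return float(self.values.mean()) if self.values.size else 0.0


# ---------------------------------------------------------------------------
# triples
# ---------------------------------------------------------------------------

def load_triples(path: str | Path) -> list[Triple]:
    """Load (head, relation, tail) triples from 3+ column delimited text.

    Lines starting with ``#`` and blank lines are skipped.  Fields are split
    on tabs when present, otherwise on any whitespace.  Exact duplicates are
    collapsed, preserving first-seen order.
    """
    path = Path(path)
    triples: list[Triple] = []
    seen: set[Triple] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            fields = [f.strip() for f in fields]
            if len(fields) < 3 or any(not f for f in fields[:3]):
                raise ValueError(f"{path}:{lineno}: malformed triple line: {raw.rstrip()!r}")
            t = Triple(fields[0], fields[1], fields[2])
            if t not in seen:
                seen.add(t)
                triples.append(t)
    if not triples:
        raise ValueError(f"{path}: no triples found")
    return triples


def write_triples(triples: Iterable[Triple], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for t in triples:
            _validate_triple(t)
            fh.write(f"{t.head}\t{t.relation}\t{t.tail}\n")


def triple_stats(triples: Sequence[Triple]) -> dict[str, int]:
    """Counts of entities, relations and triples in a loaded set."""
    entities = {t.head for t in triples} | {t.tail for t in triples}
    relations = {t.relation for t in triples}
    return {"n_triples": len(triples), "n_entities": len(entities), "n_relations": len(relations)}


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def _sniff_sep(path: Path) -> str:
    with path.open() as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def load_matrix(path: str | Path, kind: str) -> SimilarityMatrix | InteractionMatrix:
    """Load a delimited matrix with a header row of ids and a leading id column.

    ``kind`` is ``"similarity"`` (square, symmetric, [0,1], unit diagonal;
    asymmetry up to 1e-6 is silently averaged out) or ``"interaction"``
    (entries must already be exactly 0 or 1).
    """
    path = Path(path)
    if kind not in ("similarity", "interaction"):
        raise ValueError(f"unknown matrix kind {kind!r}")
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    values = df.to_numpy(dtype=float)
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if kind == "similarity":
        if row_ids != col_ids:
            raise ValueError(f"{path}: similarity row ids and column ids differ")
        return SimilarityMatrix(values, tuple(row_ids))
    return InteractionMatrix(values, tuple(row_ids), tuple(col_ids))


def write_matrix(matrix: SimilarityMatrix | InteractionMatrix, path: str | Path, sep: str = "\t") -> None:
    if isinstance(matrix, SimilarityMatrix):
        df = pd.DataFrame(matrix.values, index=list(matrix.ids), columns=list(matrix.ids))
    else:
        df = pd.DataFrame(matrix.values, index=list(matrix.drug_ids), columns=list(matrix.target_ids))
    df.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# edge lists
# ---------------------------------------------------------------------------

def edges_to_matrix(
    triples: Iterable[Triple],
    relation: str,
    drug_ids: Sequence[str],
    target_ids: Sequence[str],
) -> InteractionMatrix:
    """Build the binary interaction matrix Y[d, t] = 1 iff (d, relation, t) exists."""
    drug_index = {d: i for i, d in enumerate(drug_ids)}
    target_index = {t: j for j, t in enumerate(target_ids)}
    values = np.zeros((len(drug_ids), len(target_ids)), dtype=np.int8)
    offenders = []
    for t in triples:
        if t.relation != relation:
            continue
        if t.head not in drug_index or t.tail not in target_index:
            offenders.append((t.head, t.tail))
            continue
        values[drug_index[t.head], target_index[t.tail]] = 1
    if offenders:
        raise ValueError(f"triples reference ids missing from the id lists: {offenders[:10]}")
    return InteractionMatrix(values, tuple(drug_ids), tuple(target_ids))


def matrix_to_edges(matrix: InteractionMatrix, relation: str = "interacts") -> list[Triple]:
    rows, cols = np.nonzero(matrix.values)
    return [Triple(matrix.drug_ids[i], relation, matrix.target_ids[j]) for i, j in zip(rows, cols)]


def load_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Load a 2-column (drug, target) edge list; comments and blanks skipped."""
    path = Path(path)
    edges: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: malformed edge line: {raw.rstrip()!r}")
            edges.append((fields[0], fields[1]))
    return edges


def write_edge_list(matrix: InteractionMatrix, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        rows, cols = np.nonzero(matrix.values)
        for i, j in zip(rows, cols):
            fh.write(f"{matrix.drug_ids[i]}\t{matrix.target_ids[j]}\n")
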