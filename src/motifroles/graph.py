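"""Directed-graph container, file I/O, degree statistics and random digraphs.

Graphs are binary, loop-free and directed. Internally nodes are indexed
0..N-1; all file outputs and reports use 1-based ids plus labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("motifroles")

#: toy fixture edge lists on labels A, B, C
_TOY_EDGES = {
    "two_path": [("A", "B"), ("B", "C")],
    "cycle3": [("A", "B"), ("B", "C"), ("C", "A")],
    "ffl": [("A", "B"), ("A", "C"), ("B", "C")],
    "recip_plus_out": [("A", "B"), ("B", "A"), ("B", "C")],
    "complete_triad": [
        ("A", "B"), ("B", "A"), ("A", "C"), ("C", "A"), ("B", "C"), ("C", "B"),
    ],
}


class GraphValidationError(ValueError):
    """Raised when an adjacency matrix or edge list violates the model."""


@dataclass
class DirectedGraph:
    """A directed, binary, loop-free network.

    Parameters
    ----------
    adjacency
        N x N matrix with entries in {0, 1}; ``adjacency[i, j] == 1`` iff
        there is an edge i -> j.  Self-connections are forbidden.
    node_labels
        Optional list of N unique strings.
    """

    adjacency: np.ndarray
    node_labels: list[str] | None = None
    name: str = field(default="graph")

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise GraphValidationError(f"adjacency must be square, got {a.shape}")
        if a.shape[0] < 1:
            raise GraphValidationError("graph needs at least one node")
        if not np.isin(a, (0, 1)).all():
            raise GraphValidationError("adjacency entries must be 0 or 1")
        if np.trace(np.abs(a)) != 0:
            raise GraphValidationError("self-loop: diagonal must be all zero")
        self.adjacency = a.astype(np.int64)
        if self.node_labels is not None:
            labels = [str(x) for x in self.node_labels]
            if len(labels) != a.shape[0]:
                raise GraphValidationError(
                    f"{len(labels)} labels for {a.shape[0]} nodes"
                )
            if len(set(labels)) != len(labels):
                raise GraphValidationError("node labels must be unique")
            self.node_labels = labels

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    def labels_or_ids(self) -> list[str]:
        """Labels if present, else 1-based ids as strings."""
        if self.node_labels is not None:
            return list(self.node_labels)
        return [str(i + 1) for i in range(self.n_nodes)]

    def index_of(self, label: str) -> int:
        """0-based index of a node label."""
        return self.labels_or_ids().index(str(label))


def binarize(matrix: np.ndarray, name: str = "graph",
             labels: list[str] | None = None) -> DirectedGraph:
    """Coerce any weighted/multi adjacency to a binary DirectedGraph.

    Nonzero entries become 1; a warning is logged if anything was collapsed.
    The diagonal is zeroed (with a warning) rather than rejected.
    """
    a = np.asarray(matrix, dtype=float)
    b = (a != 0).astype(np.int64)
    if not np.array_equal(a, b):
        logger.warning("%s: non-binary entries binarized (any nonzero -> 1)", name)
    if np.trace(b) != 0:
        logger.warning("%s: %d self-loops dropped", name, int(np.trace(b)))
        np.fill_diagonal(b, 0)
    return DirectedGraph(b, node_labels=labels, name=name)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def load_edge_list(path: str | Path, index_base: int = 0,
                   n_nodes: int | None = None, strict: bool = True,
                   labels: list[str] | None = None) -> DirectedGraph:
    """Read a two-column TSV/CSV edge list into a DirectedGraph.

    An optional header line ``source<sep>target`` is skipped.  Duplicate
    rows collapse to a single edge.  In strict mode a self-loop row is an
    error; otherwise it is dropped with a logged warning.
    """
    path = Path(path)
    if index_base not in (0, 1):
        raise ValueError("index_base must be 0 or 1")
    pairs: list[tuple[int, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split("\t")
            parts = [p.strip() for p in parts if p.strip() != ""]
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 columns, got {len(parts)}"
                )
            if lineno == 1 and not (parts[0].lstrip("-").isdigit()
                                    and parts[1].lstrip("-").isdigit()):
                continue  # header row
            try:
                s, t = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed line {line!r}") from exc
            s -= index_base
            t -= index_base
            if s == t:
                if strict:
                    raise GraphValidationError(
                        f"{path}:{lineno}: self-loop on node {s + index_base}"
                    )
                logger.warning("%s:%d: self-loop dropped", path, lineno)
                continue
            if s < 0 or t < 0:
                raise ValueError(f"{path}:{lineno}: index below base")
            pairs.append((s, t))
    n = n_nodes if n_nodes is not None else (max(max(p) for p in pairs) + 1
                                             if pairs else 1)
    if pairs and max(max(p) for p in pairs) >= n:
        raise ValueError("edge index out of range for n_nodes")
    a = np.zeros((n, n), dtype=np.int64)
    for s, t in pairs:
        a[s, t] = 1
    return DirectedGraph(a, node_labels=labels, name=path.stem)


def write_edge_list(g: DirectedGraph, path: str | Path,
                    index_base: int = 1) -> None:
    """Write a graph as a two-column TSV edge list (1-based by default)."""
    rows = np.argwhere(g.adjacency == 1) + index_base
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for s, t in rows:
            fh.write(f"{s}\t{t}\n")


def load_adjacency_csv(path: str | Path, labels: str = "auto") -> DirectedGraph:
    """Read a dense 0/1 adjacency matrix from CSV.

    ``labels='auto'`` detects an optional first row/column of node labels
    (any non-numeric header cell); 'yes'/'no' force the choice.
    """
    path = Path(path)
    raw = pd.read_csv(path, header=None, dtype=str)
    has_labels = False
    if labels == "auto":
        try:
            float(raw.iloc[0, raw.shape[1] - 1])
        except (TypeError, ValueError):
            has_labels = True
    elif labels == "yes":
        has_labels = True
    if has_labels:
        body = raw.iloc[1:, 1:].astype(float).to_numpy()
        names = [str(x) for x in raw.iloc[0, 1:]]
    else:
        body = raw.astype(float).to_numpy()
        names = None
    return binarize(body, name=path.stem, labels=names)


def write_adjacency_csv(g: DirectedGraph, path: str | Path) -> None:
    labels = g.labels_or_ids()
    df = pd.DataFrame(g.adjacency, index=labels, columns=labels)
    df.to_csv(path, index_label="")


def load_node_labels(path: str | Path, index_base: int = 1) -> dict[int, str]:
    """Read a two-column ``id<TAB>label`` table; ids converted to 0-based."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "label"],
                     comment="#")
    if str(df.iloc[0, 0]).lower() in ("id", "node_id"):
        df = df.iloc[1:]
    return {int(r.id) - index_base: str(r.label) for r in df.itertuples()}


# ---------------------------------------------------------------------------
# degree statistics
# ---------------------------------------------------------------------------

def reciprocal_matrix(g: DirectedGraph) -> np.ndarray:
    """Binary matrix with 1 wherever an edge is reciprocated (A ∘ Aᵀ)."""
    return g.adjacency * g.adjacency.T


def degree_table(g: DirectedGraph) -> pd.DataFrame:
    """Per-node in/out/reciprocal/total degrees.

    Columns: node_id (1-based), label, d_in, d_out, d_recip, d_tot.
    d_recip counts reciprocal partners, i.e. row sums of A ∘ Aᵀ.
    """
    a = g.adjacency
    r = reciprocal_matrix(g)
    return pd.DataFrame({
        "node_id": np.arange(1, g.n_nodes + 1),
        "label": g.labels_or_ids(),
        "d_in": a.sum(axis=0).astype(np.int64),
        "d_out": a.sum(axis=1).astype(np.int64),
        "d_recip": r.sum(axis=1).astype(np.int64),
        "d_tot": (a.sum(axis=0) + a.sum(axis=1)).astype(np.int64),
    })


# ---------------------------------------------------------------------------
# fixtures and random digraphs
# ---------------------------------------------------------------------------

def toy_graph(name: str) -> DirectedGraph:
    """Named 3-node fixtures covering the canonical triad patterns."""
    if name not in _TOY_EDGES:
        raise KeyError(
            f"unknown toy graph {name!r}; valid names: {sorted(_TOY_EDGES)}"
        )
    labels = ["A", "B", "C"]
    a = np.zeros((3, 3), dtype=np.int64)
    for s, t in _TOY_EDGES[name]:
        a[labels.index(s), labels.index(t)] = 1
    return DirectedGraph(a, node_labels=labels, name=name)


def random_digraph(n: int, p: float, reciprocity: float | None = None,
                   seed: int = 0) -> DirectedGraph:
    """Seeded Erdős–Rényi-style random digraph.

    Without ``reciprocity``, each ordered pair (i, j), i != j, carries an
    edge independently with probability p.  With reciprocity rho, unordered
    pairs are assigned {none, single (random direction), reciprocal} with
    P(reciprocal) = p*rho and P(single) = 2p(1-rho), so the marginal edge
    probability stays p and the probability that a present edge is
    reciprocated is rho.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if reciprocity is None:
        a = (rng.random((n, n)) < p).astype(np.int64)
        np.fill_diagonal(a, 0)
        return DirectedGraph(a, name=f"gnp(n={n},p={p},seed={seed})")
    rho = float(reciprocity)
    if not 0.0 <= rho <= 1.0:
        raise ValueError("reciprocity must be in [0, 1]")
    q2 = p * rho                 # unordered pair is reciprocal
    q1 = 2.0 * p * (1.0 - rho)   # unordered pair carries one edge
    if q1 + q2 > 1.0 + 1e-12:
        raise ValueError(
            f"infeasible: p={p}, reciprocity={rho} need p*(2-rho) <= 1"
        )
    a = np.zeros((n, n), dtype=np.int64)
    iu, ju = np.triu_indices(n, k=1)
    u = rng.random(iu.size)
    direction = rng.random(iu.size) < 0.5
    recip = u < q2
    single = (u >= q2) & (u < q2 + q1)
    a[iu[recip], ju[recip]] = 1
    a[ju[recip], iu[recip]] = 1
    fwd = single & direction
    bwd = single & ~direction
    a[iu[fwd], ju[fwd]] = 1
    a[ju[bwd], iu[bwd]] = 1
    return DirectedGraph(a, name=f"gnp(n={n},p={p},rho={rho},seed={seed})")
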