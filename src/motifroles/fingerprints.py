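"""Per-node motif-role fingerprints and their aggregations.

A *functional* occurrence of a pattern on a node triple is any subset of
the present edges isomorphic to the pattern (partial / edge-induced); a
*structural* occurrence requires the induced edge set to equal the pattern
(node-induced).  Entry (r, i) of a role-fingerprint matrix counts the
occurrences of role r's pattern with the reference node at i, one count
per distinct edge subset.

The fast path computes all 30 functional rows with dense matrix products
organized by the 9 ego-pattern families; the O(N^3) brute-force triple
enumeration is kept as the independent oracle and as the structural
counter.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np

from .catalog import (MotifCatalog, _pairs, _weakly_connected, default_catalog,
                      mask_to_edges, rooted_canonical_form)
from .graph import DirectedGraph, reciprocal_matrix


class ConsistencyError(RuntimeError):
    """An internal counting identity failed — signals a bug, not bad input."""


@dataclass
class RoleFingerprintMatrix:
    """L x N matrix of per-node role counts (L = 30, row r-1 = role r)."""

    flavor: str                      # "functional" | "structural"
    values: np.ndarray
    graph_ref: str = "graph"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.shape[0] != 30:
            raise ValueError("role fingerprint matrix must have 30 rows")
        if self.flavor not in ("functional", "structural"):
            raise ValueError(f"unknown flavor {self.flavor!r}")
        if (self.values < 0).any():
            raise ValueError("fingerprint counts must be nonnegative")

    def role(self, r: int) -> np.ndarray:
        """Per-node counts for paper role id r (1-based)."""
        return self.values[r - 1]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]


@dataclass
class MotifFingerprintMatrix:
    """M x N matrix of per-node motif participation counts (M = 13)."""

    flavor: str
    values: np.ndarray
    graph_ref: str = "graph"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.shape[0] != 13:
            raise ValueError("motif fingerprint matrix must have 13 rows")

    def motif(self, m: int) -> np.ndarray:
        return self.values[m - 1]


@dataclass
class CountVector:
    """Network-wide motif (length 13) or role (length 30) counts."""

    level: str                       # "motif" | "role"
    flavor: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        expect = {"motif": 13, "role": 30}[self.level]
        if self.values.shape != (expect,):
            raise ValueError(f"{self.level} counts must have length {expect}")


@dataclass
class RoleLayoutMatrix:
    """13 x 3 layout: row m holds the role counts of motif m's orbits.

    Rows with three nonzero entries are constant; in two-entry rows one
    entry is twice the other (the plurality-2 orbit); single-entry rows
    carry a factor 3.
    """

    values: np.ndarray
    flavor: str


# ---------------------------------------------------------------------------
# fast path: dense matrix algebra per ego-pattern family
# ---------------------------------------------------------------------------

def _diag3(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """diag(X @ Y @ Z) with one matmul and a Hadamard product."""
    return ((x @ y) * z.T).sum(axis=1)


def functional_role_fingerprints(g: DirectedGraph,
                                 catalog: MotifCatalog | None = None,
                                 ) -> RoleFingerprintMatrix:
    """All 30 functional role counts per node, from the adjacency matrix.

    Each family of rows uses at most two dense products plus Hadamard
    masks with the reciprocal-edge matrix R = A ∘ Aᵀ; exact integer
    arithmetic throughout.  Equals the brute-force triple census.
    """
    if catalog is None:
        catalog = default_catalog()
    a = g.adjacency
    at = a.T
    r = reciprocal_matrix(g)
    d_out = a.sum(axis=1)
    d_in = a.sum(axis=0)
    d_rec = r.sum(axis=1)

    f = np.zeros((30, g.n_nodes), dtype=np.int64)
    # singleton families: ego -> one neighbor, third node hangs off it
    f[0] = a @ d_out - d_rec                      # 1: chain source
    f[1] = a @ d_in - d_out                       # 2: co-source of convergence
    f[2] = a @ d_rec - d_rec                      # 3: edge into a mutual dyad
    f[3] = at @ d_in - d_rec                      # 4: chain sink
    f[4] = at @ d_out - d_in                      # 5: co-target of divergence
    f[5] = at @ d_rec - d_rec                     # 6: edge out of a mutual dyad
    f[6] = r @ d_out - d_rec                      # 7: dyad member, partner out
    f[7] = r @ d_in - d_rec                       # 8: dyad member, partner in
    f[8] = r @ d_rec - d_rec                      # 9: dyad chained to a dyad
    # degree-pair families with no required cross edge
    f[9] = d_in * (d_in - 1) // 2                 # 10: convergent pair
    f[12] = d_out * (d_out - 1) // 2              # 13: divergent pair
    f[15] = d_in * d_out - d_rec                  # 16: two-path middle
    f[19] = d_rec * (d_out - 1)                   # 20: recip + out
    f[23] = d_rec * (d_in - 1)                    # 24: recip + in
    f[27] = d_rec * (d_rec - 1) // 2              # 28: two recip partners
    # triangle closures (cross edge between the two neighbors)
    f[10] = _diag3(at, a, a)                      # 11: FFL sink
    f[11] = _diag3(at, r, a) // 2                 # 12
    f[13] = _diag3(a, a, at)                      # 14: FFL source
    f[14] = _diag3(a, r, at) // 2                 # 15
    f[16] = _diag3(at, a, at)                     # 17: FFL middle
    f[17] = _diag3(a, a, a)                       # 18: cycle
    f[18] = _diag3(at, r, at)                     # 19
    f[20] = _diag3(r, a, at)                      # 21
    f[21] = _diag3(r, at, at)                     # 22
    f[22] = _diag3(r, r, at)                      # 23
    f[24] = _diag3(r, a, a)                       # 25
    f[25] = _diag3(r, at, a)                      # 26
    f[26] = _diag3(r, r, a)                       # 27
    f[28] = _diag3(r, a, r)                       # 29
    f[29] = _diag3(r, r, r) // 2                  # 30: complete triad
    return RoleFingerprintMatrix("functional", f, graph_ref=g.name)


# ---------------------------------------------------------------------------
# brute-force oracle (triple enumeration via 64-state lookup tables)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4)
def _triple_tables(catalog_id: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Per-position role increments for each of the 64 triple edge states.

    Returns (functional, structural), each of shape (64, 3, 30):
    entry [mask, p, r-1] is the number of role-r occurrences position p
    picks up when the triple's present-edge bitmask is ``mask``.
    """
    cat = default_catalog()
    func = np.zeros((64, 3, 30), dtype=np.int64)
    struct = np.zeros((64, 3, 30), dtype=np.int64)
    for mask in range(64):
        edges = mask_to_edges(mask, 3)
        if _weakly_connected(mask, 3):
            for p in range(3):
                rid = cat.role_ids[rooted_canonical_form(edges, p, 3)]
                struct[mask, p, rid - 1] = 1
        # functional: every weakly connected spanning edge subset
        sub = mask
        while True:
            if sub and _weakly_connected(sub, 3):
                func[mask] += struct[sub]
            if sub == 0:
                break
            sub = (sub - 1) & mask
    return func, struct


def role_fingerprints_bruteforce(g: DirectedGraph,
                                 catalog: MotifCatalog | None = None,
                                 flavor: str = "functional",
                                 limit: int = 2000) -> RoleFingerprintMatrix:
    """O(N^3) triple-enumeration counter — the reference implementation.

    Structural: each weakly connected induced triple is classified into
    exactly one motif class and each member's orbit row is incremented.
    Functional: every weakly connected spanning edge subset of the triple
    counts once.
    """
    if flavor not in ("functional", "structural"):
        raise ValueError(f"unknown flavor {flavor!r}")
    n = g.n_nodes
    if n > limit:
        raise ValueError(
            f"N={n} exceeds brute-force limit {limit}; use the fast path "
            "(functional_role_fingerprints) or raise `limit`")
    func, struct = _triple_tables()
    table = func if flavor == "functional" else struct
    a = g.adjacency
    pairs = _pairs(3)  # bit order shared with the catalog
    f = np.zeros((30, n), dtype=np.int64)
    for trip in itertools.combinations(range(n), 3):
        mask = 0
        for b, (s, t) in enumerate(pairs):
            if a[trip[s], trip[t]]:
                mask |= 1 << b
        if mask:
            f[:, trip] += table[mask].T
    return RoleFingerprintMatrix(flavor, f, graph_ref=g.name)


# ---------------------------------------------------------------------------
# aggregations
# ---------------------------------------------------------------------------

def motif_fingerprints(rfp: RoleFingerprintMatrix,
                       catalog: MotifCatalog | None = None,
                       ) -> MotifFingerprintMatrix:
    """Sum role rows within each motif's role set Q_m (13 x N)."""
    if catalog is None:
        catalog = default_catalog()
    vals = np.zeros((13, rfp.n_nodes), dtype=np.int64)
    for m in range(1, 14):
        rows = [r - 1 for r in catalog.roles_of_motif(m)]
        vals[m - 1] = rfp.values[rows].sum(axis=0)
    return MotifFingerprintMatrix(rfp.flavor, vals, graph_ref=rfp.graph_ref)


def motif_counts(mfp: MotifFingerprintMatrix) -> CountVector:
    """Network-wide motif counts: row sums / 3 (each motif touches 3 nodes)."""
    sums = mfp.values.sum(axis=1)
    if (sums % 3).any():
        raise ConsistencyError(
            "motif fingerprint row sums not divisible by 3 — counting bug")
    return CountVector("motif", mfp.flavor, sums // 3)


def role_counts(rfp: RoleFingerprintMatrix) -> CountVector:
    """Network-wide role counts: plain row sums of the fingerprint matrix."""
    return CountVector("role", rfp.flavor, rfp.values.sum(axis=1))


def role_layout(counts: CountVector,
                catalog: MotifCatalog | None = None) -> RoleLayoutMatrix:
    """Arrange role counts as a 13 x 3 matrix, one motif per row.

    Entry (m, q) is the network-wide count of motif m's q-th role (ascending
    role id), which already carries the plurality weighting: a plurality-P
    orbit's count is P times the motif count.
    """
    if counts.level != "role":
        raise ValueError("role_layout expects role-level counts")
    if catalog is None:
        catalog = default_catalog()
    vals = np.zeros((13, 3), dtype=np.int64)
    for m in range(1, 14):
        for q, r in enumerate(catalog.roles_of_motif(m)):
            vals[m - 1, q] = counts.values[r - 1]
    return RoleLayoutMatrix(vals, counts.flavor)


def layout_to_motif_counts(layout: RoleLayoutMatrix) -> CountVector:
    """Recover motif counts: (layout @ 1_3) / 3."""
    sums = layout.values @ np.ones(3, dtype=np.int64)
    if (sums % 3).any():
        raise ConsistencyError("layout row sums not divisible by 3")
    return CountVector("motif", layout.flavor, sums // 3)


def role_counts_from_motif_counts(counts: CountVector,
                                  catalog: MotifCatalog | None = None,
                                  ) -> CountVector:
    """Expand motif counts back to role counts via pluralities."""
    if counts.level != "motif":
        raise ValueError("expects motif-level counts")
    if catalog is None:
        catalog = default_catalog()
    vals = np.zeros(30, dtype=np.int64)
    for r in range(1, 31):
        m = catalog.motif_of_role(r)
        vals[r - 1] = catalog.plurality[r] * counts.values[m - 1]
    return CountVector("role", counts.flavor, vals)


def write_fingerprints(fp: RoleFingerprintMatrix | MotifFingerprintMatrix,
                       g: DirectedGraph, path: str | Path,
                       header_extra: str = "") -> None:
    """TSV export: node_id, node_label, then role_1..role_30 / motif_1..13."""
    prefix = "role" if isinstance(fp, RoleFingerprintMatrix) else "motif"
    labels = g.labels_or_ids()
    with open(path, "w") as fh:
        fh.write(f"# motifroles {prefix} fingerprints; flavor={fp.flavor}; "
                 f"graph={fp.graph_ref}")
        if header_extra:
            fh.write(f"; {header_extra}")
        fh.write("\n")
        cols = [f"{prefix}_{i + 1}" for i in range(fp.values.shape[0])]
        fh.write("node_id\tnode_label\t" + "\t".join(cols) + "\n")
        for i in range(fp.values.shape[1]):
            row = "\t".join(str(int(x)) for x in fp.values[:, i])
            fh.write(f"{i + 1}\t{labels[i]}\t{row}\n")
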