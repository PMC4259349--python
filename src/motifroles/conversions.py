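"""Invertible functional <-> structural conversion matrices.

A structural occurrence of pattern s on a node triple contains a fixed
number of functional occurrences of each pattern f — the number of weakly
connected spanning edge subsets of s isomorphic to f (reference node
preserved, at role level).  Collecting these counts gives a unimodular
integer matrix T with

    functional(f) = sum_s T[s, f] * structural(s)

at the role level (30 x 30) and the motif level (13 x 13).  T is
triangular with unit diagonal when patterns are sorted by edge count, so
its exact integer inverse recovers structural statistics from functional
ones — the uniqueness result this package is built around.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .catalog import (MOTIF_DEFS, ROLE_DEFS, MotifCatalog, _weakly_connected,
                      canonical_form, default_catalog, edges_to_mask,
                      mask_to_edges, rooted_canonical_form)
from .fingerprints import (CountVector, MotifFingerprintMatrix,
                           RoleFingerprintMatrix)

_OPPOSITE = {"functional": "structural", "structural": "functional"}


class ConversionError(ValueError):
    """Raised on non-unimodular matrices or unrealizable inputs."""


@dataclass
class ConversionMatrix:
    """Square integer matrix converting between the two flavors.

    ``values[s-1, f-1]`` counts copies of functional pattern f inside
    structural pattern s.  ``direction`` names the conversion the matrix
    performs when applied via :func:`apply_conversion`.
    """

    level: str                       # "role" | "motif"
    values: np.ndarray
    direction: str = "structural_to_functional"
    ordering: str = "paper"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        expect = {"role": 30, "motif": 13}[self.level]
        if self.values.shape != (expect, expect):
            raise ValueError(f"{self.level} matrix must be {expect}x{expect}")

    @property
    def size(self) -> int:
        return self.values.shape[0]


def _spanning_connected_subsets(edges: Iterable[tuple[int, int]]):
    """Weakly connected spanning edge subsets of a 3-node pattern."""
    mask = edges_to_mask(list(edges), 3)
    sub = mask
    while True:
        if sub and _weakly_connected(sub, 3):
            yield mask_to_edges(sub, 3)
        if sub == 0:
            break
        sub = (sub - 1) & mask


def derive_role_conversion(catalog: MotifCatalog | None = None,
                           ) -> ConversionMatrix:
    """30 x 30 role-level matrix by exhaustive edge-subset enumeration.

    Entry (s, f): connected spanning edge subsets of role s's motif that
    realize role f's pattern with the same reference node.
    """
    if catalog is None:
        catalog = default_catalog()
    t = np.zeros((30, 30), dtype=np.int64)
    for s, edges in ROLE_DEFS.items():
        for sub in _spanning_connected_subsets(edges):
            f = catalog.role_ids[rooted_canonical_form(sub, 0, 3)]
            t[s - 1, f - 1] += 1
    return ConversionMatrix("role", t)


def derive_motif_conversion(catalog: MotifCatalog | None = None,
                            ) -> ConversionMatrix:
    """13 x 13 motif-level matrix: spanning subsets isomorphic to motif f."""
    if catalog is None:
        catalog = default_catalog()
    t = np.zeros((13, 13), dtype=np.int64)
    for s, edges in MOTIF_DEFS.items():
        for sub in _spanning_connected_subsets(edges):
            f = catalog.motif_ids[canonical_form(sub, 3)]
            t[s - 1, f - 1] += 1
    return ConversionMatrix("motif", t)


def invert_conversion(t: ConversionMatrix) -> ConversionMatrix:
    """Exact integer inverse; errors if the input is not unimodular."""
    det = round(float(np.linalg.det(t.values)))
    if det not in (1, -1):
        raise ConversionError(
            f"conversion matrix has determinant {det}, expected +-1 — "
            "derivation bug")
    inv = np.rint(np.linalg.inv(t.values)).astype(np.int64)
    if not np.array_equal(t.values @ inv, np.eye(t.size, dtype=np.int64)):
        raise ConversionError("integer inverse verification failed")
    return ConversionMatrix(t.level, inv, direction=_flip(t.direction),
                            ordering=t.ordering)


def _flip(direction: str) -> str:
    a, _, b = direction.partition("_to_")
    return f"{b}_to_{a}"


def apply_conversion(stat, t: ConversionMatrix):
    """Convert a fingerprint matrix or count vector to the opposite flavor.

    ``functional = T^T @ structural`` for the structural->functional
    direction, and conversely with the inverse matrix.  Structural results
    must come out as nonnegative integers; anything else means the input
    was not a realizable statistic of the claimed flavor.
    """
    src, _, dst = t.direction.partition("_to_")
    if isinstance(stat, RoleFingerprintMatrix):
        level, values = "role", stat.values
    elif isinstance(stat, MotifFingerprintMatrix):
        level, values = "motif", stat.values
    elif isinstance(stat, CountVector):
        level, values = stat.level, stat.values
    else:
        raise TypeError(f"cannot convert {type(stat).__name__}")
    if level != t.level:
        raise ValueError(f"{level}-level statistic vs {t.level}-level matrix")
    if stat.flavor != src:
        raise ValueError(
            f"matrix converts {src}->{dst} but statistic is {stat.flavor}")
    out = t.values.T @ values
    if dst == "structural" and (out < 0).any():
        raise ConversionError(
            "conversion produced negative structural counts — input was not "
            "a realizable functional statistic")
    if isinstance(stat, RoleFingerprintMatrix):
        return RoleFingerprintMatrix(dst, out, graph_ref=stat.graph_ref)
    if isinstance(stat, MotifFingerprintMatrix):
        return MotifFingerprintMatrix(dst, out, graph_ref=stat.graph_ref)
    return CountVector(level, dst, out)


def empirical_conversion(level: str,
                         graphs: Sequence,
                         functional_fn: Callable,
                         structural_fn: Callable,
                         catalog: MotifCatalog | None = None,
                         ) -> ConversionMatrix:
    """Recover the conversion matrix from data instead of combinatorics.

    Solves ``functional = X @ structural`` in the least-squares sense
    across the per-node statistics of sample graphs, then rounds to
    integers.  Both counters must be supplied; at the 3-node level the
    result equals the combinatorial derivation exactly.

    Raises ConversionError if the sampled structural statistics are rank
    deficient (e.g. all-empty samples) — use more or denser samples.
    """
    if catalog is None:
        catalog = default_catalog()
    dim = {"role": 30, "motif": 13}[level]
    f_cols, s_cols = [], []
    for g in graphs:
        f_cols.append(np.asarray(functional_fn(g), dtype=float))
        s_cols.append(np.asarray(structural_fn(g), dtype=float))
    fmat = np.column_stack([c.reshape(dim, -1) for c in f_cols])
    smat = np.column_stack([c.reshape(dim, -1) for c in s_cols])
    if np.linalg.matrix_rank(smat) < dim:
        raise ConversionError(
            f"structural samples span rank {np.linalg.matrix_rank(smat)} "
            f"< {dim}; supply more or denser random graphs")
    # F = X S  =>  X^T solves S^T x = F^T column-wise
    x, *_ = np.linalg.lstsq(smat.T, fmat.T, rcond=None)
    values = np.rint(x.T).astype(np.int64)
    return ConversionMatrix(level, values.T,
                            direction="structural_to_functional")


def conversion_frame(t: ConversionMatrix) -> pd.DataFrame:
    """Matrix as a labeled table (paper ids as headers)."""
    prefix = "role" if t.level == "role" else "motif"
    ids = [f"{prefix}_{i + 1}" for i in range(t.size)]
    return pd.DataFrame(t.values, index=ids, columns=ids)


def export_conversion(t: ConversionMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# motifroles conversion matrix; level={t.level}; "
                 f"direction={t.direction}; ordering={t.ordering}\n")
        conversion_frame(t).to_csv(fh, sep="\t", index_label="")
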