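"""Degree-preserving randomization, null ensembles and role overabundance.

The null model rewires by repeated double-edge swaps (a->b, c->d) =>
(a->d, c->b), rejecting swaps that would create self-loops or duplicate
edges.  In- and out-degree sequences are preserved exactly; reciprocal
degree is not (an optional mode that additionally preserves it swaps
single edges and reciprocal pairs separately, off by default).

Per-node role overabundance compares observed functional role counts with
the null-ensemble mean, optionally scaled by total degree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import MotifCatalog, default_catalog
from .clustering import clustering_coefficients, transitivities
from .fingerprints import functional_role_fingerprints
from .graph import DirectedGraph, degree_table

logger = logging.getLogger("motifroles")


@dataclass
class NullEnsemble:
    """Metric records over degree-preserving replicates of one graph."""

    source: str
    n_random: int
    seed: int
    swap_attempts: int
    metrics: tuple[str, ...]
    transitivity_records: pd.DataFrame | None = None   # one row per replicate
    clustering_records: pd.DataFrame | None = None     # global means per rep
    role_fingerprints: list[np.ndarray] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        out: dict = {"source": self.source, "n_random": self.n_random,
                     "seed": self.seed, "swap_attempts": self.swap_attempts}
        if self.transitivity_records is not None:
            out["transitivity_mean"] = self.transitivity_records.mean().to_dict()
            out["transitivity_sd"] = (
                self.transitivity_records.std(ddof=1).to_dict()
                if self.n_random > 1 else
                {k: 0.0 for k in self.transitivity_records.columns})
        if self.clustering_records is not None:
            out["clustering_mean"] = self.clustering_records.mean().to_dict()
            out["clustering_sd"] = (
                self.clustering_records.std(ddof=1).to_dict()
                if self.n_random > 1 else
                {k: 0.0 for k in self.clustering_records.columns})
        if self.flags:
            out["flags"] = list(self.flags)
        return out


def randomize_degree_preserving(g: DirectedGraph, seed: int = 0,
                                attempts: int | None = None,
                                preserve_reciprocity: bool = False,
                                ) -> DirectedGraph:
    """One degree-preserving rewiring of ``g`` via double-edge swaps.

    ``attempts`` is the swap-attempt budget (default 100x edge count).
    Deterministic given the seed.  If not a single swap succeeds within the
    budget, the original adjacency is returned with a logged warning (the
    graph is too constrained to rewire).
    """
    if g.n_edges < 2:
        raise ValueError("need at least 2 edges to swap")
    if attempts is None:
        attempts = 100 * g.n_edges
    if attempts < 1:
        raise ValueError("attempts must be >= 1")
    rng = np.random.default_rng(seed)
    a = g.adjacency.copy()
    if preserve_reciprocity:
        successes = _swap_within(a, a * a.T == 1, rng, attempts // 2,
                                 reciprocal=True)
        successes += _swap_within(a, (a == 1) & (a.T == 0), rng,
                                  attempts - attempts // 2, reciprocal=False)
    else:
        successes = _swap_any(a, rng, attempts)
    if successes == 0:
        logger.warning("%s: no successful swaps in %d attempts; "
                       "returning original copy", g.name, attempts)
    out = DirectedGraph(a, node_labels=g.node_labels,
                        name=f"{g.name}|null(seed={seed})")
    out.rewired = successes > 0  # type: ignore[attr-defined]
    return out


def _swap_any(a: np.ndarray, rng: np.random.Generator, attempts: int) -> int:
    edges = np.argwhere(a == 1)
    m = len(edges)
    successes = 0
    pick = rng.integers(0, m, size=(attempts, 2))
    for e1, e2 in pick:
        s1, t1 = edges[e1]
        s2, t2 = edges[e2]
        # proposed: s1->t2, s2->t1
        if s1 == t2 or s2 == t1:
            continue
        if a[s1, t2] or a[s2, t1]:
            continue
        if not (a[s1, t1] and a[s2, t2]):  # stale entries after prior swaps
            continue
        a[s1, t1] = a[s2, t2] = 0
        a[s1, t2] = a[s2, t1] = 1
        edges[e1] = (s1, t2)
        edges[e2] = (s2, t1)
        successes += 1
    return successes


def _swap_within(a: np.ndarray, mask: np.ndarray, rng: np.random.Generator,
                 attempts: int, reciprocal: bool) -> int:
    """Swap endpoints within one edge family (single or reciprocal pairs)."""
    if reciprocal:
        pairs = np.argwhere(np.triu(mask))
    else:
        pairs = np.argwhere(mask)
    m = len(pairs)
    if m < 2:
        return 0
    successes = 0
    pick = rng.integers(0, m, size=(attempts, 2))
    for e1, e2 in pick:
        (s1, t1), (s2, t2) = pairs[e1], pairs[e2]
        if reciprocal:
            # exchange partners of two reciprocal pairs: {s1,t2}, {s2,t1}
            if len({s1, t1, s2, t2}) != 4:
                continue
            if a[s1, t2] or a[t2, s1] or a[s2, t1] or a[t1, s2]:
                continue
            for x, y in ((s1, t1), (s2, t2)):
                a[x, y] = a[y, x] = 0
            for x, y in ((s1, t2), (s2, t1)):
                a[x, y] = a[y, x] = 1
            pairs[e1] = sorted((s1, t2))
            pairs[e2] = sorted((s2, t1))
        else:
            if s1 == t2 or s2 == t1:
                continue
            # keep swapped edges single in both directions
            if (a[s1, t2] or a[t2, s1] or a[s2, t1] or a[t1, s2]):
                continue
            a[s1, t1] = a[s2, t2] = 0
            a[s1, t2] = a[s2, t1] = 1
            pairs[e1] = (s1, t2)
            pairs[e2] = (s2, t1)
        successes += 1
    return successes


def ensemble_metrics(g: DirectedGraph, n_random: int, seed: int = 0,
                     metrics: tuple[str, ...] = ("transitivities",
                                                 "clustering",
                                                 "role_fingerprints"),
                     attempts: int | None = None,
                     catalog: MotifCatalog | None = None,
                     preserve_reciprocity: bool = False) -> NullEnsemble:
    """Build a null ensemble and record the requested metrics per replicate.

    Replicates use seeds seed, seed+1, ... so runs are reproducible and
    individually recomputable.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    if catalog is None:
        catalog = default_catalog()
    budget = attempts if attempts is not None else 100 * g.n_edges
    ens = NullEnsemble(source=g.name, n_random=n_random, seed=seed,
                       swap_attempts=budget, metrics=tuple(metrics))
    t_rows, c_rows = [], []
    for k in range(n_random):
        null = randomize_degree_preserving(
            g, seed=seed + k, attempts=budget,
            preserve_reciprocity=preserve_reciprocity)
        if not getattr(null, "rewired", True):
            ens.flags.append(f"replicate {k}: no successful swaps")
        rfp = functional_role_fingerprints(null, catalog)
        if "role_fingerprints" in metrics:
            ens.role_fingerprints.append(rfp.values)
        if "transitivities" in metrics:
            t_rows.append(transitivities(rfp, catalog).as_dict())
        if "clustering" in metrics:
            rep = clustering_coefficients(rfp, degree_table(null))
            c_rows.append({f"C_{s}": rep.mean(s) for s in
                           ("tot", "in", "out", "mid", "cyc", "3ff")})
    if t_rows:
        ens.transitivity_records = pd.DataFrame(t_rows)
    if c_rows:
        ens.clustering_records = pd.DataFrame(c_rows)
    return ens


def overabundance(g: DirectedGraph, ensemble: NullEnsemble,
                  scale_by_degree: bool = False,
                  catalog: MotifCatalog | None = None) -> pd.DataFrame:
    """Observed vs null-mean functional role counts, per (node, role).

    Columns: node_id, label, role_id, observed, null_mean, null_sd, excess
    (observed - null mean) and, with ``scale_by_degree``, scaled_excess =
    excess / d_tot (0 for isolated nodes).  Rows are sorted within each
    role by descending excess.
    """
    if not ensemble.role_fingerprints:
        raise ValueError("ensemble does not store role fingerprints; "
                         "request metrics=('role_fingerprints', ...)")
    if catalog is None:
        catalog = default_catalog()
    observed = functional_role_fingerprints(g, catalog).values
    stack = np.stack(ensemble.role_fingerprints)        # (reps, 30, N)
    null_mean = stack.mean(axis=0)
    null_sd = (stack.std(axis=0, ddof=1) if stack.shape[0] > 1
               else np.zeros_like(null_mean, dtype=float))
    labels = g.labels_or_ids()
    d_tot = degree_table(g)["d_tot"].to_numpy(dtype=float)
    rows = []
    for r in range(1, 31):
        excess = observed[r - 1] - null_mean[r - 1]
        order = np.argsort(-excess)
        for i in order:
            row = {
                "node_id": int(i + 1),
                "label": labels[i],
                "role_id": r,
                "observed": int(observed[r - 1, i]),
                "null_mean": float(null_mean[r - 1, i]),
                "null_sd": float(null_sd[r - 1, i]),
                "excess": float(excess[i]),
            }
            if scale_by_degree:
                row["scaled_excess"] = (float(excess[i] / d_tot[i])
                                        if d_tot[i] > 0 else 0.0)
            rows.append(row)
    return pd.DataFrame(rows)
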