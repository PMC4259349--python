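"""Directed clustering coefficients and transitivities from role counts.

Six per-node clustering coefficients (total, in, out, middleman, cycle,
3-feedforward) and the matching network-wide transitivities, plus the
undirected transitivity of the direction-collapsed graph — all expressed
as ratios of functional motif-role counts:

    C_tot = b / D            b = F11 + F14 + F17 + F18 (closed directed
                             triangles, Fagiolo), D = d_tot(d_tot-1) -
                             2 d_recip = 2 (F10 + F13 + F16)
    C_in  = 0.5 F11 / F10    closed convergent pairs over convergent pairs
    C_out = 0.5 F14 / F13
    C_mid = F17 / F16        feed-forward middles over two-path middles
    C_cyc = F18 / F16
    C_3ff = (F11+F14+F17) / (2 F10 + 2 F13 + F16)

Division by zero yields 0.  Transitivities are the same ratios formed
from network totals (ratio of sums, not mean of ratios).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import MotifCatalog, default_catalog
from .conversions import (apply_conversion, derive_role_conversion,
                          invert_conversion)
from .fingerprints import RoleFingerprintMatrix, role_counts
from .graph import DirectedGraph, degree_table

logger = logging.getLogger("motifroles")

SUBTYPES = ("tot", "in", "out", "mid", "cyc", "3ff")

#: integer weights on triangle roles reproducing Fagiolo's closed-triangle
#: count b = diag((A+A^T)^3)/2 — one per three-edge triangle pattern
#: (cycle and the three feed-forward roles); cross-checked by brute force
#: against the matrix-power route in the test suite.
TRIANGLE_ROLE_WEIGHTS = {11: 1, 14: 1, 17: 1, 18: 1}


@dataclass
class TrianglePotentialVectors:
    """b: closed directed triangles per node; D: potential triangles."""

    closed: np.ndarray
    potential: np.ndarray


@dataclass
class ClusteringReport:
    """Per-node clustering vectors and global means for the six subtypes."""

    per_node: pd.DataFrame              # node_id, label, C_<subtype> columns
    global_means: pd.DataFrame          # subtype, mean_all, mean_defined, n_star
    flavor: str = "functional"

    def vector(self, subtype: str) -> np.ndarray:
        return self.per_node[f"C_{subtype}"].to_numpy()

    def mean(self, subtype: str, over: str = "defined") -> float:
        """Global mean; ``over`` is 'defined' (n* nodes, headline) or 'all'."""
        row = self.global_means.set_index("subtype").loc[subtype]
        return float(row["mean_defined" if over == "defined" else "mean_all"])


@dataclass
class TransitivityReport:
    """Network-wide transitivities (six directed + one undirected)."""

    T_tot: float
    T_in: float
    T_out: float
    T_mid: float
    T_cyc: float
    T_3ff: float
    T_undirected: float
    notes: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k)
                for k in ("T_tot", "T_in", "T_out", "T_mid", "T_cyc",
                          "T_3ff", "T_undirected")}


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros(len(num), dtype=float)
    np.divide(num, den, out=out, where=den > 0)
    return out


def _numerators_denominators(rfp: RoleFingerprintMatrix,
                             ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Numerator/denominator vectors of the six subtypes, as role sums.

    D = d_tot(d_tot-1) - 2 d_recip equals 2(F10 + F13 + F16) identically,
    so every quantity here is a pure role-fingerprint expression.
    """
    f = rfp.values.astype(float)
    b = sum(w * f[r - 1] for r, w in TRIANGLE_ROLE_WEIGHTS.items())
    big_d = 2.0 * (f[9] + f[12] + f[15])
    # the 0.5 factors: two possible edges close roles 10 and 13 into a
    # feed-forward triangle
    return {
        "tot": (b, big_d),
        "in": (0.5 * f[10], f[9]),
        "out": (0.5 * f[13], f[12]),
        "mid": (f[16], f[15]),
        "cyc": (f[17], f[15]),
        "3ff": (f[10] + f[13] + f[16], 2 * f[9] + 2 * f[12] + f[15]),
    }


def triangle_potential(g: DirectedGraph,
                       rfp_functional: RoleFingerprintMatrix,
                       ) -> TrianglePotentialVectors:
    """Fagiolo's closed-triangle and potential-triangle vectors.

    b is a fixed integer-weighted sum of the triangle-role fingerprints,
    equal to half the diagonal of the cubed symmetrized adjacency;
    D_i = d_tot(d_tot - 1) - 2 d_recip, computed from the degree table.
    """
    deg = degree_table(g)
    d_tot = deg["d_tot"].to_numpy(dtype=np.int64)
    d_rec = deg["d_recip"].to_numpy(dtype=np.int64)
    b, _ = _numerators_denominators(rfp_functional)["tot"]
    return TrianglePotentialVectors(
        closed=b.astype(np.int64),
        potential=d_tot * (d_tot - 1) - 2 * d_rec)


def clustering_coefficients(rfp: RoleFingerprintMatrix,
                            degrees: pd.DataFrame,
                            allow_structural: bool = False,
                            ) -> ClusteringReport:
    """Per-node directed clustering coefficients, all six subtypes.

    Global means are reported both over all N nodes and over the n* nodes
    whose denominator is nonzero (the headline variant); nodes with a zero
    denominator get coefficient 0.

    Structural role counts in the same formulas are an experimental
    variant, enabled only with ``allow_structural=True``.
    """
    if rfp.flavor == "structural" and not allow_structural:
        raise ValueError("structural clustering coefficients are experimental; "
                         "pass allow_structural=True")
    parts = _numerators_denominators(rfp)
    data = {"node_id": degrees["node_id"].to_numpy(),
            "label": degrees["label"].to_numpy()}
    means = []
    for name in SUBTYPES:
        num, den = parts[name]
        c = _safe_div(num, den)
        data[f"C_{name}"] = c
        defined = den > 0
        n_star = int(defined.sum())
        means.append({
            "subtype": name,
            "mean_all": float(c.mean()),
            "mean_defined": float(c[defined].mean()) if n_star else 0.0,
            "n_star": n_star,
        })
    return ClusteringReport(per_node=pd.DataFrame(data),
                            global_means=pd.DataFrame(means),
                            flavor=rfp.flavor)


def transitivities(rfp_functional: RoleFingerprintMatrix,
                   catalog: MotifCatalog | None = None,
                   ) -> TransitivityReport:
    """Network-wide transitivities: summed numerators over summed
    denominators for each subtype, plus the undirected transitivity from
    structural motif counts.

    The cycle denominator is the total two-path count (all three roles of
    motif 2 sum to it identically).  An empty denominator yields 0 with a
    logged note.
    """
    if rfp_functional.flavor != "functional":
        raise ValueError("transitivities are defined from functional counts")
    if catalog is None:
        catalog = default_catalog()
    parts = _numerators_denominators(rfp_functional)
    notes: list[str] = []
    vals = {}
    for name in SUBTYPES:
        num, den = parts[name]
        total = den.sum()
        if total == 0:
            notes.append(f"T_{name}: empty denominator, reported as 0")
            logger.info("T_%s: empty denominator, reported as 0", name)
            vals[name] = 0.0
        else:
            vals[name] = float(num.sum() / total)
    t_und = _undirected_transitivity(rfp_functional, catalog, notes)
    return TransitivityReport(
        T_tot=vals["tot"], T_in=vals["in"], T_out=vals["out"],
        T_mid=vals["mid"], T_cyc=vals["cyc"], T_3ff=vals["3ff"],
        T_undirected=t_und, notes=notes)


def _undirected_transitivity(rfp_functional: RoleFingerprintMatrix,
                             catalog: MotifCatalog,
                             notes: list[str]) -> float:
    """3 x (triangle-class structural total) / triangle-weighted triad
    census; equals the standard transitivity of the collapsed graph."""
    t_inv = invert_conversion(derive_role_conversion(catalog))
    s_role = apply_conversion(role_counts(rfp_functional), t_inv)
    motif_totals = np.zeros(13, dtype=np.int64)
    for m in range(1, 14):
        rows = [r - 1 for r in catalog.roles_of_motif(m)]
        motif_totals[m - 1] = s_role.values[rows].sum() // 3
    tri_ids = catalog.triangle_motifs
    tri = motif_totals[[m - 1 for m in tri_ids]].sum()
    open_total = motif_totals[[m - 1 for m in range(1, 14)
                               if m not in tri_ids]].sum()
    denom = 3 * tri + open_total
    if denom == 0:
        notes.append("T_undirected: no connected triples, reported as 0")
        logger.info("T_undirected: no connected triples, reported as 0")
        return 0.0
    return float(3 * tri / denom)


def clustering_report_frames(g: DirectedGraph,
                             catalog: MotifCatalog | None = None,
                             ) -> tuple[ClusteringReport, TransitivityReport]:
    """Convenience: full clustering + transitivity analysis of a graph."""
    from .fingerprints import functional_role_fingerprints
    rfp = functional_role_fingerprints(g, catalog)
    report = clustering_coefficients(rfp, degree_table(g))
    trans = transitivities(rfp, catalog)
    return report, trans
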