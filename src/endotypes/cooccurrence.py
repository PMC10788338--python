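"""Comorbidity co-occurrence statistics and the association network.

For each pair of comorbidity flags (i, j) the relative risk of
co-occurrence is the observed joint count over the count expected under
independence,

    RR_ij = C_ij * N / (P_i * P_j),

with C_ij the number of patients carrying both conditions, P_i and P_j
the single-condition prevalence counts and N the cohort size (Hidalgo-
style disease-network RR). Uncertainty uses the log-scale Katz-style
interval ``log RR +/- z * sqrt(1/C_ij)`` and a two-sided Fisher exact
test on the pair's 2x2 table. Edges passing ``p < p_max`` and
``RR > rr_min`` form the association network; the RR used for display is
capped while the true value is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PairAssociation", "pair_stats", "all_pairs", "build_network",
           "network_to_frame"]


@dataclass(frozen=True)
class PairAssociation:
    """Co-occurrence statistics for one comorbidity pair (i < j)."""

    i: int
    j: int
    name_i: str
    name_j: str
    c_ij: int        # joint count
    p_i: int         # prevalence count of i
    p_j: int         # prevalence count of j
    n: int           # cohort size
    rr: float
    ci_low: float
    ci_high: float
    p_value: float


def pair_stats(matrix, i: int, j: int, z: float = 1.959963984540054
               ) -> PairAssociation:
    """Relative risk, CI and Fisher p-value for one pair of columns.

    When either marginal prevalence is zero the RR is undefined and
    reported as NaN; when C_ij = 0 the RR is 0 and the CI is undefined.
    """
    if i == j:
        raise ValueError("pair_stats requires two distinct categories")
    x = matrix.to_numpy() if hasattr(matrix, "to_numpy") else np.asarray(matrix)
    names = (list(matrix.columns) if hasattr(matrix, "columns")
             else [str(c) for c in range(x.shape[1])])
    a = x[:, i].astype(bool)
    b = x[:, j].astype(bool)
    n = x.shape[0]
    c_ij = int((a & b).sum())
    p_i = int(a.sum())
    p_j = int(b.sum())

    if p_i == 0 or p_j == 0:
        rr = float("nan")
    else:
        rr = c_ij * n / (p_i * p_j)

    if c_ij > 0 and np.isfinite(rr) and rr > 0:
        half = z * np.sqrt(1.0 / c_ij)
        ci_low = float(np.exp(np.log(rr) - half))
        ci_high = float(np.exp(np.log(rr) + half))
    else:
        ci_low = ci_high = float("nan")

    table = [[c_ij, p_i - c_ij], [p_j - c_ij, n - p_i - p_j + c_ij]]
    p_value = float(stats.fisher_exact(table, alternative="two-sided")[1])

    lo, hi = min(i, j), max(i, j)
    if lo != i:
        p_i, p_j = p_j, p_i
    return PairAssociation(i=lo, j=hi, name_i=names[lo], name_j=names[hi],
                           c_ij=c_ij, p_i=p_i, p_j=p_j, n=n, rr=float(rr),
                           ci_low=ci_low, ci_high=ci_high, p_value=p_value)


def all_pairs(matrix) -> list[PairAssociation]:
    """PairAssociation for every unordered column pair, i < j."""
    x = matrix.to_numpy() if hasattr(matrix, "to_numpy") else np.asarray(matrix)
    j = x.shape[1]
    if j < 2:
        raise ValueError("need at least two comorbidity columns")
    return [pair_stats(matrix, a, b) for a, b in combinations(range(j), 2)]


def build_network(pairs, matrix=None, p_max: float = 0.05,
                  rr_min: float = 1.5, rr_cap: float = 5.0) -> nx.Graph:
    """Filtered association network as a networkx graph.

    Edges with ``p < p_max`` and ``RR > rr_min`` (both strict) are kept.
    Each edge stores the true RR (``rr``), a capped display value
    (``rr_display = min(rr, rr_cap)``), the joint count and the p-value.
    Node ``prevalence`` attributes come from `matrix` column sums when a
    comorbidity matrix is supplied, else from the pair records.
    """
    g = nx.Graph(p_max=p_max, rr_min=rr_min, rr_cap=rr_cap)
    prevalence: dict[str, int] = {}
    for pa in pairs:
        prevalence.setdefault(pa.name_i, pa.p_i)
        prevalence.setdefault(pa.name_j, pa.p_j)
    if matrix is not None and hasattr(matrix, "columns"):
        prevalence = {c: int(matrix[c].sum()) for c in matrix.columns}
    for name, prev in prevalence.items():
        g.add_node(name, prevalence=prev)
    for pa in pairs:
        if np.isfinite(pa.rr) and pa.rr > rr_min and pa.p_value < p_max:
            g.add_edge(pa.name_i, pa.name_j, rr=pa.rr,
                       rr_display=min(pa.rr, rr_cap), c_ij=pa.c_ij,
                       p_value=pa.p_value)
    return g


def network_to_frame(pairs) -> pd.DataFrame:
    """All pair statistics as a tidy DataFrame (one row per pair)."""
    return pd.DataFrame([asdict(p) for p in pairs])
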