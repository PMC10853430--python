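"""Spearman co-occurrence network inference.

Nodes are per-sample features — van Krevelen class percentages, element
group percentages, soil-chemistry variables, and genus relative
abundances — and an edge connects two features whose Spearman rank
correlation is significant at ``alpha`` (raw p < 0.05 by default; an
optional Benjamini-Hochberg mode adjusts across all tested pairs).
Edge sign records the correlation direction.

p-values come from the exact permutation distribution of rho when the
sample count is small (n <= 9 by default) and from the usual
t-approximation otherwise; with 12 samples (3 replicates x 4 conditions,
the scale this is built for) the approximation is standard practice.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

FEATURE_CATEGORIES = ("compound_class", "element_group", "chemistry", "genus")

#: Largest n for which the exact permutation null is enumerated by default.
EXACT_N_MAX = 9


@dataclass(frozen=True, slots=True)
class Edge:
    """A significant signed Spearman association between two features."""

    node_a: str
    node_b: str
    rho: float
    p_value: float

    @property
    def sign(self) -> str:
        return "positive" if self.rho > 0 else "negative"


def _rank_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    """Pearson correlation of two (average-tied) rank vectors."""
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        raise ValueError("constant vector: Spearman correlation undefined")
    return float(rx @ ry) / denom


def _exact_p(rx: np.ndarray, ry: np.ndarray, rho: float) -> float:
    """Two-sided p from the full permutation distribution of rho.

    Enumerates all n! pairings of the two rank vectors; feasible for the
    small n this path is reserved for (9! ~ 3.6e5).
    """
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
    ry_c = ry - ry.mean()
    rx_c = rx - rx.mean()
    denom = math.sqrt(float(rx_c @ rx_c) * float(ry_c @ ry_c))
    rhos = (rx_c[perms] @ ry_c) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))


def spearman_pair(
    x: np.ndarray | list[float],
    y: np.ndarray | list[float],
    method: str = "auto",
) -> tuple[float, float]:
    """Spearman rho and two-sided p-value for one feature pair.

    ``method`` is ``"exact"`` (full permutation null), ``"asymptotic"``
    (t-approximation), or ``"auto"`` (exact iff n <= 9).  Requires equal
    lengths, n >= 4, and non-constant vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 4:
        raise ValueError(f"need at least 4 samples for a correlation, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman correlation undefined")
    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _rank_rho(rx, ry)
    if method == "exact" or (method == "auto" and n <= EXACT_N_MAX):
        return rho, _exact_p(rx, ry, rho)
    # t-approximation on ranks (the textbook large-sample Spearman test)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return rho, p


def build_network(
    matrix: pd.DataFrame,
    categories: dict[str, str] | pd.Series | None = None,
    alpha: float = 0.05,
    bh: bool = False,
    method: str = "auto",
) -> list[Edge]:
    """Test every unordered feature pair and keep the significant edges.

    ``matrix`` holds samples as rows and features as columns;
    ``categories`` optionally maps feature -> category (kept as node
    metadata on export).  Constant features are skipped with a warning.
    With ``bh=True`` the edge criterion becomes BH-adjusted p < alpha.
    Edges are returned sorted by |rho| descending (name order on ties).
    """
    if len(matrix) < 4:
        raise ValueError(f"need at least 4 samples, got {len(matrix)}")
    if matrix.isna().any().any():
        n0 = len(matrix)
        matrix = matrix.dropna(axis=0)
        logger.warning("dropped %d rows with missing entries", n0 - len(matrix))
        if len(matrix) < 4:
            raise ValueError("fewer than 4 complete samples after dropping missing rows")
    usable = []
    for col in matrix.columns:
        if np.ptp(matrix[col].to_numpy(dtype=float)) == 0:
            logger.warning("feature %r is constant; skipped", col)
        else:
            usable.append(col)
    tested: list[tuple[str, str, float, float]] = []
    for a, b in itertools.combinations(usable, 2):
        rho, p = spearman_pair(matrix[a].to_numpy(float), matrix[b].to_numpy(float), method)
        tested.append((a, b, rho, p))
    if not tested:
        return []
    pvals = np.array([t[3] for t in tested])
    crit = stats.false_discovery_control(pvals) if bh else pvals
    edges = [
        Edge(a, b, rho, p)
        for (a, b, rho, p), q in zip(tested, crit)
        if q < alpha
    ]
    edges.sort(key=lambda e: (-abs(e.rho), e.node_a, e.node_b))
    logger.info("network: %d/%d pairs significant at alpha=%g%s",
                len(edges), len(tested), alpha, " (BH)" if bh else "")
    return edges


def edges_to_frame(edges: list[Edge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"node_a": e.node_a, "node_b": e.node_b, "rho": e.rho, "p_value": e.p_value, "sign": e.sign}
            for e in edges
        ],
        columns=["node_a", "node_b", "rho", "p_value", "sign"],
    )


def to_graph(
    edges: list[Edge], categories: dict[str, str] | pd.Series | None = None
) -> nx.Graph:
    """Undirected graph with rho/p/sign edge attributes and node categories."""
    g = nx.Graph()
    for e in edges:
        g.add_edge(e.node_a, e.node_b, rho=e.rho, p_value=e.p_value, sign=e.sign)
    if categories is not None:
        cat = dict(categories)
        for node in g.nodes:
            if node in cat:
                g.nodes[node]["category"] = cat[node]
    return g


def write_graphml(
    edges: list[Edge],
    path: str | Path,
    categories: dict[str, str] | pd.Series | None = None,
) -> None:
    nx.write_graphml(to_graph(edges, categories), str(path))
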