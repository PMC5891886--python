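"""Differential Spearman correlation networks between ratio groups.

For each ratio group x tissue compartment, every unordered endpoint pair is
tested for Spearman rank correlation; pairs with rho >= 0.75 and p <= 0.01
form that stratum's significant edge set.  Within a compartment, edges
present in both groups are *shared* and removed; the remaining *exclusive*
edges form each group's differential network, whose nodes carry their degree
(number of exclusive correlations) and a modularity community label.

The rho filter is one-sided positive by default (taken literally from the
significance rule); pass ``abs_rho=True`` for the absolute-value variant.
p-values use the two-sided t approximation ``t = rho * sqrt((n-2)/(1-rho^2))``
on n-2 degrees of freedom; a perfect correlation is reported at the exact
permutation value 2/n!.  An exact full-enumeration permutation p is available
for small samples (n <= 8) and serves as the small-n oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations, permutations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_RHO_MIN = 0.75
DEFAULT_P_MAX = 0.01
MIN_PAIRS = 4

HIGH_RATIO = "high"
LOW_RATIO = "low"


@dataclass(frozen=True)
class CorrelationEdge:
    """A significant correlation between two endpoints (canonical order)."""

    endpoint_a: str
    endpoint_b: str
    rho: float
    p_value: float
    n_obs: int

    def __post_init__(self) -> None:
        if self.endpoint_a >= self.endpoint_b:
            raise ValueError("edge endpoints must be in lexicographic order")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.endpoint_a, self.endpoint_b)


@dataclass
class EndpointMatrix:
    """Reduced abundances for one group x compartment (cases x endpoints)."""

    group: str
    compartment: str
    cases: list[str]
    endpoints: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape != (len(self.cases), len(self.endpoints)):
            raise ValueError("matrix shape does not match labels")
        if len(set(self.cases)) != len(self.cases):
            raise ValueError("duplicate case ids")
        if len(set(self.endpoints)) != len(self.endpoints):
            raise ValueError("duplicate endpoint names")

    @classmethod
    def from_frame(cls, group: str, compartment: str, df: pd.DataFrame) -> "EndpointMatrix":
        return cls(
            group=group,
            compartment=compartment,
            cases=[str(c) for c in df.index],
            endpoints=[str(c) for c in df.columns],
            values=df.to_numpy(float),
        )


@dataclass
class EdgeSet:
    """Significant correlation edges for one group x compartment."""

    group: str
    compartment: str
    edges: dict[tuple[str, str], CorrelationEdge]
    n_pairs_evaluated: int = 0
    n_pairs_skipped: int = 0

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(self.edges)

    def __len__(self) -> int:
        return len(self.edges)


def _canonical(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


def _t_approx_p(rho: float, n: int) -> float:
    if abs(rho) >= 1.0 - 1e-12:
        return 2.0 / math.factorial(n)
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float | None:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return None
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_edge(
    x, y, method: str = "t_approx"
) -> tuple[float, float, int] | None:
    """Spearman rho with p-value for one endpoint pair.

    Missing values are removed pairwise.  Returns ``(rho, p, n_obs)`` or
    ``None`` when fewer than four complete pairs remain or either vector has
    zero variance.  ``method`` is ``"t_approx"`` (default) or
    ``"permutation"`` (exact full enumeration, n <= 8): the permutation p is
    the two-sided tail probability P(|rho_perm| >= |rho_obs|) over all n!
    rank orderings.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < MIN_PAIRS:
        return None
    rho = _spearman_rho(x, y)
    if rho is None:
        return None
    if method == "t_approx":
        p = _t_approx_p(rho, n)
    elif method == "permutation":
        if n > 8:
            raise ValueError("exact permutation p supported only for n <= 8")
        ry = stats.rankdata(y)
        rhos = []
        for perm in permutations(stats.rankdata(x)):
            r = np.corrcoef(perm, ry)[0, 1]
            rhos.append(r)
        rhos = np.array(rhos)
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        raise ValueError(f"unknown p-value method {method!r}")
    return rho, p, n


def _rho_matrix(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman rho on a complete (no-NaN) matrix; returns
    (rho matrix, column standard deviations of the ranks)."""
    ranks = np.apply_along_axis(stats.rankdata, 0, values)
    sd = ranks.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    return rho, sd


def significant_edges(
    matrix: EndpointMatrix,
    rho_min: float = DEFAULT_RHO_MIN,
    p_max: float = DEFAULT_P_MAX,
    abs_rho: bool = False,
) -> EdgeSet:
    """Evaluate every unordered endpoint pair and keep significant edges.

    An edge is significant when rho >= rho_min (|rho| >= rho_min with
    ``abs_rho``) AND p <= p_max; both conditions are enforced.  Pairs with
    fewer than four complete observations or zero rank variance are skipped
    and counted in ``n_pairs_skipped``.
    """
    endpoints = matrix.endpoints
    values = matrix.values
    m = len(endpoints)
    edges: dict[tuple[str, str], CorrelationEdge] = {}
    n_eval = 0
    n_skip = 0

    def admit(i: int, j: int, rho: float, n: int) -> None:
        nonlocal n_eval
        n_eval += 1
        stat = abs(rho) if abs_rho else rho
        if stat < rho_min:
            return
        p = _t_approx_p(rho, n)
        if p > p_max:
            return
        a, b = _canonical(endpoints[i], endpoints[j])
        edges[(a, b)] = CorrelationEdge(a, b, rho, p, n)

    if not np.isnan(values).any():
        rho_mat, sd = _rho_matrix(values)
        n = values.shape[0]
        for i, j in combinations(range(m), 2):
            if n < MIN_PAIRS or sd[i] == 0 or sd[j] == 0:
                n_skip += 1
                continue
            admit(i, j, float(rho_mat[i, j]), n)
    else:
        for i, j in combinations(range(m), 2):
            res = spearman_edge(values[:, i], values[:, j])
            if res is None:
                n_skip += 1
                continue
            rho, _, n = res
            admit(i, j, rho, n)

    return EdgeSet(
        group=matrix.group,
        compartment=matrix.compartment,
        edges=edges,
        n_pairs_evaluated=n_eval,
        n_pairs_skipped=n_skip,
    )


def shared_and_exclusive(
    edges_a: EdgeSet, edges_b: EdgeSet
) -> tuple[set[tuple[str, str]], EdgeSet, EdgeSet]:
    """Partition two same-compartment edge sets into shared and exclusive.

    ``shared`` holds the pairs significant in both groups; each exclusive set
    keeps its own group's rho/p for pairs absent from the other group.
    """
    if edges_a.compartment != edges_b.compartment:
        raise ValueError(
            f"compartment mismatch: {edges_a.compartment!r} vs {edges_b.compartment!r}"
        )
    shared = edges_a.pairs & edges_b.pairs
    excl_a = EdgeSet(
        group=edges_a.group,
        compartment=edges_a.compartment,
        edges={k: v for k, v in edges_a.edges.items() if k not in shared},
        n_pairs_evaluated=edges_a.n_pairs_evaluated,
        n_pairs_skipped=edges_a.n_pairs_skipped,
    )
    excl_b = EdgeSet(
        group=edges_b.group,
        compartment=edges_b.compartment,
        edges={k: v for k, v in edges_b.edges.items() if k not in shared},
        n_pairs_evaluated=edges_b.n_pairs_evaluated,
        n_pairs_skipped=edges_b.n_pairs_skipped,
    )
    return shared, excl_a, excl_b


@dataclass
class DifferentialNetwork:
    """Graph of exclusive edges; node size = degree, edge weight = rho."""

    group: str
    compartment: str
    graph: nx.Graph
    communities: dict[str, int] = field(default_factory=dict)
    n_subgroups: int = 0


def build_network(edges: EdgeSet) -> DifferentialNetwork:
    """Build the differential network graph from an (exclusive) edge set.

    Endpoints with no incident edge are omitted; node insertion order is the
    sorted endpoint order so downstream algorithms are deterministic.
    """
    g = nx.Graph()
    nodes = sorted({n for pair in edges.edges for n in pair})
    g.add_nodes_from(nodes)
    for (a, b), e in sorted(edges.edges.items()):
        g.add_edge(a, b, weight=float(e.rho), rho=float(e.rho), p_value=float(e.p_value))
    for n in g.nodes:
        g.nodes[n]["degree"] = int(g.degree[n])
    return DifferentialNetwork(edges.group, edges.compartment, g)


def detect_subgroups(
    network: DifferentialNetwork, seed: int, resolution: float = 1.0
) -> tuple[dict[str, int], int]:
    """Partition the network into modularity subgroups (seeded Louvain).

    Edge weights are the Spearman rho values.  Community ids are relabelled
    contiguously from 0 in order of each community's lexicographically
    smallest member, so the labelling is reproducible for a fixed seed.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        network.communities, network.n_subgroups = {}, 0
        return {}, 0
    comms = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=seed
    )
    comms = sorted((sorted(c) for c in comms if c), key=lambda c: c[0])
    labels = {node: cid for cid, members in enumerate(comms) for node in members}
    network.communities = labels
    network.n_subgroups = len(comms)
    for node, cid in labels.items():
        g.nodes[node]["community"] = int(cid)
    return labels, len(comms)


def export_network(network: DifferentialNetwork, path, format: str = "gexf") -> None:
    """Write the network to GEXF or GraphML."""
    if format == "gexf":
        nx.write_gexf(network.graph, path)
    elif format == "graphml":
        nx.write_graphml(network.graph, path)
    else:
        raise ValueError(f"unknown export format {format!r}")


def read_network(path, format: str = "gexf") -> nx.Graph:
    if format == "gexf":
        g = nx.read_gexf(path)
    elif format == "graphml":
        g = nx.read_graphml(path)
    else:
        raise ValueError(f"unknown export format {format!r}")
    return g


def edge_table(
    edge_set: EdgeSet, shared: set[tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Tabulate an edge set (before partitioning) with shared/exclusive status."""
    rows = []
    for (a, b), e in sorted(edge_set.edges.items()):
        status = "shared" if shared is not None and (a, b) in shared else "exclusive"
        rows.append((a, b, e.rho, e.p_value, e.n_obs, status))
    return pd.DataFrame(
        rows, columns=["endpoint_a", "endpoint_b", "rho", "p", "n_obs", "status"]
    )


def endpoint_matrices(
    reduced_wide: pd.DataFrame,
    group_labels: dict[str, str],
    exclude_cases: set[str] | None = None,
) -> dict[tuple[str, str], EndpointMatrix]:
    """Split a reduced wide matrix into the four group x compartment matrices.

    ``reduced_wide`` is indexed by (case_id, compartment); ``group_labels``
    maps case_id to ``"high"``/``"low"``.  Excluded cases are dropped first.
    """
    exclude_cases = exclude_cases or set()
    out: dict[tuple[str, str], EndpointMatrix] = {}
    for group in (HIGH_RATIO, LOW_RATIO):
        case_ids = [
            c
            for c, gl in group_labels.items()
            if gl == group and c not in exclude_cases
        ]
        for comp in sorted({ix[1] for ix in reduced_wide.index}):
            sub = reduced_wide.loc[
                [(c, comp) for c in case_ids if (c, comp) in reduced_wide.index]
            ]
            df = sub.droplevel("compartment")
            out[(group, comp)] = EndpointMatrix.from_frame(group, comp, df)
    return out
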