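"""Multi-omic feature selection around a seed gene and BIC-scored
Bayesian-network structure learning.

Feature selection is the two-stage correlation procedure: transcripts whose
absolute Pearson correlation with the seed gene exceeds the mRNA threshold,
then variables in the other layers (microRNA, DNA methylation, protein)
correlated above their layer thresholds with ANY selected transcript.

Structure learning is greedy hill climbing over add/delete/reverse moves on
a linear-Gaussian BIC score (all layers treated as continuous), restarted
from seeded random DAGs, with acyclicity enforced at every move and a
maximum in-degree to bound overfitting at small n.  The score decomposes
per node, so each move rescoring touches only the affected nodes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from raceqtl.errors import ConfigError

#: default absolute-correlation thresholds per layer
DEFAULT_THRESHOLDS = {"mrna": 0.38, "mirna": 0.45, "methylation": 0.40, "protein": 0.30}
DEFAULT_MAX_PARENTS = 3
DEFAULT_RESTARTS = 20


@dataclass
class OmicsLayers:
    """Aligned per-sample values for the four omic layers.

    ``data`` is samples x variables with no missing values after alignment;
    ``layers`` labels each variable with its layer name.
    """

    data: pd.DataFrame
    layers: pd.Series

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ConfigError("omics layers contain missing values after alignment")
        unknown = set(self.data.columns) - set(self.layers.index)
        if unknown:
            raise ConfigError(f"variables without layer labels: {sorted(unknown)}")


@dataclass
class NetworkModel:
    """A learned DAG with its decomposable score."""

    graph: nx.DiGraph
    score: float
    local_scores: dict[str, float]

    def edges_frame(self, layers: pd.Series | None = None) -> pd.DataFrame:
        rows = []
        for parent, child in sorted(self.graph.edges):
            rows.append(
                {
                    "parent": parent,
                    "child": child,
                    "parent_layer": None if layers is None else layers.get(parent),
                    "child_layer": None if layers is None else layers.get(child),
                }
            )
        return pd.DataFrame(rows, columns=["parent", "child", "parent_layer", "child_layer"])


def select_features(
    layers: OmicsLayers,
    seed_gene: str,
    thresholds: dict[str, float] | None = None,
) -> list[str]:
    """Two-stage correlation-thresholded selection around the seed gene."""
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    for t in thresholds.values():
        if not 0.0 < t < 1.0:
            raise ConfigError("thresholds must lie in (0, 1)")
    if seed_gene not in layers.data.columns:
        raise ConfigError(f"seed gene {seed_gene} absent from mRNA layer")
    if layers.layers[seed_gene] != "mrna":
        raise ConfigError(f"seed gene {seed_gene} is not an mRNA variable")
    corr = layers.data.corr(method="pearson")
    mrna_vars = [
        v for v in layers.data.columns
        if layers.layers[v] == "mrna" and v != seed_gene
    ]
    stage1 = [v for v in mrna_vars if abs(corr.loc[seed_gene, v]) > thresholds["mrna"]]
    transcripts = [seed_gene] + stage1
    selected = set(transcripts)
    for v in layers.data.columns:
        layer = layers.layers[v]
        if layer == "mrna" or v in selected:
            continue
        t = thresholds.get(layer)
        if t is None:
            continue
        if any(abs(corr.loc[v, tr]) > t for tr in transcripts):
            selected.add(v)
    # deterministic order: seed first, then original column order
    return [v for v in layers.data.columns if v in selected]


def _local_bic(data: pd.DataFrame, node: str, parents: tuple[str, ...]) -> float:
    """Gaussian log-likelihood of node | parents minus (k/2) log n.

    k counts the intercept, the regression coefficients, and the residual
    variance.  Higher is better.
    """
    y = data[node].to_numpy(dtype=float)
    n = len(y)
    if parents:
        x = np.column_stack([np.ones(n)] + [data[p].to_numpy(dtype=float) for p in parents])
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
    else:
        resid = y - y.mean()
    sigma2 = max(float(resid @ resid) / n, 1e-12)
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    k = len(parents) + 2
    return loglik - 0.5 * k * np.log(n)


def bic_score(data: pd.DataFrame, dag: nx.DiGraph) -> float:
    """Decomposable linear-Gaussian BIC of a DAG; higher is better."""
    if not nx.is_directed_acyclic_graph(dag):
        raise ConfigError("graph must be acyclic")
    return sum(
        _local_bic(data, node, tuple(sorted(dag.predecessors(node))))
        for node in dag.nodes
    )


def _random_dag(nodes: list[str], rng: np.random.Generator, p_edge: float = 0.15,
                max_parents: int = DEFAULT_MAX_PARENTS) -> nx.DiGraph:
    order = list(rng.permutation(nodes))
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for i, j in itertools.combinations(range(len(order)), 2):
        if rng.random() < p_edge and g.in_degree(order[j]) < max_parents:
            g.add_edge(order[i], order[j])
    return g


def _candidate_moves(g: nx.DiGraph, nodes: list[str], max_parents: int):
    """Lexicographically ordered add/delete/reverse moves preserving the DAG."""
    for u, v in itertools.permutations(nodes, 2):
        if g.has_edge(u, v):
            yield ("delete", u, v)
            if g.in_degree(u) < max_parents and not _would_cycle_reversed(g, u, v):
                yield ("reverse", u, v)
        elif g.in_degree(v) < max_parents and not nx.has_path(g, v, u):
            yield ("add", u, v)


def _would_cycle_reversed(g: nx.DiGraph, u: str, v: str) -> bool:
    g.remove_edge(u, v)
    cyc = nx.has_path(g, u, v)
    g.add_edge(u, v)
    return cyc


def hill_climb(
    data: pd.DataFrame,
    nodes: list[str] | None = None,
    restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
    max_parents: int = DEFAULT_MAX_PARENTS,
) -> NetworkModel:
    """Greedy BIC hill climbing with seeded random restarts.

    Each restart begins from a random DAG (the first from the empty graph),
    repeatedly applies the best score-improving add/delete/reverse move, and
    stops at a local optimum; the best-scoring restart wins.  Ties break by
    lexicographic move order, so results are seed-deterministic.
    """
    nodes = list(data.columns) if nodes is None else list(nodes)
    if len(nodes) < 2:
        raise ConfigError("need at least 2 nodes")
    if len(data) <= max_parents + 1:
        raise ConfigError("need more samples than the in-degree bound")
    rng = np.random.default_rng(seed)
    sub = data[nodes]
    best: NetworkModel | None = None
    for r in range(restarts):
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        if r > 0:
            g = _random_dag(nodes, rng, max_parents=max_parents)
        local = {
            v: _local_bic(sub, v, tuple(sorted(g.predecessors(v)))) for v in nodes
        }
        while True:
            best_gain, best_move = 1e-9, None
            for move, u, v in _candidate_moves(g, nodes, max_parents):
                gain = _move_gain(sub, g, local, move, u, v)
                if gain > best_gain:
                    best_gain, best_move = gain, (move, u, v)
            if best_move is None:
                break
            _apply_move(g, *best_move)
            move, u, v = best_move
            local[v] = _local_bic(sub, v, tuple(sorted(g.predecessors(v))))
            if move == "reverse":
                local[u] = _local_bic(sub, u, tuple(sorted(g.predecessors(u))))
        total = sum(local.values())
        if best is None or total > best.score:
            best = NetworkModel(graph=g, score=total, local_scores=dict(local))
    assert best is not None
    return best


def _move_gain(data, g, local, move, u, v) -> float:
    """Score change of one move, rescoring only the affected nodes."""
    pv = set(g.predecessors(v))
    if move == "add":
        new_v = _local_bic(data, v, tuple(sorted(pv | {u})))
        return new_v - local[v]
    if move == "delete":
        new_v = _local_bic(data, v, tuple(sorted(pv - {u})))
        return new_v - local[v]
    # reverse u->v: v loses parent u, u gains parent v
    pu = set(g.predecessors(u))
    new_v = _local_bic(data, v, tuple(sorted(pv - {u})))
    new_u = _local_bic(data, u, tuple(sorted(pu | {v})))
    return (new_v - local[v]) + (new_u - local[u])


def _apply_move(g: nx.DiGraph, move: str, u: str, v: str) -> None:
    if move == "add":
        g.add_edge(u, v)
    elif move == "delete":
        g.remove_edge(u, v)
    else:
        g.remove_edge(u, v)
        g.add_edge(v, u)
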