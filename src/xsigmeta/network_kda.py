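"""Weighted key-driver analysis.

Each candidate hub (degree >= min_degree) is scored by the weighted overlap
of its immediate neighborhood with a DEG set.  The null permutes DEG-set
membership over network nodes with exactly matched set size; the empirical
one-sided p-value and permutation z-score feed BH control per DEG set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import PipelineError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class KDResult:
    deg_set: str
    node: str
    neighborhood_size: int
    observed: float
    expected: float
    ratio: float
    z: float
    pvalue: float
    fdr: float = float("nan")
    significant: bool = False


def read_network(path) -> nx.Graph:
    """Edge-list TSV (node_a, node_b, weight) -> validated undirected graph."""
    edges = pd.read_csv(path, sep="\t", dtype={"node_a": str, "node_b": str})
    required = ("node_a", "node_b", "weight")
    missing = [c for c in required if c not in edges.columns]
    if missing:
        raise ValidationError(f"network: missing column(s) {missing}")
    graph = nx.Graph()
    for row in edges.itertuples(index=False):
        validate_edge(graph, str(row.node_a), str(row.node_b), float(row.weight))
        graph.add_edge(str(row.node_a), str(row.node_b), weight=float(row.weight))
    return graph


def validate_edge(graph: nx.Graph, a: str, b: str, weight: float) -> None:
    if a == b:
        raise ValidationError(f"network: self-loop at {a!r}")
    if graph.has_edge(a, b):
        raise ValidationError(f"network: duplicate edge {a!r}-{b!r}")
    if not (np.isfinite(weight) and weight > 0):
        raise ValidationError(f"network: non-positive weight on {a!r}-{b!r}")


def write_network(graph: nx.Graph, path) -> None:
    rows = [
        {"node_a": a, "node_b": b, "weight": data.get("weight", 1.0)}
        for a, b, data in sorted(graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def neighborhood(graph: nx.Graph, node: str, depth: int = 1) -> dict[str, float]:
    """Nodes reachable within ``depth`` edges of ``node`` (hub excluded).

    Each neighbor carries the maximum first-edge weight over the paths that
    reach it; at depth 1 this is simply its edge weight.
    """
    if node not in graph:
        raise ValidationError(f"neighborhood: unknown node {node!r}")
    result: dict[str, float] = {}
    for first, data in graph[node].items():
        w = float(data.get("weight", 1.0))
        reachable = nx.single_source_shortest_path_length(graph, first, cutoff=depth - 1)
        for other in reachable:
            if other == node:
                continue
            result[other] = max(result.get(other, 0.0), w)
    return result


def kd_score(
    neighborhood_weights: dict[str, float],
    deg_set,
    n_network_nodes: int,
    n_deg_in_network: int,
) -> tuple[float, float]:
    """(observed weighted overlap, observed / expected ratio)."""
    if not neighborhood_weights:
        raise ValidationError("kd_score: empty neighborhood")
    if n_deg_in_network == 0:
        raise ValidationError("kd_score: DEG fraction in network is zero")
    deg = set(deg_set)
    observed = sum(w for n, w in neighborhood_weights.items() if n in deg)
    total = sum(neighborhood_weights.values())
    expected = total * (n_deg_in_network / n_network_nodes)
    return float(observed), float(observed / expected) if expected > 0 else 0.0


def run_wkda(
    graph: nx.Graph,
    deg_sets: dict[str, list],
    min_degree: int = 5,
    depth: int = 1,
    n_perm: int = 1_000,
    seed: int | None = None,
    fdr_threshold: float = 0.05,
) -> list[KDResult]:
    """Score every candidate hub against every labeled DEG set.

    Deterministic for a fixed seed.  Returns an empty list (with a warning)
    when no node meets the degree threshold.
    """
    if graph.number_of_nodes() == 0:
        raise PipelineError("run_wkda: empty network")
    nodes = sorted(graph.nodes)
    node_index = {n: i for i, n in enumerate(nodes)}
    candidates = [n for n in nodes if graph.degree(n) >= min_degree]
    if not candidates:
        logger.warning("run_wkda: no node with degree >= %d", min_degree)
        return []
    # candidate x node matrix of neighborhood weights
    W = np.zeros((len(candidates), len(nodes)), dtype=float)
    sizes = []
    for i, cand in enumerate(candidates):
        weights = neighborhood(graph, cand, depth=depth)
        sizes.append(len(weights))
        for other, w in weights.items():
            W[i, node_index[other]] = w
    totals = W.sum(axis=1)
    rng = np.random.default_rng(seed)
    results: list[KDResult] = []
    for label, deg in deg_sets.items():
        deg_nodes = [n for n in set(deg) if n in node_index]
        m = len(deg_nodes)
        if m == 0:
            raise ValidationError(f"run_wkda: DEG set {label!r} disjoint from network")
        indicator = np.zeros(len(nodes), dtype=float)
        indicator[[node_index[n] for n in deg_nodes]] = 1.0
        observed = W @ indicator
        expected = totals * (m / len(nodes))
        # null: exactly size-matched uniform membership permutations
        perm = np.zeros((len(nodes), n_perm), dtype=float)
        for p in range(n_perm):
            perm[rng.choice(len(nodes), size=m, replace=False), p] = 1.0
        null = W @ perm  # (candidates, n_perm)
        mean = null.mean(axis=1)
        sd = null.std(axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(sd > 0, (observed - mean) / sd, 0.0)
        pvals = (1.0 + (null >= observed[:, None] - 1e-12).sum(axis=1)) / (n_perm + 1.0)
        fdrs = multipletests(pvals, method="fdr_bh")[1]
        for i, cand in enumerate(candidates):
            results.append(
                KDResult(
                    deg_set=label,
                    node=cand,
                    neighborhood_size=sizes[i],
                    observed=float(observed[i]),
                    expected=float(expected[i]),
                    ratio=float(observed[i] / expected[i]) if expected[i] > 0 else 0.0,
                    z=float(z[i]),
                    pvalue=float(pvals[i]),
                    fdr=float(fdrs[i]),
                    significant=bool(fdrs[i] < fdr_threshold),
                )
            )
    results.sort(key=lambda r: (r.deg_set, r.pvalue, -r.z, r.node))
    return results


def kda_to_frame(results: list[KDResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "deg_set": r.deg_set,
                "node": r.node,
                "neighborhood_size": r.neighborhood_size,
                "observed": r.observed,
                "expected": r.expected,
                "ratio": r.ratio,
                "z": r.z,
                "pvalue": r.pvalue,
                "fdr": r.fdr,
                "significant": r.significant,
            }
            for r in results
        ],
        columns=[
            "deg_set",
            "node",
            "neighborhood_size",
            "observed",
            "expected",
            "ratio",
            "z",
            "pvalue",
            "fdr",
            "significant",
        ],
    )
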