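"""Graph-theoretic quantification of causal graphs.

Metrics are computed on the binarized significant graph: out-degree,
in-degree, net causal outflow (out - in), and per-node shortest directed
path length to every other node normalized by (M - 1). Outflow hubs are
nodes whose net outflow is extreme relative to the other nodes.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .inference import CausalGraph

__all__ = ["degree_metrics", "path_length", "node_metrics", "hub_test"]


def _adjacency(g: CausalGraph | np.ndarray) -> np.ndarray:
    """adjacency[source, target] in {0, 1}, zero diagonal."""
    if isinstance(g, CausalGraph):
        adj = g.adjacency()
    else:
        adj = (np.asarray(g) != 0).astype(int)
    adj = adj.copy()
    np.fill_diagonal(adj, 0)
    return adj


def degree_metrics(g: CausalGraph | np.ndarray) -> pd.DataFrame:
    """Out/in-degree and net causal outflow per node (significant edges).

    Net outflow sums to zero over nodes by conservation.
    """
    adj = _adjacency(g)
    out_deg = adj.sum(axis=1)
    in_deg = adj.sum(axis=0)
    names = (g.region_names if isinstance(g, CausalGraph)
             else [f"n{i}" for i in range(adj.shape[0])])
    return pd.DataFrame({
        "region": list(names),
        "out_degree": out_deg,
        "in_degree": in_deg,
        "net_outflow": out_deg - in_deg,
    })


def path_length(g: CausalGraph | np.ndarray,
                unreachable: str = "penalty") -> np.ndarray:
    """Per-node mean shortest directed path length, normalized by (M - 1).

    Unit edge lengths. Unreachable targets contribute a finite penalty of
    M (exceeding any realizable path) by default, or are excluded with
    ``unreachable='exclude'`` (a node reaching no target gets NaN).
    """
    adj = _adjacency(g)
    M = adj.shape[0]
    G = nx.from_numpy_array(adj, create_using=nx.DiGraph)
    sp = dict(nx.all_pairs_shortest_path_length(G))
    out = np.empty(M)
    for i in range(M):
        dists = []
        for j in range(M):
            if j == i:
                continue
            d = sp.get(i, {}).get(j)
            if d is None:
                if unreachable == "penalty":
                    dists.append(M)
                elif unreachable != "exclude":
                    raise ValueError("unreachable must be 'penalty' or 'exclude'")
            else:
                dists.append(d)
        out[i] = np.mean(dists) if dists else np.nan
    return out


def node_metrics(g: CausalGraph | np.ndarray,
                 unreachable: str = "penalty") -> pd.DataFrame:
    """All four node metrics on the binarized significant graph."""
    df = degree_metrics(g)
    df["path_length"] = path_length(g, unreachable=unreachable)
    return df


def hub_test(per_subject_metrics: pd.DataFrame, metric: str = "net_outflow",
             alpha: float = 0.05) -> pd.DataFrame:
    """Per-node two-sample t-test of a metric against all other nodes.

    ``per_subject_metrics`` has columns (subject, region, <metric>); each
    node's vector across subjects is tested against the pooled vector of
    every other node, with BH-FDR across nodes. Requires >= 3 subjects
    and >= 2 nodes.
    """
    if metric not in per_subject_metrics.columns:
        raise ValueError(f"metric '{metric}' not in table")
    regions = sorted(per_subject_metrics["region"].unique())
    if len(regions) < 2:
        raise ValueError("need at least 2 nodes to compare")
    n_sub = per_subject_metrics["subject"].nunique()
    if n_sub < 3:
        raise ValueError(f"need at least 3 subjects, got {n_sub}")
    rows = []
    for region in regions:
        own = per_subject_metrics.loc[
            per_subject_metrics["region"] == region, metric].to_numpy(float)
        rest = per_subject_metrics.loc[
            per_subject_metrics["region"] != region, metric].to_numpy(float)
        if np.ptp(own) == 0 and np.ptp(rest) == 0 and own.mean() == rest.mean():
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(own, rest)
        rows.append({"region": region, "mean": own.mean(),
                     "mean_others": rest.mean(), "t": float(t), "p": float(p)})
    df = pd.DataFrame(rows)
    rej, q, *_ = multipletests(df["p"], alpha=alpha, method="fdr_bh")
    df["q"] = q
    df["significant"] = rej
    return df
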