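"""Shared nonparametric inference: empirical p-values, FDR, causal graphs.

Edge tests compare an observed group statistic against its surrogate null
with the add-one empirical p-value (r+1)/(n+1); multiplicity across the
M(M-1) off-diagonal edges is controlled by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .surrogate import NullDistribution

__all__ = ["CausalGraph", "empirical_pvalues", "edge_inference",
           "difference_null"]


def empirical_pvalues(
    observed: np.ndarray,
    null_values: np.ndarray,
    alternative: str = "two-sided",
) -> np.ndarray:
    """Add-one empirical p-values per edge.

    observed: (M, M); null_values: (n_surrogates, M, M). ``two-sided``
    counts surrogates at least as extreme in absolute value, ``greater``
    counts surrogates >= observed.
    """
    n = null_values.shape[0]
    if alternative == "two-sided":
        r = (np.abs(null_values) >= np.abs(observed)[None]).sum(axis=0)
    elif alternative == "greater":
        r = (null_values >= observed[None]).sum(axis=0)
    else:
        raise ValueError("alternative must be 'two-sided' or 'greater'")
    return (r + 1) / (n + 1)


def fdr_offdiag(p: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg over the off-diagonal entries only.

    Returns (q, reject) as full M x M arrays; diagonal q = 1, reject False.
    """
    M = p.shape[0]
    mask = ~np.eye(M, dtype=bool)
    rej, q_off, *_ = multipletests(p[mask], alpha=alpha, method="fdr_bh")
    q = np.ones_like(p)
    reject = np.zeros_like(p, dtype=bool)
    q[mask] = q_off
    reject[mask] = rej
    return q, reject


@dataclass
class CausalGraph:
    """Directed weighted graph over regions with per-edge inference.

    ``strength[m, n]`` is the estimated influence of region n on region m
    (row = target). The diagonal is excluded from inference.
    """

    region_names: tuple[str, ...]
    strength: np.ndarray
    p: np.ndarray
    q: np.ndarray
    significant: np.ndarray
    alpha: float = 0.01
    method: str = ""

    def __post_init__(self):
        M = len(self.region_names)
        for name in ("strength", "p", "q", "significant"):
            a = np.asarray(getattr(self, name))
            if a.shape != (M, M):
                raise ValueError(f"{name} must be {M} x {M}")
            setattr(self, name, a)
        if np.any(self.p < 0) or np.any(self.p > 1):
            raise ValueError("p-values must lie in [0, 1]")
        np.fill_diagonal(self.significant, False)
        if np.any(self.significant & (self.q > self.alpha * (1 + 1e-9))):
            raise ValueError("significant edges must have q below alpha")

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    def adjacency(self) -> np.ndarray:
        """Binarized significant graph as adjacency[source, target]."""
        return self.significant.T.astype(int)

    def to_edge_list(self) -> pd.DataFrame:
        """Edge-list table: source, target, strength, p, q, significant."""
        rows = []
        M = self.n_regions
        for m in range(M):
            for n in range(M):
                if m == n:
                    continue
                rows.append({
                    "source": self.region_names[n],
                    "target": self.region_names[m],
                    "strength": self.strength[m, n],
                    "p": self.p[m, n],
                    "q": self.q[m, n],
                    "significant": bool(self.significant[m, n]),
                })
        return pd.DataFrame(rows)

    @classmethod
    def from_edge_list(cls, df: pd.DataFrame, alpha: float = 0.01,
                       method: str = "") -> "CausalGraph":
        # target column preserves the original region order (row-major emit)
        regions = tuple(dict.fromkeys(list(df["target"]) + list(df["source"])))
        M = len(regions)
        idx = {r: i for i, r in enumerate(regions)}
        strength, p = np.zeros((M, M)), np.ones((M, M))
        q, sig = np.ones((M, M)), np.zeros((M, M), dtype=bool)
        for _, row in df.iterrows():
            m, n = idx[row["target"]], idx[row["source"]]
            strength[m, n] = row["strength"]
            p[m, n] = row["p"]
            q[m, n] = row["q"]
            sig[m, n] = bool(row["significant"])
        return cls(regions, strength, p, q, sig, alpha=alpha, method=method)


def edge_inference(
    region_names: tuple[str, ...],
    statistic: np.ndarray,
    null: NullDistribution,
    alpha: float = 0.01,
    fdr: bool = True,
    alternative: str = "two-sided",
    require_positive: bool = False,
    method: str = "",
) -> CausalGraph:
    """Test every off-diagonal edge statistic against its surrogate null."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    M = len(region_names)
    if null.values.shape[1] != M:
        raise ValueError("null distribution and statistic disagree on edge set")
    p = empirical_pvalues(statistic, null.values, alternative=alternative)
    np.fill_diagonal(p, 1.0)
    if fdr:
        q, reject = fdr_offdiag(p, alpha)
    else:
        q = p.copy()
        reject = p < alpha
        reject[np.eye(M, dtype=bool)] = False
    if require_positive:
        reject = reject & (statistic > 0)
    return CausalGraph(tuple(region_names), statistic.copy(), p, q, reject,
                       alpha=alpha, method=method)


def difference_null(nullA: NullDistribution, nullB: NullDistribution,
                    pairs: str = "all", max_per_group: int = 250
                    ) -> NullDistribution:
    """Null distribution of group differences of surrogate statistics.

    ``pairs='all'`` (default) forms every cross-pair difference between
    the two groups' surrogate values (up to ``max_per_group`` from each),
    giving a much finer-grained empirical null than the surrogate count
    alone; ``pairs='matched'`` subtracts them index-by-index.
    """
    a, b = nullA.values, nullB.values
    if pairs == "all":
        a = a[:max_per_group]
        b = b[:max_per_group]
        vals = (a[:, None] - b[None, :]).reshape(-1, *a.shape[1:])
    elif pairs == "matched":
        n = min(a.shape[0], b.shape[0])
        vals = a[:n] - b[:n]
    else:
        raise ValueError("pairs must be 'all' or 'matched'")
    return NullDistribution(
        statistic_name=f"diff({nullA.statistic_name})",
        values=vals, method=nullA.method)
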