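"""Thresholded Pearson co-expression networks between DE feature sets.

Edges connect DE features of two species whose sample-wise Pearson
correlation passes |r| >= min_abs_r and p < alpha, with the sign recorded
(and optionally required, e.g. negative-only for miRNA-mRNA).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

EDGE_COLUMNS = ["node_a", "species_a", "node_b", "species_b", "r", "p", "sign"]


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-distribution p-value.

    p comes from t = r * sqrt((n - 2) / (1 - r^2)) on n - 2 degrees of
    freedom; |r| = 1 gives p = 0.  Constant vectors are an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    n = x.size
    if n < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    xc, yc = x - x.mean(), y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(p)


@dataclass
class CorrelationRule:
    """Edge admission rule: |r| and p gates plus a sign requirement."""

    min_abs_r: float = 0.99
    alpha: float = 0.05
    required_sign: str = "any"  # any | positive | negative

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_abs_r <= 1.0):
            raise ValueError("min_abs_r must lie in [0, 1]")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must lie in (0, 1]")
        if self.required_sign not in ("any", "positive", "negative"):
            raise ValueError(f"bad required_sign {self.required_sign!r}")


def correlation_matrix(
    matrix_a: ExpressionMatrix, matrix_b: ExpressionMatrix,
    features_a, features_b, samples,
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Pearson r and p between two feature sets over ``samples``."""
    a = matrix_a.values.loc[list(features_a), list(samples)].to_numpy(dtype=float)
    b = matrix_b.values.loc[list(features_b), list(samples)].to_numpy(dtype=float)
    n = a.shape[1]
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    norm_a = np.sqrt((ac ** 2).sum(axis=1))
    norm_b = np.sqrt((bc ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (ac @ bc.T) / np.outer(norm_a, norm_b)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(r) == 1.0, 0.0, p)
    return r, p


def build_pair_network(
    matrix_a: ExpressionMatrix,
    matrix_b: ExpressionMatrix,
    de_set_a,
    de_set_b,
    rule: CorrelationRule = CorrelationRule(),
    samples=None,
) -> pd.DataFrame:
    """Edge list of DE-feature pairs passing the correlation rule.

    ``samples`` restricts the correlation to a subset of shared samples
    (e.g. the two conditions of one comparison); default is every sample
    shared by both matrices.  Self pairs and duplicate unordered pairs
    are excluded.
    """
    if samples is None:
        samples = [s for s in matrix_a.sample_ids if s in set(matrix_b.sample_ids)]
    if len(samples) == 0:
        raise ValueError("matrices share no samples")
    fa = sorted(set(de_set_a) & set(matrix_a.feature_ids))
    fb = sorted(set(de_set_b) & set(matrix_b.feature_ids))
    if not fa or not fb:
        return pd.DataFrame(columns=EDGE_COLUMNS)
    r, p = correlation_matrix(matrix_a, matrix_b, fa, fb, samples)
    keep = (np.abs(r) >= rule.min_abs_r) & (p < rule.alpha)
    if rule.required_sign == "positive":
        keep &= r > 0
    elif rule.required_sign == "negative":
        keep &= r < 0
    ii, jj = np.nonzero(keep)
    rows = []
    seen = set()
    for i, j in zip(ii, jj):
        node_a, node_b = fa[i], fb[j]
        if matrix_a.species == matrix_b.species:
            if node_a == node_b:
                continue
            key = tuple(sorted((node_a, node_b)))
            if key in seen:
                continue
            seen.add(key)
        rows.append(
            (node_a, matrix_a.species, node_b, matrix_b.species,
             float(r[i, j]), float(p[i, j]),
             "positive" if r[i, j] > 0 else "negative")
        )
    out = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    return out.sort_values(["node_a", "node_b"], ignore_index=True)


@dataclass
class NetworkSummary:
    degrees: dict[str, int]
    n_edges: int
    n_components: int

    def top_nodes(self, n: int = 10) -> list[tuple[str, int]]:
        return sorted(self.degrees.items(), key=lambda kv: (-kv[1], kv[0]))[:n]


def summarize_network(edges: pd.DataFrame) -> NetworkSummary:
    """Node degrees, edge count and connected-component count."""
    import networkx as nx

    g = nx.Graph()
    for _, row in edges.iterrows():
        g.add_edge(row["node_a"], row["node_b"])
    degrees = {node: int(d) for node, d in g.degree()}
    return NetworkSummary(
        degrees=degrees,
        n_edges=len(edges),
        n_components=nx.number_connected_components(g) if g.number_of_nodes() else 0,
    )
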