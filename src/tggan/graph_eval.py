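"""Fidelity evaluation of synthesized connectomes.

Two complementary pipelines compare a synthesized dataset against the
acquired one it was generated from:

* averaged-matrix pipeline — average the matrices of each group, binarize
  at edge-density thresholds (5%..25% by default), compute nodal
  distributions of connectivity strength (degree), betweenness centrality
  and clustering coefficient, and quantify distribution similarity with
  the KL divergence between kernel-density estimates;
* per-matrix pipeline — binarize every subject's matrix, compute five
  graph measures (betweenness, clustering, modularity, global and local
  efficiency; nodal measures averaged across regions) and summarise the
  acquired-vs-synthesized difference with paired Cohen's d.

Graph measures are computed through networkx.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ConnectivityMatrix, ConnectomeDataset

__all__ = [
    "DEFAULT_DENSITIES",
    "MetricDistribution",
    "FidelityReport",
    "binarize_by_density",
    "graph_metrics",
    "metric_kl",
    "cohens_d",
    "mean_difference_matrix",
    "fidelity_report",
]

DEFAULT_DENSITIES = (0.05, 0.10, 0.15, 0.20, 0.25)
AVERAGED_METRICS = ("strength", "betweenness", "clustering")
PER_MATRIX_METRICS = (
    "betweenness",
    "clustering",
    "modularity",
    "global_efficiency",
    "local_efficiency",
)


@dataclass(frozen=True)
class MetricDistribution:
    metric_name: str
    edge_density: float
    values: np.ndarray
    source: str  # "acquired" | "synthesized"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64).ravel()
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite {self.metric_name} values")
        object.__setattr__(self, "values", v)


def binarize_by_density(m: ConnectivityMatrix, density: float) -> ConnectivityMatrix:
    """Keep the ⌊density·E⌋ strongest undirected edges, weights set to 1.

    Ties at the cut are broken deterministically by (weight desc, i asc,
    j asc); the result is rank-based, hence invariant to uniform rescaling.
    """
    if not (0 < density <= 1):
        raise ValueError("density must be in (0, 1]")
    n = m.n_nodes
    rows, cols = np.tril_indices(n, k=-1)
    w = m.weights[rows, cols]
    k = int(np.floor(density * w.size))
    order = np.lexsort((cols, rows, -w))  # weight desc, then i, then j
    keep = order[:k]
    out = np.zeros_like(m.weights)
    out[rows[keep], cols[keep]] = 1.0
    out = out + out.T
    return ConnectivityMatrix(weights=out, node_labels=m.node_labels)


def _as_graph(m: ConnectivityMatrix) -> nx.Graph:
    g = nx.from_numpy_array(m.weights)
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


def _check_binary(m: ConnectivityMatrix):
    if not np.all(np.isin(m.weights, (0.0, 1.0))):
        raise ValueError("graph metrics expect a binarized matrix")


def _local_efficiency_nodal(g: nx.Graph) -> np.ndarray:
    vals = np.zeros(g.number_of_nodes())
    for v in g.nodes:
        neighbors = list(g[v])
        if len(neighbors) < 2:
            continue
        vals[v] = nx.global_efficiency(g.subgraph(neighbors))
    return vals


def graph_metrics(
    m: ConnectivityMatrix, normalized_betweenness: bool = True
) -> dict[str, np.ndarray | float]:
    """All supported measures of one binarized graph.

    Nodal measures (strength/degree, betweenness, clustering, local
    efficiency) are returned per node; modularity (greedy maximisation)
    and global efficiency are scalars.  Disconnected graphs follow the
    convention that unreachable pairs contribute zero efficiency.
    """
    _check_binary(m)
    g = _as_graph(m)
    betweenness = np.array(
        [
            v
            for _, v in sorted(
                nx.betweenness_centrality(g, normalized=normalized_betweenness).items()
            )
        ]
    )
    clustering = np.array([v for _, v in sorted(nx.clustering(g).items())])
    if g.number_of_edges() > 0:
        communities = nx.community.greedy_modularity_communities(g)
        modularity = float(nx.community.modularity(g, communities))
    else:
        modularity = 0.0
    return {
        "strength": m.weights.sum(axis=1),
        "betweenness": betweenness,
        "clustering": clustering,
        "modularity": modularity,
        "global_efficiency": float(nx.global_efficiency(g)),
        "local_efficiency": _local_efficiency_nodal(g),
    }


def weighted_strength(m: ConnectivityMatrix) -> np.ndarray:
    """Node strength of the unthresholded weighted matrix."""
    return m.weights.sum(axis=1)


def _kde(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Gaussian KDE (Silverman bandwidth) with a degenerate-sample floor."""
    sd = values.std(ddof=1) if values.size > 1 else 0.0
    if sd == 0.0:
        # zero-variance fallback: a narrow kernel around the constant value
        bw = max(1e-6, 1e-6 * abs(values.mean()))
        dens = np.exp(-0.5 * ((grid - values.mean()) / bw) ** 2)
    else:
        kde = stats.gaussian_kde(values, bw_method="silverman")
        dens = kde(grid)
    dens = np.clip(dens, 1e-12, None)
    return dens / dens.sum()


def metric_kl(
    acquired: MetricDistribution, synthesized: MetricDistribution, n_grid: int = 512
) -> float:
    """KL(P_acquired ‖ P_synthesized) between KDE estimates on a shared grid."""
    if acquired.metric_name != synthesized.metric_name:
        raise ValueError("metric names differ")
    if acquired.edge_density != synthesized.edge_density:
        raise ValueError("edge densities differ")
    a, s = acquired.values, synthesized.values
    if a.size < 5 or s.size < 5:
        raise ValueError("need at least 5 values per distribution")
    lo = min(a.min(), s.min())
    hi = max(a.max(), s.max())
    span = (hi - lo) or max(1.0, abs(hi))
    grid = np.linspace(lo - 0.1 * span, hi + 0.1 * span, n_grid)
    p = _kde(a, grid)
    q = _kde(s, grid)
    return float(np.sum(p * np.log(p / q)))


def cohens_d(
    acquired_values, synthesized_values, paired: bool = True
) -> float:
    """Standardized mean difference, sign = synthesized − acquired.

    Paired form divides the mean within-pair difference by the SD of the
    differences; the unpaired form uses the pooled SD.  An all-zero paired
    difference returns 0 by convention.
    """
    a = np.asarray(acquired_values, dtype=np.float64).ravel()
    s = np.asarray(synthesized_values, dtype=np.float64).ravel()
    if paired:
        if a.size != s.size:
            raise ValueError("paired comparison needs equal lengths")
        diffs = s - a
        if np.allclose(diffs, 0.0):
            return 0.0
        sd = diffs.std(ddof=1)
        if sd == 0:
            raise ValueError("zero SD of constant nonzero differences")
        return float(diffs.mean() / sd)
    na, ns = a.size, s.size
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (ns - 1) * s.var(ddof=1)) / (na + ns - 2)
    )
    if pooled == 0:
        if np.isclose(s.mean(), a.mean()):
            return 0.0
        raise ValueError("zero pooled SD")
    return float((s.mean() - a.mean()) / pooled)


def mean_difference_matrix(
    acquired: ConnectomeDataset, synthesized: ConnectomeDataset
) -> np.ndarray:
    """Elementwise mean over subjects of (acquired − synthesized)."""
    if len(acquired) != len(synthesized):
        raise ValueError("datasets must pair subject for subject")
    return (acquired.matrices() - synthesized.matrices()).mean(axis=0)


def average_matrix(d: ConnectomeDataset) -> ConnectivityMatrix:
    return ConnectivityMatrix(
        weights=d.matrices().mean(axis=0),
        node_labels=d.samples[0].matrix.node_labels,
    )


@dataclass
class FidelityReport:
    """KL divergences, per-matrix effect sizes, and the mean difference."""

    mean_difference: np.ndarray
    kl_table: pd.DataFrame  # rows: density; columns: averaged metrics
    cohens_d_table: pd.DataFrame  # rows: density; columns: per-matrix measures

    def to_json(self) -> str:
        return json.dumps(
            {
                "mean_difference": self.mean_difference.tolist(),
                "kl_table": self.kl_table.to_dict(orient="index"),
                "cohens_d_table": self.cohens_d_table.to_dict(orient="index"),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FidelityReport":
        obj = json.loads(text)

        def table(d):
            df = pd.DataFrame.from_dict(d, orient="index")
            df.index = df.index.astype(float)
            return df.sort_index()

        return cls(
            mean_difference=np.array(obj["mean_difference"]),
            kl_table=table(obj["kl_table"]),
            cohens_d_table=table(obj["cohens_d_table"]),
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_json())
        return path


def fidelity_report(
    acquired: ConnectomeDataset,
    synthesized: ConnectomeDataset,
    densities=DEFAULT_DENSITIES,
) -> FidelityReport:
    """Run both comparison pipelines over the requested densities."""
    if len(acquired) != len(synthesized):
        raise ValueError("datasets must pair subject for subject")
    avg_a = average_matrix(acquired)
    avg_s = average_matrix(synthesized)

    kl_rows = {}
    for dens in densities:
        ma = graph_metrics(binarize_by_density(avg_a, dens))
        ms = graph_metrics(binarize_by_density(avg_s, dens))
        kl_rows[dens] = {
            name: metric_kl(
                MetricDistribution(name, dens, ma[name], "acquired"),
                MetricDistribution(name, dens, ms[name], "synthesized"),
            )
            for name in AVERAGED_METRICS
        }

    d_rows = {}
    per_matrix_a = {dens: {m: [] for m in PER_MATRIX_METRICS} for dens in densities}
    per_matrix_s = {dens: {m: [] for m in PER_MATRIX_METRICS} for dens in densities}
    for ds, store in ((acquired, per_matrix_a), (synthesized, per_matrix_s)):
        for sample in ds:
            for dens in densities:
                metrics = graph_metrics(binarize_by_density(sample.matrix, dens))
                for name in PER_MATRIX_METRICS:
                    v = metrics[name]
                    store[dens][name].append(
                        float(np.mean(v)) if np.ndim(v) else float(v)
                    )
    for dens in densities:
        d_rows[dens] = {
            name: cohens_d(
                per_matrix_a[dens][name], per_matrix_s[dens][name], paired=True
            )
            for name in PER_MATRIX_METRICS
        }

    return FidelityReport(
        mean_difference=mean_difference_matrix(acquired, synthesized),
        kl_table=pd.DataFrame.from_dict(kl_rows, orient="index")[
            list(AVERAGED_METRICS)
        ],
        cohens_d_table=pd.DataFrame.from_dict(d_rows, orient="index")[
            list(PER_MATRIX_METRICS)
        ],
    )
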