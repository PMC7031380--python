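"""Co-occurrence networks of functional genes.

A network is built per nutrient group from the Spearman correlation matrix
of gene relative abundances: an edge requires both |rho| at or above a
correlation threshold and a Benjamini–Hochberg adjusted p below alpha. The
threshold is chosen by random-matrix theory: scanning candidate thresholds,
the nearest-neighbour spacing distribution (NNSD) of the unfolded eigenvalue
spectrum transitions from Wigner–Dyson (GOE, random) to Poisson (modular);
the smallest threshold on the Poisson side is returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.interpolate
import scipy.stats

from .stats import bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationMatrices",
    "CoNetwork",
    "TopologyReport",
    "correlation_matrix",
    "rmt_threshold",
    "nnsd_spacings",
    "nnsd_fit",
    "build_network",
    "topology",
    "compare_networks",
]


@dataclass
class CorrelationMatrices:
    """Pairwise Spearman rho, raw p and BH-adjusted q among features."""

    features: list[str]
    rho: np.ndarray
    p: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.features)
        for name in ("rho", "p", "q"):
            m = getattr(self, name)
            if m.shape != (k, k):
                raise ValueError(f"{name} matrix shape mismatch")
            if not np.allclose(m, m.T, atol=1e-10, equal_nan=True):
                raise ValueError(f"{name} matrix is not symmetric")


@dataclass
class CoNetwork:
    """Thresholded signed co-occurrence graph."""

    graph: nx.Graph
    threshold: float
    alpha: float
    group_label: str = ""

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "rho": d["rho"], "q": d["q"], "sign": d["sign"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "rho", "q", "sign"])


@dataclass
class TopologyReport:
    average_degree: float
    graph_density: float
    average_clustering_coefficient: float
    node_degrees: dict[str, int]
    n_nodes: int
    n_edges: int

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "average_degree": self.average_degree,
            "graph_density": self.graph_density,
            "average_clustering_coefficient": self.average_clustering_coefficient,
            "node_degrees": self.node_degrees,
        }


def correlation_matrix(profile) -> CorrelationMatrices:
    """Pairwise Spearman correlations among profile features (rows) across
    the samples of one nutrient group; q from BH over the upper triangle.

    Zero-variance features are dropped with a warning; fewer than 4 samples
    is an error.
    """
    if isinstance(profile, pd.DataFrame):
        values = profile
    elif hasattr(profile, "values") and isinstance(profile.values, pd.DataFrame):
        values = profile.values  # ProfileMatrix
    else:
        values = pd.DataFrame(profile)
    if values.shape[1] < 4:
        raise ValueError("need at least 4 samples for a correlation matrix")
    variable = values.std(axis=1) > 0
    dropped = values.index[~variable].tolist()
    if dropped:
        logger.warning("dropping zero-variance feature(s): %s", dropped)
    values = values.loc[variable]
    features = list(values.index)
    k = len(features)
    if k < 2:
        raise ValueError("need at least 2 variable features")
    if k == 2:  # scipy returns a scalar for exactly two variables
        res = scipy.stats.spearmanr(values.iloc[0], values.iloc[1])
        rho = np.array([[1.0, res.statistic], [res.statistic, 1.0]])
        p = np.array([[0.0, res.pvalue], [res.pvalue, 0.0]])
    else:
        rho, p = scipy.stats.spearmanr(values.to_numpy().T)
        rho = np.asarray(rho, dtype=float)
        p = np.asarray(p, dtype=float)
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    iu = np.triu_indices(k, k=1)
    q = np.zeros_like(p)
    q[iu] = bh_fdr(p[iu])
    q = q + q.T
    return CorrelationMatrices(features=features, rho=rho, p=p, q=q)


def nnsd_spacings(
    rho: np.ndarray,
    s: float,
    n_knots: int = 8,
    dedup_tol: float = 1e-8,
) -> np.ndarray | None:
    """Nearest-neighbour spacings of the unfolded eigenvalue spectrum after
    zeroing entries with |rho| < s.

    Duplicate eigenvalues (degenerate, from isolated rows) are collapsed
    before unfolding; the staircase function is smoothed with a cubic spline
    on ``n_knots`` interior knots. Returns ``None`` when too few distinct
    eigenvalues remain for a meaningful distribution.
    """
    m = rho.copy()
    m[np.abs(m) < s] = 0.0
    np.fill_diagonal(m, 1.0)
    eig = np.sort(np.linalg.eigvalsh(m))
    keep = np.concatenate([[True], np.diff(eig) > dedup_tol])
    eig = eig[keep]
    n = eig.size
    if n < 12:
        return None
    # cubic-spline fit to the cumulative spectral density (unfolding)
    staircase = np.arange(1, n + 1, dtype=float)
    knots = np.quantile(eig, np.linspace(0, 1, n_knots + 2)[1:-1])
    knots = np.unique(knots[(knots > eig[0]) & (knots < eig[-1])])
    try:
        spline = scipy.interpolate.LSQUnivariateSpline(eig, staircase, knots, k=3)
    except ValueError:
        return None
    unfolded = spline(eig)
    spacings = np.diff(unfolded)
    spacings = spacings[spacings > 0]
    if spacings.size < 10:
        return None
    return spacings / spacings.mean()


def nnsd_fit(spacings: np.ndarray, n_bins: int = 20) -> dict[str, float]:
    """Chi-square goodness of fit of spacings against the Poisson
    (``exp(−s)``) and GOE Wigner-surmise (``(πs/2)exp(−πs²/4)``) NNSD forms.

    Uses equal-probability bins under each candidate law; bin count shrinks
    automatically so that each expected count is at least 5.
    """
    n = spacings.size
    bins = int(min(n_bins, max(4, n // 5)))
    u = np.linspace(0, 1, bins + 1)

    def chi2_against(quantile_fn) -> float:
        edges = quantile_fn(u)
        edges[0], edges[-1] = -np.inf, np.inf
        observed, _ = np.histogram(spacings, bins=edges)
        expected = n / bins
        return float(((observed - expected) ** 2 / expected).sum())

    poisson_q = lambda q: -np.log1p(-np.clip(q, 0, 1 - 1e-12))
    goe_q = lambda q: np.sqrt(-4.0 * np.log1p(-np.clip(q, 0, 1 - 1e-12)) / np.pi)
    chi2_poisson = chi2_against(poisson_q)
    chi2_goe = chi2_against(goe_q)
    df = bins - 1
    return {
        "chi2_poisson": chi2_poisson,
        "chi2_goe": chi2_goe,
        "p_poisson": float(scipy.stats.chi2.sf(chi2_poisson, df)),
        "p_goe": float(scipy.stats.chi2.sf(chi2_goe, df)),
        "n_bins": bins,
    }


def rmt_threshold(
    rho: np.ndarray,
    grid_step: float = 0.01,
    s_range: tuple[float, float] = (0.3, 0.99),
    n_knots: int = 8,
    n_bins: int = 20,
    alpha: float = 0.05,
    sustain: float = 0.05,
) -> float:
    """Correlation threshold at the GOE→Poisson transition of the NNSD.

    Scans candidate thresholds from low to high; at each, the spectrum of
    the thresholded matrix is unfolded and its NNSD tested against Poisson
    and GOE. Returns the smallest threshold at which the Poisson form fits
    (p > ``alpha``, and better than GOE) and keeps fitting over the next
    ``sustain`` span of thresholds — transient Poisson flickers inside the
    transition region are skipped.
    """
    rho = np.asarray(rho, dtype=float)
    if rho.shape[0] < 20:
        raise ValueError(
            "matrix smaller than 20×20: spectrum too short for RMT; "
            "set the threshold manually"
        )
    off = np.abs(rho[np.triu_indices(rho.shape[0], k=1)])
    if not (off > 1e-12).any():
        raise ValueError("degenerate spectrum: no off-diagonal correlation signal")
    lo, hi = s_range
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    window = max(1, int(round(sustain / grid_step)))
    poisson_ok = np.zeros(grid.size, dtype=bool)
    evaluable = np.zeros(grid.size, dtype=bool)
    for i, s in enumerate(grid):
        spacings = nnsd_spacings(rho, s, n_knots=n_knots)
        if spacings is None:
            continue
        evaluable[i] = True
        fit = nnsd_fit(spacings, n_bins=n_bins)
        poisson_ok[i] = (
            fit["p_poisson"] > alpha and fit["chi2_poisson"] < fit["chi2_goe"]
        )
    for i in range(grid.size):
        if not poisson_ok[i]:
            continue
        ahead = slice(i, min(i + window, grid.size))
        # unevaluable points (spectrum exhausted) do not break the run
        if np.all(poisson_ok[ahead] | ~evaluable[ahead]):
            return float(round(grid[i], 10))
    raise ValueError(
        f"no GOE→Poisson transition found in s ∈ [{lo}, {hi}]; widen s_range"
    )


def build_network(
    corr: CorrelationMatrices,
    threshold: float,
    alpha: float = 0.01,
    group_label: str = "",
) -> CoNetwork:
    """Edge (i,j) iff |rho_ij| ≥ threshold and q_ij < alpha.

    Isolated nodes are retained (flagged with ``isolated=True``).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    g = nx.Graph()
    g.add_nodes_from(corr.features)
    k = len(corr.features)
    for i in range(k):
        for j in range(i + 1, k):
            r = corr.rho[i, j]
            q = corr.q[i, j]
            if np.isfinite(r) and abs(r) >= threshold and q < alpha:
                g.add_edge(
                    corr.features[i],
                    corr.features[j],
                    rho=float(r),
                    q=float(q),
                    sign=1 if r > 0 else -1,
                )
    for node in g.nodes:
        g.nodes[node]["isolated"] = g.degree(node) == 0
    return CoNetwork(graph=g, threshold=float(threshold), alpha=alpha,
                     group_label=group_label)


def topology(net: CoNetwork | nx.Graph) -> TopologyReport:
    """Average degree 2E/N, density 2E/(N(N−1)), mean local clustering
    coefficient (0 for degree < 2) and per-node degrees."""
    g = net.graph if isinstance(net, CoNetwork) else net
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    e = g.number_of_edges()
    density = 2.0 * e / (n * (n - 1)) if n > 1 else 0.0
    clustering = nx.average_clustering(g) if n > 0 else 0.0
    return TopologyReport(
        average_degree=2.0 * e / n,
        graph_density=density,
        average_clustering_coefficient=float(clustering),
        node_degrees={node: int(d) for node, d in g.degree()},
        n_nodes=n,
        n_edges=e,
    )


def compare_networks(
    report_a: TopologyReport, report_b: TopologyReport
) -> dict[str, object]:
    """Elementwise topology differences (B − A) and per-node degree deltas."""
    nodes = sorted(set(report_a.node_degrees) | set(report_b.node_degrees))
    return {
        "average_degree": report_b.average_degree - report_a.average_degree,
        "graph_density": report_b.graph_density - report_a.graph_density,
        "average_clustering_coefficient": (
            report_b.average_clustering_coefficient
            - report_a.average_clustering_coefficient
        ),
        "node_degree_delta": {
            v: report_b.node_degrees.get(v, 0) - report_a.node_degrees.get(v, 0)
            for v in nodes
        },
    }
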