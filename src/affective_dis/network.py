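"""Scale-free substrate of AI-agent couplings and its degree statistics.

The collective behavior of the mean-field model depends on the graph only
through its degree sequence: the mean degree <k> and the normalized second
moment

    zeta = (1 / (N <k>)) * sum_i k_i^2 = <k^2> / <k>,

which amplifies the network-enforced gain of the collective affective field
and lowers the synchronization threshold.  Graphs are generated by sampling
a truncated discrete power-law degree sequence p(k) ~ k^(-nu) on
[k_min, N-1] and wiring it with a configuration-model pass, then stripping
self-loops and multi-edges (loops are inadmissible on the substrate).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy import optimize, special

__all__ = [
    "NetworkModel",
    "generate_scale_free",
    "degree_stats",
    "fit_degree_exponent",
    "annealed_adjacency",
    "read_edge_list",
    "write_edge_list",
    "star_graph",
    "ring_graph",
]

logger = logging.getLogger(__name__)


@dataclass
class NetworkModel:
    """Undirected simple graph plus the degree statistics that drive dynamics."""

    graph: nx.Graph
    nu: float | None = None
    seed: int | None = None
    _adjacency: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def adjacency(self) -> np.ndarray:
        if self._adjacency is None:
            a = nx.to_numpy_array(self.graph, nodelist=sorted(self.graph.nodes()))
            self._adjacency = a.astype(float)
        return self._adjacency

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    @property
    def mean_degree(self) -> float:
        return float(self.degrees.mean())

    @property
    def zeta(self) -> float:
        k = self.degrees
        total = int(k.sum())
        if total == 0:
            raise ValueError("zeta is undefined for an empty graph")
        return float((k.astype(np.int64) ** 2).sum() / total)

    def summary(self) -> dict:
        k = self.degrees
        stats = degree_stats(self)
        try:
            nu_hat = fit_degree_exponent(k, int(max(k.min(), 2)))
        except ValueError:
            nu_hat = None  # degenerate or too-small degree sample
        return {
            "N": self.n_nodes,
            "mean_degree": stats["mean_degree"],
            "zeta": stats["zeta"],
            "k_min": int(k.min()),
            "k_max": int(k.max()),
            "nu_hat": nu_hat,
        }

    def summary_json(self) -> str:
        return json.dumps(self.summary())


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

def _sample_powerlaw_degrees(
    n: int, nu: float, k_min: int, k_max: int, rng: np.random.Generator
) -> np.ndarray:
    ks = np.arange(k_min, k_max + 1)
    pmf = ks.astype(float) ** (-nu)
    pmf /= pmf.sum()
    return rng.choice(ks, size=n, p=pmf)


def generate_scale_free(
    N: int, nu: float, k_min: int = 2, seed: int | None = None
) -> NetworkModel:
    """Configuration-model graph with a truncated power-law degree sequence.

    Degrees are drawn from p(k) ~ k^(-nu) on [k_min, N-1]; if their sum is
    odd the last degree is resampled until parity holds.  The multigraph is
    collapsed to a simple graph (self-loops and parallel edges removed), so
    realized degrees can drop slightly below the sampled sequence.
    Bit-reproducible for a fixed seed.
    """
    if N < 3:
        raise ValueError("need N >= 3 nodes")
    if nu <= 1:
        raise ValueError("degree exponent nu must exceed 1")
    if not (1 <= k_min < N):
        raise ValueError("require 1 <= k_min < N")
    rng = np.random.default_rng(seed)
    for _ in range(100):
        degs = _sample_powerlaw_degrees(N, nu, k_min, N - 1, rng)
        for _ in range(100):
            if degs.sum() % 2 == 0:
                break
            degs[-1] = _sample_powerlaw_degrees(1, nu, k_min, N - 1, rng)[0]
        if degs.sum() % 2 != 0:
            continue
        multi = nx.configuration_model(degs.tolist(), seed=int(rng.integers(2**31)))
        g = nx.Graph(multi)  # collapses parallel edges
        g.remove_edges_from(nx.selfloop_edges(g))
        if g.number_of_edges() > 0:
            net = NetworkModel(graph=g, nu=nu, seed=seed)
            comps = max(nx.connected_components(g), key=len)
            if len(comps) < 0.9 * N:
                logger.warning(
                    "largest component holds %d/%d nodes", len(comps), N
                )
            return net
    raise RuntimeError("failed to realize a degree sequence in 100 attempts")


def star_graph(N: int) -> NetworkModel:
    """Hub node 0 connected to N-1 leaves; the extreme-zeta reference case."""
    return NetworkModel(graph=nx.star_graph(N - 1))


def ring_graph(N: int) -> NetworkModel:
    return NetworkModel(graph=nx.cycle_graph(N))


# --------------------------------------------------------------------------
# statistics
# --------------------------------------------------------------------------

def degree_stats(net: NetworkModel) -> dict:
    """<k>, zeta, extremes and histogram, with single-division semantics."""
    k = net.degrees
    total = int(k.sum())
    if total == 0:
        raise ValueError("degree statistics need at least one edge")
    n = net.n_nodes
    sum_sq = int((k.astype(np.int64) ** 2).sum())
    hist = np.bincount(k)
    return {
        "mean_degree": total / n,
        "zeta": sum_sq / total,
        "k_min": int(k.min()),
        "k_max": int(k.max()),
        "histogram": hist,
    }


def fit_degree_exponent(degrees: np.ndarray, k_min: int) -> float:
    """Maximum-likelihood exponent of a discrete power law with lower cutoff.

    Maximizes the discrete power-law likelihood with Hurwitz-zeta
    normalization over degrees >= k_min; degrees below the cutoff are
    discarded.  Requires at least 20 tail degrees and a non-degenerate
    sample.
    """
    k = np.asarray(degrees)
    k = k[k >= k_min]
    if k.size < 20:
        raise ValueError("need at least 20 degrees >= k_min for the MLE")
    if np.all(k == k[0]):
        raise ValueError("degenerate degree sample: no finite MLE")
    mean_log = float(np.mean(np.log(k)))

    def neg_loglik(nu: float) -> float:
        return math.log(special.zeta(nu, k_min)) + nu * mean_log

    res = optimize.minimize_scalar(neg_loglik, bounds=(1.01, 12.0), method="bounded")
    return float(res.x)


def annealed_adjacency(net: NetworkModel, zero_diagonal: bool = False) -> np.ndarray:
    """Degree-product (annealed) adjacency A_ij = k_i k_j / (N <k>).

    The formula gives a nonzero diagonal k_i^2/(N<k>); it is kept by default
    (it enters mean-field sums only at O(1/N)) and can be zeroed via the
    flag.  Row sums reproduce the degree sequence exactly when kept.
    """
    k = net.degrees.astype(float)
    total = k.sum()
    if total <= 0:
        raise ValueError("annealed adjacency needs <k> > 0")
    a = np.outer(k, k) / total
    if zero_diagonal:
        np.fill_diagonal(a, 0.0)
    return a


# --------------------------------------------------------------------------
# edge-list plumbing
# --------------------------------------------------------------------------

def read_edge_list(path: str | Path) -> NetworkModel:
    """Whitespace-separated 0-based integer pairs, one edge per line, '#' comments.

    Duplicate and reversed edges are deduplicated; a self-loop aborts the
    parse with the offending line number.
    """
    g = nx.Graph()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.split()
            if len(tokens) != 2:
                raise ValueError(f"line {lineno}: expected two node ids, got {raw!r}")
            try:
                u, v = int(tokens[0]), int(tokens[1])
            except ValueError:
                raise ValueError(f"line {lineno}: non-integer token in {raw!r}") from None
            if u == v:
                raise ValueError(f"line {lineno}: self-loop {u}-{v} is inadmissible")
            if u < 0 or v < 0:
                raise ValueError(f"line {lineno}: node ids must be nonnegative")
            g.add_edge(u, v)
    g.add_nodes_from(range(max(g.nodes, default=-1) + 1))
    return NetworkModel(graph=g)


def write_edge_list(net: NetworkModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# N={net.n_nodes}\n")
        for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges()):
            fh.write(f"{u} {v}\n")
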