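"""Synthetic comparative-judgement study generator.

Emulates the study design end to end: wards on an adjacency graph, quality
parameters drawn from the normalised matrix-exponential (or Wishart)
covariance prior, and pairwise comparisons drawn from the tied
Bradley-Terry model, with pairs chosen uniformly at random among unordered
ward pairs and roughly ten comparisons per ward.  The tie parameter can be
set directly or calibrated so the expected tie fraction hits a target
(the sensitivity designs span ~5% to ~75% ties).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import wishart

from .likelihood import ComparisonTable, _log_sigmoid, outcome_probabilities
from .spatial import PriorSpec, WardGraph, network_covariance

__all__ = [
    "SimulationDesign",
    "delta_for_tie_fraction",
    "expected_tie_fraction",
    "grid_graph",
    "simulate_comparisons",
    "simulate_design",
    "simulate_lambda",
    "wishart_covariance",
]


@dataclass
class SimulationDesign:
    """One synthetic study: graph/covariance kind, size, tie level, seed.

    Exactly one of ``delta_true`` / ``target_tie_fraction`` must be set.
    ``comparisons_per_ward`` defaults to 10, the standard data-collection
    recommendation for comparative judgement.
    """

    n_wards: int
    comparisons_per_ward: float = 10.0
    graph_kind: str = "grid"  # {"grid", "random"}
    covariance_kind: str = "network"  # {"network", "wishart"}
    delta_true: float | None = None
    target_tie_fraction: float | None = None
    alpha2_true: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if (self.delta_true is None) == (self.target_tie_fraction is None):
            raise ValueError(
                "set exactly one of delta_true / target_tie_fraction"
            )
        if self.n_wards < 2:
            raise ValueError("need at least 2 wards")

    @property
    def n_comparisons(self) -> int:
        return max(1, round(self.comparisons_per_ward * self.n_wards))


def grid_graph(n_wards: int) -> WardGraph:
    """Near-square lattice on ``n_wards`` nodes (always connected).

    Stand-in for a real ward adjacency map: rows x cols lattice with
    ``rows = floor(sqrt(n))``, truncated row-major to n nodes.
    """
    import networkx as nx

    if n_wards < 2:
        raise ValueError("need at least 2 wards")
    rows = max(1, int(np.sqrt(n_wards)))
    cols = int(np.ceil(n_wards / rows))
    g = nx.grid_2d_graph(rows, cols)
    order = sorted(g.nodes())[:n_wards]
    sub = g.subgraph(order)
    index = {node: k for k, node in enumerate(order)}
    adj = np.zeros((n_wards, n_wards), dtype=np.int64)
    for u, v in sub.edges():
        adj[index[u], index[v]] = adj[index[v], index[u]] = 1
    labels = [f"W{k:03d}" for k in range(n_wards)]
    return WardGraph(ward_labels=labels, adjacency=adj)


def random_graph(n_wards: int, rng: np.random.Generator, edge_prob: float = 0.15) -> WardGraph:
    """Connected Erdos-Renyi-style graph (a random spanning tree plus noise edges)."""
    if n_wards < 2:
        raise ValueError("need at least 2 wards")
    adj = np.zeros((n_wards, n_wards), dtype=np.int64)
    order = rng.permutation(n_wards)
    for k in range(1, n_wards):  # random tree guarantees connectivity
        parent = order[rng.integers(0, k)]
        adj[order[k], parent] = adj[parent, order[k]] = 1
    extra = rng.random((n_wards, n_wards)) < edge_prob
    extra = np.triu(extra, 1)
    adj |= (extra | extra.T).astype(np.int64)
    np.fill_diagonal(adj, 0)
    labels = [f"W{k:03d}" for k in range(n_wards)]
    return WardGraph(ward_labels=labels, adjacency=adj)


def wishart_covariance(n_wards: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-diagonal covariance from a normalised Wishart(I, df=N) draw.

    The raw draw W is rescaled as D^{-1/2} W D^{-1/2} with D = diag(W),
    the same normalisation applied to the matrix-exponential covariance.
    """
    if n_wards < 2:
        raise ValueError("need at least 2 wards")
    w = wishart.rvs(df=n_wards, scale=np.eye(n_wards), random_state=rng)
    d = np.sqrt(np.diag(w))
    cov = w / np.outer(d, d)
    np.fill_diagonal(cov, 1.0)
    return 0.5 * (cov + cov.T)


def simulate_lambda(prior: PriorSpec, rng: np.random.Generator, alpha2: float | None = None) -> np.ndarray:
    """One quality vector drawn from the multivariate-normal prior."""
    if alpha2 is None:
        alpha2 = 1.0 if prior.infer_alpha2 else float(prior.alpha2)
    return prior.mean + np.sqrt(alpha2) * (
        prior.base_cholesky() @ rng.standard_normal(prior.n_wards)
    )


def simulate_comparisons(
    lam: np.ndarray,
    delta: float,
    n_comparisons: int,
    rng: np.random.Generator,
    ward_labels: list[str] | None = None,
    pairs: np.ndarray | None = None,
) -> ComparisonTable:
    """Draw comparisons from the tied Bradley-Terry model.

    Pairs are chosen uniformly at random from all unordered ward pairs
    (or from an explicit ``pairs`` array of shape (k, 2), which supports
    familiarity-restricted designs); each outcome is multinomial with the
    win/loss/tie probabilities of the model.
    """
    lam = np.asarray(lam, dtype=float).ravel()
    n = lam.size
    if n < 2:
        raise ValueError("need at least 2 wards")
    if n_comparisons < 1:
        raise ValueError("need at least one comparison")
    if ward_labels is None:
        ward_labels = [f"W{k:03d}" for k in range(n)]
    if pairs is None:
        iu, ju = np.triu_indices(n, k=1)
        pairs = np.column_stack([iu, ju])
    pairs = np.asarray(pairs)

    if delta < 0:
        raise ValueError(f"tie parameter delta must be nonnegative, got {delta}")
    wins = np.zeros((n, n), dtype=np.int64)
    ties = np.zeros((n, n), dtype=np.int64)
    choice = rng.integers(0, pairs.shape[0], size=n_comparisons)
    i, j = pairs[choice, 0], pairs[choice, 1]
    diff = lam[i] - lam[j]
    p_ij = np.exp(_log_sigmoid(diff - delta))
    p_ji = np.exp(_log_sigmoid(-diff - delta))
    u = rng.random(n_comparisons)
    win_ij = u < p_ij
    win_ji = ~win_ij & (u < p_ij + p_ji)
    tie = ~win_ij & ~win_ji
    np.add.at(wins, (i[win_ij], j[win_ij]), 1)
    np.add.at(wins, (j[win_ji], i[win_ji]), 1)
    np.add.at(ties, (i[tie], j[tie]), 1)
    np.add.at(ties, (j[tie], i[tie]), 1)
    return ComparisonTable(ward_labels=list(ward_labels), wins=wins, ties=ties)


def expected_tie_fraction(lam: np.ndarray, delta: float, pairs: np.ndarray | None = None) -> float:
    """Population tie fraction: the tie probability averaged over uniform pairs."""
    lam = np.asarray(lam, dtype=float).ravel()
    if pairs is None:
        iu, ju = np.triu_indices(lam.size, k=1)
    else:
        iu, ju = np.asarray(pairs).T
    p = [outcome_probabilities(lam[i], lam[j], delta)[2] for i, j in zip(iu, ju)]
    return float(np.mean(p))


def delta_for_tie_fraction(
    target: float, lam: np.ndarray, pairs: np.ndarray | None = None
) -> float:
    """Tie parameter whose expected tie fraction equals ``target``.

    The expected fraction is continuous and strictly increasing in delta,
    from 0 at delta = 0 towards 1, so a monotone root-find (Brent) on an
    expanding bracket solves it.
    """
    if not 0 < target < 1:
        raise ValueError(f"target tie fraction must be in (0, 1), got {target}")
    f = lambda d: expected_tie_fraction(lam, d, pairs) - target
    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e4:  # tie fraction < target even for absurd delta
            raise ValueError(f"target tie fraction {target} unreachable")
    return float(brentq(f, 0.0, hi, xtol=1e-10))


def simulate_design(design: SimulationDesign):
    """Realise a full synthetic study.

    Returns ``(data, truth)`` where ``truth`` is a dict holding the graph
    or covariance, the prior, and the true lambda / delta / alpha^2.
    """
    rng = np.random.default_rng(design.seed)
    graph = None
    if design.covariance_kind == "network":
        if design.graph_kind == "grid":
            graph = grid_graph(design.n_wards)
        elif design.graph_kind == "random":
            graph = random_graph(design.n_wards, rng)
        else:
            raise ValueError(f"unknown graph_kind {design.graph_kind!r}")
        base_cov = network_covariance(graph, alpha2=1.0)
        labels = graph.ward_labels
    elif design.covariance_kind == "wishart":
        base_cov = wishart_covariance(design.n_wards, rng)
        labels = [f"W{k:03d}" for k in range(design.n_wards)]
    else:
        raise ValueError(f"unknown covariance_kind {design.covariance_kind!r}")

    prior = PriorSpec(base_covariance=base_cov, alpha2=design.alpha2_true)
    lam = simulate_lambda(prior, rng, alpha2=design.alpha2_true)
    if design.delta_true is not None:
        delta = float(design.delta_true)
    else:
        delta = delta_for_tie_fraction(design.target_tie_fraction, lam)
    data = simulate_comparisons(
        lam, delta, design.n_comparisons, rng, ward_labels=labels
    )
    truth = {
        "graph": graph,
        "base_covariance": base_cov,
        "prior": prior,
        "lambda": lam,
        "delta": delta,
        "alpha2": design.alpha2_true,
    }
    return data, truth
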