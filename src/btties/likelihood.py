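"""Bradley-Terry probability model with tied comparisons.

The standard Bradley-Terry model assigns each object (here, a UK electoral
ward) a real-valued quality ``lambda_i`` and models the probability that
ward ``i`` is judged higher than ward ``j`` as a logistic function of
``lambda_i - lambda_j``.  The Rao-Kupper extension adds a nonnegative tie
parameter ``delta``:

    P(i beats j) = exp(lambda_i) / (exp(lambda_i) + exp(lambda_j + delta))
    P(i ties j)  = (exp(2*delta) - 1) * P(i beats j) * P(j beats i)

At ``delta = 0`` ties have probability zero and the standard model is
recovered.  All computations are carried out on the log scale so that
quality draws from wide priors (|lambda| up to ~50) do not overflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "ComparisonTable",
    "DesignMatrix",
    "aggregate_comparisons",
    "build_design_matrix",
    "log_likelihood_standard",
    "log_likelihood_ties",
    "outcome_probabilities",
]


@dataclass
class ComparisonTable:
    """Aggregated pairwise comparison counts over N wards.

    Parameters
    ----------
    ward_labels
        Unique string identifiers, one per ward.  Internal indices are the
        positions in this list.
    wins
        ``(N, N)`` integer matrix; entry ``(i, j)`` counts comparisons in
        which ward ``i`` was judged higher than ward ``j``.  Zero diagonal.
    ties
        ``(N, N)`` symmetric integer matrix of tie counts; zero diagonal.
    """

    ward_labels: list[str]
    wins: np.ndarray
    ties: np.ndarray

    def __post_init__(self) -> None:
        self.wins = np.asarray(self.wins)
        self.ties = np.asarray(self.ties)
        n = len(self.ward_labels)
        if len(set(self.ward_labels)) != n:
            raise ValueError("ward labels must be unique")
        for name, m in (("wins", self.wins), ("ties", self.ties)):
            if m.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}, got {m.shape}")
            if np.any(m < 0):
                raise ValueError(f"{name} contains negative counts")
            if np.any(np.diag(m) != 0):
                raise ValueError(f"{name} has nonzero diagonal (self-comparison)")
        if not np.array_equal(self.ties, self.ties.T):
            raise ValueError("ties matrix must be symmetric")

    @property
    def n_wards(self) -> int:
        return len(self.ward_labels)

    @property
    def n_comparisons(self) -> int:
        """Total comparisons: sum over unordered pairs of wins both ways plus ties."""
        return int(self.wins.sum() + np.triu(self.ties).sum())

    @property
    def n_ties(self) -> int:
        return int(np.triu(self.ties).sum())

    def to_long(self) -> pd.DataFrame:
        """Expand back to one row per comparison (``ward_a, ward_b, outcome``)."""
        rows = []
        n = self.n_wards
        for i in range(n):
            for j in range(n):
                rows.extend(
                    [(self.ward_labels[i], self.ward_labels[j], "a")]
                    * int(self.wins[i, j])
                )
                if i < j:
                    rows.extend(
                        [(self.ward_labels[i], self.ward_labels[j], "tie")]
                        * int(self.ties[i, j])
                    )
        return pd.DataFrame(rows, columns=["ward_a", "ward_b", "outcome"])


@dataclass
class DesignMatrix:
    """Sparse +1/-1 design over ordered ward pairs with positive exposure.

    Row ``r`` represents the ordered pair ``(i, j) = (rows_i[r], rows_j[r])``
    and applied to a quality vector yields ``lambda_i - lambda_j``.  Only
    ordered pairs with exposure ``b_ij = y_ij + t_ij > 0`` appear, in
    lexicographic order.
    """

    n_wards: int
    rows_i: np.ndarray
    rows_j: np.ndarray
    exposures: np.ndarray  # b_ij = y_ij + t_ij per row, >= 1

    @property
    def n_rows(self) -> int:
        return self.rows_i.size

    @property
    def pair_index(self) -> list[tuple[int, int]]:
        return list(zip(self.rows_i.tolist(), self.rows_j.tolist()))

    def dot(self, lam: np.ndarray) -> np.ndarray:
        """X @ lambda: the vector of quality differences, one per row."""
        lam = np.asarray(lam, dtype=float)
        return lam[self.rows_i] - lam[self.rows_j]

    def transpose_dot(self, v: np.ndarray) -> np.ndarray:
        """X.T @ v accumulated without materialising the dense matrix."""
        out = np.zeros(self.n_wards)
        np.add.at(out, self.rows_i, v)
        np.subtract.at(out, self.rows_j, v)
        return out

    def weighted_gram(self, w: np.ndarray) -> np.ndarray:
        """X.T @ diag(w) @ X as a dense ``(N, N)`` matrix.

        Each row contributes ``w_r`` to the (i,i) and (j,j) entries and
        ``-w_r`` to (i,j) and (j,i) — a weighted graph Laplacian, hence
        zero row sums.
        """
        g = np.zeros((self.n_wards, self.n_wards))
        np.add.at(g, (self.rows_i, self.rows_i), w)
        np.add.at(g, (self.rows_j, self.rows_j), w)
        np.subtract.at(g, (self.rows_i, self.rows_j), w)
        np.subtract.at(g, (self.rows_j, self.rows_i), w)
        return g

    def to_sparse(self) -> sp.csr_matrix:
        r = np.arange(self.n_rows)
        data = np.concatenate([np.ones(self.n_rows), -np.ones(self.n_rows)])
        ij = (np.concatenate([r, r]), np.concatenate([self.rows_i, self.rows_j]))
        return sp.csr_matrix((data, ij), shape=(self.n_rows, self.n_wards))


def _log_sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    """log(1/(1+e^{-x})), overflow-safe for large |x|."""
    x = np.asarray(x, dtype=float)
    return np.where(x >= 0, -np.log1p(np.exp(-np.abs(x))), x - np.log1p(np.exp(-np.abs(x))))


def _log_expm1_2delta(delta: float) -> float:
    """log(e^{2 delta} - 1) computed stably for any delta > 0."""
    if delta <= 0.0:  # limit: ties have probability zero
        return -np.inf
    if delta < 0.5:
        return math.log(math.expm1(2.0 * delta))
    return 2.0 * delta + math.log1p(-math.exp(-2.0 * delta))


def outcome_probabilities(
    lambda_i: float, lambda_j: float, delta: float
) -> tuple[float, float, float]:
    """Win/loss/tie probabilities for one comparison of wards i and j.

    Returns ``(P(i beats j), P(j beats i), P(tie))``; the three sum to one.
    Evaluated via log-sigmoids so that quality differences up to ~100 in
    magnitude are handled without overflow.
    """
    if delta < 0:
        raise ValueError(f"tie parameter delta must be nonnegative, got {delta}")
    eta_ij = lambda_i - lambda_j - delta
    eta_ji = lambda_j - lambda_i - delta
    log_p_ij = _log_sigmoid(eta_ij)
    log_p_ji = _log_sigmoid(eta_ji)
    p_ij = float(np.exp(log_p_ij))
    p_ji = float(np.exp(log_p_ji))
    if delta == 0:
        return p_ij, p_ji, 0.0
    log_p_tie = _log_expm1_2delta(delta) + log_p_ij + log_p_ji
    return p_ij, p_ji, float(np.exp(log_p_tie))


def _check_dims(data: ComparisonTable, lam: np.ndarray) -> np.ndarray:
    lam = np.asarray(lam, dtype=float).ravel()
    if lam.size != data.n_wards:
        raise ValueError(
            f"quality vector has length {lam.size}, expected {data.n_wards}"
        )
    return lam


def log_likelihood_ties(data: ComparisonTable, lam: np.ndarray, delta: float) -> float:
    """Log-likelihood of the tied Bradley-Terry model.

    Summed over unordered pairs as
    ``y_ij log p(i>j) + y_ji log p(j>i) + t_ij log p(tie)``.  Because
    ``p(tie) = (e^{2 delta}-1) p(i>j) p(j>i)`` exactly, this equals
    ``T log(e^{2 delta}-1) + sum over ordered pairs (y_ij+t_ij) log p(i>j)``
    with ``T`` the total tie count.  Invariant under ``lambda -> lambda + c``.
    """
    if delta < 0:
        raise ValueError(f"tie parameter delta must be nonnegative, got {delta}")
    lam = _check_dims(data, lam)
    i, j = np.nonzero(data.wins + data.ties)
    if i.size == 0:
        return 0.0
    eta = lam[i] - lam[j] - delta
    b = (data.wins + data.ties)[i, j].astype(float)
    total = float(np.dot(b, _log_sigmoid(eta)))
    n_ties = data.n_ties
    if n_ties > 0:
        total += n_ties * _log_expm1_2delta(delta)
    return total


def log_likelihood_standard(data: ComparisonTable, lam: np.ndarray) -> float:
    """Binomial log-likelihood of the standard (no-ties) Bradley-Terry model.

    Includes the binomial coefficients; requires a tie-free table.
    """
    if np.any(data.ties != 0):
        raise ValueError(
            "standard Bradley-Terry model does not admit ties; use log_likelihood_ties"
        )
    lam = _check_dims(data, lam)
    iu, ju = np.triu_indices(data.n_wards, k=1)
    y_ij = data.wins[iu, ju].astype(float)
    y_ji = data.wins[ju, iu].astype(float)
    n = y_ij + y_ji
    mask = n > 0
    if not np.any(mask):
        return 0.0
    y_ij, y_ji, n = y_ij[mask], y_ji[mask], n[mask]
    eta = lam[iu[mask]] - lam[ju[mask]]
    from scipy.special import gammaln

    log_binom = gammaln(n + 1) - gammaln(y_ij + 1) - gammaln(y_ji + 1)
    return float(
        np.sum(log_binom + y_ij * _log_sigmoid(eta) + y_ji * _log_sigmoid(-eta))
    )


def build_design_matrix(data: ComparisonTable) -> DesignMatrix:
    """One +1/-1 row per ordered pair (i, j) with ``y_ij + t_ij > 0``.

    A tie contributes exposure to both orders of the pair.  Rows are in
    lexicographic (i, j) order, which fixes the layout of the Polya-Gamma
    latent vector.
    """
    exposure = data.wins + data.ties
    i, j = np.nonzero(exposure)  # np.nonzero is row-major, i.e. lexicographic
    return DesignMatrix(
        n_wards=data.n_wards,
        rows_i=i.astype(np.int64),
        rows_j=j.astype(np.int64),
        exposures=exposure[i, j].astype(np.int64),
    )


def aggregate_comparisons(
    records: pd.DataFrame, ward_labels: Sequence[str] | None = None
) -> ComparisonTable:
    """Aggregate long-format comparison records into a :class:`ComparisonTable`.

    Parameters
    ----------
    records
        Data frame with columns ``ward_a, ward_b, outcome`` where outcome is
        ``"a"`` (ward_a judged higher), ``"b"`` or ``"tie"``.
    ward_labels
        Full ward list to aggregate onto (e.g. all nodes of the adjacency
        graph, including wards never compared).  Defaults to the sorted
        labels present in the records.
    """
    required = {"ward_a", "ward_b", "outcome"}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    a = records["ward_a"].astype(str)
    b = records["ward_b"].astype(str)
    outcome = records["outcome"].astype(str).str.strip().str.lower()

    bad = ~outcome.isin(["a", "b", "tie"])
    if bad.any():
        lines = (records.index[bad] + 1).tolist()
        raise ValueError(
            f"unknown outcome tokens {sorted(outcome[bad].unique())} "
            f"at record(s) {lines}; expected 'a', 'b' or 'tie'"
        )
    selfcmp = a == b
    if selfcmp.any():
        raise ValueError(
            f"ward compared with itself at record(s) {(records.index[selfcmp] + 1).tolist()}"
        )

    if ward_labels is None:
        ward_labels = sorted(set(a) | set(b))
    ward_labels = list(ward_labels)
    index = {w: k for k, w in enumerate(ward_labels)}
    unknown = sorted((set(a) | set(b)) - set(ward_labels))
    if unknown:
        raise ValueError(f"wards present in comparisons but not in ward list: {unknown}")

    n = len(ward_labels)
    wins = np.zeros((n, n), dtype=np.int64)
    ties = np.zeros((n, n), dtype=np.int64)
    ia = a.map(index).to_numpy()
    ib = b.map(index).to_numpy()
    out = outcome.to_numpy()
    np.add.at(wins, (ia[out == "a"], ib[out == "a"]), 1)
    np.add.at(wins, (ib[out == "b"], ia[out == "b"]), 1)
    np.add.at(ties, (ia[out == "tie"], ib[out == "tie"]), 1)
    np.add.at(ties, (ib[out == "tie"], ia[out == "tie"]), 1)
    return ComparisonTable(ward_labels=ward_labels, wins=wins, ties=ties)
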