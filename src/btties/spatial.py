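"""Graph-structured multivariate-normal priors on ward qualities.

The prior covariance is built from the ward adjacency matrix A via the
normalised matrix exponential

    Sigma = alpha^2 * D^{-1/2} exp(A) D^{-1/2},

where D holds the diagonal of exp(A).  Wards connected by many short paths
get high prior correlation; the normalisation gives unit diagonal so the
signal variance alpha^2 is interpretable on its own.  alpha^2 may be fixed
or given a conjugate inverse-gamma hyperprior and Gibbs-sampled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.stats import multivariate_normal

__all__ = [
    "WardGraph",
    "PriorSpec",
    "network_covariance",
    "prior_logpdf",
    "read_adjacency",
    "sample_alpha2",
    "total_quality_distribution",
]

logger = logging.getLogger(__name__)


@dataclass
class WardGraph:
    """Undirected ward adjacency: symmetric binary matrix, zero diagonal."""

    ward_labels: list[str]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency)
        n = len(self.ward_labels)
        if self.adjacency.shape != (n, n):
            raise ValueError(f"adjacency must be {n}x{n}")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency matrix must be symmetric")
        if not np.isin(self.adjacency, [0, 1]).all():
            raise ValueError("adjacency must be binary")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("adjacency must have zero diagonal (no self-loops)")

    @property
    def n_wards(self) -> int:
        return len(self.ward_labels)

    def is_connected(self) -> bool:
        import networkx as nx

        return nx.is_connected(nx.from_numpy_array(self.adjacency))


def network_covariance(graph: WardGraph, alpha2: float = 1.0) -> np.ndarray:
    """Matrix-exponential covariance ``alpha^2 D^{-1/2} e^A D^{-1/2}``.

    Symmetric positive definite with every diagonal entry equal to
    ``alpha2``.  Disconnected graphs are permitted (e^A stays PD; prior
    correlation across components is simply weak) but logged.
    """
    if alpha2 <= 0:
        raise ValueError(f"alpha2 must be positive, got {alpha2}")
    if not graph.is_connected():
        logger.warning(
            "ward graph is disconnected; prior correlation across components is weak"
        )
    expa = sla.expm(graph.adjacency.astype(float))
    expa = 0.5 * (expa + expa.T)  # enforce exact symmetry after expm round-off
    d = np.sqrt(np.diag(expa))
    cov = alpha2 * (expa / np.outer(d, d))
    np.fill_diagonal(cov, alpha2)
    return cov


@dataclass
class PriorSpec:
    """Multivariate-normal prior on qualities plus the delta prior rate.

    ``base_covariance`` is the alpha^2 = 1 covariance (unit diagonal);
    ``alpha2`` either a fixed positive scalar or the string ``"inferred"``,
    in which case it carries an InverseGamma(alpha2_shape, alpha2_scale)
    hyperprior and is Gibbs-updated during sampling.  ``chi`` is the rate of
    the exponential prior on the tie parameter delta.
    """

    base_covariance: np.ndarray
    mean: np.ndarray | None = None
    alpha2: float | str = "inferred"
    alpha2_shape: float = 0.01
    alpha2_scale: float = 0.01
    chi: float = 0.01

    def __post_init__(self) -> None:
        self.base_covariance = np.asarray(self.base_covariance, dtype=float)
        n = self.base_covariance.shape[0]
        if self.base_covariance.shape != (n, n):
            raise ValueError("base_covariance must be square")
        if not np.allclose(self.base_covariance, self.base_covariance.T, atol=1e-12):
            raise ValueError("base_covariance must be symmetric")
        if np.max(np.abs(np.diag(self.base_covariance) - 1.0)) > 1e-10:
            raise ValueError("base_covariance must have unit diagonal (alpha^2 = 1 scale)")
        try:
            self._chol0 = np.linalg.cholesky(self.base_covariance)
        except np.linalg.LinAlgError as err:
            raise ValueError("base_covariance is not positive definite") from err
        if self.mean is None:
            self.mean = np.zeros(n)
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        if self.mean.size != n:
            raise ValueError("prior mean has wrong length")
        if isinstance(self.alpha2, str):
            if self.alpha2 != "inferred":
                raise ValueError("alpha2 must be a positive number or 'inferred'")
        elif self.alpha2 <= 0:
            raise ValueError("fixed alpha2 must be positive")
        for name in ("alpha2_shape", "alpha2_scale", "chi"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n_wards(self) -> int:
        return self.base_covariance.shape[0]

    @property
    def infer_alpha2(self) -> bool:
        return self.alpha2 == "inferred"

    def covariance(self, alpha2: float | None = None) -> np.ndarray:
        """Sigma at the given (or fixed) alpha^2."""
        if alpha2 is None:
            if self.infer_alpha2:
                raise ValueError("alpha2 is inferred; pass its current value")
            alpha2 = float(self.alpha2)
        return alpha2 * self.base_covariance

    def base_precision(self) -> np.ndarray:
        """Inverse of the alpha^2 = 1 covariance (computed once, via Cholesky)."""
        if not hasattr(self, "_prec0"):
            self._prec0 = sla.cho_solve((self._chol0, True), np.eye(self.n_wards))
        return self._prec0

    def base_cholesky(self) -> np.ndarray:
        return self._chol0


def prior_logpdf(lam: np.ndarray, prior: PriorSpec, alpha2: float | None = None) -> float:
    """Multivariate-normal log density of the qualities, constant included."""
    lam = np.asarray(lam, dtype=float).ravel()
    cov = prior.covariance(alpha2)
    try:
        return float(
            multivariate_normal.logpdf(lam, mean=prior.mean, cov=cov, allow_singular=False)
        )
    except (np.linalg.LinAlgError, ValueError) as err:
        raise ValueError("prior covariance is singular") from err


def sample_alpha2(
    lam: np.ndarray,
    base_covariance: np.ndarray,
    shape: float,
    scale: float,
    rng: np.random.Generator,
    mean: np.ndarray | None = None,
) -> float:
    """Conjugate Gibbs draw of the signal variance alpha^2.

    With lambda | alpha^2 ~ N(mu, alpha^2 Sigma_0) and
    alpha^2 ~ InvGamma(shape, scale), the full conditional is
    InvGamma(shape + N/2, scale + (lambda-mu)^T Sigma_0^{-1} (lambda-mu) / 2).
    """
    lam = np.asarray(lam, dtype=float).ravel()
    if mean is not None:
        lam = lam - np.asarray(mean, dtype=float).ravel()
    base_covariance = np.asarray(base_covariance, dtype=float)
    try:
        chol = sla.cho_factor(base_covariance, lower=True)
    except np.linalg.LinAlgError as err:
        raise ValueError("base covariance is not positive definite") from err
    qform = float(lam @ sla.cho_solve(chol, lam))
    post_shape = shape + lam.size / 2.0
    post_scale = scale + qform / 2.0
    # InvGamma(a, b) draw as b / Gamma(a, 1)
    return post_scale / rng.gamma(post_shape)


def total_quality_distribution(
    prior: PriorSpec, alpha2: float | None = None
) -> tuple[float, float]:
    """Prior law of the average quality ``Lambda = (1/N) sum_i lambda_i``.

    Under lambda ~ N(mu, Sigma): Lambda ~ N(1'mu / N, 1'Sigma 1 / N^2).
    """
    n = prior.n_wards
    cov = prior.covariance(alpha2)
    return float(prior.mean.sum() / n), float(cov.sum() / n**2)


def read_adjacency(path) -> WardGraph:
    """Read an undirected edge list CSV with header ``ward_a,ward_b``."""
    df = pd.read_csv(path, dtype=str)
    if not {"ward_a", "ward_b"}.issubset(df.columns):
        raise ValueError("adjacency CSV must have columns ward_a,ward_b")
    labels = sorted(set(df["ward_a"]) | set(df["ward_b"]))
    index = {w: k for k, w in enumerate(labels)}
    n = len(labels)
    adj = np.zeros((n, n), dtype=np.int64)
    for a, b in zip(df["ward_a"], df["ward_b"]):
        if a == b:
            raise ValueError(f"self-loop on ward {a!r}")
        i, j = index[a], index[b]
        adj[i, j] = adj[j, i] = 1
    return WardGraph(ward_labels=labels, adjacency=adj)


def write_adjacency(graph: WardGraph, path) -> None:
    i, j = np.nonzero(np.triu(graph.adjacency))
    pd.DataFrame(
        {
            "ward_a": [graph.ward_labels[k] for k in i],
            "ward_b": [graph.ward_labels[k] for k in j],
        }
    ).to_csv(path, index=False)
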