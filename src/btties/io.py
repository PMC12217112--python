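"""Readers, writers and convergence diagnostics for fit/simulate workflows.

All files are plain CSV; every fit or simulation also writes a JSON run
manifest (inputs, resolved configuration, seed, package version, wall
time, acceptance rates) so a run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .likelihood import ComparisonTable, aggregate_comparisons, outcome_probabilities
from .sampler import PosteriorTrace, effective_sample_size

__all__ = [
    "diagnose_trace",
    "read_comparisons",
    "read_covariance",
    "read_trace",
    "split_rhat",
    "write_comparisons",
    "write_manifest",
    "write_trace",
]


def read_comparisons(path, ward_labels: list[str] | None = None) -> ComparisonTable:
    """Read a long-format comparisons CSV (``ward_a,ward_b,outcome``)."""
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as err:
        raise ValueError(f"comparisons file {path} is empty") from err
    if df.empty:
        raise ValueError(f"comparisons file {path} contains no records")
    return aggregate_comparisons(df, ward_labels=ward_labels)


def write_comparisons(data: ComparisonTable, path) -> None:
    data.to_long().to_csv(path, index=False)


def read_covariance(path) -> np.ndarray:
    """Dense covariance matrix CSV (square, with or without header)."""
    cov = pd.read_csv(path, header=None).to_numpy(dtype=float)
    if cov.shape[0] + 1 == cov.shape[1] or np.isnan(cov[0]).any():
        cov = pd.read_csv(path).to_numpy(dtype=float)  # header present
    if cov.shape[0] != cov.shape[1]:
        raise ValueError(f"covariance in {path} is not square: {cov.shape}")
    return cov


def write_trace(trace: PosteriorTrace, path) -> None:
    trace.to_dataframe().to_csv(path, index=False)


def read_trace(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = {"iteration", "delta"}
    if not expected.issubset(df.columns) or not any(
        c.startswith("lambda_") for c in df.columns
    ):
        raise ValueError(f"{path} is not a trace file (truncated or wrong columns)")
    if df.isna().any().any():
        raise ValueError(f"trace file {path} is truncated (missing values)")
    return df


def split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for a single chain."""
    x = np.asarray(x, dtype=float).ravel()
    half = x.size // 2
    if half < 2:
        return float("nan")
    if np.var(x) < 1e-300:
        return float("nan")
    import arviz as az

    return float(az.rhat(x[: 2 * half].reshape(2, half), method="rank"))


def diagnose_trace(df: pd.DataFrame) -> pd.DataFrame:
    """ESS and split R-hat per parameter column; constant columns flagged."""
    rows = []
    for col in df.columns:
        if col == "iteration":
            continue
        x = df[col].to_numpy(dtype=float)
        constant = bool(np.var(x) < 1e-300)
        rows.append(
            {
                "parameter": col,
                "mean": x.mean(),
                "median": float(np.median(x)),
                "ess": effective_sample_size(x),
                "rhat": split_rhat(x),
                "constant": constant,
            }
        )
    return pd.DataFrame(rows)


def plot_delta_diagnostics(df: pd.DataFrame, path) -> None:
    """Trace plot and histogram of the tie parameter."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.2))
    axes[0].plot(df["iteration"], df["delta"], lw=0.5)
    axes[0].set_xlabel("iteration")
    axes[0].set_ylabel(r"$\delta$")
    axes[1].hist(df["delta"], bins=40, density=True)
    axes[1].set_xlabel(r"$\delta$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def tie_probability_curve(delta: float, max_diff: float = 5.0, n: int = 201):
    """P(tie) as a function of the quality difference at a fixed delta.

    At difference zero the curve equals tanh(delta/2).
    """
    diffs = np.linspace(-max_diff, max_diff, n)
    probs = np.array([outcome_probabilities(d, 0.0, delta)[2] for d in diffs])
    return diffs, probs


def plot_tie_probability(delta: float, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    diffs, probs = tie_probability_curve(delta)
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(diffs, probs)
    ax.set_xlabel(r"$\lambda_i - \lambda_j$")
    ax.set_ylabel("P(tie)")
    ax.set_title(rf"posterior-median $\delta$ = {delta:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_manifest(
    path,
    *,
    inputs: dict,
    config,
    seed,
    wall_time: float,
    extras: dict | None = None,
) -> None:
    from . import __version__

    manifest = {
        "inputs": {k: str(v) for k, v in inputs.items()},
        "config": asdict(config) if not isinstance(config, dict) else config,
        "seed": seed,
        "package_version": __version__,
        "wall_time_seconds": wall_time,
        "written_at_unix": time.time(),
    }
    if extras:
        manifest.update(extras)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
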