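"""Post-fit reporting and interpretation helpers.

Explained variance, per-parameter posterior probabilities and credible
intervals, effective self-connection rates under given experimental
contexts, and a tabular summary of a fitted model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .integrate import Dataset, Prediction
from .inversion import FitResult
from .model import ModelSpec, SELF_RATE, unvectorise
from .neural import half_life as _half_life
from .neural import time_constant as _time_constant

__all__ = ["explained_variance", "posterior_probability",
           "effective_self_connection", "self_connection_time_constant",
           "summarise", "FitReport", "plot_fit"]

Z90 = float(stats.norm.ppf(0.95))


def explained_variance(prediction: Prediction, data: Dataset) -> float:
    """Percentage of data variance captured by the model, all regions jointly.

    Variance explained by the confound regressors is removed from both the
    data and the prediction first, so the figure reflects the dynamic part
    of the model only.  Floored at zero.
    """
    Y = data.Y
    y_hat = prediction.y_hat
    if y_hat.shape != Y.shape:
        raise ValueError("prediction and data shapes differ")
    X0 = data.X0
    if X0 is not None and X0.size:
        # residual-forming projector for the confound space
        pinv = np.linalg.pinv(X0)
        Yr = Y - X0 @ (pinv @ Y)
        Hr = y_hat - X0 @ (pinv @ y_hat)
    else:
        Yr, Hr = Y, y_hat
    ss_data = float(np.sum(Yr ** 2))
    if ss_data <= 1e-12 * max(float(np.sum(Y ** 2)), 1.0):
        raise ValueError("data have zero variance outside the confound space")
    ss_res = float(np.sum((Yr - Hr) ** 2))
    return max(0.0, 100.0 * (1.0 - ss_res / ss_data))


def posterior_probability(mean: float, variance: float) -> float:
    """Probability that a parameter with posterior N(mean, variance) is not zero.

    Phi(|mean| / sd), the posterior mass on the side of zero indicated by
    the sign of the mean.
    """
    if not variance > 0:
        raise ValueError("variance must be positive")
    return float(stats.norm.cdf(abs(mean) / np.sqrt(variance)))


def effective_self_connection(result: FitResult, spec: ModelSpec, region: int, u) -> float:
    """Self-connection rate (Hz) of ``region`` in input context ``u``.

    Evaluates -0.5 exp(A_I) exp(sum_k B_I^(k) u_k) at the posterior means.
    """
    if not 0 <= region < spec.n_regions:
        raise ValueError(f"region {region} out of range")
    u = np.asarray(u, dtype=float).ravel()
    params = unvectorise(result.posterior.mean, spec)
    exponent = params.a[region, region] + float(params.b[:, region, region] @ u)
    return SELF_RATE * np.exp(exponent)


def self_connection_time_constant(result: FitResult, spec: ModelSpec, region: int, u):
    """Time constant and half-life (s) of a region's effective self-connection."""
    rate = effective_self_connection(result, spec, region, u)
    return _time_constant(rate), _half_life(rate)


@dataclass
class FitReport:
    """Per-parameter summary table plus model-level statistics."""

    table: pd.DataFrame
    F: float
    accuracy: float
    complexity: float
    explained_variance: float | None
    n_iterations: int
    converged: bool

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def summarise(result: FitResult, spec: ModelSpec,
              data: Dataset | None = None) -> FitReport:
    """Tabulate every free parameter with its posterior summary.

    Columns: parameter label (extrinsic connections use the
    ``source → target`` convention), family, units (Hz for extrinsic and
    driving rates; log-scaling parameters are unitless), posterior mean and
    sd, 90% credible interval and the probability of being non-zero.
    """
    post = result.posterior
    sds = post.sd()
    rows = []
    for i, e in enumerate(post.index):
        lo, hi = post.credible_interval(i)
        rows.append({
            "parameter": e.label,
            "family": e.family,
            "units": e.units,
            "mean": post.mean[i],
            "sd": sds[i],
            "ci90_low": lo,
            "ci90_high": hi,
            "probability": posterior_probability(post.mean[i], sds[i] ** 2)
            if sds[i] > 0 else 0.5,
        })
    ev = explained_variance(result.prediction, data) if data is not None else None
    return FitReport(
        table=pd.DataFrame(rows),
        F=result.F,
        accuracy=result.accuracy,
        complexity=result.complexity,
        explained_variance=ev,
        n_iterations=result.n_iterations,
        converged=result.converged,
    )


def plot_fit(result: FitResult, data: Dataset, spec: ModelSpec, path) -> None:
    """Predicted vs observed timeseries per region, with stimulus blocks underlaid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    V = data.n_volumes
    t = np.arange(V) * data.TR
    R = spec.n_regions
    fig, axes = plt.subplots(R, 1, figsize=(8, 2.0 * R), sharex=True, squeeze=False)
    U = data.U
    on = (U.values > U.values.min(axis=0)) if U.centred else (U.values > 0)
    tu = np.arange(U.n_bins) * U.dt
    for r in range(R):
        ax = axes[r, 0]
        for k in range(U.n_conditions):
            ax.fill_between(tu, 0, 1, where=on[:, k], alpha=0.08,
                            transform=ax.get_xaxis_transform())
        ax.plot(t, data.Y[:, r], ".", ms=2, color="grey", label="observed")
        ax.plot(t, result.prediction.y_hat[:, r], color="C0", label="predicted")
        ax.set_ylabel(spec.region_names[r])
        if r == 0:
            ax.legend(loc="upper right", fontsize=8)
    axes[-1, 0].set_xlabel("time (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
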