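"""EFSA-style model performance criteria: PPC, NRMSE and SPPE.

All three operate on observed survivor counts versus posterior-predictive
summaries and are reported in percent, so values are comparable across
datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["MetricsReport", "ppc", "nrmse", "sppe", "compute_metrics"]


@dataclass
class MetricsReport:
    """Performance summary of one calibrated model on one dataset.

    ``ppc_pass_fraction``: % of observations inside the predicted
    uncertainty limits; ``nrmse``: RMSE of predicted medians normalized by
    the mean observation, in %; ``sppe_per_replicate``: final-timepoint
    prediction error per replicate, in % of the initial group size, with
    the dataset-level min/max extremes.
    """

    ppc_pass_fraction: float
    nrmse: float
    sppe_per_replicate: list[float]
    sppe_min: float
    sppe_max: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "ppc_percent": self.ppc_pass_fraction,
                "nrmse_percent": self.nrmse,
                "sppe_percent_per_replicate": self.sppe_per_replicate,
                "sppe_min_percent": self.sppe_min,
                "sppe_max_percent": self.sppe_max,
            },
            indent=2,
        )


def ppc(observed_counts, predicted_intervals) -> float:
    """Predictive posterior check: percentage of observations falling inside
    their predicted uncertainty limits (boundary counts as inside)."""
    obs = np.asarray(observed_counts, dtype=float)
    iv = np.asarray(predicted_intervals, dtype=float)
    if iv.ndim != 2 or iv.shape[1] != 2 or len(obs) != len(iv):
        raise ValueError("need one (lo, hi) interval per observation")
    inside = (obs >= iv[:, 0]) & (obs <= iv[:, 1])
    return float(100.0 * inside.sum() / len(obs))


def nrmse(observed_counts, predicted_medians) -> float:
    """Root-mean-square error normalized by the mean of all observations, %."""
    obs = np.asarray(observed_counts, dtype=float)
    pred = np.asarray(predicted_medians, dtype=float)
    if obs.size == 0 or obs.shape != pred.shape:
        raise ValueError("observed and predicted must be nonempty and equally long")
    mean_obs = obs.mean()
    if mean_obs <= 0:
        raise ValueError("mean of observations is zero: NRMSE undefined")
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    return 100.0 * rmse / mean_obs


def sppe(observed_final, predicted_final, n_initial) -> np.ndarray:
    """Survival-probability prediction error per replicate, in %.

    ``100 * (observed - predicted) / n_initial`` at the final timepoint.
    The sign is implemented exactly as the formula reads: positive when the
    model predicts fewer survivors than observed (effects overestimated),
    negative when it predicts more (effects underestimated).
    """
    obs = np.asarray(observed_final, dtype=float)
    pred = np.asarray(predicted_final, dtype=float)
    n0 = np.asarray(n_initial, dtype=float)
    if np.any(n0 <= 0):
        raise ValueError("n_initial must be positive")
    return 100.0 * (obs - pred) / n0


def compute_metrics(prediction_table) -> MetricsReport:
    """Build the full report from a posterior-predictive table
    (as produced by :func:`bufferguts.calibration.posterior_predict`)."""
    obs = prediction_table["observed"].to_numpy()
    med = prediction_table["predicted_median"].to_numpy()
    iv = prediction_table[["predicted_lo", "predicted_hi"]].to_numpy()
    ppc_val = ppc(obs, iv)
    nrmse_val = nrmse(obs, med)
    finals = prediction_table.sort_values("time_days").groupby("replicate").last()
    sppe_vals = sppe(
        finals["observed"].to_numpy(),
        finals["predicted_median"].to_numpy(),
        finals["n_initial"].to_numpy(),
    )
    return MetricsReport(
        ppc_pass_fraction=ppc_val,
        nrmse=nrmse_val,
        sppe_per_replicate=[float(v) for v in sppe_vals],
        sppe_min=float(np.min(sppe_vals)),
        sppe_max=float(np.max(sppe_vals)),
    )
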