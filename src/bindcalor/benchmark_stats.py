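"""Accuracy metrics against the ITC benchmark: RMSE, squared Pearson
correlation, tie-corrected Kendall tau-b, and the 2 kcal/mol outlier rule."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

OUTLIER_THRESHOLD = 2.0  # kcal/mol


class UndefinedMetricError(ValueError):
    pass


def _paired(pred, exp) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if pred.shape != exp.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {exp.shape}")
    if pred.size < 1:
        raise ValueError("empty input")
    if not (np.all(np.isfinite(pred)) and np.all(np.isfinite(exp))):
        raise ValueError("missing or non-finite values are not allowed")
    return pred, exp


def rmse(pred, exp) -> float:
    """Root-mean-square error, kcal/mol."""
    pred, exp = _paired(pred, exp)
    return float(np.sqrt(np.mean((pred - exp) ** 2)))


def r_squared(pred, exp) -> float:
    """Squared Pearson correlation (not the identity-line R²)."""
    pred, exp = _paired(pred, exp)
    if pred.size < 2:
        raise UndefinedMetricError("correlation requires n >= 2")
    if np.var(pred) == 0 or np.var(exp) == 0:
        raise UndefinedMetricError("zero variance: correlation undefined")
    r = stats.pearsonr(pred, exp).statistic
    return float(r * r)


def r2_identity(pred, exp) -> float:
    """Coefficient of determination about the identity line (diagnostic)."""
    pred, exp = _paired(pred, exp)
    ss_res = np.sum((exp - pred) ** 2)
    ss_tot = np.sum((exp - exp.mean()) ** 2)
    if ss_tot == 0:
        raise UndefinedMetricError("zero variance: R2 about identity undefined")
    return float(1.0 - ss_res / ss_tot)


def kendall_tau(pred, exp) -> float:
    """Kendall tau-b (tie-corrected)."""
    pred, exp = _paired(pred, exp)
    if pred.size < 2:
        raise UndefinedMetricError("Kendall tau requires n >= 2")
    result = stats.kendalltau(pred, exp, variant="b")
    tau = float(result.statistic)
    if np.isnan(tau):
        raise UndefinedMetricError("Kendall tau undefined (all-tied input)")
    return tau


def flag_outliers(deviations: dict, threshold: float = OUTLIER_THRESHOLD) -> list:
    """System ids with |deviation| strictly above threshold, worst first."""
    for system_id, dev in deviations.items():
        if dev < 0:
            raise ValueError(f"deviation for {system_id} must be >= 0")
    flagged = [(system_id, dev) for system_id, dev in deviations.items() if dev > threshold]
    flagged.sort(key=lambda item: -item[1])
    return [system_id for system_id, _ in flagged]


@dataclass(frozen=True)
class BenchmarkResult:
    n: int
    rmse: float
    r_squared: float
    kendall_tau: float
    deviations: dict  # system_id -> |pred - exp|
    outlier_ids: list

    def __post_init__(self):
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")


def score_benchmark(
    predictions: dict, experiments: dict, threshold: float = OUTLIER_THRESHOLD
) -> BenchmarkResult:
    """Score predicted dH against experimental dH (both {system_id: value}).

    Systems missing on either side are dropped pairwise with a warning.
    """
    import logging

    common = [sid for sid in experiments if sid in predictions]
    dropped = sorted(set(experiments) ^ set(predictions))
    if dropped:
        logging.getLogger("bindcalor").warning(
            "dropping unpaired systems: %s", ", ".join(dropped)
        )
    if len(common) < 2:
        raise UndefinedMetricError("need >= 2 paired systems for correlation metrics")
    pred = np.array([predictions[sid] for sid in common])
    exp = np.array([experiments[sid] for sid in common])
    deviations = {sid: float(abs(p - e)) for sid, p, e in zip(common, pred, exp)}
    return BenchmarkResult(
        n=len(common),
        rmse=rmse(pred, exp),
        r_squared=r_squared(pred, exp),
        kendall_tau=kendall_tau(pred, exp),
        deviations=deviations,
        outlier_ids=flag_outliers(deviations, threshold),
    )
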