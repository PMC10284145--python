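"""Flyvbjerg–Petersen blocking analysis with the max-SEM selection rule.

For an autocorrelated series the naive SEM underestimates the error of the
mean.  Blocking repeatedly averages consecutive pairs; once blocks are longer
than the correlation time the block-level SEM stops growing.  Rather than
detect that plateau we report the maximum SEM across levels, a conservative
convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .io_formats import EnergySeries


class BlockingLevel(NamedTuple):
    level: int
    n_blocks: int
    block_mean: float
    sem: float


@dataclass(frozen=True)
class BlockingCurve:
    """SEM of the mean at each blocking level."""

    levels: tuple[BlockingLevel, ...]

    def __iter__(self):
        return iter(self.levels)

    def __len__(self):
        return len(self.levels)


@dataclass(frozen=True)
class LegEstimate:
    """Mean potential energy of one leg with its blocking SEM (kcal/mol)."""

    leg: str
    mean: float
    sem: float
    n_replicas: int
    n_frames_total: int
    selection_rule: str

    def __post_init__(self):
        if not np.isfinite(self.mean):
            raise ValueError("mean must be finite")
        if self.sem < 0:
            raise ValueError("sem must be >= 0")


class InsufficientDataError(ValueError):
    pass


def _level_sem(blocks: np.ndarray) -> float:
    n = blocks.size
    if n < 2:
        return float("nan")
    return float(np.sqrt(np.var(blocks, ddof=1) / n))


def blocking_curve(series: EnergySeries | np.ndarray, min_blocks: int = 8) -> BlockingCurve:
    """Blocking curve of a series.

    Level 0 is the raw data; level b+1 averages consecutive non-overlapping
    pairs of level-b blocks, dropping an odd trailing block.  Only levels with
    at least ``min_blocks`` blocks are retained.
    """
    values = series.values if isinstance(series, EnergySeries) else np.asarray(series, float)
    if min_blocks < 2:
        raise ValueError("min_blocks must be >= 2")
    if values.size < min_blocks:
        raise InsufficientDataError(
            f"series of length {values.size} is shorter than min_blocks={min_blocks}"
        )
    levels = []
    blocks = values
    level = 0
    while blocks.size >= min_blocks:
        levels.append(
            BlockingLevel(
                level=level,
                n_blocks=int(blocks.size),
                block_mean=float(blocks.mean()),
                sem=_level_sem(blocks),
            )
        )
        n_pairs = blocks.size // 2
        blocks = (blocks[: 2 * n_pairs : 2] + blocks[1 : 2 * n_pairs : 2]) / 2.0
        level += 1
    return BlockingCurve(levels=tuple(levels))


def select_sem(curve: BlockingCurve) -> tuple[float, int]:
    """Maximum SEM across levels; ties resolved to the lowest level."""
    if len(curve) == 0:
        raise ValueError("empty blocking curve")
    best = max(curve, key=lambda lv: (lv.sem, -lv.level))
    return best.sem, best.level


def blocked_estimate(values: np.ndarray, min_blocks: int = 8) -> tuple[float, float, int]:
    """(mean, max-SEM, level) of a raw array; falls back to the naive SEM
    when the array is too short to block."""
    values = np.asarray(values, float)
    if values.size >= max(min_blocks, 2):
        curve = blocking_curve(values, min_blocks=min_blocks)
        sem, level = select_sem(curve)
        return float(values.mean()), sem, level
    if values.size >= 2:
        return float(values.mean()), float(np.sqrt(np.var(values, ddof=1) / values.size)), 0
    return float(values.mean()), 0.0, 0


def estimate_leg(
    replicas: Sequence[EnergySeries],
    min_blocks: int = 8,
    mode: str = "per_replica",
    discard_frames: int = 0,
) -> LegEstimate:
    """Pool replicas of one leg into a single (mean, SEM) estimate.

    mode="concat": blocking on the concatenation of all replicas.
    mode="per_replica": blocking per replica; the pooled mean is the
    unweighted mean of replica means and the SEM is the larger of the
    quadrature-pooled per-replica SEM and the standard error of the replica
    means (the between-replica scatter dominates when replicas disagree).
    """
    replicas = list(replicas)
    if not replicas:
        raise ValueError("at least one replica is required")
    leg = replicas[0].leg
    dt = replicas[0].dt
    for r in replicas:
        if r.leg != leg:
            raise ValueError(f"mixed legs: {r.leg!r} vs {leg!r}")
        if r.dt != dt:
            raise ValueError("mixed frame spacings across replicas")
    arrays = [r.values[discard_frames:] for r in replicas]
    if any(a.size == 0 for a in arrays):
        raise InsufficientDataError("discard_frames leaves an empty replica")
    n_total = int(sum(a.size for a in arrays))

    if mode == "concat":
        concat = np.concatenate(arrays)
        curve = blocking_curve(concat, min_blocks=min_blocks)
        sem, level = select_sem(curve)
        return LegEstimate(
            leg=leg,
            mean=float(concat.mean()),
            sem=sem,
            n_replicas=len(replicas),
            n_frames_total=n_total,
            selection_rule=f"concat,max-SEM,level={level},min_blocks={min_blocks}",
        )
    if mode == "per_replica":
        means = []
        sems = []
        levels = []
        for a in arrays:
            m, s, lv = blocked_estimate(a, min_blocks=min_blocks)
            means.append(m)
            sems.append(s)
            levels.append(lv)
        means = np.asarray(means)
        R = means.size
        pooled = float(np.sqrt(np.sum(np.square(sems))) / R)
        scatter = float(np.sqrt(np.var(means, ddof=1) / R)) if R > 1 else 0.0
        sem = max(pooled, scatter)
        rule = (
            f"per_replica,max-SEM,levels={levels},min_blocks={min_blocks},"
            f"sem={'scatter' if scatter >= pooled else 'pooled'}"
        )
        return LegEstimate(
            leg=leg,
            mean=float(means.mean()),
            sem=sem,
            n_replicas=R,
            n_frames_total=n_total,
            selection_rule=rule,
        )
    raise ValueError(f"unknown mode {mode!r}; expected 'concat' or 'per_replica'")
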