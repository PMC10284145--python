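"""State-conditioned enthalpy estimation and ΔG/ΔH/TΔS bookkeeping.

Energy frames are restricted to the maximal contiguous runs of one loop
state; blocking never crosses a state boundary (concatenating non-contiguous
frames would fabricate spurious decorrelation).  Only the complex leg is
conditioned by default — the apo-receptor state split is below the error of
interest — with an opt-in for receptor conditioning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .direct_enthalpy import EnthalpyEstimate, combine_legs
from .io_formats import EnergySeries, ThermoRecord
from .loop_dynamics import UNASSIGNED, ZA1, ZA2, StateTrace
from .reblocking import LegEstimate, blocked_estimate, estimate_leg


@dataclass(frozen=True)
class ConditionedSeries:
    """Contiguous single-state segments of an energy series."""

    parent: EnergySeries
    segments: tuple[tuple[int, int], ...]  # inclusive (start, stop) frame intervals
    state: str

    def __post_init__(self):
        prev_stop = -1
        for start, stop in self.segments:
            if start <= prev_stop:
                raise ValueError("segments must be ordered and non-overlapping")
            if stop < start:
                raise ValueError("segment stop before start")
            prev_stop = stop

    @property
    def n_frames(self) -> int:
        return sum(stop - start + 1 for start, stop in self.segments)

    def arrays(self) -> list[np.ndarray]:
        return [self.parent.values[start : stop + 1] for start, stop in self.segments]


def condition_series(series: EnergySeries, trace: StateTrace, state: str) -> ConditionedSeries:
    """Maximal contiguous runs of ``state``; UNASSIGNED frames break runs."""
    if len(series) != len(trace):
        raise ValueError(
            f"series ({len(series)} frames) and trace ({len(trace)}) are not frame-aligned"
        )
    segments = []
    start = None
    for i, label in enumerate(trace.labels):
        if label == state:
            if start is None:
                start = i
        else:
            if start is not None:
                segments.append((start, i - 1))
                start = None
    if start is not None:
        segments.append((start, len(trace) - 1))
    return ConditionedSeries(parent=series, segments=tuple(segments), state=state)


def _pooled_segment_estimate(arrays: Sequence[np.ndarray], min_blocks: int) -> tuple[float, float, int]:
    """Length-weighted mean over segments with blocking inside each segment.

    SEM propagates as sqrt(sum (w_i sem_i)^2) / W for weights w_i = len_i.
    """
    lengths = np.array([a.size for a in arrays], dtype=float)
    W = lengths.sum()
    if W == 0:
        raise ValueError("no frames in any segment")
    means = []
    sems = []
    for a in arrays:
        m, s, _ = blocked_estimate(a, min_blocks=min_blocks)
        means.append(m)
        sems.append(s)
    means = np.asarray(means)
    sems = np.asarray(sems)
    mean = float(np.sum(lengths * means) / W)
    sem = float(np.sqrt(np.sum((lengths * sems) ** 2)) / W)
    return mean, sem, int(W)


def state_energy_difference(
    series: EnergySeries, trace: StateTrace, min_blocks: int = 8
) -> tuple[float, float]:
    """ΔE = <E | ZA1> - <E | ZA2> with quadrature SEM.

    Per-state means use segment-wise blocking pooled by segment length.
    """
    per_state = {}
    for state in (ZA1, ZA2):
        cond = condition_series(series, trace, state)
        if cond.n_frames == 0:
            raise ValueError(f"state {state} absent from the trace")
        if cond.n_frames < min_blocks:
            raise ValueError(f"state {state} has fewer than min_blocks={min_blocks} frames")
        per_state[state] = _pooled_segment_estimate(cond.arrays(), min_blocks)
    mean1, sem1, _ = per_state[ZA1]
    mean2, sem2, _ = per_state[ZA2]
    return mean1 - mean2, math.sqrt(sem1**2 + sem2**2)


def _conditioned_leg_estimate(
    replicas: Sequence[EnergySeries],
    traces: Sequence[StateTrace],
    state: str,
    min_blocks: int,
) -> LegEstimate:
    """Per-replica segment-pooled estimates, then replica pooling as in
    estimate_leg (unweighted replica means; max of pooled/scatter SEM)."""
    if len(replicas) != len(traces):
        raise ValueError("one StateTrace per complex replica is required")
    rep_means = []
    rep_sems = []
    n_total = 0
    for series, trace in zip(replicas, traces):
        cond = condition_series(series, trace, state)
        if cond.n_frames == 0:
            continue
        m, s, n = _pooled_segment_estimate(cond.arrays(), min_blocks)
        rep_means.append(m)
        rep_sems.append(s)
        n_total += n
    if not rep_means:
        raise ValueError(f"requested state {state} is empty in every replica")
    means = np.asarray(rep_means)
    R = means.size
    pooled = float(np.sqrt(np.sum(np.square(rep_sems))) / R)
    scatter = float(np.sqrt(np.var(means, ddof=1) / R)) if R > 1 else 0.0
    return LegEstimate(
        leg=replicas[0].leg,
        mean=float(means.mean()),
        sem=max(pooled, scatter),
        n_replicas=R,
        n_frames_total=n_total,
        selection_rule=f"conditioned[{state}],segment-blocking,min_blocks={min_blocks}",
    )


def conditional_enthalpy(
    complex_replicas: Sequence[EnergySeries],
    solvent_replicas: Sequence[EnergySeries],
    receptor_replicas: Sequence[EnergySeries],
    ligand_replicas: Sequence[EnergySeries],
    traces: Sequence[StateTrace],
    condition: str = "all",
    min_blocks: int = 8,
    mode: str = "per_replica",
    system_id: str = "",
    receptor_traces: Sequence[StateTrace] | None = None,
) -> EnthalpyEstimate:
    """Binding enthalpy with the complex leg restricted to one loop state.

    condition="all" is the plain estimate on every frame; "ZA1"/"ZA2"
    restrict the complex leg to that state's contiguous segments;
    "combined" pools all replicas (e.g. runs started in either state) as one
    unconditioned set.  Receptor conditioning is opt-in via receptor_traces.
    """
    if condition in ("all", "combined"):
        complex_est = estimate_leg(complex_replicas, min_blocks=min_blocks, mode=mode)
    elif condition in (ZA1, ZA2):
        complex_est = _conditioned_leg_estimate(complex_replicas, traces, condition, min_blocks)
    else:
        raise ValueError(f"unknown condition {condition!r}")
    if receptor_traces is not None and condition in (ZA1, ZA2):
        receptor_est = _conditioned_leg_estimate(
            receptor_replicas, receptor_traces, condition, min_blocks
        )
    else:
        receptor_est = estimate_leg(receptor_replicas, min_blocks=min_blocks, mode=mode)
    solvent_est = estimate_leg(solvent_replicas, min_blocks=min_blocks, mode=mode)
    ligand_est = estimate_leg(ligand_replicas, min_blocks=min_blocks, mode=mode)
    return combine_legs(
        complex_est, solvent_est, receptor_est, ligand_est,
        condition=condition, system_id=system_id,
    )


def infer_entropy_and_check(
    dH: float,
    dG: float,
    stored_TdS: float | None = None,
    tolerance: float = 0.02,
) -> tuple[float, bool]:
    """TdS = dH - dG; flag (True) when a stored TdS disagrees beyond tolerance.

    The default 0.02 kcal/mol tolerance absorbs two-decimal table rounding.
    """
    computed = dH - dG
    inconsistent = stored_TdS is not None and abs(stored_TdS - computed) > tolerance
    return computed, inconsistent


def check_record(record: ThermoRecord, tolerance: float = 0.02) -> tuple[float, bool]:
    """Entropy consistency of one thermodynamic record."""
    return infer_entropy_and_check(record.dH, record.dG, record.TdS, tolerance)
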