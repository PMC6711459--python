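"""Experimental input matrices.

Each experimental condition occupies one column of the input matrix U,
defined on a microtime grid much finer than the repetition time (by
default 16 bins per TR).  Conditions with positive durations are boxcars
with value one during stimulation; conditions consisting entirely of
zero-duration events carry value 1/dt in each event bin, so that the
integral of the column equals the number of events regardless of the
microtime resolution.  Mean-centring subtracts each column's mean, after
which the average-connectivity matrix A is interpretable as the average
effective connectivity across conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MICROTIME_BINS_PER_TR",
    "ConditionTiming",
    "InputMatrix",
    "build_input_matrix",
    "mean_centre",
]

#: default microtime resolution (bins per TR)
MICROTIME_BINS_PER_TR = 16


@dataclass(frozen=True)
class ConditionTiming:
    """Onsets and durations (seconds) of one experimental condition.

    Onsets are measured from the start of the first volume.  A duration of
    zero marks an event; mixing events and blocks within one condition is
    rejected because the event scaling is defined only for all-event
    conditions.
    """

    name: str
    onsets: tuple
    durations: tuple

    def __post_init__(self):
        onsets = tuple(float(o) for o in self.onsets)
        durations = tuple(float(d) for d in self.durations)
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "durations", durations)
        if len(onsets) != len(durations):
            raise ValueError(f"condition {self.name!r}: onsets and durations "
                             "must have equal length")
        if any(o < 0 for o in onsets):
            raise ValueError(f"condition {self.name!r}: onsets must be non-negative")
        if any(d < 0 for d in durations):
            raise ValueError(f"condition {self.name!r}: durations must be non-negative")
        order = np.argsort(onsets)
        if len(set(onsets)) != len(onsets):
            raise ValueError(f"condition {self.name!r}: duplicate onsets")
        # overlap within the condition is rejected (between conditions it is fine)
        srt_on = [onsets[i] for i in order]
        srt_off = [onsets[i] + durations[i] for i in order]
        for prev_off, nxt_on in zip(srt_off[:-1], srt_on[1:]):
            if nxt_on < prev_off - 1e-12:
                raise ValueError(f"condition {self.name!r}: overlapping intervals")

    @property
    def is_event_condition(self) -> bool:
        return all(d == 0 for d in self.durations)

    def sorted(self) -> "ConditionTiming":
        order = np.argsort(self.onsets)
        return ConditionTiming(self.name,
                               tuple(self.onsets[i] for i in order),
                               tuple(self.durations[i] for i in order))


@dataclass
class InputMatrix:
    """Experimental inputs on the microtime grid: T_U bins x K conditions."""

    values: np.ndarray
    dt: float
    condition_names: list
    centred: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array (bins x conditions)")
        if not np.isfinite(self.values).all():
            raise ValueError("input matrix contains non-finite values")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        self.condition_names = [str(c) for c in self.condition_names]
        if len(self.condition_names) != self.values.shape[1]:
            raise ValueError("one condition name per column is required")
        if self.centred:
            tol = 1e-10 * max(self.values.shape[0], 1)
            if np.abs(self.values.sum(axis=0)).max() > tol:
                raise ValueError("centred flag set but columns do not sum to zero")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_bins * self.dt


def build_input_matrix(timings: list, total_duration: float, dt: float) -> InputMatrix:
    """Build the (uncentred) input matrix U from condition timings.

    Block conditions give boxcar columns of unit height; all-event
    conditions place a value of ``1/dt`` in each event bin, so a column's
    integral equals its event count.  Onsets or offsets beyond
    ``total_duration`` are rejected.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if total_duration <= 0:
        raise ValueError("total_duration must be positive")
    n_bins = int(np.ceil(total_duration / dt - 1e-9))
    values = np.zeros((n_bins, len(timings)))
    names = []
    for k, timing in enumerate(timings):
        if not isinstance(timing, ConditionTiming):
            timing = ConditionTiming(*timing)
        names.append(timing.name)
        durations = timing.durations
        if timing.is_event_condition:
            for onset in timing.onsets:
                if onset > total_duration + 1e-9:
                    raise ValueError(f"condition {timing.name!r}: onset {onset} s "
                                     f"beyond total duration {total_duration} s")
                i = min(int(np.floor(onset / dt + 1e-9)), n_bins - 1)
                values[i, k] += 1.0 / dt
        else:
            if any(d == 0 for d in durations):
                raise ValueError(
                    f"condition {timing.name!r} mixes events (zero duration) and "
                    "blocks; split it into separate conditions")
            for onset, dur in zip(timing.onsets, durations):
                if onset + dur > total_duration + 1e-9:
                    raise ValueError(f"condition {timing.name!r}: interval "
                                     f"[{onset}, {onset + dur}] s exceeds total "
                                     f"duration {total_duration} s")
                i0 = int(np.floor(onset / dt + 1e-9))
                i1 = max(i0 + 1, int(np.floor((onset + dur) / dt + 1e-9)))
                values[i0:min(i1, n_bins), k] = 1.0
    return InputMatrix(values=values, dt=dt, condition_names=names, centred=False)


def mean_centre(U: InputMatrix) -> InputMatrix:
    """Subtract each column's mean; refuses to centre twice.

    Double centring is a no-op numerically, but silently accepting it would
    hide bookkeeping bugs, so an already-centred matrix is rejected.
    """
    if U.centred:
        raise ValueError("input matrix is already mean-centred")
    values = U.values - U.values.mean(axis=0, keepdims=True)
    return InputMatrix(values=values, dt=U.dt,
                       condition_names=list(U.condition_names), centred=True)
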