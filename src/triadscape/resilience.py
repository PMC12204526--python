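"""Resilience metrics on the mature-biomass trajectory.

Three complementary metrics characterise the response of the landscape
mature biomass B_L to a pulse disturbance at the event time (year 100 of a
[0, 200] run on the 10-year grid):

resistance R        closeness of the post-event value A (t = 100) to the
                    pre-event value B (t = 90): 1 = unchanged, 0 = total
                    loss.
net change NC       signed fractional difference between the end value E
                    (t = 200) and B.
rate of recovery RR inverse of the years needed after the event to regain
                    B; floored at 0.01 (= 1/100 years) when the value is
                    not regained within the simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "ResilienceSummary",
    "resistance",
    "net_change",
    "recovery_rate",
    "summarize_run",
]


@dataclass(frozen=True)
class Trajectory:
    """A variable sampled on the 10-year grid with a pulse event."""

    times: np.ndarray
    values: np.ndarray
    event_time: float = 100.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.size == 0:
            raise ValueError("empty trajectory")
        if t.size != v.size:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("trajectory values must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def at(self, time: float) -> float:
        idx = np.flatnonzero(np.isclose(self.times, time))
        if idx.size == 0:
            raise ValueError(f"trajectory has no sample at t={time}")
        return float(self.values[idx[0]])

    @property
    def pre_value(self) -> float:
        return self.at(self.event_time - 10.0)

    @property
    def post_value(self) -> float:
        return self.at(self.event_time)

    @property
    def end_value(self) -> float:
        return float(self.values[-1])


def resistance(before: float, after: float) -> float:
    """Resistance R in [0, 1]: 1 = no change, 0 = total loss.

    Displacement form R = 1 - 2|D| / (C + |D|) with C the pre-event value
    and D = after - before.  (The source formulation's literal reading,
    1 - 2B/(A+B), returns 0 for an unchanged trajectory under either
    assignment of A/B and so cannot satisfy its own stated range; the
    displacement form is the unique reading that does.)  Gains use |D| and
    the result is floored at 0, so a displacement beyond twice the
    pre-event value still counts as maximum change.
    """
    if before <= 0:
        raise ValueError("resistance undefined for a non-positive pre-event value")
    if after < 0:
        raise ValueError("post-event value must be non-negative")
    d = abs(after - before)
    return max(0.0, 1.0 - 2.0 * d / (before + d))


def net_change(before: float, end: float) -> float:
    """Signed fractional change of the end value relative to pre-event."""
    if before <= 0:
        raise ValueError("net change undefined for a non-positive pre-event value")
    return (end - before) / before


def recovery_rate(trajectory: Trajectory) -> float:
    """1 / (years to regain the pre-event value after the event).

    The first sample t > event_time with value >= the pre-event value sets
    the recovery time t - event_time; with the 10-year grid this quantises
    RR to {1/10, 1/20, ..., 1/100}.  If the value is never regained (or
    only at the very end, t - event = 100 years), RR is 0.01.
    """
    pre = trajectory.pre_value
    t0 = trajectory.event_time
    after = trajectory.times > t0
    if not after.any():
        raise ValueError("trajectory does not extend past the event")
    recovered = after & (trajectory.values >= pre)
    if not recovered.any():
        return 0.01
    t_rec = float(trajectory.times[recovered][0])
    return 1.0 / (t_rec - t0)


@dataclass(frozen=True)
class ResilienceSummary:
    R: float
    NC: float
    RR: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.R <= 1.0:
            raise ValueError("R must lie in [0, 1]")
        if not 0.01 <= self.RR <= 0.1:
            raise ValueError("RR must lie in [0.01, 0.1]")


@dataclass(frozen=True)
class RunSeries:
    """Per-step output variables of one simulation run."""

    times: np.ndarray
    B_L: np.ndarray  # mature landscape biomass, Mg
    FD_mean: np.ndarray  # area-weighted mean stand FD
    B_FG: np.ndarray  # (n_times, n_groups), all-age group biomass, Mg


def summarize_run(series: RunSeries, event_time: float = 100.0) -> tuple[
    ResilienceSummary, pd.DataFrame
]:
    """Resilience metrics of the B_L trajectory plus long-format variables.

    Returns (summary, variables) where variables holds one row per
    (time, variable): B_L, FD_mean and one B_FG_<g> column per group.
    """
    traj = Trajectory(series.times, series.B_L, event_time=event_time)
    summary = ResilienceSummary(
        R=resistance(traj.pre_value, traj.post_value),
        NC=net_change(traj.pre_value, traj.end_value),
        RR=recovery_rate(traj),
    )
    frames = [
        pd.DataFrame({"time": series.times, "variable": "B_L", "value": series.B_L}),
        pd.DataFrame(
            {"time": series.times, "variable": "FD_mean", "value": series.FD_mean}
        ),
    ]
    for g in range(series.B_FG.shape[1]):
        frames.append(
            pd.DataFrame(
                {
                    "time": series.times,
                    "variable": f"B_FG_{g + 1}",
                    "value": series.B_FG[:, g],
                }
            )
        )
    return summary, pd.concat(frames, ignore_index=True)
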