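"""Random-walk locomotion paths from a behavior strip.

The locomotion cycle is forward run -> reversal -> turn -> resumed forward
run.  Forward intervals advance along the current heading at 0.15 mm/s;
reversals retrace at 0.075 mm/s along the reversed heading; pauses are
stationary.  When forward motion resumes immediately after a reversal a turn
is drawn: regular with probability 0.65 (angle uniform on -90..90 degrees)
or omega with probability 0.35 (a deep reorientation, magnitude uniform on
90..270 degrees with a random left/right sign).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .behavior import BehaviorSequence

__all__ = ["PathRealization", "TurnEvent", "simulate_path",
           "FORWARD_SPEED_MM_S", "REVERSAL_SPEED_MM_S", "P_OMEGA"]

FORWARD_SPEED_MM_S = 0.15
REVERSAL_SPEED_MM_S = 0.075
P_OMEGA = 0.35
REGULAR_RANGE_DEG = (-90.0, 90.0)
OMEGA_RANGE_DEG = (90.0, 270.0)


@dataclass(frozen=True)
class TurnEvent:
    time: float          # minutes, at the resumption of forward motion
    angle_deg: float     # signed heading change
    kind: str            # "regular" | "omega"


@dataclass
class PathRealization:
    """One 2-D agar-plate path realization.

    ``times`` (minutes) and ``vertices`` (mm, shape (n+1, 2)) give the worm's
    position at every behavior-interval boundary; ``states`` holds the
    interval state between consecutive vertices.
    """

    times: np.ndarray
    vertices: np.ndarray
    states: tuple[str, ...]
    headings_deg: np.ndarray
    turn_events: tuple[TurnEvent, ...]
    seed: int

    @property
    def path_length(self) -> float:
        """Total distance traveled in mm (forward + retraced reversal)."""
        return float(np.sum(np.linalg.norm(np.diff(self.vertices, axis=0),
                                           axis=1)))


def simulate_path(seq: BehaviorSequence, seed: int = 0,
                  forward_speed: float = FORWARD_SPEED_MM_S,
                  reversal_speed: float = REVERSAL_SPEED_MM_S,
                  p_omega: float = P_OMEGA,
                  regular_range: tuple[float, float] = REGULAR_RANGE_DEG,
                  omega_range: tuple[float, float] = OMEGA_RANGE_DEG,
                  initial_heading_deg: float = 0.0,
                  initial_position=(0.0, 0.0)) -> PathRealization:
    """Simulate one locomotion path realization from a behavior strip.

    Speeds are in mm/s; interval durations come from the strip (minutes).
    The same seed reproduces the same path exactly.
    """
    if seq.dt <= 0:
        raise ValueError("behavior sequence must span a positive duration")
    rng = np.random.default_rng(seed)
    intervals = seq.intervals()
    pos = np.asarray(initial_position, dtype=float)
    heading = float(initial_heading_deg)
    times = [intervals[0][1]]
    verts = [pos.copy()]
    states = []
    headings = []
    turns: list[TurnEvent] = []
    prev_state: str | None = None
    for state, t_start, t_end in intervals:
        dur_s = (t_end - t_start) * 60.0
        if state == "F" and prev_state == "R":
            # resumption of forward motion after a reversal: draw a turn
            if rng.random() < p_omega:
                mag = rng.uniform(*omega_range)
                angle = mag if rng.random() < 0.5 else -mag
                kind = "omega"
            else:
                angle = rng.uniform(*regular_range)
                kind = "regular"
            heading += angle
            turns.append(TurnEvent(time=t_start, angle_deg=angle, kind=kind))
        u = np.array([np.cos(np.deg2rad(heading)), np.sin(np.deg2rad(heading))])
        if state == "F":
            pos = pos + forward_speed * dur_s * u
        elif state == "R":
            pos = pos - reversal_speed * dur_s * u
        times.append(t_end)
        verts.append(pos.copy())
        states.append(state)
        headings.append(heading)
        prev_state = state
    return PathRealization(times=np.asarray(times),
                           vertices=np.asarray(verts),
                           states=tuple(states),
                           headings_deg=np.asarray(headings),
                           turn_events=tuple(turns), seed=seed)
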