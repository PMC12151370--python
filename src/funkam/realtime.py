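"""Frame-by-frame streaming pipeline (IK -> EMA -> differences -> ID).

Each incoming frame is solved by one warm-started IK step, the coordinates
are smoothed with a causal exponential moving average (alpha = 0.1525),
velocities and accelerations come from first/second backward differences of
the filtered coordinates, and one Newton-Euler evaluation produces the joint
moments.  Step times are measured against the robot-control deadline of
8 ms through an injectable clock, so replay tests are deterministic and
wall-clock performance is reported but never asserted.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field

import numpy as np

from .dynamics import (
    G,
    AppliedWrench,
    WrenchSeries,
    newton_euler_id,
)
from .errors import ValidationError
from .ik import default_marker_weights, solve_ik_frame
from .markers import MarkerTrajectorySet
from .model import Anthropometry, Model
from .signals import DEFAULT_EMA_ALPHA, EmaState

__all__ = ["RTFrame", "RTSessionStats", "RTState", "rt_step", "rt_session", "replay_trial"]

DEADLINE_S = 0.008


@dataclass
class RTFrame:
    timestamp: float
    q: np.ndarray
    eam: float  # %BWHt
    moments: dict  # joint -> lab 3-vector (N·m)
    fit_rms: float
    step_time: float
    overran: bool
    held: bool = False  # True when IK failed and the previous output was held


@dataclass
class RTSessionStats:
    frames: int
    mean_step_time: float
    sd_step_time: float
    max_step_time: float
    overrun_count: int
    overrun_percent: float

    @staticmethod
    def from_frames(frames: list[RTFrame]) -> "RTSessionStats":
        if not frames:
            raise ValidationError("empty real-time session")
        st = np.array([f.step_time for f in frames])
        n_over = int(sum(f.overran for f in frames))
        return RTSessionStats(
            frames=len(frames),
            mean_step_time=float(st.mean()),
            sd_step_time=float(st.std()),
            max_step_time=float(st.max()),
            overrun_count=n_over,
            overrun_percent=100.0 * n_over / len(frames),
        )


class RTState:
    """Mutable streaming state: model, filter, coordinate history, clock."""

    def __init__(
        self,
        model: Model,
        anthro: Anthropometry,
        rate: float,
        labels: list[str] | None = None,
        weights: np.ndarray | None = None,
        alpha: float = DEFAULT_EMA_ALPHA,
        deadline: float = DEADLINE_S,
        clock=None,
        contact_segment: str = "calcaneus",
    ):
        self.model = model
        self.anthro = anthro
        self.rate = rate
        self.labels = labels
        self.weights = weights
        self.ema = EmaState(alpha)
        self.deadline = deadline
        self.clock = clock if clock is not None else _time.perf_counter
        self.contact_segment = contact_segment
        self.q_prev: np.ndarray | None = None
        self.y_hist: list[np.ndarray] = []  # filtered q history (last 3)
        self.last_frame: RTFrame | None = None
        self.i_add = model.coord_index["knee_adduction"]

    def norm_factor(self) -> float:
        return 100.0 / (self.anthro.mass * G * self.anthro.height)


def rt_step(
    state: RTState,
    timestamp: float,
    labels: list[str],
    positions: np.ndarray,
    wrench: AppliedWrench | None,
) -> RTFrame:
    """Process one frame; on IK failure the previous output is held."""
    t0 = state.clock()
    if state.weights is None:
        w = default_marker_weights(labels)
    else:
        w = state.weights
    try:
        q, rms, ok = solve_ik_frame(
            state.model, labels, positions, w, state.q_prev, check_observability=False
        )
    except Exception:  # degenerate frame: hold the previous coordinates
        ok = False
        rms = float("nan")
        q = (
            state.q_prev.copy()
            if state.q_prev is not None
            else np.zeros(state.model.n_coordinates)
        )
    state.q_prev = q

    y = state.ema.step(q)
    state.y_hist.append(y)
    if len(state.y_hist) > 3:
        state.y_hist.pop(0)
    h = state.y_hist
    r = state.rate
    if len(h) >= 2:
        qd = (h[-1] - h[-2]) * r
    else:
        qd = np.zeros_like(y)
    if len(h) >= 3:
        qdd = (h[-1] - 2 * h[-2] + h[-3]) * r * r
    else:
        qdd = np.zeros_like(y)

    ext = [wrench] if wrench is not None else None
    res = newton_euler_id(state.model, y, qd, qdd, ext)
    eam = res.external_generalized[state.i_add] * state.norm_factor()
    step_time = state.clock() - t0
    frame = RTFrame(
        timestamp=timestamp,
        q=y,
        eam=float(eam),
        moments={k: v for k, v in res.joint_moment.items()},
        fit_rms=float(rms),
        step_time=step_time,
        overran=step_time > state.deadline,
        held=not ok,
    )
    state.last_frame = frame
    return frame


def rt_session(state: RTState, stream) -> tuple[RTSessionStats, list[RTFrame]]:
    """Consume an iterable of ``(timestamp, labels, positions, wrench)``."""
    frames = [rt_step(state, ts, lab, pos, wr) for ts, lab, pos, wr in stream]
    return RTSessionStats.from_frames(frames), frames


def replay_trial(
    state: RTState,
    trial: MarkerTrajectorySet,
    wrench: WrenchSeries | None,
    contact_segment: str = "calcaneus",
) -> tuple[RTSessionStats, list[RTFrame]]:
    """Replay a recorded trial through the streaming pipeline."""

    def stream():
        for f in range(trial.n_frames):
            vis = ~trial.occluded[f]
            labels = [l for l, v in zip(trial.labels, vis) if v]
            pos = trial.positions[f][vis]
            wr = None
            if wrench is not None:
                s = wrench.sample(trial.times[f])
                wr = AppliedWrench(contact_segment, s.force, s.moment, s.point)
            yield trial.times[f], labels, pos, wr

    return rt_session(state, stream())
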