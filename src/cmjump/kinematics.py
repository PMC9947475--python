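"""Jump event detection, velocity/power integration and take-off-velocity height.

The same routines serve smartphone and force-platform traces.  The phase
structure of a countermovement jump on a gravity-free vertical acceleration
trace is: static ≈ 0 → unweighting dip (a < 0) → braking/propulsion hump
(a > 0) → release to free fall → flight at −g.  Detected instants:

* ``t0``    movement onset: 30 ms before the first sample deviating from the
            static phase by more than 8 standard deviations.
* ``tUB``   unweighting→braking transition, coincides with the velocity
            minimum ``tv_min``.
* ``tBP``   braking→propulsion transition: first upward zero crossing of the
            velocity after ``tv_min``.
* ``tTO``   take-off: first sample with a ≤ −g.  The search starts at the
            propulsive acceleration peak so that a deep unweighting dip on a
            noisy handheld trace cannot trigger it early.

Velocity is the cumulative trapezoidal integral of a on [t0, tTO] with
v(t0) = 0; mass-normalized power is P = (a + g)·v (W/kg); jump height follows
from the take-off velocity as h = v_TO² / (2 g).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import MalformedJumpError, NoFlightError, NoJumpError
from .io import G, AccelTrace

ONSET_BACKTRACK_S = 0.030  # onset precedes the threshold crossing by 30 ms
ONSET_SIGMA_FACTOR = 8.0


@dataclass
class JumpEvents:
    """Characteristic time instants of one jump, in seconds."""

    t0: float
    t_ub: float
    t_bp: float
    t_to: float
    t_a_min: float
    t_a_max: float
    t_v_min: float
    t_p_min: float
    t_p_max: float

    def ordering_violations(self) -> list[str]:
        """Phase-structure checks; empty list when the jump is well formed."""
        out = []
        if not self.t0 <= self.t_ub:
            out.append("t0 > tUB")
        if self.t_ub != self.t_v_min:
            out.append("tUB != tv_min")
        if not self.t_ub <= self.t_bp:
            out.append("tUB > tBP")
        if not self.t_bp < self.t_to:
            out.append("tBP >= tTO")
        if not self.t_a_min < self.t_a_max <= self.t_to:
            out.append("acceleration extrema out of order")
        return out

    def as_dict(self) -> dict[str, float]:
        return {
            "t0": self.t0,
            "tUB": self.t_ub,
            "tBP": self.t_bp,
            "tTO": self.t_to,
            "ta_min": self.t_a_min,
            "ta_max": self.t_a_max,
            "tv_min": self.t_v_min,
            "tP_min": self.t_p_min,
            "tP_max": self.t_p_max,
        }


@dataclass
class KinematicSeries:
    """Velocity and mass-normalized power on the [t0, tTO] grid of the trace."""

    t: np.ndarray
    v: np.ndarray
    p: np.ndarray


@dataclass
class JumpMeasurement:
    """Full single-jump analysis result."""

    events: JumpEvents
    kin: KinematicSeries
    v_to: float
    height: float


def detect_onset(trace: AccelTrace, static_window: tuple[float, float]) -> float:
    """Movement onset t0 from the 8-sigma deviation rule, backtracked 30 ms."""
    win = trace.window(*static_window)
    sigma = float(np.std(trace.a[win]))
    thr = ONSET_SIGMA_FACTOR * sigma
    start = win.stop
    dev = np.flatnonzero(np.abs(trace.a[start:]) > thr)
    if dev.size == 0:
        raise NoJumpError(
            f"no sample beyond {ONSET_SIGMA_FACTOR}·sigma = {thr:.3f} m/s² after the static window"
        )
    i_dev = start + int(dev[0])
    i0 = max(0, i_dev - int(round(ONSET_BACKTRACK_S * trace.fs)))
    return float(trace.t[i0])


def detect_takeoff(trace: AccelTrace, search_from: float) -> float:
    """Take-off: first sample at/after ``search_from`` with a ≤ −g."""
    i_start = int(np.searchsorted(trace.t, search_from, side="left"))
    below = np.flatnonzero(trace.a[i_start:] <= -G)
    if below.size == 0:
        raise NoFlightError("no sample with a <= -g: no flight phase found")
    return float(trace.t[i_start + int(below[0])])


def integrate_velocity(trace: AccelTrace, t0: float, t_to: float) -> KinematicSeries:
    """Cumulative trapezoidal velocity on [t0, tTO], v(t0) = 0 (power unset)."""
    if not t0 < t_to:
        raise ValueError(f"t0={t0} must precede tTO={t_to}")
    seg = trace.window(t0, t_to)
    t = trace.t[seg]
    v = cumulative_trapezoid(trace.a[seg], t, initial=0.0)
    return KinematicSeries(t=t, v=v, p=np.full_like(v, np.nan))


def compute_power(trace: AccelTrace, kin: KinematicSeries) -> KinematicSeries:
    """Mass-normalized mechanical power P = (a + g)·v in W/kg on the same grid."""
    seg = trace.window(kin.t[0], kin.t[-1])
    a = trace.a[seg]
    if a.shape != kin.v.shape:
        raise ValueError("velocity series does not match the trace grid")
    kin.p = (a + G) * kin.v
    return kin


def detect_phase_events(
    trace: AccelTrace, kin: KinematicSeries, t0: float, t_to: float
) -> JumpEvents:
    """Locate all phase events on [t0, tTO]; argmin/argmax ties -> earliest index."""
    seg = trace.window(t0, t_to)
    a = trace.a[seg]
    t = trace.t[seg]
    # the propulsive peak is the global maximum; the countermovement minimum
    # must precede it — the take-off sample itself has a <= -g and would
    # otherwise always win the global argmin
    i_a_max = int(np.argmax(a))
    i_a_min = int(np.argmin(a[: i_a_max + 1])) if i_a_max > 0 else 0
    i_v_min = int(np.argmin(kin.v))
    after = np.flatnonzero(kin.v[i_v_min:] > 0)
    if after.size == 0:
        raise MalformedJumpError("velocity never becomes positive after its minimum")
    i_bp = i_v_min + int(after[0])
    i_p_min = int(np.argmin(kin.p))
    i_p_max = int(np.argmax(kin.p))
    return JumpEvents(
        t0=float(t[0]),
        t_ub=float(t[i_v_min]),
        t_bp=float(t[i_bp]),
        t_to=float(t[-1]),
        t_a_min=float(t[i_a_min]),
        t_a_max=float(t[i_a_max]),
        t_v_min=float(t[i_v_min]),
        t_p_min=float(t[i_p_min]),
        t_p_max=float(t[i_p_max]),
    )


def tov_height(v_to: float, g: float = G) -> float:
    """Take-off-velocity jump height h = v_TO²/(2g), metres."""
    return float(v_to) ** 2 / (2.0 * g)


def measure_jump(
    trace: AccelTrace,
    static_window: tuple[float, float],
    subsample_takeoff: bool = True,
) -> JumpMeasurement:
    """Run the full single-trace analysis chain.

    Onset and a provisional a ≤ −g crossing bracket the movement; the
    take-off search is then restarted from the propulsive acceleration peak
    inside that bracket, which is a no-op on clean traces but prevents a deep
    unweighting dip from being mistaken for flight on corrupted ones.

    With ``subsample_takeoff`` the take-off velocity is corrected for the
    sampling-grid bias of the a ≤ −g rule: the true −g crossing lies
    somewhere inside the sample interval preceding the detected take-off
    sample, so the integral to that sample contains on average half a sample
    of free fall.  Placing the crossing at the interval midpoint adds
    g·Δt/2 back to v_TO, halving the worst-case error at low sampling rates
    (events themselves stay sample-aligned).
    """
    t0 = detect_onset(trace, static_window)
    t_cross = detect_takeoff(trace, search_from=t0)
    seg = trace.window(t0, t_cross)
    i_a_max = seg.start + int(np.argmax(trace.a[seg]))
    t_to = detect_takeoff(trace, search_from=float(trace.t[i_a_max]))
    kin = integrate_velocity(trace, t0, t_to)
    kin = compute_power(trace, kin)
    events = detect_phase_events(trace, kin, t0, t_to)
    v_to = float(kin.v[-1])
    if subsample_takeoff:
        v_to += G / (2.0 * trace.fs)
    return JumpMeasurement(events=events, kin=kin, v_to=v_to, height=tov_height(v_to))
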