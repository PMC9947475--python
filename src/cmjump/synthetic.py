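"""Synthetic paired force-platform / smartphone countermovement-jump traces.

The generator builds a ground-truth vertical acceleration profile of a CMJ
from smooth half-wave segments — static phase at 0, unweighting dip to a
negative minimum ``b``, braking/propulsion hump to a positive peak ``e``, a
short release ramp down to −g, ballistic flight at −g, and a landing
transient — with the net ground-phase impulse constrained by construction to
the take-off velocity √(2·g·h_true), so every jump has an exact known height.

The force-platform (FP) trace samples this profile cleanly at 1000 samples/s.
The smartphone (SP) trace samples it at 128 samples/s and is corrupted by the
artifact structure a handheld sensor suffers:

* an amplitude-distortion gain < 1 on the ground-contact portion (the hand
  renders an attenuated copy of the center-of-mass acceleration; during
  flight the phone is itself in free fall and reads −g regardless);
* damped-sinusoid soft-tissue / arm wobble starting at movement onset,
  default frequencies near 6 and 3.5 Hz so the decomposition features are
  informative;
* white sensor noise and quantization to the ±8 g, 16-bit grid.

Dataset generation draws heights from a truncated normal, 25.6 ± 7.4 cm on
[0.10, 0.41] m, and couples the SP gain linearly to the true height — higher
jumps are attenuated more — which makes the raw SP height error grow with
jump height (the heteroscedastic, negatively biased behavior the learning
stage must compensate).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConstraintError
from .io import G, AccelTrace, RawForceRecord, RawImuRecord, write_fp_csv, write_imu_csv
from .kinematics import JumpEvents

SP_FS = 128.0
FP_FS = 1000.0
QUANT_STEP = 16.0 * G / 2 ** 16  # ±8 g full scale on a 16-bit grid


@dataclass
class JumpSpec:
    """Ground-truth parameters of one simulated jump."""

    h_true: float = 0.25  # m
    m_body: float = 67.5  # kg
    t_static: float = 1.5  # s of initial quiet standing
    dip_duration: float = 0.35  # unweighting half-wave, s
    push_duration: float = 0.30  # braking+propulsion half-wave, s
    release_duration: float = 0.04  # ramp from 0 down to -g, s
    dip_depth: float = -6.0  # minimum acceleration target b, m/s²
    landing_duration: float = 0.12  # landing half-sine, s
    tail: float = 1.0  # quiet standing after landing, s
    wobble: tuple = ((6.0, 1.2, 3.0), (3.5, 0.8, 2.0))  # (freq Hz, amp m/s², damping 1/s)
    sp_gain: float = 0.85  # ground-phase amplitude distortion
    noise_sd: float = 0.15  # SP white noise, m/s²
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.05 <= self.h_true <= 0.50:
            raise ConstraintError(f"h_true={self.h_true} outside [0.05, 0.50] m")
        for name in ("dip_duration", "push_duration", "release_duration", "landing_duration"):
            if getattr(self, name) <= 0:
                raise ConstraintError(f"{name} must be positive")
        if not -9.0 < self.dip_depth < 0.0:
            raise ConstraintError(
                f"dip_depth={self.dip_depth} m/s²: the unweighting dip must stay in (-9, 0)"
            )
        if not 0.5 <= self.sp_gain <= 1.0:
            raise ConstraintError(f"sp_gain={self.sp_gain} outside [0.5, 1.0]")
        if self.m_body <= 0:
            raise ConstraintError("m_body must be positive")

    # --- derived ground-truth quantities -----------------------------------

    @property
    def v_to(self) -> float:
        """Take-off velocity implied by the height, m/s."""
        return float(np.sqrt(2.0 * G * self.h_true))

    @property
    def flight_time(self) -> float:
        return 2.0 * self.v_to / G

    @property
    def v_min(self) -> float:
        """Velocity at the end of the unweighting dip (negative)."""
        return 2.0 * self.dip_depth * self.dip_duration / np.pi

    @property
    def push_peak(self) -> float:
        """Positive acceleration peak e making the net impulse equal v_to."""
        return (
            np.pi
            * (self.v_to - self.v_min + 2.0 * G * self.release_duration / np.pi)
            / (2.0 * self.push_duration)
        )


@dataclass
class JumpPair:
    """One simulated jump: clean FP trace, corrupted SP trace, and the truth."""

    fp: AccelTrace
    sp: AccelTrace
    spec: JumpSpec
    truth: JumpEvents

    @property
    def static_window(self) -> tuple[float, float]:
        """Safe quiet-standing interval for onset statistics and tilt correction."""
        return (0.1, self.spec.t_static - 0.1)


def _ground_profile(t: np.ndarray, spec: JumpSpec) -> np.ndarray:
    """Noise-free center-of-mass vertical acceleration (gravity removed)."""
    ts = spec.t_static
    d1, d2, dr = spec.dip_duration, spec.push_duration, spec.release_duration
    e = spec.push_peak
    t_to = ts + d1 + d2 + dr
    t_land = t_to + spec.flight_time
    d_land = spec.landing_duration
    land_peak = np.pi * spec.v_to / (2.0 * d_land)

    a = np.zeros_like(t)
    m = (t >= ts) & (t < ts + d1)
    a[m] = spec.dip_depth * np.sin(np.pi * (t[m] - ts) / d1)
    m = (t >= ts + d1) & (t < ts + d1 + d2)
    a[m] = e * np.sin(np.pi * (t[m] - ts - d1) / d2)
    m = (t >= ts + d1 + d2) & (t < t_to)
    a[m] = -G * np.sin(np.pi * (t[m] - ts - d1 - d2) / (2.0 * dr))
    m = (t >= t_to) & (t < t_land)
    a[m] = -G
    m = (t >= t_land) & (t < t_land + d_land)
    a[m] = land_peak * np.sin(np.pi * (t[m] - t_land) / d_land)
    return a


def _truth_events(spec: JumpSpec) -> JumpEvents:
    """Analytic event times of the noise-free profile (detection convention)."""
    ts = spec.t_static
    d1, d2 = spec.dip_duration, spec.push_duration
    e = spec.push_peak
    t_to = ts + d1 + d2 + spec.release_duration
    # braking -> propulsion: upward zero crossing of v inside the push hump
    c = 1.0 + spec.v_min * np.pi / (e * d2)
    tau = (d2 / np.pi) * np.arccos(np.clip(c, -1.0, 1.0))
    t_bp = ts + d1 + tau

    # power extrema located numerically on a fine grid of the ground phase
    tg = np.arange(ts - 0.05, t_to + 1e-9, 1e-4)
    ag = _ground_profile(tg, spec)
    vg = np.concatenate([[0.0], np.cumsum((ag[1:] + ag[:-1]) / 2.0) * 1e-4])
    pg = (ag + G) * vg
    t_p_min = float(tg[np.argmin(pg)])
    t_p_max = float(tg[np.argmax(pg)])

    return JumpEvents(
        t0=ts - 0.030,
        t_ub=ts + d1,
        t_bp=float(t_bp),
        t_to=float(t_to),
        t_a_min=ts + d1 / 2.0,
        t_a_max=ts + d1 + d2 / 2.0,
        t_v_min=ts + d1,
        t_p_min=t_p_min,
        t_p_max=t_p_max,
    )


def quantize(a: np.ndarray, step: float = QUANT_STEP, full_scale: float = 8.0 * G) -> np.ndarray:
    """Round to the ADC grid and clip to the stated ±8 g full scale."""
    return np.clip(np.round(a / step) * step, -full_scale, full_scale)


def simulate_jump(spec: JumpSpec) -> JumpPair:
    """Simulate one paired FP/SP recording from a :class:`JumpSpec`."""
    total = (
        spec.t_static
        + spec.dip_duration
        + spec.push_duration
        + spec.release_duration
        + spec.flight_time
        + spec.landing_duration
        + spec.tail
    )
    rng = np.random.default_rng(spec.seed)

    t_fp = np.arange(0.0, total, 1.0 / FP_FS)
    fp = AccelTrace(t=t_fp, a=_ground_profile(t_fp, spec), fs=FP_FS, source="FP")

    t_sp = np.arange(0.0, total, 1.0 / SP_FS)
    ts = spec.t_static
    t_lift = ts + spec.dip_duration + spec.push_duration + spec.release_duration
    t_land = t_lift + spec.flight_time
    a_sp = _ground_profile(t_sp, spec) * spec.sp_gain
    in_flight = (t_sp >= t_lift) & (t_sp < t_land)
    a_sp[in_flight] = -G  # free fall is rendered faithfully, not attenuated
    after = t_sp >= ts
    rel = t_sp[after] - ts
    for freq, amp, damping in spec.wobble:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        jitter = rng.uniform(0.7, 1.3)
        a_sp[after] += amp * jitter * np.exp(-damping * rel) * np.sin(
            2.0 * np.pi * freq * rel + phase
        )
    if spec.noise_sd > 0:
        a_sp += rng.normal(0.0, spec.noise_sd, size=a_sp.size)
    sp = AccelTrace(t=t_sp, a=quantize(a_sp), fs=SP_FS, source="SP")

    return JumpPair(fp=fp, sp=sp, spec=spec, truth=_truth_events(spec))


@dataclass
class DatasetConfig:
    """Population distribution from which jump specs are drawn."""

    h_mean: float = 0.256  # m
    h_sd: float = 0.074  # m
    h_range: tuple[float, float] = (0.10, 0.41)
    m_mean: float = 67.5  # kg
    m_sd: float = 10.9
    dip_mean: float = -6.0  # m/s²
    dip_sd: float = 0.5
    dip_duration_mean: float = 0.35  # s
    dip_duration_sd: float = 0.03
    push_duration_mean: float = 0.30  # s
    push_duration_sd: float = 0.02
    gain_base: float = 0.90
    gain_height_slope: float = 0.50  # gain = gain_base - slope * h_true
    noise_sd: float = 0.15  # m/s²
    wobble: tuple = ((6.0, 1.2, 3.0), (3.5, 0.8, 2.0))


def _truncated_normal(rng, mean, sd, lo, hi):
    while True:
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)


def simulate_dataset(
    n: int, config: DatasetConfig | None = None, seed: int = 0
) -> list[JumpPair]:
    """Draw ``n`` jump specs from the population and simulate each pair."""
    if n < 8:
        raise ConstraintError("a dataset needs at least 8 jumps")
    cfg = config or DatasetConfig()
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n):
        h = _truncated_normal(rng, cfg.h_mean, cfg.h_sd, *cfg.h_range)
        gain = float(np.clip(cfg.gain_base - cfg.gain_height_slope * h, 0.5, 1.0))
        spec = JumpSpec(
            h_true=h,
            m_body=_truncated_normal(rng, cfg.m_mean, cfg.m_sd, 40.0, 120.0),
            dip_depth=_truncated_normal(rng, cfg.dip_mean, cfg.dip_sd, -8.5, -2.0),
            dip_duration=_truncated_normal(
                rng, cfg.dip_duration_mean, cfg.dip_duration_sd, 0.2, 0.6
            ),
            push_duration=_truncated_normal(
                rng, cfg.push_duration_mean, cfg.push_duration_sd, 0.2, 0.5
            ),
            sp_gain=gain,
            noise_sd=cfg.noise_sd,
            wobble=cfg.wobble,
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        )
        pairs.append(simulate_jump(spec))
    return pairs


def write_dataset(pairs: list[JumpPair], outdir) -> Path:
    """Write SP/FP CSVs in the default dialects plus a ground-truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth_rows = []
    for j, pair in enumerate(pairs):
        sp, fp, spec = pair.sp, pair.fp, pair.spec
        imu = RawImuRecord(
            t=sp.t,
            acc=np.column_stack([np.zeros_like(sp.a), np.zeros_like(sp.a), sp.a + G]),
            gyro=np.zeros((sp.a.size, 3)),
            fs=sp.fs,
        )
        write_imu_csv(imu, outdir / f"sp_{j:04d}.csv")
        force = RawForceRecord(t=fp.t, fz=spec.m_body * (fp.a + G), fs=fp.fs)
        write_fp_csv(force, outdir / f"fp_{j:04d}.csv")
        truth_rows.append(
            {"jump_id": j, "h_true_m": spec.h_true, "m_body_kg": spec.m_body,
             "sp_gain": spec.sp_gain, **pair.truth.as_dict()}
        )
    pd.DataFrame(truth_rows).to_csv(outdir / "truth.csv", index=False)
    return outdir
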