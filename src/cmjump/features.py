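"""The 26-descriptor feature set of one countermovement jump.

All features are computed from the handheld-sensor vertical acceleration on
the ground-contact interval [t0, tTO], its integrated velocity and
mass-normalized power, and a K = 3 variational mode decomposition of the same
segment.  Naming convention: capital letters are time durations (s), small
letters are amplitudes/ratios, ``f1 > f2 > f3`` are the VMD central
frequencies (Hz).  ``hSP`` is the raw take-off-velocity height of the
handheld trace itself.

========  =========================================================  =======
name      definition                                                 unit
========  =========================================================  =======
hSP       take-off-velocity height from the handheld trace           m
A         unweighting phase duration [t0, tUB]                       s
b         minimum acceleration a(ta_min)                             m/s²
C         time from minimum to maximum acceleration [ta_min,ta_max]  s
D         main positive impulse time: first a>0 sample after tUB     s
          to the last a>0 sample before tTO
e         maximum acceleration a(ta_max)                             m/s²
F         time from acceleration peak to take-off [ta_max, tTO]      s
G         ground contact duration [t0, tTO]                          s
H         time from minimum acceleration to end of braking           s
i         maximum positive slope of a on [ta_min, ta_max]            m/s³
k         acceleration at the end of the braking phase a(tBP)        m/s²
J         braking phase duration [tv_min, tBP]                       s
l         negative peak power P(tP_min)                              W/kg
M         positive power duration                                    s
n         positive peak power P(tP_max)                              W/kg
O         time from positive peak power to take-off [tP_max, tTO]    s
p         mean slope between acceleration peaks (e − b)/C            –
q         shape factor: area under a over the D window / (D·e)       –
r         impulse ratio b/e                                          –
s         minimum negative velocity v(tv_min)                        m/s
u         mean concentric power, mean of P on [tBP, tTO]             W/kg
W         power peaks delta time [tP_min, tP_max]                    s
z         mean eccentric power, mean of P on [t0, tBP]               W/kg
f1,f2,f3  VMD central frequencies, descending                        Hz
========  =========================================================  =======
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import FeatureUndefinedError
from .io import AccelTrace
from .kinematics import JumpEvents, JumpMeasurement, KinematicSeries, measure_jump, tov_height
from .vmd import VmdParams, central_frequencies, vmd_decompose

#: canonical feature order (case-sensitive, preserved in all file outputs)
FEATURE_NAMES: tuple[str, ...] = (
    "hSP", "A", "b", "C", "D", "e", "F", "G", "H", "i", "k", "J", "l",
    "M", "n", "O", "p", "q", "r", "s", "u", "W", "z", "f1", "f2", "f3",
)

N_FEATURES = len(FEATURE_NAMES)  # 26


def _trapz_mean(t: np.ndarray, y: np.ndarray) -> float:
    """Trapezoidal time average of y(t); falls back to y[0] on a single sample."""
    if t[-1] == t[0]:
        return float(y[0])
    return float(np.trapezoid(y, t) / (t[-1] - t[0]))


def extract_features(
    trace: AccelTrace,
    events: JumpEvents,
    kin: KinematicSeries,
    vmd_freqs: tuple[float, float, float],
) -> dict[str, float]:
    """Compute the 26 named descriptors from one analyzed jump.

    ``kin`` must hold velocity and power on [t0, tTO]; ``vmd_freqs`` are the
    descending central frequencies of the 3-mode decomposition of the same
    segment.  Raises :class:`FeatureUndefinedError` naming the feature when a
    defining window is empty.
    """
    seg = trace.window(events.t0, events.t_to)
    a = trace.a[seg]
    t = trace.t[seg]
    if a.shape != kin.v.shape:
        raise ValueError("kinematic series not on the [t0, tTO] grid of the trace")
    dt = 1.0 / trace.fs

    idx = {name: int(np.argmin(np.abs(t - when))) for name, when in (
        ("ub", events.t_ub), ("bp", events.t_bp),
        ("amin", events.t_a_min), ("amax", events.t_a_max),
        ("vmin", events.t_v_min), ("pmin", events.t_p_min), ("pmax", events.t_p_max),
    )}

    f: dict[str, float] = {}
    f["hSP"] = tov_height(float(kin.v[-1]))
    f["A"] = events.t_ub - events.t0
    f["b"] = float(a[idx["amin"]])
    f["C"] = events.t_a_max - events.t_a_min
    f["e"] = float(a[idx["amax"]])
    f["F"] = events.t_to - events.t_a_max
    f["G"] = events.t_to - events.t0
    f["H"] = events.t_bp - events.t_a_min
    f["J"] = events.t_bp - events.t_v_min
    f["k"] = float(a[idx["bp"]])

    # D window: first positive-a sample after tUB to the last one before tTO
    pos = np.flatnonzero(a[idx["ub"]:] > 0)
    if pos.size == 0:
        raise FeatureUndefinedError("D", "no positive acceleration after tUB")
    i_d0 = idx["ub"] + int(pos[0])
    i_d1 = idx["ub"] + int(pos[-1])
    if i_d1 <= i_d0:
        raise FeatureUndefinedError("D", "positive-acceleration window is a single sample")
    f["D"] = float(t[i_d1] - t[i_d0])

    if f["C"] <= 0:
        raise FeatureUndefinedError("p", "acceleration extrema coincide")
    f["p"] = (f["e"] - f["b"]) / f["C"]
    if f["e"] == 0:
        raise FeatureUndefinedError("r", "zero maximum acceleration")
    f["r"] = f["b"] / f["e"]
    area = float(np.trapezoid(a[i_d0:i_d1 + 1], t[i_d0:i_d1 + 1]))
    f["q"] = area / (f["D"] * f["e"])

    # i: max forward-looking slope via central differences, restricted window
    lo, hi = idx["amin"], idx["amax"]
    if hi <= lo:
        raise FeatureUndefinedError("i", "ta_min does not precede ta_max")
    slope = np.gradient(a[lo:hi + 1], dt)
    f["i"] = float(np.max(slope))

    f["l"] = float(kin.p[idx["pmin"]])
    f["n"] = float(kin.p[idx["pmax"]])
    f["O"] = events.t_to - events.t_p_max
    f["W"] = events.t_p_max - events.t_p_min
    f["s"] = float(kin.v[idx["vmin"]])

    # M: longest contiguous run of positive power inside [t0, tTO]
    positive = kin.p > 0
    if not positive.any():
        raise FeatureUndefinedError("M", "power never positive")
    runs = np.diff(np.concatenate([[0], positive.view(np.int8), [0]]))
    starts = np.flatnonzero(runs == 1)
    stops = np.flatnonzero(runs == -1)
    longest = int(np.argmax(stops - starts))
    f["M"] = float((stops[longest] - starts[longest]) * dt)

    f["u"] = _trapz_mean(t[idx["bp"]:], kin.p[idx["bp"]:])
    f["z"] = _trapz_mean(t[:idx["bp"] + 1], kin.p[:idx["bp"] + 1])

    f["f1"], f["f2"], f["f3"] = (float(x) for x in vmd_freqs)

    out = {name: f[name] for name in FEATURE_NAMES}
    bad = [k for k, v in out.items() if not np.isfinite(v)]
    if bad:
        raise FeatureUndefinedError(bad[0], "non-finite value")
    return out


def features_from_trace(
    trace: AccelTrace,
    static_window: tuple[float, float],
    vmd_params: VmdParams | None = None,
) -> tuple[dict[str, float], JumpMeasurement]:
    """End-to-end single-trace feature extraction.

    Runs event detection + kinematics, decomposes the [t0, tTO] segment with
    K = 3 VMD, and returns the feature dict together with the underlying
    :class:`~cmjump.kinematics.JumpMeasurement`.
    """
    meas = measure_jump(trace, static_window)
    seg = trace.window(meas.events.t0, meas.events.t_to)
    # the decomposition needs >= 64 samples; very short jumps borrow quiet
    # pre-onset samples, which add no spectral content of their own
    if seg.stop - seg.start < 64:
        seg = slice(max(0, seg.stop - 64), seg.stop)
    res = vmd_decompose(trace.a[seg], fs=trace.fs, k=3, params=vmd_params)
    freqs = central_frequencies(res)
    feats = extract_features(trace, meas.events, meas.kin, freqs)
    return feats, meas


def feature_table(rows: list[dict[str, float]], ids=None, h_fp=None) -> pd.DataFrame:
    """Assemble per-jump feature dicts into the canonical CSV layout."""
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    if h_fp is not None:
        df.insert(0, "hFP", np.asarray(h_fp, dtype=float))
    df.insert(0, "jump_id", ids if ids is not None else np.arange(len(df)))
    return df
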