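"""Time-series analyses: FRAP S/N recovery, MTOC phenotypes, spindle angles.

FRAP traces are expressed as Signal/Noise (S/N): the background-subtracted
centrosomal intensity divided by the background-subtracted cytoplasmic
intensity.  This normalization cancels illumination drift and acquisition
gain, so traces from different cells are directly comparable.

Spindle orientation is the undirected axis through the two pole positions.
Because an axis is defined only modulo 180 deg, frame-to-frame changes are
unwrapped under the assumption that the spindle turns by less than 90 deg
between consecutive frames (movies are acquired at ~minutes intervals,
rotation is slow).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclass
class FrapTrace:
    """Raw photometry of one bleached (or control) centrosome over time."""

    times: np.ndarray  # s, strictly increasing
    centrosome_signal: np.ndarray
    cytoplasm_signal: np.ndarray
    background: np.ndarray
    bleach_frame: int | None = None
    stage_annotations: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.centrosome_signal = np.asarray(self.centrosome_signal, float)
        self.cytoplasm_signal = np.asarray(self.cytoplasm_signal, float)
        self.background = np.asarray(self.background, float)
        n = len(self.times)
        for name in ("centrosome_signal", "cytoplasm_signal", "background"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length must match times")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class SpindleTrack:
    """Per-frame spindle-pole coordinates (um) with mitosis annotations."""

    pole1: np.ndarray  # (T, 2)
    pole2: np.ndarray  # (T, 2)
    nebd_frame: int = 0
    anaphase_frame: int | None = None
    previous_division_axis: float | None = None  # degrees

    def __post_init__(self) -> None:
        self.pole1 = np.asarray(self.pole1, float)
        self.pole2 = np.asarray(self.pole2, float)
        if self.pole1.shape != self.pole2.shape or self.pole1.ndim != 2:
            raise ValueError("pole tracks must be matching (T, 2) arrays")
        if self.anaphase_frame is None:
            self.anaphase_frame = len(self.pole1) - 1
        if not self.nebd_frame < self.anaphase_frame:
            raise ValueError("nebd_frame must precede anaphase_frame")
        if np.any(np.all(self.pole1 == self.pole2, axis=1)):
            raise ValueError("spindle poles coincide at some frame")


@dataclass
class MTOCTrace:
    """Apical/basal microtubule intensity over an interphase window."""

    apical: np.ndarray
    basal: np.ndarray
    cytoplasm: np.ndarray
    window: tuple[int, int] = (0, -1)  # inclusive frame range

    def __post_init__(self) -> None:
        self.apical = np.asarray(self.apical, float)
        self.basal = np.asarray(self.basal, float)
        self.cytoplasm = np.asarray(self.cytoplasm, float)
        lo, hi = self.window
        n = len(self.apical)
        hi = hi % n
        if hi < lo:
            raise ValueError("empty interphase window")
        self.window = (lo, hi)


# ---------------------------------------------------------------------------
# FRAP


def sn_series(trace: FrapTrace) -> np.ndarray:
    """Signal/Noise per frame: (centrosome - bg) / (cytoplasm - bg).

    Frames where the cytoplasm does not exceed background are undefined
    and returned as NaN.
    """
    denom = trace.cytoplasm_signal - trace.background
    sn = np.full(len(trace.times), np.nan)
    ok = denom > 0
    sn[ok] = (trace.centrosome_signal[ok] - trace.background[ok]) / denom[ok]
    return sn


def recovery_metrics(
    sn: np.ndarray, times: np.ndarray, bleach_frame: int
) -> dict:
    """Descriptive recovery metrics from an S/N series.

    ``pre_mean`` — mean S/N over pre-bleach frames; ``post_min`` — minimum
    post-bleach S/N; ``recovery_fraction`` — (sn - post_min)/(pre_mean -
    post_min) over post-bleach frames; ``half_time`` — first time (linear
    interpolation between frames) at which the recovery fraction reaches
    0.5, measured from the bleach frame, or None if never reached.
    """
    sn = np.asarray(sn, float)
    times = np.asarray(times, float)
    if bleach_frame < 3:
        raise ValueError("need >= 3 pre-bleach frames")
    pre = sn[:bleach_frame]
    post = sn[bleach_frame:]
    t_post = times[bleach_frame:]
    pre_mean = float(np.nanmean(pre))
    post_min = float(np.nanmin(post))
    span = pre_mean - post_min
    if span <= 0:
        frac = np.zeros_like(post)
    else:
        frac = (post - post_min) / span

    half_time = None
    t0 = times[bleach_frame]
    for i, f in enumerate(frac):
        if np.isnan(f):
            continue
        if f >= 0.5:
            if i == 0 or np.isnan(frac[i - 1]):
                half_time = float(t_post[i] - t0)
            else:
                f0, f1 = frac[i - 1], f
                half_time = float(
                    t_post[i - 1] + (0.5 - f0) / (f1 - f0) * (t_post[i] - t_post[i - 1]) - t0
                )
            break
    return {
        "pre_mean": pre_mean,
        "post_min": post_min,
        "recovery_fraction": frac,
        "half_time": half_time,
    }


def fit_recovery(
    sn: np.ndarray, times: np.ndarray, bleach_frame: int
) -> dict:
    """Single-exponential fit of the post-bleach S/N recovery.

    Model: ``sn(t) = floor + amplitude * (1 - exp(-rate * (t - t_bleach)))``.
    Returns the fitted rate (1/s), its half-time ln2/rate (s), the floor and
    amplitude, and the implied immobile fraction relative to the pre-bleach
    mean.  Fitting pools information across the whole trace, so the
    half-time estimate is far less noise-sensitive than the first-crossing
    metric of :func:`recovery_metrics`.
    """
    sn = np.asarray(sn, float)
    times = np.asarray(times, float)
    post = sn[bleach_frame:]
    t = times[bleach_frame:] - times[bleach_frame]
    ok = ~np.isnan(post)
    post, t = post[ok], t[ok]
    if len(post) < 4:
        raise ValueError("need >= 4 post-bleach frames to fit recovery")
    pre_mean = float(np.nanmean(sn[:bleach_frame])) if bleach_frame >= 1 else float("nan")

    def model(t, floor, amplitude, rate):
        return floor + amplitude * (1.0 - np.exp(-rate * t))

    floor0 = float(post.min())
    amp0 = max(float(post.max() - post.min()), 1e-9)
    # rate guess from the time span
    rate0 = 1.0 / max(t[-1] / 3.0, 1e-9)
    popt, _ = curve_fit(
        model, t, post, p0=(floor0, amp0, rate0),
        bounds=([-np.inf, 0.0, 1e-12], [np.inf, np.inf, np.inf]), maxfev=20000,
    )
    floor, amplitude, rate = map(float, popt)
    bleach_loss = pre_mean - floor
    immobile = 1.0 - amplitude / bleach_loss if bleach_loss > 0 else float("nan")
    return {
        "rate": rate,
        "half_time": math.log(2.0) / rate,
        "floor": floor,
        "amplitude": amplitude,
        "immobile_fraction": immobile,
    }


def aggregate_traces(
    traces: list[FrapTrace], align: str = "bleach_frame"
) -> pd.DataFrame:
    """Mean +/- SD of S/N across traces at aligned time points.

    ``align="bleach_frame"`` indexes frames relative to each trace's bleach
    event (unbleached traces align on frame 0).  Returns one row per aligned
    frame offset with columns mean, sd, n, time (mean time at that offset).
    """
    if len(traces) < 2:
        raise ValueError("need >= 2 traces to aggregate")
    if align not in ("bleach_frame", "mitotic_stage", "start"):
        raise ValueError(f"unknown alignment {align!r}")
    buckets: dict[int, list[tuple[float, float]]] = {}
    for tr in traces:
        sn = sn_series(tr)
        ref = tr.bleach_frame if (align == "bleach_frame" and tr.bleach_frame is not None) else 0
        for i in range(len(sn)):
            if np.isnan(sn[i]):
                continue
            buckets.setdefault(i - ref, []).append((tr.times[i] - tr.times[ref], sn[i]))
    rows = []
    for off in sorted(buckets):
        vals = np.array([v for _, v in buckets[off]])
        ts = np.array([t for t, _ in buckets[off]])
        rows.append(
            dict(frame_offset=off, time=ts.mean(), mean=vals.mean(),
                 sd=vals.std(ddof=0), n=len(vals))
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# MTOC phenotype


def classify_mtoc_phenotype(
    trace: MTOCTrace, activity_ratio_threshold: float = 1.5
) -> str:
    """Score interphase MTOC activity of the apical and basal centrosome.

    A pole is *active* when the median intensity/cytoplasm ratio over the
    interphase window reaches the threshold.  Wild type shows exactly one
    active (apical) MTOC; ``gain`` means both are active, ``loss`` covers no
    active MTOC or an inactive apical pole.
    """
    lo, hi = trace.window
    sl = slice(lo, hi + 1)
    cyto = trace.cytoplasm[sl]
    if np.any(cyto <= 0):
        raise ValueError("cytoplasm reference must be positive over the window")
    apical_active = float(np.median(trace.apical[sl] / cyto)) >= activity_ratio_threshold
    basal_active = float(np.median(trace.basal[sl] / cyto)) >= activity_ratio_threshold
    if apical_active and not basal_active:
        return "wildtype_asymmetry"
    if apical_active and basal_active:
        return "gain"
    return "loss"


# ---------------------------------------------------------------------------
# spindle angles


def axis_angles(track: SpindleTrack) -> np.ndarray:
    """Continuously unwrapped spindle-axis orientation per frame (degrees).

    The pole-pole axis is undirected (defined modulo 180 deg); consecutive
    frames are connected by the change of smallest magnitude (|delta| <= 90),
    which resolves the ambiguity and makes pole-label swaps invisible.
    """
    d = track.pole2 - track.pole1
    raw = np.degrees(np.arctan2(d[:, 1], d[:, 0])) % 180.0
    out = np.empty_like(raw)
    out[0] = raw[0]
    for i in range(1, len(raw)):
        delta = (raw[i] - out[i - 1]) % 180.0
        if delta > 90.0:
            delta -= 180.0
        out[i] = out[i - 1] + delta
    return out


def spindle_rotation(track: SpindleTrack) -> dict:
    """Net and maximum spindle rotation between NEBD and anaphase (degrees).

    ``net_rotation`` — |theta(anaphase) - theta(NEBD)| on the unwrapped
    axis; ``max_rotation`` — the largest excursion from the NEBD orientation
    anywhere in the window.
    """
    theta = axis_angles(track)
    i0, i1 = track.nebd_frame, track.anaphase_frame
    window = theta[i0 : i1 + 1]
    ref = theta[i0]
    return {
        "net_rotation": float(abs(theta[i1] - ref)),
        "max_rotation": float(np.max(np.abs(window - ref))),
    }


def division_orientation_change(axis_current: float, axis_previous: float) -> float:
    """Smallest angle (degrees, in [0, 90]) between two undirected axes."""
    d = abs(axis_current - axis_previous) % 180.0
    return min(d, 180.0 - d)
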