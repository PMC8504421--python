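"""Timeline segmentation and derived neurovascular metrics.

The experiment timeline is segmented from the red-blood-cell velocity trace
into three periods:

* **baseline** — everything before the vasoconstrictor injection;
* **ischemia** — the five minutes following the peak drop in velocity;
* **partial recovery** — from the first sustained return of velocity to 80%
  of the baseline mean (absent if the trace never re-crosses that level).

Derived metrics link the vascular record to the neuronal one: the distance
travelled by RBCs per period (time-integral of velocity, mm), band-power
changes between periods (%), and the velocity fraction of baseline at each
spreading-depolarization onset (the quantity whose ~35% trigger level the
detectors are built around).

Velocity is smoothed with a 30 s moving median before the argmin/threshold
rules so single-window LS-PIV outliers cannot define the nadir; the width is
configurable.  Internally everything is seconds and mm/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.ndimage import median_filter

from .events import SdEvent
from .lfp import BandPowerSummary
from .lspiv import VelocityTrace

__all__ = [
    "PeriodSegmentation",
    "NeurovascularSummary",
    "segment_periods",
    "rbc_distance",
    "power_change",
    "vrbc_fraction_at_onset",
    "smoothed_velocity",
]

ISCHEMIA_DURATION_S = 300.0


@dataclass
class PeriodSegmentation:
    """Period boundaries recovered from a velocity trace (seconds)."""

    baseline: tuple[float, float]
    ischemia: tuple[float, float]
    partial_recovery: tuple[float, float] | None
    peak_drop_time: float
    baseline_vrbc: float  # mm/s

    @property
    def recovery_absent(self) -> bool:
        return self.partial_recovery is None


@dataclass
class NeurovascularSummary:
    """Per-period distance and power metrics plus per-SD velocity fractions."""

    rbc_distance_mm: dict[str, float]
    power_change_pct: dict[str, float] | None
    vrbc_fraction_at_sd_onset: list[float]


def _valid(trace: VelocityTrace) -> tuple[np.ndarray, np.ndarray]:
    keep = np.isfinite(trace.v)
    if not np.any(keep):
        raise ValueError("velocity trace holds no valid samples")
    return trace.time[keep], trace.v[keep]


def smoothed_velocity(
    trace: VelocityTrace, window_s: float = 30.0
) -> tuple[np.ndarray, np.ndarray]:
    """Moving-median velocity (times, values).

    The window is converted to samples via the median sampling interval, so
    mildly irregular traces (post quality filtering) are handled
    approximately; heavily gapped traces should be re-windowed upstream.
    """
    t, v = _valid(trace)
    if t.size < 3:
        return t, v
    dt = float(np.median(np.diff(t)))
    size = max(1, int(round(window_s / dt)))
    if size % 2 == 0:
        size += 1
    return t, median_filter(v, size=size, mode="nearest")


def segment_periods(
    trace: VelocityTrace,
    injection_time: float,
    smooth_window_s: float = 30.0,
    recovery_fraction: float = 0.8,
    sustain_s: float = 10.0,
    min_baseline_s: float = 60.0,
) -> PeriodSegmentation:
    """Segment baseline / ischemia / partial recovery from a velocity trace.

    The ischemia window is pinned to ``[peak_drop_time, peak_drop_time +
    300 s]``; partial recovery begins at the first post-ischemia time the
    smoothed velocity stays at or above ``recovery_fraction`` of the baseline
    mean for at least ``sustain_s`` (transient spikes excluded).
    """
    t, v = _valid(trace)
    if t[0] > injection_time - min_baseline_s:
        raise ValueError(
            f"need at least {min_baseline_s:.0f} s of pre-injection data "
            f"(trace starts at {t[0]:.1f} s, injection at {injection_time:.1f} s)"
        )
    if t[-1] <= injection_time:
        raise ValueError("trace does not span the injection time")

    ts, vs = smoothed_velocity(trace, smooth_window_s)
    pre = ts < injection_time
    baseline_vrbc = float(np.mean(v[t < injection_time]))
    if baseline_vrbc <= 0:
        raise ValueError("baseline velocity must be positive")

    post = ts >= injection_time
    v_post, t_post = vs[post], ts[post]
    if float(np.min(v_post)) >= 0.95 * baseline_vrbc:
        raise ValueError("no ischemic drop detected (post-injection velocity "
                         "never falls below baseline)")
    # The moving median localizes the nadir robustly but biases the argmin on
    # asymmetric drop/creep profiles; refine on the unsmoothed trace within
    # one smoothing half-window of the smoothed minimum.
    t_coarse = float(t_post[np.argmin(v_post)])
    near = (t > injection_time) & (np.abs(t - t_coarse) <= smooth_window_s / 2.0)
    if np.any(near):
        peak_drop_time = float(t[near][np.argmin(v[near])])
    else:
        peak_drop_time = t_coarse
    ischemia = (peak_drop_time, peak_drop_time + ISCHEMIA_DURATION_S)

    partial_recovery = None
    after = ts >= ischemia[1]
    if np.any(after):
        above = vs[after] >= recovery_fraction * baseline_vrbc
        t_after = ts[after]
        # first sustained (>= sustain_s) supra-threshold run
        start = None
        for a, b in _true_runs(above):
            if t_after[b - 1] - t_after[a] >= sustain_s:
                start = float(t_after[a])
                break
        if start is not None:
            partial_recovery = (start, float(t[-1]))

    return PeriodSegmentation(
        baseline=(float(t[0]), float(injection_time)),
        ischemia=ischemia,
        partial_recovery=partial_recovery,
        peak_drop_time=peak_drop_time,
        baseline_vrbc=baseline_vrbc,
    )


def _true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    if not np.any(mask):
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    return list(zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)))


def rbc_distance(
    trace: VelocityTrace,
    period: tuple[float, float],
    max_gap_fraction: float = 0.2,
) -> float:
    """Distance travelled by RBCs over a period: trapezoidal integral of
    velocity, in mm.  Data gaps are bridged linearly; if gaps cover more than
    ``max_gap_fraction`` of the period an error names the coverage."""
    t, v = _valid(trace)
    a, b = float(period[0]), float(period[1])
    if not (t[0] <= a < b <= t[-1] + 1e-9):
        raise ValueError(f"period ({a}, {b}) not inside trace span ({t[0]}, {t[-1]})")
    inside = (t > a) & (t < b)
    ti = np.concatenate([[a], t[inside], [b]])
    vi = np.concatenate([[np.interp(a, t, v)], v[inside], [np.interp(b, t, v)]])
    nominal = float(np.median(np.diff(t)))
    gaps = np.diff(ti)
    gap_time = float(np.sum(np.maximum(0.0, gaps - 3.0 * nominal)))
    coverage = 1.0 - gap_time / (b - a)
    if coverage < 1.0 - max_gap_fraction:
        raise ValueError(
            f"period covered only at fraction {coverage:.2f} "
            f"(gaps exceed {max_gap_fraction:.0%} of the period)"
        )
    return float(np.trapezoid(vi, ti))


def power_change(
    power_ref: BandPowerSummary, power_test: BandPowerSummary
) -> dict[str, float]:
    """Percent change in band power, test vs reference, per band and total.

    Bands with zero reference power get NaN (flagged with a warning).
    """
    if set(power_ref.power) != set(power_test.power):
        raise ValueError("band sets differ between reference and test summaries")
    out: dict[str, float] = {}
    for name, ref in power_ref.power.items():
        if ref == 0.0:
            warnings.warn(f"zero reference power in band {name!r}; change undefined",
                          stacklevel=2)
            out[name] = float("nan")
        else:
            out[name] = 100.0 * (power_test.power[name] - ref) / ref
    if power_ref.total == 0.0:
        warnings.warn("zero total reference power; change undefined", stacklevel=2)
        out["total"] = float("nan")
    else:
        out["total"] = 100.0 * (power_test.total - power_ref.total) / power_ref.total
    return out


def vrbc_fraction_at_onset(
    trace: VelocityTrace,
    segmentation: PeriodSegmentation,
    sd: SdEvent,
    smooth_window_s: float = 30.0,
    max_gap_s: float = 10.0,
) -> float:
    """Smoothed velocity at an SD onset as a fraction of baseline velocity.

    Returns NaN (with a warning) when the onset falls in a data gap wider
    than ``max_gap_s``.
    """
    ts, vs = smoothed_velocity(trace, smooth_window_s)
    if not ts[0] <= sd.onset <= ts[-1]:
        raise ValueError(f"SD onset {sd.onset:.1f} s outside velocity trace span")
    right = int(np.searchsorted(ts, sd.onset))
    left = max(0, right - 1)
    right = min(ts.size - 1, right)
    if ts[right] - ts[left] > max_gap_s:
        warnings.warn(
            f"SD onset at {sd.onset:.1f} s sits in a {ts[right] - ts[left]:.1f} s "
            "velocity gap; fraction undefined",
            stacklevel=2,
        )
        return float("nan")
    return float(np.interp(sd.onset, ts, vs) / segmentation.baseline_vrbc)
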