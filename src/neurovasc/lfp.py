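"""LFP conditioning and spectral quantities.

DC-coupled local field potential traces carry two kinds of information that
are analysed on different representations of the same recording:

* slow DC shifts (spreading depolarizations) are read off the **raw** trace,
  which must therefore never be filtered on ingest;
* oscillatory power (FFT band power, band-wise continuous wavelet transform)
  is computed on a conditioned copy: zero-phase 1 Hz high-pass plus a 60 Hz
  line-noise notch.

Frequency bands follow the conventional LFP partition used throughout the
package: theta 2-10 Hz, alpha 10-15 Hz, beta 15-30 Hz, low gamma 30-80 Hz,
high gamma 80-120 Hz.  Bands abut; a frequency bin sitting exactly on a
shared boundary is assigned to the lower band (intervals ``(f_low, f_high]``,
with the bottom edge of the lowest band included).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pywt
import yaml
from scipy import signal

__all__ = [
    "LfpTrace",
    "BandDefinition",
    "BandSeries",
    "BaselineStats",
    "BandPowerSummary",
    "DEFAULT_BANDS",
    "BAND_BY_NAME",
    "load_bands",
    "preprocess_for_power",
    "band_power",
    "cwt_band_series",
]

BAND_NAMES = ("theta", "alpha", "beta", "low_gamma", "high_gamma")

# Analytic Morlet-type wavelet with ~6 cycles of effective support:
# pywt's cmorB-C is exp(2*pi*1j*C*t) * exp(-t**2 / B); B=2, C=6/(2*pi)
# reproduces the classic omega0=6 Morlet.
DEFAULT_WAVELET = "cmor2.0-0.9549"


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band ``[f_low, f_high]`` in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not self.f_low < self.f_high:
            raise ValueError(
                f"band {self.name!r}: f_low ({self.f_low}) must be < f_high ({self.f_high})"
            )
        if self.f_low <= 0:
            raise ValueError(f"band {self.name!r}: f_low must be positive")

    @property
    def width(self) -> float:
        return self.f_high - self.f_low

    def component_frequencies(self) -> np.ndarray:
        """Integer frequencies inside the band, endpoints inclusive."""
        return np.arange(int(np.ceil(self.f_low)), int(np.floor(self.f_high)) + 1)


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("theta", 2.0, 10.0),
    BandDefinition("alpha", 10.0, 15.0),
    BandDefinition("beta", 15.0, 30.0),
    BandDefinition("low_gamma", 30.0, 80.0),
    BandDefinition("high_gamma", 80.0, 120.0),
)

BAND_BY_NAME: dict[str, BandDefinition] = {b.name: b for b in DEFAULT_BANDS}

#: Full analysis range used for "total" power, both edges included.
TOTAL_RANGE = (2.0, 120.0)


def load_bands(path) -> tuple[BandDefinition, ...]:
    """Load band definitions from a YAML mapping ``name: [f_low, f_high]``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping) or not raw:
        raise ValueError(f"{path}: expected a non-empty mapping of name -> [f_low, f_high]")
    return tuple(BandDefinition(str(name), float(lo), float(hi)) for name, (lo, hi) in raw.items())


@dataclass
class LfpTrace:
    """A DC-coupled local field potential recording.

    Parameters
    ----------
    samples : ndarray
        Potential in mV.  The DC component is preserved on ingest because
        spreading-depolarization detection reads the raw trace.
    fs : float
        Sampling rate in Hz (recordings in this line of work are digitized
        at 10 kHz; synthetic traces may use less).
    t0 : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float = 10_000.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    def index_of(self, t: float) -> int:
        return int(round((t - self.t0) * self.fs))

    def segment(self, start: float, end: float) -> "LfpTrace":
        """Return the sub-trace covering ``[start, end)`` seconds."""
        if start < self.t0 - 0.5 / self.fs or end > self.t_end + 0.5 / self.fs:
            raise ValueError(
                f"window ({start}, {end}) outside trace span ({self.t0}, {self.t_end})"
            )
        if not end > start:
            raise ValueError("window end must exceed start")
        i0 = max(0, self.index_of(start))
        i1 = min(self.samples.size, self.index_of(end))
        return LfpTrace(self.samples[i0:i1], fs=self.fs, t0=self.t0 + i0 / self.fs)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.times, "potential_mV": self.samples}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "LfpTrace":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy(float)
        if t.size < 2:
            raise ValueError("trace CSV must hold at least two samples")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("trace CSV must be uniformly sampled")
        return cls(df["potential_mV"].to_numpy(float), fs=1.0 / dt[0], t0=t[0])


@dataclass(frozen=True)
class BaselineStats:
    """Mean/SD of a presumed event-free reference window."""

    mean: float
    sd: float
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError("baseline sd must be positive")


def baseline_stats(trace: LfpTrace, window: tuple[float, float]) -> BaselineStats:
    seg = trace.segment(*window)
    sd = float(np.std(seg.samples))
    if sd == 0.0:
        raise ValueError("baseline window has zero variance")
    return BaselineStats(float(np.mean(seg.samples)), sd, (float(window[0]), float(window[1])))


# ---------------------------------------------------------------------------
# Conditioning for power analyses
# ---------------------------------------------------------------------------

def preprocess_for_power(
    trace: LfpTrace,
    highpass_hz: float = 1.0,
    notch_hz: float = 60.0,
    notch_q: float = 30.0,
) -> LfpTrace:
    """Zero-phase 1 Hz high-pass plus 60 Hz notch.

    Filtering is forward-backward (zero phase) so event timing downstream is
    unbiased.  The input trace is untouched; spreading-depolarization
    detection keeps reading the raw DC-coupled signal.
    """
    if trace.fs <= 2 * notch_hz:
        raise ValueError(
            f"fs = {trace.fs} Hz too low for a {notch_hz} Hz notch (needs fs > {2 * notch_hz})"
        )
    sos = signal.butter(2, highpass_hz, btype="highpass", fs=trace.fs, output="sos")
    x = signal.sosfiltfilt(sos, trace.samples)
    b, a = signal.iirnotch(notch_hz, notch_q, fs=trace.fs)
    x = signal.filtfilt(b, a, x)
    return LfpTrace(x, fs=trace.fs, t0=trace.t0)


# ---------------------------------------------------------------------------
# FFT band power
# ---------------------------------------------------------------------------

@dataclass
class BandPowerSummary:
    """Band-integrated periodogram power (mV^2) over one analysis window."""

    power: dict[str, float]
    total: float
    window: tuple[float, float]
    relative_change: dict[str, float] | None = None

    def bands(self) -> tuple[str, ...]:
        return tuple(self.power)


def band_power(
    trace: LfpTrace,
    window: tuple[float, float],
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    preprocess: bool = True,
    expected_window_s: float = 120.0,
) -> BandPowerSummary:
    """Integrate periodogram power over each band for one time window.

    Power analysis conventionally uses two-minute windows; shorter windows
    are allowed with a warning.  Band intervals are half-open
    ``(f_low, f_high]`` — a bin on a shared boundary belongs to the lower
    band — so abutting bands partition the spectrum exactly; the bottom edge
    of the lowest band is included.
    """
    seg = trace.segment(*window)
    narrowest_flow = min(b.f_low for b in bands)
    if seg.duration < 2.0 / narrowest_flow:
        raise ValueError(
            f"window of {seg.duration:.3f} s too short for bands starting at {narrowest_flow} Hz"
        )
    if seg.duration < expected_window_s - 1e-9:
        warnings.warn(
            f"power window of {seg.duration:.1f} s is shorter than the "
            f"conventional {expected_window_s:.0f} s",
            stacklevel=2,
        )
    if preprocess:
        seg = preprocess_for_power(seg)
    freqs, pxx = signal.periodogram(seg.samples, fs=seg.fs)
    df = freqs[1] - freqs[0]
    f_floor = min(b.f_low for b in bands)
    power: dict[str, float] = {}
    for b in bands:
        mask = (freqs > b.f_low) & (freqs <= b.f_high)
        if b.f_low == f_floor:
            mask |= freqs == b.f_low
        power[b.name] = float(np.sum(pxx[mask]) * df)
    tmask = (freqs >= TOTAL_RANGE[0]) & (freqs <= TOTAL_RANGE[1])
    total = float(np.sum(pxx[tmask]) * df)
    return BandPowerSummary(power=power, total=total, window=(float(window[0]), float(window[1])))


# ---------------------------------------------------------------------------
# Band-wise continuous wavelet transform
# ---------------------------------------------------------------------------

@dataclass
class BandSeries:
    """Scale-averaged CWT coefficient magnitude for one band.

    ``fs`` is the (possibly decimated) sampling rate of the series; the
    decimation applied relative to the input trace is declared in
    ``decimated_from``.
    """

    times: np.ndarray
    magnitude: np.ndarray
    fs: float
    band: BandDefinition
    decimated_from: float | None = None


def _resample_to(x: np.ndarray, fs: float, fs_target: float) -> tuple[np.ndarray, float]:
    frac = Fraction(fs_target / fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    if up == down:
        return x, fs
    y = signal.resample_poly(x, up, down)
    return y, fs * up / down


def cwt_band_series(
    trace: LfpTrace,
    band: BandDefinition,
    voices_per_octave: int = 8,
    wavelet: str = DEFAULT_WAVELET,
    max_fs: float = 500.0,
) -> BandSeries:
    """Magnitude of the CWT averaged over log-spaced scales spanning the band.

    The trace is decimated to at most ``max_fs`` (kept above twice the
    band's upper edge) before the transform; DC-event detection never goes
    through this path so the decimation is purely a spectral-analysis choice.
    """
    if band.f_high >= trace.fs / 2:
        raise ValueError(
            f"band {band.name!r} upper edge {band.f_high} Hz is at/above Nyquist "
            f"({trace.fs / 2} Hz)"
        )
    fs_target = min(trace.fs, max_fs)
    if fs_target <= 2 * band.f_high:
        fs_target = trace.fs  # decimation would alias the band; skip it
    x, fs_eff = _resample_to(trace.samples, trace.fs, fs_target)

    n_octaves = np.log2(band.f_high / band.f_low)
    n_freqs = max(2, int(np.ceil(n_octaves * voices_per_octave)) + 1)
    freqs = np.geomspace(band.f_low, band.f_high, n_freqs)
    fc = pywt.central_frequency(wavelet)
    scales = fc * fs_eff / freqs
    # precision=14 refines the discretized wavelet; the default leaves a
    # ~1e-2 broadband error floor that masquerades as out-of-band response.
    coeffs, _ = pywt.cwt(x, scales, wavelet, sampling_period=1.0 / fs_eff,
                         method="fft", precision=14)
    mag = np.abs(coeffs).mean(axis=0)
    times = trace.t0 + np.arange(mag.size) / fs_eff
    return BandSeries(
        times=times,
        magnitude=mag,
        fs=fs_eff,
        band=band,
        decimated_from=None if fs_eff == trace.fs else trace.fs,
    )
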