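"""Line-scan particle image velocimetry (LS-PIV).

Red-blood-cell velocity is estimated from a kymograph — the space-time image
formed by scanning the same line along a vessel's longitudinal axis over and
over.  Moving cells appear as slanted streaks whose slope (pixels per line)
encodes velocity:

    v [mm/s] = shift [px/line] * pixel_size [um] / line_period [ms]

The estimator cross-correlates sequential line scans inside sliding blocks
of lines, averages the per-pair normalized correlation over the block, and
refines the peak lag to sub-pixel precision with a three-point parabolic
fit.  Positive velocity means motion toward increasing column index; the
sign convention is declared in the trace metadata (arteriole/venule identity
is caller-supplied metadata, not computed here).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "Kymograph",
    "VelocityTrace",
    "AliasingError",
    "estimate_velocity",
    "quality_filter",
]

SIGN_CONVENTION = "positive velocity = motion toward increasing column index"

VESSEL_CLASSES = ("proximal", "distal", "vein", "unclassified")


class AliasingError(ValueError):
    """Per-line displacement too large for the line width."""


@dataclass
class Kymograph:
    """A 2-D line-scan image: rows are successive lines (time), columns are
    position along the vessel."""

    intensity: np.ndarray
    line_period_ms: float
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        if self.intensity.ndim != 2:
            raise ValueError("kymograph intensity must be 2-D (lines x pixels)")
        if self.intensity.shape[0] < 2:
            raise ValueError("kymograph needs at least 2 lines")
        if self.intensity.shape[1] < 16:
            raise ValueError("kymograph needs at least 16 pixels per line")
        if not 0.1 <= self.line_period_ms <= 10.0:
            raise ValueError("line_period_ms must lie in [0.1, 10] ms")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_lines(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.intensity.shape[1]

    @property
    def line_period_s(self) -> float:
        return self.line_period_ms / 1000.0

    @property
    def duration(self) -> float:
        return self.n_lines * self.line_period_s

    def mirrored(self) -> "Kymograph":
        """Reflect the position axis (velocity sign flips)."""
        return Kymograph(self.intensity[:, ::-1].copy(), self.line_period_ms, self.pixel_size_um)

    # -- TIFF + JSON sidecar interchange format --------------------------------
    def to_tiff(self, path, seed: int | None = None) -> None:
        path = Path(path)
        tifffile.imwrite(path, self.intensity.astype(np.float32))
        meta = {
            "line_period_ms": self.line_period_ms,
            "pixel_size_um": self.pixel_size_um,
            "seed": seed,
        }
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def from_tiff(cls, path) -> "Kymograph":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            tifffile.imread(path),
            line_period_ms=float(meta["line_period_ms"]),
            pixel_size_um=float(meta["pixel_size_um"]),
        )


@dataclass
class VelocityTrace:
    """Per-window signed RBC velocity with correlation quality.

    ``quality`` is the normalized correlation peak in [0, 1]; windows whose
    content could not be correlated (e.g. constant intensity) carry
    quality 0 and NaN velocity.
    """

    time: np.ndarray
    v: np.ndarray
    quality: np.ndarray
    vessel_class: str = "unclassified"
    metadata: dict = field(default_factory=lambda: {"sign_convention": SIGN_CONVENTION})

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.quality = np.asarray(self.quality, dtype=float)
        if not (self.time.shape == self.v.shape == self.quality.shape):
            raise ValueError("time, v and quality must have identical shapes")
        if self.time.size > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if self.vessel_class not in VESSEL_CLASSES:
            raise ValueError(f"vessel_class must be one of {VESSEL_CLASSES}")

    def __len__(self) -> int:
        return self.time.size

    @property
    def span(self) -> tuple[float, float]:
        return (float(self.time[0]), float(self.time[-1]))

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.time, "v_mm_s": self.v, "quality": self.quality}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "VelocityTrace":
        df = pd.read_csv(path)
        return cls(
            df["time_s"].to_numpy(float),
            df["v_mm_s"].to_numpy(float),
            df["quality"].to_numpy(float),
        )


def _pair_correlations(lines: np.ndarray, max_shift: int) -> np.ndarray:
    """Circular normalized cross-correlation of each consecutive line pair.

    Returns an array (n_lines-1, 2*max_shift+1); column ``max_shift + lag``
    holds the correlation at that lag.  Lines are mean-subtracted (removes
    the illumination offset that otherwise dominates the peak) and
    L2-normalized so values lie in [-1, 1]; constant lines contribute zeros.
    """
    x = lines.astype(np.float64)
    x = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    np.divide(x, norms, out=x, where=norms > 0)

    n = x.shape[1]
    F = np.fft.rfft(x, axis=1)
    cross = np.conj(F[:-1]) * F[1:]
    corr = np.fft.irfft(cross, n=n, axis=1)  # corr[:, lag] = sum_x a(x) b(x+lag)
    lags = np.arange(-max_shift, max_shift + 1)
    return corr[:, lags % n]


def estimate_velocity(
    kymo: Kymograph,
    window_lines: int = 32,
    overlap_fraction: float = 0.5,
    max_shift: int | None = None,
    chunk_pairs: int = 262_144,
) -> VelocityTrace:
    """Estimate the RBC velocity time course from a kymograph.

    Parameters
    ----------
    window_lines : int
        Lines per correlation block (>= 4).  Each block yields one velocity
        sample timed at the block center.
    overlap_fraction : float
        Fractional overlap between successive blocks, in [0, 1).
    max_shift : int, optional
        Search half-range in pixels; defaults to ``n_pixels // 4`` and must
        stay below half the line width.
    """
    if window_lines < 4:
        raise ValueError("window_lines must be >= 4")
    if window_lines > kymo.n_lines:
        raise ValueError(
            f"window of {window_lines} lines larger than image ({kymo.n_lines} lines)"
        )
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must lie in [0, 1)")
    if max_shift is None:
        max_shift = kymo.n_pixels // 4
    if not 0 < max_shift < kymo.n_pixels / 2:
        raise ValueError("max_shift must lie in (0, n_pixels/2)")

    step = max(1, int(round(window_lines * (1.0 - overlap_fraction))))
    n_pairs = kymo.n_lines - 1
    pairs_per_window = window_lines - 1

    # Correlations of all consecutive line pairs, restricted to the lag window
    # (chunked so large kymographs stay within memory).
    n_lagwin = 2 * max_shift + 1
    corr = np.empty((n_pairs, n_lagwin), dtype=np.float32)
    for start in range(0, n_pairs, chunk_pairs):
        stop = min(n_pairs, start + chunk_pairs)
        corr[start:stop] = _pair_correlations(kymo.intensity[start : stop + 1], max_shift)

    starts = np.arange(0, kymo.n_lines - window_lines + 1, step)
    # Mean correlation per window via a cumulative sum over pairs.
    csum = np.vstack([np.zeros((1, n_lagwin)), np.cumsum(corr, axis=0, dtype=np.float64)])
    win = (csum[starts + pairs_per_window] - csum[starts]) / pairs_per_window

    lags = np.arange(-max_shift, max_shift + 1)
    # Tie-break equal peaks toward the smaller |lag| (minimal-motion prior):
    # scan lags in order of increasing |lag| and keep the first maximum.
    order = np.argsort(np.abs(lags), kind="stable")
    peak_pos = order[np.argmax(win[:, order], axis=1)]
    peak_val = win[np.arange(win.shape[0]), peak_pos]

    shift = lags[peak_pos].astype(float)
    # Three-point parabolic sub-pixel refinement where neighbors exist.
    inner = (peak_pos > 0) & (peak_pos < n_lagwin - 1)
    idx = np.where(inner)[0]
    c0 = win[idx, peak_pos[idx]]
    cm = win[idx, peak_pos[idx] - 1]
    cp = win[idx, peak_pos[idx] + 1]
    denom = cm - 2.0 * c0 + cp
    delta = np.zeros_like(c0)
    ok = denom < 0
    delta[ok] = 0.5 * (cm[ok] - cp[ok]) / denom[ok]
    np.clip(delta, -0.5, 0.5, out=delta)
    shift[idx] += delta

    quality = np.clip(peak_val, 0.0, 1.0)
    v = shift * kymo.pixel_size_um / kymo.line_period_ms  # um/ms == mm/s
    v[quality == 0.0] = np.nan  # uncorrelatable (e.g. constant) windows

    time = (starts + window_lines / 2.0) * kymo.line_period_s
    return VelocityTrace(time=time, v=v, quality=quality)


def quality_filter(trace: VelocityTrace, min_quality: float) -> VelocityTrace:
    """Drop samples below a correlation-quality threshold, keeping time gaps."""
    if not 0 <= min_quality <= 1:
        raise ValueError("min_quality must lie in [0, 1]")
    keep = trace.quality >= min_quality
    if not np.any(keep):
        warnings.warn("quality filter removed every sample; returning an empty trace",
                      stacklevel=2)
    return VelocityTrace(
        trace.time[keep],
        trace.v[keep],
        trace.quality[keep],
        vessel_class=trace.vessel_class,
        metadata=dict(trace.metadata),
    )
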