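"""Synthetic kymographs, LFP traces and coupled ischemia scenarios.

Nothing here simulates biophysics; the generator reproduces the *statistics*
and geometry of the recordings so that every downstream stage can be tested
against machine-readable ground truth:

* **Kymographs** — dark RBC streaks on a bright plasma background (unlabeled
  cells exclude the intravascular dye), rendered so the local streak slope is
  exactly ``v(t) * line_period / pixel_size`` pixels per line.  Rows are
  successive lines (time), columns position; positive velocity moves streaks
  toward increasing column index.
* **LFP traces** — Gaussian baseline noise around a positive DC level, with
  spreading depolarizations (SDs) rendered as smooth trapezoidal negative DC
  deflections (sigmoidal 5 s fall, plateau, sigmoidal 5 s recovery) and
  post-ischemic potentials (PIPs) as band-limited oscillatory bursts.
* **Scenarios** — a coupled velocity time course with an ET-1-like drop,
  transient recovery above 80% of baseline and a late plateau, plus an LFP in
  which SD onsets fall strictly inside the interval where velocity sits below
  the trigger fraction of baseline, and every PIP begins only after the last
  SD has ended.

Event placement within a scenario is a deterministic function of the
configuration; the random seed drives only the noise streams (image noise,
streak positions, LFP noise, PIP phases), so two seeds give different noise
but identical ground-truth event tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.signal.windows import tukey

from .lfp import LfpTrace
from .lspiv import AliasingError, Kymograph

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "SdSpec",
    "PipSpec",
    "generate_kymograph",
    "generate_lfp",
    "generate_scenario",
    "scenario_ground_truth",
    "constant_profile",
]

#: Logistic steepness such that a transition spans 1% -> 99% over its width.
_LOGISTIC_SPAN = 2.0 * np.log(99.0)

SD_EDGE_S = 5.0  # sigmoidal fall/recovery time of a rendered SD


def _logistic(t: np.ndarray, center: float, width: float) -> np.ndarray:
    z = np.clip(_LOGISTIC_SPAN / width * (t - center), -700.0, 700.0)
    return 1.0 / (1.0 + np.exp(-z))


def constant_profile(v: float) -> Callable[[np.ndarray], np.ndarray]:
    return lambda t: np.full_like(np.asarray(t, dtype=float), float(v))


@dataclass(frozen=True)
class SdSpec:
    """Ground-truth spreading depolarization: a negative DC deflection."""

    onset: float  # s, start of the sigmoidal fall
    amplitude: float  # mV, positive magnitude of the deflection
    duration: float  # s, fall start to recovery end
    location: str = "injection_site"

    @property
    def end(self) -> float:
        return self.onset + self.duration

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.duration <= 2 * SD_EDGE_S:
            raise ValueError(
                f"SD needs positive amplitude and duration > {2 * SD_EDGE_S:.0f} s "
                f"(got {self.amplitude} mV, {self.duration} s)"
            )


@dataclass(frozen=True)
class PipSpec:
    """Ground-truth post-ischemic potential: a band-limited burst.

    ``rel_amplitude`` is the burst RMS expressed in units of the baseline
    noise RMS.
    """

    onset: float
    duration: float
    f_center: float = 6.0
    rel_amplitude: float = 4.0

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass
class ScenarioConfig:
    """Study conditions for a coupled ischemia scenario.

    Defaults follow the experimental conditions the package emulates:
    ~5 min of baseline, a rapid post-injection arteriolar velocity drop to
    ~30% of baseline, transient recovery above 80% starting ~45 min after
    injection, a late plateau near 35%, SDs triggered while velocity sits
    below 35% of baseline, a ~4 mV DC baseline, and 10 kHz sampling.
    Times are seconds, velocities mm/s, potentials mV.
    """

    injection_time: float = 300.0
    baseline_duration: float = 300.0
    duration: float = 3600.0
    baseline_vrbc: float = 6.0
    peak_drop_fraction: float = 0.30
    drop_duration: float = 60.0
    recovery_onset_time: float = 3000.0
    transient_peak_fraction: float = 0.85
    transient_hold: float = 120.0
    plateau_fraction: float = 0.35
    sd_trigger_fraction: float = 0.35
    lfp_baseline_mean: float = 4.0
    lfp_baseline_sd: float = 0.1
    n_sds: int = 2
    pip_rate_post_sd: float = 2.0  # events/min after the last SD
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.peak_drop_fraction < self.plateau_fraction <= 1:
            raise ValueError("need 0 <= peak_drop_fraction < plateau_fraction <= 1")
        if not self.injection_time < self.recovery_onset_time:
            raise ValueError("injection_time must precede recovery_onset_time")
        if self.baseline_duration > self.injection_time:
            raise ValueError("baseline_duration cannot exceed injection_time")
        if self.baseline_duration < 60.0:
            raise ValueError("need at least 60 s of pre-injection baseline")
        if self.recovery_onset_time >= self.duration:
            raise ValueError("recovery_onset_time must fall inside the recording")
        if self.baseline_vrbc <= 0 or self.lfp_baseline_sd <= 0:
            raise ValueError("baseline velocity and LFP noise SD must be positive")


@dataclass
class GroundTruth:
    """Machine-readable truth accompanying every generated object."""

    velocity_profile: Callable[[np.ndarray], np.ndarray] | None = None
    sd_events: list[SdSpec] = field(default_factory=list)
    pip_events: list[PipSpec] = field(default_factory=list)
    baseline_vrbc: float | None = None
    peak_drop_time: float | None = None
    recovery_crossing_time: float | None = None
    sub_threshold_interval: tuple[float, float] | None = None
    velocity_per_line: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "type": "sd",
                "onset_s": e.onset,
                "duration_s": e.duration,
                "amplitude_mV": e.amplitude,
                "band": "",
                "location": e.location,
            }
            for e in self.sd_events
        ] + [
            {
                "type": "pip",
                "onset_s": e.onset,
                "duration_s": e.duration,
                "amplitude_mV": e.rel_amplitude,
                "band": "theta" if e.f_center < 10 else "alpha",
                "location": "peri_injection",
            }
            for e in self.pip_events
        ]
        return pd.DataFrame(rows, columns=["type", "onset_s", "duration_s",
                                           "amplitude_mV", "band", "location"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Kymograph generator
# ---------------------------------------------------------------------------

def generate_kymograph(
    velocity_profile: Callable[[np.ndarray], np.ndarray] | float,
    n_lines: int,
    n_pixels: int = 64,
    line_period_ms: float = 1.2,
    pixel_size_um: float = 1.0,
    streak_density: float = 4.0,
    contrast: float = 0.35,
    noise_sd: float = 0.0,
    seed: int = 0,
    streak_sigma_px: float = 1.5,
) -> tuple[Kymograph, GroundTruth]:
    """Render a line-scan kymograph for a prescribed velocity time course.

    Streaks are Gaussian-profile dark bands on a unit background, all moving
    with the instantaneous velocity (plug flow); positions wrap around the
    line so streak density stays constant.  Ground truth carries the
    velocity sampled at every line.
    """
    if line_period_ms <= 0 or pixel_size_um <= 0:
        raise ValueError("line_period_ms and pixel_size_um must be positive")
    if callable(velocity_profile):
        profile = velocity_profile
    else:
        profile = constant_profile(float(velocity_profile))

    t_lines = np.arange(n_lines) * (line_period_ms / 1000.0)
    v_lines = np.asarray(profile(t_lines), dtype=float)
    disp = v_lines * line_period_ms / pixel_size_um  # px advanced between lines
    max_disp = float(np.max(np.abs(disp)))
    if max_disp >= n_pixels / 2:
        raise AliasingError(
            f"per-line displacement {max_disp:.2f} px >= half line width "
            f"({n_pixels / 2:.0f} px); velocity is aliased at this line period"
        )

    rng = np.random.default_rng(seed)
    n_streaks = max(1, int(round(streak_density)))
    x0 = rng.uniform(0.0, n_pixels, size=n_streaks)
    cumdisp = np.concatenate([[0.0], np.cumsum(disp[1:])])

    img = np.ones((n_lines, n_pixels), dtype=np.float32)
    half = int(np.ceil(4 * streak_sigma_px))
    offsets = np.arange(-half, half + 1)
    chunk = max(1, 2_000_000 // (n_streaks * offsets.size))
    for s in range(0, n_lines, chunk):
        e = min(n_lines, s + chunk)
        pos = (x0[:, None] + cumdisp[None, s:e]) % n_pixels  # (k, m)
        base = np.floor(pos)
        cols = (base[..., None] + offsets) % n_pixels  # (k, m, o)
        w = np.exp(-((base[..., None] + offsets - pos[..., None]) ** 2)
                   / (2.0 * streak_sigma_px**2))
        rows = np.broadcast_to(np.arange(s, e)[None, :, None], cols.shape)
        flat = (rows * n_pixels + cols.astype(np.int64)).ravel()
        dip = np.bincount(flat, weights=(contrast * w).ravel(),
                          minlength=n_lines * n_pixels)
        img -= dip.reshape(n_lines, n_pixels).astype(np.float32)
    if noise_sd > 0:
        img += noise_sd * rng.standard_normal(img.shape, dtype=np.float32)

    kymo = Kymograph(img, line_period_ms=line_period_ms, pixel_size_um=pixel_size_um)
    truth = GroundTruth(velocity_profile=profile, velocity_per_line=v_lines)
    return kymo, truth


# ---------------------------------------------------------------------------
# LFP generator
# ---------------------------------------------------------------------------

def _sd_depth(t: np.ndarray, sd: SdSpec) -> np.ndarray:
    """Smooth trapezoid: sigmoidal fall, plateau, sigmoidal recovery."""
    fall = _logistic(t, sd.onset + SD_EDGE_S / 2.0, SD_EDGE_S)
    rise = _logistic(t, sd.end - SD_EDGE_S / 2.0, SD_EDGE_S)
    return sd.amplitude * fall * (1.0 - rise)


def generate_lfp(
    duration: float,
    fs: float = 10_000.0,
    baseline_mean: float = 4.0,
    baseline_sd: float = 0.1,
    sd_specs: Sequence[SdSpec] = (),
    pip_specs: Sequence[PipSpec] = (),
    seed: int = 0,
) -> tuple[LfpTrace, GroundTruth]:
    """Render a DC-coupled LFP trace with known SD and PIP events."""
    sds = sorted(sd_specs, key=lambda e: e.onset)
    pips = sorted(pip_specs, key=lambda e: e.onset)
    if pips and fs < 2 * max(p.f_center for p in pips):
        raise ValueError("fs must be at least twice the highest PIP frequency")
    for ev in list(sds) + list(pips):
        if ev.onset < 0 or ev.end > duration:
            raise ValueError(f"event window ({ev.onset}, {ev.end}) outside [0, {duration}]")
    for a, b in zip(sds, sds[1:]):
        if b.onset < a.end:
            raise ValueError(
                f"overlapping SDs at {a.onset:.1f} s and {b.onset:.1f} s; "
                "detector semantics assume non-overlap"
            )

    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    x = baseline_mean + baseline_sd * rng.standard_normal(n)
    t = np.arange(n) / fs

    for sd in sds:
        i0 = max(0, int((sd.onset - 4 * SD_EDGE_S) * fs))
        i1 = min(n, int((sd.end + 4 * SD_EDGE_S) * fs))
        x[i0:i1] -= _sd_depth(t[i0:i1], sd)

    for pip in pips:
        i0 = max(0, int(pip.onset * fs))
        i1 = min(n, int(pip.end * fs))
        if i1 <= i0:
            continue
        phase = rng.uniform(0.0, 2 * np.pi)
        env = tukey(i1 - i0, alpha=0.25)
        amp = pip.rel_amplitude * np.sqrt(2.0) * baseline_sd  # RMS-matched
        x[i0:i1] += amp * env * np.sin(2 * np.pi * pip.f_center * (t[i0:i1] - pip.onset) + phase)

    trace = LfpTrace(x, fs=fs, t0=0.0)
    truth = GroundTruth(sd_events=list(sds), pip_events=list(pips))
    return trace, truth


# ---------------------------------------------------------------------------
# Coupled scenario
# ---------------------------------------------------------------------------

def _scenario_profile(cfg: ScenarioConfig) -> Callable[[np.ndarray], np.ndarray]:
    """Monotone-segment (PCHIP) velocity profile with a unique nadir."""
    v0 = cfg.baseline_vrbc
    d = max(cfg.peak_drop_fraction, 1e-3)
    t_nadir = cfg.injection_time + cfg.drop_duration
    rise_dur = 60.0
    t_rise0 = max(t_nadir + 30.0, cfg.recovery_onset_time - rise_dur)
    t_peak = cfg.recovery_onset_time + 20.0
    t_hold_end = t_peak + cfg.transient_hold
    t_plateau = min(t_hold_end + 120.0, cfg.duration - 1.0)
    knots_t = [0.0, cfg.injection_time, t_nadir, t_rise0, t_peak, t_hold_end,
               t_plateau, cfg.duration]
    creep = min(1.15 * d, 0.9 * cfg.transient_peak_fraction)  # slow reperfusion drift
    knots_f = [1.0, 1.0, d, max(d, creep),
               cfg.transient_peak_fraction, cfg.transient_peak_fraction,
               cfg.plateau_fraction, cfg.plateau_fraction]
    # PCHIP needs strictly increasing knots; nudge duplicates.
    tt, ff = [knots_t[0]], [knots_f[0]]
    for t, f in zip(knots_t[1:], knots_f[1:]):
        if t <= tt[-1]:
            t = tt[-1] + 1e-6
        tt.append(t)
        ff.append(f)
    interp = PchipInterpolator(np.array(tt), v0 * np.array(ff))
    t_max = tt[-1]

    def profile(t: np.ndarray) -> np.ndarray:
        t = np.clip(np.asarray(t, dtype=float), 0.0, t_max)
        return interp(t)

    return profile


def scenario_ground_truth(cfg: ScenarioConfig) -> GroundTruth:
    """Velocity profile plus deterministic SD/PIP event placement."""
    profile = _scenario_profile(cfg)
    dt = 0.05
    tg = np.arange(0.0, cfg.duration, dt)
    vg = profile(tg)
    v0 = cfg.baseline_vrbc

    post = tg >= cfg.injection_time
    peak_drop_time = float(tg[post][np.argmin(vg[post])])
    above = (tg >= peak_drop_time) & (vg >= 0.8 * v0)
    recovery_crossing = float(tg[above][0]) if np.any(above) else None

    below = post & (vg < cfg.sd_trigger_fraction * v0)
    truth = GroundTruth(
        velocity_profile=profile,
        baseline_vrbc=v0,
        peak_drop_time=peak_drop_time,
        recovery_crossing_time=recovery_crossing,
    )
    if not np.any(below):
        if cfg.n_sds > 0:
            raise ValueError(
                f"velocity never falls below the SD trigger "
                f"({cfg.sd_trigger_fraction:.2f} x baseline = "
                f"{cfg.sd_trigger_fraction * v0:.2f} mm/s; "
                f"minimum is {vg[post].min():.2f} mm/s)"
            )
        return truth
    t_a, t_b = float(tg[below][0]), float(tg[below][-1])
    truth.sub_threshold_interval = (t_a, t_b)

    if cfg.n_sds > 0:
        # Deterministic placement: onsets evenly spaced inside the
        # sub-threshold interval, durations cycling a fixed pattern.
        margin = min(10.0, 0.05 * (t_b - t_a))
        lo, hi = t_a + margin, t_b - margin
        dur_cycle = [45.0, 60.0, 30.0, 50.0]
        durations = [dur_cycle[i % len(dur_cycle)] for i in range(cfg.n_sds)]
        amp_cycle = [20.0, 15.0, 25.0, 18.0]
        gap = 30.0
        needed = sum(durations) + gap * (cfg.n_sds - 1)
        if needed > hi - lo:
            scale = max(0.1, (hi - lo - gap * (cfg.n_sds - 1)) / sum(durations))
            durations = [max(12.0, s * scale) for s in durations]
        slot = max(0.0, (hi - lo - sum(durations) - gap * (cfg.n_sds - 1)) / (cfg.n_sds + 1))
        t = lo + slot
        for i in range(cfg.n_sds):
            if t > hi:
                raise ValueError(
                    f"sub-threshold interval ({t_a:.0f}-{t_b:.0f} s) too short for "
                    f"{cfg.n_sds} non-overlapping SDs"
                )
            truth.sd_events.append(
                SdSpec(onset=t, amplitude=amp_cycle[i % len(amp_cycle)],
                       duration=durations[i])
            )
            t += durations[i] + gap + slot

    # PIPs strictly after the last SD end, at a fixed rate.
    start = (truth.sd_events[-1].end if truth.sd_events else cfg.injection_time) + 20.0
    stop = cfg.duration - 10.0
    if cfg.pip_rate_post_sd > 0 and stop > start:
        period = 60.0 / cfg.pip_rate_post_sd
        n_pips = int((stop - start) / period)
        dur_cycle = [2.3, 2.8, 2.2, 2.6]
        f_cycle = [6.0, 12.0]
        for i in range(n_pips):
            truth.pip_events.append(
                PipSpec(
                    onset=start + (i + 0.5) * period,
                    duration=dur_cycle[i % len(dur_cycle)],
                    f_center=f_cycle[i % len(f_cycle)],
                    rel_amplitude=4.0,
                )
            )
    return truth


def generate_scenario(
    cfg: ScenarioConfig,
    lfp_fs: float = 10_000.0,
    render_kymograph: bool = True,
    kymo_pixels: int = 64,
    kymo_line_period_ms: float = 1.2,
    kymo_pixel_size_um: float = 1.0,
    kymo_noise_sd: float = 0.05,
    streak_density: float = 4.0,
) -> tuple[Kymograph | None, LfpTrace, GroundTruth]:
    """Generate a coupled (kymograph, LFP, ground truth) triple.

    SD onsets in the LFP fall strictly inside the interval where the
    ground-truth velocity sits below ``sd_trigger_fraction`` of baseline, and
    every PIP begins after the final SD ends.  With ``render_kymograph=False``
    the (possibly very large) image is skipped and ``None`` returned in its
    place; the ground truth is identical either way.
    """
    truth = scenario_ground_truth(cfg)
    lfp, _ = generate_lfp(
        duration=cfg.duration,
        fs=lfp_fs,
        baseline_mean=cfg.lfp_baseline_mean,
        baseline_sd=cfg.lfp_baseline_sd,
        sd_specs=truth.sd_events,
        pip_specs=truth.pip_events,
        seed=cfg.seed,
    )
    kymo = None
    if render_kymograph:
        n_lines = int(round(cfg.duration / (kymo_line_period_ms / 1000.0)))
        kymo, ktruth = generate_kymograph(
            truth.velocity_profile,
            n_lines=n_lines,
            n_pixels=kymo_pixels,
            line_period_ms=kymo_line_period_ms,
            pixel_size_um=kymo_pixel_size_um,
            streak_density=streak_density,
            noise_sd=kymo_noise_sd,
            seed=cfg.seed + 1,
        )
        truth.velocity_per_line = ktruth.velocity_per_line
    return kymo, lfp, truth
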