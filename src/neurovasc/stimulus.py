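"""Band-limited optogenetic drive waveforms and stimulation schedules.

A band waveform superposes equal-amplitude sinusoids at every integer
frequency inside the band (endpoints inclusive: theta 2-10 Hz has nine
components), with seeded random phases to bound the crest factor.  The sum
is normalized to [0, 1] and uniformly quantized — by default to 12 bits at a
500 Hz sample rate, matching what a microcontroller DAC driving a laser
diode consumes.  Physical light intensity is metadata for the rig, not
modeled here.

Stimulation protocols present each band once per block, for 60 s with a 60 s
interstimulus interval, in seeded random order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lfp import DEFAULT_BANDS, BandDefinition

__all__ = [
    "StimulusWaveform",
    "StimulationSchedule",
    "ScheduleEntry",
    "synthesize_band_waveform",
    "build_schedule",
    "write_waveform_csv",
    "write_schedule_csv",
]


@dataclass
class StimulusWaveform:
    """A quantized, band-limited optical drive signal.

    ``samples`` holds the quantized normalized drive in [0, 1]; ``levels``
    the corresponding integer DAC codes in ``[0, 2**quantization_bits - 1]``;
    ``ideal`` the unquantized normalized waveform.
    """

    samples: np.ndarray
    levels: np.ndarray
    ideal: np.ndarray
    fs: float
    band: BandDefinition
    quantization_bits: int
    component_frequencies: np.ndarray
    phases: np.ndarray
    seed: int | None = None

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


class StimulusAliasingError(ValueError):
    """Band components at or above Nyquist for the requested sample rate."""


def synthesize_band_waveform(
    band: BandDefinition,
    duration: float = 60.0,
    fs: float = 500.0,
    bits: int = 12,
    seed: int | None = 0,
) -> StimulusWaveform:
    """Sum unit sinusoids at 1 Hz increments across the band and quantize.

    The quantizer is mid-rise with ``2**bits`` levels: level
    ``floor(x * 2**bits)`` (clipped), reconstructed at the level midpoint, so
    the worst-case reconstruction error is exactly ``2**-(bits + 1)`` of full
    scale.  Phases are drawn once per component from the seeded generator and
    recorded in the waveform metadata.
    """
    if duration <= 0 or fs <= 0:
        raise ValueError("duration and fs must be positive")
    if bits < 1:
        raise ValueError("bits must be >= 1")
    freqs = band.component_frequencies().astype(float)
    if freqs.size == 0:
        raise ValueError(f"band {band.name!r} contains no integer frequencies")
    offending = freqs[freqs >= fs / 2]
    if offending.size:
        raise StimulusAliasingError(
            f"band {band.name!r} components {offending.astype(int).tolist()} Hz "
            f"at/above Nyquist ({fs / 2:.1f} Hz) for fs = {fs} Hz"
        )

    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=freqs.size)
    t = np.arange(int(round(duration * fs))) / fs
    x = np.sin(2.0 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]).sum(axis=0)

    lo, hi = float(x.min()), float(x.max())
    ideal = (x - lo) / (hi - lo) if hi > lo else np.full_like(x, 0.5)

    n_levels = 2**bits
    levels = np.clip(np.floor(ideal * n_levels).astype(np.int64), 0, n_levels - 1)
    samples = (levels + 0.5) / n_levels

    return StimulusWaveform(
        samples=samples,
        levels=levels,
        ideal=ideal,
        fs=fs,
        band=band,
        quantization_bits=bits,
        component_frequencies=freqs.astype(int),
        phases=phases,
        seed=seed,
    )


@dataclass(frozen=True)
class ScheduleEntry:
    band: str
    start: float  # s
    duration: float  # s


@dataclass
class StimulationSchedule:
    """Ordered stimulation entries with fixed duration and interstimulus gap."""

    entries: list[ScheduleEntry]
    isi: float
    seed: int

    @property
    def total_duration(self) -> float:
        if not self.entries:
            return 0.0
        last = self.entries[-1]
        return last.start + last.duration


def build_schedule(
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    stim_duration: float = 60.0,
    isi: float = 60.0,
    n_blocks: int = 1,
    seed: int = 0,
) -> StimulationSchedule:
    """Per block, a seeded uniform permutation of the bands.

    Entries run ``stim_duration`` seconds and are separated by ``isi``
    seconds, across block boundaries too.
    """
    if not bands:
        raise ValueError("band list is empty")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = np.random.default_rng(seed)
    entries: list[ScheduleEntry] = []
    slot = 0
    for _ in range(n_blocks):
        for j in rng.permutation(len(bands)):
            entries.append(
                ScheduleEntry(bands[j].name, slot * (stim_duration + isi), stim_duration)
            )
            slot += 1
    return StimulationSchedule(entries=entries, isi=isi, seed=seed)


def write_waveform_csv(path, wf: StimulusWaveform) -> None:
    pd.DataFrame(
        {"time_s": wf.times, "level_0_1": wf.samples, "level_int": wf.levels}
    ).to_csv(path, index=False)


def write_schedule_csv(path, schedule: StimulationSchedule) -> None:
    pd.DataFrame(
        [{"band": e.band, "start_s": e.start, "duration_s": e.duration}
         for e in schedule.entries]
    ).to_csv(path, index=False)
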