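"""Bespoke statistical summaries and the per-experiment report.

Two small tests recur in this analysis: a chi-squared goodness-of-fit test of
event counts against a uniform split across locations (or stimulation
bands), and a Pearson correlation between spreading-depolarization AUC and
post-ischemic-potential counts.  Group-level mixed-effects comparisons are
deliberately out of scope; the report is a descriptive per-experiment
document.

``chi_squared_uniform`` offers the asymptotic closed form
``sum((o - e)**2 / e)`` with ``e = total / k`` and, for small totals, an
exact p-value by full multinomial enumeration (useful as a finite-sample
check on the asymptotic value).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .events import PipEvent, SdEvent
from .lspiv import VelocityTrace
from .segmentation import NeurovascularSummary, PeriodSegmentation

__all__ = [
    "TestResult",
    "chi_squared_uniform",
    "pearson_correlation",
    "build_report",
    "REPORT_SCHEMA_VERSION",
]

REPORT_SCHEMA_VERSION = "1.0"


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")
        if self.df < 1:
            raise ValueError("df must be >= 1")


def _round_sig(x: float, sig: int = 4) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + sig - 1)


def chi_squared_uniform(counts: Sequence[int], method: str = "asymptotic") -> TestResult:
    """Goodness-of-fit of counts against a uniform split across cells.

    ``method='asymptotic'`` uses the chi-squared survival function with
    ``df = k - 1``; ``method='exact'`` enumerates the full multinomial
    distribution under the uniform null and reports
    ``P(statistic >= observed)`` (only feasible for small totals).
    """
    counts = [int(c) for c in counts]
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ValueError("total count is zero")
    k = len(counts)
    if k < 2:
        raise ValueError("need at least two cells")
    e = total / k
    stat = float(sum((o - e) ** 2 / e for o in counts))
    df = k - 1
    if method == "asymptotic":
        p = float(sps.chi2.sf(stat, df))
        return TestResult(stat, df, p, "chi-squared goodness-of-fit (asymptotic)")
    if method == "exact":
        if math.comb(total + k - 1, k - 1) > 200_000:
            raise ValueError("total too large for exact multinomial enumeration")
        p = 0.0
        probs = np.full(k, 1.0 / k)
        for combo in itertools.combinations(range(total + k - 1), k - 1):
            # stars-and-bars: dividers -> composition of `total` into k cells
            cells = []
            prev = -1
            for c in combo:
                cells.append(c - prev - 1)
                prev = c
            cells.append(total + k - 2 - prev)
            s = sum((o - e) ** 2 / e for o in cells)
            if s >= stat - 1e-12:
                p += float(sps.multinomial.pmf(cells, n=total, p=probs))
        return TestResult(stat, df, min(1.0, p), "chi-squared goodness-of-fit (exact multinomial)")
    raise ValueError("method must be 'asymptotic' or 'exact'")


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson r with a two-sided p-value from the t-transform, df = n - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if x.size < 3:
        raise ValueError("need at least three points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in an input")
    res = sps.pearsonr(x, y)
    return TestResult(float(res.statistic), x.size - 2, float(res.pvalue),
                      "Pearson correlation (t-transform)")


def _test_to_dict(t: TestResult) -> dict:
    d = asdict(t)
    d["statistic"] = _round_sig(d["statistic"])
    d["p_value"] = _round_sig(d["p_value"])
    return d


def build_report(
    velocity: VelocityTrace,
    segmentation: PeriodSegmentation,
    sds: Sequence[SdEvent],
    pips: Sequence[PipEvent],
    summary: NeurovascularSummary | None = None,
    sd_location_counts: dict[str, int] | None = None,
    experiment_points: Sequence[tuple[float, int]] | None = None,
) -> dict:
    """Assemble the per-experiment JSON-ready report document.

    ``experiment_points`` are optional (total SD AUC, PIP count) pairs from
    several experiments; with three or more, the AUC-vs-PIP-count Pearson
    correlation is included, otherwise the entry is marked not applicable.
    Raises on mismatched time bases (events outside the velocity record,
    with slack for the final SD which may outlast the imaging).
    """
    t0, t1 = velocity.span
    for ev in sds:
        if ev.onset < t0 - 1.0 or ev.onset > t1 + 1.0:
            raise ValueError(
                f"SD onset {ev.onset:.1f} s outside velocity record "
                f"({t0:.1f}-{t1:.1f} s): mismatched time bases"
            )

    periods: dict[str, tuple[float, float] | None] = {
        "baseline": segmentation.baseline,
        "ischemia": segmentation.ischemia,
        "partial_recovery": segmentation.partial_recovery,
    }
    vrbc_stats = {}
    valid = np.isfinite(velocity.v)
    for name, per in periods.items():
        if per is None:
            vrbc_stats[name] = None
            continue
        m = valid & (velocity.time >= per[0]) & (velocity.time < per[1])
        vrbc_stats[name] = (
            {"mean_mm_s": float(np.mean(velocity.v[m])),
             "sd_mm_s": float(np.std(velocity.v[m])),
             "n": int(np.sum(m))}
            if np.any(m) else None
        )

    if sd_location_counts is None:
        sd_location_counts = {
            loc: sum(1 for e in sds if e.location == loc)
            for loc in ("injection_site", "peri_injection")
        }
    total_located = sum(sd_location_counts.values())
    location_test = (
        _test_to_dict(chi_squared_uniform(list(sd_location_counts.values())))
        if total_located > 0
        else "not applicable (no located SDs)"
    )

    if experiment_points is not None and len(experiment_points) >= 3:
        aucs = [p[0] for p in experiment_points]
        npips = [p[1] for p in experiment_points]
        try:
            auc_pip = _test_to_dict(pearson_correlation(aucs, npips))
        except ValueError as exc:
            auc_pip = f"not applicable ({exc})"
    else:
        auc_pip = "not applicable (needs >= 3 experiments)"

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "periods_s": {k: list(v) if v else None for k, v in periods.items()},
        "peak_drop_time_s": segmentation.peak_drop_time,
        "baseline_vrbc_mm_s": segmentation.baseline_vrbc,
        "vrbc_per_period": vrbc_stats,
        "sd_events": [
            {
                "onset_s": e.onset,
                "end_s": e.end,
                "amplitude_mV": e.amplitude,
                "duration_s": e.duration,
                "auc_mV_min": e.auc,
                "location": e.location,
                "delay_from_injection_min": e.delay_from_injection,
                "truncated": e.truncated,
            }
            for e in sds
        ],
        "pip_events": [
            {"onset_s": e.onset, "duration_s": e.duration,
             "bands": list(e.bands), "peak_z": e.peak_z}
            for e in pips
        ],
        "sd_location_counts": sd_location_counts,
        "sd_location_uniformity": location_test,
        "sd_auc_vs_pip_count": auc_pip,
    }
    if summary is not None:
        report["rbc_distance_mm"] = summary.rbc_distance_mm
        report["power_change_pct"] = summary.power_change_pct
        report["vrbc_fraction_at_sd_onset"] = summary.vrbc_fraction_at_sd_onset
    return report


def write_report(path, report: dict) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)
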