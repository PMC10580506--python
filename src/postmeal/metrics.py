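"""Postprandial glycemic outcome metrics from a CGM trace.

Implements the outcome set of a 5-h postprandial CGM protocol: window
mean glucose, peak and time-to-peak, total and incremental AUC, time in
/ above / below range, hypoglycemic episode detection, 30-min glucose
excursions, and MAGE (mean amplitude of glycemic excursions).

Conventions
-----------
* Window means use closed intervals: a reading at 120 min contributes to
  both the 0–120 and the 120–240 window.
* The peak is the highest reading *after* the baseline, over (0, t_end];
  ties are broken by the earliest time.
* AUCs are trapezoidal.  The incremental AUC (iAUC) subtracts the t = 0
  baseline G0; the ``net`` policy keeps negative area, ``positive_only``
  truncates sub-baseline segments at zero with linear interpolation at
  the baseline crossings.
* Range occupancy is the fraction of discrete readings (flash-monitor
  samples), not interpolated duration: in range is the closed interval
  [low, high], above/below are strict.
* A hypoglycemic episode is a maximal run of consecutive readings
  strictly below threshold; a single reading qualifies.
* MAGE follows the classical turning-point definition: amplitudes
  between consecutive local extrema of the trace, averaged over those
  exceeding one trace SD, counted in the direction (rising or falling)
  of the first qualifying amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trace import Episode, GlucoseTrace

#: the five reporting windows (min) used for mean glucose.
WINDOWS = ((0, 120), (0, 240), (0, 300), (120, 240), (240, 300))

#: glycemic target range bounds, mmol/L.
RANGE_LOW = 3.9
RANGE_HIGH = 10.0


def mean_glucose(trace: GlucoseTrace, t_start: float, t_end: float) -> float:
    """Arithmetic mean of readings with t_start <= t <= t_end."""
    mask = (trace.times >= t_start) & (trace.times <= t_end)
    if not mask.any():
        raise ValueError(f"no readings in window [{t_start}, {t_end}] min")
    return float(trace.values[mask].mean())


def peak_glucose(trace: GlucoseTrace) -> tuple[float, float]:
    """(peak mmol/L, time-to-peak min) over the post-baseline readings.

    The baseline reading itself is excluded; ties go to the earliest time.
    """
    if len(trace) < 2:
        raise ValueError("trace has no post-baseline readings")
    post_t = trace.times[1:]
    post_v = trace.values[1:]
    i = int(np.argmax(post_v))  # argmax returns the first maximum
    return float(post_v[i]), float(post_t[i])


def _check_t_end(trace: GlucoseTrace, t_end: float) -> int:
    idx = np.flatnonzero(trace.times == t_end)
    if idx.size == 0:
        raise ValueError(f"t_end={t_end} is not a sampled time of the trace")
    return int(idx[0])


def total_auc(trace: GlucoseTrace, t_end: float | None = None) -> float:
    """Trapezoidal area under the glucose curve over [0, t_end], mmol/L·min."""
    if t_end is None:
        t_end = trace.t_end
    i = _check_t_end(trace, t_end)
    return float(np.trapezoid(trace.values[: i + 1], trace.times[: i + 1]))


def incremental_auc(
    trace: GlucoseTrace, t_end: float | None = None, policy: str = "net"
) -> float:
    """Trapezoidal area of (G(t) − G0) over [0, t_end], mmol/L·min.

    ``policy='net'`` keeps area below baseline (may be negative);
    ``policy='positive_only'`` counts only area above baseline,
    splitting segments at baseline crossings.
    """
    if t_end is None:
        t_end = trace.t_end
    i = _check_t_end(trace, t_end)
    t = trace.times[: i + 1]
    d = trace.values[: i + 1] - trace.g0
    if policy == "net":
        return float(np.trapezoid(d, t))
    if policy != "positive_only":
        raise ValueError(f"policy must be 'net' or 'positive_only', got {policy!r}")
    area = 0.0
    for k in range(len(t) - 1):
        t1, t2 = t[k], t[k + 1]
        d1, d2 = d[k], d[k + 1]
        if d1 >= 0 and d2 >= 0:
            area += 0.5 * (d1 + d2) * (t2 - t1)
        elif d1 <= 0 and d2 <= 0:
            continue
        else:
            tc = t1 + d1 / (d1 - d2) * (t2 - t1)  # baseline crossing
            if d1 > 0:
                area += 0.5 * d1 * (tc - t1)
            else:
                area += 0.5 * d2 * (t2 - tc)
    return float(area)


def time_in_ranges(
    trace: GlucoseTrace, low: float = RANGE_LOW, high: float = RANGE_HIGH
) -> tuple[float, float, float]:
    """(tir, tar, tbr) percentages of readings in [low, high], > high, < low."""
    if low >= high:
        raise ValueError(f"low must be below high, got {low} >= {high}")
    v = trace.values
    n = v.size
    tar = float((v > high).sum()) / n * 100.0
    tbr = float((v < low).sum()) / n * 100.0
    return 100.0 - tar - tbr, tar, tbr


def detect_hypoglycemia(trace: GlucoseTrace, threshold: float = RANGE_LOW) -> list[Episode]:
    """Maximal runs of consecutive readings strictly below ``threshold``."""
    below = trace.values < threshold
    episodes: list[Episode] = []
    start = None
    for i, b in enumerate(below):
        if b and start is None:
            start = i
        elif not b and start is not None:
            episodes.append(_episode(trace, start, i - 1))
            start = None
    if start is not None:
        episodes.append(_episode(trace, start, len(below) - 1))
    return episodes


def _episode(trace: GlucoseTrace, i0: int, i1: int) -> Episode:
    seg = trace.values[i0 : i1 + 1]
    return Episode(
        onset_min=float(trace.times[i0]),
        end_min=float(trace.times[i1]),
        nadir_mmol_l=float(seg.min()),
    )


def excursions_30min(trace: GlucoseTrace) -> np.ndarray:
    """Successive 30-min glucose differences G(30k) − G(30(k−1)).

    Requires readings at every 30-min multiple up to the trace end; no
    interpolation is attempted.
    """
    k_max = int(trace.t_end // 30)
    grid = np.arange(0, (k_max + 1) * 30, 30, dtype=float)
    vals = np.array([trace.value_at(t) for t in grid])  # raises on a gap
    return np.diff(vals)


def mage(trace: GlucoseTrace) -> float:
    """Mean amplitude of glycemic excursions (classical turning-point rule).

    Amplitudes are differences between consecutive local extrema of the
    reading sequence; those exceeding one trace SD qualify, and the mean
    is taken over qualifying amplitudes in the direction of the first
    one.  Returns 0 when no amplitude exceeds 1 SD.
    """
    if len(trace) < 3:
        raise ValueError("MAGE requires at least 3 readings")
    v = trace.values
    sd = float(np.std(v, ddof=1))
    # collapse plateaus so turning-point detection is well defined
    keep = np.r_[True, np.diff(v) != 0]
    w = v[keep]
    if w.size < 2 or sd == 0:
        return 0.0
    ext = [w[0]]
    for i in range(1, w.size - 1):
        if (w[i] - w[i - 1]) * (w[i + 1] - w[i]) < 0:
            ext.append(w[i])
    ext.append(w[-1])
    diffs = np.diff(ext)
    qualifying = diffs[np.abs(diffs) > sd]
    if qualifying.size == 0:
        return 0.0
    direction = np.sign(qualifying[0])
    chosen = qualifying[np.sign(qualifying) == direction]
    return float(np.abs(chosen).mean())


@dataclass
class GlycemicSummary:
    """All outcome parameters of one trace."""

    subject_id: str
    arm: str
    g0: float
    means: dict[tuple[int, int], float]
    peak: float
    time_to_peak: float
    auc_total: float
    iauc: dict[int, float]
    mage: float
    delta_peak: float
    delta_low: float
    tir_pct: float
    tar_pct: float
    tbr_pct: float
    episodes: list[Episode]
    excursions: np.ndarray = field(repr=False)

    def scalars(self) -> dict[str, float]:
        """Flat name → value mapping of every scalar outcome."""
        out: dict[str, float] = {"fasting_glucose": self.g0}
        out["peak_glucose"] = self.peak
        out["time_to_peak_min"] = self.time_to_peak
        for (a, b), m in self.means.items():
            out[f"mean_glucose_{a}_{b}"] = m
        out["auc_total"] = self.auc_total
        for t, val in self.iauc.items():
            out[f"iauc_0_{t}"] = val
        out["mage"] = self.mage
        out["delta_peak"] = self.delta_peak
        out["delta_low"] = self.delta_low
        out["tir_pct"] = self.tir_pct
        out["tar_pct"] = self.tar_pct
        out["tbr_pct"] = self.tbr_pct
        for k, dg in enumerate(self.excursions, start=1):
            out[f"excursion_{30 * (k - 1)}_{30 * k}"] = float(dg)
        out["n_hypo_episodes"] = float(len(self.episodes))
        return out


def summarize(
    trace: GlucoseTrace,
    low: float = RANGE_LOW,
    high: float = RANGE_HIGH,
    iauc_policy: str = "net",
) -> GlycemicSummary:
    """Compute the full outcome set for one trace."""
    peak, ttp = peak_glucose(trace)
    means = {
        (a, b): mean_glucose(trace, a, b)
        for (a, b) in WINDOWS
        if a <= trace.t_end
    }
    iauc_times = [int(t) for t in np.arange(30, trace.t_end + 1, 30)]
    tir, tar, tbr = time_in_ranges(trace, low, high)
    return GlycemicSummary(
        subject_id=trace.subject_id,
        arm=trace.arm,
        g0=trace.g0,
        means=means,
        peak=peak,
        time_to_peak=ttp,
        auc_total=total_auc(trace),
        iauc={t: incremental_auc(trace, t, iauc_policy) for t in iauc_times},
        mage=mage(trace),
        delta_peak=peak - trace.g0,
        delta_low=float(trace.values.min()) - trace.g0,
        tir_pct=tir,
        tar_pct=tar,
        tbr_pct=tbr,
        episodes=detect_hypoglycemia(trace, low),
        excursions=excursions_30min(trace),
    )


@dataclass
class CohortSummary:
    """Per-arm mean ± SE of every scalar outcome, plus episode counts."""

    metrics: pd.DataFrame  # rows = metric, columns = (arm, 'mean'|'se')
    episodes: pd.DataFrame  # rows = arm: n, n_with_episode, pct_with_episode


def cohort_summarize(
    traces: list[GlucoseTrace], iauc_policy: str = "net"
) -> CohortSummary:
    """Aggregate traces by arm: mean and SE (sample SD/√n) per outcome."""
    by_arm: dict[str, list[GlycemicSummary]] = {}
    for tr in traces:
        by_arm.setdefault(tr.arm or "all", []).append(
            summarize(tr, iauc_policy=iauc_policy)
        )
    metric_cols: dict[tuple[str, str], pd.Series] = {}
    episode_rows = {}
    for arm, summaries in sorted(by_arm.items()):
        if len(summaries) < 2:
            raise ValueError(f"arm {arm!r} has fewer than 2 traces")
        df = pd.DataFrame([s.scalars() for s in summaries])
        metric_cols[(arm, "mean")] = df.mean()
        metric_cols[(arm, "se")] = df.std(ddof=1) / np.sqrt(len(df))
        n_with = sum(1 for s in summaries if s.episodes)
        episode_rows[arm] = {
            "n": len(summaries),
            "n_with_episode": n_with,
            "pct_with_episode": 100.0 * n_with / len(summaries),
        }
    metrics = pd.DataFrame(metric_cols)
    metrics.columns = pd.MultiIndex.from_tuples(metrics.columns, names=["arm", "stat"])
    return CohortSummary(metrics=metrics, episodes=pd.DataFrame(episode_rows).T)
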