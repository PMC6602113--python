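"""Summary statistics for Clarke-electrode O2 traces.

A trace is a strictly increasing time grid with one dissolved-O2 reading (μM)
per point.  The statistics mirror standard electrode-assay practice: strip the
pre-injection baseline, compute consumption rates as negated least-squares
slopes over a sliding window (10 s by default), and report the maximum rate.
Consumption is reported positive (O2 falling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Trace:
    """O2 time series: time (s, strictly increasing) vs concentration (μM)."""

    t: np.ndarray
    o2: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.o2 = np.asarray(self.o2, dtype=float)
        if self.t.ndim != 1 or self.t.size < 2:
            raise ValueError("trace needs at least 2 points")
        if self.o2.shape != self.t.shape:
            raise ValueError("time and O2 arrays differ in length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.t)) or not np.all(np.isfinite(self.o2)):
            raise ValueError("trace values must be finite")

    @property
    def span(self) -> float:
        return float(self.t[-1] - self.t[0])

    def __len__(self) -> int:
        return self.t.size


@dataclass
class RateSeries:
    """O2-consumption rate (μM/s, positive = O2 falling) vs window-center time."""

    t: np.ndarray
    rate: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.rate.shape != self.t.shape:
            raise ValueError("time and rate arrays differ in length")
        if self.t.size and np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def max_rate(self) -> float:
        return float(np.max(self.rate))


def strip_baseline(trace: Trace, baseline_s: float = 100.0) -> Trace:
    """Drop the baseline-stabilization prefix and re-zero time at the cut.

    Keeps all samples with ``t >= t[0] + baseline_s``; the irregularity of a
    non-uniform grid is preserved.
    """
    if baseline_s < 0:
        raise ValueError("baseline duration must be >= 0")
    if baseline_s == 0:
        return Trace(trace.t.copy(), trace.o2.copy(), dict(trace.metadata))
    cut = trace.t[0] + baseline_s
    keep = trace.t >= cut
    if keep.sum() < 2:
        raise ValueError(
            f"trace (span {trace.span:.6g} s) too short for a {baseline_s:.6g} s baseline"
        )
    return Trace(trace.t[keep] - trace.t[keep][0], trace.o2[keep], dict(trace.metadata))


def windowed_rate(trace: Trace, window_s: float = 10.0) -> RateSeries:
    """Sliding-window least-squares consumption rate.

    For every window of width ``window_s`` (advanced by one sample), the rate
    is the negated slope of the ordinary least-squares line through the
    (t, O2) points inside ``[t_i, t_i + window_s]``; the window is stamped at
    its center time.  Windows with fewer than two samples are skipped.
    """
    if window_s <= 0:
        raise ValueError("window width must be > 0")
    if trace.span < window_s:
        raise ValueError(
            f"trace span {trace.span:.6g} s shorter than window {window_s:.6g} s"
        )
    t, o2 = trace.t, trace.o2
    centers, rates = [], []
    for i in range(t.size):
        j = int(np.searchsorted(t, t[i] + window_s, side="right"))
        if j - i < 2:
            continue
        if t[j - 1] - t[i] < window_s - 1e-9:  # truncated trailing window
            break
        tw, ow = t[i:j], o2[i:j]
        tc = tw - tw.mean()
        slope = float(tc @ (ow - ow.mean()) / (tc @ tc))
        centers.append(0.5 * (tw[0] + tw[-1]))
        rates.append(-slope)
    if not rates:
        raise ValueError("no complete window fits inside the trace")
    return RateSeries(np.array(centers), np.array(rates))


def max_consumption_rate(
    trace: Trace, window_s: float = 10.0, baseline_s: float = 100.0
) -> float:
    """Maximum windowed O2-consumption rate after the baseline cut (μM/s)."""
    return windowed_rate(strip_baseline(trace, baseline_s), window_s).max_rate
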