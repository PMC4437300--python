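"""LTP quantification from evoked synaptic-response amplitude series.

A session is a series of evoked EPSP/EPSC peak amplitudes (nominally one
stimulus every 20 s) with a series-resistance log and a high-frequency
stimulation (HFS) event.  Quantification follows standard slice-physiology
practice: sessions whose series resistance drifts by more than 20% (or
whose baseline trends) are discarded; amplitudes are normalized to the
pre-HFS baseline mean; the LTP magnitude is the mean normalized response
25-30 min after HFS, in percent of baseline.

ΔLTP% between genotypes compares potentiation above baseline:
ΔLTP = 100 · (P_wt − P_ko) / P_wt with P = magnitude − 100, so that a
knockout with no LTP at all maps to a 100% reduction.  A raw-magnitude
ratio is available as an alternative convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .stats import pearson_regression

__all__ = [
    "LTPSeries",
    "QCFlags",
    "LTPResult",
    "DeltaLTPPoint",
    "qc_series",
    "ltp_magnitude",
    "delta_ltp",
    "density_ltp_correlation",
]

MAX_RS_CHANGE = 0.20  # fraction; strict inequality per the discard rule
DEFAULT_BASELINE_S = 300.0  # 5 min immediately preceding HFS
DEFAULT_WINDOW_MIN = (25.0, 30.0)


@dataclass
class LTPSeries:
    """One synaptic-plasticity session."""

    times_s: np.ndarray
    amplitudes: np.ndarray
    rs_mohm: Optional[np.ndarray]
    hfs_time_s: float
    baseline_window_s: Optional[tuple] = None

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.rs_mohm is not None:
            self.rs_mohm = np.asarray(self.rs_mohm, dtype=float)
            if self.rs_mohm.shape != self.times_s.shape:
                raise ValueError("series-resistance log must match times")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("stimulus times must be increasing")
        if self.baseline_window_s is None:
            self.baseline_window_s = (
                max(self.times_s[0], self.hfs_time_s - DEFAULT_BASELINE_S),
                self.hfs_time_s,
            )
        lo, hi = self.baseline_window_s
        if hi > self.hfs_time_s + 1e-9:
            raise ValueError("baseline window must precede HFS")


@dataclass
class QCFlags:
    rs_change_fraction: Optional[float]
    rs_ok: Optional[bool]  # None = indeterminate (no log)
    baseline_slope_per_min: float
    baseline_stable: bool

    @property
    def passed(self) -> bool:
        return bool(self.rs_ok) and self.baseline_stable


@dataclass
class LTPResult:
    normalized: np.ndarray
    times_s: np.ndarray
    magnitude_percent: float
    qc: QCFlags


def qc_series(series: LTPSeries, max_rs_change: float = MAX_RS_CHANGE,
              max_baseline_slope: float = 0.05) -> QCFlags:
    """Series-resistance and baseline-stability checks.

    Fails when the series resistance deviates from its initial value by
    strictly more than ``max_rs_change`` (default 20%).  An absent log
    leaves the Rs check *indeterminate* (not passed).  Baseline
    stability: the fitted linear trend of baseline amplitudes must stay
    below ``max_baseline_slope`` (fraction of baseline mean per minute).
    """
    if series.rs_mohm is None or series.rs_mohm.size == 0:
        rs_change, rs_ok = None, None
    else:
        rs0 = series.rs_mohm[0]
        rs_change = float(np.max(np.abs(series.rs_mohm - rs0)) / rs0)
        rs_ok = rs_change <= max_rs_change  # strict ">20%" discard rule
    lo, hi = series.baseline_window_s
    in_base = (series.times_s >= lo) & (series.times_s <= hi)
    tb, ab = series.times_s[in_base], series.amplitudes[in_base]
    if tb.size >= 3 and np.ptp(tb) > 0:
        slope = float(np.polyfit(tb / 60.0, ab, 1)[0] / np.mean(ab))
    else:
        slope = 0.0
    return QCFlags(rs_change, rs_ok, slope, abs(slope) <= max_baseline_slope)


def ltp_magnitude(series: LTPSeries, window_min: tuple = DEFAULT_WINDOW_MIN,
                  require_qc: bool = True, max_rs_change: float = MAX_RS_CHANGE) -> LTPResult:
    """Baseline-normalized LTP magnitude in the post-HFS window.

    Amplitudes are divided by the baseline-window mean; the magnitude is
    100 × the mean normalized amplitude at post-HFS times within
    ``window_min`` (endpoints inclusive, default 25-30 min).
    """
    qc = qc_series(series, max_rs_change=max_rs_change)
    if require_qc and not qc.passed:
        raise ValueError(f"series fails QC: {qc}")
    lo, hi = series.baseline_window_s
    in_base = (series.times_s >= lo) & (series.times_s <= hi)
    if not in_base.any():
        raise ValueError("no points in the baseline window")
    base_mean = float(np.mean(series.amplitudes[in_base]))
    if base_mean == 0:
        raise ValueError("zero baseline mean")
    norm = series.amplitudes / base_mean
    post_min = (series.times_s - series.hfs_time_s) / 60.0
    in_win = (post_min >= window_min[0] - 1e-9) & (post_min <= window_min[1] + 1e-9)
    if not in_win.any():
        raise ValueError(f"no points in the {window_min} min post-HFS window")
    return LTPResult(norm, series.times_s, 100.0 * float(np.mean(norm[in_win])), qc)


def delta_ltp(wt_percent: float, ko_percent: float, convention: str = "potentiation"):
    """Percentage reduction of LTP in the knockout relative to wild type.

    ``potentiation`` (default): ΔLTP = 100 (P_wt − P_ko)/P_wt with
    P = magnitude − 100; undefined (returns ``None`` with a reason) when
    the wild type shows no potentiation.  ``ratio``: 100 (wt − ko)/wt on
    raw magnitudes.
    """
    if convention == "ratio":
        return 100.0 * (wt_percent - ko_percent) / wt_percent, None
    if convention != "potentiation":
        raise ValueError("convention must be 'potentiation' or 'ratio'")
    p_wt = wt_percent - 100.0
    if p_wt <= 0:
        return None, "wild-type magnitude <= 100%: reduction of potentiation undefined"
    return 100.0 * (p_wt - (ko_percent - 100.0)) / p_wt, None


@dataclass
class DeltaLTPPoint:
    label: str
    wt_percent: float
    ko_percent: float
    density_pa_per_pf: float
    delta_ltp_percent: Optional[float] = field(default=None)

    def __post_init__(self):
        if self.delta_ltp_percent is None:
            self.delta_ltp_percent, _ = delta_ltp(self.wt_percent, self.ko_percent)


def density_ltp_correlation(points: Sequence) -> tuple:
    """Pearson r and regression F-test p for (density, ΔLTP%) points.

    ``points`` is a sequence of (density, delta_ltp) pairs or
    :class:`DeltaLTPPoint` records.
    """
    dens, dltp = [], []
    for p in points:
        if isinstance(p, DeltaLTPPoint):
            dens.append(p.density_pa_per_pf)
            dltp.append(p.delta_ltp_percent)
        else:
            dens.append(float(p[0]))
            dltp.append(float(p[1]))
    if len(dens) < 3:
        raise ValueError("need >= 3 points")
    reg = pearson_regression(dens, dltp)
    return reg.r, reg.p_value
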