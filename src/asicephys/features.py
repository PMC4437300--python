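"""Spike-train and passive membrane features from current-clamp step families.

Six per-cell features drive the downstream taxonomy:

* accommodating ratio — max over qualifying sweeps (< 400 pA injected,
  > 10 spikes in the 1 s step) of mean(last five ISIs) / mean(first five);
* spike delay — latency of the first spike on the rheobase sweep;
* rheobase — smallest step current eliciting at least one spike;
* maximal CV of ISI ratios — per sweep, ratios r_i = ISI_{i+1}/ISI_i,
  CV = sample SD / mean; the maximum CV over step sweeps;
* maximal mean firing rate — largest spike count in a 1 s step, in Hz;
* input resistance — steady-state voltage deflection over the injected
  hyperpolarizing current (-25 or -50 pA), in MOhm.

A feature that cannot be computed for a cell is reported as *missing with
a reason*, never silently defaulted — missingness propagates to the
classifier's case handling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .sweeps import SweepRecording

__all__ = [
    "SpikeTrain",
    "EphysFeatures",
    "EphysFeatureExtractor",
    "detect_spikes",
    "accommodating_ratio",
    "spike_delay_and_rheobase",
    "max_cv_isi_ratio",
    "max_mean_firing_rate",
    "input_resistance",
    "extract_features",
]

QUALIFYING_MAX_CURRENT_PA = 400.0
QUALIFYING_MIN_SPIKES = 10  # strictly more than 10 spikes per second
DEFAULT_THRESHOLD_MV = 0.0
REFRACTORY_MS = 1.0
STEADY_STATE_WINDOW_S = 0.2


@dataclass
class SpikeTrain:
    """Spike times (ms, relative to step onset) of one sweep."""

    times_ms: np.ndarray
    injected_pa: float
    step_duration_s: float

    def __post_init__(self):
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.times_ms.size and np.any(np.diff(self.times_ms) <= 0):
            raise ValueError("spike times must be strictly increasing")

    @property
    def n_spikes(self) -> int:
        return int(self.times_ms.size)

    @property
    def isis_ms(self) -> np.ndarray:
        return np.diff(self.times_ms)


@dataclass
class EphysFeatures:
    """The per-cell feature vector; missing entries carry a reason."""

    accommodating_ratio: Optional[float] = None
    spike_delay_ms: Optional[float] = None
    max_cv_isi_ratio: Optional[float] = None
    max_rate_hz: Optional[float] = None
    input_resistance_mohm: Optional[float] = None
    rheobase_pa: Optional[float] = None
    missing: Dict[str, str] = field(default_factory=dict)

    CLUSTER_FEATURES = (
        "accommodating_ratio",
        "spike_delay_ms",
        "max_cv_isi_ratio",
        "max_rate_hz",
    )

    def as_dict(self) -> dict:
        return {
            "accommodating_ratio": self.accommodating_ratio,
            "spike_delay_ms": self.spike_delay_ms,
            "max_cv_isi_ratio": self.max_cv_isi_ratio,
            "max_rate_hz": self.max_rate_hz,
            "input_resistance_mohm": self.input_resistance_mohm,
            "rheobase_pa": self.rheobase_pa,
        }


def detect_spikes(sweep: SweepRecording, threshold_mv: float = DEFAULT_THRESHOLD_MV) -> SpikeTrain:
    """Upward threshold crossings with a 1 ms refractory period.

    Spike times are reported at the crossing sample, in ms relative to
    the step onset (or trace start if no step window is set).
    """
    if sweep.clamp != "current":
        raise TypeError("spike detection requires a current-clamp sweep")
    v = sweep.samples
    above = v >= threshold_mv
    crossings = np.nonzero(above[1:] & ~above[:-1])[0] + 1
    onset = sweep.step_window[0] if sweep.step_window else 0.0
    duration = (sweep.step_window[1] - sweep.step_window[0]) if sweep.step_window else sweep.time_s[-1]
    times = (sweep.time_s[crossings] - onset) * 1000.0
    # enforce refractory: drop crossings within 1 ms of the last kept spike
    kept: List[float] = []
    for t in times:
        if not kept or t - kept[-1] >= REFRACTORY_MS:
            kept.append(float(t))
    return SpikeTrain(np.array(kept), sweep.injected_pa or 0.0, duration)


def accommodating_ratio(trains: Sequence[SpikeTrain]) -> float:
    """Maximum over qualifying sweeps of mean(last 5 ISIs)/mean(first 5 ISIs).

    A sweep qualifies when its injected current is below 400 pA and it
    fires more than 10 spikes within its step.  Raises ``ValueError``
    when no sweep qualifies (the caller records the feature as missing).
    """
    ratios = []
    for tr in trains:
        if tr.injected_pa >= QUALIFYING_MAX_CURRENT_PA or tr.injected_pa <= 0:
            continue
        if tr.n_spikes <= QUALIFYING_MIN_SPIKES:
            continue
        isis = tr.isis_ms
        ratios.append(float(np.mean(isis[-5:]) / np.mean(isis[:5])))
    if not ratios:
        raise ValueError("no qualifying sweep (< 400 pA with > 10 spikes)")
    return max(ratios)


def spike_delay_and_rheobase(trains: Sequence[SpikeTrain]) -> tuple:
    """First-spike latency on the rheobase (smallest spiking) sweep.

    Returns ``(delay_ms, rheobase_pa)``; raises when no sweep spikes.
    """
    spiking = [tr for tr in trains if tr.n_spikes > 0 and tr.injected_pa > 0]
    if not spiking:
        raise ValueError("no depolarizing sweep with spikes")
    rheo = min(spiking, key=lambda tr: tr.injected_pa)
    return float(rheo.times_ms[0]), float(rheo.injected_pa)


def max_cv_isi_ratio(trains: Sequence[SpikeTrain]) -> float:
    """Maximum over sweeps of the CV (sample SD / mean) of successive ISI ratios."""
    cvs = []
    for tr in trains:
        isis = tr.isis_ms
        if isis.size < 3:  # need >= 2 ratios for a CV
            continue
        ratios = isis[1:] / isis[:-1]
        mean = float(np.mean(ratios))
        if mean == 0.0:
            continue
        cvs.append(float(np.std(ratios, ddof=1)) / mean)
    if not cvs:
        raise ValueError("no sweep with >= 4 spikes (>= 2 ISI ratios)")
    return max(cvs)


def max_mean_firing_rate(trains: Sequence[SpikeTrain]) -> float:
    """Largest spike count over 1 s step sweeps, expressed in Hz."""
    best = 0.0
    for tr in trains:
        if tr.step_duration_s <= 0:
            continue
        best = max(best, tr.n_spikes / tr.step_duration_s)
    return best


def input_resistance(sweep: SweepRecording) -> float:
    """Steady-state voltage change over hyperpolarizing current, in MOhm.

    The steady state is the mean of the final 200 ms of the step; the
    baseline is the mean of the pre-step samples.
    """
    if sweep.clamp != "current":
        raise TypeError("input resistance requires a current-clamp sweep")
    i_pa = sweep.injected_pa
    if i_pa is None or i_pa >= 0:
        raise ValueError("input resistance needs a hyperpolarizing (-25/-50 pA) sweep")
    if sweep.step_window is None:
        raise ValueError("sweep lacks a step window")
    start, end = sweep.step_window
    base = sweep.samples[sweep.time_s < start]
    # step is active on [start, end): keep the end sample out of the window
    ss = sweep.samples[(sweep.time_s >= end - STEADY_STATE_WINDOW_S) & (sweep.time_s < end)]
    if base.size == 0 or ss.size == 0:
        raise ValueError("trace too short for baseline/steady-state windows")
    dv_mv = float(np.mean(ss) - np.mean(base))
    # mV / pA = GOhm; report MOhm, positive by convention
    return abs(dv_mv / i_pa) * 1000.0


def extract_features(
    sweeps: Sequence[SweepRecording], threshold_mv: float = DEFAULT_THRESHOLD_MV
) -> EphysFeatures:
    """Assemble the six-feature vector of one cell from its step family."""
    if not sweeps:
        raise ValueError("empty recording")
    feats = EphysFeatures()
    depol = [s for s in sweeps if (s.injected_pa or 0) > 0]
    trains = [detect_spikes(s, threshold_mv) for s in depol]

    try:
        feats.accommodating_ratio = accommodating_ratio(trains)
    except ValueError as err:
        feats.missing["accommodating_ratio"] = str(err)
    try:
        delay, rheo = spike_delay_and_rheobase(trains)
        feats.spike_delay_ms, feats.rheobase_pa = delay, rheo
    except ValueError as err:
        feats.missing["spike_delay_ms"] = str(err)
        feats.missing["rheobase_pa"] = str(err)
    try:
        feats.max_cv_isi_ratio = max_cv_isi_ratio(trains)
    except ValueError as err:
        feats.missing["max_cv_isi_ratio"] = str(err)
    feats.max_rate_hz = max_mean_firing_rate(trains) if trains else 0.0

    hyper = [s for s in sweeps if (s.injected_pa or 0) in (-25.0, -50.0)]
    if hyper:
        feats.input_resistance_mohm = float(
            np.mean([input_resistance(s) for s in hyper])
        )
    else:
        feats.missing["input_resistance_mohm"] = "no -25/-50 pA hyperpolarizing sweep"
    return feats


class EphysFeatureExtractor(BaseEstimator, TransformerMixin):
    """Transformer: list of per-cell sweep families -> feature DataFrame.

    ``transform`` accepts an iterable of sweep collections (one per cell)
    and returns a DataFrame with one row per cell and the six feature
    columns, plus a ``missing`` column concatenating the per-feature
    reasons (empty string when complete).
    """

    def __init__(self, threshold_mv: float = DEFAULT_THRESHOLD_MV):
        self.threshold_mv = threshold_mv

    def fit(self, X, y=None):  # stateless
        return self

    def transform(self, X) -> pd.DataFrame:
        rows = []
        for cell in X:
            f = extract_features(cell, self.threshold_mv)
            row = f.as_dict()
            row["missing"] = "; ".join(f"{k}: {v}" for k, v in f.missing.items())
            rows.append(row)
        return pd.DataFrame(rows)
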