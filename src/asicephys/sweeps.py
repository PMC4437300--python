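"""Stimulus-locked sweep container shared by all trace-analysis stages.

A :class:`SweepRecording` is one voltage trace (current clamp, mV) or one
current trace (voltage clamp, pA) together with the stimulus metadata that
downstream feature extraction and kinetics fitting need: the injected step
current, the step or agonist-pulse window, the sampling rate, and — for
voltage-clamp sweeps — the test pH and holding potential.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["SweepRecording"]


@dataclass
class SweepRecording:
    """One stimulus-locked trace with its acquisition metadata.

    Parameters
    ----------
    time_s : ndarray
        Uniformly spaced time base in seconds, starting at 0.
    samples : ndarray
        Membrane potential (mV, current clamp) or membrane current
        (pA, voltage clamp), one value per time point.
    clamp : {"current", "voltage"}
        Recording mode; decides the physical unit of ``samples``.
    sampling_khz : float
        Sampling rate in kHz.
    injected_pa : float, optional
        Amplitude of the injected current step (current clamp only).
    step_window : (float, float), optional
        Start and end of the current step, in seconds.
    pulse_window : (float, float), optional
        Start and end of the agonist (low-pH) application, in seconds.
    ph : float, optional
        Test pH of the applied solution (voltage clamp).
    holding_mv : float, optional
        Holding potential in mV (voltage clamp).
    meta : dict
        Free-form extras (seed, planted parameters, labels).
    """

    time_s: np.ndarray
    samples: np.ndarray
    clamp: str
    sampling_khz: float
    injected_pa: Optional[float] = None
    step_window: Optional[tuple] = None
    pulse_window: Optional[tuple] = None
    ph: Optional[float] = None
    holding_mv: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.clamp not in ("current", "voltage"):
            raise ValueError(f"clamp must be 'current' or 'voltage', got {self.clamp!r}")
        if self.time_s.shape != self.samples.shape:
            raise ValueError("time_s and samples must have identical shapes")
        if self.sampling_khz <= 0:
            raise ValueError("sampling rate must be positive")
        for win, name in ((self.step_window, "step_window"), (self.pulse_window, "pulse_window")):
            if win is not None:
                lo, hi = win
                if not (0 <= lo < hi <= self.time_s[-1] + 1e-12):
                    raise ValueError(f"{name} {win} not inside the trace")

    @property
    def units(self) -> str:
        return "mV" if self.clamp == "current" else "pA"

    @property
    def dt(self) -> float:
        """Sample interval in seconds."""
        return 1.0 / (self.sampling_khz * 1000.0)

    def window_mask(self, window: tuple) -> np.ndarray:
        lo, hi = window
        return (self.time_s >= lo - 1e-12) & (self.time_s <= hi + 1e-12)
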