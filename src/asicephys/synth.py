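"""Synthetic electrophysiology, plasticity, and behavior generators.

Every input class the pipeline consumes can be generated here with known
planted parameters, so all downstream stages are testable end to end
without recorded data:

* current-clamp step families for seven firing phenotypes
  (accommodating, stuttering, delay-firing, fast-spiking, late-spiking,
  early-spiking, low-threshold bursting);
* proton-evoked inward currents with exponential desensitization and a
  steady-state component;
* normalized pH-response families following a Hill law in [H+];
* quadratic I-V point tables with a planted reversal potential;
* repeated-pulse amplitude series with exponential cumulative run-down
  (tachyphylaxis);
* evoked-EPSP amplitude series with baseline/plateau structure around an
  HFS event plus a series-resistance log;
* freezing-bout sequences under a stated conditioning protocol;
* labeled multi-phenotype cohorts for classifier-recovery studies.

All randomness flows from the single ``SimConfig.seed`` through a
counter-based stream split: the k-th draw from a config uses
``SeedSequence((seed, k))``, so a fresh config with the same seed replays
byte-identical outputs regardless of platform.

Spikes are rendered as stereotyped 2 ms triangular depolarizations to
+30 mV whose 0 mV upstroke crossing falls exactly on the planted spike
time — only spike times matter downstream, so waveform realism is not a
goal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .behavior import FreezingSession, ProtocolSpec
from .kinetics import HillFit
from .plasticity import LTPSeries
from .sweeps import SweepRecording

__all__ = [
    "PHENOTYPES",
    "PhenotypeSpec",
    "SimConfig",
    "gen_step_family",
    "gen_asic_current",
    "gen_ph_response",
    "gen_iv_points",
    "gen_tachyphylaxis_series",
    "gen_ltp_series",
    "gen_freezing_session",
    "gen_cohort",
    "bla_cohort_specs",
    "cel_cohort_specs",
]

PHENOTYPES = (
    "accommodating",
    "stuttering",
    "delay_firing",
    "fast_spiking",
    "late_spiking",
    "early_spiking",
    "low_threshold_bursting",
)

BASELINE_MV = -65.0
SPIKE_PEAK_MV = 30.0
SPIKE_RISE_MS = 1.0
SPIKE_FALL_MS = 1.0
MEMBRANE_TAU_S = 0.02


@dataclass
class PhenotypeSpec:
    """Planted firing-phenotype parameters of one cell type.

    ``accommodation_factor`` is the target ratio of late to early mean
    ISIs; ``first_spike_delay_ms`` is the latency at rheobase;
    ``cv_isi`` is the target maximal CV of ISI ratios (realized exactly
    only for regular/accommodating trains, approximately for bursting
    ones); burst parameters shape the stuttering/bursting phenotypes.
    """

    name: str
    accommodation_factor: float = 1.0
    first_spike_delay_ms: float = 20.0
    max_rate_hz: float = 30.0
    input_resistance_mohm: float = 150.0
    rheobase_pa: float = 75.0
    cv_isi: float = 0.05
    burst_len: int = 3
    intra_burst_isi_ms: float = 8.0
    gap_ms: float = 150.0
    gap_jitter_ms: float = 0.0

    def __post_init__(self):
        if self.name not in PHENOTYPES:
            raise ValueError(
                f"unknown phenotype {self.name!r}; valid names: {', '.join(PHENOTYPES)}"
            )
        if self.first_spike_delay_ms < 0:
            raise ValueError("first-spike delay must be non-negative")
        if self.max_rate_hz < 0:
            raise ValueError("max rate must be non-negative")


@dataclass
class SimConfig:
    """Seed, acquisition parameters, and noise levels for all generators.

    A fresh config with the same field values replays identical outputs;
    each generator call consumes one child stream of the seed.
    """

    seed: int = 0
    sampling_khz: float = 10.0
    step_amps_pa: Tuple[float, ...] = (-50.0, -25.0, 25.0, 50.0, 75.0, 100.0, 150.0, 200.0, 300.0)
    step_duration_s: float = 1.0
    step_onset_s: float = 0.1
    noise_mv: float = 0.0
    noise_pa: float = 0.0
    _counter: int = field(default=0, repr=False, compare=False)

    def __post_init__(self):
        if self.sampling_khz <= 0:
            raise ValueError("sampling rate must be positive")

    def rng(self) -> np.random.Generator:
        """Next counter-split child stream of the config seed."""
        g = np.random.default_rng(np.random.SeedSequence((int(self.seed), self._counter)))
        self._counter += 1
        return g


# --------------------------------------------------------------------------
# spike-time construction per phenotype


def _geometric_train(delay_ms, n_spikes, factor, window_ms):
    """Spike train with geometric ISIs: mean(last 5)/mean(first 5) = factor."""
    m = n_spikes - 1  # ISI count
    if m < 1:
        return np.array([delay_ms])
    g = factor ** (1.0 / (m - 5)) if m > 5 else 1.0
    weights = g ** np.arange(m)
    isi0 = (window_ms - delay_ms) * 0.98 / weights.sum()
    return delay_ms + np.concatenate([[0.0], np.cumsum(isi0 * weights)])


def _regular_train(delay_ms, n_spikes, window_ms):
    if n_spikes == 1:
        return np.array([delay_ms])
    isi = (window_ms - delay_ms) * 0.98 / (n_spikes - 1)
    return delay_ms + isi * np.arange(n_spikes)


def _burst_train(delay_ms, spec: PhenotypeSpec, window_ms, rng, n_bursts=None):
    times = []
    t = delay_ms
    b = 0
    while t < window_ms * 0.99 and (n_bursts is None or b < n_bursts):
        for k in range(spec.burst_len):
            tt = t + k * spec.intra_burst_isi_ms
            if tt >= window_ms * 0.99:
                break
            times.append(tt)
        gap = spec.gap_ms + (rng.uniform(-1, 1) * spec.gap_jitter_ms if spec.gap_jitter_ms else 0.0)
        t = t + (spec.burst_len - 1) * spec.intra_burst_isi_ms + max(gap, spec.intra_burst_isi_ms)
        b += 1
    return np.array(times)


def _spike_times_for(spec: PhenotypeSpec, amp_pa: float, cfg: SimConfig, rng) -> np.ndarray:
    """Planted spike times (ms from step onset) for one depolarizing sweep."""
    if amp_pa < spec.rheobase_pa:
        return np.array([])
    window_ms = cfg.step_duration_s * 1000.0
    amps = [a for a in cfg.step_amps_pa if a >= spec.rheobase_pa]
    top = max(amps) if amps else amp_pa
    frac = 0.0 if top == spec.rheobase_pa else (amp_pa - spec.rheobase_pa) / (top - spec.rheobase_pa)
    delay = spec.first_spike_delay_ms / (1.0 + 3.0 * frac)

    if spec.name in ("accommodating",):
        n = max(2, round((12 + (spec.max_rate_hz - 12) * frac) * cfg.step_duration_s))
        return _geometric_train(delay, n, spec.accommodation_factor, window_ms)
    if spec.name == "fast_spiking":
        n = max(2, round(spec.max_rate_hz * (0.5 + 0.5 * frac) * cfg.step_duration_s))
        return _regular_train(delay, n, window_ms)
    if spec.name in ("delay_firing", "late_spiking", "early_spiking"):
        # delay is the signature: keep the planted latency on the rheobase sweep
        if frac == 0.0:
            delay = spec.first_spike_delay_ms
        n_max = max(1, round(spec.max_rate_hz * cfg.step_duration_s))
        n = max(1, round(n_max * (0.3 + 0.7 * frac)))
        # fit whatever spikes remain after the delay
        n = min(n, max(1, int((window_ms - delay) / 20.0)))
        return _regular_train(delay, n, window_ms)
    if spec.name == "stuttering":
        return _burst_train(delay, spec, window_ms, rng)
    if spec.name == "low_threshold_bursting":
        burst = _burst_train(delay, spec, window_ms, rng, n_bursts=1)
        rest_start = (burst[-1] if burst.size else delay) + spec.gap_ms
        n_rest = max(0, round(spec.max_rate_hz * frac * cfg.step_duration_s * 0.5))
        rest = (
            _regular_train(rest_start, n_rest, window_ms)
            if n_rest and rest_start < window_ms * 0.9
            else np.array([])
        )
        return np.concatenate([burst, rest[rest > (burst[-1] if burst.size else 0)]])
    raise ValueError(f"unknown phenotype {spec.name!r}")  # pragma: no cover


def _render_sweep(spec: PhenotypeSpec, amp_pa: float, spike_ms: np.ndarray, cfg: SimConfig, rng) -> SweepRecording:
    dt = 1.0 / (cfg.sampling_khz * 1000.0)
    t_end = cfg.step_onset_s + cfg.step_duration_s + 0.1
    t = np.arange(0.0, t_end + dt / 2, dt)
    v = np.full_like(t, BASELINE_MV)
    # passive membrane charging toward R*I during the step
    dv = amp_pa * spec.input_resistance_mohm / 1000.0  # mV
    on, off = cfg.step_onset_s, cfg.step_onset_s + cfg.step_duration_s
    in_step = (t >= on) & (t < off)
    v[in_step] += dv * (1.0 - np.exp(-(t[in_step] - on) / MEMBRANE_TAU_S))
    after = t >= off
    v_off = dv * (1.0 - math.exp(-cfg.step_duration_s / MEMBRANE_TAU_S))
    v[after] += v_off * np.exp(-(t[after] - off) / MEMBRANE_TAU_S)
    # stereotyped spikes: 0 mV upstroke crossing exactly at the planted time
    base_at = BASELINE_MV + (dv if amp_pa > 0 else 0.0)
    rise_frac = (0.0 - base_at) / (SPIKE_PEAK_MV - base_at)
    for s_ms in spike_ms:
        t_cross = on + s_ms / 1000.0
        t_start = t_cross - rise_frac * SPIKE_RISE_MS / 1000.0
        t_peak = t_start + SPIKE_RISE_MS / 1000.0
        t_end_sp = t_peak + SPIKE_FALL_MS / 1000.0
        seg = (t >= t_start) & (t <= t_end_sp)
        ts = t[seg]
        up = ts <= t_peak
        wave = np.where(
            up,
            base_at + (SPIKE_PEAK_MV - base_at) * (ts - t_start) / (SPIKE_RISE_MS / 1000.0),
            SPIKE_PEAK_MV + (base_at - SPIKE_PEAK_MV) * (ts - t_peak) / (SPIKE_FALL_MS / 1000.0),
        )
        v[seg] = np.maximum(v[seg], wave)
    if cfg.noise_mv > 0:
        v = v + rng.normal(0.0, cfg.noise_mv, size=v.shape)
    return SweepRecording(
        time_s=t,
        samples=v,
        clamp="current",
        sampling_khz=cfg.sampling_khz,
        injected_pa=amp_pa,
        step_window=(on, off),
        meta={"phenotype": spec.name, "planted_spike_ms": spike_ms, "seed": cfg.seed},
    )


def gen_step_family(spec: PhenotypeSpec, cfg: SimConfig) -> List[SweepRecording]:
    """Current-clamp step family of one cell with planted spike times.

    Step amplitudes must be strictly increasing.  Hyperpolarizing steps
    carry a steady-state deflection equal to the planted input
    resistance times the injected current; depolarizing steps at or
    above rheobase carry phenotype-shaped spike trains.
    """
    amps = cfg.step_amps_pa
    if any(b <= a for a, b in zip(amps, amps[1:])):
        raise ValueError("step amplitudes must be strictly increasing")
    if spec.first_spike_delay_ms >= cfg.step_duration_s * 1000.0:
        raise ValueError(
            f"planted delay {spec.first_spike_delay_ms} ms exceeds the "
            f"{cfg.step_duration_s} s step; lengthen the step"
        )
    rng = cfg.rng()
    sweeps = []
    for amp in amps:
        spikes = _spike_times_for(spec, amp, cfg, rng) if amp > 0 else np.array([])
        sweeps.append(_render_sweep(spec, amp, spikes, cfg, rng))
    return sweeps


# --------------------------------------------------------------------------
# voltage-clamp and derived-table generators


def gen_asic_current(
    peak_pa: float,
    tau_ms: float,
    steady_pa: float,
    pulse: Tuple[float, float],
    cfg: SimConfig,
    ph: float = 5.0,
    holding_mv: float = -60.0,
) -> SweepRecording:
    """Proton-evoked current: zero before the pulse, then
    (peak − steady)·exp(−t/τ) + steady during it, plus Gaussian noise."""
    onset, duration = pulse
    if duration <= 0:
        raise ValueError("pulse duration must be positive")
    if tau_ms <= 0:
        raise ValueError("tau must be positive")
    dt = 1.0 / (cfg.sampling_khz * 1000.0)
    t_end = onset + duration + 0.1
    t = np.arange(0.0, t_end + dt / 2, dt)
    if onset < 0 or onset + duration > t[-1] + 1e-12:
        raise ValueError("pulse must lie inside the trace")
    i = np.zeros_like(t)
    in_pulse = (t >= onset) & (t <= onset + duration)
    rel = t[in_pulse] - onset
    i[in_pulse] = (peak_pa - steady_pa) * np.exp(-rel / (tau_ms / 1000.0)) + steady_pa
    if cfg.noise_pa > 0:
        i = i + cfg.rng().normal(0.0, cfg.noise_pa, size=i.shape)
    return SweepRecording(
        time_s=t,
        samples=i,
        clamp="voltage",
        sampling_khz=cfg.sampling_khz,
        pulse_window=(onset, onset + duration),
        ph=ph,
        holding_mv=holding_mv,
        meta={"planted": {"peak_pa": peak_pa, "tau_ms": tau_ms, "steady_pa": steady_pa},
              "seed": cfg.seed},
    )


def gen_ph_response(
    hill: HillFit, ph_values: Sequence[float], noise_sd: float, cfg: SimConfig
) -> pd.DataFrame:
    """Normalized peak responses along a pH series, Hill law in [H+]."""
    ph_values = np.asarray(ph_values, dtype=float)
    if ph_values.size == 0:
        raise ValueError("ph_values must be non-empty")
    if np.any((ph_values < 4.0) | (ph_values > 8.0)):
        raise ValueError("pH values must lie within [4, 8]")
    resp = hill.predict(ph_values)
    if noise_sd > 0:
        resp = resp + cfg.rng().normal(0.0, noise_sd, size=resp.shape)
    return pd.DataFrame({"ph": ph_values, "response": resp})


def gen_iv_points(
    vrev_mv: float,
    voltages_mv: Sequence[float],
    curvature: float,
    cfg: SimConfig,
    slope_pa_per_mv: float = 5.0,
    noise_pa: float = 0.0,
) -> pd.DataFrame:
    """I-V table from I(V) = slope·(V − vrev) + curvature·(V − vrev)².

    The planted reversal is the guaranteed in-span zero crossing; the
    voltage grid must span it.
    """
    v = np.asarray(voltages_mv, dtype=float)
    if not (v.min() <= vrev_mv <= v.max()):
        raise ValueError(
            f"planted reversal {vrev_mv} mV outside voltage span "
            f"[{v.min()}, {v.max()}]: interpolation contract violated"
        )
    if curvature != 0.0:
        other_root = vrev_mv - slope_pa_per_mv / curvature
        if v.min() <= other_root <= v.max():
            raise ValueError(
                f"curvature {curvature} puts a second zero crossing at "
                f"{other_root:.1f} mV inside the span; reduce |curvature|"
            )
    dv = v - vrev_mv
    i = slope_pa_per_mv * dv + curvature * dv**2
    if noise_pa > 0:
        i = i + cfg.rng().normal(0.0, noise_pa, size=i.shape)
    return pd.DataFrame({"v_mv": v, "i_pa": i})


def gen_tachyphylaxis_series(
    tau_s: float,
    plateau: float,
    interval_s: float,
    n_pulses: int,
    cfg: SimConfig,
    noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Normalized peak amplitudes under repeated agonist pulses:
    amplitude(t) = (1 − plateau)·exp(−t/τ) + plateau, t = 0 at pulse 1."""
    if n_pulses < 3:
        raise ValueError("need at least 3 pulses for a fittable series")
    if interval_s <= 0:
        raise ValueError("inter-pulse interval must be positive")
    t = interval_s * np.arange(n_pulses)
    amp = (1.0 - plateau) * np.exp(-t / tau_s) + plateau
    if noise_sd > 0:
        noise = cfg.rng().normal(0.0, noise_sd, size=amp.shape)
        noise[0] = 0.0  # first amplitude defines the normalization
        amp = amp + noise
    return pd.DataFrame({"time_s": t, "amplitude": amp})


def gen_ltp_series(
    baseline_mean: float,
    plateau_ratio: float,
    hfs_time_min: float,
    duration_min: float,
    cfg: SimConfig,
    isi_s: float = 20.0,
    noise_cv: float = 0.0,
    rs_drift: float = 0.0,
    rs0_mohm: float = 15.0,
) -> LTPSeries:
    """Evoked-response amplitude series with a post-HFS plateau.

    Pre-HFS amplitudes fluctuate around ``baseline_mean``; post-HFS
    around ``baseline_mean × plateau_ratio`` (both with multiplicative
    Gaussian noise of CV ``noise_cv``).  The series-resistance log
    drifts linearly by ``rs_drift`` (fraction of its initial value) over
    the whole session.
    """
    if plateau_ratio <= 0:
        raise ValueError("plateau_ratio must be positive")
    if hfs_time_min >= duration_min:
        raise ValueError("HFS must occur before the end of the session")
    times = np.arange(isi_s, duration_min * 60.0 + isi_s / 2, isi_s)
    hfs_s = hfs_time_min * 60.0
    # the stimulus coinciding with HFS is still a baseline response
    level = np.where(times <= hfs_s, baseline_mean, baseline_mean * plateau_ratio)
    rng = cfg.rng()
    if noise_cv > 0:
        level = level * (1.0 + rng.normal(0.0, noise_cv, size=level.shape))
    rs = rs0_mohm * (1.0 + rs_drift * times / times[-1])
    return LTPSeries(times_s=times, amplitudes=level, rs_mohm=rs, hfs_time_s=hfs_s)


def gen_freezing_session(
    protocol: ProtocolSpec,
    freeze_fraction_per_epoch: Sequence[float],
    bout_scale_s: float,
    cfg: SimConfig,
) -> FreezingSession:
    """Freezing bouts as an alternating freeze/move renewal process.

    Within each epoch, freeze bouts are exponential with mean
    ``bout_scale_s`` and gaps exponential with a mean chosen so the
    expected frozen fraction matches the requested one; bouts are
    clipped to their epoch.  Fractions 0 and 1 are handled exactly
    (no bouts / one epoch-spanning bout).
    """
    epochs = protocol.epochs
    fractions = list(freeze_fraction_per_epoch)
    if len(fractions) != len(epochs):
        raise ValueError(
            f"got {len(fractions)} fractions for {len(epochs)} protocol epochs"
        )
    if any(f < 0 or f > 1 for f in fractions):
        raise ValueError("freeze fractions must lie in [0, 1]")
    rng = cfg.rng()
    bouts: List[Tuple[float, float]] = []
    for epoch, f in zip(epochs, fractions):
        if f <= 0.0:
            continue
        if f >= 1.0:
            bouts.append((epoch.start_s, epoch.end_s))
            continue
        gap_scale = bout_scale_s * (1.0 - f) / f
        t = epoch.start_s + rng.exponential(gap_scale / 2.0)
        while t < epoch.end_s:
            dur = rng.exponential(bout_scale_s)
            end = min(t + dur, epoch.end_s)
            if end > t:
                bouts.append((t, end))
            t = end + rng.exponential(gap_scale)
    return FreezingSession(protocol=protocol, bouts=bouts)


# --------------------------------------------------------------------------
# cohort generation


#: feature columns of a generated cohort, in classification order
COHORT_FEATURES = ("accommodating_ratio", "spike_delay_ms", "max_cv_isi_ratio", "max_rate_hz")

DEFAULT_DISPERSION = {
    "accommodating_ratio": 0.3,
    "spike_delay_ms": 15.0,
    "max_cv_isi_ratio": 0.05,
    "max_rate_hz": 8.0,
}

FEATURE_BOUNDS = {
    "accommodating_ratio": (0.05, None),
    "spike_delay_ms": (0.0, None),
    "max_cv_isi_ratio": (0.0, None),
    "max_rate_hz": (0.5, None),
    "input_resistance_mohm": (10.0, None),
    "rheobase_pa": (5.0, None),
}


def _spec_feature_means(spec: PhenotypeSpec) -> Dict[str, float]:
    return {
        "accommodating_ratio": spec.accommodation_factor,
        "spike_delay_ms": spec.first_spike_delay_ms,
        "max_cv_isi_ratio": spec.cv_isi,
        "max_rate_hz": spec.max_rate_hz,
        "input_resistance_mohm": spec.input_resistance_mohm,
        "rheobase_pa": spec.rheobase_pa,
    }


def gen_cohort(
    specs: Sequence[Tuple[PhenotypeSpec, int, Optional[Dict[str, float]]]],
    cfg: SimConfig,
    render_traces: bool = False,
):
    """Labeled cohort with planted per-cell feature values.

    ``specs`` is a sequence of (phenotype spec, n cells, feature-SD dict);
    per-cell values are drawn Normal(type mean, SD) and truncated to
    valid ranges.  Ground-truth labels are retained in the ``phenotype``
    column for recovery tests.  With ``render_traces=True`` the return
    also includes per-cell step families built from the drawn values.
    """
    rng = cfg.rng()
    rows = []
    cells: Dict[str, List[SweepRecording]] = {}
    cell_idx = 0
    for spec, n, dispersion in specs:
        if n < 1:
            raise ValueError("need n >= 1 cells per type")
        disp = dict(DEFAULT_DISPERSION)
        if dispersion:
            disp.update(dispersion)
        if any(sd <= 0 for sd in disp.values()):
            raise ValueError("feature dispersions must be positive")
        means = _spec_feature_means(spec)
        for _ in range(n):
            cell_id = f"cell{cell_idx:03d}"
            row = {"cell_id": cell_id, "phenotype": spec.name}
            for feat, mu in means.items():
                sd = disp.get(feat, 0.0)
                val = rng.normal(mu, sd) if sd > 0 else mu
                lo, hi = FEATURE_BOUNDS.get(feat, (None, None))
                if lo is not None:
                    val = max(val, lo)
                if hi is not None:
                    val = min(val, hi)
                row[feat] = float(val)
            rows.append(row)
            if render_traces:
                cell_spec = replace(
                    spec,
                    accommodation_factor=row["accommodating_ratio"],
                    first_spike_delay_ms=row["spike_delay_ms"],
                    max_rate_hz=row["max_rate_hz"],
                    input_resistance_mohm=row["input_resistance_mohm"],
                    rheobase_pa=row["rheobase_pa"],
                )
                cells[cell_id] = gen_step_family(cell_spec, cfg)
            cell_idx += 1
    table = pd.DataFrame(rows)
    return (table, cells) if render_traces else table


def bla_cohort_specs(n_total: int = 72):
    """Default four-phenotype cohort emulating a 72-cell GABAergic sample.

    Cluster sizes are a design choice (per-type counts were not reported
    for the full sample); feature means follow the qualitative phenotype
    descriptions and the printed delay/density anchors.
    """
    fractions = (26, 20, 12, 14)  # AcIN, StIN, DFIN, FSIN
    scale = n_total / sum(fractions)
    ns = [max(1, round(f * scale)) for f in fractions]
    ns[0] += n_total - sum(ns)  # largest type absorbs rounding drift
    specs = [
        PhenotypeSpec("accommodating", accommodation_factor=2.0, first_spike_delay_ms=30.0,
                      max_rate_hz=30.0, cv_isi=0.15),
        PhenotypeSpec("stuttering", accommodation_factor=1.1, first_spike_delay_ms=40.0,
                      max_rate_hz=45.0, cv_isi=1.0, gap_jitter_ms=60.0),
        PhenotypeSpec("delay_firing", accommodation_factor=1.0, first_spike_delay_ms=500.0,
                      max_rate_hz=25.0, cv_isi=0.1),
        PhenotypeSpec("fast_spiking", accommodation_factor=1.0, first_spike_delay_ms=15.0,
                      max_rate_hz=120.0, cv_isi=0.05),
    ]
    disp = [
        {"accommodating_ratio": 0.25, "spike_delay_ms": 12.0, "max_cv_isi_ratio": 0.05, "max_rate_hz": 6.0},
        {"accommodating_ratio": 0.15, "spike_delay_ms": 15.0, "max_cv_isi_ratio": 0.15, "max_rate_hz": 8.0},
        {"accommodating_ratio": 0.12, "spike_delay_ms": 120.0, "max_cv_isi_ratio": 0.04, "max_rate_hz": 5.0},
        {"accommodating_ratio": 0.08, "spike_delay_ms": 6.0, "max_cv_isi_ratio": 0.02, "max_rate_hz": 15.0},
    ]
    return [(s, n, d) for s, n, d in zip(specs, ns, disp)]


def cel_cohort_specs(
    n_ls: int = 46, delay_ls: float = 1769.0, sem_ls: float = 24.0,
    n_es: int = 26, delay_es: float = 778.0, sem_es: float = 86.0,
):
    """Two-population central-amygdala cohort defined by printed summary stats.

    Per-cell SDs are reconstructed from the reported SEMs as SEM·sqrt(n).
    Only the spike delay separates the populations; the remaining
    features are held at common means.
    """
    ls = PhenotypeSpec("late_spiking", first_spike_delay_ms=delay_ls, max_rate_hz=20.0)
    es = PhenotypeSpec("early_spiking", first_spike_delay_ms=delay_es, max_rate_hz=20.0)
    return [
        (ls, n_ls, {"spike_delay_ms": sem_ls * math.sqrt(n_ls)}),
        (es, n_es, {"spike_delay_ms": sem_es * math.sqrt(n_es)}),
    ]
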