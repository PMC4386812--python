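"""Evaluation protocols for the reduced NL models.

These reproduce the standard characterization battery for auditory
coincidence detector models: average spike waveform under non-phase-locked
drive, response classification to DC current steps (phasic vs tonic),
rate vs interaural phase difference curves, robustness sweeps of the
thresholding parameters, and a forward-Euler time-step reliability test.

Reference bands used throughout (from in vivo barn-owl NL recordings):
spike amplitude 4-13 mV and half-width 0.3-0.5 ms; "typical discharge range"
79-522 spikes/s (favorable/unfavorable ITD); modulation-depth criterion
180 spikes/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inputs import (
    ConductanceTrace,
    InputParams,
    SpikeTrain,
    binaural_conductance,
    binaural_trains,
    conductance_from_trains,
    noise_drive,
)
from .kinetics import klva_dinf_tau
from .model import ModelSpec, ModelState, find_holding_current, node_steady_state
from .simulate import SimulationResult, simulate

__all__ = [
    "TYPICAL_DISCHARGE_RANGE",
    "MODULATION_DEPTH_CRITERION",
    "IN_VIVO_AMPLITUDE_RANGE",
    "IN_VIVO_WIDTH_RANGE",
    "StepResponseClass",
    "SpikeShapeStats",
    "RatePhaseCurve",
    "SweepResult",
    "ReliabilityResult",
    "vector_strength",
    "classify_step_response",
    "step_response_ladder",
    "average_spike_shape",
    "rate_phase_curve",
    "sweep_threshold",
    "sweep_refractory",
    "reliability_max_dt",
]

# In vivo reference values (owl NL): discharge-rate band mean-SD (unfavorable)
# to mean+SD (favorable ITD), and the modulation-depth criterion derived from
# the rate change between favorable and unfavorable ITDs.
TYPICAL_DISCHARGE_RANGE: tuple[float, float] = (79.0, 522.0)  # spikes/s
MODULATION_DEPTH_CRITERION: float = 180.0  # spikes/s
IN_VIVO_AMPLITUDE_RANGE: tuple[float, float] = (4.0, 13.0)  # mV
IN_VIVO_WIDTH_RANGE: tuple[float, float] = (0.3, 0.5)  # ms


def vector_strength(times_ms: np.ndarray, freq_hz: float) -> float:
    """Vector strength: magnitude of the mean unit phasor of spike phases."""
    t = np.asarray(times_ms, dtype=float)
    if t.size == 0:
        raise ValueError("vector strength of an empty spike train is undefined")
    phase = 2.0 * np.pi * freq_hz * 1e-3 * t
    return float(np.abs(np.exp(1j * phase).mean()))


# ---------------------------------------------------------------------------
# Step-current classification
# ---------------------------------------------------------------------------

StepResponseClass = str  # "no_spike" | "phasic" | "tonic"


def _holding_state(spec: ModelSpec, v_hold: float) -> ModelState:
    d0 = klva_dinf_tau(v_hold, spec.kinetics)[0] if spec.has_klva else 0.0
    vn0 = node_steady_state(v_hold, spec) if spec.two_comp else None
    return ModelState(t=0.0, v_soma=v_hold, d=d0, v_node=vn0)


def classify_step_response(
    spec: ModelSpec,
    i_step: float,
    duration: float = 50.0,
    *,
    v_hold: float = -60.0,
    settle: float = 20.0,
    onset_window: float = 5.0,
    dt: float | None = None,
) -> StepResponseClass:
    """Classify the response to a DC step on top of the -60 mV holding current.

    ``no_spike``: no spike during the step; ``phasic``: spikes confined to the
    onset window (default 5 ms); ``tonic``: any spike after the onset window.
    The default step honours the small nodal compartment's stability limit
    (~3.3 us) in the two-compartment variant.
    """
    if dt is None:
        dt = 0.002 if spec.two_comp else 0.005
    i_base = find_holding_current(spec, v_hold)
    state = _holding_state(spec, v_hold)
    settled = simulate(spec, None, i_base, duration=settle, dt=dt, initial=state)
    res = simulate(
        spec, None, i_base + i_step, duration=duration, dt=dt,
        initial=settled.final_state(),
    )
    onset = settled.final_state().t
    spikes = res.spike_times[res.spike_times > onset] - onset
    if spikes.size == 0:
        return "no_spike"
    if np.all(spikes <= onset_window):
        return "phasic"
    return "tonic"


def step_response_ladder(
    spec: ModelSpec,
    i_steps: np.ndarray | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Classification across an increasing ladder of step amplitudes (pA)."""
    if i_steps is None:
        i_steps = np.arange(0.0, 3001.0, 100.0)
    labels = [classify_step_response(spec, i, **kwargs) for i in i_steps]
    return pd.DataFrame({"i_step_pA": np.asarray(i_steps, float), "response": labels})


# ---------------------------------------------------------------------------
# Average spike shape
# ---------------------------------------------------------------------------


@dataclass
class SpikeShapeStats:
    """Average somatic spike waveform and its summary statistics."""

    lags: np.ndarray          # ms relative to threshold crossing
    waveform: np.ndarray      # mV, averaged across aligned spikes
    amplitude: float          # mV, peak minus pre-spike baseline
    half_width: float         # ms, width at half the amplitude
    amplitude_from_threshold: float  # mV, peak minus V_theta (alternative convention)
    baseline: float           # mV
    n_spikes: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_ms": self.lags, "v_mV": self.waveform})


def _half_width(lags: np.ndarray, wave: np.ndarray, level: float) -> float:
    """Width of the first excursion above ``level``, linearly interpolated."""
    i_pk = int(np.argmax(wave))
    above = wave >= level
    # walk left and right from the peak to the half-level crossings
    i = i_pk
    while i > 0 and above[i - 1]:
        i -= 1
    j = i_pk
    while j < len(wave) - 1 and above[j + 1]:
        j += 1
    if i == 0 or j == len(wave) - 1:
        raise RuntimeError("half-width window does not bracket the spike")
    frac_l = (level - wave[i - 1]) / (wave[i] - wave[i - 1])
    t_l = lags[i - 1] + frac_l * (lags[i] - lags[i - 1])
    frac_r = (wave[j] - level) / (wave[j] - wave[j + 1])
    t_r = lags[j] + frac_r * (lags[j + 1] - lags[j])
    return float(t_r - t_l)


def average_spike_shape(
    spec: ModelSpec,
    n_spikes: int = 1500,
    seed: int = 0,
    *,
    p: InputParams | None = None,
    m_fibers: int = 300,
    dt: float = 0.002,
    window: tuple[float, float] = (-1.0, 2.0),
    baseline_window: tuple[float, float] = (-1.0, -0.5),
    chunk: float = 2000.0,
    max_chunks: int = 50,
) -> SpikeShapeStats:
    """Average spike waveform under non-phase-locked (homogeneous Poisson) drive.

    ``m_fibers`` independent 500-Hz Poisson fibers drive the model; output
    spikes are aligned at the threshold-crossing sample and the somatic
    potential is averaged over ``window``.  Amplitude is peak minus the
    pre-spike baseline (waveform mean over ``baseline_window``); the
    peak-minus-threshold value is reported alongside.  Simulation chunks are
    appended until ``n_spikes`` usable spikes are collected.
    """
    if spec.gen is None:
        raise ValueError("the non-spiking variant has no spikes to average")
    if p is None:
        p = InputParams()
    pre = int(round(-window[0] / dt))
    post = int(round(window[1] / dt))
    lags = dt * np.arange(-pre, post + 1)
    acc = np.zeros(pre + post + 1)
    n_acc = 0
    state: ModelState | str = "rest"
    for k in range(max_chunks):
        g = noise_drive(p, m_fibers, chunk, dt, seed=seed * max_chunks + k)
        res = simulate(spec, g, dt=dt, initial=state)
        t0 = res.t0
        idx = np.round((res.spike_times - t0) / dt).astype(int)
        idx = idx[(idx >= pre) & (idx <= len(res.v_soma) - 1 - post)]
        for i in idx:
            if n_acc >= n_spikes:
                break
            acc += res.v_soma[i - pre : i + post + 1]
            n_acc += 1
        if n_acc >= n_spikes:
            break
        state = res.final_state()
        state.t = 0.0  # restart clock; refractory carry-over is negligible
        if state.t_last_spike is not None:
            state.t_last_spike -= res.times[-1]
    if n_acc < n_spikes:
        raise RuntimeError(f"collected only {n_acc}/{n_spikes} spikes")
    wave = acc / n_acc
    b_lo = np.searchsorted(lags, baseline_window[0] - 1e-12)
    b_hi = np.searchsorted(lags, baseline_window[1] + 1e-12)
    baseline = float(wave[b_lo:b_hi].mean())
    peak = float(wave.max())
    amplitude = peak - baseline
    width = _half_width(lags, wave, baseline + 0.5 * amplitude)
    return SpikeShapeStats(
        lags=lags,
        waveform=wave,
        amplitude=amplitude,
        half_width=width,
        amplitude_from_threshold=peak - spec.gen.v_theta,
        baseline=baseline,
        n_spikes=n_acc,
    )


# ---------------------------------------------------------------------------
# Binaural rate protocols
# ---------------------------------------------------------------------------


def _rates_for_deltas(
    spec: ModelSpec,
    g_ipsi: ConductanceTrace,
    g_contra: ConductanceTrace,
    deltas: np.ndarray,
    p: InputParams,
    dt: float,
    warmup: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Spike rate and SE at each interaural phase, reusing one realization."""
    t_count = g_ipsi.duration - warmup
    rates = np.empty(len(deltas))
    ses = np.empty(len(deltas))
    for i, delta in enumerate(deltas):
        g = binaural_conductance(g_ipsi, g_contra, float(delta), p.f_stim)
        res = simulate(spec, g, dt=dt)
        n = int((res.spike_times > warmup).sum())
        rates[i] = n / (t_count * 1e-3)
        ses[i] = math.sqrt(max(n, 1)) / (t_count * 1e-3)
    return rates, ses


@dataclass
class RatePhaseCurve:
    """Spike rate as a function of the interaural phase difference delta."""

    deltas: np.ndarray        # rad
    rates: np.ndarray         # spikes/s
    rate_se: np.ndarray       # spikes/s, Poisson standard error sqrt(N)/T
    in_phase_rate: float
    out_of_phase_rate: float
    in_phase_se: float
    out_of_phase_se: float

    @property
    def modulation_depth(self) -> float:
        return self.in_phase_rate - self.out_of_phase_rate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"delta_rad": self.deltas, "rate_sps": self.rates, "se_sps": self.rate_se}
        )


def default_delta_grid() -> np.ndarray:
    """-2 pi .. 2 pi at pi/8 spacing."""
    return np.pi / 8.0 * np.arange(-16, 17)


def rate_phase_curve(
    spec: ModelSpec,
    p: InputParams | None = None,
    deltas: np.ndarray | None = None,
    t_per_delta: float = 10.0,
    seed: int = 0,
    *,
    dt: float = 0.01,
    warmup: float = 20.0,
) -> RatePhaseCurve:
    """Rate vs interaural phase difference, common input across the grid.

    One bilateral realization of ``t_per_delta`` seconds (plus warm-up) is
    generated and the contralateral trace is phase-shifted per grid point.
    The in-phase (out-of-phase) rate is read at the grid point nearest
    delta = 0 (delta = pi), where the curve's extrema sit by construction.
    """
    if p is None:
        p = InputParams()
    if deltas is None:
        deltas = default_delta_grid()
    deltas = np.asarray(deltas, dtype=float)
    duration = warmup + t_per_delta * 1e3
    ipsi, contra = binaural_trains(p, duration, seed)
    g_i = conductance_from_trains(ipsi, p, dt, duration)
    g_c = conductance_from_trains(contra, p, dt, duration)
    rates, ses = _rates_for_deltas(spec, g_i, g_c, deltas, p, dt, warmup)
    i_in = int(np.argmin(np.abs(deltas)))
    i_out = int(np.argmin(np.abs(np.abs(deltas) - np.pi)))
    return RatePhaseCurve(
        deltas=deltas,
        rates=rates,
        rate_se=ses,
        in_phase_rate=float(rates[i_in]),
        out_of_phase_rate=float(rates[i_out]),
        in_phase_se=float(ses[i_in]),
        out_of_phase_se=float(ses[i_out]),
    )


# ---------------------------------------------------------------------------
# Parameter sweeps
# ---------------------------------------------------------------------------


@dataclass
class SweepResult:
    """In-/out-of-phase rates across a thresholding-parameter grid."""

    parameter: str            # "v_theta" (mV) or "t_ref" (ms)
    values: np.ndarray
    in_rates: np.ndarray      # spikes/s
    out_rates: np.ndarray
    in_se: np.ndarray
    out_se: np.ndarray

    @property
    def modulation_depth(self) -> np.ndarray:
        return self.in_rates - self.out_rates

    def criterion_interval_width(
        self, criterion: float = MODULATION_DEPTH_CRITERION
    ) -> float:
        """Length of the parameter interval where modulation depth > criterion.

        Crossing points are located by linear interpolation between grid
        points; an excursion still above the criterion at a grid edge is
        truncated at that edge.
        """
        depth = self.modulation_depth - criterion
        x = self.values
        width = 0.0
        inside = depth[0] > 0
        start = x[0] if inside else None
        for i in range(1, len(x)):
            if (depth[i] > 0) != inside:
                frac = depth[i - 1] / (depth[i - 1] - depth[i])
                xc = x[i - 1] + frac * (x[i] - x[i - 1])
                if inside:
                    width += xc - start
                    start = None
                else:
                    start = xc
                inside = depth[i] > 0
        if inside and start is not None:
            width += x[-1] - start
        return float(width)

    def argmax_depth(self) -> float:
        return float(self.values[int(np.argmax(self.modulation_depth))])

    def in_rate_at(self, value: float) -> float:
        return float(self.in_rates[int(np.argmin(np.abs(self.values - value)))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                self.parameter: self.values,
                "in_rate_sps": self.in_rates,
                "out_rate_sps": self.out_rates,
                "modulation_depth_sps": self.modulation_depth,
                "in_se_sps": self.in_se,
                "out_se_sps": self.out_se,
            }
        )


def _sweep(
    spec_for,
    values: np.ndarray,
    parameter: str,
    p: InputParams,
    t_per_point: float,
    seed: int,
    dt: float,
    warmup: float,
) -> SweepResult:
    duration = warmup + t_per_point * 1e3
    ipsi, contra = binaural_trains(p, duration, seed)
    g_i = conductance_from_trains(ipsi, p, dt, duration)
    g_c = conductance_from_trains(contra, p, dt, duration)
    g_in = binaural_conductance(g_i, g_c, 0.0, p.f_stim)
    g_out = binaural_conductance(g_i, g_c, np.pi, p.f_stim)
    t_count = duration - warmup
    in_rates = np.empty(len(values))
    out_rates = np.empty(len(values))
    in_se = np.empty(len(values))
    out_se = np.empty(len(values))
    for i, val in enumerate(values):
        spec = spec_for(float(val))
        for g, rates, ses in ((g_in, in_rates, in_se), (g_out, out_rates, out_se)):
            res = simulate(spec, g, dt=dt)
            n = int((res.spike_times > warmup).sum())
            rates[i] = n / (t_count * 1e-3)
            ses[i] = math.sqrt(max(n, 1)) / (t_count * 1e-3)
    return SweepResult(parameter, np.asarray(values, float),
                       in_rates, out_rates, in_se, out_se)


def sweep_threshold(
    spec: ModelSpec,
    p: InputParams | None = None,
    v_theta_grid: np.ndarray | None = None,
    t_per_point: float = 10.0,
    seed: int = 0,
    *,
    dt: float = 0.01,
    warmup: float = 20.0,
) -> SweepResult:
    """In-/out-of-phase rates vs the IF threshold, common random numbers.

    The default grid spans 5 mV around the variant's default threshold at
    0.2-mV spacing.  The same bilateral realization is reused at every grid
    point so differences across thresholds are not masked by input noise.
    """
    if spec.gen is None:
        raise ValueError("the non-spiking variant has no threshold to sweep")
    if p is None:
        p = InputParams()
    if v_theta_grid is None:
        v0 = spec.gen.v_theta
        v_theta_grid = v0 + np.arange(-12, 14) * 0.2
    return _sweep(
        lambda v: spec.with_gen(v_theta=v),
        np.asarray(v_theta_grid, float), "v_theta_mV",
        p, t_per_point, seed, dt, warmup,
    )


def sweep_refractory(
    spec: ModelSpec,
    p: InputParams | None = None,
    t_ref_grid: np.ndarray | None = None,
    t_per_point: float = 10.0,
    seed: int = 0,
    *,
    dt: float = 0.01,
    warmup: float = 20.0,
) -> SweepResult:
    """In-/out-of-phase rates vs the absolute refractory period (threshold fixed)."""
    if spec.gen is None:
        raise ValueError("the non-spiking variant has no refractory period")
    if p is None:
        p = InputParams()
    if t_ref_grid is None:
        t_ref_grid = np.arange(0.2, 1.601, 0.1)
    return _sweep(
        lambda tr: spec.with_gen(t_ref=tr),
        np.asarray(t_ref_grid, float), "t_ref_ms",
        p, t_per_point, seed, dt, warmup,
    )


# ---------------------------------------------------------------------------
# Time-step reliability
# ---------------------------------------------------------------------------


@dataclass
class ReliabilityResult:
    """Forward-Euler reliability against a fine-step reference.

    A step is "unreliable" when the somatic potential computed with it
    deviates anywhere (on the coarse grid, over any trace) by more than
    ``tolerance`` from the reference computed with ``dt_ref`` on identical
    presynaptic input.
    """

    dt_us: np.ndarray           # tested steps, microseconds
    max_discrepancy: np.ndarray  # mV, per tested step
    dt_ref_us: float
    tolerance: float
    n_traces: int

    @property
    def reliable(self) -> np.ndarray:
        return self.max_discrepancy <= self.tolerance

    @property
    def max_allowable_dt_us(self) -> float | None:
        ok = self.dt_us[self.reliable]
        return float(ok.max()) if ok.size else None

    @property
    def min_unreliable_dt_us(self) -> float | None:
        bad = self.dt_us[~self.reliable]
        return float(bad.min()) if bad.size else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dt_us": self.dt_us,
                "max_discrepancy_mV": self.max_discrepancy,
                "reliable": self.reliable,
            }
        )


def reliability_max_dt(
    spec: ModelSpec,
    dt_list_us: np.ndarray,
    seed: int = 0,
    *,
    p: InputParams | None = None,
    n_traces: int = 3,
    trace_duration: float = 1000.0,
    dt_ref_us: float = 0.1,
    tolerance: float = 0.5,
    delta: float = 0.0,
    monitor: str = "soma",
) -> ReliabilityResult:
    """Maximum-allowable Euler step under the fine-reference criterion.

    For each of ``n_traces`` input realizations the presynaptic event times
    are drawn once; the synaptic conductance is then *re-sampled* (not
    re-drawn) on each candidate grid, so all runs integrate the same input.
    Each candidate run (threshold detection live) is compared with a
    ``dt_ref`` reference that *replays* the candidate's own spike times as
    forced spike-current injections — those times lie on the candidate grid
    and hence exactly on the fine grid, so the comparison (taken at the
    coarse grid's time points) measures pure integration error of one and
    the same spike sequence.  A raw trajectory comparison would instead be
    dominated by near-threshold discrimination noise: with stochastic
    4-kHz drive, oscillation peaks grazing within ~0.1 mV of threshold flip
    individual spikes between any two grids, after which the traces differ
    by a full spike height.  A candidate whose integration diverges
    (non-finite potential) is recorded as infinitely discrepant.
    ``monitor`` selects the compared potential ("soma" or, for the
    two-compartment variant, "node").
    """
    if p is None:
        p = InputParams()
    dt_list_us = np.asarray(dt_list_us, dtype=float)
    dt_ref = dt_ref_us * 1e-3
    max_disc = np.zeros(len(dt_list_us))
    for trace_i in range(n_traces):
        ipsi, contra = binaural_trains(p, trace_duration, seed=seed * n_traces + trace_i)
        trains = ipsi + contra  # delta = 0: both sides coincident
        if delta != 0.0:
            shift = delta / (2.0 * np.pi * p.f_stim) * 1e3
            contra_shifted = [
                SpikeTrain(np.sort((tr.times - shift) % tr.duration), tr.duration,
                           tr.fiber_id)
                for tr in contra
            ]
            trains = ipsi + contra_shifted
        g_ref = conductance_from_trains(trains, p, dt_ref, trace_duration)
        for j, dt_us in enumerate(dt_list_us):
            dt = dt_us * 1e-3
            ratio = dt / dt_ref
            if abs(ratio - round(ratio)) > 1e-9:
                raise ValueError("candidate steps must be integer multiples of dt_ref")
            g = conductance_from_trains(trains, p, dt, trace_duration)
            try:
                res = simulate(spec, g, dt=dt)
            except FloatingPointError:
                max_disc[j] = np.inf
                continue
            res_ref = simulate(
                spec, g_ref, dt=dt_ref, forced_spike_times=res.spike_times
            )
            v = res.v_node if monitor == "node" else res.v_soma
            v_ref = res_ref.v_node if monitor == "node" else res_ref.v_soma
            v_sub = v_ref[:: int(round(ratio))]
            m = min(len(v), len(v_sub))
            disc = float(np.max(np.abs(v[:m] - v_sub[:m])))
            if disc > max_disc[j]:
                max_disc[j] = disc
    return ReliabilityResult(
        dt_us=dt_list_us,
        max_discrepancy=max_disc,
        dt_ref_us=dt_ref_us,
        tolerance=tolerance,
        n_traces=n_traces,
    )
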