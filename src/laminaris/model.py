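"""Model definitions and steady-state analysis for the reduced NL neuron models.

Four variants of the barn-owl nucleus laminaris (NL) coincidence detector are
supported, all sharing the same somatic circuit (leak + K_LVA + synapse):

``two_comp_active_if``
    Soma coupled through an axonal conductance to a small nodal compartment
    that carries the integrate-and-fire (IF) thresholding unit; spikes are
    detected on the nodal potential.
``one_comp_active_if``
    The node and axon collapsed into a thresholding unit acting directly on
    the soma.
``one_comp_passive_if``
    As above but with the K_LVA conductance removed and the leak raised to
    keep the input resistance; the classical leaky IF limit.
``non_spiking``
    The subthreshold somatic circuit alone (no thresholding unit, no
    constant nodal current); used for membrane-response analysis.

The thresholding unit replaces the Na/K_HVA spike machinery: when the
monitored potential crosses ``v_theta`` a stereotyped double-exponential
current ``I_spike(t) = A1 exp(-t/tau1) + A2 exp(-t/tau2)`` is injected and
detection is disabled for an absolute refractory period ``t_ref``.

Unit system: mV, ms, nS, pF, pA (so nS*mV = pA and pA/pF = mV/ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.optimize import brentq

from .kinetics import KLVAKinetics, klva_dinf_slope, klva_dinf_tau

__all__ = [
    "SomaParams",
    "NodeParams",
    "SpikeGenerator",
    "ModelSpec",
    "ModelState",
    "VARIANTS",
    "spike_current",
    "steady_state_residual",
    "find_holding_current",
    "resting_potential",
    "node_steady_state",
    "input_resistance",
    "membrane_time_constant",
    "impedance_magnitude",
]

Variant = Literal[
    "two_comp_active_if", "one_comp_active_if", "one_comp_passive_if", "non_spiking"
]
VARIANTS: tuple[str, ...] = (
    "two_comp_active_if",
    "one_comp_active_if",
    "one_comp_passive_if",
    "non_spiking",
)


@dataclass(frozen=True)
class SomaParams:
    """Somatic membrane parameters (capacitance pF, conductances nS, potentials mV)."""

    c_soma: float = 24.0
    g_leak: float = 48.0
    g_klva: float = 192.0
    e_leak: float = -60.0
    e_k: float = -75.0
    e_syn: float = 0.0

    def __post_init__(self) -> None:
        if self.c_soma <= 0:
            raise ValueError("c_soma must be positive")
        if self.g_leak < 0 or self.g_klva < 0:
            raise ValueError("conductances must be non-negative")
        if not (self.e_k < self.e_leak < self.e_syn):
            raise ValueError("expected E_K < E_L < E_syn")


@dataclass(frozen=True)
class NodeParams:
    """Nodal compartment of the two-compartment variant."""

    c_node: float = 0.2
    g_leak: float = 2.0
    g_axon: float = 117.8

    def __post_init__(self) -> None:
        if self.c_node <= 0:
            raise ValueError("c_node must be positive")
        if self.g_leak < 0 or self.g_axon < 0:
            raise ValueError("conductances must be non-negative")


@dataclass(frozen=True)
class SpikeGenerator:
    """Integrate-and-fire thresholding unit (currents pA, times ms)."""

    i_const: float = 200.0
    a1: float = 3500.0
    a2: float = 3000.0
    tau1: float = 0.02
    tau2: float = 0.20
    v_theta: float = -58.3
    t_ref: float = 0.9

    def __post_init__(self) -> None:
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("spike-current time constants must be positive")
        if self.t_ref < 0:
            raise ValueError("refractory period must be non-negative")
        if self.a1 < 0 or self.a2 < 0:
            raise ValueError("spike-current amplitudes must be non-negative")


def spike_current(t_since_threshold: float | np.ndarray, gen: SpikeGenerator):
    """Stereotyped spike current ``I_spike`` (pA) at ``t`` ms after threshold.

    Zero for negative argument; at t = 0 equals A1 + A2.
    """
    t = np.asarray(t_since_threshold, dtype=float)
    out = np.where(
        t >= 0.0,
        gen.a1 * np.exp(-np.clip(t, 0.0, None) / gen.tau1)
        + gen.a2 * np.exp(-np.clip(t, 0.0, None) / gen.tau2),
        0.0,
    )
    if np.ndim(t_since_threshold) == 0:
        return float(out)
    return out


# Default thresholding parameters per variant (Vθ and spike-current amplitudes
# differ between the model reductions; time constants and refractoriness are shared).
_DEFAULT_GEN = {
    "two_comp_active_if": SpikeGenerator(a1=4000.0, a2=3000.0, v_theta=-56.7),
    "one_comp_active_if": SpikeGenerator(a1=3500.0, a2=3000.0, v_theta=-58.3),
    "one_comp_passive_if": SpikeGenerator(a1=4000.0, a2=4000.0, v_theta=-58.6),
}


@dataclass(frozen=True)
class ModelSpec:
    """One of the four reduced NL model variants with all its parameters."""

    variant: str
    soma: SomaParams
    node: NodeParams | None = None
    gen: SpikeGenerator | None = None
    kinetics: KLVAKinetics = field(default_factory=KLVAKinetics)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "two_comp_active_if":
            if self.node is None:
                raise ValueError("two-compartment variant requires node parameters")
        elif self.node is not None:
            raise ValueError("node parameters only apply to the two-compartment variant")
        if self.variant == "non_spiking":
            if self.gen is not None:
                raise ValueError("non-spiking variant has no thresholding unit")
        elif self.gen is None:
            raise ValueError(f"variant {self.variant!r} requires a thresholding unit")
        if self.variant == "one_comp_passive_if" and self.soma.g_klva != 0.0:
            raise ValueError("passive variant must have g_klva = 0")

    @property
    def has_klva(self) -> bool:
        return self.soma.g_klva > 0.0

    @property
    def two_comp(self) -> bool:
        return self.variant == "two_comp_active_if"

    @classmethod
    def default(cls, variant: str, **overrides) -> "ModelSpec":
        """Default parameter set for ``variant`` (the published tables)."""
        if variant == "two_comp_active_if":
            spec = cls(variant, SomaParams(), NodeParams(), _DEFAULT_GEN[variant])
        elif variant == "one_comp_active_if":
            spec = cls(variant, SomaParams(), None, _DEFAULT_GEN[variant])
        elif variant == "one_comp_passive_if":
            spec = cls(variant, SomaParams(g_leak=240.0, g_klva=0.0), None,
                       _DEFAULT_GEN[variant])
        elif variant == "non_spiking":
            spec = cls(variant, SomaParams(), None, None)
        else:
            raise ValueError(f"unknown variant {variant!r}")
        if overrides:
            spec = replace(spec, **overrides)
        return spec

    def with_gen(self, **gen_overrides) -> "ModelSpec":
        """Copy of the spec with thresholding-unit fields replaced."""
        if self.gen is None:
            raise ValueError("variant has no thresholding unit")
        return replace(self, gen=replace(self.gen, **gen_overrides))


@dataclass
class ModelState:
    """Instantaneous dynamical state of a model during integration.

    ``s1``/``s2`` are the amplitudes of the two exponential components of the
    accumulated spike current, updated exactly (decay factor per step), so the
    total IF current at the soma or node is ``i_const + s1 + s2``.
    """

    t: float
    v_soma: float
    d: float = 0.0
    v_node: float | None = None
    s1: float = 0.0
    s2: float = 0.0
    t_last_spike: float | None = None


# ---------------------------------------------------------------------------
# Steady-state analysis
# ---------------------------------------------------------------------------

def node_steady_state(v_soma: float, spec: ModelSpec) -> float:
    """Nodal potential at its own steady state given a clamped soma (mV).

    Balances nodal leak, axial current and the constant IF current:
    g_ln (E_L - Vn) + g_ax (Vs - Vn) + I_const = 0.
    """
    if not spec.two_comp:
        raise ValueError("node only exists in the two-compartment variant")
    node = spec.node
    assert node is not None and spec.gen is not None
    return (node.g_leak * spec.soma.e_leak + node.g_axon * v_soma + spec.gen.i_const) / (
        node.g_leak + node.g_axon
    )


def steady_state_residual(v_soma: float, spec: ModelSpec, i_ext: float = 0.0) -> float:
    """Net somatic current (pA) at ``v_soma`` with g_syn = 0 and d = d_inf(V).

    Zero iff ``v_soma`` is an equilibrium.  For the two-compartment variant the
    node is eliminated at its conditional steady state, so the constant IF
    current enters through the axial term rather than directly.
    """
    soma = spec.soma
    resid = soma.g_leak * (soma.e_leak - v_soma) + i_ext
    if spec.has_klva:
        dinf, _ = klva_dinf_tau(v_soma, spec.kinetics)
        resid += soma.g_klva * dinf * (soma.e_k - v_soma)
    if spec.two_comp:
        v_node = node_steady_state(v_soma, spec)
        resid += spec.node.g_axon * (v_node - v_soma)
    elif spec.gen is not None:
        resid += spec.gen.i_const
    return resid


def find_holding_current(spec: ModelSpec, v_hold: float) -> float:
    """Constant current ``I_base`` (pA) holding the soma at ``v_hold`` (mV).

    The residual is linear in the injected current with unit coefficient, so
    the root is the negated zero-current residual; currents outside a
    +/-10 nA window are rejected as unphysiological.
    """
    if not (-90.0 < v_hold < -40.0):
        raise ValueError("v_hold outside the supported (-90, -40) mV range")
    i_base = -steady_state_residual(v_hold, spec, 0.0)
    if abs(i_base) > 1.0e4:
        raise RuntimeError("no holding current within the +/-10 nA search window")
    return i_base


def resting_potential(spec: ModelSpec, bracket: tuple[float, float] = (-80.0, -40.0)) -> float:
    """Resting membrane potential (mV): the zero of the steady-state residual."""
    lo, hi = bracket
    f_lo = steady_state_residual(lo, spec)
    f_hi = steady_state_residual(hi, spec)
    if f_lo * f_hi > 0:
        raise RuntimeError(f"no resting potential bracketed in ({lo}, {hi}) mV")
    return float(brentq(steady_state_residual, lo, hi, args=(spec,), xtol=1e-10))


def _steady_voltage(spec: ModelSpec, i_ext: float) -> float:
    """Steady-state somatic potential under constant current ``i_ext`` (pA)."""
    lo, hi = -95.0, -30.0
    return float(brentq(steady_state_residual, lo, hi, args=(spec, i_ext), xtol=1e-12))


def input_resistance(spec: ModelSpec, v_hold: float, delta_i: float = 10.0) -> float:
    """Slope (differential) input resistance (MOhm) about ``v_hold``.

    Probes the steady state with small current steps ``I_base +/- delta_i``
    and central-differences the voltages, so for the active variants the
    d_inf(V) slope contribution of K_LVA is included.
    """
    if delta_i <= 0 or delta_i > 20.0:
        raise ValueError("delta_i must be in (0, 20] pA for a small-signal probe")
    i_base = find_holding_current(spec, v_hold)
    v_plus = _steady_voltage(spec, i_base + delta_i)
    v_minus = _steady_voltage(spec, i_base - delta_i)
    return (v_plus - v_minus) / (2.0 * delta_i) * 1.0e3  # mV/pA = GOhm -> MOhm


def membrane_time_constant(spec: ModelSpec, v_hold: float) -> float:
    """Effective somatic time constant R_slope * C_soma (ms) at ``v_hold``."""
    r_mohm = input_resistance(spec, v_hold)
    return r_mohm * 1.0e-3 * spec.soma.c_soma  # GOhm * pF = ms


def impedance_magnitude(
    spec: ModelSpec,
    v_hold: float,
    freq_hz: float | np.ndarray,
    *,
    include_klva: bool | None = None,
    include_axon: bool | None = None,
):
    """Small-signal somatic impedance magnitude |Z| (MOhm) at ``freq_hz``.

    Linearizes the soma (and the node, when present) about ``v_hold``.  The
    K_LVA contribution splits into an instantaneous chord term
    ``g_klva * d_inf`` and a relaxing slope term
    ``g_klva * (V - E_K) * d_inf'(V) / (1 + i w tau_d)``; at zero frequency the
    impedance therefore equals the slope input resistance.  ``include_klva``
    and ``include_axon`` switch off the respective branches to reproduce the
    "RC only" / "RC + K_LVA" / "RC + axon" decompositions.
    """
    if include_klva is None:
        include_klva = spec.has_klva
    if include_axon is None:
        include_axon = spec.two_comp
    f = np.asarray(freq_hz, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    omega = 2.0 * np.pi * f * 1.0e-3  # rad/ms
    soma = spec.soma
    y = soma.g_leak + 1j * omega * soma.c_soma  # nS
    if include_klva and spec.has_klva:
        dinf, tau = klva_dinf_tau(v_hold, spec.kinetics)
        slope = klva_dinf_slope(v_hold, spec.kinetics)
        y = y + soma.g_klva * dinf
        y = y + soma.g_klva * (v_hold - soma.e_k) * slope / (1.0 + 1j * omega * tau)
    if include_axon and spec.two_comp:
        node = spec.node
        y_node = node.g_leak + node.g_axon + 1j * omega * node.c_node
        y = y + node.g_axon - node.g_axon**2 / y_node
    z = 1.0 / np.abs(y) * 1.0e3  # 1/nS = GOhm -> MOhm
    if np.ndim(freq_hz) == 0:
        return float(z)
    return z
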