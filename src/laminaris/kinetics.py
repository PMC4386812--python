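"""Activation kinetics of the low-voltage-activated potassium (K_LVA) conductance.

The K_LVA conductance (Kv1-type, dendrotoxin-sensitive) is partially open near
the resting potential of auditory brainstem coincidence detector neurons.  Its
single activation gate ``d`` relaxes toward the voltage-dependent steady state
``d_inf(V)`` with time constant ``tau_d(V)``:

    dd/dt = (d_inf(V) - d) / tau_d(V)

with opening/closing rates (1/ms, V in mV) measured in chick brainstem slices
at room temperature:

    alpha_d(V) = 0.20 * exp((V + 60) / 21.8)
    beta_d(V)  = 0.17 * exp(-(V + 60) / 14)

Simulations run at avian body temperature, so the time constant is sped up by
the usual Q10 correction, ``tau_d ∝ Q10 ** (-(T1 - T0) / 10)`` (a ~4.74-fold
acceleration for Q10 = 2.5 between 23 and 40 degC).  The exponent sign is a
configurable convention: ``temperature_factor`` below returns the multiplier
applied to 1/(alpha+beta).

Units throughout the package: mV, ms, nS, pF, pA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KLVAKinetics",
    "klva_rates",
    "klva_dinf_tau",
]


@dataclass(frozen=True)
class KLVAKinetics:
    """Temperature-correction parameters for the K_LVA gate.

    Parameters
    ----------
    q10 : float
        Rate increase per 10 degC of warming (dimensionless).
    t_rec : float
        Temperature of the slice recordings the rates come from (degC).
    t_sim : float
        Simulation (body) temperature (degC).
    speedup : bool
        If True (default, the physiological convention) warming *shortens*
        tau_d by Q10**((t_sim - t_rec)/10); if False the literal slow-down
        reading is used instead.
    """

    q10: float = 2.5
    t_rec: float = 23.0
    t_sim: float = 40.0
    speedup: bool = True

    def temperature_factor(self) -> float:
        """Multiplier applied to 1/(alpha+beta) to obtain tau_d."""
        exponent = (self.t_sim - self.t_rec) / 10.0
        if self.speedup:
            exponent = -exponent
        return self.q10 ** exponent


def klva_rates(v: float | np.ndarray) -> tuple[float | np.ndarray, float | np.ndarray]:
    """Opening and closing rates (alpha_d, beta_d) in 1/ms at potential ``v`` (mV)."""
    alpha = 0.20 * np.exp((np.asarray(v, dtype=float) + 60.0) / 21.8)
    beta = 0.17 * np.exp(-(np.asarray(v, dtype=float) + 60.0) / 14.0)
    if np.isscalar(v) or np.ndim(v) == 0:
        return float(alpha), float(beta)
    return alpha, beta


def klva_dinf_tau(
    v: float | np.ndarray, kin: KLVAKinetics = KLVAKinetics()
) -> tuple[float | np.ndarray, float | np.ndarray]:
    """Steady-state activation ``d_inf(v)`` and time constant ``tau_d(v)`` (ms)."""
    alpha, beta = klva_rates(v)
    total = np.add(alpha, beta)
    dinf = np.divide(alpha, total)
    tau = kin.temperature_factor() / total
    if np.isscalar(v) or np.ndim(v) == 0:
        return float(dinf), float(tau)
    return dinf, tau


def klva_dinf_slope(v: float, kin: KLVAKinetics = KLVAKinetics()) -> float:
    """Analytic derivative d(d_inf)/dV at ``v`` (1/mV), used for linearization.

    d_inf = a/(a+b) with a' = a/21.8 and b' = -b/14, so
    d(d_inf)/dV = (a'b - ab') / (a+b)^2 = a*b*(1/21.8 + 1/14)/(a+b)^2.
    """
    a, b = klva_rates(v)
    return a * b * (1.0 / 21.8 + 1.0 / 14.0) / (a + b) ** 2
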