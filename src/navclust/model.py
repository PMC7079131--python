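"""Closed-form gating models for the cardiac sodium channel Nav1.5.

The whole-cell Na+ conductance is described by the Hodgkin-Huxley m3h
formulation: three identical activation gates (m) and one inactivation gate
(h), each relaxing mono-exponentially after a voltage step.  Steady-state
gate occupancies follow two-state Boltzmann curves; the slope factor k maps
to an effective gating charge through k = RT/zF.  These functions are the
single source of truth shared by the synthetic-data generators and the
fitting pipeline.

Units: voltages mV, times ms, conductances nS, currents pA, temperature K.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Sense",
    "BoltzmannParams",
    "HHState",
    "DecayParams",
    "boltzmann_curve",
    "nernst_potential",
    "conductance_from_current",
    "hh_m3h_timecourse",
    "recovery_fraction",
    "double_exp_decay",
    "charge_from_slope",
    "RT_OVER_F_MV",
]

#: Gas constant x temperature / Faraday constant, in mV, at temperature T (K).
RT_OVER_F_MV = lambda temperature: 1000.0 * 8.314462618 * temperature / 96485.33212  # noqa: E731


class Sense(str, enum.Enum):
    """Direction of a steady-state gating curve."""

    ACTIVATION = "activation"
    INACTIVATION = "inactivation"


@dataclass(frozen=True)
class BoltzmannParams:
    """Steady-state Boltzmann gating curve, 1/(1 + exp(±(V − V½)/k)).

    k is stored positive; ``sense`` orients the curve (activation rises with
    depolarization, inactivation falls).  This removes the sign ambiguity
    that otherwise creeps into reported slope factors.
    """

    vhalf: float
    k: float
    sense: Sense = Sense.ACTIVATION

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError(f"slope factor k must be positive, got {self.k}")

    def __call__(self, v):
        return boltzmann_curve(v, self)


@dataclass(frozen=True)
class HHState:
    """Endpoints and time constants of one m3h conductance transient.

    G(t) = gmax * [m∞ − (m∞−m0) e^(−t/τm)]³ * [h∞ − (h∞−h0) e^(−t/τh)] + offset
    """

    m0: float
    m_inf: float
    h0: float
    h_inf: float
    tau_m: float
    tau_h: float
    gmax: float
    offset: float = 0.0

    def __post_init__(self) -> None:
        for name in ("m0", "m_inf", "h0", "h_inf"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"gating endpoint {name}={val} outside [0, 1]")
        if not (self.tau_m > 0 and self.tau_h > 0):
            raise ValueError("time constants must be positive")


@dataclass(frozen=True)
class DecayParams:
    """Double-exponential current decay, y = −A1 e^(−t/τ1) − A2 e^(−t/τ2).

    By convention tau1 < tau2 (fast component first).
    """

    a1: float
    a2: float
    tau1: float
    tau2: float

    def __post_init__(self) -> None:
        if not (self.tau1 > 0 and self.tau2 > 0):
            raise ValueError("decay time constants must be positive")

    def ordered(self) -> "DecayParams":
        """Return an equivalent parameter set with tau1 <= tau2."""
        if self.tau1 <= self.tau2:
            return self
        return DecayParams(a1=self.a2, a2=self.a1, tau1=self.tau2, tau2=self.tau1)


def boltzmann_curve(v, p: BoltzmannParams):
    """Steady-state gate occupancy at voltage(s) ``v`` (mV).

    Activation: 1/(1 + exp((V½ − V)/k)), increasing with V.
    Inactivation: 1/(1 + exp((V − V½)/k)), decreasing with V.
    Exactly 0.5 at V = V½ in either sense.
    """
    v = np.asarray(v, dtype=float)
    if p.sense is Sense.ACTIVATION:
        arg = (p.vhalf - v) / p.k
    else:
        arg = (v - p.vhalf) / p.k
    out = 1.0 / (1.0 + np.exp(arg))
    return out if out.ndim else float(out)


def nernst_potential(c_out: float, c_in: float, slope_mv_per_decade: float = 58.0) -> float:
    """Equilibrium potential (mV) for an ion at the given concentrations (mM).

    The slope is exposed as a parameter (default 58 mV per tenfold gradient,
    the textbook room-temperature monovalent value) rather than computed from
    RT/F at an assumed temperature.
    """
    if c_out <= 0 or c_in <= 0:
        raise ValueError("concentrations must be positive")
    return slope_mv_per_decade * math.log10(c_out / c_in)


def conductance_from_current(i, v: float, e_na: float):
    """Chord conductance G = I/(V − E_Na) (nS from pA and mV).

    Raises at the reversal potential where the driving force vanishes.
    """
    if v == e_na:
        raise ZeroDivisionError(
            f"driving force is zero at V = E_Na = {e_na} mV; conductance undefined"
        )
    return np.asarray(i, dtype=float) / (v - e_na) if np.ndim(i) else i / (v - e_na)


def hh_m3h_timecourse(t, s: HHState):
    """m3h conductance transient G(t) (nS) at times ``t`` (ms) after a step."""
    t = np.asarray(t, dtype=float)
    m = s.m_inf - (s.m_inf - s.m0) * np.exp(-t / s.tau_m)
    h = s.h_inf - (s.h_inf - s.h0) * np.exp(-t / s.tau_h)
    g = s.gmax * m**3 * h + s.offset
    return g if g.ndim else float(g)


def recovery_fraction(t, tau: float):
    """Recovered availability 1 − exp(−t/τ) after an interval t (ms)."""
    if tau <= 0:
        raise ValueError(f"recovery time constant must be positive, got {tau}")
    t = np.asarray(t, dtype=float)
    out = 1.0 - np.exp(-t / tau)
    return out if out.ndim else float(out)


def double_exp_decay(t, p: DecayParams):
    """Double-exponential inward-current decay (pA), negative by convention."""
    t = np.asarray(t, dtype=float)
    y = -p.a1 * np.exp(-t / p.tau1) - p.a2 * np.exp(-t / p.tau2)
    return y if y.ndim else float(y)


def charge_from_slope(k: float, temperature: float = 295.15) -> float:
    """Effective gating charge z (elementary charges) from a slope factor.

    k = RT/zF, so z = (RT/F)/k with RT/F expressed in mV.  Default
    temperature 295.15 K (22 C, room-temperature recording).
    """
    if k <= 0:
        raise ValueError(f"slope factor must be positive, got {k}")
    return RT_OVER_F_MV(temperature) / k
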