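"""Biophysical ground-truth models shared by the synthetic generators.

The whole-cell Ca2+ current of an inner hair cell is described by a
Boltzmann-gated conductance with a linear (ohmic) driving force,

    I(V) = g_max * P_o(V) * (V - v_rev),    P_o(V) = 1 / (1 + exp((v_half - V)/k)),

plus a linear leak ``g_leak * (V - holding)``.  Units are chosen so that
conductances in nS and voltages in mV give currents in pA.

The fluorescence of a single-wavelength Ca2+ indicator follows a
saturating hyperbola of the local Ca2+ concentration,

    F(c) = f_min + (f_max - f_min) * c / (c + k_d).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["ChannelModel", "IndicatorModel"]


@dataclass(frozen=True)
class ChannelModel:
    """Boltzmann-gated whole-cell Ca2+ channel with linear leak.

    Parameters
    ----------
    g_max : float
        Maximal whole-cell conductance (nS).
    v_rev : float
        Reversal potential of the Ca2+ current (mV).
    v_half : float
        Voltage of half-maximal activation (mV).
    k : float
        Slope factor / voltage sensitivity of activation (mV); smaller is
        steeper.
    g_leak : float
        Linear leak conductance referenced to the holding potential (nS).
    """

    g_max: float
    v_rev: float = 45.0
    v_half: float = -29.4
    k: float = 6.92
    g_leak: float = 0.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"slope factor k must be > 0, got {self.k}")
        if self.g_max < 0:
            raise ValueError(f"g_max must be >= 0, got {self.g_max}")
        if self.g_leak < 0:
            raise ValueError(f"g_leak must be >= 0, got {self.g_leak}")
        if self.v_rev <= self.v_half:
            raise ValueError(
                f"v_rev ({self.v_rev}) must exceed v_half ({self.v_half})"
            )

    def open_probability(self, v):
        """Fractional activation P_o(V) in [0, 1]."""
        v = np.asarray(v, dtype=float)
        return 1.0 / (1.0 + np.exp((self.v_half - v) / self.k))

    def channel_current(self, v):
        """Ca2+ current g_max * P_o(V) * (V - v_rev) in pA (leak excluded)."""
        v = np.asarray(v, dtype=float)
        return self.g_max * self.open_probability(v) * (v - self.v_rev)

    def leak_current(self, v, holding: float):
        """Linear leak current g_leak * (V - holding) in pA."""
        v = np.asarray(v, dtype=float)
        return self.g_leak * (v - holding)

    def peak_inward(self, v_lo: float = -90.0, v_hi: float = 40.0, n: int = 20001):
        """(voltage, current) of the most inward channel current on a fine grid."""
        grid = np.linspace(v_lo, v_hi, n)
        i = self.channel_current(grid)
        j = int(np.argmin(i))
        return float(grid[j]), float(i[j])

    def with_peak_current(self, peak_pa: float) -> "ChannelModel":
        """Return a copy whose g_max gives a peak inward current of |peak_pa| pA.

        The scaling is the algebraic inversion g_max = |I_peak| / |P_o(V*) (V* - v_rev)|
        at the voltage V* of maximal inward driving.
        """
        probe = replace(self, g_max=1.0)
        _, i_unit = probe.peak_inward()
        if i_unit >= 0:
            raise ValueError("model has no inward limb; cannot scale to a peak current")
        return replace(self, g_max=abs(peak_pa) / abs(i_unit))


@dataclass(frozen=True)
class IndicatorModel:
    """Saturating single-wavelength Ca2+ indicator (e.g. Fluo4-FF, k_d = 10 uM)."""

    k_d: float = 10.0  # uM
    f_min: float = 100.0  # a.u., fluorescence at zero Ca2+
    f_max: float = 2000.0  # a.u., fluorescence at saturation

    def __post_init__(self) -> None:
        if self.k_d <= 0:
            raise ValueError(f"k_d must be > 0, got {self.k_d}")
        if not (self.f_max > self.f_min >= 0):
            raise ValueError(
                f"require f_max > f_min >= 0, got f_min={self.f_min}, f_max={self.f_max}"
            )

    def fluorescence(self, c):
        """F(c) for Ca2+ concentration c (uM); saturates at f_max."""
        c = np.asarray(c, dtype=float)
        return self.f_min + (self.f_max - self.f_min) * c / (c + self.k_d)

    def dff(self, c):
        """(F(c) - F(0)) / F(0), the ideal background-free dF/F0."""
        if self.f_min <= 0:
            raise ValueError("dff undefined for f_min == 0")
        return (self.fluorescence(c) - self.f_min) / self.f_min

    def conc_for_dff(self, dff: float) -> float:
        """Invert dff -> Ca2+ concentration (uM); errors if dff is unreachable."""
        span = (self.f_max - self.f_min) / self.f_min
        if not 0 <= dff < span:
            raise ValueError(f"dF/F0 of {dff} unreachable (max {span:.3g})")
        if dff == 0:
            return 0.0
        return self.k_d * dff / (span - dff)
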