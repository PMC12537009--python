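"""Voltage-clamp command protocols.

A protocol is an ordered list of piecewise-linear segments
``(duration_ms, start_mV, end_mV)`` preceded/followed by holding periods.
All voltages here are true membrane potentials (liquid-junction-potential
corrected); generators can re-express them as amplifier commands by adding
the LJP back (see `ribbonphys.synth.currents.simulate_current`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoltageProtocol", "make_step_protocol", "make_ramp_pair", "InvalidProtocolError"]

HOLDING_DEFAULT = -87.0  # mV


class InvalidProtocolError(ValueError):
    """Raised for ill-formed command protocols."""


@dataclass(frozen=True)
class VoltageProtocol:
    """Piecewise-linear command waveform.

    Attributes
    ----------
    sample_interval : float
        Sampling step (ms).
    segments : tuple of (duration_ms, start_mV, end_mV)
        Concatenated linear pieces; contiguous in time.
    holding : float
        Holding potential (mV).
    label : str
        Protocol kind: ``step`` | ``ramp`` | ``leak_pulse``.
    analysis_window : tuple or None
        (start_ms, end_ms) of the depolarization of interest, set by the
        constructors below.
    """

    sample_interval: float
    segments: tuple
    holding: float = HOLDING_DEFAULT
    label: str = "step"
    analysis_window: tuple | None = field(default=None)

    def __post_init__(self) -> None:
        if self.sample_interval <= 0:
            raise InvalidProtocolError("sample_interval must be > 0")
        if not self.segments:
            raise InvalidProtocolError("protocol needs at least one segment")
        for dur, _, _ in self.segments:
            if dur <= 0:
                raise InvalidProtocolError(f"segment duration must be > 0, got {dur}")

    @property
    def total_duration(self) -> float:
        return float(sum(d for d, _, _ in self.segments))

    def times(self) -> np.ndarray:
        """Sample times (ms), half-open grid [0, total_duration)."""
        n = int(round(self.total_duration / self.sample_interval))
        return np.arange(n) * self.sample_interval

    def voltage_at(self, t) -> np.ndarray:
        """Command voltage at arbitrary times (ms), piecewise-linear."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        durs = np.array([d for d, _, _ in self.segments])
        edges = np.concatenate([[0.0], np.cumsum(durs)])
        idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(durs) - 1)
        v = np.empty_like(t)
        for i, (dur, v0, v1) in enumerate(self.segments):
            m = idx == i
            if np.any(m):
                frac = (t[m] - edges[i]) / dur
                v[m] = v0 + (v1 - v0) * frac
        return v

    def voltages(self) -> np.ndarray:
        """Command voltage on the sampling grid of `times`."""
        return self.voltage_at(self.times())

    def scaled(self, factor: float, label: str = "leak_pulse") -> "VoltageProtocol":
        """Protocol with depolarizations scaled by `factor` about holding (p/N pulses)."""
        segs = tuple(
            (d, self.holding + factor * (v0 - self.holding), self.holding + factor * (v1 - self.holding))
            for d, v0, v1 in self.segments
        )
        return VoltageProtocol(self.sample_interval, segs, self.holding, label, self.analysis_window)


def make_step_protocol(
    hold: float = HOLDING_DEFAULT,
    v_start: float = -82.0,
    v_stop: float = 63.0,
    increment: float = 5.0,
    duration: float = 20.0,
    *,
    pre: float = 10.0,
    post: float = 10.0,
    sample_interval: float = 0.05,
) -> list[VoltageProtocol]:
    """Family of square step depolarizations, one protocol per step voltage.

    Mirrors the whole-cell IV protocol: 20 ms steps in 5 mV increments from
    a -87 mV holding potential.  For a degenerate range (v_start == v_stop)
    a single protocol stepping to that voltage is returned, even when the
    step amplitude is zero (documented convention).
    """
    if duration <= 0:
        raise InvalidProtocolError(f"step duration must be > 0, got {duration}")
    if increment <= 0:
        raise InvalidProtocolError(f"increment must be > 0, got {increment}")
    if v_stop < v_start:
        raise InvalidProtocolError("v_stop must be >= v_start")
    n_steps = int(np.floor((v_stop - v_start) / increment + 1e-9)) + 1
    steps = v_start + increment * np.arange(n_steps)
    protocols = []
    for v in steps:
        segs = ((pre, hold, hold), (duration, float(v), float(v)), (post, hold, hold))
        protocols.append(
            VoltageProtocol(
                sample_interval,
                segs,
                holding=hold,
                label="step",
                analysis_window=(pre, pre + duration),
            )
        )
    return protocols


def make_ramp_pair(
    v_start: float = -87.0,
    v_end: float = 63.0,
    duration: float = 150.0,
    shift: float = 5.0,
    *,
    hold: float = HOLDING_DEFAULT,
    lead: float = 0.0,
    tail: float = 10.0,
    sample_interval: float = 0.1,
) -> tuple[VoltageProtocol, VoltageProtocol]:
    """Pair of identical voltage ramps, the second delayed by `shift` ms.

    The standard single-active-zone imaging stimulus is a -87 -> 63 mV ramp
    over 150 ms (slope 1 mV/ms); interleaving two ramps shifted by 5 ms
    doubles the voltage resolution of the fluorescence-voltage curve.
    """
    if duration <= 0:
        raise InvalidProtocolError("ramp duration must be > 0")
    if shift < 0 or shift >= duration:
        raise InvalidProtocolError(f"shift must satisfy 0 <= shift < duration, got {shift}")
    if v_end == v_start:
        raise InvalidProtocolError("zero-span ramp: v_end must differ from v_start")

    def one(extra_lead: float) -> VoltageProtocol:
        segs = []
        total_lead = lead + extra_lead
        if total_lead > 0:
            segs.append((total_lead, hold, hold))
        segs.append((duration, v_start, v_end))
        segs.append((tail, hold, hold))
        return VoltageProtocol(
            sample_interval,
            tuple(segs),
            holding=hold,
            label="ramp",
            analysis_window=(total_lead, total_lead + duration),
        )

    return one(0.0), one(shift)
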