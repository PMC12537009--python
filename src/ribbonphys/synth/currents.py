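"""Synthetic whole-cell current sweeps with p/4 leak-pulse companions."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..models import ChannelModel
from ..protocols import VoltageProtocol

__all__ = ["CurrentSweep", "simulate_current"]


@dataclass
class CurrentSweep:
    """One voltage-clamp sweep: command waveform and recorded current.

    ``voltage`` is the *recorded command* voltage; when the generator is run
    with a nonzero ``ljp`` it is offset by +LJP relative to the true membrane
    potential, so the analysis must apply the offline LJP correction.
    ``leak_sweeps`` hold the quarter-amplitude p/4 companion currents.
    """

    time: np.ndarray  # ms
    voltage: np.ndarray  # mV (command, possibly LJP-uncorrected)
    current: np.ndarray  # pA
    leak_sweeps: tuple = ()
    protocol: VoltageProtocol | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.time) == len(self.voltage) == len(self.current)):
            raise ValueError("time/voltage/current must have equal length")
        for ls in self.leak_sweeps:
            if len(ls) != len(self.current):
                raise ValueError("each leak sweep must match the test sweep length")


def simulate_current(
    protocol: VoltageProtocol,
    model: ChannelModel,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    *,
    n_leak: int = 4,
    ljp: float = 0.0,
) -> CurrentSweep:
    """Simulate one sweep of Boltzmann-gated Ca2+ current plus linear leak.

    I(t) = g_max P_o(V) (V - v_rev) + g_leak (V - holding) + noise, with
    ``n_leak`` quarter-amplitude leak-pulse repetitions (channels closed,
    leak only) for p/4 correction.  Deterministic for a fixed seed.

    Parameters
    ----------
    noise_sd : float
        Gaussian current noise SD (pA), applied independently per sweep.
    ljp : float
        Liquid junction potential (mV).  The physics is computed on the
        protocol's true membrane voltages; the *recorded* command trace is
        offset by +ljp, to be undone offline by `ribbonphys.vclamp.ljp_correct`.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = protocol.times()
    v = protocol.voltages()
    i = model.channel_current(v) + model.leak_current(v, protocol.holding)
    if noise_sd > 0:
        i = i + rng.normal(0.0, noise_sd, size=i.shape)
    leaks = []
    quarter = protocol.scaled(0.25)
    vq = quarter.voltages()
    for _ in range(n_leak):
        il = model.leak_current(vq, protocol.holding)
        if noise_sd > 0:
            il = il + rng.normal(0.0, noise_sd, size=il.shape)
        leaks.append(il)
    return CurrentSweep(
        time=t,
        voltage=v + ljp,
        current=np.asarray(i, dtype=float),
        leak_sweeps=tuple(leaks),
        protocol=protocol,
        meta={"noise_sd": noise_sd, "model": model, "ljp": ljp, "n_leak": n_leak},
    )
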