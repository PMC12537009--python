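"""Synthetic perforated-patch capacitance recordings with a depletion pool model.

Exocytosis is modeled as a fast readily-releasable pool (RRP) that depletes
single-exponentially plus a linear sustained component that engages after
20 ms of depolarization:

    dCm(t_dur) = rrp_size * (1 - exp(-t_dur / tau_fast))
                 + sustained_rate * max(0, t_dur - t_onset_sustained)

The membrane-capacitance track is undefined (NaN) during the depolarization
itself: the sine-wave Cm estimate is not available while the stimulus runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..models import ChannelModel

__all__ = ["PoolModel", "CapacitanceRecording", "simulate_capacitance_recording"]


@dataclass(frozen=True)
class PoolModel:
    """RRP + sustained exocytosis pool (sizes in fF, times in ms)."""

    rrp_size: float = 15.0
    tau_fast: float = 9.0
    sustained_rate: float = 0.35  # fF/ms
    t_onset_sustained: float = 20.0

    def delta_cm(self, t_dur):
        t = np.asarray(t_dur, dtype=float)
        fast = self.rrp_size * (1.0 - np.exp(-t / self.tau_fast))
        sustained = self.sustained_rate * np.maximum(0.0, t - self.t_onset_sustained)
        return fast + sustained


@dataclass
class CapacitanceRecording:
    """One depolarization: Cm track (NaN during the pulse) and Ca2+ current."""

    time: np.ndarray  # ms
    c_m: np.ndarray  # fF, NaN inside pulse_window
    current: np.ndarray  # pA
    pulse_window: tuple  # (start, end) ms
    truth: dict = field(default_factory=dict)


def simulate_capacitance_recording(
    durations,
    pool: PoolModel | None = None,
    model: ChannelModel | None = None,
    noise_sd: float = 3.0,
    seed: int | np.random.Generator = 0,
    *,
    v_pulse: float = -17.0,
    holding: float = -87.0,
    baseline_cm: float = 10_000.0,  # 10 pF cell
    pre: float = 600.0,
    post: float = 700.0,
    sample_interval: float = 0.2,
) -> list[CapacitanceRecording]:
    """One recording per pulse duration (ms), e.g. (2, 5, 10, 20, 50, 100).

    The Cm track is flat at ``baseline_cm`` before the pulse and jumps by the
    pool model's dCm after it, with Gaussian noise of SD ``noise_sd`` (fF).
    The paired current trace carries the Ca2+ + leak current of ``model``
    during the pulse at ``v_pulse``.
    """
    if pool is None:
        pool = PoolModel()
    if model is None:
        model = ChannelModel(g_max=2.0)
    durations = list(durations)
    if any(d <= 0 for d in durations):
        raise ValueError("pulse durations must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for dur in durations:
        total = pre + dur + post
        t = np.arange(int(round(total / sample_interval))) * sample_interval
        in_pulse = (t >= pre) & (t < pre + dur)
        jump = float(pool.delta_cm(dur))
        cm = np.where(t < pre, baseline_cm, baseline_cm + jump)
        cm = cm + rng.normal(0.0, noise_sd, size=cm.shape)
        cm[in_pulse] = np.nan
        v = np.where(in_pulse, v_pulse, holding)
        i = np.where(
            in_pulse,
            model.channel_current(v_pulse) + model.leak_current(v_pulse, holding),
            0.0,
        ) + np.zeros_like(t)
        out.append(
            CapacitanceRecording(
                time=t,
                c_m=cm,
                current=i,
                pulse_window=(pre, pre + dur),
                truth={
                    "delta_cm": jump,
                    "duration": float(dur),
                    "pool": pool,
                    "model": model,
                    "baseline_cm": baseline_cm,
                    "noise_sd": noise_sd,
                    "v_pulse": v_pulse,
                },
            )
        )
    return out
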