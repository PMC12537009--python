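"""Synthetic auditory-brainstem-response (ABR) level series.

One averaged waveform per stimulus level (0...120 dB in 5 dB steps).  At and
above the true threshold a stereotyped wave complex (three alternating
Gaussian-windowed peaks, as in murine waves I-III) appears and grows
linearly with level; below threshold the trace is noise only.  The noise is
band-limited (Gaussian-smoothed then rescaled), emulating the residual
noise of an averaged, filtered ABR trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = ["ABRSeries", "simulate_abr_series"]

LEVELS_DB = np.arange(0, 121, 5)


@dataclass
class ABRSeries:
    """Stimulus levels, time base, and one averaged waveform per level."""

    levels: np.ndarray  # dB
    time: np.ndarray  # ms
    waveforms: np.ndarray  # (n_levels, n_samples), uV
    truth_threshold: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.waveforms.shape != (len(self.levels), len(self.time)):
            raise ValueError("need one waveform per level")
        if np.any(np.diff(self.levels) <= 0):
            raise ValueError("levels must be strictly increasing")


STIM_ONSET_MS = 8.0  # pre-stimulus baseline length


def _wave_complex(t: np.ndarray, onset: float = STIM_ONSET_MS) -> np.ndarray:
    """Unit-amplitude stereotyped ABR wave shape on time base t (ms)."""
    peaks = [(1.5, 0.25, 1.0), (2.7, 0.30, -0.8), (4.0, 0.35, 0.6)]
    w = np.zeros_like(t)
    for mu, sig, amp in peaks:
        w += amp * np.exp(-((t - onset - mu) ** 2) / (2 * sig**2))
    return w


def simulate_abr_series(
    true_threshold: float = 40.0,
    growth_rate: float = 0.1,
    noise_sd: float = 0.05,
    seed: int | np.random.Generator = 0,
    *,
    levels: np.ndarray = LEVELS_DB,
    duration: float = 18.0,
    stim_onset: float = STIM_ONSET_MS,
    sample_interval: float = 0.1,
    noise_smooth_ms: float = 0.6,
) -> ABRSeries:
    """Simulate one animal's level series for a single stimulus.

    Parameters
    ----------
    true_threshold : float
        Lowest level (dB) at which a response is present; the response
        amplitude at level L >= threshold is growth_rate * (L - threshold + 5).
    growth_rate : float
        Response growth (uV peak amplitude per dB); 0 means no response at
        any level.
    noise_sd : float
        SD (uV) of the band-limited residual noise.
    """
    if not 0 <= true_threshold <= 120:
        raise ValueError("true_threshold must be within 0...120 dB")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(int(round(duration / sample_interval))) * sample_interval
    shape = _wave_complex(t, onset=stim_onset)
    smooth_sigma = noise_smooth_ms / sample_interval
    waves = np.empty((len(levels), len(t)))
    for i, lvl in enumerate(levels):
        noise = gaussian_filter1d(rng.normal(size=len(t)), smooth_sigma, mode="wrap")
        sd = noise.std()
        noise = noise / sd * noise_sd if sd > 0 else noise
        amp = growth_rate * (lvl - true_threshold + 5.0) if lvl >= true_threshold else 0.0
        waves[i] = amp * shape + noise
    return ABRSeries(
        levels=np.asarray(levels, dtype=float),
        time=t,
        waveforms=waves,
        truth_threshold=float(true_threshold) if growth_rate > 0 else None,
        meta={"growth_rate": growth_rate, "noise_sd": noise_sd, "stim_onset": stim_onset},
    )
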