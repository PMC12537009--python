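"""Automated ABR threshold detection and group threshold-shift summaries.

The manual "clearly recognizable potential" call is replaced by an explicit
surrogate: a level is detectable when the response-window peak-to-peak
amplitude exceeds ``criterion_sd`` times the noise SD estimated from the
lowest-level waveform, and the threshold is the lowest level at which that
level *and every higher level* are detectable (guarding against isolated
noise crossings).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth.abr import ABRSeries

__all__ = ["ThresholdResult", "detect_threshold", "threshold_shift"]


@dataclass
class ThresholdResult:
    """Detected threshold (dB, or None if never detectable) plus diagnostics."""

    threshold: float | None
    criterion: float  # multiplier of the noise SD
    noise_sd: float  # uV
    per_level_amplitude: np.ndarray  # peak-to-peak uV, one per level
    detectable: np.ndarray  # boolean per level


def detect_threshold(
    series: ABRSeries,
    criterion_sd: float = 6.0,
    *,
    noise_window: tuple[float, float] = (0.0, 8.0),
    response_window: tuple[float, float] = (8.5, 12.5),
) -> ThresholdResult:
    """Detect the ABR threshold of one level series.

    The noise SD comes from the pre-stimulus ``noise_window`` of the
    lowest-level waveform; a level counts as detectable if its
    ``response_window`` peak-to-peak amplitude exceeds ``criterion_sd``
    x noise SD.  The default multiplier of 6 reflects that the statistic
    is a *range*: the null expectation of the peak-to-peak of a few
    effectively independent band-limited noise samples is already ~2.5
    noise SDs, and the SD itself is estimated from a finite baseline
    window, so a 6x bar keeps isolated noise crossings rare while a
    genuine evoked wave clears it by a wide margin.
    """
    if len(series.levels) < 2:
        raise ValueError("need at least two stimulus levels")
    n0, n1 = noise_window
    r0, r1 = response_window
    if max(n0, r0) < min(n1, r1):
        raise ValueError("noise and response windows must not overlap")
    t = series.time
    noise_sel = (t >= n0) & (t < n1)
    resp_sel = (t >= r0) & (t < r1)
    if noise_sel.sum() < 2 or resp_sel.sum() < 2:
        raise ValueError("windows select fewer than 2 samples")
    noise_sd = float(series.waveforms[0, noise_sel].std(ddof=1))
    amps = series.waveforms[:, resp_sel].max(axis=1) - series.waveforms[:, resp_sel].min(axis=1)
    detectable = amps > criterion_sd * noise_sd
    threshold = None
    # lowest level such that it and all higher levels are detectable
    ok_above = np.logical_and.accumulate(detectable[::-1])[::-1]
    hits = np.nonzero(ok_above)[0]
    if len(hits):
        threshold = float(series.levels[hits[0]])
    return ThresholdResult(
        threshold=threshold,
        criterion=criterion_sd,
        noise_sd=noise_sd,
        per_level_amplitude=np.asarray(amps, dtype=float),
        detectable=detectable,
    )


def threshold_shift(group_a: dict, group_b: dict) -> "pd.DataFrame":
    """Mean threshold difference (B - A) per frequency with SEM.

    ``group_a``/``group_b`` map frequency labels to per-animal thresholds
    (dB).  The SEM of the shift combines both groups' SEMs in quadrature and
    is NaN when either group has a single animal.  Statistical testing is
    delegated to `ribbonphys.stats`.
    """
    import pandas as pd

    if set(group_a) != set(group_b):
        raise ValueError(
            f"frequency labels differ: {sorted(group_a)} vs {sorted(group_b)}"
        )
    rows = []
    for freq in group_a:
        xa = np.asarray(group_a[freq], dtype=float)
        xb = np.asarray(group_b[freq], dtype=float)
        shift = float(xb.mean() - xa.mean())
        if len(xa) > 1 and len(xb) > 1:
            sem = float(
                np.sqrt(xa.var(ddof=1) / len(xa) + xb.var(ddof=1) / len(xb))
            )
        else:
            sem = float("nan")
        rows.append(
            {"frequency": freq, "shift_db": shift, "sem": sem, "n_a": len(xa), "n_b": len(xb)}
        )
    return pd.DataFrame(rows)
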