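"""Synthetic single-active-zone Ca2+-imaging movies.

A hotspot movie emulates spinning-disc imaging of Fluo4-FF fluorescence at
a ribbon-containing plane while the cell is driven by a pair of voltage
ramps (the second shifted by 5 ms).  Frames are acquired at 100 Hz with a
103 nm pixel size.  The local Ca2+ concentration at the hotspot follows the
instantaneous inward Ca2+ current on the ramp; pixel fluorescence is the
saturating indicator response shaped as an isotropic Gaussian spot on top
of the cell's resting fluorescence, with an out-of-cell margin at the
camera offset so a background region is resolvable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..models import ChannelModel, IndicatorModel
from ..protocols import VoltageProtocol

__all__ = ["HotspotMovie", "simulate_hotspot_movie"]

FRAME_INTERVAL_MS = 10.0  # 100 Hz
PIXEL_SIZE_UM = 0.103


@dataclass
class HotspotMovie:
    """Frame series for the two interleaved ramps at one imaging plane.

    ``frames_a``/``frames_b`` are the movies recorded during ramp A and the
    5 ms-shifted ramp B; both share the acquisition clock (frame i spans
    [i*dt, (i+1)*dt)).  ``onset_a``/``onset_b`` are the ramp onset times on
    that clock.  ``truth`` records the generator's ground truth (hotspot
    center, background level, channel model, analytic dF/F0).
    """

    frames_a: np.ndarray  # (n_frames, h, w)
    frames_b: np.ndarray
    frame_interval: float  # ms
    pixel_size: float  # um
    ramp_a: VoltageProtocol
    ramp_b: VoltageProtocol
    onset_a: float  # ms
    onset_b: float
    n_baseline: int
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frames_a.shape != self.frames_b.shape:
            raise ValueError("the two ramp movies must have identical shape")
        if self.n_baseline < 1:
            raise ValueError("need at least one baseline frame before ramp onset")

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.frames_a.shape[0]) * self.frame_interval

    def frame_mid_times(self) -> np.ndarray:
        return self.frame_times + 0.5 * self.frame_interval


def _ramp_segment(p: VoltageProtocol):
    if p.analysis_window is None:
        raise ValueError("ramp protocol lacks an analysis window")
    t0, t1 = p.analysis_window
    v0 = float(p.voltage_at(t0 + 1e-9)[0])
    v1 = float(p.voltage_at(t1 - 1e-9)[0])
    return t0, t1, v0, v1


def simulate_hotspot_movie(
    ramp_pair: tuple[VoltageProtocol, VoltageProtocol],
    model: ChannelModel,
    indicator: IndicatorModel | None = None,
    *,
    center: tuple[float, float] = (60.0, 50.0),
    sigma_px: float = 2.0,
    frame_shape: tuple[int, int] = (120, 168),
    cell_cols: int = 100,
    bg_offset: float = 20.0,
    frame_interval: float = FRAME_INTERVAL_MS,
    n_baseline: int = 10,
    n_tail: int = 2,
    noise_sd: float = 2.0,
    dff_peak: float | None = 1.6,
    c_scale: float | None = None,
    seed: int | np.random.Generator = 0,
) -> HotspotMovie:
    """Simulate the pair of hotspot movies for two interleaved voltage ramps.

    Parameters
    ----------
    center, sigma_px
        Hotspot center (row, col) and Gaussian width in pixels; the center
        must lie inside the in-cell region of the frame.
    cell_cols
        Columns < cell_cols are "inside the cell" (resting indicator
        fluorescence); the remaining columns carry only the camera offset,
        providing the out-of-cell background region.
    bg_offset
        Camera/stray-light offset added to every pixel (a.u.).
    dff_peak
        Target analytic center-pixel dF/F0 at the voltage of maximal Ca2+
        drive; fixes the Ca2+-per-current scaling.  Ignored if ``c_scale``
        is given.  The value 1.6 matches typical wild-type single-AZ
        maximal dF/F0.
    c_scale
        Ca2+ concentration (uM) per pA of inward Ca2+ current at the spot.
    """
    if indicator is None:
        indicator = IndicatorModel()
    if n_baseline < 3:
        raise ValueError("need >= 3 baseline frames")
    h, w = frame_shape
    cy, cx = center
    if not (0 <= cy < h and 0 <= cx < w):
        raise ValueError(f"spot center {center} outside frame {frame_shape}")
    if cx >= cell_cols:
        raise ValueError("spot center must lie inside the cell region")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    ramp_a, ramp_b = ramp_pair
    a0, a1, va0, va1 = _ramp_segment(ramp_a)
    b0, b1, vb0, vb1 = _ramp_segment(ramp_b)
    if (va0, va1, a1 - a0) != (vb0, vb1, b1 - b0):
        raise ValueError("the two ramps must be identical apart from the shift")
    shift = b0 - a0  # onset difference, ms
    duration = a1 - a0

    onset_a = n_baseline * frame_interval
    onset_b = onset_a + shift
    n_frames = n_baseline + int(np.ceil((shift + duration) / frame_interval)) + n_tail
    mids = (np.arange(n_frames) + 0.5) * frame_interval

    slope = (va1 - va0) / duration

    def drive_at(t_rel: np.ndarray) -> np.ndarray:
        """Inward Ca2+ current magnitude (pA) at time t_rel on the ramp."""
        v = va0 + slope * np.clip(t_rel, 0.0, duration)
        i = model.channel_current(v)
        d = np.where((t_rel >= 0) & (t_rel <= duration), np.maximum(0.0, -i), 0.0)
        return d

    # Ca2+ per pA scaling: hit the requested analytic peak dF/F0.
    probe = np.linspace(0.0, duration, 3001)
    unit_drive = drive_at(probe)
    max_drive = float(unit_drive.max())
    if c_scale is None:
        if max_drive > 0 and dff_peak is not None and dff_peak > 0:
            c_scale = indicator.conc_for_dff(dff_peak) / max_drive
        else:
            c_scale = 0.0

    yy, xx = np.mgrid[0:h, 0:w]
    gauss = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma_px**2))
    cell = (xx < cell_cols).astype(float)

    def render(onset: float) -> tuple[np.ndarray, np.ndarray]:
        frames = np.empty((n_frames, h, w), dtype=float)
        c_peaks = c_scale * drive_at(mids - onset)
        for j in range(n_frames):
            c_map = c_peaks[j] * gauss
            f = bg_offset + cell * indicator.fluorescence(c_map)
            frames[j] = f + rng.normal(0.0, noise_sd, size=f.shape)
        return frames, c_peaks

    frames_a, c_a = render(onset_a)
    frames_b, c_b = render(onset_b)

    dff_center_a = indicator.dff(c_a)
    # analytic 3x3-averaged dF/F0 at the hotspot (what extract_trace measures)
    offsets = np.array([(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)])
    g9 = np.exp(-(offsets**2).sum(axis=1) / (2.0 * sigma_px**2))
    dff_3x3_a = np.array(
        [(indicator.fluorescence(c * g9).mean() - indicator.f_min) / indicator.f_min for c in c_a]
    )
    truth = {
        "center": (float(cy), float(cx)),
        "sigma_px": sigma_px,
        "bg_offset": bg_offset,
        "f0": indicator.f_min,
        "model": model,
        "indicator": indicator,
        "c_scale": c_scale,
        "max_drive_pa": max_drive,
        "dff_center_a": dff_center_a,
        "dff_3x3_a": dff_3x3_a,
        "dff_peak_analytic": float(dff_center_a.max(initial=0.0)),
        "noise_sd": noise_sd,
    }
    return HotspotMovie(
        frames_a=frames_a,
        frames_b=frames_b,
        frame_interval=frame_interval,
        pixel_size=PIXEL_SIZE_UM,
        ramp_a=ramp_a,
        ramp_b=ramp_b,
        onset_a=onset_a,
        onset_b=onset_b,
        n_baseline=n_baseline,
        truth=truth,
    )
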