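"""Single-active-zone Ca2+-imaging analysis.

Pipeline: dF image -> plane/hotspot selection -> 3x3 intensity-time trace
with out-of-cell background subtraction -> dF/F0 -> dual-ramp
fluorescence-voltage (FV) curve -> modified-Boltzmann fit, G_max-line
normalization and Boltzmann fractional-activation fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.optimize import curve_fit

from .synth.hotspot import HotspotMovie

__all__ = [
    "HotspotTrace",
    "FVCurve",
    "FVFit",
    "ImagingError",
    "delta_f_image",
    "select_hotspot",
    "extract_trace",
    "build_fv",
    "fit_fv",
    "dff_max",
]


class ImagingError(RuntimeError):
    """Raised for degenerate imaging input (no activation limb, zero baseline...)."""


@dataclass
class HotspotTrace:
    """Background-subtracted 3x3 intensity-time profile of one hotspot."""

    time: np.ndarray  # frame mid-times, ms
    f_raw: np.ndarray  # 3x3-averaged intensity, a.u. (background already subtracted)
    f_bg: float  # background level that was subtracted, a.u.
    f0: float  # baseline mean after background subtraction, a.u.
    dff: np.ndarray  # (F - F0)/F0 per frame
    stim_mask: np.ndarray = field(default=None)  # frames whose midpoint lies on the ramp
    ramp_onset: float = 0.0  # ms on the acquisition clock
    which: str = "a"


@dataclass
class FVCurve:
    """Merged fluorescence-voltage curve from the two interleaved ramps."""

    voltages: np.ndarray  # mV, ascending
    dff: np.ndarray
    source: np.ndarray  # "a" / "b" per point
    duplicate_voltages: bool = False

    def __post_init__(self) -> None:
        if np.any(np.diff(self.voltages) < 0):
            raise ValueError("FV voltages must be sorted ascending")


@dataclass
class FVFit:
    """Staged FV analysis result.

    ``v_half``/``k`` come from the Boltzmann fit of the fractional-activation
    curve (FV fit divided by the G_max line); ``fv_params`` holds the
    modified-Boltzmann parameters (a, v_rev, v_half, k, offset) of
    dF/F0(V) = a (v_rev - V) P_o(V) + offset.
    """

    v_half: float
    k: float
    dff_max: float
    gmax_line: tuple  # (slope, intercept)
    fractional_activation: np.ndarray
    frac_voltages: np.ndarray
    fv_params: tuple
    line_window: tuple


# ---------------------------------------------------------------- dF image


def delta_f_image(
    movie: HotspotMovie,
    n_stim: int = 5,
    *,
    peak_drive_voltage: float = -17.0,
    which: str = "a",
) -> np.ndarray:
    """Pixelwise mean(stimulation frames) - mean(baseline frames).

    Stimulation frames are the ``n_stim`` frames whose midpoint command
    voltage is nearest ``peak_drive_voltage`` (the voltage of maximal Ca2+
    drive for these cells); baseline frames precede the ramp onset.
    """
    frames = movie.frames_a if which == "a" else movie.frames_b
    onset = movie.onset_a if which == "a" else movie.onset_b
    ramp = movie.ramp_a if which == "a" else movie.ramp_b
    nb = movie.n_baseline
    if nb < 3:
        raise ImagingError(f"need >= 3 baseline frames, movie has {nb}")
    mids = movie.frame_mid_times()
    t0, t1 = ramp.analysis_window
    dur = t1 - t0
    on_ramp = (mids >= onset) & (mids <= onset + dur)
    if on_ramp.sum() < n_stim:
        raise ImagingError(
            f"only {int(on_ramp.sum())} stimulation frames, need {n_stim}"
        )
    v_mid = np.full(len(mids), np.inf)
    rel = mids[on_ramp] - onset
    v_mid[on_ramp] = ramp.voltage_at(t0 + rel)
    order = np.argsort(np.abs(v_mid - peak_drive_voltage), kind="stable")
    stim_idx = np.sort(order[:n_stim])
    return frames[stim_idx].mean(axis=0) - frames[:nb].mean(axis=0)


def select_hotspot(delta_f_images: list[np.ndarray]) -> tuple[int, tuple[int, int]]:
    """Choose the plane with the strongest 3x3-smoothed dF signal.

    Returns (plane index, (row, col) of the maximum pixel); the earliest
    plane wins exact ties.  Raises for all-zero images (no hotspot).
    """
    if len(delta_f_images) < 1:
        raise ImagingError("need at least one plane")
    best = None
    for idx, img in enumerate(delta_f_images):
        img = np.asarray(img, dtype=float)
        sm = uniform_filter(img, size=3, mode="nearest")
        peak = float(sm.max())
        if best is None or peak > best[0]:
            # smoothing can plateau around a sharp maximum: within the
            # plateau, the brightest raw pixel is the hotspot center
            cand = np.argwhere(sm == peak)
            j = int(np.argmax(img[tuple(cand.T)]))
            best = (peak, idx, (int(cand[j][0]), int(cand[j][1])))
    if best[0] <= 0.0:
        raise ImagingError("degenerate: no plane shows a positive dF signal")
    return best[1], best[2]


# ---------------------------------------------------------------- trace


def _auto_background_block(
    shape: tuple[int, int], center: tuple[float, float], block: int = 60, stride: int = 4
) -> tuple[int, int]:
    """Top-left corner of the block-sized square maximally distant from center."""
    h, w = shape
    if h < block or w < block:
        raise ImagingError(f"frame {shape} too small for a {block}x{block} background block")
    rows = np.arange(0, h - block + 1, stride)
    cols = np.arange(0, w - block + 1, stride)
    cy, cx = center
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    d2 = (rr + block / 2 - cy) ** 2 + (cc + block / 2 - cx) ** 2
    j = int(np.argmax(d2))
    return int(rr.flat[j]), int(cc.flat[j])


def extract_trace(
    movie: HotspotMovie,
    center: tuple[int, int],
    *,
    which: str = "a",
    bg_region: tuple[int, int] | None = None,
    bg_block: int = 60,
    spot_exclusion_px: float = 10.0,
) -> HotspotTrace:
    """3x3-averaged intensity-time profile at `center`, background subtracted.

    The background is the mean of a ``bg_block`` x ``bg_block`` pixel region
    (auto-placed maximally distant from the hotspot, or given as the
    top-left corner via ``bg_region``), averaged over all frames.  F0 is the
    baseline-frame mean after background subtraction; dF/F0 follows.
    """
    frames = movie.frames_a if which == "a" else movie.frames_b
    onset = movie.onset_a if which == "a" else movie.onset_b
    ramp = movie.ramp_a if which == "a" else movie.ramp_b
    n, h, w = frames.shape
    cy, cx = int(center[0]), int(center[1])
    if not (1 <= cy < h - 1 and 1 <= cx < w - 1):
        raise ImagingError(f"hotspot center {center} closer than 1 px to the frame edge")
    if bg_region is None:
        r0, c0 = _auto_background_block((h, w), (cy, cx), block=bg_block)
    else:
        r0, c0 = bg_region
        if not (0 <= r0 <= h - bg_block and 0 <= c0 <= w - bg_block):
            raise ImagingError("background region does not fit in the frame")
    # block must not touch the hotspot
    near_r = np.clip(cy, r0, r0 + bg_block - 1)
    near_c = np.clip(cx, c0, c0 + bg_block - 1)
    if np.hypot(near_r - cy, near_c - cx) < spot_exclusion_px:
        raise ImagingError("background region overlaps the hotspot")
    f_bg = float(frames[:, r0 : r0 + bg_block, c0 : c0 + bg_block].mean())
    f_raw = frames[:, cy - 1 : cy + 2, cx - 1 : cx + 2].mean(axis=(1, 2)) - f_bg
    f0 = float(f_raw[: movie.n_baseline].mean())
    noise_scale = float(frames[: movie.n_baseline].std())
    if f0 <= 3.0 * noise_scale / np.sqrt(9 * movie.n_baseline) or f0 <= 0:
        raise ImagingError("zero baseline: F0 indistinguishable from background")
    mids = movie.frame_mid_times()
    t0, t1 = ramp.analysis_window
    stim = (mids >= onset) & (mids <= onset + (t1 - t0))
    return HotspotTrace(
        time=mids,
        f_raw=f_raw,
        f_bg=f_bg,
        f0=f0,
        dff=(f_raw - f0) / f0,
        stim_mask=stim,
        ramp_onset=onset,
        which=which,
    )


# ---------------------------------------------------------------- FV curve


def build_fv(
    trace_a: HotspotTrace,
    trace_b: HotspotTrace,
    ramps,
    ljp: float = 0.0,
) -> FVCurve:
    """Merge the two shifted-ramp dF/F0 traces into one voltage-sorted FV curve.

    Each stimulation frame is assigned the command voltage at its midpoint;
    the interleaved 5 ms shift halves the effective voltage spacing.  Pass
    ``ljp`` > 0 when the ramps are expressed as raw amplifier commands.
    """
    ramp_a, ramp_b = ramps
    if len(trace_a.time) != len(trace_b.time):
        raise ValueError("mismatched frame counts between the two ramp traces")
    pts = []
    for trace, ramp, tag in ((trace_a, ramp_a, "a"), (trace_b, ramp_b, "b")):
        t0, t1 = ramp.analysis_window
        v0 = float(ramp.voltage_at(t0 + 1e-9)[0])
        v1 = float(ramp.voltage_at(t1 - 1e-9)[0])
        if v1 == v0:
            raise ValueError("flat ramp: FV undefined without a voltage span")
        slope = (v1 - v0) / (t1 - t0)
        rel = trace.time - trace.ramp_onset
        sel = trace.stim_mask if trace.stim_mask is not None else (rel >= 0) & (rel <= t1 - t0)
        for t_rel, d in zip(rel[sel], trace.dff[sel]):
            pts.append((v0 + slope * t_rel - ljp, float(d), tag))
    pts.sort(key=lambda p: p[0])
    v = np.array([p[0] for p in pts])
    dup = bool(np.any(np.diff(v) == 0))
    return FVCurve(
        voltages=v,
        dff=np.array([p[1] for p in pts]),
        source=np.array([p[2] for p in pts]),
        duplicate_voltages=dup,
    )


# ---------------------------------------------------------------- FV fit


def _modified_boltzmann(v, a, v_rev, v_half, k, c):
    return a * (v_rev - v) / (1.0 + np.exp((v_half - v) / k)) + c


def _boltzmann(v, v_half, k):
    return 1.0 / (1.0 + np.exp((v_half - v) / k))


def fit_fv(
    fv: FVCurve,
    *,
    line_margin: tuple[float, float] = (10.0, 10.0),
    v_rev_init: float = 45.0,
    v_rev_bounds: tuple[float, float] = (20.0, 80.0),
) -> FVFit:
    """Staged FV analysis.

    1. Fit the modified Boltzmann dF/F0(V) = a (v_rev - V) P_o(V) + c
       (sigmoidal activation times the linear driving force).
    2. Fit a line (the G_max line) to the descending limb, over voltages
       from ``peak + line_margin[0]`` to ``v_rev - line_margin[1]``.
    3. Divide the FV fit by the G_max line to obtain fractional activation
       over the pre-reversal range, and
    4. fit that ratio with a plain Boltzmann -> (v_half, k).

    ``dff_max`` is the mean of the 5 points of highest Ca2+ drive (nearest
    the FV peak voltage).  Raises `ImagingError` at the failing stage.
    """
    v = np.asarray(fv.voltages, dtype=float)
    d = np.asarray(fv.dff, dtype=float)
    if len(v) < 8:
        raise ImagingError(f"FV curve has only {len(v)} points")
    span = float(d.max() - d.min())
    if span < 1e-9 or d.max() <= 0:
        raise ImagingError("no activation limb: flat FV curve")

    # stage 1: modified Boltzmann
    j_peak = int(np.argmax(d))
    v_peak0 = float(v[j_peak])
    a0 = max(d.max(), 1e-6) / max(v_rev_init - v_peak0, 5.0)
    half = np.nonzero(d[: j_peak + 1] >= 0.5 * d.max())[0]
    v_half0 = float(v[half[0]]) if len(half) else v_peak0 - 10.0
    p0 = (a0, v_rev_init, v_half0, 6.0, 0.0)
    bounds = (
        (0.0, v_rev_bounds[0], -80.0, 1.0, -np.inf),
        (np.inf, v_rev_bounds[1], 10.0, 30.0, np.inf),
    )
    try:
        popt, _ = curve_fit(_modified_boltzmann, v, d, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        raise ImagingError(f"stage 1 (modified Boltzmann) did not converge: {exc}") from exc
    a_f, v_rev_f, v_half_f, k_f, c_f = (float(x) for x in popt)

    # stage 2: G_max line on the descending limb
    grid = np.linspace(v.min(), v.max(), 1001)
    v_peak_fit = float(grid[np.argmax(_modified_boltzmann(grid, *popt))])
    lo = v_peak_fit + line_margin[0]
    hi = v_rev_f - line_margin[1]
    line_sel = (v >= lo) & (v <= hi)
    if line_sel.sum() < 3:
        raise ImagingError(
            f"stage 2: only {int(line_sel.sum())} FV points in the decay window [{lo:.1f}, {hi:.1f}] mV"
        )
    slope, intercept = np.polyfit(v[line_sel], d[line_sel], 1)
    slope, intercept = float(slope), float(intercept)

    # stage 3: fractional activation = FV fit / G_max line, pre-reversal range
    frac_sel = v <= hi
    v_frac = v[frac_sel]
    line_vals = slope * v_frac + intercept
    if np.any(line_vals <= 0):
        good = line_vals > 0
        v_frac, line_vals = v_frac[good], line_vals[good]
    if len(v_frac) < 6:
        raise ImagingError("stage 3: G_max line non-positive over the activation range")
    frac = _modified_boltzmann(v_frac, *popt) / line_vals
    frac = np.clip(frac, 0.0, 1.5)

    # stage 4: Boltzmann fit of the fractional-activation curve
    try:
        (v_half, k), _ = curve_fit(
            _boltzmann,
            v_frac,
            frac,
            p0=(v_half_f, max(k_f, 2.0)),
            bounds=((-80.0, 0.5), (20.0, 30.0)),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise ImagingError(f"stage 4 (Boltzmann of fractional activation) failed: {exc}") from exc

    order = np.argsort(np.abs(v - v_peak_fit), kind="stable")
    dff_max_val = float(d[np.sort(order[:5])].mean())
    return FVFit(
        v_half=float(v_half),
        k=float(k),
        dff_max=dff_max_val,
        gmax_line=(slope, intercept),
        fractional_activation=_boltzmann(v_frac, v_half, k),
        frac_voltages=v_frac,
        fv_params=(a_f, v_rev_f, v_half_f, k_f, c_f),
        line_window=(lo, hi),
    )


def dff_max(trace: HotspotTrace) -> float:
    """Mean of the 5 consecutive stimulation points centered on the dF/F0 maximum."""
    if trace.stim_mask is None or trace.stim_mask.sum() < 5:
        raise ImagingError("need >= 5 stimulation frames")
    idx = np.nonzero(trace.stim_mask)[0]
    d = trace.dff[idx]
    j = int(np.argmax(d))
    lo = min(max(0, j - 2), len(d) - 5)
    return float(d[lo : lo + 5].mean())
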