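"""Whole-cell voltage-clamp analysis.

Covers recording quality control, p/4 leak subtraction, offline liquid-
junction-potential correction, IV extraction, Boltzmann fractional-
activation fitting, exocytosis quantification (dCm, Q_Ca) and membrane-
capacitance estimation from the measured admittance (Lindau-Neher style
three-element circuit inversion).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit

from .models import ChannelModel
from .synth.capacitance import CapacitanceRecording
from .synth.currents import CurrentSweep

__all__ = [
    "RecordingQC",
    "qc_recording",
    "p4_leak_correct",
    "ljp_correct",
    "IVCurve",
    "extract_iv",
    "ActivationFit",
    "FitError",
    "fit_activation",
    "compute_qca",
    "compute_delta_cm",
    "circuit_admittance",
    "estimate_cm_from_admittance",
    "ExocytosisPoint",
    "ExocytosisSummary",
    "exocytosis_curve",
]

LJP_MV = 17.0

# QC inclusion thresholds, by configuration
RUPTURED_MAX_RS = 14.0  # MOhm
RUPTURED_MAX_LEAK = 50.0  # |pA| at holding
RUPTURED_MAX_RUNDOWN = 0.25
PERFORATED_MAX_RS = 30.0  # MOhm (strict <)
PERFORATED_MAX_LEAK = 30.0  # |pA| (strict <)


class FitError(RuntimeError):
    """Raised when an activation fit fails or the IV is degenerate."""


# ---------------------------------------------------------------- QC


@dataclass(frozen=True)
class RecordingQC:
    """Per-recording quality control verdict.

    Ruptured-patch recordings pass iff R_s <= 14 MOhm, |leak| <= 50 pA at
    holding, and Ca2+ current rundown <= 25%.  Perforated-patch recordings
    pass iff |leak| < 30 pA and R_s < 30 MOhm.
    """

    mode: str  # "ruptured" | "perforated"
    r_s: float  # MOhm
    leak_current_hold: float  # pA
    rundown_fraction: float | None = None
    passed: bool = False
    reasons: tuple = ()


def qc_recording(
    mode: str,
    r_s: float | None,
    leak_current_hold: float | None,
    rundown_fraction: float | None = None,
) -> RecordingQC:
    """Apply the inclusion criteria for the stated patch configuration."""
    if mode not in ("ruptured", "perforated"):
        raise ValueError(f"mode must be 'ruptured' or 'perforated', got {mode!r}")
    for name, val in (("r_s", r_s), ("leak_current_hold", leak_current_hold)):
        if val is None:
            raise ValueError(f"missing QC field: {name}")
    reasons = []
    if mode == "ruptured":
        if rundown_fraction is None:
            raise ValueError("missing QC field: rundown_fraction")
        if r_s > RUPTURED_MAX_RS:
            reasons.append(f"R_s {r_s} MOhm > {RUPTURED_MAX_RS}")
        if abs(leak_current_hold) > RUPTURED_MAX_LEAK:
            reasons.append(f"|leak| {abs(leak_current_hold)} pA > {RUPTURED_MAX_LEAK}")
        if rundown_fraction > RUPTURED_MAX_RUNDOWN:
            reasons.append(f"rundown {rundown_fraction:.0%} > {RUPTURED_MAX_RUNDOWN:.0%}")
    else:
        if abs(leak_current_hold) >= PERFORATED_MAX_LEAK:
            reasons.append(f"|leak| {abs(leak_current_hold)} pA >= {PERFORATED_MAX_LEAK}")
        if r_s >= PERFORATED_MAX_RS:
            reasons.append(f"R_s {r_s} MOhm >= {PERFORATED_MAX_RS}")
    return RecordingQC(
        mode=mode,
        r_s=r_s,
        leak_current_hold=leak_current_hold,
        rundown_fraction=rundown_fraction,
        passed=not reasons,
        reasons=tuple(reasons),
    )


# ---------------------------------------------------------------- corrections


def p4_leak_correct(sweep: CurrentSweep) -> CurrentSweep:
    """Subtract the scaled p/4 leak estimate: I_corr = I - 4 * mean(leak sweeps)."""
    if not sweep.leak_sweeps:
        raise ValueError("sweep carries no leak sweeps; p/4 correction impossible")
    leak = np.mean(np.stack(sweep.leak_sweeps), axis=0)
    corrected = sweep.current - 4.0 * leak
    meta = dict(sweep.meta)
    meta["leak_corrected"] = True
    return CurrentSweep(
        time=sweep.time,
        voltage=sweep.voltage,
        current=corrected,
        leak_sweeps=(),
        protocol=sweep.protocol,
        meta=meta,
    )


def ljp_correct(voltages, ljp: float = LJP_MV) -> np.ndarray:
    """Offline liquid-junction-potential correction: V_true = V_command - LJP."""
    return np.asarray(voltages, dtype=float) - ljp


# ---------------------------------------------------------------- IV extraction


@dataclass
class IVCurve:
    """Current-voltage relation: one averaged current per step voltage."""

    voltages: np.ndarray  # mV, strictly increasing
    currents: np.ndarray  # pA
    windows: list = field(default_factory=list)  # (start, end) ms per step

    def __post_init__(self) -> None:
        if len(self.voltages) != len(self.currents):
            raise ValueError("one current per voltage required")
        if np.any(np.diff(self.voltages) <= 0):
            raise ValueError("voltages must be strictly increasing")


def extract_iv(
    sweeps: list[CurrentSweep],
    window_len: float = 5.0,
    *,
    ljp: float = 0.0,
) -> IVCurve:
    """Build the IV curve from a leak-corrected step family.

    For each sweep the sliding window of length ``window_len`` (ms) inside
    the depolarization that minimizes the mean current (i.e. the maximal
    inward region) is averaged; on exact ties the earliest window wins.
    Step voltages are LJP-corrected with ``ljp`` (pass 17 for raw amplifier
    commands; the synthetic protocols already store corrected voltages).
    """
    points = []
    for sweep in sweeps:
        proto = sweep.protocol
        if proto is None or proto.analysis_window is None:
            raise ValueError("sweep lacks a protocol analysis window")
        t0, t1 = proto.analysis_window
        if t1 - t0 < window_len:
            raise ValueError(
                f"step of {t1 - t0} ms shorter than the {window_len} ms analysis window"
            )
        dt = proto.sample_interval
        sel = (sweep.time >= t0) & (sweep.time < t1)
        seg = sweep.current[sel]
        n_win = max(1, int(round(window_len / dt)))
        # mean over each contiguous window of n_win samples
        c = np.concatenate([[0.0], np.cumsum(seg)])
        means = (c[n_win:] - c[:-n_win]) / n_win
        j = int(np.argmin(means))  # argmin returns the earliest tie
        t_start = sweep.time[sel][0] + j * dt
        v_step = float(np.median(sweep.voltage[sel])) - ljp
        points.append((v_step, float(means[j]), (t_start, t_start + window_len)))
    points.sort(key=lambda p: p[0])
    return IVCurve(
        voltages=np.array([p[0] for p in points]),
        currents=np.array([p[1] for p in points]),
        windows=[p[2] for p in points],
    )


# ---------------------------------------------------------------- activation fit


@dataclass
class ActivationFit:
    """Boltzmann activation parameters fitted to an IV curve.

    ``i_max`` is reported as a magnitude (pA); ``i_max_sign`` keeps the
    inward-negative sign convention explicit.
    """

    v_half: float  # mV
    k: float  # mV
    g_max: float  # nS
    v_rev: float  # mV
    i_max: float  # pA, magnitude of the most-inward IV current
    i_max_sign: int
    fractional_activation: np.ndarray  # per IV voltage, in [0, 1]
    fit_rms: float  # pA

    def open_probability(self, v):
        v = np.asarray(v, dtype=float)
        return 1.0 / (1.0 + np.exp((self.v_half - v) / self.k))


def _iv_model(v, g_max, v_rev, v_half, k):
    return g_max * (v - v_rev) / (1.0 + np.exp((v_half - v) / k))


def fit_activation(
    iv: IVCurve,
    *,
    v_rev_init: float = 45.0,
    v_rev_bounds: tuple[float, float] = (20.0, 80.0),
    k_init: float = 7.0,
) -> ActivationFit:
    """Least-squares fit of I(V) = g_max (V - v_rev) P_o(V) to the IV curve.

    Initialization is deterministic: conductances G = I/(V - v_rev_init)
    are normalized to locate the half-activation voltage; k starts at
    ``k_init``.  Raises `FitError` for degenerate (flat) IVs or on
    non-convergence.
    """
    v = np.asarray(iv.voltages, dtype=float)
    i = np.asarray(iv.currents, dtype=float)
    if len(v) < 8:
        raise FitError(f"need >= 8 IV points spanning activation, got {len(v)}")
    i_span = float(np.max(np.abs(i)))
    if i_span < 1e-6:
        raise FitError("degenerate IV: no measurable current (g_max ~ 0)")

    mask = np.abs(v - v_rev_init) > 5.0
    g = np.zeros_like(v)
    g[mask] = i[mask] / (v[mask] - v_rev_init)
    g_max0 = float(np.max(g))
    if g_max0 <= 0:
        raise FitError("degenerate IV: no inward conductance limb")
    gn = np.clip(g / g_max0, 0.0, 1.0)
    above = np.nonzero(gn >= 0.5)[0]
    v_half0 = float(v[above[0]]) if len(above) else float(v[np.argmax(gn)])

    p0 = (g_max0, v_rev_init, v_half0, k_init)
    bounds = (
        (0.0, v_rev_bounds[0], -80.0, 0.5),
        (np.inf, v_rev_bounds[1], 20.0, 30.0),
    )
    try:
        popt, _ = curve_fit(_iv_model, v, i, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"activation fit did not converge from p0={p0}: {exc}") from exc
    g_max, v_rev, v_half, k = (float(x) for x in popt)
    resid = i - _iv_model(v, *popt)
    j_min = int(np.argmin(i))
    frac = 1.0 / (1.0 + np.exp((v_half - v) / k))
    return ActivationFit(
        v_half=v_half,
        k=k,
        g_max=g_max,
        v_rev=v_rev,
        i_max=float(abs(i[j_min])),
        i_max_sign=int(np.sign(i[j_min]) or 1),
        fractional_activation=frac,
        fit_rms=float(np.sqrt(np.mean(resid**2))),
    )


# ---------------------------------------------------------------- exocytosis


def compute_qca(sweep: CurrentSweep, pulse_window: tuple[float, float]) -> float:
    """Ca2+ charge: trapezoidal time integral of the leak-subtracted current
    over the depolarization, returned as a positive magnitude in pC."""
    t0, t1 = pulse_window
    if t1 <= t0:
        raise ValueError("empty integration window")
    sel = (sweep.time >= t0) & (sweep.time <= t1)
    if sel.sum() < 2:
        raise ValueError("integration window contains fewer than 2 samples")
    q = np.trapezoid(sweep.current[sel], sweep.time[sel])  # pA * ms = fC
    return abs(float(q)) / 1000.0  # pC


def compute_delta_cm(
    rec: CapacitanceRecording, seg_len: float = 400.0, skip: float = 100.0
) -> float:
    """Exocytic capacitance jump (fF).

    dCm = mean(Cm over ``seg_len`` ms starting ``skip`` ms after the pulse)
    minus mean(Cm over ``seg_len`` ms ending at pulse onset).
    """
    p0, p1 = rec.pulse_window
    t = rec.time
    pre_sel = (t >= p0 - seg_len) & (t < p0)
    post_sel = (t >= p1 + skip) & (t < p1 + skip + seg_len)
    dt = float(np.median(np.diff(t)))
    need = int(round(seg_len / dt))
    if pre_sel.sum() < need:
        raise ValueError(
            f"need {seg_len} ms of Cm before the pulse, have {pre_sel.sum() * dt:.0f} ms"
        )
    if post_sel.sum() < need:
        raise ValueError(
            f"need {skip}+{seg_len} ms of Cm after the pulse, have {post_sel.sum() * dt:.0f} ms"
        )
    pre = np.nanmean(rec.c_m[pre_sel])
    post = np.nanmean(rec.c_m[post_sel])
    return float(post - pre)


@dataclass(frozen=True)
class ExocytosisPoint:
    """One depolarization duration with its capacitance jump and Ca2+ charge."""

    duration: float  # ms
    delta_cm: float  # fF
    q_ca: float | None = None  # pC

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")


@dataclass
class ExocytosisSummary:
    """dCm/Q_Ca versus duration plus fast-pool and sustained-rate estimates."""

    durations: np.ndarray
    delta_cm: np.ndarray
    q_ca: np.ndarray
    fast_delta_cm: float  # mean dCm for durations <= fast_cutoff
    sustained_rate: float | None  # fF/ms slope over durations > fast_cutoff
    sustained_intercept: float | None
    fast_cutoff: float


def exocytosis_curve(
    points: list[ExocytosisPoint], fast_cutoff: float = 20.0
) -> ExocytosisSummary:
    """Summarize the dCm / Q_Ca versus pulse-duration relation.

    The fast (readily-releasable) component is the mean dCm over durations
    <= ``fast_cutoff`` ms; the sustained component is the slope of a linear
    fit over longer durations (None when fewer than two such durations).
    """
    if len(points) < 1:
        raise ValueError("need at least one exocytosis point")
    pts = sorted(points, key=lambda p: p.duration)
    d = np.array([p.duration for p in pts])
    dcm = np.array([p.delta_cm for p in pts])
    q = np.array([np.nan if p.q_ca is None else p.q_ca for p in pts])
    fast_mask = d <= fast_cutoff
    fast = float(np.mean(dcm[fast_mask])) if fast_mask.any() else float("nan")
    slow_mask = d > fast_cutoff
    if slow_mask.sum() >= 2:
        slope, intercept = np.polyfit(d[slow_mask], dcm[slow_mask], 1)
        slope, intercept = float(slope), float(intercept)
    else:
        slope = intercept = None
    return ExocytosisSummary(
        durations=d,
        delta_cm=dcm,
        q_ca=q,
        fast_delta_cm=fast,
        sustained_rate=slope,
        sustained_intercept=intercept,
        fast_cutoff=fast_cutoff,
    )


# ---------------------------------------------------------------- admittance


def circuit_admittance(c_m: float, g_m: float, g_s: float, omega: float) -> complex:
    """Forward model: admittance (nS) of the series-conductance three-element
    circuit g_s in series with (g_m parallel c_m) at angular frequency omega.

    ``c_m`` in fF, conductances in nS, omega in rad/s.
    """
    y_m = g_m + 1j * omega * c_m * 1e-6  # fF * rad/s -> nS requires 1e-6
    return g_s * y_m / (g_s + y_m)


def estimate_cm_from_admittance(
    y_real: float, y_imag: float, omega: float, g_t: float
) -> tuple[float, float, float]:
    """Invert the measured admittance to (c_m fF, g_m nS, g_s nS).

    Given the real/imaginary admittance at ``omega`` plus the DC conductance
    ``g_t`` = g_s g_m / (g_s + g_m), the three-element circuit has the unique
    solution

        g_s = (A^2 + B^2 - A T) / (A - T)
        g_m = T g_s / (g_s - T)
        c_m = g_s^2 B / (omega ((g_s - A)^2 + B^2))

    with A = y_real, B = y_imag, T = g_t.  Raises on physically
    inconsistent input (B <= 0 or A <= T).
    """
    a, b, t = float(y_real), float(y_imag), float(g_t)
    if b <= 0:
        raise ValueError("y_imag must be > 0: no capacitive component to estimate")
    if a <= t:
        raise ValueError(
            "inconsistent input: Re(Y) must exceed the DC conductance at omega > 0"
        )
    g_s = (a * a + b * b - a * t) / (a - t)
    if g_s <= t:
        raise ValueError("inconsistent input: implied series conductance <= DC conductance")
    g_m = t * g_s / (g_s - t)
    c_m = g_s**2 * b / (omega * ((g_s - a) ** 2 + b * b)) * 1e6  # nS/ (rad/s) -> fF
    return c_m, g_m, g_s
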