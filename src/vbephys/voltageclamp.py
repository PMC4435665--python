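"""Voltage-clamp pipelines: whole-cell capacitance from the 5-mV transient,
offline linear leak correction, current-density I-V curves, prepulse
separation of T-type and high-voltage-activated (HVA) calcium currents,
blocker-sensitive current extraction by sweep subtraction, tail-current
activation curves with Boltzmann fits, and Hill EC50 dose-response fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .traces import VOLTAGE_CLAMP, ProtocolLadder, Sweep


@dataclass
class IVCurve:
    """Peak current (and density) versus test potential."""

    voltages: np.ndarray  # mV
    peak_current_pA: np.ndarray
    capacitance_pF: float | None = None
    current_density_pA_per_pF: np.ndarray | None = None

    def __post_init__(self):
        self.voltages = np.asarray(self.voltages, float)
        self.peak_current_pA = np.asarray(self.peak_current_pA, float)
        if len(self.voltages) != len(self.peak_current_pA):
            raise ValueError("voltage/current length mismatch")
        if self.capacitance_pF is not None and self.current_density_pA_per_pF is None:
            self.current_density_pA_per_pF = self.peak_current_pA / self.capacitance_pF


@dataclass
class ActivationCurve:
    """Normalized tail-current amplitudes vs conditioning potential."""

    prepulse_mV: np.ndarray
    tail_peak_pA: np.ndarray
    normalized: np.ndarray
    fit: dict = field(default_factory=dict)  # v50_mV, slope_mV, residual

    def __post_init__(self):
        self.prepulse_mV = np.asarray(self.prepulse_mV, float)
        self.tail_peak_pA = np.asarray(self.tail_peak_pA, float)
        self.normalized = np.asarray(self.normalized, float)


@dataclass
class DoseResponse:
    concentrations_nM: np.ndarray
    fraction_blocked: np.ndarray
    ec50_nM: float | None = None
    hill_n: float | None = None

    def __post_init__(self):
        self.concentrations_nM = np.asarray(self.concentrations_nM, float)
        self.fraction_blocked = np.asarray(self.fraction_blocked, float)
        if self.ec50_nM is not None and self.ec50_nM <= 0:
            raise ValueError("ec50 must be > 0")


def _step_bounds(sweep: Sweep) -> tuple[int, int, float, float]:
    """Indices and levels of the largest command step (onset, offset)."""
    cmd = sweep.command
    edges = np.flatnonzero(np.diff(cmd) != 0) + 1
    if len(edges) == 0:
        raise ValueError("no step found in command")
    on = edges[0]
    off = edges[1] if len(edges) > 1 else len(cmd)
    return int(on), int(off), float(cmd[0]), float(cmd[on])


def whole_cell_capacitance(
    transient_sweep: Sweep, transient_ms: float = 8.0, rs_correct: bool = True
) -> float:
    """Whole-cell capacitance from a small voltage-step transient.

    Cm = integral of (I - I_ss) over the capacitive transient, divided by the
    step magnitude (pA*ms/mV = pF).  The steady-state current is taken as a
    straight line fitted to the post-transient segment of the step, which
    removes slow gating drift, and the integral runs over the first
    ``transient_ms`` of the step (the transient itself lasts well under 1 ms).

    With ``rs_correct`` (default) the estimate is divided by the squared
    voltage-divider factor ``(1 - g_app * R_s)**2``, where the access
    resistance is read off the instantaneous current jump ``R_s = dV/I_peak``
    and ``g_app`` is the apparent steady-state conductance: this removes the
    systematic underestimate an uncompensated series resistance causes, using
    only quantities measured from the sweep itself.
    """
    if transient_sweep.mode != VOLTAGE_CLAMP:
        raise ValueError("capacitance estimation expects a voltage-clamp sweep")
    on, off, v0, v1 = _step_bounds(transient_sweep)
    dv = v1 - v0
    if dv == 0:
        raise ValueError("step not found in command")
    i = transient_sweep.response
    dt = transient_sweep.dt
    n_tr = min(max(1, int(round(transient_ms / dt))), off - on - 2)
    # pre-step baseline and late-segment drift line
    base = float(np.mean(i[max(0, on - int(5.0 / dt)) : on]))
    t_late = np.arange(on + n_tr, off) * dt
    slope, intercept = np.polyfit(t_late, i[on + n_tr : off], 1)
    t_tr = np.arange(on, on + n_tr) * dt
    q = float(np.trapezoid(i[on : on + n_tr] - (slope * t_tr + intercept), dx=dt))
    cm = q / dv
    if rs_correct:
        i_peak = i[on] - base
        i_ss = slope * t_late[0] + intercept - base
        if i_peak != 0 and abs(i_ss) < abs(i_peak):
            rs = dv / i_peak * 1000.0  # MOhm
            g_app = i_ss / dv  # nS
            cm = cm / (1.0 - g_app * rs / 1000.0) ** 2
    return cm


def leak_correct(
    ladder: ProtocolLadder,
    calibration: ProtocolLadder | None = None,
    cal_vmax: float = -80.0,
) -> ProtocolLadder:
    """Offline linear (ohmic) leak subtraction.

    The leak line I = g (V - E) is fitted to the steady-state currents of
    calibration steps lying in a voltage range where the gated channels are
    closed (test potential <= ``cal_vmax``; the calibration steps may come
    from the analyzed ladder itself or a dedicated small-step ladder), then
    the scaled leak is subtracted from every sample of every sweep using the
    command trace.  Idempotent up to noise.
    """
    cal = calibration if calibration is not None else ladder
    pts = []
    for amp, sw in zip(cal.protocol.amplitudes, cal.sweeps):
        if amp > cal_vmax:
            continue
        on, off, _, v_step = _step_bounds_or_flat(sw)
        n_ss = max(1, (off - on) // 4)
        pts.append((v_step, float(np.mean(sw.response[off - n_ss : off]))))
    if len(pts) < 2:
        raise ValueError(
            f"need >= 2 calibration steps at or below {cal_vmax} mV, got {len(pts)}"
        )
    v, i = np.array(pts).T
    g, b = np.polyfit(v, i, 1)  # I = g*V + b  =>  E = -b/g
    out = []
    for sw in ladder.sweeps:
        c = sw.copy()
        c.response = c.response - (g * c.command + b)
        c.meta["leak_corrected"] = True
        c.meta["leak_g_nS"] = float(g)
        c.meta["leak_E_mV"] = float(-b / g) if g != 0 else math.nan
        out.append(c)
    return ProtocolLadder(ladder.protocol, out)


def _step_bounds_or_flat(sweep: Sweep):
    try:
        return _step_bounds(sweep)
    except ValueError:
        n = sweep.n_samples
        return n // 4, 3 * n // 4, float(sweep.command[0]), float(sweep.command[0])


def build_iv(
    ladder: ProtocolLadder,
    capacitance: float | None = None,
    blank_ms: float = 2.0,
    direction: str = "inward",
) -> IVCurve:
    """Peak current per test potential over a (leak-corrected) ladder.

    The peak is the signed extremum toward the expected current direction
    (inward by default: calcium and HCN currents here are inward), measured
    inside the test pulse after blanking the first ``blank_ms`` of capacitive
    transient.
    """
    proto = ladder.protocol
    on = ladder.sweeps[0].index_at(proto.step_start_ms + blank_ms)
    off = ladder.sweeps[0].index_at(proto.step_end_ms)
    peaks = []
    for sw in ladder.sweeps:
        seg = sw.response[on:off]
        peaks.append(float(np.min(seg) if direction == "inward" else np.max(seg)))
    return IVCurve(
        voltages=np.array(proto.amplitudes),
        peak_current_pA=np.array(peaks),
        capacitance_pF=capacitance,
    )


def zd_sensitive_current(
    control_ladder: ProtocolLadder, blocked_ladder: ProtocolLadder
) -> ProtocolLadder:
    """Sweep-wise subtraction control - blocked (isolates the drug-sensitive
    component, e.g. the ZD7288-sensitive I_h)."""
    pa, pb = control_ladder.protocol, blocked_ladder.protocol
    if pa.amplitudes != pb.amplitudes:
        raise ValueError("protocol mismatch: amplitudes differ")
    out = []
    for a, b in zip(control_ladder.sweeps, blocked_ladder.sweeps):
        if a.n_samples != b.n_samples or a.dt != b.dt:
            raise ValueError("protocol mismatch: sweep shapes differ")
        c = a.copy()
        c.response = a.response - b.response
        c.meta["subtracted"] = True
        out.append(c)
    return ProtocolLadder(pa, out)


def isolate_t_type(
    total_iv_ladder: ProtocolLadder,
    prepulse_iv_ladder: ProtocolLadder,
    capacitance: float | None = None,
    blank_ms: float = 2.0,
) -> tuple[IVCurve, IVCurve]:
    """Prepulse separation of T-type and HVA calcium currents.

    The inactivating prepulse (-50 mV/100 ms) removes the T-type component,
    so the prepulse ladder's I-V is the HVA current; subtracting it sweep-wise
    from the no-prepulse (total) ladder yields the T-type component.
    Both ladders must be leak-corrected and share the test-voltage vector.
    Returns ``(T, HVA)`` I-V curves.
    """
    pa, pb = total_iv_ladder.protocol, prepulse_iv_ladder.protocol
    if pa.amplitudes != pb.amplitudes:
        raise ValueError("voltage-vector mismatch between ladders")
    hva = build_iv(prepulse_iv_ladder, capacitance, blank_ms)
    # align on the test-step window of each protocol before subtracting
    t_peaks = []
    for amp, sa, sb in zip(
        pa.amplitudes, total_iv_ladder.sweeps, prepulse_iv_ladder.sweeps
    ):
        a0 = sa.index_at(pa.step_start_ms + blank_ms)
        a1 = sa.index_at(pa.step_end_ms)
        b0 = sb.index_at(pb.step_start_ms + blank_ms)
        diff = sa.response[a0:a1] - sb.response[b0 : b0 + (a1 - a0)]
        t_peaks.append(float(np.min(diff)))
    t_curve = IVCurve(
        voltages=np.array(pa.amplitudes),
        peak_current_pA=np.array(t_peaks),
        capacitance_pF=capacitance,
    )
    return t_curve, hva


def tail_current_activation(
    zd_sensitive_ladder: ProtocolLadder,
    blank_ms: float = 2.0,
    measure_ms: float = 1.5,
    fit: bool = True,
) -> ActivationCurve:
    """Tail-current activation curve from a subtracted conditioning-step family.

    Each sweep holds a conditioning (prepulse) potential for the step segment
    and then jumps to the common tail potential.  The tail amplitude is the
    inward extremum within ``[tail onset + blank_ms, + blank_ms + measure_ms]``
    (the blanking excludes the capacitive transient and the short window
    keeps re-activation at the tail potential from contaminating the
    measurement), minus the pre-step baseline; amplitudes are normalized to
    the most hyperpolarized conditioning potential, where activation is
    maximal.
    """
    proto = zd_sensitive_ladder.protocol
    if proto.post_level is None:
        raise ValueError("ladder has no tail segment (post_level unset)")
    t_tail = proto.step_end_ms
    peaks = []
    for sw in zd_sensitive_ladder.sweeps:
        base = float(np.mean(sw.response[: sw.index_at(proto.pre_ms)]))
        a = sw.index_at(t_tail + blank_ms)
        b = sw.index_at(t_tail + blank_ms + measure_ms)
        peaks.append(float(np.min(sw.response[a:b])) - base)
    peaks = np.array(peaks)
    v = np.array(proto.amplitudes)
    ref = peaks[int(np.argmin(v))]
    if ref == 0:
        raise ValueError("zero tail current at the most hyperpolarized prepulse")
    norm = peaks / ref
    curve = ActivationCurve(prepulse_mV=v, tail_peak_pA=peaks, normalized=norm)
    if fit:
        curve.fit = fit_boltzmann(curve)
    return curve


# ---------------------------------------------------------------------------
# Curve fits.  Deterministic multi-start from a fixed coarse grid followed by
# local least squares, so the results are reproducible and robust to the
# usual local minima of sigmoid fitting.
# ---------------------------------------------------------------------------


def boltzmann(v, v50, k):
    """Activation falling with depolarization: f = 1/(1 + exp((V - V50)/k)),
    k > 0 (the parameterization used for HCN activation curves)."""
    return 1.0 / (1.0 + np.exp((np.asarray(v, float) - v50) / k))


def fit_boltzmann(curve, normalized=None) -> dict:
    """Least-squares Boltzmann fit of an activation curve.

    Accepts an :class:`ActivationCurve` or a voltage array plus ``normalized``
    values.  Returns ``{"v50_mV", "slope_mV", "residual"}``; raises if no
    start converges.
    """
    if isinstance(curve, ActivationCurve):
        v, y = curve.prepulse_mV, curve.normalized
    else:
        v = np.asarray(curve, float)
        y = np.asarray(normalized, float)
    if len(v) < 4:
        raise ValueError("need >= 4 points spanning the transition")

    def resid(p):
        return boltzmann(v, p[0], p[1]) - y

    best = None
    v50_grid = np.linspace(v.min(), v.max(), 9)
    for v50 in v50_grid:
        for k in (1.0, 2.0, 4.0, 8.0, 16.0):
            try:
                sol = least_squares(resid, [v50, k], bounds=([-200, 0.05], [50, 100]))
            except ValueError:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise RuntimeError("Boltzmann fit failed from every grid start")
    return {
        "v50_mV": float(best.x[0]),
        "slope_mV": float(best.x[1]),
        "residual": float(math.sqrt(2.0 * best.cost)),
    }


def hill(c, ec50, n):
    c = np.asarray(c, float)
    return c**n / (c**n + ec50**n)


def fit_hill_ec50(dose_response: DoseResponse) -> DoseResponse:
    """Fit fraction blocked = c^n / (c^n + EC50^n) to a dose-response set.

    Requires at least 3 concentrations with at least two fractional (strictly
    between 0 and 1) responses; returns a new :class:`DoseResponse` carrying
    the fitted ``ec50_nM`` and ``hill_n``.
    """
    c = dose_response.concentrations_nM
    y = dose_response.fraction_blocked
    if len(c) < 3:
        raise ValueError("need >= 3 concentrations")
    frac = np.sum((y > 0) & (y < 1))
    if frac < 2:
        raise ValueError("degenerate dose-response: need >= 2 fractional points")

    def resid(p):
        return hill(c, math.exp(p[0]), p[1]) - y

    pos = c[c > 0]
    best = None
    for lec in np.linspace(math.log(pos.min()), math.log(pos.max()), 7):
        for n in (0.5, 1.0, 2.0, 3.0):
            sol = least_squares(resid, [lec, n], bounds=([-20, 0.05], [30, 10]))
            if best is None or sol.cost < best.cost:
                best = sol
    return DoseResponse(
        concentrations_nM=c,
        fraction_blocked=y,
        ec50_nM=float(math.exp(best.x[0])),
        hill_n=float(best.x[1]),
    )
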