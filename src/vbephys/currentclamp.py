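"""Current-clamp analyses: spike and burst detection, rebound- and
depolarization-evoked burst thresholds over a step ladder, passive membrane
properties, burst morphology metrics, tonic firing, and input-output curves.

A *burst* follows the operational criterion used for these neurons: a minimum
of three action potentials within a 100-ms window.  A *rebound* burst is
searched in a window after the offset of a hyperpolarizing step (the
low-threshold calcium spike rides the post-inhibitory rebound); a
depolarization-evoked burst is searched inside the step itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .traces import CURRENT_CLAMP, ProtocolLadder, Sweep

#: default action-potential detection threshold (mV) and peak-merge window (ms)
AP_THRESHOLD_MV = -20.0
AP_MERGE_MS = 1.0
#: burst criterion defaults: >= 3 APs within 100 ms
MIN_APS = 3
SPAN_MS = 100.0
#: rebound bursts are searched within this window after step offset (ms)
REBOUND_SEARCH_MS = 300.0


@dataclass
class SpikeTrain:
    """Action-potential peak times (ms), strictly increasing."""

    times: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be 1-D")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self):
        return len(self.times)

    def in_window(self, t0: float, t1: float) -> "SpikeTrain":
        m = (self.times >= t0) & (self.times <= t1)
        return SpikeTrain(self.times[m])


@dataclass
class BurstEvent:
    """Burst classification plus morphology metrics of one sweep.

    Latencies are measured from the reference time passed to the analysis
    (step offset for rebound bursts, step onset for depolarization-evoked
    ones).  ``inflection``/``deflection`` are the potentials at which the
    membrane begins its regenerative depolarization and repolarization; they
    are ``None`` (with ``missing_morphology`` True) when no qualifying point
    is found.
    """

    is_burst: bool
    n_aps: int = 0
    window_start: float | None = None
    window_end: float | None = None
    inflection_mV: float | None = None
    deflection_mV: float | None = None
    latency_to_inflection_ms: float | None = None
    latency_to_ap_ms: float | None = None
    latency_inflection_to_ap_ms: float | None = None
    latency_to_deflection_ms: float | None = None
    inflect_to_deflect_ms: float | None = None
    ahp_mV: float | None = None
    ahp_minus_rest_mV: float | None = None
    missing_morphology: bool = False


@dataclass
class PassiveProperties:
    rmp_mV: float
    rin_MOhm: float | None
    sag_mV: float
    max_hyperpolarization_mV: float
    pre_burst_potential_mV: float


@dataclass
class BurstThresholdResult:
    """Threshold current plus the metric set of the threshold sweep.

    ``threshold_pA`` is ``None`` when no sweep in the scanned direction meets
    the burst criterion ("no-burst" is a value, not an error: full T-type
    block legitimately produces it).
    """

    threshold_pA: float | None
    threshold_sweep_index: int | None
    burst: BurstEvent | None
    passive: PassiveProperties | None
    aps_per_burst: int | None

    @property
    def is_burst(self) -> bool:
        return self.threshold_pA is not None


def detect_action_potentials(
    sweep: Sweep,
    ap_threshold_mV: float = AP_THRESHOLD_MV,
    merge_ms: float = AP_MERGE_MS,
) -> SpikeTrain:
    """One spike per upward threshold crossing followed by a downward one;
    the spike time is the local maximum between the crossings.  Peaks closer
    than ``merge_ms`` are merged (refractory merging)."""
    if sweep.mode != CURRENT_CLAMP:
        raise ValueError("spike detection expects a current-clamp sweep")
    v = sweep.response
    above = v >= ap_threshold_mV
    d = np.diff(above.astype(np.int8))
    ups = np.flatnonzero(d == 1) + 1
    downs = np.flatnonzero(d == -1) + 1
    times = []
    for u in ups:
        after = downs[downs > u]
        end = after[0] if len(after) else len(v)
        peak = u + int(np.argmax(v[u:end]))
        t = sweep.t0 + peak * sweep.dt
        if times and t - times[-1] < merge_ms:
            continue
        times.append(t)
    return SpikeTrain(np.array(times))


def classify_burst(
    train: SpikeTrain,
    search_window: tuple[float, float],
    min_aps: int = MIN_APS,
    span_ms: float = SPAN_MS,
) -> BurstEvent:
    """Sliding-window burst criterion.

    The train is a burst iff some window of length ``span_ms`` inside
    ``search_window`` contains at least ``min_aps`` spikes; ``n_aps`` is the
    spike count of the maximal qualifying window (first such window on ties).
    """
    if min_aps < 2:
        raise ValueError("min_aps must be >= 2")
    if span_ms <= 0:
        raise ValueError("span_ms must be > 0")
    t0, t1 = search_window
    times = train.in_window(t0, t1).times
    best_n = 0
    best_i = None
    for i, t in enumerate(times):
        # windows anchored at each spike are sufficient: any qualifying
        # window can be slid left until its first spike starts it
        n = int(np.sum((times >= t) & (times <= t + span_ms)))
        if n > best_n:
            best_n, best_i = n, i
    if best_n >= min_aps:
        sel = times[(times >= times[best_i]) & (times <= times[best_i] + span_ms)]
        return BurstEvent(
            is_burst=True,
            n_aps=best_n,
            window_start=float(sel[0]),
            window_end=float(sel[-1]),
        )
    return BurstEvent(is_burst=False, n_aps=int(best_n))


def passive_properties(sweep: Sweep, ladder: ProtocolLadder | None = None,
                       step_start: float | None = None,
                       step_end: float | None = None) -> PassiveProperties:
    """Passive metrics of a hyperpolarizing-step sweep.

    rmp = mean of the last 50 ms before the step; maximum hyperpolarization =
    minimum V during the step; pre-burst potential = mean of the last 10 ms of
    the step; sag = pre-burst potential - maximum hyperpolarization (positive
    for the depolarizing relaxation produced by I_h).
    """
    if step_start is None or step_end is None:
        if ladder is None:
            raise ValueError("need ladder or explicit step bounds")
        step_start = ladder.protocol.step_start_ms
        step_end = ladder.protocol.step_end_ms
    v = sweep.response
    i0 = sweep.index_at(step_start)
    i1 = sweep.index_at(step_end)
    pre = v[sweep.index_at(step_start - 50.0) : i0]
    rmp = float(np.mean(pre)) if len(pre) else float(v[0])
    vmin = float(np.min(v[i0:i1]))
    tail = v[sweep.index_at(step_end - 10.0) : i1]
    pre_burst = float(np.mean(tail))
    amp = float(sweep.command[(i0 + i1) // 2] - sweep.command[0])
    rin = None
    if amp < 0:
        rin = abs(vmin - rmp) / abs(amp) * 1000.0
    return PassiveProperties(
        rmp_mV=rmp,
        rin_MOhm=rin,
        sag_mV=pre_burst - vmin,
        max_hyperpolarization_mV=vmin,
        pre_burst_potential_mV=pre_burst,
    )


def input_resistance(sweep: Sweep, amplitude_pA: float,
                     step_start: float, step_end: float) -> float:
    """R_in (MOhm) = |max hyperpolarizing deflection| / |injected current|."""
    if amplitude_pA == 0:
        raise ValueError("zero-amplitude step")
    p = passive_properties(sweep, step_start=step_start, step_end=step_end)
    return abs(p.max_hyperpolarization_mV - p.rmp_mV) / abs(amplitude_pA) * 1000.0


def _boxcar(x: np.ndarray, n: int) -> np.ndarray:
    if n <= 1:
        return x
    kernel = np.ones(n) / n
    return np.convolve(x, kernel, mode="same")


def _clip_spikes(sweep: Sweep, spikes: SpikeTrain, half_ms: float = 2.0) -> np.ndarray:
    """Linear interpolation across +-half_ms of each AP peak."""
    v = sweep.response.copy()
    for t in spikes.times:
        a = sweep.index_at(t - half_ms)
        b = sweep.index_at(t + half_ms)
        if b > a:
            v[a : b + 1] = np.linspace(v[a], v[b], b - a + 1)
    return v


def burst_inflection_deflection(
    sweep: Sweep,
    spikes: SpikeTrain,
    ref_time: float,
    k_on: float = 3.0,
    k_off: float = 3.0,
    baseline_window_ms: float = 100.0,
    sustain_ms: float = 2.0,
    sd_floor: float = 0.005,
):
    """Inflection/deflection points of a low-threshold-spike burst.

    Spikes are clipped from the trace (linear interpolation across +-2 ms)
    and the trace smoothed with a 1-ms boxcar.  dV/dt is then thresholded:
    the inflection is the first time at or after ``ref_time`` where dV/dt
    exceeds the detection threshold for at least ``sustain_ms``; the
    deflection the first time after the last AP where dV/dt stays below the
    negative threshold as long.  The threshold is the larger of
    ``k_on * SD`` of the pre-reference derivative and 25 % of the maximal
    slope of the segment being searched — the relative floor keeps the
    detector locked to the regenerative (low-threshold-spike) phase rather
    than the passive rebound in low-noise recordings.  Returns
    (inflection_mV, deflection_mV, t_inflection, t_deflection) with None
    entries (flagged-missing) when no qualifying point exists.
    """
    dt = sweep.dt
    v = _clip_spikes(sweep, spikes)
    v = _boxcar(v, max(1, int(round(1.0 / dt))))
    dvdt = np.gradient(v, dt)
    i_ref = sweep.index_at(ref_time)
    i_base0 = sweep.index_at(ref_time - baseline_window_ms)
    sd = float(np.std(dvdt[i_base0:i_ref])) if i_ref > i_base0 else 0.0
    sd = max(sd, sd_floor)
    n_sustain = max(1, int(round(sustain_ms / dt)))

    def _first_sustained(mask: np.ndarray, start: int, stop: int) -> int | None:
        run = 0
        for i in range(start, min(stop, len(mask))):
            run = run + 1 if mask[i] else 0
            if run >= n_sustain:
                return i - n_sustain + 1
        return None

    t_inf = v_inf = t_def = v_def = None
    if len(spikes) > 0:
        # stop before the first AP foot (clip half-width + smoothing margin)
        i_stop_on = sweep.index_at(spikes.times[0] - 4.0)
    else:
        i_stop_on = sweep.n_samples
    seg = dvdt[i_ref:i_stop_on]
    if len(seg) > 2:
        i_min, i_max = int(np.argmin(seg)), int(np.argmax(seg))
        s_min, s_max = float(seg[i_min]), float(seg[i_max])
        span = s_max - s_min
        decelerating_first = (
            i_min < i_max
            and i_min > 0
            and s_max > k_on * sd
            and float(seg[:i_min].max()) > s_min + 0.25 * span
        )
        if decelerating_first:
            # passive-then-regenerative shape: the onset of the exponential
            # depolarization is the deceleration minimum of dV/dt
            i_inf = i_ref + i_min
        else:
            # monotone shape: first sustained crossing of the threshold
            thr_on = max(k_on * sd, 0.25 * s_max)
            i_inf = _first_sustained(dvdt > thr_on, i_ref, i_stop_on)
        if i_inf is not None:
            t_inf = sweep.t0 + i_inf * dt
            v_inf = float(v[i_inf])
    if len(spikes) > 0:
        # repolarization begins at the end of the post-spike crest
        i_last = sweep.index_at(spikes.times[-1] + 2.0)
        i_end = min(sweep.n_samples, sweep.index_at(spikes.times[-1] + 300.0))
        if i_end - i_last > 2:
            i_crest = i_last + int(np.argmax(v[i_last:i_end]))
            collapse = dvdt[i_crest:i_end]
            if len(collapse) > 2:
                thr_off = max(k_off * sd, 0.15 * -float(collapse.min()))
                i_def = _first_sustained(dvdt < -thr_off, i_crest, i_end)
                if i_def is not None:
                    t_def = sweep.t0 + i_def * dt
                    v_def = float(v[i_def])
    return v_inf, v_def, t_inf, t_def


def _burst_metrics(
    sweep: Sweep,
    spikes: SpikeTrain,
    event: BurstEvent,
    ref_time: float,
    rmp: float,
) -> BurstEvent:
    """Fill morphology metrics of a classified burst in place."""
    v_inf, v_def, t_inf, t_def = burst_inflection_deflection(sweep, spikes, ref_time)
    first_ap = float(event.window_start)
    event.inflection_mV = v_inf
    event.deflection_mV = v_def
    event.latency_to_ap_ms = first_ap - ref_time
    if t_inf is not None:
        event.latency_to_inflection_ms = t_inf - ref_time
        event.latency_inflection_to_ap_ms = first_ap - t_inf
    if t_def is not None:
        event.latency_to_deflection_ms = t_def - ref_time
        if t_inf is not None:
            event.inflect_to_deflect_ms = t_def - t_inf
    event.missing_morphology = t_inf is None or t_def is None
    # afterhyperpolarization: minimum V in the 200 ms following repolarization
    t_after = t_def if t_def is not None else float(event.window_end) + 5.0
    a = sweep.index_at(t_after)
    b = sweep.index_at(t_after + 200.0)
    if b > a:
        event.ahp_mV = float(np.min(sweep.response[a:b]))
        event.ahp_minus_rest_mV = event.ahp_mV - rmp
    return event


def _threshold_scan(
    ladder: ProtocolLadder,
    hyperpolarizing: bool,
    ap_threshold_mV: float,
    min_aps: int,
    span_ms: float,
    search_ms: float,
) -> BurstThresholdResult:
    proto = ladder.protocol
    onset, offset = proto.step_start_ms, proto.step_end_ms
    holding = proto.holding
    if hyperpolarizing:
        candidates = [
            (i, a) for i, a in enumerate(proto.amplitudes) if a < holding
        ]
        if not candidates:
            raise ValueError("ladder contains no hyperpolarizing steps")
        window = (offset, offset + search_ms)
        ref = offset
    else:
        candidates = [
            (i, a) for i, a in enumerate(proto.amplitudes) if a > holding
        ]
        if not candidates:
            raise ValueError("ladder contains no depolarizing steps")
        window = (onset, offset)
        ref = onset
    candidates.sort(key=lambda ia: abs(ia[1] - holding))
    for i, amp in candidates:
        sweep = ladder.sweeps[i]
        spikes = detect_action_potentials(sweep, ap_threshold_mV)
        event = classify_burst(spikes, window, min_aps, span_ms)
        if event.is_burst:
            passive = passive_properties(sweep, ladder)
            event = _burst_metrics(sweep, spikes, event, ref, passive.rmp_mV)
            return BurstThresholdResult(
                threshold_pA=amp - holding,
                threshold_sweep_index=i,
                burst=event,
                passive=passive,
                aps_per_burst=_burst_cluster_size(spikes, window, span_ms),
            )
    return BurstThresholdResult(None, None, None, None, None)


def _burst_cluster_size(
    spikes: SpikeTrain, window: tuple[float, float], max_gap_ms: float
) -> int:
    """Total AP count of the burst: the spike cluster that starts at the
    first spike in the window and extends while consecutive inter-spike
    intervals stay below ``max_gap_ms``.  (The classification criterion
    counts spikes inside a sliding window; the burst itself may carry a
    trailing spike just outside it.)"""
    times = spikes.in_window(*window).times
    if len(times) == 0:
        return 0
    n = 1
    for k in range(1, len(times)):
        if times[k] - times[k - 1] > max_gap_ms:
            break
        n += 1
    return n


def rebound_burst_threshold(
    ladder: ProtocolLadder,
    ap_threshold_mV: float = AP_THRESHOLD_MV,
    min_aps: int = MIN_APS,
    span_ms: float = SPAN_MS,
    search_ms: float = REBOUND_SEARCH_MS,
) -> BurstThresholdResult:
    """Smallest-|I| hyperpolarizing step whose post-offset window is a burst.

    Scans hyperpolarizing amplitudes from smallest to largest magnitude and
    returns the first that meets the burst criterion in the window
    ``[step offset, step offset + search_ms]``, with the passive and
    morphology metrics of that sweep attached.
    """
    return _threshold_scan(ladder, True, ap_threshold_mV, min_aps, span_ms, search_ms)


def depolarizing_burst_threshold(
    ladder: ProtocolLadder,
    ap_threshold_mV: float = AP_THRESHOLD_MV,
    min_aps: int = MIN_APS,
    span_ms: float = SPAN_MS,
) -> BurstThresholdResult:
    """Mirror of :func:`rebound_burst_threshold` with the burst window inside
    the depolarizing step."""
    return _threshold_scan(ladder, False, ap_threshold_mV, min_aps, span_ms, 0.0)


def tonic_firing_frequency(
    sweep: Sweep,
    step_start: float,
    step_end: float,
    ap_threshold_mV: float = AP_THRESHOLD_MV,
) -> float:
    """Tonic rate (Hz): spike count in [onset+500 ms, onset+1,000 ms] / 0.5 s
    (the late window avoids contamination by an onset burst)."""
    if step_end - step_start < 1000.0:
        raise ValueError("tonic analysis needs a step of at least 1,000 ms")
    spikes = detect_action_potentials(sweep, ap_threshold_mV)
    n = len(spikes.in_window(step_start + 500.0, step_start + 1000.0))
    return n / 0.5


def input_output_curve(
    ladder: ProtocolLadder,
    ap_threshold_mV: float = AP_THRESHOLD_MV,
    search_ms: float = REBOUND_SEARCH_MS,
    normalize_to_threshold: bool = False,
) -> list[tuple[float, float]]:
    """Per-amplitude firing frequency over an analyzed ladder.

    Hyperpolarizing steps report the AP frequency of the rebound window
    ((n-1)/duration of the spike cluster); depolarizing steps report tonic
    frequency for steps >= 1,000 ms, otherwise the in-step AP frequency.
    With ``normalize_to_threshold`` the amplitude axis is shifted so the
    rebound-burst threshold maps to 0.
    """
    proto = ladder.protocol
    onset, offset = proto.step_start_ms, proto.step_end_ms
    holding = proto.holding
    rows = []
    for amp, sweep in zip(proto.amplitudes, ladder.sweeps):
        spikes = detect_action_potentials(sweep, ap_threshold_mV)
        if amp < holding:
            win = spikes.in_window(offset, offset + search_ms)
            freq = _cluster_frequency(win.times)
        elif amp > holding:
            if proto.step_ms >= 1000.0:
                n = len(spikes.in_window(onset + 500.0, onset + 1000.0))
                freq = n / 0.5
            else:
                freq = _cluster_frequency(spikes.in_window(onset, offset).times)
        else:
            freq = 0.0
        rows.append((amp - holding, freq))
    if normalize_to_threshold:
        thr = rebound_burst_threshold(ladder, ap_threshold_mV)
        if thr.threshold_pA is None:
            raise ValueError("cannot normalize: no rebound-burst threshold")
        rows = [(a - thr.threshold_pA, f) for a, f in rows]
    return rows


def _cluster_frequency(times: np.ndarray) -> float:
    if len(times) < 2:
        return 0.0
    return (len(times) - 1) / (times[-1] - times[0]) * 1000.0


#: metric-table column names (one row per cell), mirroring the conventional
#: burst/passive summary table for these recordings
TABLE_COLUMNS = (
    "Threshold current (pA)",
    "APs per burst",
    "Burst inflection point (mV)",
    "Burst deflection point (mV)",
    "Maximum hyperpolarization (mV)",
    "Pre-Burst Membrane Potential (mV)",
    "Sag (mV)",
    "Latency to inflection (ms)",
    "Latency to AP (ms)",
    "Latency inflection to AP (ms)",
    "Latency to deflection point (ms)",
    "Inflect to deflect latency (ms)",
    "Afterhyperpolarization (mV)",
    "AHP - Vrest (mV)",
    "Resting membrane potential (mV)",
    "Input resistance (MOhm)",
)


def threshold_metric_row(result: BurstThresholdResult) -> dict:
    """Flatten a threshold result into the standard metric table row."""
    if not result.is_burst:
        return {k: math.nan for k in TABLE_COLUMNS}
    b, p = result.burst, result.passive

    def _nn(x):
        return math.nan if x is None else x

    return {
        "Threshold current (pA)": result.threshold_pA,
        "APs per burst": result.aps_per_burst,
        "Burst inflection point (mV)": _nn(b.inflection_mV),
        "Burst deflection point (mV)": _nn(b.deflection_mV),
        "Maximum hyperpolarization (mV)": p.max_hyperpolarization_mV,
        "Pre-Burst Membrane Potential (mV)": p.pre_burst_potential_mV,
        "Sag (mV)": p.sag_mV,
        "Latency to inflection (ms)": _nn(b.latency_to_inflection_ms),
        "Latency to AP (ms)": _nn(b.latency_to_ap_ms),
        "Latency inflection to AP (ms)": _nn(b.latency_inflection_to_ap_ms),
        "Latency to deflection point (ms)": _nn(b.latency_to_deflection_ms),
        "Inflect to deflect latency (ms)": _nn(b.inflect_to_deflect_ms),
        "Afterhyperpolarization (mV)": _nn(b.ahp_mV),
        "AHP - Vrest (mV)": _nn(b.ahp_minus_rest_mV),
        "Resting membrane potential (mV)": p.rmp_mV,
        "Input resistance (MOhm)": _nn(p.rin_MOhm),
    }
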