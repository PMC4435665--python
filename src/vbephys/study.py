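"""Cohort-level study pipeline: simulate two strains of ventrobasal neurons,
analyze every cell with the current- and voltage-clamp pipelines, and compare
group statistics — the in-silico analogue of a strain-comparison slice study.

Per cell this runs:

- a 1,000-ms and a 200-ms hyperpolarizing current-step ladder, analyzed for
  the rebound-burst threshold and its metric table;
- the same 1,000-ms ladder under full HCN block (ZD7288 condition): rebound
  threshold plus depolarization-evoked threshold;
- the 1,000-ms ladder under full T-type block (Z944 condition): rebound scan;
- the tail-current activation protocol with and without HCN block, subtracted
  to the blocker-sensitive current, for the I_h tail density.

Input resistance is reported from the largest hyperpolarizing step of the
1,000-ms ladder (maximal deflection / injected current), the most sensitive
measure of the extra resting/near-rest conductance carried by HCN channels.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np

from . import model, protocols
from .currentclamp import (
    depolarizing_burst_threshold,
    input_resistance,
    rebound_burst_threshold,
    threshold_metric_row,
)
from .stats import cohort_comparison
from .traces import make_step_protocol
from .voltageclamp import tail_current_activation, zd_sensitive_current

#: default per-cell recording offset SD (mV), emulating residual electrode /
#: junction offsets that spread measured potentials between cells
VOLTAGE_OFFSET_SD = 3.0

#: metrics compared between strains (a subset of the full metric table)
STUDY_METRICS = (
    "threshold_1000ms_pA",
    "threshold_200ms_pA",
    "aps_per_burst",
    "rmp_mV",
    "rin_MOhm",
    "sag_mV",
    "ih_tail_density_pA_per_pF",
    "zd_rebound_threshold_pA",
    "zd_depol_threshold_pA",
    "z944_bursts",
)


def _cc_ladder(step_ms: float, dt: float, last: float = 0.0):
    """Current-step ladder from -110 pA; ``last`` extends into depolarizing
    steps when the depolarization-evoked analysis is needed."""
    return make_step_protocol(
        0.0, 200.0, step_ms, 400.0, -110.0, last, 10.0, dt, "current_clamp"
    )


def analyze_cell(
    params: model.NeuronParams,
    seed: int,
    dt_cc: float = 0.05,
    dt_vc: float = 0.05,
    noise_sd: float = 0.1,
    voltage_offset_mV: float = 0.0,
) -> dict:
    """Full per-cell study: burst thresholds, passive properties, drug
    conditions and I_h tail density.  Returns a flat metric dict."""
    cc = model.ClampConfig.cc(seed=seed, noise_sd=noise_sd)
    cc = replace(cc, voltage_offset_mV=voltage_offset_mV)
    out: dict = {}

    lad1000 = model.simulate_ladder(params, _cc_ladder(1000.0, dt_cc), cc)
    lad200 = model.simulate_ladder(
        params, _cc_ladder(200.0, dt_cc), replace(cc, seed=cc.seed + 1)
    )
    r1000 = rebound_burst_threshold(lad1000)
    r200 = rebound_burst_threshold(lad200)
    row = threshold_metric_row(r1000)
    # cells that never burst within the ladder carry thresholds beyond its
    # deepest step: censor them at the ladder limit (conservative for the
    # strain comparison; dropping them would bias the group mean shallow)
    limit = float(min(lad1000.protocol.amplitudes))
    out["threshold_1000ms_pA"] = (
        row["Threshold current (pA)"] if r1000.is_burst else limit
    )
    out["threshold_200ms_pA"] = (
        threshold_metric_row(r200)["Threshold current (pA)"] if r200.is_burst
        else limit
    )
    out["aps_per_burst"] = row["APs per burst"]
    out["rmp_mV"] = row["Resting membrane potential (mV)"]
    out["sag_mV"] = row["Sag (mV)"]
    out["table1"] = row
    # input resistance from the largest hyperpolarizing step
    proto = lad1000.protocol
    i_max = int(np.argmin(proto.amplitudes))
    out["rin_MOhm"] = input_resistance(
        lad1000.sweeps[i_max],
        proto.amplitudes[i_max],
        proto.step_start_ms,
        proto.step_end_ms,
    )

    # ZD7288 condition: full HCN block
    zd_params = replace(params, block_h=1.0)
    lad_zd = model.simulate_ladder(
        zd_params, _cc_ladder(1000.0, dt_cc, last=200.0), replace(cc, seed=cc.seed + 2)
    )
    r_zd = rebound_burst_threshold(lad_zd)
    d_zd = depolarizing_burst_threshold(lad_zd)
    out["zd_rebound_threshold_pA"] = (
        r_zd.threshold_pA if r_zd.is_burst else math.nan
    )
    out["zd_depol_threshold_pA"] = d_zd.threshold_pA if d_zd.is_burst else math.nan
    out["zd_rmp_mV"] = threshold_metric_row(d_zd).get(
        "Resting membrane potential (mV)", math.nan
    )

    # Z944 condition: full T-type block; count of burst-positive sweeps
    z_params = replace(params, block_T=1.0)
    lad_z = model.simulate_ladder(
        z_params, _cc_ladder(1000.0, dt_cc), replace(cc, seed=cc.seed + 3)
    )
    r_z = rebound_burst_threshold(lad_z)
    out["z944_bursts"] = 1.0 if r_z.is_burst else 0.0

    # I_h tail density from the blocker-sensitive subtraction
    vc = model.ClampConfig.vc(seed=seed + 10, noise_sd=2.0)
    ih_ladder = protocols.protocol_ladder("ihtail", dt=dt_vc)
    ctrl = model.simulate_ladder(params, ih_ladder, vc)
    blocked = model.simulate_ladder(
        replace(params, block_h=1.0), ih_ladder, replace(vc, seed=vc.seed + 1)
    )
    sensitive = zd_sensitive_current(ctrl, blocked)
    act = tail_current_activation(sensitive, fit=False)
    i_ref = int(np.argmin(act.prepulse_mV))
    out["ih_tail_density_pA_per_pF"] = float(act.tail_peak_pA[i_ref]) / params.Cm
    return out


def cohort_study(
    preset_a: str = "NEC",
    preset_b: str = "GAERS",
    n: int = 15,
    seed: int = 0,
    jitter_cv: float = 0.2,
    dt_cc: float = 0.05,
    voltage_offset_sd: float = VOLTAGE_OFFSET_SD,
) -> dict:
    """Two-strain comparison study on simulated cohorts.

    Returns ``{"cells_a", "cells_b", "rows"}`` where ``rows`` is a list of
    :class:`vbephys.stats.ComparisonRow`, one per study metric.
    """
    rng = np.random.default_rng(seed)
    results = []
    for k, name in enumerate((preset_a, preset_b)):
        cells = model.generate_cohort(name, n, jitter_cv, seed=seed + 7919 * (k + 1))
        rows = []
        for i, cell in enumerate(cells):
            offset = rng.normal(0.0, voltage_offset_sd)
            rows.append(
                analyze_cell(
                    cell,
                    seed=seed + 104729 * (k + 1) + 13 * i,
                    dt_cc=dt_cc,
                    voltage_offset_mV=offset,
                )
            )
        results.append(rows)
    metrics = [m for m in STUDY_METRICS]
    rows = cohort_comparison(
        results[0], results[1], metrics=metrics, labels=(preset_a, preset_b)
    )
    return {"cells_a": results[0], "cells_b": results[1], "rows": rows}
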