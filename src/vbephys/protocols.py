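"""Named step-protocol templates.

These are the stimulus families the analyses expect:

==============  ====================================================== ======
name            description                                            mode
==============  ====================================================== ======
cc200           -110..+200 pA, 10-pA increments, 200-ms steps          CC
cc1000          -110..+200 pA, 10-pA increments, 1,000-ms steps        CC
ihtail          1,000-ms conditioning steps -110..-60 mV (5 mV), then  VC
                a 200-ms tail step to -110 mV
cavIV           200-ms test pulses -70..+10 mV (5 mV) from -90 mV      VC
cavIV_prepulse  cavIV preceded by -50 mV/100-ms inactivating prepulse  VC
                (10-ms interpulse interval)
cm5mV           5-mV step from -90 to -85 mV for 40 ms (capacitance)   VC
leakcal         small steps around -90 mV for linear leak calibration  VC
==============  ====================================================== ======
"""

from __future__ import annotations

from .traces import CURRENT_CLAMP, VOLTAGE_CLAMP, ProtocolLadder, make_step_protocol

#: default sampling intervals (ms): 50 kHz current clamp, 20 kHz voltage clamp
DT_CC = 0.02
DT_VC = 0.05


def protocol_ladder(name: str, dt: float | None = None) -> ProtocolLadder:
    """Build the command-only ladder for a named protocol template."""
    if name == "cc200":
        return make_step_protocol(
            0.0, 200.0, 200.0, 400.0, -110.0, 200.0, 10.0, dt or DT_CC, CURRENT_CLAMP
        )
    if name == "cc1000":
        return make_step_protocol(
            0.0, 200.0, 1000.0, 400.0, -110.0, 200.0, 10.0, dt or DT_CC, CURRENT_CLAMP
        )
    if name == "ihtail":
        return make_step_protocol(
            -60.0,
            200.0,
            1000.0,
            200.0,
            -110.0,
            -60.0,
            5.0,
            dt or DT_VC,
            VOLTAGE_CLAMP,
            post_level=-110.0,
        )
    if name == "cavIV":
        return make_step_protocol(
            -90.0, 100.0, 200.0, 100.0, -70.0, 10.0, 5.0, dt or DT_VC, VOLTAGE_CLAMP
        )
    if name == "cavIV_prepulse":
        return make_step_protocol(
            -90.0,
            100.0,
            200.0,
            100.0,
            -70.0,
            10.0,
            5.0,
            dt or DT_VC,
            VOLTAGE_CLAMP,
            prepulse_level=-50.0,
            prepulse_ms=100.0,
            gap_ms=10.0,
        )
    if name == "cm5mV":
        return make_step_protocol(
            -90.0, 20.0, 40.0, 40.0, -85.0, -85.0, 0.0, dt or 0.02, VOLTAGE_CLAMP
        )
    if name == "leakcal":
        return make_step_protocol(
            -90.0, 100.0, 200.0, 100.0, -100.0, -80.0, 5.0, dt or DT_VC, VOLTAGE_CLAMP
        )
    raise ValueError(f"unknown protocol template {name!r}")


PROTOCOL_NAMES = (
    "cc200",
    "cc1000",
    "ihtail",
    "cavIV",
    "cavIV_prepulse",
    "cm5mV",
    "leakcal",
)
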