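"""Shared helpers for the test suite."""

from vbephys.traces import make_step_protocol


def hyp_ladder(step_ms=1000.0, dt=0.05, last=0.0):
    """Hyperpolarizing current-step ladder (-110 .. `last` pA, 10-pA steps)."""
    return make_step_protocol(
        0.0, 200.0, step_ms, 400.0, -110.0, last, 10.0, dt, "current_clamp"
    )
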