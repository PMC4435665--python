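"""Core sweep and step-protocol data model, plus the plain-text sweep format.

Units follow patch-clamp convention throughout the package: time in ms,
potentials in mV, currents in pA, conductances in nS, capacitance in pF.
A :class:`Sweep` holds one command/response pair sampled uniformly at ``dt``;
a :class:`ProtocolLadder` is an ordered family of sweeps generated by stepping
one command level through a list of amplitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

CURRENT_CLAMP = "current_clamp"
VOLTAGE_CLAMP = "voltage_clamp"
_MODES = (CURRENT_CLAMP, VOLTAGE_CLAMP)

#: unit labels implied by recording mode: (command units, response units)
MODE_UNITS = {
    CURRENT_CLAMP: ("pA", "mV"),
    VOLTAGE_CLAMP: ("mV", "pA"),
}


class SweepFormatError(ValueError):
    """Raised when a sweep file violates the interchange format."""


@dataclass
class Sweep:
    """One recorded or simulated trace.

    Parameters
    ----------
    dt : float
        Sampling interval in ms (uniform).
    command : ndarray
        Per-sample stimulus: pA in current clamp, mV in voltage clamp.
    response : ndarray
        Per-sample measurement: mV in current clamp, pA in voltage clamp.
    mode : str
        ``"current_clamp"`` or ``"voltage_clamp"``.
    t0 : float
        Time of the first sample in ms.
    meta : dict
        Free-form annotations (cell id, condition, corrections applied...).
    """

    dt: float
    command: np.ndarray
    response: np.ndarray
    mode: str
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.command = np.asarray(self.command, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.mode not in _MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.command.ndim != 1 or self.response.ndim != 1:
            raise ValueError("command and response must be 1-D")
        if len(self.command) != len(self.response):
            raise ValueError(
                f"command ({len(self.command)}) and response "
                f"({len(self.response)}) lengths differ"
            )
        if len(self.command) < 2:
            raise ValueError("sweeps need at least 2 samples")
        cu, ru = MODE_UNITS[self.mode]
        self.meta.setdefault("units_command", cu)
        self.meta.setdefault("units_response", ru)
        if self.meta["units_command"] != cu or self.meta["units_response"] != ru:
            raise ValueError(
                f"unit labels {self.meta['units_command']}/"
                f"{self.meta['units_response']} do not match mode {self.mode}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.command)

    @property
    def duration(self) -> float:
        """Total sweep duration in ms."""
        return self.n_samples * self.dt

    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_samples)

    def index_at(self, t_ms: float) -> int:
        """Sample index of time ``t_ms`` (clipped to the sweep)."""
        i = int(round((t_ms - self.t0) / self.dt))
        return min(max(i, 0), self.n_samples - 1)

    def copy(self) -> "Sweep":
        return Sweep(
            dt=self.dt,
            command=self.command.copy(),
            response=self.response.copy(),
            mode=self.mode,
            t0=self.t0,
            meta=dict(self.meta),
        )


@dataclass
class StepProtocol:
    """A one-step command template with an amplitude ladder.

    The command is ``holding`` everywhere except the step segment
    ``[pre_ms, pre_ms + step_ms)`` where it equals the sweep's amplitude
    (an absolute level, not a delta).  Two optional extensions cover the
    protocols used here: ``prepulse_level``/``prepulse_ms``/``gap_ms`` insert
    a fixed conditioning pulse before the step, and ``post_level`` replaces
    the holding level after the step (a tail step).
    """

    holding: float
    pre_ms: float
    step_ms: float
    post_ms: float
    amplitudes: tuple
    post_level: float | None = None
    prepulse_level: float | None = None
    prepulse_ms: float = 0.0
    gap_ms: float = 0.0

    def __post_init__(self) -> None:
        self.amplitudes = tuple(float(a) for a in self.amplitudes)
        if self.pre_ms < 0 or self.post_ms < 0 or self.step_ms <= 0:
            raise ValueError("segment durations must be >= 0 and step_ms > 0")
        if len(self.amplitudes) == 0:
            raise ValueError("at least one amplitude required")
        if len(self.amplitudes) > 1:
            d = np.diff(self.amplitudes)
            if not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError("amplitudes must be strictly monotone")
        if self.prepulse_level is not None and self.prepulse_ms <= 0:
            raise ValueError("prepulse_level set but prepulse_ms <= 0")

    def segments(self, amplitude: float) -> list[tuple[float, float]]:
        """(level, duration) segments of the command for one amplitude."""
        segs = [(self.holding, self.pre_ms)]
        if self.prepulse_level is not None:
            segs.append((self.prepulse_level, self.prepulse_ms))
            if self.gap_ms > 0:
                segs.append((self.holding, self.gap_ms))
        segs.append((float(amplitude), self.step_ms))
        post = self.holding if self.post_level is None else self.post_level
        segs.append((post, self.post_ms))
        return [(lv, du) for lv, du in segs if du > 0]

    def command_trace(self, amplitude: float, dt: float) -> np.ndarray:
        parts = []
        for level, dur in self.segments(amplitude):
            n = int(round(dur / dt))
            parts.append(np.full(n, level))
        return np.concatenate(parts)

    @property
    def step_start_ms(self) -> float:
        extra = 0.0
        if self.prepulse_level is not None:
            extra = self.prepulse_ms + self.gap_ms
        return self.pre_ms + extra

    @property
    def step_end_ms(self) -> float:
        return self.step_start_ms + self.step_ms


@dataclass
class ProtocolLadder:
    """Ordered family of sweeps, one per protocol amplitude."""

    protocol: StepProtocol
    sweeps: list

    def __post_init__(self) -> None:
        if len(self.sweeps) != len(self.protocol.amplitudes):
            raise ValueError(
                f"{len(self.sweeps)} sweeps for "
                f"{len(self.protocol.amplitudes)} amplitudes"
            )
        for sw, amp in zip(self.sweeps, self.protocol.amplitudes):
            expect = self.protocol.command_trace(amp, sw.dt)
            if len(expect) != sw.n_samples or not np.allclose(
                expect, sw.command, atol=1e-6, rtol=0
            ):
                raise ValueError(
                    f"sweep command does not match protocol at amplitude {amp}"
                )

    def __len__(self) -> int:
        return len(self.sweeps)

    def __iter__(self):
        return iter(self.sweeps)

    @property
    def dt(self) -> float:
        return self.sweeps[0].dt

    @property
    def mode(self) -> str:
        return self.sweeps[0].mode

    @property
    def amplitudes(self) -> tuple:
        return self.protocol.amplitudes

    def copy(self) -> "ProtocolLadder":
        return ProtocolLadder(self.protocol, [s.copy() for s in self.sweeps])


@dataclass
class SolutionComposition:
    """Dissolved ionic species of one solution: (ion name, charge, mM)."""

    species: list  # of (name, charge, concentration_mM)
    name: str = ""

    def __post_init__(self) -> None:
        cleaned = []
        has_cation = has_anion = False
        for ion, z, c in self.species:
            z = int(z)
            c = float(c)
            if c < 0:
                raise ValueError(f"negative concentration for {ion}: {c}")
            if z > 0:
                has_cation = True
            elif z < 0:
                has_anion = True
            cleaned.append((str(ion), z, c))
        if not (has_cation and has_anion):
            raise ValueError("solution needs at least one cation and one anion")
        self.species = cleaned

    def concentration(self, ion: str, charge: int) -> float:
        return sum(c for n, z, c in self.species if n == ion and z == charge)


def make_step_protocol(
    holding: float,
    pre_ms: float,
    step_ms: float,
    post_ms: float,
    first: float,
    last: float,
    increment: float,
    dt: float,
    mode: str = CURRENT_CLAMP,
    **protocol_kwargs,
) -> ProtocolLadder:
    """Build a command-only ladder from ``first`` to ``last`` by ``increment``.

    The response arrays are zero-filled placeholders (flagged in ``meta``)
    until a simulator or recording fills them.
    """
    if increment == 0:
        if first != last:
            raise ValueError("increment is 0 but first != last")
        amplitudes = [float(first)]
    else:
        span = last - first
        n_f = span / increment
        n = round(n_f)
        if abs(n_f - n) > 1e-9 * max(1.0, abs(n_f)) or n < 0:
            raise ValueError(
                f"range not divisible: first={first}, last={last}, "
                f"increment={increment} gives a non-integer step count {n_f}"
            )
        amplitudes = [first + i * increment for i in range(int(n) + 1)]
    proto = StepProtocol(
        holding=holding,
        pre_ms=pre_ms,
        step_ms=step_ms,
        post_ms=post_ms,
        amplitudes=tuple(amplitudes),
        **protocol_kwargs,
    )
    sweeps = []
    for amp in proto.amplitudes:
        cmd = proto.command_trace(amp, dt)
        sweeps.append(
            Sweep(
                dt=dt,
                command=cmd,
                response=np.zeros_like(cmd),
                mode=mode,
                meta={"empty_response": True},
            )
        )
    return ProtocolLadder(proto, sweeps)


def infer_segments(command: np.ndarray, dt: float) -> list[tuple[float, float]]:
    """Recover (level, duration) runs from a piecewise-constant command."""
    command = np.asarray(command, dtype=float)
    edges = np.flatnonzero(np.diff(command) != 0) + 1
    bounds = np.concatenate(([0], edges, [len(command)]))
    return [
        (float(command[a]), (b - a) * dt) for a, b in zip(bounds[:-1], bounds[1:])
    ]


def infer_step_protocol(ladder_commands: Sequence[np.ndarray], dt: float) -> StepProtocol:
    """Reconstruct a :class:`StepProtocol` from the command traces alone.

    Assumes the simple one-step layout (no prepulse); the varying segment is
    identified as the one whose level changes across sweeps, or the middle
    segment when a single sweep is given.
    """
    seg_lists = [infer_segments(c, dt) for c in ladder_commands]
    n_seg = {len(s) for s in seg_lists}
    if len(n_seg) != 1:
        raise SweepFormatError("sweeps have differing segment structure")
    segs = seg_lists[0]
    if len(segs) == 1:
        # degenerate: all-holding
        lv, du = segs[0]
        return StepProtocol(lv, 0.0, du, 0.0, tuple(s[0][0] for s in seg_lists))
    levels = np.array([[lv for lv, _ in s] for s in seg_lists])
    varying = [j for j in range(levels.shape[1]) if len(set(levels[:, j])) > 1]
    step_j = varying[0] if varying else (1 if len(segs) > 2 else len(segs) - 1)
    holding = segs[0][0] if step_j != 0 else segs[-1][0]
    pre = sum(d for _, d in segs[:step_j])
    post_segs = segs[step_j + 1 :]
    post = sum(d for _, d in post_segs)
    post_level = None
    if post_segs and post_segs[0][0] != holding:
        post_level = post_segs[0][0]
    return StepProtocol(
        holding=holding,
        pre_ms=pre,
        step_ms=segs[step_j][1],
        post_ms=post,
        amplitudes=tuple(levels[:, step_j]),
        post_level=post_level,
    )


def apply_junction_correction(sweep: Sweep, ljp_mV: float) -> Sweep:
    """Offline liquid-junction-potential correction of a current-clamp sweep.

    The measured potential is shifted by ``-ljp_mV`` at every sample (a
    reported positive LJP makes the true membrane potential more negative
    than the pipette reading).  The command is unchanged and the correction
    is recorded in ``meta``; applying it twice is an error.
    """
    if sweep.mode != CURRENT_CLAMP:
        raise ValueError("junction correction applies to current-clamp sweeps")
    if "ljp_corrected_mV" in sweep.meta:
        raise ValueError(
            f"sweep already LJP-corrected by {sweep.meta['ljp_corrected_mV']} mV"
        )
    out = sweep.copy()
    out.response = out.response - ljp_mV
    out.meta["ljp_corrected_mV"] = float(ljp_mV)
    return out


# ---------------------------------------------------------------------------
# Sweep interchange format
#
# UTF-8 text; "#key=value" header lines (required: mode, dt_ms, units_command,
# units_response, n_sweeps); then one column block per sweep of
# "command<TAB>response" rows, blank line between sweeps.  Protocol parameters
# and per-sweep metadata ride along as extra header keys.
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = ("mode", "dt_ms", "units_command", "units_response", "n_sweeps")
_PROTO_KEYS = (
    "holding",
    "pre_ms",
    "step_ms",
    "post_ms",
    "post_level",
    "prepulse_level",
    "prepulse_ms",
    "gap_ms",
)


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def write_sweeps(ladder: ProtocolLadder, path) -> None:
    """Write a ladder in the plain-text sweep interchange format."""
    proto = ladder.protocol
    sw0 = ladder.sweeps[0]
    lines = [
        f"#mode={sw0.mode}",
        f"#dt_ms={_fmt(sw0.dt)}",
        f"#units_command={sw0.meta['units_command']}",
        f"#units_response={sw0.meta['units_response']}",
        f"#n_sweeps={len(ladder)}",
        f"#amplitudes={','.join(_fmt(a) for a in proto.amplitudes)}",
    ]
    for k in _PROTO_KEYS:
        v = getattr(proto, k)
        if v is not None:
            lines.append(f"#protocol.{k}={_fmt(v)}")
    for i, sw in enumerate(ladder.sweeps):
        for k, v in sorted(sw.meta.items()):
            if k in ("units_command", "units_response"):
                continue
            lines.append(f"#sweep.{i}.{k}={v}")
    for sw in ladder.sweeps:
        lines.append("")
        for c, r in zip(sw.command, sw.response):
            lines.append(f"{_fmt(c)}\t{_fmt(r)}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def _parse_meta_value(s: str):
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            pass
    if s in ("True", "False"):
        return s == "True"
    return s


def read_sweeps(path) -> ProtocolLadder:
    """Read a ladder from the plain-text sweep interchange format.

    Raises :class:`SweepFormatError` (naming the offending line) on missing
    header keys, ragged columns, or unit labels inconsistent with the mode.
    """
    header: dict[str, str] = {}
    blocks: list[list[tuple[float, float]]] = []
    current: list[tuple[float, float]] | None = None
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("#"):
                if "=" not in line:
                    raise SweepFormatError(f"line {lineno}: malformed header {line!r}")
                k, v = line[1:].split("=", 1)
                header[k.strip()] = v.strip()
            elif line.strip() == "":
                current = None
            else:
                cols = line.split("\t")
                if len(cols) != 2:
                    raise SweepFormatError(
                        f"line {lineno}: expected 2 tab-separated columns, "
                        f"got {len(cols)}"
                    )
                try:
                    pair = (float(cols[0]), float(cols[1]))
                except ValueError as e:
                    raise SweepFormatError(f"line {lineno}: {e}") from None
                if current is None:
                    current = []
                    blocks.append(current)
                current.append(pair)
    missing = [k for k in _REQUIRED_KEYS if k not in header]
    if missing:
        raise SweepFormatError(f"missing header keys: {', '.join(missing)}")
    mode = header["mode"]
    if mode not in _MODES:
        raise SweepFormatError(f"unknown mode {mode!r}")
    cu, ru = MODE_UNITS[mode]
    if header["units_command"] != cu or header["units_response"] != ru:
        raise SweepFormatError(
            f"units {header['units_command']}/{header['units_response']} "
            f"inconsistent with mode {mode} (expected {cu}/{ru})"
        )
    n_sweeps = int(header["n_sweeps"])
    if len(blocks) != n_sweeps:
        raise SweepFormatError(
            f"header declares {n_sweeps} sweeps but file contains {len(blocks)}"
        )
    dt = float(header["dt_ms"])
    sweeps = []
    for i, block in enumerate(blocks):
        arr = np.array(block, dtype=float)
        meta = {}
        prefix = f"sweep.{i}."
        for k, v in header.items():
            if k.startswith(prefix):
                meta[k[len(prefix) :]] = _parse_meta_value(v)
        sweeps.append(
            Sweep(dt=dt, command=arr[:, 0], response=arr[:, 1], mode=mode, meta=meta)
        )
    if "protocol.holding" in header:
        kwargs = {}
        for k in _PROTO_KEYS:
            if f"protocol.{k}" in header:
                kwargs[k] = float(header[f"protocol.{k}"])
        amps = tuple(float(a) for a in header["amplitudes"].split(","))
        proto = StepProtocol(amplitudes=amps, **kwargs)
    else:
        proto = infer_step_protocol([s.command for s in sweeps], dt)
    return ProtocolLadder(proto, sweeps)


# ---------------------------------------------------------------------------
# Flat key/value run-configuration files
# ---------------------------------------------------------------------------


def read_config(path) -> dict:
    """Read a flat ``key = value`` config document ('#' comments allowed)."""
    out: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected 'key = value'")
            k, v = line.split("=", 1)
            out[k.strip()] = _parse_meta_value(v.strip())
    return out


def write_config(config: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in config.items():
            fh.write(f"{k} = {v}\n")
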