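"""Generalized Henderson liquid-junction-potential (LJP) calculator.

The potential across the free-diffusion junction between the pipette and bath
solutions is computed with the generalized Henderson equation

    V = (RT/F) * [ sum_i z_i u_i dc_i / sum_i z_i^2 u_i dc_i ]
              * ln( sum_i z_i^2 u_i c_i^pip / sum_i z_i^2 u_i c_i^bath )

with dc_i = c_i^pip - c_i^bath and u_i the relative ionic mobility (K+ = 1).
The result is reported with the pipette-minus-bath sign convention used for
offline correction of patch-clamp recordings: a K-gluconate pipette in a
NaCl-based bath yields a *positive* LJP, and the true membrane potential is
the recorded value minus the LJP
(:func:`vbephys.traces.apply_junction_correction`).

Activity coefficients and full electro-diffusion are out of scope; weak
acids/chelators enter at fixed fractional charges chosen for pH 7.2 (see
:mod:`vbephys.solutions`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .traces import SolutionComposition

R_GAS = 8.314462618  # J mol^-1 K^-1
FARADAY = 96485.33212  # C mol^-1
#: default bath temperature (K), ~34 C
DEFAULT_TEMPERATURE_K = 307.0
#: charged species at or below this concentration (mM) may be silently dropped
DROP_THRESHOLD_MM = 1.0


class UnknownIonError(KeyError):
    """A charged species above the drop threshold has no mobility entry."""


@dataclass
class IonMobilityTable:
    """Relative ionic mobilities (K+ = 1) keyed by (name, charge)."""

    entries: dict  # (name, charge) -> mobility

    def __post_init__(self):
        for (name, z), u in self.entries.items():
            if u <= 0:
                raise ValueError(f"non-positive mobility for {name} ({z:+d})")
        if ("K", 1) not in self.entries or self.entries[("K", 1)] != 1.0:
            raise ValueError("table must contain K+ with mobility 1")

    def lookup(self, name: str, charge: int) -> float | None:
        return self.entries.get((name, charge))

    @classmethod
    def default(cls) -> "IonMobilityTable":
        text = (
            resources.files("vbephys").joinpath("data/ion_mobilities.tsv").read_text()
        )
        entries = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, z, u = line.split("\t")[:3]
            entries[(name, int(z))] = float(u)
        return cls(entries)


@dataclass
class LJPResult:
    """LJP in mV, pipette-minus-bath convention, plus a species audit."""

    ljp_mV: float
    temperature_K: float
    species_used: list = field(default_factory=list)
    species_dropped: list = field(default_factory=list)


def _collect(pipette, bath, table):
    """Union of resolvable ions with (charge, mobility, c_pip, c_bath)."""
    conc: dict = {}
    for side, sol in (("pip", pipette), ("bath", bath)):
        for name, z, c in sol.species:
            key = (name, z)
            conc.setdefault(key, [0.0, 0.0])
            conc[key][0 if side == "pip" else 1] += c
    used, dropped = [], []
    for (name, z), (cp, cb) in sorted(conc.items()):
        u = table.lookup(name, z)
        if u is None:
            if max(cp, cb) > DROP_THRESHOLD_MM:
                raise UnknownIonError(
                    f"no mobility for {name} ({z:+d}) at "
                    f"{max(cp, cb):g} mM (> {DROP_THRESHOLD_MM} mM)"
                )
            dropped.append(name)
            continue
        used.append((name, z, u, cp, cb))
    return used, dropped


def henderson_ljp(
    pipette: SolutionComposition,
    bath: SolutionComposition,
    table: IonMobilityTable | None = None,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> LJPResult:
    """Generalized Henderson LJP of a pipette/bath solution pair.

    Charged species missing from the mobility table are dropped when at or
    below 1 mM and raise :class:`UnknownIonError` otherwise.  Identical
    solutions give exactly 0; swapping pipette and bath negates the result.
    """
    table = table or IonMobilityTable.default()
    used, dropped = _collect(pipette, bath, table)
    if not used:
        raise ValueError("no resolvable charged species")
    z = np.array([u[1] for u in used], float)
    u_ = np.array([u[2] for u in used], float)
    cp = np.array([u[3] for u in used], float)
    cb = np.array([u[4] for u in used], float)
    dc = cp - cb
    s_pip = float(np.sum(z * z * u_ * cp))
    s_bath = float(np.sum(z * z * u_ * cb))
    if s_pip <= 0 or s_bath <= 0:
        raise ValueError("degenerate solution: zero total ionic conductance")
    num = float(np.sum(z * u_ * dc))
    den = float(np.sum(z * z * u_ * dc))
    if abs(den) < 1e-12 * max(s_pip, s_bath):
        # symmetric exchange (e.g. identical solutions): no junction potential
        ljp = 0.0
    else:
        rt_f = R_GAS * temperature_K / FARADAY * 1000.0  # mV
        # orientation fixed so the conventional patch-clamp corrections come
        # out positive (pipette-minus-bath; see module docstring)
        ljp = rt_f * (num / den) * math.log(s_pip / s_bath)
    return LJPResult(
        ljp_mV=ljp,
        temperature_K=temperature_K,
        species_used=[(n, zz, c_p, c_b) for (n, zz, _, c_p, c_b) in used],
        species_dropped=dropped,
    )
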