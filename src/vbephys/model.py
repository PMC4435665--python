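"""Single-compartment conductance-based ventrobasal (VB) thalamocortical
relay neuron, runnable in current- and voltage-clamp modes.

The membrane equation is

    Cm dV/dt = -(I_leak + I_T + I_h + I_HVA + I_Na + I_K) + I_inj

with
  I_leak = g_leak (V - E_leak)
  I_T    = g_T m^2 h (V - E_Ca)      low-threshold (T-type) calcium current
  I_h    = g_h r (V - E_h)           HCN cation current ("sag"/rebound drive)
  I_HVA  = g_HVA q^2 (V - E_Ca)      high-voltage-activated calcium current
  I_Na, I_K                          Hodgkin-Huxley spike currents

T-type kinetics follow the classic thalamocortical relay-cell description
(window current near -60 mV; inactivation recovery time constants of
hundreds of ms at -90 mV, which is what makes 200-ms and 1,000-ms
hyperpolarizing steps behave differently).  HCN activation is a Boltzmann
with V50 = -86 mV and slope 4.2 mV, matching values reported for these
neurons, with a bell-shaped time constant that is slow (~250 ms) in the
hyperpolarized activation range and fast above -75 mV.

Pharmacology is modelled as conductance scaling: ``block_h`` emulates
ZD7288 (HCN blocker), ``block_T`` emulates Z944 (pan T-type blocker).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
import numpy as np
from scipy.optimize import brentq

from . import _kernel
from .traces import (
    CURRENT_CLAMP,
    VOLTAGE_CLAMP,
    ProtocolLadder,
    Sweep,
)

#: maximum internal RK4 step (ms); commands sampled coarser are subdivided
MAX_INTERNAL_DT = 0.025
#: floor on effective series resistance (MOhm) to keep the clamp ODE non-stiff
MIN_RS_EFF = 0.5

_TAU_FORMS = {"constant": 0, "bell": 1, "recip2exp": 2, "piecewise_exp": 3}


class SimulationError(RuntimeError):
    """Raised when the integrator produces a non-finite state."""


@dataclass(frozen=True)
class GateKinetics:
    """Voltage dependence of one first-order gate.

    ``x_inf(V) = 1 / (1 + exp((v_half - V) / slope))``: a positive slope
    gives a gate opening with depolarization (activation), a negative slope
    one opening with hyperpolarization (inactivation, or HCN activation).
    ``tau_form``/``tau_params`` name the functional form of the voltage-
    dependent time constant (see :mod:`vbephys._kernel`).
    """

    v_half: float
    slope: float
    tau_form: str
    tau_params: tuple

    def __post_init__(self):
        if self.slope == 0:
            raise ValueError("slope must be nonzero")
        if self.tau_form not in _TAU_FORMS:
            raise ValueError(f"unknown tau form {self.tau_form!r}")
        for v in (-120.0, -80.0, -40.0, 0.0, 40.0):
            if self.tau(v) <= 0:
                raise ValueError(f"tau_fn not positive at {v} mV")

    def x_inf(self, v):
        return 1.0 / (1.0 + np.exp((self.v_half - np.asarray(v, float)) / self.slope))

    def tau(self, v):
        p = np.zeros(6)
        p[: len(self.tau_params)] = self.tau_params
        return _kernel._tau(_TAU_FORMS[self.tau_form], p, float(v))

    def encode(self) -> np.ndarray:
        row = np.zeros(9)
        row[0] = self.v_half
        row[1] = self.slope
        row[2] = _TAU_FORMS[self.tau_form]
        row[3 : 3 + len(self.tau_params)] = self.tau_params
        return row


def default_t_activation() -> GateKinetics:
    # thalamocortical T-current activation (m), time constant ~1-2 ms
    return GateKinetics(
        v_half=-58.5,
        slope=6.2,
        tau_form="recip2exp",
        tau_params=(0.612, 1.0, -131.6, 16.7, -16.8, 18.2),
    )


def default_t_inactivation() -> GateKinetics:
    # T-current inactivation (h): mostly inactivated at rest, de-inactivating
    # below ~-80 mV with recovery tau ~290 ms at -90 mV, so 200-ms and
    # 1,000-ms conditioning steps recruit clearly different T-current pools
    return GateKinetics(
        v_half=-83.0,
        slope=-4.0,
        tau_form="piecewise_exp",
        tau_params=(-467.0, 66.6, 16.0, -21.88, -80.0, 14.0),
    )


def default_h_activation() -> GateKinetics:
    # HCN activation (r): Boltzmann V50 -86 mV, slope 4.2 mV.  The bell time
    # constant peaks at 250 ms near -95 mV (a 1,000-ms conditioning step
    # settles) and falls to tens of ms above -75 mV, so the current shapes
    # the hyperpolarized trough but deactivates quickly during the rebound.
    return GateKinetics(
        v_half=-86.0,
        slope=-4.2,
        tau_form="bell",
        tau_params=(40.0, 210.0, -90.0, 18.0),
    )


def default_hva_activation() -> GateKinetics:
    # high-threshold calcium activation (q), fast, non-inactivating
    return GateKinetics(v_half=-25.0, slope=5.0, tau_form="constant", tau_params=(1.5,))


@dataclass
class NeuronParams:
    """Conductance densities and gating parameters of the synthetic VB neuron.

    Conductances in nS, capacitance in pF, potentials in mV.  ``block_T`` and
    ``block_h`` are fractional pharmacological blocks in [0, 1] (Z944 and
    ZD7288 surrogates respectively).
    """

    Cm: float = 67.0
    g_leak: float = 5.0
    E_leak: float = -80.0
    g_T: float = 79.0
    T_act: GateKinetics = field(default_factory=default_t_activation)
    T_inact: GateKinetics = field(default_factory=default_t_inactivation)
    E_Ca: float = 120.0
    g_h: float = 8.0
    h_act: GateKinetics = field(default_factory=default_h_activation)
    E_h: float = -43.0
    g_HVA: float = 16.0
    HVA_act: GateKinetics = field(default_factory=default_hva_activation)
    g_Na: float = 1400.0
    g_K: float = 3000.0
    E_Na: float = 50.0
    E_K: float = -100.0
    V_T_spike: float = -47.0
    phi_n: float = 0.3
    block_T: float = 0.0
    block_h: float = 0.0

    def __post_init__(self):
        for name in ("Cm",):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("g_leak", "g_T", "g_h", "g_HVA", "g_Na", "g_K"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("block_T", "block_h"):
            b = getattr(self, name)
            if not 0.0 <= b <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    # effective (block-scaled) conductances
    @property
    def g_T_eff(self) -> float:
        return self.g_T * (1.0 - self.block_T)

    @property
    def g_h_eff(self) -> float:
        return self.g_h * (1.0 - self.block_h)

    def encode(self) -> tuple[np.ndarray, np.ndarray]:
        pvec = np.array(
            [
                self.Cm,
                self.g_leak,
                self.E_leak,
                self.g_T_eff,
                self.E_Ca,
                self.g_h_eff,
                self.E_h,
                self.g_HVA,
                self.g_Na,
                self.E_Na,
                self.g_K,
                self.E_K,
                self.V_T_spike,
                self.phi_n,
            ]
        )
        kin = np.vstack(
            [
                self.T_act.encode(),
                self.T_inact.encode(),
                self.h_act.encode(),
                self.HVA_act.encode(),
            ]
        )
        return pvec, kin

    def steady_state_current(self, v: float) -> float:
        """Total ionic current (pA) with every gate at steady state at V."""
        mT = self.T_act.x_inf(v)
        hT = self.T_inact.x_inf(v)
        r = self.h_act.x_inf(v)
        q = self.HVA_act.x_inf(v)
        pvec, _ = self.encode()
        u = v - self.V_T_spike
        am = 0.32 * _vtrap(13.0 - u, 4.0)
        bm = 0.28 * _vtrap(u - 40.0, 5.0)
        ah = 0.128 * math.exp(-(u - 17.0) / 18.0)
        bh = 4.0 / (1.0 + math.exp(-(u - 40.0) / 5.0))
        an = 0.032 * _vtrap(15.0 - u, 5.0)
        bn = 0.5 * math.exp(-(u - 10.0) / 40.0)
        m = am / (am + bm)
        h = ah / (ah + bh)
        n = an / (an + bn)
        return (
            self.g_leak * (v - self.E_leak)
            + self.g_T_eff * mT**2 * hT * (v - self.E_Ca)
            + self.g_h_eff * r * (v - self.E_h)
            + self.g_HVA * q**2 * (v - self.E_Ca)
            + self.g_Na * m**3 * h * (v - self.E_Na)
            + self.g_K * n**4 * (v - self.E_K)
        )


def _vtrap(x, y):
    if abs(x / y) < 1e-6:
        return y * (1.0 - x / (2.0 * y))
    return x / (math.exp(x / y) - 1.0)


def resting_potential(params: NeuronParams) -> float:
    """Most hyperpolarized zero of the steady-state ionic current.

    This is the fixed point the relaxed initial state converges to in the
    absence of injected current.
    """
    grid = np.arange(-120.0, -35.0, 1.0)
    vals = np.array([params.steady_state_current(v) for v in grid])
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            return float(grid[i])
        if vals[i] * vals[i + 1] < 0:
            return float(
                brentq(params.steady_state_current, grid[i], grid[i + 1], xtol=1e-9)
            )
    raise SimulationError("no resting fixed point found in [-120, -35] mV")


@dataclass
class ClampConfig:
    """Recording-rig model: series resistance, compensation, noise, seed.

    ``noise_sd`` is the SD of additive Gaussian noise applied to the response
    after integration (mV in current clamp, pA in voltage clamp), keeping the
    underlying dynamics deterministic for a fixed seed.
    ``voltage_offset_mV`` is a constant recording offset added to current-clamp
    responses (residual electrode/junction offset after correction); it shifts
    every reported potential of a cell without affecting the dynamics.
    """

    mode: str = CURRENT_CLAMP
    R_series: float = 10.0
    rs_compensation: float = 0.7
    noise_sd: float = 0.0
    voltage_offset_mV: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.rs_compensation <= 1.0:
            raise ValueError("rs_compensation must be in [0, 1]")
        if self.R_series < 0 or self.noise_sd < 0:
            raise ValueError("R_series and noise_sd must be >= 0")

    @classmethod
    def cc(cls, seed: int = 0, noise_sd: float = 0.1) -> "ClampConfig":
        """Current-clamp defaults (noise SD 0.1 mV)."""
        return cls(mode=CURRENT_CLAMP, noise_sd=noise_sd, seed=seed)

    @classmethod
    def vc(cls, seed: int = 0, noise_sd: float = 5.0) -> "ClampConfig":
        """Voltage-clamp defaults: Rs 10 MOhm, 70 % compensation, 5 pA noise."""
        return cls(mode=VOLTAGE_CLAMP, noise_sd=noise_sd, seed=seed)

    @property
    def rs_eff(self) -> float:
        return max((1.0 - self.rs_compensation) * self.R_series, MIN_RS_EFF)


SETTLE_MS = 500.0


def _command_array(command, dt):
    if isinstance(command, Sweep):
        return command.command, command.dt
    if dt is None:
        raise ValueError("dt required when command is a bare array")
    return np.asarray(command, dtype=float), float(dt)


def _settled_state(params, clamp, mode_flag, level, dt):
    """Resting (or holding) steady state found by relaxation.

    The relaxation starts from the analytic fixed point (gates at steady
    state), so a short settle suffices to polish slow-gate equilibria.
    """
    substeps = max(1, int(math.ceil(dt / MAX_INTERNAL_DT)))
    pvec, kin = params.encode()
    v0 = resting_potential(params) if mode_flag == 0 else float(level)
    y = _kernel.init_state(v0, pvec, kin)
    n_settle = int(round(SETTLE_MS / dt))
    settle_cmd = np.full(n_settle, level)
    scratch = np.empty(n_settle)
    bad = _kernel.integrate(
        settle_cmd, dt, substeps, y, mode_flag, pvec, kin, clamp.rs_eff, scratch
    )
    if bad >= 0:
        raise SimulationError(f"non-finite state during settling at t={bad * dt:.3f} ms")
    return y


def _simulate(params, command, clamp, dt, mode, initial_state=None):
    cmd, dt = _command_array(command, dt)
    substeps = max(1, int(math.ceil(dt / MAX_INTERNAL_DT)))
    pvec, kin = params.encode()
    mode_flag = 0 if mode == CURRENT_CLAMP else 1
    if initial_state is None:
        y = _settled_state(params, clamp, mode_flag, cmd[0], dt)
    else:
        y = initial_state.copy()
    record = np.empty(len(cmd))
    bad = _kernel.integrate(
        cmd, dt, substeps, y, mode_flag, pvec, kin, clamp.rs_eff, record
    )
    if bad >= 0:
        raise SimulationError(f"non-finite state at t={bad * dt:.3f} ms")
    if clamp.noise_sd > 0:
        rng = np.random.default_rng(clamp.seed)
        record = record + rng.normal(0.0, clamp.noise_sd, size=record.shape)
    if mode == CURRENT_CLAMP and clamp.voltage_offset_mV != 0.0:
        record = record + clamp.voltage_offset_mV
    return Sweep(
        dt=dt,
        command=cmd.copy(),
        response=record,
        mode=mode,
        meta={"simulated": True, "seed": clamp.seed, "noise_sd": clamp.noise_sd},
    )


def simulate_current_clamp(
    params: NeuronParams, command, clamp: ClampConfig | None = None,
    dt: float | None = None, initial_state=None,
) -> Sweep:
    """Integrate the membrane response (mV) to an injected-current command (pA).

    The initial state is the resting steady state found by relaxation; the
    result is deterministic given (params, command, clamp.seed).
    """
    clamp = clamp or ClampConfig.cc()
    return _simulate(params, command, clamp, dt, CURRENT_CLAMP, initial_state)


def simulate_voltage_clamp(
    params: NeuronParams, command, clamp: ClampConfig | None = None,
    dt: float | None = None, initial_state=None,
) -> Sweep:
    """Integrate the whole-cell clamp current (pA) for a potential command (mV).

    The recorded current is the amplifier current through the residual series
    resistance ``(1 - rs_compensation) * R_series`` and therefore contains the
    capacitive transient and ohmic leak, as in a real recording.
    """
    clamp = clamp or ClampConfig.vc()
    return _simulate(params, command, clamp, dt, VOLTAGE_CLAMP, initial_state)


def simulate_ladder(
    params: NeuronParams, ladder: ProtocolLadder, clamp: ClampConfig
) -> ProtocolLadder:
    """Run every sweep of a command-only ladder.

    All sweeps start from the same relaxed resting (or holding) state, found
    once per ladder; per-sweep noise seeds are derived deterministically from
    ``clamp.seed``.
    """
    sim = (
        simulate_current_clamp if clamp.mode == CURRENT_CLAMP else simulate_voltage_clamp
    )
    mode_flag = 0 if clamp.mode == CURRENT_CLAMP else 1
    sw0 = ladder.sweeps[0]
    y0 = _settled_state(params, clamp, mode_flag, sw0.command[0], sw0.dt)
    out = []
    for i, sw in enumerate(ladder.sweeps):
        cfg = replace(clamp, seed=(clamp.seed * 100003 + i) % (2**31 - 1))
        out.append(sim(params, sw, cfg, initial_state=y0))
    return ProtocolLadder(ladder.protocol, out)


# ---------------------------------------------------------------------------
# Cohort presets.  NEC = non-epileptic control strain; GAERS = the epileptic
# strain, which differs only by a larger HCN conductance (g_h) and a somewhat
# smaller T-type conductance (g_T), with the smaller input resistance that the
# extra resting HCN conductance implies.  *_ZD sets block_h = 1 (ZD7288 20 uM
# surrogate); *_Z944 sets block_T = 1.  P7P9_* presets model the younger
# animals used for calcium-current voltage clamp: smaller cells, ~25 % lower
# T-type density in the epileptic strain, and a slightly larger HVA density.
# Magnitudes are package defaults chosen to land burst thresholds in the
# tens-of-pA range and current densities at the tens-of-pA/pF scale.
# ---------------------------------------------------------------------------

_ADULT_COMMON = dict(Cm=67.0, g_leak=5.0, E_leak=-80.0, g_HVA=16.0)


def preset(name: str) -> NeuronParams:
    """Named parameter presets for the simulated cohorts."""
    table: dict[str, dict] = {
        "NEC": dict(_ADULT_COMMON, g_T=79.0, g_h=8.0),
        "GAERS": dict(_ADULT_COMMON, g_T=77.0, g_h=18.0, g_HVA=19.0),
        # P7-P9 presets model the calcium-current voltage-clamp condition:
        # smaller cells, ~25 % lower T density in the epileptic strain, and
        # spike and HCN conductances silenced by the recording solutions
        # (Cs/TEA/4-AP internal blocks K and HCN, TEA-substituted low-sodium
        # bath)
        "P7P9_NEC": dict(
            Cm=40.0, g_leak=4.0, E_leak=-80.0, g_T=10.4, g_h=0.0, g_HVA=7.8,
            g_Na=0.0, g_K=0.0,
        ),
        "P7P9_GAERS": dict(
            Cm=40.0, g_leak=4.0, E_leak=-80.0, g_T=7.8, g_h=0.0, g_HVA=9.4,
            g_Na=0.0, g_K=0.0,
        ),
    }
    base = name
    blocks: dict = {}
    if name.endswith("_ZD"):
        base, blocks = name[: -len("_ZD")], dict(block_h=1.0)
    elif name.endswith("_Z944"):
        base, blocks = name[: -len("_Z944")], dict(block_T=1.0)
    if base not in table:
        raise ValueError(f"unknown preset {name!r}")
    return NeuronParams(**table[base], **blocks)


PRESET_NAMES = (
    "NEC",
    "GAERS",
    "NEC_ZD",
    "GAERS_ZD",
    "NEC_Z944",
    "GAERS_Z944",
    "P7P9_NEC",
    "P7P9_GAERS",
)


def scale_t_inactivation_tau(kin: GateKinetics, s: float) -> GateKinetics:
    """Scale the T-inactivation time constant by a factor ``s`` (both the
    hyperpolarized recovery branch and the depolarized decay branch of the
    piecewise-exponential form)."""
    if kin.tau_form != "piecewise_exp":
        raise ValueError("tau scaling implemented for the piecewise form only")
    p0, p1, p2, p3, p4, p5 = kin.tau_params
    ln_s = math.log(s)
    return replace(
        kin,
        tau_params=(p0 - p1 * ln_s, p1, p2 * s, p3 + p5 * ln_s, p4, p5),
    )


def generate_cohort(
    preset_name: str,
    n: int,
    jitter_cv: float = 0.2,
    seed: int = 0,
    rmp_jitter_sd: float = 1.2,
    tau_jitter_cv: float = 0.0,
) -> list[NeuronParams]:
    """Draw ``n`` cells around a preset.

    Conductances and Cm are drawn log-normally with coefficient of variation
    ``jitter_cv`` (means preserved).  Two further sources of between-cell
    variability emulate real cohorts: additive Gaussian jitter of the leak
    reversal (SD ``rmp_jitter_sd`` mV, spreading resting potentials) and a
    log-normal scale factor on the T-type inactivation time constant
    (CV ``tau_jitter_cv``, spreading burst durations and AP counts).
    Reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if jitter_cv < 0 or rmp_jitter_sd < 0 or tau_jitter_cv < 0:
        raise ValueError("jitter parameters must be >= 0")
    base = preset(preset_name)
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + jitter_cv**2))
    sigma_tau = math.sqrt(math.log(1.0 + tau_jitter_cv**2))
    cells = []
    for _ in range(n):
        kw = {}
        for name in ("Cm", "g_leak", "g_T", "g_h", "g_HVA", "g_Na", "g_K"):
            mean = getattr(base, name)
            if sigma > 0 and mean > 0:
                kw[name] = mean * math.exp(rng.normal(-0.5 * sigma**2, sigma))
            else:
                kw[name] = mean
        e_leak = base.E_leak + (
            rng.normal(0.0, rmp_jitter_sd) if rmp_jitter_sd > 0 else 0.0
        )
        t_inact = base.T_inact
        if sigma_tau > 0:
            s = math.exp(rng.normal(-0.5 * sigma_tau**2, sigma_tau))
            t_inact = scale_t_inactivation_tau(t_inact, s)
        cells.append(
            replace(base, E_leak=e_leak, T_inact=t_inact, **kw)
        )
    return cells
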