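import numpy as np
import pytest
from dataclasses import replace

from vbephys import protocols
from vbephys.model import ClampConfig, NeuronParams, preset, simulate_ladder
from vbephys.traces import Sweep, make_step_protocol
from vbephys.voltageclamp import (
    ActivationCurve,
    DoseResponse,
    boltzmann,
    build_iv,
    fit_boltzmann,
    fit_hill_ec50,
    hill,
    isolate_t_type,
    leak_correct,
    tail_current_activation,
    whole_cell_capacitance,
    zd_sensitive_current,
)

GOOD_CLAMP = ClampConfig(mode="voltage_clamp", rs_compensation=0.95, noise_sd=0.0)


class TestCapacitance:
    def test_rectangular_surrogate_transient(self):
        """A synthetic rectangular transient of 250 pA*ms over a 5-mV step
        must integrate to 50 pF."""
        lad = make_step_protocol(
            -90.0, 20.0, 40.0, 20.0, -85.0, -85.0, 0.0, 0.02, "voltage_clamp"
        )
        sw = lad.sweeps[0]
        i = np.zeros(sw.n_samples)
        on = sw.index_at(20.0)
        i[on : on + int(1.0 / 0.02)] = 250.0  # 250 pA for 1 ms
        sw.response = i
        assert whole_cell_capacitance(sw, rs_correct=False) == pytest.approx(
            50.0, rel=0.01
        )

    def test_simulated_recovery(self, passive_params, quiet_vc):
        lad = simulate_ladder(passive_params, protocols.protocol_ladder("cm5mV"),
                              quiet_vc)
        cm = whole_cell_capacitance(lad.sweeps[0])
        assert cm == pytest.approx(67.0, rel=0.02)

    def test_independent_of_leak_over_10x_range(self, passive_params, quiet_vc):
        ests = []
        for g in (2.0, 20.0):
            p = replace(passive_params, g_leak=g)
            lad = simulate_ladder(p, protocols.protocol_ladder("cm5mV"), quiet_vc)
            ests.append(whole_cell_capacitance(lad.sweeps[0]))
        assert abs(ests[1] / ests[0] - 1) < 0.02

    def test_robust_to_doubled_series_resistance(self, passive_params, quiet_vc):
        base = whole_cell_capacitance(
            simulate_ladder(passive_params, protocols.protocol_ladder("cm5mV"),
                            quiet_vc).sweeps[0]
        )
        doubled = whole_cell_capacitance(
            simulate_ladder(
                passive_params,
                protocols.protocol_ladder("cm5mV"),
                replace(quiet_vc, R_series=20.0),
            ).sweeps[0]
        )
        assert abs(doubled / base - 1) < 0.05

    def test_no_step_is_error(self):
        sw = Sweep(0.05, np.full(100, -90.0), np.zeros(100), "voltage_clamp")
        with pytest.raises(ValueError, match="step"):
            whole_cell_capacitance(sw)


class TestLeakCorrection:
    def test_ohmic_cell_cancels_exactly(self, passive_params, quiet_vc):
        lad = simulate_ladder(passive_params, protocols.protocol_ladder("leakcal"),
                              quiet_vc)
        corr = leak_correct(lad)
        for sw in corr.sweeps:
            ss = sw.response[sw.index_at(200.0) : sw.index_at(290.0)]
            assert np.max(np.abs(ss)) < 1.0  # |I| < 1 pA at steady state

    def test_idempotent(self, passive_params, quiet_vc):
        lad = simulate_ladder(passive_params, protocols.protocol_ladder("leakcal"),
                              quiet_vc)
        once = leak_correct(lad)
        twice = leak_correct(once)
        for a, b in zip(once.sweeps, twice.sweeps):
            assert np.max(np.abs(a.response - b.response)) < 1.0

    def test_insufficient_calibration_steps(self, passive_params, quiet_vc):
        lad = simulate_ladder(
            passive_params,
            make_step_protocol(-90.0, 50.0, 100.0, 50.0, -70.0, -10.0, 10.0,
                               0.05, "voltage_clamp"),
            quiet_vc,
        )
        with pytest.raises(ValueError, match="calibration"):
            leak_correct(lad)


@pytest.fixture(scope="module")
def p7p9_pipeline():
    """Leak-corrected total and prepulse calcium I-V families plus direct
    channel-off references, simulated under a well-compensated clamp."""
    p = preset("P7P9_NEC")
    cal = simulate_ladder(p, protocols.protocol_ladder("leakcal"), GOOD_CLAMP)
    tot = leak_correct(
        simulate_ladder(p, protocols.protocol_ladder("cavIV"), GOOD_CLAMP),
        calibration=cal,
    )
    pre = leak_correct(
        simulate_ladder(p, protocols.protocol_ladder("cavIV_prepulse"), GOOD_CLAMP),
        calibration=cal,
    )
    t_only = replace(p, g_HVA=0.0)
    hva_only = replace(p, g_T=0.0)
    t_direct = build_iv(
        leak_correct(
            simulate_ladder(t_only, protocols.protocol_ladder("cavIV"), GOOD_CLAMP),
            calibration=simulate_ladder(t_only, protocols.protocol_ladder("leakcal"),
                                        GOOD_CLAMP),
        )
    )
    hva_direct = build_iv(
        leak_correct(
            simulate_ladder(hva_only, protocols.protocol_ladder("cavIV_prepulse"),
                            GOOD_CLAMP),
            calibration=simulate_ladder(hva_only, protocols.protocol_ladder("leakcal"),
                                        GOOD_CLAMP),
        )
    )
    return dict(params=p, tot=tot, pre=pre, t_direct=t_direct, hva_direct=hva_direct)


class TestIVCurves:
    def test_seventeen_test_potentials(self):
        lad = protocols.protocol_ladder("cavIV")
        assert len(lad) == 17
        assert lad.protocol.amplitudes[0] == -70.0
        assert lad.protocol.amplitudes[-1] == 10.0

    def test_zero_conductance_cell_gives_zero_curve(self, passive_params, quiet_vc):
        p = replace(passive_params, g_leak=5.0)
        lad = leak_correct(
            simulate_ladder(p, protocols.protocol_ladder("cavIV"), quiet_vc),
            calibration=simulate_ladder(p, protocols.protocol_ladder("leakcal"),
                                        quiet_vc),
        )
        iv = build_iv(lad)
        assert np.max(np.abs(iv.peak_current_pA)) < 2.0

    def test_peak_equals_bruteforce_min(self, p7p9_pipeline):
        tot = p7p9_pipeline["tot"]
        iv = build_iv(tot)
        proto = tot.protocol
        for sw, peak in zip(tot.sweeps, iv.peak_current_pA):
            a = sw.index_at(proto.step_start_ms + 2.0)
            b = sw.index_at(proto.step_end_ms)
            assert peak == np.min(sw.response[a:b])

    def test_density_is_peak_over_capacitance(self, p7p9_pipeline):
        iv = build_iv(p7p9_pipeline["tot"], capacitance=40.0)
        np.testing.assert_allclose(
            iv.current_density_pA_per_pF, iv.peak_current_pA / 40.0
        )


class TestPrepulseSeparation:
    def test_identical_ladders_give_zero_t(self, p7p9_pipeline):
        pre = p7p9_pipeline["pre"]
        t, hva = isolate_t_type(pre, pre)
        assert np.max(np.abs(t.peak_current_pA)) < 20.0  # blank-window residue only

    def test_t_recovers_channel_off_simulation(self, p7p9_pipeline):
        t, _ = isolate_t_type(p7p9_pipeline["tot"], p7p9_pipeline["pre"])
        ref = p7p9_pipeline["t_direct"]
        i = int(np.argmin(ref.peak_current_pA))
        assert t.peak_current_pA[i] == pytest.approx(
            ref.peak_current_pA[i], rel=0.05
        )

    def test_hva_recovers_channel_off_simulation(self, p7p9_pipeline):
        _, hva = isolate_t_type(p7p9_pipeline["tot"], p7p9_pipeline["pre"])
        ref = p7p9_pipeline["hva_direct"]
        j = int(np.argmin(ref.peak_current_pA))
        assert hva.peak_current_pA[j] == pytest.approx(
            ref.peak_current_pA[j], rel=0.05
        )

    def test_t_peaks_more_negative_than_hva(self, p7p9_pipeline):
        t, hva = isolate_t_type(p7p9_pipeline["tot"], p7p9_pipeline["pre"])
        v_t = t.voltages[int(np.argmin(t.peak_current_pA))]
        v_hva = hva.voltages[int(np.argmin(hva.peak_current_pA))]
        assert v_t < v_hva

    def test_voltage_mismatch_is_error(self, p7p9_pipeline):
        tot = p7p9_pipeline["tot"]
        other = make_step_protocol(-90.0, 100.0, 200.0, 100.0, -60.0, 10.0, 5.0,
                                   0.05, "voltage_clamp")
        for sw in other.sweeps:
            sw.response = np.zeros(sw.n_samples)
        with pytest.raises(ValueError, match="mismatch"):
            isolate_t_type(tot, other)

    def test_subtraction_commutes_with_scaling(self, p7p9_pipeline):
        """Linearity: scaling both inputs scales the separated components."""
        tot, pre = p7p9_pipeline["tot"], p7p9_pipeline["pre"]
        t1, _ = isolate_t_type(tot, pre)
        tot2, pre2 = tot.copy(), pre.copy()
        for sw in (*tot2.sweeps, *pre2.sweeps):
            sw.response = 2.0 * sw.response
        t2, _ = isolate_t_type(tot2, pre2)
        np.testing.assert_allclose(t2.peak_current_pA, 2.0 * t1.peak_current_pA,
                                   rtol=1e-12)


class TestBlockerSubtraction:
    def test_identical_inputs_zero(self, p7p9_pipeline):
        tot = p7p9_pipeline["tot"]
        sub = zd_sensitive_current(tot, tot)
        assert max(np.abs(s.response).max() for s in sub.sweeps) == 0.0

    def test_recovers_pure_hcn_current(self, quiet_vc):
        p = preset("NEC")
        lad = protocols.protocol_ladder("ihtail")
        ctrl = simulate_ladder(p, lad, GOOD_CLAMP)
        blocked = simulate_ladder(replace(p, block_h=1.0), lad, GOOD_CLAMP)
        sub = tail_current_activation(zd_sensitive_current(ctrl, blocked), fit=False)
        pure = replace(p, g_leak=0.0, g_T=0.0, g_HVA=0.0, g_Na=0.0, g_K=0.0)
        ref = tail_current_activation(simulate_ladder(pure, lad, GOOD_CLAMP),
                                      fit=False)
        i = int(np.argmin(sub.prepulse_mV))
        assert sub.tail_peak_pA[i] == pytest.approx(ref.tail_peak_pA[i], rel=0.02)

    def test_noise_variance_adds(self):
        """Subtracting sweeps with independent noise sums the variances."""
        p = preset("P7P9_NEC")
        lad = protocols.protocol_ladder("leakcal")
        a = simulate_ladder(p, lad, ClampConfig.vc(seed=1, noise_sd=4.0))
        b = simulate_ladder(p, lad, ClampConfig.vc(seed=2, noise_sd=3.0))
        sub = zd_sensitive_current(a, b)
        ss = sub.sweeps[0]
        seg = ss.response[ss.index_at(150.0) : ss.index_at(290.0)]
        assert np.var(seg) == pytest.approx(16.0 + 9.0, rel=0.25)


@pytest.fixture(scope="module")
def nec_activation():
    p = preset("NEC")
    lad = protocols.protocol_ladder("ihtail")
    ctrl = simulate_ladder(p, lad, GOOD_CLAMP)
    blocked = simulate_ladder(replace(p, block_h=1.0), lad, GOOD_CLAMP)
    return tail_current_activation(zd_sensitive_current(ctrl, blocked))


class TestTailActivation:

    def test_most_hyperpolarized_prepulse_normalizes_to_one(self, nec_activation):
        i = int(np.argmin(nec_activation.prepulse_mV))
        assert nec_activation.normalized[i] == pytest.approx(1.0)

    def test_matches_simulator_steady_state_activation(self, nec_activation):
        p = preset("NEC")
        rinf = p.h_act.x_inf(nec_activation.prepulse_mV)
        assert np.max(np.abs(nec_activation.normalized - rinf)) < 0.05

    def test_monotone_nonincreasing_with_depolarization(self, nec_activation):
        order = np.argsort(nec_activation.prepulse_mV)
        norm = nec_activation.normalized[order]
        assert np.all(np.diff(norm) <= 0.01)

    def test_gaers_tail_density_exceeds_nec(self, quiet_vc):
        lad = protocols.protocol_ladder("ihtail")
        dens = {}
        for name in ("NEC", "GAERS"):
            p = preset(name)
            ctrl = simulate_ladder(p, lad, GOOD_CLAMP)
            blk = simulate_ladder(replace(p, block_h=1.0), lad, GOOD_CLAMP)
            act = tail_current_activation(zd_sensitive_current(ctrl, blk), fit=False)
            i = int(np.argmin(act.prepulse_mV))
            dens[name] = act.tail_peak_pA[i] / p.Cm
        assert abs(dens["GAERS"]) > abs(dens["NEC"])

    def test_missing_tail_segment_is_error(self):
        lad = make_step_protocol(-60.0, 100.0, 500.0, 100.0, -110.0, -70.0, 10.0,
                                 0.05, "voltage_clamp")
        for sw in lad.sweeps:
            sw.response = np.zeros(sw.n_samples)
        with pytest.raises(ValueError, match="tail"):
            tail_current_activation(lad)


def grid_search_boltzmann(v, y):
    """Independent 2-D lattice oracle for the Boltzmann fit."""
    best = (None, None, np.inf)
    for v50 in np.arange(-110.0, -59.9, 0.25):
        for k in np.arange(0.5, 12.01, 0.25):
            sse = float(np.sum((boltzmann(v, v50, k) - y) ** 2))
            if sse < best[2]:
                best = (v50, k, sse)
    return best


class TestBoltzmannFit:
    V = np.arange(-110.0, -59.9, 5.0)

    def test_exact_recovery_on_noiseless_samples(self):
        y = boltzmann(self.V, -86.2, 4.2)
        fit = fit_boltzmann(self.V, y)
        assert fit["v50_mV"] == pytest.approx(-86.2, abs=1e-4)
        assert fit["slope_mV"] == pytest.approx(4.2, abs=1e-4)

    def test_monte_carlo_recovery_under_noise(self):
        rng = np.random.default_rng(42)
        v50s, ks = [], []
        for _ in range(200):
            y = boltzmann(self.V, -86.2, 4.2) + rng.normal(0, 0.03, len(self.V))
            fit = fit_boltzmann(self.V, y)
            v50s.append(fit["v50_mV"])
            ks.append(fit["slope_mV"])
        assert np.mean(np.abs(np.array(v50s) + 86.2)) < 1.0
        assert np.mean(np.abs(np.array(ks) - 4.2)) < 0.5

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(3)
        y = boltzmann(self.V, -84.0, 5.0) + rng.normal(0, 0.05, len(self.V))
        fit = fit_boltzmann(self.V, y)
        v50_g, k_g, sse_g = grid_search_boltzmann(self.V, y)
        sse_fit = float(np.sum((boltzmann(self.V, fit["v50_mV"], fit["slope_mV"])
                                - y) ** 2))
        assert sse_fit <= sse_g + 1e-9
        assert fit["v50_mV"] == pytest.approx(v50_g, abs=0.5)
        assert fit["slope_mV"] == pytest.approx(k_g, abs=0.5)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match=">= 4"):
            fit_boltzmann(np.array([-100.0, -90.0, -80.0]), np.array([1, 0.5, 0.1]))


class TestHillFit:
    C = np.array([0.3, 1.0, 3.0, 10.0, 30.0, 100.0])

    def test_exact_recovery(self):
        dr = DoseResponse(self.C, hill(self.C, 3.8, 1.0))
        fit = fit_hill_ec50(dr)
        assert fit.ec50_nM == pytest.approx(3.8, abs=1e-3)
        assert fit.hill_n == pytest.approx(1.0, abs=1e-3)

    def test_half_block_at_ec50(self):
        assert hill(3.8, 3.8, 1.0) == pytest.approx(0.5)

    def test_matches_grid_oracle(self):
        rng = np.random.default_rng(5)
        y = np.clip(hill(self.C, 5.0, 1.3) + rng.normal(0, 0.03, len(self.C)), 0, 1)
        fit = fit_hill_ec50(DoseResponse(self.C, y))
        best = (None, None, np.inf)
        for lec in np.arange(np.log(0.3), np.log(100.0), 0.02):
            for n in np.arange(0.3, 4.01, 0.05):
                sse = float(np.sum((hill(self.C, np.exp(lec), n) - y) ** 2))
                if sse < best[2]:
                    best = (np.exp(lec), n, sse)
        assert fit.ec50_nM == pytest.approx(best[0], rel=0.05)
        assert fit.hill_n == pytest.approx(best[1], abs=0.1)

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_hill_ec50(DoseResponse(self.C, np.ones(len(self.C))))
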