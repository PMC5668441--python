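"""Unit and property tests of the membrane model."""

import math

import numpy as np
import pytest

import cardiopop as cp
from cardiopop import cell_model as cm


def _valid_state() -> cp.CellState:
    return cp.initial_state()


class TestCurrents:
    def test_zero_conductances_give_zero_currents(self):
        zeros = {f: 0.0 for f in cm.BASELINE_MAXIMA}
        params = cp.CellParameters(g_b_Na=0.0, g_b_Ca=0.0, **zeros)
        cur = cp.compute_currents(_valid_state(), params)
        for name in cm.CURRENT_NAMES:
            assert getattr(cur, name) == 0.0

    def test_ik1_vanishes_at_potassium_reversal(self):
        state = _valid_state()
        e_k = cm.R_GAS * cm.T / cm.F * math.log(cm.KO / cm.KI)
        state.y[0] = e_k
        cur = cp.compute_currents(state, cp.CellParameters())
        assert cur.I_K1 == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "field,current", [("i_na", "I_Na"), ("i_nal", "I_NaL"), ("i_kr", "I_Kr"), ("i_cal", "I_CaL")]
    )
    def test_block_linearity(self, field, current):
        """A block factor b scales exactly the targeted current by b."""
        params = cp.CellParameters()
        state = _valid_state()
        state.y[0] = -0.02  # depolarized so every current is nonzero
        free = cp.compute_currents(state, params)
        b = 0.37
        blocked = cp.compute_currents(state, params, cp.BlockFactors(**{field: b}))
        assert getattr(blocked, current) == pytest.approx(b * getattr(free, current), rel=1e-12)
        for other in cm.CURRENT_NAMES:
            if other != current:
                assert getattr(blocked, other) == getattr(free, other)

    def test_charge_bookkeeping(self):
        """dVm/dt equals minus the sum of all returned currents (A/F -> V/s)."""
        rng = np.random.default_rng(7)
        params = cp.CellParameters()
        for _ in range(20):
            state = _valid_state()
            state.y[0] = rng.uniform(-0.09, 0.04)
            state.y[1:17] = rng.uniform(0, 1, 16)
            dy = cp.derivatives(0.0, state, params)
            total = cp.compute_currents(state, params).total()
            assert dy[0] == pytest.approx(-total, rel=1e-12, abs=1e-12)

    def test_nonfinite_state_raises(self):
        state = _valid_state()
        state.y[0] = np.nan
        with pytest.raises(FloatingPointError):
            cp.compute_currents(state, cp.CellParameters())


class TestMutation:
    def test_apply_mutation_idempotent_and_preserves_conductances(self):
        base = cp.CellParameters.from_scale_factors({"g_Na": 1.3, "g_Kr": 0.7})
        mut = cp.apply_mutation(base)
        assert mut.genotype is cp.Genotype.V1763M
        assert cp.apply_mutation(mut) == mut
        for f in cm.SAMPLED_PARAMETERS:
            assert getattr(mut, f) == getattr(base, f)

    def test_mutant_persistent_inal_dominates_along_control_trajectory(self, baseline_runs):
        """Driving both genotypes' late-Na gate kinetics with the same recorded
        control voltage trajectory, the mutant current is at least as large
        (in magnitude) as the control one at every phase of the AP."""
        run = baseline_runs["control"]
        tr = run["result"].trace
        v = tr.Vm
        dt = tr.t[1] - tr.t[0]
        mL = run["result"].states[cm.STATE_NAMES.index("mL")]
        nai = run["result"].states[cm.STATE_NAMES.index("Nai")]
        e_na = cm.R_GAS * cm.T / cm.F * np.log(cm.NAO / nai)

        def hl_trajectory(shift, tau):
            inf = 1.0 / (1.0 + np.exp((v + 87.61 - shift) / 7.488))
            h = np.empty_like(v)
            h[0] = inf[0]
            decay = math.exp(-dt / tau)
            for i in range(1, len(v)):
                h[i] = inf[i] + (h[i - 1] - inf[i]) * decay
            return h

        g = cm.BASELINE_MAXIMA["g_NaL"]
        i_ctrl = g * mL * hl_trajectory(0.0, 0.200) * (v / 1000.0 - e_na)
        i_mut = (g * cm.MUTANT_GNAL_SCALE * mL
                 * hl_trajectory(cm.MUTANT_HL_SHIFT_MV, 0.200 * cm.MUTANT_TAU_HL_SCALE)
                 * (v / 1000.0 - e_na))
        # skip the initial relaxation transient (first two seconds)
        skip = int(2.0 / dt)
        assert np.all(-i_mut[skip:] >= -i_ctrl[skip:] - 1e-12)

    def test_voltage_clamp_persistent_ratio_exceeds_one(self):
        ctrl = cp.voltage_clamp_persistent(cp.CellParameters())
        mut = cp.voltage_clamp_persistent(cp.apply_mutation(cp.CellParameters()))
        assert mut / ctrl > 1.0


class TestKinetics:
    def test_gate_steady_state_is_fixed_point(self):
        """A gate set to its voltage-dependent steady state has zero derivative."""
        from cardiopop.cell_model import gate_steady_state, STATE_NAMES

        v_mV = -40.0
        ss = gate_steady_state(v_mV)
        state = _valid_state()
        state.y[0] = v_mV / 1000.0
        for name in ("m", "h", "j", "d", "f1", "f2", "Xr2", "Xs", "Xf", "q", "r", "mL", "hL"):
            state.y[STATE_NAMES.index(name)] = ss[name]
        dy = cp.derivatives(0.0, state, cp.CellParameters())
        for name in ("m", "h", "j", "d", "f1", "f2", "Xr2", "Xs", "Xf", "q", "r", "mL", "hL"):
            assert dy[STATE_NAMES.index(name)] == pytest.approx(0.0, abs=1e-9)

    def test_gates_stay_bounded_in_long_run(self, baseline_runs):
        states = baseline_runs["control"]["result"].states
        gates = states[1:17]
        assert gates.min() >= -1e-9
        assert gates.max() <= 1.0 + 1e-9

    def test_limit_cycle_recurrence(self, baseline_runs):
        """After the long pre-run, consecutive beats traverse nearly identical
        states: the model sits on a limit cycle (the spontaneous-cell analogue
        of a steady state)."""
        run = baseline_runs["control"]
        res = run["result"]
        cycles = cp.detect_cycles(res.trace)
        assert len(cycles) >= 4
        s1, s2 = res.states[:, cycles[-3][0]], res.states[:, cycles[-2][0]]
        rel = np.abs(s2 - s1) / (np.abs(s1) + 1e-6)
        assert rel.max() < 0.02


class TestTypes:
    def test_parameters_reject_negative_conductance(self):
        with pytest.raises(ValueError):
            cp.CellParameters(g_Na=-1.0)

    def test_parameters_dict_round_trip(self):
        p = cp.CellParameters.from_scale_factors({"g_NaL": 1.5}, cp.Genotype.V1763M)
        assert cp.CellParameters.from_dict(p.to_dict()) == p

    def test_unknown_scale_factor_rejected(self):
        with pytest.raises(KeyError):
            cp.CellParameters.from_scale_factors({"g_bogus": 1.0})

    def test_state_invariants(self):
        s = _valid_state()
        s.validate()
        bad = s.copy()
        bad.y[5] = 1.5
        with pytest.raises(ValueError):
            bad.validate()
        bad2 = s.copy()
        bad2.y[18] = -1e-6
        with pytest.raises(ValueError):
            bad2.validate()

    def test_block_factors_validated(self):
        with pytest.raises(ValueError):
            cp.BlockFactors(i_na=1.2).validate()
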