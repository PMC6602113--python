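"""Reaction-network derivatives, integration, and conservation ledgers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from opfkin import (
    AssayConditions,
    Injection,
    RateConstants,
    StateVector,
    derivatives,
    electron_balance,
    simulate,
)
from opfkin.model import SPECIES, _IDX
from opfkin.synth import dtt_assay_conditions, gsh_assay_conditions
from opfkin.traces import strip_baseline, windowed_rate

from conftest import ORACLE_SPECIES, oracle_integrate


class TestDerivatives:
    def test_equilibrium_state_has_zero_derivatives(self, default_constants):
        """Air-saturated buffer with no enzymes or reductant is a fixed point."""
        state = StateVector(O2=default_constants.o2_sat)
        d = derivatives(state, default_constants, diffusion_on=True)
        assert np.all(d == 0.0)

    def test_single_reaction_mass_action_rate(self, default_constants):
        """Only oxidized Pdi1p + GSH present: the glutathionylation step alone fires."""
        state = StateVector(PDI_ox=5.0, GSH=40000.0)
        d = derivatives(state, default_constants)
        v = default_constants.kg * 5.0 * 40000.0
        assert d[_IDX["PDI_mix"]] == pytest.approx(v, rel=1e-12)
        assert d[_IDX["GSH"]] == pytest.approx(-v, rel=1e-12)
        for ero in ("ERO_rr", "ERO_r1", "ERO_act_ox", "ERO_act_red"):
            assert d[_IDX[ero]] == 0.0

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.0, 1e4), min_size=len(SPECIES), max_size=len(SPECIES)))
    def test_enzyme_pools_are_stoichiometrically_closed(self, values):
        """Pdi1p and Ero1p state changes sum to zero for any non-negative state."""
        d = derivatives(np.array(values), RateConstants(), diffusion_on=True)
        pdi = sum(d[_IDX[s]] for s in ("PDI_ox", "PDI_mix", "PDI_red"))
        ero = sum(d[_IDX[s]] for s in ("ERO_rr", "ERO_r1", "ERO_act_ox", "ERO_act_red"))
        scale = max(1.0, np.max(np.abs(d)))
        assert abs(pdi) <= 1e-9 * scale
        assert abs(ero) <= 1e-9 * scale

    def test_negative_concentration_rejected(self, default_constants):
        y = np.zeros(len(SPECIES))
        y[_IDX["GSH"]] = -1.0
        with pytest.raises(ValueError, match="negative"):
            derivatives(y, default_constants)


class TestSimulate:
    def test_no_reductant_keeps_o2_at_saturation(self, default_constants):
        conditions = AssayConditions(
            initial=StateVector(O2=default_constants.o2_sat, PDI_ox=5.0, ERO_rr=1.0),
            duration=300.0,
        )
        traj = simulate(conditions, default_constants)
        assert np.allclose(traj.species("O2"), default_constants.o2_sat, atol=1e-6)

    def test_conservation_of_enzyme_and_glutathione_totals(self, default_constants):
        conditions = gsh_assay_conditions(pdi_uM=5.0, ero_uM=1.0, duration=600.0)
        traj = simulate(conditions, default_constants)
        after = traj.t > 100.0
        pdi = traj.species("PDI_ox") + traj.species("PDI_mix") + traj.species("PDI_red")
        ero = (traj.species("ERO_rr") + traj.species("ERO_r1")
               + traj.species("ERO_act_ox") + traj.species("ERO_act_red"))
        gmoi = traj.species("GSH") + traj.species("PDI_mix") + 2 * traj.species("GSSG")
        assert np.allclose(pdi, 5.0, rtol=1e-9)
        assert np.allclose(ero[after], 1.0, rtol=1e-9)
        assert np.allclose(ero[~after], 0.0, atol=1e-12)
        assert np.allclose(gmoi, 40000.0, rtol=1e-9)

    def test_matches_independent_fixed_step_integrator(self, default_constants):
        """60-s GSH run cross-checked against a hand-wired RK4 oracle."""
        conditions = AssayConditions(
            initial=StateVector(O2=258.0, GSH=4000.0, PDI_ox=2.0, ERO_rr=0.5),
            duration=60.0,
            sample_interval=1.0,
        )
        traj = simulate(conditions, default_constants)
        assert tuple(SPECIES) == ORACLE_SPECIES
        ref = oracle_integrate(
            conditions.initial.as_array(), default_constants, 60.0,
            h=0.005, record_at=[20.0, 40.0, 60.0],
        )
        for tt, y_ref in ref.items():
            i = int(np.argmin(np.abs(traj.t - tt)))
            scale = np.maximum(np.abs(y_ref), 1e-3)
            assert np.all(np.abs(traj.y[i] - y_ref) / scale <= 1e-6)

    def test_dtt_oracle_equivalence(self, default_constants):
        conditions = AssayConditions(
            initial=StateVector(O2=258.0, ERO_rr=1.0, DTT_red=2000.0),
            duration=60.0,
        )
        traj = simulate(conditions, default_constants)
        ref = oracle_integrate(
            conditions.initial.as_array(), default_constants, 60.0,
            h=0.005, record_at=[60.0],
        )
        y_ref = ref[60.0]
        scale = np.maximum(np.abs(y_ref), 1e-3)
        assert np.all(np.abs(traj.y[-1] - y_ref) / scale <= 1e-6)

    def test_o2_nonincreasing_closed_cell(self, default_constants):
        conditions = gsh_assay_conditions(pdi_uM=5.0, ero_uM=1.0, duration=600.0)
        conditions.diffusion_on = False
        traj = simulate(conditions, default_constants)
        assert np.all(np.diff(traj.species("O2")) <= 1e-9)

    def test_injected_ero_total_conserved_from_injection_on(self, default_constants):
        conditions = gsh_assay_conditions(pdi_uM=10.0, ero_uM=2.0, duration=400.0)
        traj = simulate(conditions, default_constants)
        ero = (traj.species("ERO_rr") + traj.species("ERO_r1")
               + traj.species("ERO_act_ox") + traj.species("ERO_act_red"))
        assert np.allclose(ero[traj.t > 100.0], 2.0, rtol=1e-9)

    def test_rate_profile_shows_lag_single_maximum_decline(self, default_constants):
        """Coupled assay: windowed rate rises from ~0, peaks once, then declines."""
        traj = simulate(gsh_assay_conditions(5.0, 1.0), default_constants)
        rs = windowed_rate(strip_baseline(traj.o2_trace(), 100.0), 10.0)
        i_max = int(np.argmax(rs.rate))
        assert rs.rate[0] < 0.1 * rs.rate[i_max]  # lag phase
        assert 50.0 < rs.t[i_max] < 800.0
        assert rs.rate[-1] < 0.5 * rs.rate[i_max]  # decline
        # single broad maximum: rises (noisy-free monotone) before, falls after
        assert np.all(np.diff(rs.rate[: i_max + 1]) > -1e-9)

    def test_instant_activation_removes_lag(self, default_constants):
        """Fast regulatory-disulfide reduction moves the rate maximum earlier."""
        slow = simulate(gsh_assay_conditions(5.0, 1.0), default_constants)
        fast_k = default_constants.with_values(ka1=10.0, ka2=10.0)
        fast = simulate(gsh_assay_conditions(5.0, 1.0), fast_k)

        def t_max(traj):
            rs = windowed_rate(strip_baseline(traj.o2_trace(), 100.0), 10.0)
            return rs.t[int(np.argmax(rs.rate))]

        assert t_max(fast) < t_max(slow)

    def test_max_rate_monotone_in_enzyme_totals(self, default_constants):
        from opfkin import max_consumption_rate

        pdi_rates = [
            max_consumption_rate(simulate(gsh_assay_conditions(p, 1.0), default_constants).o2_trace())
            for p in (1.0, 5.0, 15.0)
        ]
        assert pdi_rates == sorted(pdi_rates)
        ero_rates = [
            max_consumption_rate(simulate(gsh_assay_conditions(5.0, e), default_constants).o2_trace())
            for e in (0.25, 1.0, 2.0)
        ]
        assert ero_rates == sorted(ero_rates)


class TestGshActivationSwitch:
    def test_direct_gsh_activation_enables_pdi_free_turnover(self, default_constants):
        """With no Pdi1p, O2 is consumed only if GSH can reduce the regulatory
        disulfides directly (and the active site still needs Pdi1p or DTT, so
        flux stays zero unless DTT is present)."""
        base = dict(initial=StateVector(O2=258.0, GSH=40000.0, ERO_rr=1.0, DTT_red=100.0),
                    duration=300.0)
        off = AssayConditions(**base)
        on = AssayConditions(**base, gsh_activation=True, gsh_activation_rate=1e-4)
        o2_off = simulate(off, default_constants).species("O2")[-1]
        o2_on = simulate(on, default_constants).species("O2")[-1]
        assert o2_on < o2_off - 1.0
        # glutathione-moiety and electron ledgers still close with the switch on
        traj = simulate(on, default_constants)
        assert electron_balance(traj) <= 1e-6 * 40000.0


class TestElectronBalance:
    def test_simulated_trajectory_balances(self, default_constants):
        traj = simulate(gsh_assay_conditions(5.0, 1.0, duration=600.0), default_constants)
        assert electron_balance(traj) <= 1e-6 * 40000.0

    def test_corrupted_trajectory_detected(self, default_constants):
        traj = simulate(gsh_assay_conditions(5.0, 1.0, duration=300.0), default_constants)
        traj.y[150, _IDX["GSSG"]] += 1.0
        assert electron_balance(traj) >= 1.0

    def test_dtt_run_end_point_matches_hand_ledger(self, default_constants):
        traj = simulate(dtt_assay_conditions(duration=300.0), default_constants)
        end = traj.state_at(-1)
        hand = (
            end.GSH + end.PDI_mix
            + 2 * (end.PDI_red + end.DTT_red)
            + 2 * (end.ERO_r1 + 2 * end.ERO_act_ox + 3 * end.ERO_act_red)
            + 2 * end.H2O2
        )
        start = traj.state_at(0)
        hand0 = (
            start.GSH + start.PDI_mix
            + 2 * (start.PDI_red + start.DTT_red)
            + 2 * (start.ERO_r1 + 2 * start.ERO_act_ox + 3 * start.ERO_act_red)
            + 2 * start.H2O2
        )
        # DTT enters by injection at 100 s: add its 2 thiol-equivalents per μM
        injected = 2 * sum(
            inj.increments.get("DTT_red", 0.0) for inj in traj.conditions.injections
        )
        assert hand == pytest.approx(hand0 + injected, abs=1e-5)


class TestValidation:
    def test_injection_outside_duration_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            AssayConditions(
                initial=StateVector(O2=258.0),
                injections=(Injection(1000.0, {"ERO_rr": 1.0}),),
                duration=600.0,
            )

    def test_unknown_injection_species_rejected(self):
        with pytest.raises(ValueError, match="unknown species"):
            Injection(100.0, {"XYZ": 1.0})

    def test_negative_rate_constant_rejected(self):
        with pytest.raises(ValueError, match="kox"):
            RateConstants(kox=-1.0)
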