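"""Unit and property tests for the core NF-κB ODE model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nfkb_crosstalk import (SPECIES, ConfigError, StimulusSpec,
                            ValidationError, build_parameters,
                            canonical_parameters, derivatives,
                            inhibitor_composition, rk4_simulate, simulate,
                            steady_state)
from nfkb_crosstalk.model import (REL_POOLS, closed_test_parameters,
                                  state_array, zero_state)

IDX = {name: i for i, name in enumerate(SPECIES)}


class TestBuildParameters:
    def test_empty_config_gives_canonical_defaults(self):
        p = build_parameters({})
        assert p == canonical_parameters()
        assert p.b == 0.0005

    def test_basal_fraction_override(self):
        assert build_parameters({"b": 0.005}).b == 0.005

    def test_namespaced_keys_flat_and_nested(self):
        flat = build_parameters({"kb.IkBd.C": 0.4})
        nested = build_parameters({"kb": {"IkBd": {"C": 0.4}}})
        assert flat.kb_Id_C == nested.kb_Id_C == 0.4

    def test_affinity_ordering_violation_rejected(self):
        with pytest.raises(ValidationError):
            build_parameters({"kb.IkBd.A": 10.0, "kb.IkBd.C": 1.0})

    def test_unknown_key_names_the_key(self):
        with pytest.raises(ConfigError, match="k_bogus"):
            build_parameters({"k_bogus": 1.0})

    def test_negative_rate_rejected(self):
        with pytest.raises(ValidationError):
            build_parameters({"k_syn_A": -1.0})


class TestDerivatives:
    def test_empty_system_without_synthesis_is_fixed_point(self):
        p = build_parameters({"k_syn_A": 0, "k_syn_C": 0, "k_syn_RelB": 0,
                              "k_syn_NIK": 0, "k0_Ia": 0, "k0_Ie": 0,
                              "k0_p100": 0})
        d = derivatives(zero_state(), p)
        assert np.all(d == 0)

    def test_nik_processing_releases_sequestered_crel(self):
        state = zero_state()
        state[IDX["Id_C"]] = 5.0
        state[IDX["NIK"]] = 1.0
        d = derivatives(state, canonical_parameters())
        assert d[IDX["Id_C"]] < 0
        assert d[IDX["C_cyt"]] > 0

    def test_closed_mode_rates_conserve_each_rel_pool(self, rng):
        closed = closed_test_parameters(canonical_parameters())
        state = rng.uniform(0.0, 10.0, size=len(SPECIES))
        d = derivatives(state, closed, StimulusSpec(cd40_on=True), t=37.0)
        for pool in REL_POOLS.values():
            assert abs(sum(d[IDX[s]] for s in pool)) < 1e-12


class TestSimulate:
    def test_first_state_is_the_initial_state(self, params_low, ss_low):
        traj = simulate(params_low, ss_low, duration=10.0)
        assert np.array_equal(traj.states[0], ss_low)
        assert traj.times[0] == 0.0

    def test_output_grid_is_dense_and_even(self, params_low, ss_low):
        traj = simulate(params_low, ss_low, duration=1440.0)
        assert len(traj.times) >= 97
        assert np.allclose(np.diff(traj.times), traj.times[1] - traj.times[0])

    def test_cd40_induces_relb_without_rela(self, traj_low_cd40):
        b = traj_low_cd40["B_nuc"]
        a = traj_low_cd40["A_nuc"]
        assert b[-1] / b[0] > 2.0
        assert 0.8 <= a[-1] / a[0] <= 1.2

    def test_adaptive_solution_matches_rk4_oracle(self, params_high, ss_high):
        # fixed-step RK4 at dt=0.01 min is the brute-force oracle; a 120-min
        # CD40 window keeps it fast while exercising all stiff terms
        stim = StimulusSpec(cd40_on=True)
        ad = simulate(params_high, ss_high, 120.0, stim)
        rk = rk4_simulate(params_high, ss_high, 120.0, stim, dt=0.01)
        scale = np.maximum(np.abs(ad.states), 1e-6 * np.max(ad.states))
        assert np.max(np.abs(ad.states - rk.states) / scale) < 1e-5

    def test_conservation_along_closed_trajectory(self, params_high, ss_high):
        closed = closed_test_parameters(params_high)
        traj = simulate(closed, ss_high, 1440.0, StimulusSpec(cd40_on=True))
        for pool in REL_POOLS.values():
            total = sum(traj[s] for s in pool)
            assert np.max(np.abs(total - total[0])) / total[0] < 1e-8

    def test_non_negative_output(self, params_low):
        traj = simulate(params_low, zero_state() + 1e-3, duration=1440.0)
        assert np.all(traj.states >= 0)

    def test_zero_duration_rejected(self, params_low, ss_low):
        with pytest.raises(ValidationError):
            simulate(params_low, ss_low, duration=0.0)


class TestSteadyState:
    def test_zero_synthesis_zero_initial_stays_zero(self):
        p = build_parameters({"k_syn_A": 0, "k_syn_C": 0, "k_syn_RelB": 0,
                              "k_syn_NIK": 0, "k0_Ia": 0, "k0_Ie": 0,
                              "k0_p100": 0})
        assert np.allclose(steady_state(p), 0.0, atol=1e-12)

    def test_high_basal_elevates_nuclear_rela(self, ss_low, ss_high):
        assert ss_high[IDX["A_nuc"]] > ss_low[IDX["A_nuc"]]

    def test_idempotent(self, params_low, ss_low):
        again = steady_state(params_low, initial=ss_low, t_max=100.0)
        assert np.allclose(again, ss_low, rtol=1e-9, atol=1e-12)

    def test_residual_is_small(self, params_high, ss_high):
        d = derivatives(ss_high, params_high)
        assert np.max(np.abs(d)) < 1e-10 * np.max(ss_high)

    def test_unstimulated_resimulation_is_stable(self, params_low, ss_low):
        traj = simulate(params_low, ss_low, duration=1440.0)
        drift = np.max(np.abs(traj.states - ss_low[None, :])) / np.max(ss_low)
        assert drift < 1e-6


class TestInhibitorComposition:
    def test_pure_ikbd_pool(self):
        state = zero_state()
        state[IDX["Id_C"]] = 5.0
        comp = inhibitor_composition(state, "C")
        assert comp.f_IkBd == 1.0
        assert comp.f_IkBa == comp.f_IkBe == 0.0
        assert comp.defined

    def test_high_basal_crel_mostly_ikbd_bound(self, ss_high):
        comp = inhibitor_composition(ss_high, "C")
        assert comp.f_IkBa + comp.f_IkBe <= 0.14

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(0.0, 100.0), min_size=16, max_size=16))
    def test_fractions_sum_to_one_whenever_pool_nonempty(self, values):
        state = state_array(values)
        for dimer in ("A", "C"):
            comp = inhibitor_composition(state, dimer)
            if comp.bound_total > 0:
                assert comp.f_IkBa + comp.f_IkBe + comp.f_IkBd == \
                    pytest.approx(1.0, abs=1e-9)
            else:
                assert not comp.defined
                assert comp.f_IkBa == comp.f_IkBe == comp.f_IkBd == 0.0

    def test_unknown_dimer_rejected(self, ss_low):
        with pytest.raises(ValidationError):
            inhibitor_composition(ss_low, "B")
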