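import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cd4sim.agefun import (AGE, AGE_PLUS_FEEDBACK, STATIC, AgeModulationSet,
                           BodyConstants, Modulation, blood_volume,
                           default_modulations, effective_parameters,
                           feedback_naive_prolif, feedback_rte_death,
                           hill_down, hill_up, thymus_capacity,
                           thymus_wet_weight)
from cd4sim.parameters import KineticParameterSet


class TestHillForms:
    def test_anchors(self):
        assert hill_up(0.0, 2.0, 1.5, 50.0, 3.0) == 2.0
        assert hill_up(50.0, 2.0, 1.5, 50.0, 3.0) == pytest.approx(2.0 * 1.75)
        assert hill_up(1e6, 2.0, 1.5, 50.0, 3.0) == pytest.approx(
            2.0 * 2.5, rel=1e-6)
        assert hill_down(0.0, 2.0, 1.0, 50.0, 1.0) == 2.0
        assert hill_down(50.0, 2.0, 0.8, 50.0, 1.0) == pytest.approx(
            2.0 * 0.6)
        assert hill_down(1e9, 2.0, 1.0, 50.0, 1.0) == pytest.approx(
            0.0, abs=1e-6)

    def test_validation(self):
        with pytest.raises(ValueError):
            hill_up(1.0, 1.0, 1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            hill_down(1.0, 1.0, 1.5, 50.0, 1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(age=st.floats(0, 120), h=st.floats(1, 10),
           age50=st.floats(1, 100), amax=st.floats(0, 5))
    def test_up_bounded_and_monotone(self, age, h, age50, amax):
        v = hill_up(age, 1.0, amax, age50, h)
        assert 1.0 <= v <= 1.0 + amax + 1e-12
        assert hill_up(age + 1.0, 1.0, amax, age50, h) >= v - 1e-12


class TestPhysiology:
    def test_blood_volume_anchors(self):
        assert blood_volume(0.0) == pytest.approx(5.0 * 3.5 / 70.0, rel=1e-9)
        assert blood_volume(90.0) == pytest.approx(5.0, rel=1e-3)

    def test_blood_volume_monotone(self):
        ages = np.linspace(0, 90, 400)
        bv = np.array([blood_volume(a) for a in ages])
        assert np.all(np.diff(bv) >= 0)

    def test_wet_weight_peaks_early_with_stated_constants(self):
        c = BodyConstants(wet_weight_tau_g=0.5, wet_weight_gain=1.5,
                          involution_rate=0.044)
        ages = np.linspace(0, 20, 4001)
        w = np.array([thymus_wet_weight(a, c) for a in ages])
        assert 0.5 <= ages[np.argmax(w)] <= 2.5

    def test_capacity_no_involution_plateau(self):
        c = BodyConstants(involution_rate=0.0)
        tc_inf, _ = thymus_capacity(1e6, c)
        assert tc_inf == pytest.approx(
            c.cortical_capacity_birth * (1 + c.wet_weight_gain), rel=1e-6)

    def test_capacity_involution_monotone(self):
        assert thymus_capacity(80.0)[0] < thymus_capacity(20.0)[0]
        assert all(v > 0 for v in thymus_capacity(120.0))


class TestFeedback:
    def test_naive_prolif_anchors(self):
        base = 0.0012
        assert feedback_naive_prolif(0.0, base, 0.4167, 60.0) == base
        assert feedback_naive_prolif(60.0, base, 0.4167, 60.0) == \
            pytest.approx(base * (1 - 0.4167 / 2))

    def test_naive_prolif_ratio_across_transition(self):
        # old-age (low RTE) over young-adult (high RTE) rate ratio ~ 1.7
        fb = default_modulations().feedback
        lam_old = feedback_naive_prolif(5.0, fb.lamN4_base, fb.lamN4_max,
                                        fb.lamN4_c50, fb.lamN4_hill)
        lam_young = feedback_naive_prolif(400.0, fb.lamN4_base, fb.lamN4_max,
                                          fb.lamN4_c50, fb.lamN4_hill)
        assert lam_old / lam_young == pytest.approx(0.0012 / 0.0007, rel=0.02)

    def test_rte_death_anchors_and_monotone(self):
        base = 0.003
        assert feedback_rte_death(0.0, base, 1.5, 60.0) == base
        assert feedback_rte_death(60.0, base, 1.5, 60.0) == \
            pytest.approx(base * 1.75)
        grid = np.linspace(0, 500, 100)
        vals = [feedback_rte_death(c, base, 1.5, 60.0) for c in grid]
        assert np.all(np.diff(vals) > 0)

    def test_naive_prolif_non_increasing(self):
        grid = np.linspace(0, 500, 100)
        vals = [feedback_naive_prolif(c, 0.0012, 0.4, 60.0) for c in grid]
        assert np.all(np.diff(vals) <= 0)


class TestEffectiveParameters:
    def test_static_leaves_rates_at_base(self, params, mod_static):
        eff = effective_parameters(75.0, 3.0, params, mod_static)
        assert eff.lamA4 == 1.725
        for name, v in params.to_dict().items():
            assert getattr(eff, name) == v

    def test_age_variant_at_age_zero_equals_base(self, params, mod_age):
        eff = effective_parameters(0.0, 0.0, params, mod_age)
        for name, v in params.to_dict().items():
            assert getattr(eff, name) == pytest.approx(v, rel=1e-12)

    def test_age_modulation_inventory(self, mod_age):
        ups = {m.target for m in mod_age.modulations if m.direction == "up"}
        downs = {m.target for m in mod_age.modulations
                 if m.direction == "down"}
        assert ups == {"lamN4", "lamA4", "omegaEM4lung_bl",
                       "omegaEFF4bl_git", "omegaEFF4bl_lung",
                       "omegaEFF4bl_tis"}
        assert downs == {"muRTE4", "omegaRTE4bl_lt", "phiCM4", "phiEM4",
                         "omegaA4lt_bl", "omegaCM4lt_bl", "omegaEFF4lt_bl"}
        dmax_one = {m.target for m in mod_age.modulations
                    if m.direction == "down" and m.max_change == 1.0}
        assert dmax_one == {"omegaRTE4bl_lt", "phiCM4", "phiEM4",
                            "omegaA4lt_bl", "omegaCM4lt_bl",
                            "omegaEFF4lt_bl"}
        hills = {m.target: m.hill for m in mod_age.modulations}
        assert hills["lamN4"] == 10.0 and hills["phiCM4"] == 3.0

    def test_feedback_variant_replaces_two_age_functions(self, mod_fb):
        active = {m.target for m in mod_fb.active_modulations()}
        assert "lamN4" not in active and "muRTE4" not in active
        assert len(active) == 11
        assert mod_fb.feedback.lamN4_hill == 10.0
        assert mod_fb.feedback.muRTE4_hill == 10.0

    def test_feedback_at_zero_concentration_gives_base_rates(
            self, params, mod_fb, mod_age):
        eff = effective_parameters(30.0, 0.0, params, mod_fb)
        assert eff.lamN4 == mod_fb.feedback.lamN4_base
        assert eff.muRTE4 == mod_fb.feedback.muRTE4_base
        eff_age = effective_parameters(30.0, 0.0, params, mod_age)
        for m in mod_fb.active_modulations():
            assert getattr(eff, m.target) == pytest.approx(
                getattr(eff_age, m.target), rel=1e-12)

    def test_zero_amplitude_age_variant_reproduces_static(self, params):
        mods = tuple(
            Modulation(m.target, m.direction, 0.0, m.half_effect, m.hill)
            for m in default_modulations(AGE).modulations)
        zero = AgeModulationSet(variant=AGE, modulations=mods)
        static = default_modulations(STATIC)
        for age in (0.0, 33.0, 90.0):
            e1 = effective_parameters(age, 0.0, params, zero)
            e2 = effective_parameters(age, 0.0, params, static)
            for name in params.to_dict():
                assert getattr(e1, name) == getattr(e2, name)

    def test_shared_age50_group_members_shift_together(self, mod_age):
        group = [m for m in mod_age.modulations if m.group == "late"]
        assert len(group) == 5
        assert len({m.half_effect for m in group}) == 1

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(age=st.floats(0, 120), c=st.floats(0, 1e4))
    def test_effective_rates_never_negative(self, age, c):
        params = KineticParameterSet()
        eff = effective_parameters(age, c, params, default_modulations())
        assert all(v >= 0 for v in eff.values.values())
        assert eff.Tcortmax > 0 and eff.BV > 0

    def test_unknown_modulation_target_rejected(self, params):
        bad = AgeModulationSet(
            variant=AGE,
            modulations=(Modulation("nonexistent", "up", 1.0, 10.0),))
        with pytest.raises(ValueError, match="unknown parameter"):
            effective_parameters(10.0, 0.0, params, bad)
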