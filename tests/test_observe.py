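import numpy as np
import pandas as pd
import pytest

from cd4sim import layout as L
from cd4sim.agefun import blood_volume
from cd4sim.model import simulate_trajectory
from cd4sim.observe import (CALIBRATION_OBSERVABLES, CalibrationDataset,
                            FitResult, aic, aic_compare,
                            observables_from_state, percent_difference,
                            proportional_loglik, reference_cd4_counts,
                            rse_estimate)


class TestObservables:
    def test_blood_concentration_arithmetic(self):
        y = np.zeros(24)
        y[L.I_N_BL] = 5.0e9
        obs = observables_from_state(y, 5.0)
        assert obs["BL_N_conc"] == pytest.approx(1000.0)

    def test_equal_lymphoid_counts_give_equal_percentages(self):
        y = np.zeros(24)
        for sub in ("RTE", "N", "A", "CM", "EM", "EFF"):
            y[L.LAYOUT.idx(sub, "LT")] = 7.0e8
        obs = observables_from_state(y, 1.0)
        for sub in ("RTE", "N", "A", "CM", "EM", "EFF"):
            assert obs[f"LT_{sub}_pct"] == pytest.approx(100.0 / 6.0)

    def test_memory_total_is_cm_plus_em(self, newborn_ss):
        obs = observables_from_state(newborn_ss, 0.25)
        assert obs["BL_memory_conc"] == pytest.approx(
            obs["BL_CM_conc"] + obs["BL_EM_conc"])
        assert obs["BL_total_conc"] == pytest.approx(
            sum(obs[f"BL_{s}_conc"] for s in ("RTE", "N", "A",
                                              "CM", "EM", "EFF")))

    def test_degenerate_compartment_flagged(self):
        obs = observables_from_state(np.zeros(24), 1.0)
        assert set(obs.attrs["degenerate_compartments"]) == {"LT", "GIT",
                                                             "LUNG"}
        assert obs["GIT_N_pct"] == 0.0

    def test_nonpositive_blood_volume_rejected(self):
        with pytest.raises(ValueError):
            observables_from_state(np.zeros(24), 0.0)

    def test_percentages_normalized_along_lifetime(self, params, mod_fb,
                                                   newborn_ss):
        t = np.linspace(0, 80 * 365.25, 60)
        traj = simulate_trajectory(newborn_ss, params, mod_fb, t)
        for i in range(0, 60, 7):
            obs = observables_from_state(traj.states[i],
                                         blood_volume(traj.age_years[i]))
            for comp, subs in (("LT", 6), ("GIT", 4), ("LUNG", 4)):
                tot = sum(obs[k] for k in obs.index
                          if k.startswith(comp) and k.endswith("_pct")
                          and "memory" not in k)
                assert tot == pytest.approx(100.0, abs=1e-9)


class TestReferenceArithmetic:
    @pytest.mark.parametrize("total,ratio,expected", [
        (8.0e9, 2.0, 16.0e9 / 3.0),
        (1.7e10, 1.0, 8.5e9),
        (3.6e11, 2.0, 2.4e11),
    ])
    def test_cd4_share_of_total_t(self, total, ratio, expected):
        assert reference_cd4_counts(total, ratio) == pytest.approx(expected)

    def test_limits_and_identities(self):
        assert reference_cd4_counts(1.0e10, 1.0) == 5.0e9
        assert reference_cd4_counts(1.0e10, 1e12) == pytest.approx(
            1.0e10, rel=1e-9)
        with pytest.raises(ValueError):
            reference_cd4_counts(1.0, 0.0)

    @pytest.mark.parametrize("pred,obs,expected", [
        (5.09e9, 5.3e9, 4.0),
        (4.14e9, 6.5e9, 36.0),
        (7.0, 7.0, 0.0),
    ])
    def test_percent_difference(self, pred, obs, expected):
        assert round(percent_difference(pred, obs), 0) == pytest.approx(
            expected, abs=0.5)

    def test_percent_difference_requires_positive_reference(self):
        with pytest.raises(ValueError):
            percent_difference(1.0, 0.0)


def _single_row_dataset(obs, cv):
    return CalibrationDataset(pd.DataFrame([{
        "observable_id": "BL_N_conc", "compartment": "BL",
        "subpopulation": "N", "age_lo": 0.0, "age_hi": 0.5,
        "mean": obs, "ci_lo": obs * 0.9, "ci_hi": obs * 1.1,
        "cv": cv, "role": "calibration"}]))


class TestLikelihood:
    def test_hand_computed_single_row(self):
        ds = _single_row_dataset(110.0, 0.1)
        nll = proportional_loglik(np.array([100.0]), ds)
        assert nll == pytest.approx(0.5 * np.log(2 * np.pi * 100.0) + 0.5)

    def test_zero_residual_leaves_only_normalization(self):
        ds = _single_row_dataset(100.0, 0.2)
        nll = proportional_loglik(np.array([100.0]), ds)
        assert nll == pytest.approx(0.5 * np.log(2 * np.pi * 400.0))

    def test_doubling_cv_halves_quadratic_term(self):
        lo = _single_row_dataset(110.0, 0.1)
        hi = _single_row_dataset(110.0, 0.2)
        pred = np.array([100.0])
        quad = lambda ds, cv: (proportional_loglik(pred, ds)
                               - 0.5 * np.log(2 * np.pi * (cv * 100) ** 2))
        assert quad(hi, 0.2) < quad(lo, 0.1)

    def test_nll_improves_toward_observation(self, rng):
        ds = _single_row_dataset(90.0, 0.15)
        worse = proportional_loglik(np.array([140.0]), ds)
        better = proportional_loglik(np.array([100.0]), ds)
        assert better < worse

    def test_zero_prediction_with_observation_flagged_large(self):
        ds = _single_row_dataset(50.0, 0.1)
        assert proportional_loglik(np.array([0.0]), ds) >= 1e10


class TestModelSelection:
    def test_reference_aic_ordering(self):
        f1 = FitResult("AGE_PLUS_FEEDBACK", {"a": 1}, {}, nll=0,
                       aic=4753.23)
        f2 = FitResult("AGE", {"a": 1}, {}, nll=0, aic=4862.35)
        assert aic_compare([f2, f1]) is f1

    def test_aic_formula(self):
        assert aic(0.0, 1) == 2.0

    def test_tie_broken_by_fewer_parameters(self):
        small = FitResult("A", {f"p{i}": 1.0 for i in range(5)}, {},
                          nll=0, aic=100.0)
        big = FitResult("B", {f"p{i}": 1.0 for i in range(7)}, {},
                        nll=0, aic=100.0)
        assert aic_compare([big, small]) is small

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            aic_compare([])


class TestRse:
    def test_quadratic_toy_gives_analytic_se(self):
        nll = lambda th: 0.5 * ((th[0] - 2.0) / 0.5) ** 2
        rse, flagged = rse_estimate(nll, np.array([2.0]), ["theta"])
        assert rse["theta"] == pytest.approx(25.0, rel=1e-3)
        assert flagged == []

    def test_threshold_flags_unidentifiable(self):
        # SE chosen so that RSE just exceeds 51%
        se = 0.52 * 2.0
        nll = lambda th: 0.5 * ((th[0] - 2.0) / se) ** 2
        rse, flagged = rse_estimate(nll, np.array([2.0]), ["theta"])
        assert rse["theta"] > 51.0
        assert flagged == ["theta"]

    def test_flat_direction_flagged_singular(self):
        nll = lambda th: 0.5 * (th[0] - 1.0) ** 2  # th[1] unused
        rse, flagged = rse_estimate(nll, np.array([1.0, 3.0]), ["a", "b"])
        assert "b" in flagged


class TestCiOverlap:
    def test_overlap_and_limit_rules(self):
        from cd4sim.observe import ci_overlap_score
        obs = pd.DataFrame({"ci_lo": [10.0, 100.0, 10.0],
                            "ci_hi": [20.0, 102.0, 20.0]})
        pred = pd.DataFrame({
            "ci_lo": [15.0,    # overlaps
                      103.0,   # no overlap, both limits within 30% -> counts
                      40.0],   # far off
            "ci_hi": [25.0, 130.0, 60.0]})
        assert ci_overlap_score(obs, pred) == pytest.approx(200.0 / 3.0)


class TestDataset:
    def test_cv_from_ci(self):
        cv = CalibrationDataset.cv_from_ci(100.0, 119.6)
        assert cv == pytest.approx(0.1)

    def test_invalid_interval_rejected(self):
        df = _single_row_dataset(100.0, 0.1).table.copy()
        df.loc[0, "ci_hi"] = 90.0
        with pytest.raises(ValueError, match="bracket"):
            CalibrationDataset(df)

    def test_round_trip_csv(self, tmp_path):
        ds = _single_row_dataset(100.0, 0.1)
        path = tmp_path / "ds.csv"
        ds.to_csv(path)
        back = CalibrationDataset.from_csv(path)
        pd.testing.assert_frame_equal(ds.table, back.table)
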