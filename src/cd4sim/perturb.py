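"""Homeostasis perturbations: thymectomy and adaptation knockouts.

Complete thymectomy is simulated by initializing the model at the healthy
steady state for the age at surgery, then clamping the SP4 thymocyte pool
(and hence thymic egress) to zero for all later times.  A paired healthy
trajectory from the same initial state serves as the reference.

Adaptation knockouts probe the two RTE-concentration feedbacks: each
knocked-out feedback is replaced by the constant rate the full model
exhibits at the healthy newborn operating point, so differences between
scenarios isolate the adaptive response rather than baseline shifts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .agefun import (AGE_PLUS_FEEDBACK, AgeModulationSet, blood_volume,
                     feedback_naive_prolif, feedback_rte_death)
from .layout import DAYS_PER_YEAR, I_RTE_BL, I_SP4, LAYOUT
from .model import (StateVector, Trajectory, simulate_trajectory,
                    steady_state_direct)
from .observe import observables_from_state
from .parameters import KineticParameterSet

#: age-at-surgery groups (label, lo_years, hi_years)
THYMECTOMY_GROUPS: tuple[tuple[str, float, float], ...] = (
    ("0-1mo", 0.0, 1.0 / 12.0),
    ("1-2mo", 1.0 / 12.0, 2.0 / 12.0),
    ("2mo-1y", 2.0 / 12.0, 1.0),
    ("1-1.5y", 1.0, 1.5),
    ("1.5-3y", 1.5, 3.0),
    (">3y", 3.0, math.inf),
)


def group_for_age(age_at_surgery: float) -> str:
    if age_at_surgery < 0:
        raise ValueError("age at surgery must be non-negative")
    for label, lo, hi in THYMECTOMY_GROUPS:
        if lo <= age_at_surgery < hi:
            return label
    return THYMECTOMY_GROUPS[-1][0]


@dataclass
class ThymectomyScenario:
    age_at_surgery: float
    observation_ages: tuple[float, ...]
    group: str = ""
    pre_surgery_observed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = group_for_age(self.age_at_surgery)
        if not self.group:
            self.group = expected
        elif self.group != expected:
            raise ValueError(
                f"group {self.group!r} inconsistent with surgery age "
                f"{self.age_at_surgery} (expected {expected!r})")
        if any(a < self.age_at_surgery for a in self.observation_ages):
            raise ValueError("observation ages must follow surgery")


@dataclass
class ThymectomyResult:
    scenario: ThymectomyScenario
    thymectomized: Trajectory
    healthy: Trajectory

    def observables(self, which: str = "thymectomized"):
        import pandas as pd
        traj = getattr(self, which)
        rows = []
        for i, t in enumerate(traj.t_days):
            age = traj.age0_years + t / DAYS_PER_YEAR
            obs = observables_from_state(traj.states[i], blood_volume(age))
            rows.append(pd.Series(obs, name=age))
        df = pd.DataFrame(rows)
        df.index.name = "age_years"
        return df


def simulate_thymectomy(scenario: ThymectomyScenario,
                        params: KineticParameterSet,
                        modulation: AgeModulationSet,
                        *, n_points: int = 120,
                        initial: np.ndarray | None = None) -> ThymectomyResult:
    """Paired thymectomized / healthy simulation from the surgery-age
    steady state to the last observation age."""
    a0 = scenario.age_at_surgery
    y0 = (steady_state_direct(params, modulation, a0)
          if initial is None else np.asarray(initial, float))
    horizon = (max(scenario.observation_ages) - a0) * DAYS_PER_YEAR
    t_grid = np.linspace(0.0, max(horizon, 1.0), n_points)
    y_thx = y0.copy()
    y_thx[I_SP4] = 0.0
    thx = simulate_trajectory(y_thx, params, modulation, t_grid,
                              age0=a0, clamp_sp4=True)
    healthy = simulate_trajectory(y0, params, modulation, t_grid, age0=a0)
    return ThymectomyResult(scenario, thx, healthy)


def baseline_correction(scenario: ThymectomyScenario,
                        predicted_state: np.ndarray,
                        bv_litres: float) -> np.ndarray:
    """Rescale a predicted pre-surgery state to observed blood values.

    Each subpopulation with an observed blood concentration
    (``BL_<SUB>_conc`` keys) is scaled — in every compartment — by its
    observed/predicted ratio; subpopulations without an observation are
    scaled by the total-CD4 ratio.
    """
    if not scenario.pre_surgery_observed:
        return np.asarray(predicted_state, float).copy()
    y = np.asarray(predicted_state, float).copy()
    obs = observables_from_state(y, bv_litres)
    ratios: dict[str, float] = {}
    for key, val in scenario.pre_surgery_observed.items():
        if not (key.startswith("BL_") and key.endswith("_conc")):
            raise ValueError(f"unsupported pre-surgery observable {key!r}")
        sub = key[3:-5]
        pred = obs[key]
        if pred <= 0:
            raise ValueError(f"predicted baseline for {key} is zero")
        if sub != "total":
            ratios[sub] = val / pred
    if "BL_total_conc" in scenario.pre_surgery_observed:
        total_ratio = (scenario.pre_surgery_observed["BL_total_conc"]
                       / obs["BL_total_conc"])
    elif ratios:
        total_ratio = float(np.mean(list(ratios.values())))
    else:
        total_ratio = 1.0
    for sub in ("RTE", "N", "A", "CM", "EM", "EFF"):
        r = ratios.get(sub, total_ratio)
        for comp in ("BL", "LT", "GIT", "LUNG"):
            if (sub, comp) in LAYOUT.index:
                y[LAYOUT.idx(sub, comp)] *= r
    return y


# ---------------------------------------------------------------------------
# adaptation knockouts
# ---------------------------------------------------------------------------

KNOCKOUT_MODES = ("none", "no_naive_prolif_adapt", "no_rte_death_adapt",
                  "neither")


def frozen_feedback_modulation(modulation: AgeModulationSet, mode: str,
                               params: KineticParameterSet,
                               freeze_at: str = "newborn_operating_point"
                               ) -> AgeModulationSet:
    """Replace knocked-out feedbacks by constants.

    ``newborn_operating_point`` freezes each knocked-out rate at the value
    the full model exhibits at the healthy newborn steady state;
    ``base`` freezes at the zero-concentration base rate instead.
    """
    if mode not in KNOCKOUT_MODES:
        raise ValueError(f"unknown knockout mode {mode!r}")
    if mode == "none":
        return modulation
    fb = modulation.feedback
    if freeze_at == "newborn_operating_point":
        y0 = steady_state_direct(params, modulation, 0.0)
        c0 = y0[I_RTE_BL] / (blood_volume(0.0, modulation.body) * 1.0e6)
        lam_frozen = feedback_naive_prolif(c0, fb.lamN4_base, fb.lamN4_max,
                                           fb.lamN4_c50, fb.lamN4_hill)
        mu_frozen = feedback_rte_death(c0, fb.muRTE4_base, fb.muRTE4_max,
                                       fb.muRTE4_c50, fb.muRTE4_hill)
    elif freeze_at == "base":
        lam_frozen, mu_frozen = fb.lamN4_base, fb.muRTE4_base
    else:
        raise ValueError(f"unknown freeze_at {freeze_at!r}")
    if mode in ("no_naive_prolif_adapt", "neither"):
        fb = replace(fb, lamN4_base=lam_frozen, lamN4_max=0.0)
    if mode in ("no_rte_death_adapt", "neither"):
        fb = replace(fb, muRTE4_base=mu_frozen, muRTE4_max=0.0)
    return replace(modulation, feedback=fb)


@dataclass
class KnockoutReport:
    mode: str
    freeze_at: str
    ages: tuple[float, ...]
    reduction_pct: dict[float, float]
    trajectory: Trajectory
    reference: Trajectory


def lymphoid_total(traj: Trajectory, age: float) -> float:
    """Total lymphoid-tissue CD4 count interpolated at an age (years)."""
    lt = [i for i in LAYOUT.compartment_states("LT")]
    totals = traj.states[:, lt].sum(axis=1)
    ages = traj.age_years
    if not (ages[0] <= age <= ages[-1]):
        raise ValueError(f"age {age} outside trajectory range")
    return float(np.interp(age, ages, totals))


def scenario_percent_reduction(traj_scenario: Trajectory,
                               traj_reference: Trajectory,
                               age: float) -> float:
    """100*(ref - scenario)/ref on the lymphoid-tissue total CD4 count."""
    a = lymphoid_total(traj_scenario, age)
    b = lymphoid_total(traj_reference, age)
    if b == 0:
        raise ValueError("reference trajectory is zero at this age")
    return 100.0 * (b - a) / b


def adaptation_knockout(mode: str,
                        params: KineticParameterSet,
                        modulation: AgeModulationSet,
                        ages: tuple[float, ...] = (20.0, 80.0),
                        *, freeze_at: str = "newborn_operating_point",
                        n_points: int = 160) -> KnockoutReport:
    """Simulate a lifetime with one or both RTE feedbacks disabled.

    Both the scenario and the full-model reference start from their own
    newborn steady states and are integrated over the whole age span; the
    report gives the percent reduction in lymphoid-organ CD4 count
    relative to the full model at each requested age.
    """
    if modulation.variant != AGE_PLUS_FEEDBACK:
        raise ValueError("knockouts require the feedback variant")
    horizon = max(ages) * DAYS_PER_YEAR
    t_grid = np.linspace(0.0, horizon, n_points)
    mod_ko = frozen_feedback_modulation(modulation, mode, params, freeze_at)
    y0_ref = steady_state_direct(params, modulation, 0.0)
    y0_ko = steady_state_direct(params, mod_ko, 0.0)
    ref = simulate_trajectory(y0_ref, params, modulation, t_grid, age0=0.0)
    traj = simulate_trajectory(y0_ko, params, mod_ko, t_grid, age0=0.0)
    red = {float(a): scenario_percent_reduction(traj, ref, float(a))
           for a in ages}
    return KnockoutReport(mode, freeze_at, tuple(float(a) for a in ages),
                          red, traj, ref)
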