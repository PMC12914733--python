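"""The 24-state ODE system: thymopoiesis plus peripheral CD4+ trafficking.

Thymus: DN and DP thymocytes grow logistically against the cortical niche
capacity, DP cells surviving selection split between the SP4 and SP8
lineages, SP cells grow logistically against the medullary capacity, and
SP4 cells egress into blood as recent thymic emigrants.  The zero state is
an (unstable) fixed point — the thymus has no external source term — so
simulations start from a small positive thymocyte seed.

Periphery: first-order mass-action kinetics.  RTE cells home from blood to
lymphoid tissue and mature there into naive cells; naive cells are
activated in lymphoid tissue; activated cells expand logistically against
a whole-body carrying capacity ``TA4max`` and differentiate into
central-memory (fraction ``f4``) and effector cells; CM -> EM -> EFF
differentiation proceeds in every organ where the source resides.  N and
CM recirculate between blood, lymphoid tissue, gut and lung; EM and EFF
lack the lymph-homing receptors and only exit lymphoid tissue; EFF cells
do not return from peripheral organs.  ``omega*bl_tis`` terms are
irreversible losses to unmodelled tissues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

from .agefun import (AGE_PLUS_FEEDBACK, AgeModulationSet, EffectiveRates,
                     blood_volume, effective_parameters)
from .layout import (DAYS_PER_YEAR, I_A_BL, I_A_LT, I_CM_BL, I_CM_GIT,
                     I_CM_LT, I_CM_LUNG, I_DN, I_DP, I_EFF_BL, I_EFF_GIT,
                     I_EFF_LT, I_EFF_LUNG, I_EM_BL, I_EM_GIT, I_EM_LT,
                     I_EM_LUNG, I_N_BL, I_N_GIT, I_N_LT, I_N_LUNG, I_RTE_BL,
                     I_RTE_LT, I_SP4, I_SP8, LAYOUT, N_STATES, STATE_LABELS)
from .parameters import KineticParameterSet


class StructuralError(ValueError):
    """State vector does not match the compartment layout."""


class ValidationError(ValueError):
    """An input violates a model precondition (e.g. a negative rate)."""


class IntegrationError(RuntimeError):
    """The ODE solver failed; carries the state and time of failure."""


class SteadyStateError(RuntimeError):
    """Equilibrium search did not converge; carries the final residual."""


@dataclass
class StateVector:
    """Cell counts for all 24 states with an age/time stamp."""

    counts: np.ndarray
    t_days: float = 0.0
    age0_years: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (N_STATES,):
            raise StructuralError(
                f"expected {N_STATES} states, got shape {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValidationError("cell counts must be non-negative")

    @property
    def age_years(self) -> float:
        return self.age0_years + self.t_days / DAYS_PER_YEAR

    def __getitem__(self, key: tuple[str, str]) -> float:
        return float(self.counts[LAYOUT.idx(*key)])


def full_rhs(y: np.ndarray, eff: EffectiveRates, *,
             clamp_sp4: bool = False, logistic_s: float | None = None,
             validate: bool = True) -> np.ndarray:
    """Time derivative (cells/day) of the full 24-state system.

    ``logistic_s`` optionally freezes the activated-cell logistic factor
    ``1 - (A_BL + A_LT)/TA4max`` at a fixed value; this makes the
    peripheral system exactly linear and is used by the direct
    steady-state solver.  ``clamp_sp4`` zeroes SP4 dynamics and egress
    (complete thymectomy).  A (24, k) batch of states evaluates all k
    columns at once.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (N_STATES,) and not (y.ndim == 2
                                       and y.shape[0] == N_STATES):
        raise StructuralError(f"expected {N_STATES} states, got {y.shape}")
    if validate:
        bad = [k for k, v in eff.values.items()
               if isinstance(v, float) and (not np.isfinite(v) or v < 0)]
        if bad:
            raise ValidationError(f"negative or non-finite rate(s): {bad}")
    p = eff
    d = np.zeros_like(y)

    DN, DP, SP4, SP8 = y[I_DN], y[I_DP], y[I_SP4], y[I_SP8]
    cort = 1.0 - (DN + DP) / p.Tcortmax
    med = 1.0 - (SP4 + SP8) / p.Tmedmax
    d[I_DN] = p.thy_lamDN * DN * cort - (p.thy_phiDN + p.thy_muDN) * DN
    d[I_DP] = (p.thy_lamDP * DP * cort + p.thy_phiDN * DN
               - (p.thy_phiDP + p.thy_muDP) * DP)
    d[I_SP4] = (p.thy_lamSP * SP4 * med + p.thy_fSP4 * p.thy_phiDP * DP
                - (p.thy_muSP + p.thy_epsSP4) * SP4)
    d[I_SP8] = (p.thy_lamSP * SP8 * med + (1.0 - p.thy_fSP4) * p.thy_phiDP * DP
                - (p.thy_muSP + p.thy_epsSP8) * SP8)
    egress = 0.0 if clamp_sp4 else p.thy_epsSP4 * SP4
    if clamp_sp4:
        d[I_SP4] = 0.0

    # --- RTE: blood <-> lymphoid tissue, maturation in LT ---
    rte_bl, rte_lt = y[I_RTE_BL], y[I_RTE_LT]
    d[I_RTE_BL] = egress - (p.omegaRTE4bl_lt + p.muRTE4) * rte_bl
    d[I_RTE_LT] = (p.omegaRTE4bl_lt * rte_bl
                   - (p.phiRTE4 + p.muRTE4) * rte_lt)

    # --- naive: homeostatic proliferation in the blood/lymphoid
    # recirculation pool (not in gut/lung, where the slow exit rates would
    # otherwise let proliferation outrun removal); activation in LT only
    n_bl, n_lt, n_git, n_lung = y[I_N_BL], y[I_N_LT], y[I_N_GIT], y[I_N_LUNG]
    d[I_N_BL] = ((p.lamN4 - p.muN4) * n_bl
                 + p.omegaN4lt_bl * n_lt
                 + p.omegaN4git_bl * n_git + p.omegaN4lung_bl * n_lung
                 - (p.omegaN4bl_lt + p.omegaN4bl_git + p.omegaN4bl_lung
                    + p.omegaN4bl_tis) * n_bl)
    d[I_N_LT] = (p.phiRTE4 * rte_lt
                 + (p.lamN4 - p.muN4 - p.phiN4) * n_lt
                 + p.omegaN4bl_lt * n_bl - p.omegaN4lt_bl * n_lt)
    d[I_N_GIT] = (-p.muN4 * n_git
                  + p.omegaN4bl_git * n_bl - p.omegaN4git_bl * n_git)
    d[I_N_LUNG] = (-p.muN4 * n_lung
                   + p.omegaN4bl_lung * n_bl - p.omegaN4lung_bl * n_lung)

    # --- activated: logistic clonal expansion and differentiation, both in
    # lymphoid tissue (the antigen-presentation site); blood A only traffics
    a_bl, a_lt = y[I_A_BL], y[I_A_LT]
    s = (1.0 - (a_bl + a_lt) / p.TA4max) if logistic_s is None else logistic_s
    d[I_A_BL] = (-p.muA4 * a_bl
                 + p.omegaA4lt_bl * a_lt
                 - (p.omegaA4bl_lt + p.omegaA4bl_tis) * a_bl)
    d[I_A_LT] = (p.phiN4 * n_lt
                 + p.lamA4 * s * a_lt - (p.muA4 + p.phiA4) * a_lt
                 + p.omegaA4bl_lt * a_bl - p.omegaA4lt_bl * a_lt)

    # --- central-memory: from activated (fraction f4), CM -> EM everywhere ---
    cm_bl, cm_lt, cm_git, cm_lung = (y[I_CM_BL], y[I_CM_LT],
                                     y[I_CM_GIT], y[I_CM_LUNG])
    net_cm = p.lamCM4 - p.muCM4 - p.phiCM4
    d[I_CM_BL] = (net_cm * cm_bl
                  + p.omegaCM4lt_bl * cm_lt
                  + p.omegaCM4git_bl * cm_git + p.omegaCM4lung_bl * cm_lung
                  - (p.omegaCM4bl_lt + p.omegaCM4bl_git + p.omegaCM4bl_lung
                     + p.omegaCM4bl_tis) * cm_bl)
    d[I_CM_LT] = (p.f4 * p.phiA4 * a_lt + net_cm * cm_lt
                  + p.omegaCM4bl_lt * cm_bl - p.omegaCM4lt_bl * cm_lt)
    d[I_CM_GIT] = (net_cm * cm_git
                   + p.omegaCM4bl_git * cm_bl - p.omegaCM4git_bl * cm_git)
    d[I_CM_LUNG] = (net_cm * cm_lung
                    + p.omegaCM4bl_lung * cm_bl - p.omegaCM4lung_bl * cm_lung)

    # --- effector-memory: from CM, EM -> EFF everywhere, LT exit only ---
    em_bl, em_lt, em_git, em_lung = (y[I_EM_BL], y[I_EM_LT],
                                     y[I_EM_GIT], y[I_EM_LUNG])
    net_em = p.lamEM4 - p.muEM4 - p.phiEM4
    d[I_EM_BL] = (p.phiCM4 * cm_bl + net_em * em_bl
                  + p.omegaEM4lt_bl * em_lt
                  + p.omegaEM4git_bl * em_git + p.omegaEM4lung_bl * em_lung
                  - (p.omegaEM4bl_git + p.omegaEM4bl_lung
                     + p.omegaEM4bl_tis) * em_bl)
    d[I_EM_LT] = (p.phiCM4 * cm_lt + net_em * em_lt - p.omegaEM4lt_bl * em_lt)
    d[I_EM_GIT] = (p.phiCM4 * cm_git + net_em * em_git
                   + p.omegaEM4bl_git * em_bl - p.omegaEM4git_bl * em_git)
    d[I_EM_LUNG] = (p.phiCM4 * cm_lung + net_em * em_lung
                    + p.omegaEM4bl_lung * em_bl - p.omegaEM4lung_bl * em_lung)

    # --- effector: terminal, no proliferation, no return from organs ---
    eff_bl, eff_lt, eff_git, eff_lung = (y[I_EFF_BL], y[I_EFF_LT],
                                         y[I_EFF_GIT], y[I_EFF_LUNG])
    d[I_EFF_BL] = (p.phiEM4 * em_bl - p.muEFF4 * eff_bl
                   + p.omegaEFF4lt_bl * eff_lt
                   - (p.omegaEFF4bl_git + p.omegaEFF4bl_lung
                      + p.omegaEFF4bl_tis) * eff_bl)
    d[I_EFF_LT] = ((1.0 - p.f4) * p.phiA4 * a_lt + p.phiEM4 * em_lt
                   - (p.muEFF4 + p.omegaEFF4lt_bl) * eff_lt)
    d[I_EFF_GIT] = (p.phiEM4 * em_git + p.omegaEFF4bl_git * eff_bl
                    - p.muEFF4 * eff_git)
    d[I_EFF_LUNG] = (p.phiEM4 * em_lung + p.omegaEFF4bl_lung * eff_bl
                     - p.muEFF4 * eff_lung)
    return d


# ---------------------------------------------------------------------------
# flux audit
# ---------------------------------------------------------------------------

KINDS = ("source", "proliferation", "death", "differentiation_in",
         "differentiation_out", "migration_in", "migration_out")


@dataclass
class FluxBreakdown:
    """Named per-state flux decomposition; per-state sums equal the RHS."""

    per_state: dict[tuple[str, str], dict[str, float]]

    def sums(self) -> np.ndarray:
        return np.array([sum(self.per_state[lab].values())
                         for lab in STATE_LABELS])

    def to_frame(self) -> pd.DataFrame:
        rows = [{"subpopulation": s, "compartment": c, **v}
                for (s, c), v in self.per_state.items()]
        return pd.DataFrame(rows)


def flow_audit(y: np.ndarray, eff: EffectiveRates, *,
               clamp_sp4: bool = False) -> FluxBreakdown:
    """Decompose the RHS into named fluxes (cells/day).

    Built from an explicit flux list (independent of the hand-assembled
    equations in :func:`full_rhs`) so the two can be cross-checked; the
    migration pairing invariant holds by construction except for
    ``omega*bl_tis`` sinks and thymic egress.
    """
    y = np.asarray(y, dtype=float)
    p = eff
    out = {lab: {k: 0.0 for k in KINDS} for lab in STATE_LABELS}

    def S(sub, comp):
        return y[LAYOUT.idx(sub, comp)]

    def add(sub, comp, kind, value):
        out[(sub, comp)][kind] += value

    cort = 1.0 - (S("DN", "THY") + S("DP", "THY")) / p.Tcortmax
    med = 1.0 - (S("SP4", "THY") + S("SP8", "THY")) / p.Tmedmax
    add("DN", "THY", "proliferation", p.thy_lamDN * S("DN", "THY") * cort)
    add("DN", "THY", "death", -p.thy_muDN * S("DN", "THY"))
    add("DN", "THY", "differentiation_out", -p.thy_phiDN * S("DN", "THY"))
    add("DP", "THY", "differentiation_in", p.thy_phiDN * S("DN", "THY"))
    add("DP", "THY", "proliferation", p.thy_lamDP * S("DP", "THY") * cort)
    add("DP", "THY", "death", -p.thy_muDP * S("DP", "THY"))
    add("DP", "THY", "differentiation_out", -p.thy_phiDP * S("DP", "THY"))
    for sp, frac in (("SP4", p.thy_fSP4), ("SP8", 1.0 - p.thy_fSP4)):
        add(sp, "THY", "differentiation_in", frac * p.thy_phiDP * S("DP", "THY"))
        add(sp, "THY", "proliferation", p.thy_lamSP * S(sp, "THY") * med)
        add(sp, "THY", "death", -p.thy_muSP * S(sp, "THY"))
    if clamp_sp4:
        for k in KINDS:
            out[("SP4", "THY")][k] = 0.0
    else:
        add("SP4", "THY", "differentiation_out",
            -p.thy_epsSP4 * S("SP4", "THY"))
        add("RTE", "BL", "source", p.thy_epsSP4 * S("SP4", "THY"))
    add("SP8", "THY", "differentiation_out", -p.thy_epsSP8 * S("SP8", "THY"))

    def migrate(sub, a, b, rate):
        add(sub, a, "migration_out", -rate * S(sub, a))
        add(sub, b, "migration_in", rate * S(sub, a))

    def sink(sub, comp, rate):
        add(sub, comp, "migration_out", -rate * S(sub, comp))

    def die(sub, rate):
        for comp in ("BL", "LT", "GIT", "LUNG"):
            if (sub, comp) in out:
                add(sub, comp, "death", -rate * S(sub, comp))

    def grow(sub, rate):
        for comp in ("BL", "LT", "GIT", "LUNG"):
            if (sub, comp) in out:
                add(sub, comp, "proliferation", rate * S(sub, comp))

    # RTE
    die("RTE", p.muRTE4)
    migrate("RTE", "BL", "LT", p.omegaRTE4bl_lt)
    add("RTE", "LT", "differentiation_out", -p.phiRTE4 * S("RTE", "LT"))
    add("N", "LT", "differentiation_in", p.phiRTE4 * S("RTE", "LT"))
    # naive (homeostatic proliferation only in the BL/LT recirculation pool)
    die("N", p.muN4)
    add("N", "BL", "proliferation", p.lamN4 * S("N", "BL"))
    add("N", "LT", "proliferation", p.lamN4 * S("N", "LT"))
    add("N", "LT", "differentiation_out", -p.phiN4 * S("N", "LT"))
    add("A", "LT", "differentiation_in", p.phiN4 * S("N", "LT"))
    migrate("N", "LT", "BL", p.omegaN4lt_bl)
    migrate("N", "BL", "LT", p.omegaN4bl_lt)
    migrate("N", "BL", "GIT", p.omegaN4bl_git)
    migrate("N", "BL", "LUNG", p.omegaN4bl_lung)
    migrate("N", "GIT", "BL", p.omegaN4git_bl)
    migrate("N", "LUNG", "BL", p.omegaN4lung_bl)
    sink("N", "BL", p.omegaN4bl_tis)
    # activated
    die("A", p.muA4)
    s = 1.0 - (S("A", "BL") + S("A", "LT")) / p.TA4max
    add("A", "LT", "proliferation", p.lamA4 * s * S("A", "LT"))
    add("A", "LT", "differentiation_out", -p.phiA4 * S("A", "LT"))
    add("CM", "LT", "differentiation_in", p.f4 * p.phiA4 * S("A", "LT"))
    add("EFF", "LT", "differentiation_in",
        (1.0 - p.f4) * p.phiA4 * S("A", "LT"))
    migrate("A", "LT", "BL", p.omegaA4lt_bl)
    migrate("A", "BL", "LT", p.omegaA4bl_lt)
    sink("A", "BL", p.omegaA4bl_tis)
    # central-memory
    die("CM", p.muCM4)
    grow("CM", p.lamCM4)
    for comp in ("BL", "LT", "GIT", "LUNG"):
        add("CM", comp, "differentiation_out", -p.phiCM4 * S("CM", comp))
        add("EM", comp, "differentiation_in", p.phiCM4 * S("CM", comp))
    migrate("CM", "LT", "BL", p.omegaCM4lt_bl)
    migrate("CM", "BL", "LT", p.omegaCM4bl_lt)
    migrate("CM", "BL", "GIT", p.omegaCM4bl_git)
    migrate("CM", "BL", "LUNG", p.omegaCM4bl_lung)
    migrate("CM", "GIT", "BL", p.omegaCM4git_bl)
    migrate("CM", "LUNG", "BL", p.omegaCM4lung_bl)
    sink("CM", "BL", p.omegaCM4bl_tis)
    # effector-memory
    die("EM", p.muEM4)
    grow("EM", p.lamEM4)
    for comp in ("BL", "LT", "GIT", "LUNG"):
        add("EM", comp, "differentiation_out", -p.phiEM4 * S("EM", comp))
        add("EFF", comp, "differentiation_in", p.phiEM4 * S("EM", comp))
    migrate("EM", "LT", "BL", p.omegaEM4lt_bl)
    migrate("EM", "BL", "GIT", p.omegaEM4bl_git)
    migrate("EM", "BL", "LUNG", p.omegaEM4bl_lung)
    migrate("EM", "GIT", "BL", p.omegaEM4git_bl)
    migrate("EM", "LUNG", "BL", p.omegaEM4lung_bl)
    sink("EM", "BL", p.omegaEM4bl_tis)
    # effector
    die("EFF", p.muEFF4)
    migrate("EFF", "LT", "BL", p.omegaEFF4lt_bl)
    migrate("EFF", "BL", "GIT", p.omegaEFF4bl_git)
    migrate("EFF", "BL", "LUNG", p.omegaEFF4bl_lung)
    sink("EFF", "BL", p.omegaEFF4bl_tis)
    return FluxBreakdown(out)


# ---------------------------------------------------------------------------
# trajectory integration
# ---------------------------------------------------------------------------

#: default positive thymocyte seed used to leave the unstable zero state
def seed_state(dn_cells: float = 1.0e4) -> np.ndarray:
    y0 = np.zeros(N_STATES)
    y0[I_DN] = dn_cells
    return y0


@dataclass
class Trajectory:
    """Simulated trajectory on a time grid (days), with the starting age."""

    t_days: np.ndarray
    states: np.ndarray          # shape (n_times, 24)
    age0_years: float

    @property
    def age_years(self) -> np.ndarray:
        return self.age0_years + self.t_days / DAYS_PER_YEAR

    def state_at(self, i: int) -> StateVector:
        return StateVector(self.states[i], float(self.t_days[i]),
                           self.age0_years)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: time_days, age_years, subpopulation, compartment, count."""
        rows = []
        ages = self.age_years
        for i, t in enumerate(self.t_days):
            for j, (sub, comp) in enumerate(STATE_LABELS):
                rows.append((float(t), float(ages[i]), sub, comp,
                             float(self.states[i, j])))
        return pd.DataFrame(rows, columns=["time_days", "age_years",
                                           "subpopulation", "compartment",
                                           "count"])


def _rhs_factory(params: KineticParameterSet, modulation: AgeModulationSet,
                 age0: float, *, clamp_sp4: bool = False,
                 freeze_age: float | None = None):
    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        age = freeze_age if freeze_age is not None else age0 + t / DAYS_PER_YEAR
        bv = blood_volume(age, modulation.body)
        c_rte = max(y[I_RTE_BL], 0.0) / (bv * 1.0e6)
        eff = effective_parameters(age, c_rte, params, modulation)
        return full_rhs(np.maximum(y, 0.0), eff, clamp_sp4=clamp_sp4,
                        validate=False)
    return rhs


def simulate_trajectory(initial: np.ndarray | StateVector,
                        params: KineticParameterSet,
                        modulation: AgeModulationSet,
                        t_grid: np.ndarray,
                        *, age0: float = 0.0, clamp_sp4: bool = False,
                        rtol: float = 1.0e-8, atol: float = 1.0e-3,
                        freeze_age: float | None = None) -> Trajectory:
    """Integrate the stiff system over ``t_grid`` (days, strictly increasing).

    Age-dependent rates are re-evaluated continuously from
    ``age0 + t/365.25`` unless ``freeze_age`` pins them.  Output counts are
    clipped to zero only within solver tolerance.
    """
    if isinstance(initial, StateVector):
        age0 = initial.age0_years + initial.t_days / DAYS_PER_YEAR
        initial = initial.counts
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValidationError("t_grid must be strictly increasing, length >= 2")
    y0 = np.asarray(initial, dtype=float)
    if y0.shape != (N_STATES,):
        raise StructuralError(f"expected {N_STATES} states")
    if np.any(y0 < 0):
        raise ValidationError("initial state must be non-negative")
    rhs = _rhs_factory(params, modulation, age0, clamp_sp4=clamp_sp4,
                       freeze_age=freeze_age)
    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), y0, method="LSODA",
                    t_eval=t_grid, rtol=rtol, atol=atol)
    if not sol.success:
        worst = int(np.argmax(np.abs(rhs(sol.t[-1], sol.y[:, -1]))))
        raise IntegrationError(
            f"integration failed at t={sol.t[-1]:.3g} d "
            f"(state {STATE_LABELS[worst]}): {sol.message}")
    states = sol.y.T.copy()
    clip_floor = -max(1.0, 1.0e3 * atol)
    if states.min() < clip_floor:
        i, j = np.unravel_index(np.argmin(states), states.shape)
        raise IntegrationError(
            f"state {STATE_LABELS[j]} became negative ({states[i, j]:.3g}) "
            f"at t={t_grid[i]:.3g} d")
    return Trajectory(t_grid, np.maximum(states, 0.0), age0)


# ---------------------------------------------------------------------------
# steady states
# ---------------------------------------------------------------------------

def _relative_residual(y: np.ndarray, r: np.ndarray) -> float:
    return float(np.max(np.abs(r) / np.maximum(np.abs(y), 1.0)))


def steady_state_direct(params: KineticParameterSet,
                        modulation: AgeModulationSet,
                        age: float) -> np.ndarray:
    """Fast semi-analytic steady state with age frozen.

    Exploits the model's structure: the thymocyte block reduces to closed
    forms plus one scalar root (medullary crowding), the RTE block to one
    scalar root (death-rate feedback), and the remaining 18 peripheral
    states are linear once the activated-cell logistic factor is fixed,
    which leaves a final scalar fixed-point equation.
    """
    if age < 0:
        raise ValidationError("age must be non-negative")
    bv = blood_volume(age, modulation.body)
    eff0 = effective_parameters(age, 0.0, params, modulation)
    p = eff0

    # --- thymocytes -------------------------------------------------------
    y = np.zeros(N_STATES)
    growth = p.thy_lamDN
    loss = p.thy_phiDN + p.thy_muDN
    if growth > loss and p.Tcortmax > 0:
        qc = 1.0 - loss / growth                     # (DN+DP)/Tcortmax
        g_dp = p.thy_lamDP * (1.0 - qc) - (p.thy_phiDP + p.thy_muDP)
        if g_dp >= 0:
            raise SteadyStateError("DP pool has no stable interior equilibrium")
        ratio = p.thy_phiDN / (-g_dp)                # DP per DN
        dn = qc * p.Tcortmax / (1.0 + ratio)
        dp = ratio * dn
        inflow4 = p.thy_fSP4 * p.thy_phiDP * dp
        inflow8 = (1.0 - p.thy_fSP4) * p.thy_phiDP * dp

        def sp_tot(u: float) -> tuple[float, float]:
            a4 = p.thy_muSP + p.thy_epsSP4 - p.thy_lamSP * (1.0 - u)
            a8 = p.thy_muSP + p.thy_epsSP8 - p.thy_lamSP * (1.0 - u)
            if a4 <= 0 or a8 <= 0:
                raise SteadyStateError("SP pool has no stable equilibrium")
            return inflow4 / a4, inflow8 / a8

        def crowd(u: float) -> float:
            s4, s8 = sp_tot(u)
            return (s4 + s8) / p.Tmedmax - u

        hi = 1.0
        while crowd(hi) > 0:
            hi *= 2.0
        u = brentq(crowd, 0.0, hi, xtol=1.0e-14)
        sp4, sp8 = sp_tot(u)
        y[I_DN], y[I_DP], y[I_SP4], y[I_SP8] = dn, dp, sp4, sp8
    egress = p.thy_epsSP4 * y[I_SP4]
    if egress == 0.0:
        return y                                      # periphery empty

    # --- RTE block (possibly feedback on its own concentration) ----------
    if modulation.variant == AGE_PLUS_FEEDBACK:
        fb = modulation.feedback
        from .agefun import feedback_rte_death

        def c_gap(c: float) -> float:
            mu = feedback_rte_death(c, fb.muRTE4_base, fb.muRTE4_max,
                                    fb.muRTE4_c50, fb.muRTE4_hill)
            return egress / ((p.omegaRTE4bl_lt + mu) * bv * 1.0e6) - c

        c_ub = egress / ((p.omegaRTE4bl_lt + fb.muRTE4_base) * bv * 1.0e6)
        c_rte = brentq(c_gap, 0.0, c_ub * (1 + 1e-12), xtol=1.0e-12)
    else:
        c_rte = egress / ((p.omegaRTE4bl_lt + p.muRTE4) * bv * 1.0e6)
    eff = effective_parameters(age, c_rte, params, modulation)
    y[I_RTE_BL] = egress / (eff.omegaRTE4bl_lt + eff.muRTE4)
    y[I_RTE_LT] = (eff.omegaRTE4bl_lt * y[I_RTE_BL]
                   / (eff.phiRTE4 + eff.muRTE4))

    # --- peripheral linear block with scalar logistic fixed point ---------
    idx = np.arange(I_N_BL, N_STATES)
    n = len(idx)

    # one batched RHS call: n homogeneous unit columns (exact linear
    # action, no precision loss from differencing against the source
    # term) plus one source column
    batch = np.zeros((N_STATES, n + 1))
    batch[idx, :n] = np.eye(n)
    batch[:, n] = y
    batch[idx, n] = 0.0
    d_batch = full_rhs(batch, eff, logistic_s=0.0, validate=False)
    m0 = d_batch[idx, :n]
    b = d_batch[idx, n]
    d_a = np.zeros(n)
    d_a[I_A_LT - I_N_BL] = eff.lamA4

    def solve_for(s: float) -> np.ndarray:
        m = m0 + s * np.diag(d_a)
        return np.linalg.solve(m, -b)

    def gap(s: float) -> float:
        """Self-consistency defect of the logistic factor.

        Past the stability margin the linear solve turns spuriously
        negative (the true activated pool diverges there), which is
        treated as gap = -1 so the bisection backs off to smaller s.
        """
        x = solve_for(s)
        if np.any(x < -1.0e-9 * max(1.0, float(np.max(np.abs(x))))):
            return -1.0
        a_tot = x[I_A_BL - I_N_BL] + x[I_A_LT - I_N_BL]
        return 1.0 - a_tot / eff.TA4max - s

    def try_fixed_point() -> float | None:
        # in the source-limited regime the activated pool is far below
        # TA4max and s* sits just under 1: a two-step contraction map
        s = 1.0
        for _ in range(30):
            x = solve_for(s)
            if np.any(x < -1.0e-9 * max(1.0, float(np.max(np.abs(x))))):
                return None
            s_new = 1.0 - (x[I_A_BL - I_N_BL]
                           + x[I_A_LT - I_N_BL]) / eff.TA4max
            if s_new < 0:
                return None
            if abs(s_new - s) <= 1.0e-12:
                return s_new
            s = s_new
        return None

    s_star = try_fixed_point()
    if s_star is None:
        lo, hi = 0.0, 1.0
        if gap(hi) >= 0.0:
            s_star = hi
        else:
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if gap(mid) >= 0.0:
                    lo = mid
                else:
                    hi = mid
            s_star = lo
    x = solve_for(s_star)
    if np.any(x < -1.0e-6 * max(1.0, np.max(np.abs(x)))):
        raise SteadyStateError("negative steady-state component")
    y[idx] = np.maximum(x, 0.0)
    return y


def solve_steady_state(params: KineticParameterSet,
                       modulation: AgeModulationSet,
                       age_fixed: float,
                       *, tol: float = 1.0e-8,
                       t_equilibrate: float = 1.0e6,
                       initial: np.ndarray | None = None) -> StateVector:
    """Steady state with age frozen: long-time integration + root refinement.

    Integrates from a small thymocyte seed (or ``initial``) for
    ``t_equilibrate`` days at the fixed age, then polishes the endpoint
    with a Newton-type root solve on log-transformed states, which keeps
    every component positive.  Raises :class:`SteadyStateError` with the
    final residual on non-convergence.
    """
    if age_fixed < 0:
        raise ValidationError("age must be non-negative")
    rhs = _rhs_factory(params, modulation, age_fixed, freeze_age=age_fixed)
    y0 = seed_state() if initial is None else np.asarray(initial, float)
    sol = solve_ivp(rhs, (0.0, t_equilibrate), y0, method="LSODA",
                    rtol=1.0e-10, atol=1.0e-6)
    if not sol.success:
        raise SteadyStateError(f"equilibration failed: {sol.message}")
    y = np.maximum(sol.y[:, -1], 0.0)
    if _relative_residual(y, rhs(0.0, y)) <= tol and np.all(y == 0):
        return StateVector(y, 0.0, age_fixed)
    # refine in log space (all interior components positive)
    pos = y > 0
    if np.all(pos):
        z0 = np.log(y)

        def f(z: np.ndarray) -> np.ndarray:
            return rhs(0.0, np.exp(z))

        res = root(f, z0, method="hybr", tol=1.0e-12)
        if res.success:
            y = np.exp(res.x)
    r = rhs(0.0, y)
    rel = _relative_residual(y, r)
    if rel > tol:
        raise SteadyStateError(
            f"steady state did not converge: relative residual {rel:.3g}")
    if np.any(y < 0):
        raise SteadyStateError("negative component after refinement")
    return StateVector(y, 0.0, age_fixed)
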