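"""Maximum-likelihood calibration against steady-state observables.

The workflow mirrors staged model building: (1) fit kinetic rates with age
entering only through thymic capacity and blood volume; (2) select
empirical age functions by forward selection / backward elimination over
candidate (parameter, form) pairs, scored by AIC under an identifiability
constraint (RSE <= 51%); (3) replace the naive-proliferation and RTE-death
age functions with RTE-concentration feedback and re-estimate.

Observations are treated as steady-state values: each dataset row is
predicted by the model's steady state at the row's age-bin midpoint.
Optimization is derivative-free (Nelder-Mead) on log-transformed
parameters, multi-started from seeded log-uniform draws within bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .agefun import (AGE, AGE_PLUS_FEEDBACK, DMAX_ONE, AgeModulationSet,
                     Modulation, blood_volume, default_modulations)
from .model import SteadyStateError, steady_state_direct
from .observe import (CalibrationDataset, FitResult, RSE_THRESHOLD, aic,
                      observables_from_state, proportional_loglik,
                      rse_estimate)
from .parameters import KineticParameterSet

#: Hill coefficients pinned for specific age-function targets
FIXED_HILL = {"lamN4": 10.0, "phiCM4": 3.0}


# ---------------------------------------------------------------------------
# free-parameter addressing
# ---------------------------------------------------------------------------
# A free parameter is addressed by name:
#   "<rate>"                      — kinetic rate in KineticParameterSet
#   "mod.<target>.max_change"     — age-function amplitude
#   "mod.<target>.half_effect"    — age-function age50 (or slope/rate for
#                                   the non-hyperbolic forms)
#   "fb.<field>"                  — feedback constant (FeedbackConstants)


def apply_theta(params: KineticParameterSet, mod: AgeModulationSet,
                names: list[str], values: np.ndarray
                ) -> tuple[KineticParameterSet, AgeModulationSet]:
    """Return copies of (params, mod) with the named parameters set."""
    kin: dict[str, float] = {}
    mod_updates: dict[str, dict[str, float]] = {}
    fb_updates: dict[str, float] = {}
    for name, v in zip(names, values):
        if name.startswith("mod."):
            _, target, fld = name.split(".")
            mod_updates.setdefault(target, {})[fld] = float(v)
        elif name.startswith("fb."):
            fb_updates[name[3:]] = float(v)
        else:
            kin[name] = float(v)
    if kin:
        params = params.replace(**kin)
    if mod_updates:
        new = []
        seen = set()
        for m in mod.modulations:
            if m.target in mod_updates:
                m = replace(m, **mod_updates[m.target])
                seen.add(m.target)
            new.append(m)
        missing = set(mod_updates) - seen
        if missing:
            raise ValueError(f"modulation target(s) not in set: {sorted(missing)}")
        mod = replace(mod, modulations=tuple(new))
    if fb_updates:
        mod = replace(mod, feedback=replace(mod.feedback, **fb_updates))
    return params, mod


def default_bounds(name: str, nominal: float) -> tuple[float, float]:
    """Positivity-preserving search bounds for one free parameter."""
    if name.startswith("mod.") and name.endswith("max_change"):
        return (1.0e-4, 10.0)
    if name.startswith("mod.") and name.endswith("half_effect"):
        return (0.5, 120.0)
    if name.startswith("fb.") and "c50" in name:
        return (0.1, 5000.0)
    if name.startswith("fb.") and "max" in name:
        return (1.0e-4, 10.0)
    lo = nominal / 100.0 if nominal > 0 else 1.0e-8
    hi = nominal * 100.0 if nominal > 0 else 1.0
    return (lo, hi)


def nominal_value(params: KineticParameterSet, mod: AgeModulationSet,
                  name: str) -> float:
    if name.startswith("mod."):
        _, target, fld = name.split(".")
        for m in mod.modulations:
            if m.target == target:
                return getattr(m, fld)
        raise ValueError(f"no modulation for {target!r}")
    if name.startswith("fb."):
        return getattr(mod.feedback, name[3:])
    return getattr(params, name)


# ---------------------------------------------------------------------------
# steady-state predictions for a dataset
# ---------------------------------------------------------------------------

class SteadyStatePredictor:
    """Predicts dataset rows from steady states, memoized by (age, theta)."""

    def __init__(self, params: KineticParameterSet, mod: AgeModulationSet):
        self.params = params
        self.mod = mod
        self._cache: dict[tuple, np.ndarray] = {}

    def predict(self, dataset: CalibrationDataset,
                names: list[str] | None = None,
                values: np.ndarray | None = None) -> np.ndarray:
        params, mod = self.params, self.mod
        key_theta = ()
        if names:
            params, mod = apply_theta(params, mod, names, values)
            key_theta = tuple(float(v) for v in values) + tuple(names)
        t = dataset.table
        ages = dataset.age_mid()
        out = np.empty(len(t))
        for age in np.unique(ages):
            key = (round(float(age), 9), key_theta)
            obs = self._cache.get(key)
            if obs is None:
                y = steady_state_direct(params, mod, float(age))
                obs = observables_from_state(y, blood_volume(age, mod.body))
                self._cache[key] = obs
            rows = np.where(ages == age)[0]
            for i in rows:
                out[i] = obs[t["observable_id"].iloc[i]]
        return out


def dataset_nll(dataset: CalibrationDataset, params: KineticParameterSet,
                mod: AgeModulationSet) -> float:
    pred = SteadyStatePredictor(params, mod).predict(dataset)
    return proportional_loglik(pred, dataset)


# ---------------------------------------------------------------------------
# multi-start fit
# ---------------------------------------------------------------------------

_PENALTY = 1.0e12


def fit_multistart(dataset: CalibrationDataset,
                   variant: str,
                   free: list[str],
                   *,
                   base_params: KineticParameterSet | None = None,
                   base_mod: AgeModulationSet | None = None,
                   n_starts: int = 15,
                   seed: int = 0,
                   bounds: dict[str, tuple[float, float]] | None = None,
                   maxiter: int | None = None,
                   xatol: float = 1.0e-6,
                   polish: bool = True,
                   extra_starts: list[np.ndarray] | None = None,
                   compute_rse: bool = True) -> FitResult:
    """Best of ``n_starts`` local optimizations of the proportional NLL.

    The first start is the nominal value; the rest are log-uniform draws
    within bounds (default: nominal x [0.01, 100] for kinetic rates).
    Deterministic for a given seed.
    """
    params = base_params or KineticParameterSet()
    mod = (base_mod or default_modulations(variant)).with_variant(variant)
    nominals = np.array([nominal_value(params, mod, n) for n in free])
    bnds = [bounds.get(n) if bounds and n in bounds
            else default_bounds(n, nominals[i]) for i, n in enumerate(free)]
    lo = np.array([b[0] for b in bnds])
    hi = np.array([b[1] for b in bnds])
    predictor = SteadyStatePredictor(params, mod)

    def nll_nat(theta: np.ndarray) -> float:
        if np.any(theta < lo) or np.any(theta > hi):
            over = np.maximum(theta / hi, 1.0) + np.maximum(lo / np.maximum(theta, 1e-300), 1.0)
            return _PENALTY * float(np.sum(over))
        try:
            pred = predictor.predict(dataset, free, theta)
        except (SteadyStateError, FloatingPointError, ValueError):
            return _PENALTY
        return proportional_loglik(pred, dataset)

    def obj(x: np.ndarray) -> float:
        return nll_nat(np.exp(x))

    rng = np.random.default_rng(seed)
    llo, lhi = np.log(lo), np.log(hi)
    starts = [np.log(np.clip(nominals, lo, hi))]
    if extra_starts:
        starts += [np.log(np.clip(np.asarray(s, float), lo, hi))
                   for s in extra_starts]
    for _ in range(n_starts - 1):
        starts.append(rng.uniform(llo, lhi))

    best = None
    n_conv = 0
    for x0 in starts:
        res = minimize(obj, x0, method="Nelder-Mead",
                       options={"xatol": xatol, "fatol": 1.0e-9,
                                "maxiter": maxiter or 400 * len(free),
                                "adaptive": len(free) > 3})
        n_conv += bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or best.fun >= _PENALTY:
        raise RuntimeError("all optimization starts failed")
    if polish:
        res = minimize(obj, best.x, method="Powell",
                       options={"xtol": 1.0e-10, "ftol": 1.0e-12,
                                "maxiter": 50 * len(free)})
        if res.fun < best.fun:
            best = res
    theta = np.exp(best.x)
    estimates = {n: float(v) for n, v in zip(free, theta)}
    rse, flagged = ({}, [])
    if compute_rse:
        rse, flagged = rse_estimate(nll_nat, theta, free)
    fixed = {n: float(v) for n, v in params.to_dict().items()
             if n not in estimates}
    return FitResult(variant=variant, estimates=estimates, fixed=fixed,
                     nll=float(best.fun), aic=aic(best.fun, len(free)),
                     rse=rse, unidentifiable=flagged,
                     n_starts=n_starts, n_converged=n_conv, seed=seed)


# ---------------------------------------------------------------------------
# profile likelihood
# ---------------------------------------------------------------------------

#: chi-square(1)/2 threshold for a 95% profile-likelihood CI
PROFILE_DELTA = 1.92


def profile_interval(grid: np.ndarray, nll: np.ndarray,
                     nll_min: float | None = None,
                     delta: float = PROFILE_DELTA) -> tuple[float, float]:
    """Grid values whose profile NLL stays within ``delta`` of the minimum
    (the chi-square(1) 95% threshold by default)."""
    grid = np.asarray(grid, float)
    nll = np.asarray(nll, float)
    if nll_min is None:
        nll_min = float(np.nanmin(nll))
    inside = np.isfinite(nll) & (nll <= nll_min + delta)
    if not inside.any():
        return (math.nan, math.nan)
    return (float(grid[inside].min()), float(grid[inside].max()))


@dataclass
class ProfileResult:
    parameter: str
    grid: np.ndarray
    nll: np.ndarray
    nll_min: float
    ci: tuple[float, float]
    flat: bool
    failed_points: list[int] = field(default_factory=list)


def profile_likelihood(dataset: CalibrationDataset, fit: FitResult,
                       parameter: str, grid: np.ndarray,
                       *, base_params: KineticParameterSet | None = None,
                       base_mod: AgeModulationSet | None = None,
                       n_starts: int = 1, seed: int = 0,
                       flat_range: float = 0.01) -> ProfileResult:
    """Profile the NLL over ``grid`` by re-optimizing all other estimates.

    The 95% CI collects grid values with NLL <= NLL_min + 1.92; a profile
    whose total range is below ``flat_range`` is flagged as practically
    non-identifiable.
    """
    grid = np.asarray(grid, dtype=float)
    if parameter not in fit.estimates:
        raise ValueError(f"{parameter!r} was not estimated in this fit")
    est = fit.estimates[parameter]
    if not (grid.min() <= est <= grid.max()):
        import warnings
        warnings.warn("profile grid does not bracket the estimate")
    others = [n for n in fit.estimates if n != parameter]
    params = base_params or KineticParameterSet()
    mod = (base_mod or default_modulations(fit.variant)).with_variant(fit.variant)
    # hold the profiled parameter fixed by folding it into the base objects
    nlls = np.empty(len(grid))
    failed = []
    for i, v in enumerate(grid):
        p_i, m_i = apply_theta(params, mod, [parameter], np.array([v]))
        if not others:
            try:
                nlls[i] = dataset_nll(dataset, p_i, m_i)
            except SteadyStateError:
                nlls[i] = np.nan
                failed.append(i)
            continue
        try:
            sub = fit_multistart(dataset, fit.variant, others,
                                 base_params=p_i, base_mod=m_i,
                                 n_starts=n_starts, seed=seed,
                                 compute_rse=False)
            nlls[i] = sub.nll
        except (RuntimeError, SteadyStateError):
            nlls[i] = np.nan
            failed.append(i)
    ok = np.isfinite(nlls)
    nll_min = float(np.nanmin(np.append(nlls[ok], fit.nll)))
    ci = profile_interval(grid, nlls, nll_min)
    rng_ = float(np.nanmax(nlls) - np.nanmin(nlls)) if ok.any() else 0.0
    return ProfileResult(parameter, grid, nlls, nll_min, ci,
                         flat=rng_ < flat_range, failed_points=failed)


# ---------------------------------------------------------------------------
# stepwise age-function selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Candidate:
    """A (target rate, direction) slot for an empirical age dependency."""

    target: str
    direction: str  # "up" or "down"


def _candidate_free(cand: Candidate, form: str) -> list[str]:
    """Free parameter names introduced by a candidate under a given form."""
    if form == "hyperbolic":
        names = [f"mod.{cand.target}.half_effect"]
        if not (cand.direction == "down" and cand.target in DMAX_ONE):
            names.insert(0, f"mod.{cand.target}.max_change")
        return names
    return [f"mod.{cand.target}.half_effect"]  # slope/rate parameter


def _make_modulation(cand: Candidate, form: str) -> Modulation:
    hill = FIXED_HILL.get(cand.target, 1.0)
    max_change = 1.0 if (cand.direction == "down" and cand.target in DMAX_ONE) \
        else 0.5
    half = 30.0 if form == "hyperbolic" else 0.01
    return Modulation(cand.target, cand.direction, max_change, half,
                      hill=hill, form=form)


#: coarse start grids for candidate age-function constants
_GRID_MAX_CHANGE = (0.003, 0.01, 0.03, 0.1, 0.3, 0.9)
_GRID_HALF_EFFECT = (5.0, 15.0, 40.0, 80.0)
_GRID_SLOPE = (1.0e-4, 1.0e-3, 1.0e-2, 0.1)


def _grid_starts(dataset: CalibrationDataset, params: KineticParameterSet,
                 trial: AgeModulationSet, free: list[str],
                 top: int = 1) -> list[np.ndarray]:
    """Best points of a coarse NLL grid scan, used to seed the optimizer.

    The hyperbolic amplitude landscape can be extremely stiff (rates close
    to the activated-pool stability margin), so random or nominal starts
    alone often miss the basin of attraction.
    """
    if all(n.endswith("half_effect") for n in free) and len(free) == 1:
        m = next(m for m in trial.modulations
                 if f"mod.{m.target}.half_effect" == free[0])
        axis = _GRID_HALF_EFFECT if m.form == "hyperbolic" else _GRID_SLOPE
        grid = [np.array([v]) for v in axis]
    elif len(free) == 2:
        grid = [np.array([a, b]) for a in _GRID_MAX_CHANGE
                for b in _GRID_HALF_EFFECT]
    else:
        return []
    predictor = SteadyStatePredictor(params, trial)
    scored = []
    for theta in grid:
        try:
            pred = predictor.predict(dataset, free, theta)
            scored.append((proportional_loglik(pred, dataset), theta))
        except (SteadyStateError, ValueError, FloatingPointError):
            continue
    scored.sort(key=lambda kv: kv[0])
    return [theta for _, theta in scored[:top]]


@dataclass
class SelectionResult:
    modulation_set: AgeModulationSet
    audit: list[dict]
    aic: float
    nll: float


def stepwise_selection(dataset: CalibrationDataset,
                       candidates: list[Candidate],
                       *,
                       forms: tuple[str, ...] = ("hyperbolic", "linear",
                                                 "exponential", "quadratic"),
                       base_params: KineticParameterSet | None = None,
                       seed: int = 0,
                       n_starts: int = 2,
                       maxiter: int = 120,
                       max_forward_rounds: int | None = None
                       ) -> SelectionResult:
    """Forward selection / backward elimination of age dependencies.

    Kinetic rates stay fixed.  Each forward round fits every remaining
    (candidate, form) pair on top of the already-selected set (whose
    fitted constants are frozen), accepts the globally best AIC
    improvement whose new parameters are identifiable, and stops when no
    candidate improves the AIC.  Backward elimination then removes any
    selected dependency whose removal lowers the AIC.
    """
    params = base_params or KineticParameterSet()
    selected: list[Modulation] = []
    n_sel_params = 0
    audit: list[dict] = []

    def mod_set() -> AgeModulationSet:
        return AgeModulationSet(variant=AGE, modulations=tuple(selected))

    current_nll = dataset_nll(dataset, params, mod_set())
    current_aic = aic(current_nll, 0)
    remaining = list(candidates)
    round_no = 0
    while remaining:
        round_no += 1
        if max_forward_rounds and round_no > max_forward_rounds:
            break
        best = None
        for cand in remaining:
            for form in forms:
                m = _make_modulation(cand, form)
                trial = AgeModulationSet(variant=AGE,
                                         modulations=tuple(selected) + (m,))
                free = _candidate_free(cand, form)
                bnds = ({f"mod.{cand.target}.max_change": (1.0e-4, 1.0)}
                        if cand.direction == "down" and form == "hyperbolic"
                        else None)
                extras = _grid_starts(dataset, params, trial, free)
                try:
                    fr = fit_multistart(dataset, AGE, free,
                                        base_params=params, base_mod=trial,
                                        n_starts=n_starts, seed=seed,
                                        maxiter=maxiter, bounds=bnds,
                                        extra_starts=extras, polish=False)
                except (RuntimeError, SteadyStateError):
                    continue
                k = n_sel_params + len(free)
                cand_aic = aic(fr.nll, k)
                identifiable = not fr.unidentifiable
                audit.append({"round": round_no, "phase": "forward",
                              "target": cand.target, "form": form,
                              "aic": cand_aic, "nll": fr.nll,
                              "identifiable": identifiable,
                              "accepted": False})
                if not identifiable:
                    continue
                if best is None or cand_aic < best[0]:
                    _, new_mod = apply_theta(
                        params, trial, free,
                        np.array([fr.estimates[n] for n in free]))
                    best = (cand_aic, fr.nll, cand, new_mod.modulations[-1],
                            len(free))
        if best is None or best[0] >= current_aic:
            break
        current_aic, current_nll, cand, fitted_mod, n_new = best
        selected.append(fitted_mod)
        n_sel_params += n_new
        remaining = [c for c in remaining if c.target != cand.target]
        audit.append({"round": round_no, "phase": "forward",
                      "target": cand.target, "form": fitted_mod.form,
                      "aic": current_aic, "nll": current_nll,
                      "identifiable": True, "accepted": True})

    # backward elimination: drop any term whose removal lowers AIC
    changed = True
    while changed and selected:
        changed = False
        for m in list(selected):
            trial = [x for x in selected if x is not m]
            k = n_sel_params - len(_candidate_free(
                Candidate(m.target, m.direction), m.form))
            nll = dataset_nll(dataset, params,
                              AgeModulationSet(variant=AGE,
                                               modulations=tuple(trial)))
            trial_aic = aic(nll, k)
            audit.append({"round": round_no, "phase": "backward",
                          "target": m.target, "form": m.form,
                          "aic": trial_aic, "nll": nll,
                          "identifiable": True,
                          "accepted": trial_aic < current_aic})
            if trial_aic < current_aic:
                selected.remove(m)
                n_sel_params = k
                current_aic, current_nll = trial_aic, nll
                changed = True
                break
    return SelectionResult(mod_set(), audit, current_aic, current_nll)
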