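"""Global sensitivity analysis: Latin-hypercube sampling and PRCC.

Parameters are perturbed jointly within +/-25% uniform ranges (three
groups: thymocyte homeostasis, peripheral kinetics, and age/feedback
constants), steady-state outputs are evaluated at representative ages
(0, 1, 20, 50, 80 years), and the partial rank correlation coefficient
quantifies each parameter's monotone influence with the others' linear
(rank-scale) effects removed.  |PRCC| >= 0.5 is flagged significant.
Monotonicity of each parameter-output relationship is screened before
interpreting PRCC values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc, rankdata, spearmanr

from .agefun import AgeModulationSet, blood_volume
from .calibrate import apply_theta
from .model import SteadyStateError, steady_state_direct
from .observe import CALIBRATION_OBSERVABLES, observables_from_state
from .parameters import KineticParameterSet

GSA_AGES = (0.0, 1.0, 20.0, 50.0, 80.0)
SIGNIFICANCE = 0.5


@dataclass
class LhsDesign:
    """Stratified uniform design: one sample per equal-probability stratum
    per dimension."""

    names: list[str]
    bounds: dict[str, tuple[float, float]]
    samples: np.ndarray        # (n, d)
    seed: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=self.names)


def lhs_sample(bounds: dict[str, tuple[float, float]], n: int,
               seed: int) -> LhsDesign:
    if n < 2:
        raise ValueError("need at least 2 samples")
    names = list(bounds)
    lo = np.array([bounds[k][0] for k in names])
    hi = np.array([bounds[k][1] for k in names])
    if np.any(hi <= lo):
        bad = [k for k in names if bounds[k][1] <= bounds[k][0]]
        raise ValueError(f"degenerate bounds for {bad}")
    unit = qmc.LatinHypercube(d=len(names), seed=seed).random(n)
    return LhsDesign(names, dict(bounds), qmc.scale(unit, lo, hi), seed)


# ---------------------------------------------------------------------------
# PRCC
# ---------------------------------------------------------------------------

def _rank(a: np.ndarray) -> np.ndarray:
    return rankdata(a, axis=0) if a.ndim > 1 else rankdata(a)


def prcc(design: LhsDesign | np.ndarray, outputs: np.ndarray
         ) -> tuple[pd.Series, dict[str, bool]]:
    """PRCC of each design column against a scalar output.

    Rank-transforms all variables, then for each parameter regresses both
    its ranks and the output ranks on all remaining parameters (with
    intercept, via QR least squares) and correlates the residuals.
    Samples with non-finite output are dropped.  A constant output — or a
    parameter whose ranks are fully determined by the others — yields
    PRCC 0 with a degenerate flag.
    """
    if isinstance(design, LhsDesign):
        x = design.samples
        names = design.names
    else:
        x = np.asarray(design, float)
        names = [f"x{i}" for i in range(x.shape[1])]
    y = np.asarray(outputs, float)
    ok = np.isfinite(y)
    if ok.mean() < 0.9:
        raise ValueError(f"only {ok.mean():.0%} of outputs are finite")
    x, y = x[ok], y[ok]
    flags = {n: False for n in names}
    if np.ptp(y) == 0:
        return pd.Series(0.0, index=names), {n: True for n in names}
    n, d = x.shape
    rx = np.column_stack([_rank(x[:, j]) for j in range(d)])
    ry = _rank(y).astype(float)
    out = np.zeros(d)
    ones = np.ones((n, 1))
    for j, name in enumerate(names):
        if np.ptp(x[:, j]) == 0:
            flags[name] = True
            continue
        others = np.hstack([ones, np.delete(rx, j, axis=1)])
        coef_x, *_ = np.linalg.lstsq(others, rx[:, j], rcond=None)
        coef_y, *_ = np.linalg.lstsq(others, ry, rcond=None)
        res_x = rx[:, j] - others @ coef_x
        res_y = ry - others @ coef_y
        sx = np.sqrt(res_x @ res_x)
        sy = np.sqrt(res_y @ res_y)
        if sx <= 1e-10 * n or sy <= 1e-10 * n:
            flags[name] = True
            continue
        out[j] = float(np.clip((res_x @ res_y) / (sx * sy), -1.0, 1.0))
    return pd.Series(out, index=names), flags


def monotonicity_screen(design: LhsDesign | np.ndarray, outputs: np.ndarray,
                        n_bins: int = 8) -> pd.DataFrame:
    """Spearman correlation plus a binned-mean direction-consistency check.

    A parameter-output relationship is called monotone when at least 75%
    of adjacent bin-mean moves share a direction.
    """
    if isinstance(design, LhsDesign):
        x, names = design.samples, design.names
    else:
        x = np.asarray(design, float)
        names = [f"x{i}" for i in range(x.shape[1])]
    y = np.asarray(outputs, float)
    ok = np.isfinite(y)
    x, y = x[ok], y[ok]
    rows = []
    for j, name in enumerate(names):
        rho = spearmanr(x[:, j], y).statistic if np.ptp(y) > 0 else 0.0
        edges = np.quantile(x[:, j], np.linspace(0, 1, n_bins + 1))
        idx = np.clip(np.searchsorted(edges, x[:, j], side="right") - 1,
                      0, n_bins - 1)
        means = np.array([y[idx == b].mean() if (idx == b).any() else np.nan
                          for b in range(n_bins)])
        diffs = np.diff(means[np.isfinite(means)])
        nz = diffs[diffs != 0]
        consistency = (max((nz > 0).sum(), (nz < 0).sum()) / len(nz)
                       if len(nz) else 1.0)
        rows.append({"parameter": name, "spearman": float(rho),
                     "direction_consistency": float(consistency),
                     "monotone": bool(consistency >= 0.75)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model-level GSA
# ---------------------------------------------------------------------------

def gsa_parameter_bounds(params: KineticParameterSet,
                         mod: AgeModulationSet,
                         rel_range: float = 0.25
                         ) -> dict[str, tuple[float, float]]:
    """+/-25% bounds around nominal for the full sensitivity parameter set:
    kinetic and thymocyte rates plus age/feedback constants."""
    bounds: dict[str, tuple[float, float]] = {}
    for name, v in params.to_dict().items():
        if v > 0:
            bounds[name] = (v * (1 - rel_range), v * (1 + rel_range))
    for m in mod.active_modulations():
        for fld in ("max_change", "half_effect"):
            v = getattr(m, fld)
            if v > 0:
                hi = v * (1 + rel_range)
                if fld == "max_change" and m.direction == "down":
                    hi = min(hi, 1.0)  # relative decreases cannot exceed 100%
                bounds[f"mod.{m.target}.{fld}"] = (v * (1 - rel_range), hi)
    if mod.variant == "AGE_PLUS_FEEDBACK":
        for fld in ("lamN4_base", "lamN4_max", "lamN4_c50",
                    "muRTE4_base", "muRTE4_max", "muRTE4_c50"):
            v = getattr(mod.feedback, fld)
            bounds[f"fb.{fld}"] = (v * (1 - rel_range), v * (1 + rel_range))
    return bounds


@dataclass
class GsaResult:
    """PRCC per (parameter, output, age) with significance flags."""

    table: pd.DataFrame          # parameter, output, age, prcc, significant
    design: LhsDesign
    n_effective: dict[tuple[str, float], int] = field(default_factory=dict)
    monotonicity: pd.DataFrame | None = None
    convergence: pd.DataFrame | None = None

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def lookup(self, parameter: str, output: str, age: float) -> float:
        t = self.table
        row = t[(t["parameter"] == parameter) & (t["output"] == output)
                & (t["age"] == age)]
        if row.empty:
            raise KeyError((parameter, output, age))
        return float(row["prcc"].iloc[0])


def _evaluate_samples(design: LhsDesign, params: KineticParameterSet,
                      mod: AgeModulationSet, ages, outputs) -> dict:
    results = {(out, age): np.full(len(design.samples), np.nan)
               for out in outputs for age in ages}
    for i, theta in enumerate(design.samples):
        try:
            p_i, m_i = apply_theta(params, mod, design.names, theta)
        except ValueError:
            continue
        for age in ages:
            try:
                y = steady_state_direct(p_i, m_i, age)
            except (SteadyStateError, ValueError):
                continue
            obs = observables_from_state(y, blood_volume(age, m_i.body))
            for out in outputs:
                results[(out, age)][i] = obs[out]
    return results


def run_gsa(params: KineticParameterSet, mod: AgeModulationSet,
            *, ages=GSA_AGES, outputs=CALIBRATION_OBSERVABLES,
            n: int = 2000, seed: int = 0, rel_range: float = 0.25,
            bounds: dict[str, tuple[float, float]] | None = None,
            check_convergence: bool = False,
            screen_monotonicity: bool = False,
            max_failed_fraction: float = 0.10) -> GsaResult:
    """LHS + PRCC over all outputs at the selected ages.

    The reference analysis uses n = 10,000; the desk-scale default of
    2,000 can be checked with ``check_convergence`` (PRCC drift between
    the full design and its first half).
    """
    bounds = bounds or gsa_parameter_bounds(params, mod, rel_range)
    design = lhs_sample(bounds, n, seed)
    results = _evaluate_samples(design, params, mod, ages, outputs)
    rows = []
    n_eff = {}
    mono_frames = []
    for (out, age), yvals in results.items():
        ok = np.isfinite(yvals)
        if ok.mean() < 1.0 - max_failed_fraction:
            raise RuntimeError(
                f"{(~ok).sum()} of {len(yvals)} runs failed for "
                f"{out} at age {age}")
        n_eff[(out, age)] = int(ok.sum())
        vals, flags = prcc(design, yvals)
        for name, v in vals.items():
            rows.append({"parameter": name, "output": out, "age": age,
                         "prcc": v, "significant": abs(v) >= SIGNIFICANCE,
                         "degenerate": flags[name]})
        if screen_monotonicity:
            mf = monotonicity_screen(design, yvals)
            mf["output"], mf["age"] = out, age
            mono_frames.append(mf)
    table = pd.DataFrame(rows)
    conv = None
    if check_convergence:
        half = len(design.samples) // 2
        sub = LhsDesign(design.names, design.bounds,
                        design.samples[:half], design.seed)
        conv_rows = []
        for (out, age), yvals in results.items():
            v_full, _ = prcc(design, yvals)
            v_half, _ = prcc(sub, yvals[:half])
            drift = (v_full - v_half).abs()
            top = v_full.abs().sort_values(ascending=False).head(5).index
            conv_rows.append({"output": out, "age": age,
                              "max_drift_top5": float(drift[top].max())})
        conv = pd.DataFrame(conv_rows)
    mono = pd.concat(mono_frames, ignore_index=True) if mono_frames else None
    return GsaResult(table, design, n_eff, mono, conv)


def contour_grid(param_pair: tuple[str, str], grid_size: int, age: float,
                 output: str, params: KineticParameterSet,
                 mod: AgeModulationSet,
                 rel_range: float = 0.25) -> pd.DataFrame:
    """Iso-output surface on a 2-D grid (+/-25% around nominal), all other
    parameters held at nominal values."""
    p1, p2 = param_pair
    if p1 == p2:
        raise ValueError("parameter pair must be distinct")
    from .calibrate import nominal_value
    v1 = nominal_value(params, mod, p1)
    v2 = nominal_value(params, mod, p2)
    g1 = np.linspace(v1 * (1 - rel_range), v1 * (1 + rel_range), grid_size)
    g2 = np.linspace(v2 * (1 - rel_range), v2 * (1 + rel_range), grid_size)
    rows = []
    for a in g1:
        for b in g2:
            p_i, m_i = apply_theta(params, mod, [p1, p2],
                                   np.array([a, b]))
            y = steady_state_direct(p_i, m_i, age)
            obs = observables_from_state(y, blood_volume(age, m_i.body))
            rows.append({p1: float(a), p2: float(b), "age": age,
                         "output": output, "value": float(obs[output])})
    return pd.DataFrame(rows)
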