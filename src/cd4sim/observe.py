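"""Mapping model states to measurable quantities, and the fit metrics.

The calibration data are 20 steady-state observables: blood concentrations
(cells/uL) of the six peripheral subpopulations, and within-organ
percentages of the subpopulations present in lymphoid tissue (all six) and
in gut and lung (N, CM, EM, EFF).  Validation uses derived totals: total
CD4 and total memory (CM+EM) blood concentration and per-organ total
counts.  Observation noise is proportional (fixed CV per observable), so
the likelihood is Gaussian with sd = CV * |prediction|.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .layout import LAYOUT, STATE_LABELS

#: subpopulations observed per compartment
BLOOD_SUBSETS = ("RTE", "N", "A", "CM", "EM", "EFF")
ORGAN_SUBSETS = {"LT": ("RTE", "N", "A", "CM", "EM", "EFF"),
                 "GIT": ("N", "CM", "EM", "EFF"),
                 "LUNG": ("N", "CM", "EM", "EFF")}

#: the 20 calibration observable ids, in canonical order
CALIBRATION_OBSERVABLES: tuple[str, ...] = tuple(
    [f"BL_{s}_conc" for s in BLOOD_SUBSETS]
    + [f"LT_{s}_pct" for s in ORGAN_SUBSETS["LT"]]
    + [f"GIT_{s}_pct" for s in ORGAN_SUBSETS["GIT"]]
    + [f"LUNG_{s}_pct" for s in ORGAN_SUBSETS["LUNG"]]
)

VALIDATION_OBSERVABLES: tuple[str, ...] = (
    "BL_total_conc", "BL_memory_conc", "LT_memory_pct",
    "BL_total_count", "LT_total_count", "GIT_total_count", "LUNG_total_count",
)


def observables_from_state(counts: np.ndarray, bv_litres: float) -> pd.Series:
    """All observables for one state vector.

    Blood concentrations are count / (BV * 1e6) cells/uL; organ
    percentages are 100 * count / (total CD4 count in that organ).  An
    organ with zero total yields 0% entries and is listed in
    ``result.attrs['degenerate_compartments']``.
    """
    if bv_litres <= 0:
        raise ValueError("blood volume must be positive")
    counts = np.asarray(counts, dtype=float)
    out: dict[str, float] = {}
    ul = bv_litres * 1.0e6
    for s in BLOOD_SUBSETS:
        out[f"BL_{s}_conc"] = counts[LAYOUT.idx(s, "BL")] / ul
    degenerate = []
    for comp, subs in ORGAN_SUBSETS.items():
        tot = sum(counts[LAYOUT.idx(s, comp)] for s in subs)
        if tot <= 0:
            degenerate.append(comp)
            for s in subs:
                out[f"{comp}_{s}_pct"] = 0.0
        else:
            for s in subs:
                out[f"{comp}_{s}_pct"] = 100.0 * counts[LAYOUT.idx(s, comp)] / tot
    out["BL_total_conc"] = sum(out[f"BL_{s}_conc"] for s in BLOOD_SUBSETS)
    out["BL_memory_conc"] = out["BL_CM_conc"] + out["BL_EM_conc"]
    lt_tot = sum(counts[LAYOUT.idx(s, "LT")] for s in ORGAN_SUBSETS["LT"])
    out["LT_memory_pct"] = (0.0 if lt_tot <= 0 else 100.0 * (
        counts[LAYOUT.idx("CM", "LT")] + counts[LAYOUT.idx("EM", "LT")]) / lt_tot)
    for comp in ("BL", "LT", "GIT", "LUNG"):
        out[f"{comp}_total_count"] = float(sum(
            counts[j] for j, (s, c) in enumerate(STATE_LABELS)
            if c == comp and s not in ("DN", "DP", "SP4", "SP8")))
    res = pd.Series(out)
    res.attrs["degenerate_compartments"] = degenerate
    return res


def reference_cd4_counts(total_t_cells: float, cd4_cd8_ratio: float) -> float:
    """CD4+ share of a total T-cell count given a CD4:CD8 ratio."""
    if total_t_cells < 0:
        raise ValueError("total count must be non-negative")
    if cd4_cd8_ratio <= 0:
        raise ValueError("CD4:CD8 ratio must be positive")
    return total_t_cells * cd4_cd8_ratio / (1.0 + cd4_cd8_ratio)


def percent_difference(predicted: float, observed: float) -> float:
    """Absolute percentage difference, relative to the observation."""
    if observed <= 0:
        raise ValueError("observed value must be positive")
    return 100.0 * abs(predicted - observed) / observed


# ---------------------------------------------------------------------------
# calibration dataset container
# ---------------------------------------------------------------------------

DATASET_COLUMNS = ["observable_id", "compartment", "subpopulation",
                   "age_lo", "age_hi", "mean", "ci_lo", "ci_hi", "cv", "role"]


@dataclass
class CalibrationDataset:
    """Age-binned observable means with CIs and proportional-error CVs."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(DATASET_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"dataset missing column(s): {sorted(missing)}")
        t = self.table
        if (t["age_lo"] > t["age_hi"]).any():
            raise ValueError("age_lo must not exceed age_hi")
        bad = (t["ci_lo"] > t["mean"]) | (t["ci_hi"] < t["mean"])
        if bad.any():
            raise ValueError("confidence interval must bracket the mean")
        if (t["cv"] <= 0).any():
            raise ValueError("CVs must be positive")

    @property
    def calibration(self) -> pd.DataFrame:
        return self.table[self.table["role"] == "calibration"]

    @property
    def validation(self) -> pd.DataFrame:
        return self.table[self.table["role"] == "validation"]

    def age_mid(self) -> np.ndarray:
        """Regressor age per row: bin midpoint (lo == hi uses that age)."""
        return ((self.table["age_lo"] + self.table["age_hi"]) / 2.0).to_numpy()

    @staticmethod
    def cv_from_ci(mean: float, ci_hi: float) -> float:
        """Proportional-error CV implied by a 95% CI half-width."""
        if mean <= 0:
            raise ValueError("mean must be positive")
        return (ci_hi - mean) / (1.96 * mean)

    def to_csv(self, path: str | Path) -> None:
        self.table[DATASET_COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CalibrationDataset":
        t = pd.read_csv(path)
        if "cv" not in t.columns or t["cv"].isna().any():
            t["cv"] = [
                cls.cv_from_ci(m, hi) if (pd.isna(c) or c <= 0) else c
                for m, hi, c in zip(t["mean"], t["ci_hi"],
                                    t.get("cv", [np.nan] * len(t)))]
        return cls(t)


# ---------------------------------------------------------------------------
# likelihood, information criteria, identifiability
# ---------------------------------------------------------------------------

#: contribution reported when a zero prediction meets a nonzero observation
_FLAGGED_LARGE = 1.0e10


def proportional_loglik(predicted: np.ndarray,
                        data: CalibrationDataset | pd.DataFrame) -> float:
    """Negative log-likelihood under the proportional-error model.

    ``predicted`` must align row-for-row with the dataset; per row
    sd = cv * |prediction|.  Rows where the prediction is exactly zero but
    the observation is not contribute a flagged large value instead of an
    infinity so optimizers can still rank candidates.
    """
    t = data.table if isinstance(data, CalibrationDataset) else data
    pred = np.asarray(predicted, dtype=float)
    if pred.shape != (len(t),):
        raise ValueError("prediction vector does not match dataset rows")
    obs = t["mean"].to_numpy(float)
    cv = t["cv"].to_numpy(float)
    sd = cv * np.abs(pred)
    nll = 0.0
    for o, p, s in zip(obs, pred, sd):
        if s == 0.0:
            if o == 0.0 and p == 0.0:
                continue
            nll += _FLAGGED_LARGE
            continue
        nll += 0.5 * np.log(2.0 * np.pi * s * s) + (o - p) ** 2 / (2.0 * s * s)
    return float(nll)


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood calibration."""

    variant: str
    estimates: dict[str, float]
    fixed: dict[str, float]
    nll: float
    aic: float
    rse: dict[str, float] = field(default_factory=dict)
    unidentifiable: list[str] = field(default_factory=list)
    n_starts: int = 0
    n_converged: int = 0
    seed: int | None = None

    @property
    def k(self) -> int:
        return len(self.estimates)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FitResult":
        return cls(**json.loads(Path(path).read_text()))


def aic(nll: float, k: int) -> float:
    """Akaike information criterion, 2k + 2*NLL (fixed-CV convention)."""
    return 2.0 * k + 2.0 * nll


def aic_compare(fits: list[FitResult]) -> FitResult:
    """Lowest-AIC fit; ties broken by fewer estimated parameters, then order."""
    if not fits:
        raise ValueError("no fits to compare")
    for f in fits:
        if not np.isfinite(f.aic):
            raise ValueError(f"non-finite AIC in variant {f.variant}")
    return min(enumerate(fits), key=lambda kv: (kv[1].aic, kv[1].k, kv[0]))[1]


RSE_THRESHOLD = 51.0


def rse_estimate(nll_fn, theta: np.ndarray, names: list[str],
                 rel_step: float = 1.0e-4) -> tuple[dict[str, float], list[str]]:
    """Relative standard errors from the observed information at the optimum.

    Central-difference Hessian of the NLL; SE = sqrt(diag(H^-1));
    RSE = 100*SE/|estimate|.  Parameters with RSE above 51% — or with a
    singular / non-positive information matrix — are flagged unidentifiable.
    """
    theta = np.asarray(theta, dtype=float)
    n = len(theta)
    h = rel_step * np.maximum(np.abs(theta), 1.0e-8)
    hess = np.empty((n, n))
    f0 = nll_fn(theta)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            if i == j:
                val = (nll_fn(theta + ei) - 2.0 * f0 + nll_fn(theta - ei)) / h[i] ** 2
            else:
                val = (nll_fn(theta + ei + ej) - nll_fn(theta + ei - ej)
                       - nll_fn(theta - ei + ej) + nll_fn(theta - ei - ej)
                       ) / (4.0 * h[i] * h[j])
            hess[i, j] = hess[j, i] = val
    rse: dict[str, float] = {}
    flagged: list[str] = []
    try:
        cov = np.linalg.inv(hess)
        var = np.diag(cov)
    except np.linalg.LinAlgError:
        var = np.full(n, np.nan)
    for i, name in enumerate(names):
        if not np.isfinite(var[i]) or var[i] <= 0:
            rse[name] = float("nan")
            flagged.append(name)
            continue
        r = 100.0 * np.sqrt(var[i]) / max(abs(theta[i]), 1.0e-300)
        rse[name] = float(r)
        if r > RSE_THRESHOLD:
            flagged.append(name)
    return rse, flagged


def ci_overlap_score(observed: pd.DataFrame, predicted: pd.DataFrame,
                     limit_fraction: float = 0.30) -> float:
    """Share of rows whose 95% CIs overlap or whose CI-limit gap is small.

    A row counts as described when the observed and predicted intervals
    overlap, or when both CI-limit differences stay within
    ``limit_fraction`` of the observed values.
    """
    hits = 0
    for (_, o), (_, p) in zip(observed.iterrows(), predicted.iterrows()):
        overlap = (o["ci_lo"] <= p["ci_hi"]) and (p["ci_lo"] <= o["ci_hi"])
        close = (abs(p["ci_lo"] - o["ci_lo"]) <= limit_fraction * abs(o["ci_lo"])
                 and abs(p["ci_hi"] - o["ci_hi"]) <= limit_fraction * abs(o["ci_hi"]))
        hits += overlap or close
    return 100.0 * hits / max(len(observed), 1)
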