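"""Synthetic calibration datasets and thymectomy cohorts.

The generator emulates the statistical structure of a meta-analytic
calibration table: per observable and age bin, a weighted-average
concentration (blood, cells/uL) or within-organ percentage, with
multiplicative lognormal noise of fixed CV (the proportional-error model)
and a 95% CI whose half-width shrinks with the synthetic number of pooled
studies.  Generating parameters default to the packaged calibrated model,
so round-trip recovery experiments have a known truth.

Printed literature anchors (newborn blood totals, whole-body T-cell
counts, CD4:CD8 ratios, reference predicted maxima) ship as a small CSV
fixture for the validation-arithmetic workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .agefun import (AGE_PLUS_FEEDBACK, AgeModulationSet, blood_volume,
                     default_modulations)
from .layout import DAYS_PER_YEAR
from .model import steady_state_direct
from .observe import (CALIBRATION_OBSERVABLES, CalibrationDataset,
                      DATASET_COLUMNS, observables_from_state)
from .parameters import KineticParameterSet
from .perturb import (THYMECTOMY_GROUPS, ThymectomyScenario,
                      simulate_thymectomy)

#: default age-bin schemes (years): denser for blood, sparser for tissue
BLOOD_BINS = ((0.0, 0.25), (0.25, 1.0), (1.0, 5.0), (5.0, 18.0),
              (18.0, 40.0), (40.0, 60.0), (60.0, 80.0))
TISSUE_BINS = ((0.0, 18.0), (18.0, 60.0))

VALIDATION_IDS = ("BL_total_conc", "BL_memory_conc", "LT_memory_pct")


@dataclass
class SyntheticSpec:
    """Everything needed to generate a reproducible calibration dataset."""

    params: KineticParameterSet = field(default_factory=KineticParameterSet)
    modulation: AgeModulationSet = field(
        default_factory=lambda: default_modulations(AGE_PLUS_FEEDBACK))
    blood_bins: tuple = BLOOD_BINS
    tissue_bins: tuple = TISSUE_BINS
    cv_blood: float = 0.10
    cv_tissue: float = 0.15
    n_synthetic_studies: int = 6
    noiseless: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_blood <= 0 or self.cv_tissue <= 0:
            raise ValueError("CVs must be positive")
        for bins in (self.blood_bins, self.tissue_bins):
            for (l1, h1), (l2, h2) in zip(bins, bins[1:]):
                if h1 > l2:
                    raise ValueError("age bins must not overlap")


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Multiplicative noise with unit mean and the requested CV."""
    sigma2 = np.log1p(cv * cv)
    return float(np.exp(rng.normal(0.0, np.sqrt(sigma2)) - sigma2 / 2.0))


def generate_calibration_dataset(spec: SyntheticSpec) -> CalibrationDataset:
    """Steady-state predictions per bin midpoint, with proportional noise.

    Contains the 20 calibration observables plus derived validation
    totals.  In ``noiseless`` mode means equal model predictions exactly.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    cache: dict[float, pd.Series] = {}

    def predict(age: float) -> pd.Series:
        if age not in cache:
            y = steady_state_direct(spec.params, spec.modulation, age)
            cache[age] = observables_from_state(
                y, blood_volume(age, spec.modulation.body))
        return cache[age]

    for obs_id in CALIBRATION_OBSERVABLES + VALIDATION_IDS:
        comp, sub, kind = obs_id.split("_")
        is_blood = kind == "conc"
        bins = spec.blood_bins if is_blood else spec.tissue_bins
        cv = spec.cv_blood if is_blood else spec.cv_tissue
        role = "validation" if sub in ("total", "memory") else "calibration"
        for lo, hi in bins:
            mid = (lo + hi) / 2.0
            pred = float(predict(mid)[obs_id])
            mean = pred if spec.noiseless else pred * _lognormal_factor(rng, cv)
            half = 1.96 * cv * mean / np.sqrt(spec.n_synthetic_studies)
            rows.append({"observable_id": obs_id, "compartment": comp,
                         "subpopulation": sub, "age_lo": lo, "age_hi": hi,
                         "mean": mean, "ci_lo": mean - half,
                         "ci_hi": mean + half, "cv": cv, "role": role})
    return CalibrationDataset(pd.DataFrame(rows, columns=DATASET_COLUMNS))


def generate_thymectomy_cohort(n_subjects: int,
                               group_mix: dict[str, int],
                               spec: SyntheticSpec,
                               *, observation_offsets=(0.5, 1.0, 2.0, 5.0),
                               cv: float = 0.10,
                               noiseless: bool = False) -> pd.DataFrame:
    """Per-subject post-thymectomy blood concentration trajectories.

    ``group_mix`` maps age-at-surgery group labels to subject counts and
    must sum to ``n_subjects``; surgery ages are sampled uniformly within
    each group's bounds (the open-ended oldest group is capped at 6 y).
    """
    if not group_mix:
        raise ValueError("group mix must not be empty")
    if sum(group_mix.values()) != n_subjects:
        raise ValueError("group mix must sum to n_subjects")
    bounds = {label: (lo, min(hi, 6.0)) for label, lo, hi in THYMECTOMY_GROUPS}
    unknown = set(group_mix) - set(bounds)
    if unknown:
        raise ValueError(f"unknown group label(s): {sorted(unknown)}")
    rng = np.random.default_rng(spec.seed)
    records = []
    sid = 0
    for label, count in group_mix.items():
        lo, hi = bounds[label]
        for _ in range(count):
            age_s = float(rng.uniform(lo, hi))
            obs_ages = tuple(age_s + o for o in observation_offsets)
            scen = ThymectomyScenario(age_s, obs_ages)
            res = simulate_thymectomy(scen, spec.params, spec.modulation)
            obs = res.observables("thymectomized")
            for a in obs_ages:
                i = int(np.argmin(np.abs(obs.index.to_numpy() - a)))
                for key in ("BL_total_conc", "BL_N_conc", "BL_RTE_conc"):
                    val = float(obs[key].iloc[i])
                    if not noiseless:
                        val *= _lognormal_factor(rng, cv)
                    records.append({"subject_id": sid, "group": label,
                                    "age_at_surgery": age_s,
                                    "obs_age": float(obs.index[i]),
                                    "observable_id": key, "value": val})
            sid += 1
    return pd.DataFrame(records)


def load_anchors() -> pd.DataFrame:
    """Printed literature anchor values packaged with the model."""
    with resources.files("cd4sim").joinpath("data/anchors.csv").open() as fh:
        return pd.read_csv(fh).set_index("key")
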