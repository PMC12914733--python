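"""Age- and cell-count-dependent modulation of kinetic rates.

Three nested model variants are supported:

* ``STATIC`` — only thymic niche capacities and blood volume change with
  age; every kinetic rate keeps its base value.
* ``AGE`` — thirteen empirical age functions additionally modulate
  peripheral rates.  Saturating (Hill-type hyperbolic) forms are the
  default: ``base * (1 + amax * age^h / (age50^h + age^h))`` for rates that
  rise with age and ``base * (1 - dmax * age^h / (age50^h + age^h))`` for
  rates that fall.  Six of the falling rates use ``dmax = 1`` (complete
  shutdown in the old-age limit); the naive-proliferation and CM->EM
  dependencies use sharp Hill coefficients (10 and 3); five late-life
  trafficking dependencies share a single half-effect age.
* ``AGE_PLUS_FEEDBACK`` — the age functions on naive proliferation
  (``lamN4``) and RTE death (``muRTE4``) are replaced by feedback on the
  blood RTE concentration: proliferation falls, and RTE death rises, as a
  steep Hill function of RTE cells/uL.  The remaining eleven age functions
  persist.  This couples peripheral homeostasis to thymic output and is
  what lets the model adapt to perturbations such as thymectomy.

Alternative empirical forms (linear, exponential, quadratic) are provided
for the stepwise age-function selection workflow only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

from .parameters import KineticParameterSet

STATIC = "STATIC"
AGE = "AGE"
AGE_PLUS_FEEDBACK = "AGE_PLUS_FEEDBACK"
VARIANTS = (STATIC, AGE, AGE_PLUS_FEEDBACK)

#: rates modulated upward / downward with age in the AGE variant
AGE_UP = ("lamN4", "lamA4", "omegaEM4lung_bl",
          "omegaEFF4bl_git", "omegaEFF4bl_lung", "omegaEFF4bl_tis")
AGE_DOWN = ("muRTE4", "omegaRTE4bl_lt", "phiCM4", "phiEM4",
            "omegaA4lt_bl", "omegaCM4lt_bl", "omegaEFF4lt_bl")

#: falling rates whose maximal relative decrease is pinned at 1 (100%)
DMAX_ONE = ("omegaRTE4bl_lt", "phiCM4", "phiEM4",
            "omegaA4lt_bl", "omegaCM4lt_bl", "omegaEFF4lt_bl")

#: members of the shared late-life half-effect-age group
SHARED_AGE50_GROUP = ("phiEM4", "omegaEM4lung_bl",
                      "omegaEFF4bl_git", "omegaEFF4bl_lung", "omegaEFF4bl_tis")

FORMS = ("hyperbolic", "linear", "exponential", "quadratic")


# ---------------------------------------------------------------------------
# elementary age / feedback functions
# ---------------------------------------------------------------------------

def hill_up(age: float, base: float, amax: float, age50: float, h: float) -> float:
    """Saturating increase: base at age 0, base*(1+amax) in the old-age limit."""
    if age50 <= 0:
        raise ValueError("age50 must be positive")
    if age < 0:
        raise ValueError("age must be non-negative")
    frac = age**h / (age50**h + age**h) if age > 0 else 0.0
    return base * (1.0 + amax * frac)


def hill_down(age: float, base: float, dmax: float, age50: float, h: float) -> float:
    """Saturating decrease: base at age 0, base*(1-dmax) in the old-age limit."""
    if not 0.0 <= dmax <= 1.0:
        raise ValueError("dmax must lie in [0, 1]")
    if age50 <= 0:
        raise ValueError("age50 must be positive")
    if age < 0:
        raise ValueError("age must be non-negative")
    frac = age**h / (age50**h + age**h) if age > 0 else 0.0
    return base * (1.0 - dmax * frac)


def feedback_naive_prolif(c_rte: float, lam_base: float, amax: float,
                          c50: float, nh: float = 10.0) -> float:
    """Naive proliferation vs blood RTE concentration (cells/uL).

    Equals ``lam_base`` when no RTE cells circulate and falls by a fraction
    ``amax`` once the RTE concentration exceeds ``c50``; the steep Hill
    coefficient (default 10) makes the transition switch-like.
    """
    if c_rte < 0:
        raise ValueError("concentration must be non-negative")
    if not 0.0 <= amax <= 1.0:
        raise ValueError("amax must lie in [0, 1]")
    frac = c_rte**nh / (c50**nh + c_rte**nh) if c_rte > 0 else 0.0
    return lam_base * (1.0 - amax * frac)


def feedback_rte_death(c_rte: float, mu_base: float, bmax: float,
                       c50: float, nh: float = 10.0) -> float:
    """RTE death rate vs blood RTE concentration: rises from ``mu_base``."""
    if c_rte < 0:
        raise ValueError("concentration must be non-negative")
    frac = c_rte**nh / (c50**nh + c_rte**nh) if c_rte > 0 else 0.0
    return mu_base * (1.0 + bmax * frac)


@dataclass(frozen=True)
class BodyConstants:
    """Body-weight / blood-volume growth and thymus wet-weight involution."""

    bw_birth_kg: float = 3.5
    bw_adult_kg: float = 70.0
    bw_growth_rate: float = 0.226   # Gompertz rate, 1/years (~95% adult mass at 18 y)
    bv_adult_l: float = 5.0
    # thymus wet weight W(age) = W_birth*(1+g*(1-exp(-age/tau_g)))*exp(-k_inv*age)
    wet_weight_birth_g: float = 15.0
    wet_weight_gain: float = 1.5    # g: early post-natal growth, fold-change
    wet_weight_tau_g: float = 0.5   # years
    involution_rate: float = 0.044  # 1/years, exponential involution
    # niche capacities at birth wet weight (cells); reconstructed scale
    cortical_capacity_birth: float = 3.2e9
    medullary_capacity_birth: float = 1.28e9


def body_weight(age: float, c: BodyConstants) -> float:
    """Gompertz body-weight growth curve (kg)."""
    lr = math.log(c.bw_adult_kg / c.bw_birth_kg)
    return c.bw_adult_kg * math.exp(-lr * math.exp(-c.bw_growth_rate * age))


def blood_volume(age: float, c: BodyConstants | None = None) -> float:
    """Total blood volume (litres), scaled to body weight."""
    if age < 0:
        raise ValueError("age must be non-negative")
    c = c or BodyConstants()
    return c.bv_adult_l * body_weight(age, c) / c.bw_adult_kg


def thymus_wet_weight(age: float, c: BodyConstants) -> float:
    growth = 1.0 + c.wet_weight_gain * (1.0 - math.exp(-age / c.wet_weight_tau_g))
    return c.wet_weight_birth_g * growth * math.exp(-c.involution_rate * age)


def thymus_capacity(age: float, c: BodyConstants | None = None) -> tuple[float, float]:
    """Cortical and medullary niche capacities (cells) at a given age.

    Both scale with the thymus wet-weight curve: rapid growth peaking in
    the first couple of years of life, then exponential involution.
    """
    if age < 0:
        raise ValueError("age must be non-negative")
    c = c or BodyConstants()
    rel = thymus_wet_weight(age, c) / thymus_wet_weight(0.0, c)
    return c.cortical_capacity_birth * rel, c.medullary_capacity_birth * rel


# ---------------------------------------------------------------------------
# modulation bookkeeping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Modulation:
    """One empirical dependency of a kinetic rate on age."""

    target: str
    direction: Literal["up", "down"]
    max_change: float           # amax (up) or dmax (down), relative
    half_effect: float          # age50 in years (hyperbolic); rate for others
    hill: float = 1.0
    form: str = "hyperbolic"
    group: str | None = None    # shared-age50 group id

    def value(self, age: float, base: float) -> float:
        if self.form == "hyperbolic":
            f = hill_up if self.direction == "up" else hill_down
            return f(age, base, self.max_change, self.half_effect, self.hill)
        if self.form == "linear":
            s = self.half_effect
            x = 1.0 + s * age if self.direction == "up" else 1.0 - s * age
            return base * max(x, 0.0)
        if self.form == "exponential":
            k = self.half_effect
            sign = 1.0 if self.direction == "up" else -1.0
            return base * math.exp(sign * k * age)
        if self.form == "quadratic":
            s = self.half_effect
            x = 1.0 + s * age * age if self.direction == "up" else 1.0 - s * age * age
            return base * max(x, 0.0)
        raise ValueError(f"unknown form {self.form!r}")


@dataclass(frozen=True)
class FeedbackConstants:
    """RTE-concentration feedback replacing the lamN4/muRTE4 age functions."""

    lamN4_base: float = 0.0012     # naive proliferation at zero RTE conc, 1/d
    lamN4_max: float = 0.4166667   # maximal relative decrease -> 0.0007 when RTE high
    lamN4_c50: float = 22.0        # cells/uL
    lamN4_hill: float = 10.0
    muRTE4_base: float = 0.00304   # RTE death at zero RTE conc, 1/d
    muRTE4_max: float = 1.5        # maximal relative increase -> 0.0076 when RTE high
    muRTE4_c50: float = 70.0       # engages by young adulthood, earlier than
                                   # the naive-proliferation adaptation
    muRTE4_hill: float = 10.0


@dataclass(frozen=True)
class AgeModulationSet:
    """Variant selector plus all age/feedback modulation constants."""

    variant: str = STATIC
    modulations: tuple[Modulation, ...] = ()
    feedback: FeedbackConstants = field(default_factory=FeedbackConstants)
    body: BodyConstants = field(default_factory=BodyConstants)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        seen = set()
        for m in self.modulations:
            if m.target in seen:
                raise ValueError(f"duplicate modulation for {m.target}")
            seen.add(m.target)

    def active_modulations(self) -> tuple[Modulation, ...]:
        if self.variant == STATIC:
            return ()
        if self.variant == AGE_PLUS_FEEDBACK:
            return tuple(m for m in self.modulations
                         if m.target not in ("lamN4", "muRTE4"))
        return self.modulations

    def with_variant(self, variant: str) -> "AgeModulationSet":
        return replace(self, variant=variant)


def default_modulations(variant: str = AGE_PLUS_FEEDBACK) -> AgeModulationSet:
    """The packaged calibrated modulation set.

    Constants reproduce the anchored behaviour of the calibrated model:
    naive proliferation shifts from 0.0007/d to 0.0012/d across the late-life
    transition (Hill 10), the six ``DMAX_ONE`` rates decay toward zero, and
    the five late-life trafficking dependencies share a half-effect age.
    """
    mods = (
        # rising with age
        Modulation("lamN4", "up", 0.7142857, 55.0, hill=10.0),
        Modulation("lamA4", "up", 0.026, 10.0),
        Modulation("omegaEM4lung_bl", "up", 1.0, 20.0, group="late"),
        Modulation("omegaEFF4bl_git", "up", 1.0, 20.0, group="late"),
        Modulation("omegaEFF4bl_lung", "up", 1.0, 20.0, group="late"),
        Modulation("omegaEFF4bl_tis", "up", 1.0, 20.0, group="late"),
        # falling with age
        Modulation("muRTE4", "down", 0.6, 50.0, hill=10.0),
        Modulation("omegaRTE4bl_lt", "down", 1.0, 40.0),
        Modulation("phiCM4", "down", 1.0, 40.0, hill=3.0),
        Modulation("phiEM4", "down", 1.0, 20.0, group="late"),
        Modulation("omegaA4lt_bl", "down", 1.0, 60.0),
        Modulation("omegaCM4lt_bl", "down", 1.0, 60.0),
        Modulation("omegaEFF4lt_bl", "down", 1.0, 60.0),
    )
    return AgeModulationSet(variant=variant, modulations=mods)


# ---------------------------------------------------------------------------
# effective rate assembly
# ---------------------------------------------------------------------------

class EffectiveRates:
    """Kinetic rates after age/feedback modulation, plus physiology terms.

    Attribute access mirrors :class:`KineticParameterSet`; additionally
    carries ``Tcortmax``/``Tmedmax`` (cells) and ``BV`` (litres).
    """

    __slots__ = ("values", "Tcortmax", "Tmedmax", "BV")

    def __init__(self, values: dict[str, float],
                 tcort: float, tmed: float, bv: float):
        self.values = values
        self.Tcortmax = tcort
        self.Tmedmax = tmed
        self.BV = bv

    def __getattr__(self, name: str) -> float:
        try:
            return self.values[name]
        except KeyError:
            raise AttributeError(name) from None


def effective_parameters(age: float, c_rte: float,
                         base: KineticParameterSet,
                         mod: AgeModulationSet) -> EffectiveRates:
    """Evaluate all rates at a given age and blood RTE concentration.

    ``c_rte`` (cells/uL) is only consulted in the ``AGE_PLUS_FEEDBACK``
    variant; elsewhere rates depend on age alone.
    """
    vals = base.to_dict()
    for m in mod.active_modulations():
        if m.target not in vals:
            raise ValueError(f"modulation targets unknown parameter {m.target!r}")
        vals[m.target] = m.value(age, vals[m.target])
    if mod.variant == AGE_PLUS_FEEDBACK:
        fb = mod.feedback
        vals["lamN4"] = feedback_naive_prolif(
            c_rte, fb.lamN4_base, fb.lamN4_max, fb.lamN4_c50, fb.lamN4_hill)
        vals["muRTE4"] = feedback_rte_death(
            c_rte, fb.muRTE4_base, fb.muRTE4_max, fb.muRTE4_c50, fb.muRTE4_hill)
    tcort, tmed = thymus_capacity(age, mod.body)
    bv = blood_volume(age, mod.body)
    return EffectiveRates(vals, tcort, tmed, bv)
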