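"""Kinetic rate constants of the CD4+ T-cell homeostasis model.

Peripheral rates are first-order constants in d^-1 (except ``f4``, a
dimensionless fraction, and ``TA4max``, a whole-body carrying capacity in
cells).  Naming convention: ``mu`` death, ``lam`` proliferation, ``phi``
differentiation, ``omega<SUB>4<from>_<to>`` migration.  The thymocyte
submodel constants (``thy_*``) are a reconstruction of a published
thymopoiesis model: logistic growth of DN and DP limited by the cortical
niche capacity, a DP split into SP4/SP8, logistic SP growth limited by the
medullary capacity, and first-order SP4 egress into blood as RTE cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from pathlib import Path
from typing import ClassVar


@dataclass
class KineticParameterSet:
    # --- RTE ---
    muRTE4: float = 0.0076          # death rate of RTE cells
    omegaRTE4bl_lt: float = 0.217   # RTE blood -> lymphoid tissue
    phiRTE4: float = 0.0012         # RTE -> naive differentiation (in LT)
    # --- naive ---
    muN4: float = 0.000457
    lamN4: float = 0.0007
    phiN4: float = 0.0012           # naive -> activated (in LT)
    omegaN4lt_bl: float = 1.64
    omegaN4bl_lt: float = 40.0
    omegaN4bl_git: float = 0.0003
    omegaN4bl_lung: float = 0.0003
    omegaN4bl_tis: float = 0.0003   # loss to unmodelled peripheral tissues
    omegaN4git_bl: float = 0.00075
    omegaN4lung_bl: float = 0.00075
    # --- activated ---
    lamA4: float = 1.725            # logistic proliferation, capacity TA4max
    phiA4: float = 1.727            # activated -> CM/EFF differentiation (in LT)
    muA4: float = 0.04
    omegaA4lt_bl: float = 4.06
    omegaA4bl_lt: float = 40.0
    omegaA4bl_tis: float = 0.0003
    f4: float = 0.4                 # fraction of activated output routed to CM
    TA4max: float = 1.0e13          # carrying capacity of activated proliferation
    # --- central-memory ---
    lamCM4: float = 0.0391
    muCM4: float = 0.041
    phiCM4: float = 0.111           # CM -> EM, acts wherever CM resides
    omegaCM4lt_bl: float = 0.334
    omegaCM4bl_lt: float = 10.0
    omegaCM4bl_git: float = 0.12
    omegaCM4bl_lung: float = 0.12
    omegaCM4bl_tis: float = 0.12
    omegaCM4git_bl: float = 0.09
    omegaCM4lung_bl: float = 0.09
    # --- effector-memory ---
    lamEM4: float = 0.042
    muEM4: float = 0.11
    phiEM4: float = 0.035           # EM -> EFF, acts wherever EM resides
    omegaEM4lt_bl: float = 0.035
    omegaEM4bl_git: float = 0.882
    omegaEM4bl_lung: float = 0.882
    omegaEM4bl_tis: float = 0.882
    omegaEM4git_bl: float = 0.04
    omegaEM4lung_bl: float = 0.04
    # --- effector ---
    muEFF4: float = 0.87
    omegaEFF4lt_bl: float = 0.253
    omegaEFF4bl_git: float = 0.087
    omegaEFF4bl_lung: float = 0.087
    omegaEFF4bl_tis: float = 0.087
    # --- thymocyte submodel (reconstructed defaults) ---
    thy_lamDN: float = 0.30         # DN logistic proliferation
    thy_phiDN: float = 0.07         # DN -> DP
    thy_muDN: float = 0.01
    thy_lamDP: float = 0.30         # DP logistic proliferation (cortical niche)
    thy_phiDP: float = 0.35         # DP -> SP (positive selection survivors)
    thy_muDP: float = 0.32          # failed selection
    thy_fSP4: float = 0.67          # fraction of selected DP committing to SP4
    thy_lamSP: float = 0.05         # SP logistic proliferation (medullary niche)
    thy_muSP: float = 0.05
    thy_epsSP4: float = 0.10        # SP4 egress -> RTE in blood
    thy_epsSP8: float = 0.10        # SP8 egress (CD8 lineage, leaves the model)

    #: parameters estimated (rather than fixed) in the reference calibration
    ESTIMATED: ClassVar[tuple[str, ...]] = (
        "omegaRTE4bl_lt", "phiN4", "omegaN4lt_bl", "omegaN4git_bl",
        "omegaN4lung_bl", "phiA4", "omegaA4lt_bl", "omegaCM4lt_bl",
        "omegaCM4git_bl", "omegaCM4lung_bl", "phiEM4", "omegaEM4bl_git",
        "omegaEM4bl_lung", "omegaEM4bl_tis", "muEFF4", "omegaEFF4lt_bl",
        "omegaEFF4bl_git", "omegaEFF4bl_lung", "omegaEFF4bl_tis",
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and v < 0:
                raise ValueError(f"rate {f.name} must be non-negative, got {v}")
        if not 0.0 <= self.f4 <= 1.0 or not 0.0 <= self.thy_fSP4 <= 1.0:
            raise ValueError("routing fractions must lie in [0, 1]")
        if self.TA4max <= 0:
            raise ValueError("TA4max must be positive")

    # -- dict / JSON round trips ------------------------------------------
    def to_dict(self) -> dict:
        return dict(self.__dict__)

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParameterSet":
        known = {f.name for f in fields(cls) if f.name != "ESTIMATED"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def replace(self, **kw: float) -> "KineticParameterSet":
        d = self.to_dict()
        d.update(kw)
        return KineticParameterSet.from_dict(d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "KineticParameterSet":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def names(self) -> list[str]:
        return [f.name for f in fields(self) if f.name != "ESTIMATED"]
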