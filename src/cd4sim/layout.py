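"""State-vector layout for the 24-compartment CD4+ T-cell model.

The model tracks four thymocyte populations (DN, DP, SP4, SP8) inside the
thymus and six peripheral CD4+ subpopulations — recent thymic emigrants
(RTE), naive (N), activated (A), central-memory (CM), effector-memory (EM)
and effector (EFF) cells — distributed over blood (BL), lymphoid tissue
(LT), the gastro-intestinal tract (GIT) and lungs (LUNG).  Not every
subpopulation occupies every organ: RTE and A recirculate only between
blood and lymphoid tissue, while N, CM, EM and EFF also reach gut and lung.
"""

from __future__ import annotations

from dataclasses import dataclass, field

SUBPOPULATIONS = ("DN", "DP", "SP4", "SP8", "RTE", "N", "A", "CM", "EM", "EFF")
COMPARTMENTS = ("THY", "BL", "LT", "GIT", "LUNG")

#: (subpopulation, compartment) pairs, in state-vector order.
STATE_LABELS: tuple[tuple[str, str], ...] = (
    ("DN", "THY"),
    ("DP", "THY"),
    ("SP4", "THY"),
    ("SP8", "THY"),
    ("RTE", "BL"),
    ("RTE", "LT"),
    ("N", "BL"),
    ("N", "LT"),
    ("N", "GIT"),
    ("N", "LUNG"),
    ("A", "BL"),
    ("A", "LT"),
    ("CM", "BL"),
    ("CM", "LT"),
    ("CM", "GIT"),
    ("CM", "LUNG"),
    ("EM", "BL"),
    ("EM", "LT"),
    ("EM", "GIT"),
    ("EM", "LUNG"),
    ("EFF", "BL"),
    ("EFF", "LT"),
    ("EFF", "GIT"),
    ("EFF", "LUNG"),
)

N_STATES = len(STATE_LABELS)

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class CompartmentLayout:
    """Bijective mapping between (subpopulation, compartment) labels and indices."""

    labels: tuple[tuple[str, str], ...] = STATE_LABELS
    index: dict[tuple[str, str], int] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "index", {lab: i for i, lab in enumerate(self.labels)}
        )
        if len(self.index) != len(self.labels):
            raise ValueError("state labels are not unique")

    def __len__(self) -> int:
        return len(self.labels)

    def idx(self, subpopulation: str, compartment: str) -> int:
        try:
            return self.index[(subpopulation, compartment)]
        except KeyError:
            raise KeyError(
                f"no state {subpopulation!r} in {compartment!r}"
            ) from None

    def states_of(self, subpopulation: str) -> list[int]:
        """Indices of all compartments occupied by a subpopulation."""
        return [i for i, (s, _) in enumerate(self.labels) if s == subpopulation]

    def compartment_states(self, compartment: str) -> list[int]:
        return [i for i, (_, c) in enumerate(self.labels) if c == compartment]


LAYOUT = CompartmentLayout()

# Frequently used indices
I_DN = LAYOUT.idx("DN", "THY")
I_DP = LAYOUT.idx("DP", "THY")
I_SP4 = LAYOUT.idx("SP4", "THY")
I_SP8 = LAYOUT.idx("SP8", "THY")
I_RTE_BL = LAYOUT.idx("RTE", "BL")
I_RTE_LT = LAYOUT.idx("RTE", "LT")
I_N_BL = LAYOUT.idx("N", "BL")
I_N_LT = LAYOUT.idx("N", "LT")
I_N_GIT = LAYOUT.idx("N", "GIT")
I_N_LUNG = LAYOUT.idx("N", "LUNG")
I_A_BL = LAYOUT.idx("A", "BL")
I_A_LT = LAYOUT.idx("A", "LT")
I_CM_BL = LAYOUT.idx("CM", "BL")
I_CM_LT = LAYOUT.idx("CM", "LT")
I_CM_GIT = LAYOUT.idx("CM", "GIT")
I_CM_LUNG = LAYOUT.idx("CM", "LUNG")
I_EM_BL = LAYOUT.idx("EM", "BL")
I_EM_LT = LAYOUT.idx("EM", "LT")
I_EM_GIT = LAYOUT.idx("EM", "GIT")
I_EM_LUNG = LAYOUT.idx("EM", "LUNG")
I_EFF_BL = LAYOUT.idx("EFF", "BL")
I_EFF_LT = LAYOUT.idx("EFF", "LT")
I_EFF_GIT = LAYOUT.idx("EFF", "GIT")
I_EFF_LUNG = LAYOUT.idx("EFF", "LUNG")

#: indices of the 20 peripheral states (everything outside the thymus)
PERIPHERAL = tuple(range(I_RTE_BL, N_STATES))
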