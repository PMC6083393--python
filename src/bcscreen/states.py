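"""Health states of the breast-cancer natural-history model.

The state space distinguishes undiagnosed (preclinical) disease from
diagnosed-and-treated disease, and keeps separate diagnosed-but-untreated
states for scenarios in which not every detected case receives treatment.
Death states are absorbing and placed last so that ``state < BC_DEATH``
is an aliveness test on integer state arrays.
"""

from enum import IntEnum


class HealthState(IntEnum):
    HEALTHY = 0
    DCIS = 1                 # preclinical ductal carcinoma in situ
    PRE_I = 2                # preclinical (undiagnosed) invasive stage I
    PRE_II = 3
    PRE_III = 4
    PRE_IV = 5
    TREATED_DCIS = 6
    TREATED_I = 7
    TREATED_II = 8
    TREATED_III = 9
    TREATED_IV = 10
    DIAG_I = 11              # diagnosed, declined/no access to treatment
    DIAG_II = 12
    DIAG_III = 13
    DIAG_IV = 14
    BC_DEATH = 15
    OTHER_DEATH = 16


N_STATES = len(HealthState)

DEATH_STATES = (HealthState.BC_DEATH, HealthState.OTHER_DEATH)
LIVING_STATES = tuple(s for s in HealthState if s not in DEATH_STATES)

PRECLINICAL_INVASIVE = (
    HealthState.PRE_I,
    HealthState.PRE_II,
    HealthState.PRE_III,
    HealthState.PRE_IV,
)
TREATED_BY_STAGE = (
    HealthState.TREATED_I,
    HealthState.TREATED_II,
    HealthState.TREATED_III,
    HealthState.TREATED_IV,
)
DIAG_BY_STAGE = (
    HealthState.DIAG_I,
    HealthState.DIAG_II,
    HealthState.DIAG_III,
    HealthState.DIAG_IV,
)

#: States eligible to attend a screening round (alive and not yet diagnosed).
UNDIAGNOSED_STATES = (HealthState.HEALTHY, HealthState.DCIS) + PRECLINICAL_INVASIVE
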