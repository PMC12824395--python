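"""Treatment-state alphabet and the indicator → state decision tree.

Each three-month period of follow-up is summarised by four binary
indicators (antidepressant, anticonvulsant mood-stabilizer, lithium,
antipsychotic use on >= 50% of evaluable days) and mapped onto one of
seven mutually exclusive treatment states; an eighth absorbing symbol
marks censoring after death.
"""

from __future__ import annotations

# Inadequate treatment states
LACK = "LACK"
AD_MONO = "AD_MONO"
# Standard treatment states (concomitant antidepressants allowed)
MOOD_STAB = "MOOD_STAB"
ANTIPSYCH = "ANTIPSYCH"
LITHIUM = "LITHIUM"
# Augmentation states (concomitant antidepressants allowed)
AUGMENT = "AUGMENT"
LI_AUGMENT = "LI_AUGMENT"
# Absorbing censoring symbol (death)
CENSORED = "CENSORED"

#: The seven treatment states, in canonical order.
TREATMENT_STATES: tuple[str, ...] = (
    LACK,
    AD_MONO,
    MOOD_STAB,
    ANTIPSYCH,
    LITHIUM,
    AUGMENT,
    LI_AUGMENT,
)

#: Full sequence alphabet (treatment states plus the censoring symbol).
ALPHABET: tuple[str, ...] = TREATMENT_STATES + (CENSORED,)

STATE_INDEX: dict[str, int] = {s: i for i, s in enumerate(ALPHABET)}

N_PERIODS = 12
PERIOD_DAYS = 91
FOLLOWUP_DAYS = N_PERIODS * PERIOD_DAYS  # 1092

# Medication classes tracked by the exposure model.
ANTIDEPRESSANT = "antidepressant"
ANTICONVULSANT_MS = "anticonvulsant_ms"
LITHIUM_CLASS = "lithium"
ANTIPSYCHOTIC = "antipsychotic"

DRUG_CLASSES: tuple[str, ...] = (
    ANTIDEPRESSANT,
    ANTICONVULSANT_MS,
    LITHIUM_CLASS,
    ANTIPSYCHOTIC,
)

#: Which medication classes are dispensed during a period in a given state.
#: Used by the synthetic generator to emit dispensings consistent with a
#: latent state; antidepressants are added to AD_MONO only, since the
#: decision tree ignores them whenever an adequate class is present.
STATE_CLASSES: dict[str, frozenset[str]] = {
    LACK: frozenset(),
    AD_MONO: frozenset({ANTIDEPRESSANT}),
    MOOD_STAB: frozenset({ANTICONVULSANT_MS}),
    ANTIPSYCH: frozenset({ANTIPSYCHOTIC}),
    LITHIUM: frozenset({LITHIUM_CLASS}),
    AUGMENT: frozenset({ANTICONVULSANT_MS, ANTIPSYCHOTIC}),
    LI_AUGMENT: frozenset({LITHIUM_CLASS, ANTICONVULSANT_MS}),
}


def assign_state(ad: bool, ms: bool, li: bool, ap: bool) -> str:
    """Map the four period indicators to a treatment state.

    Parameters
    ----------
    ad, ms, li, ap
        Binary use indicators for antidepressants, anticonvulsant
        mood-stabilizers, lithium and antipsychotics respectively.

    Returns
    -------
    str
        One of the seven treatment states. Lithium together with any of
        the other adequate classes gives lithium-with-augmentation;
        lithium alone gives lithium; mood-stabilizer plus antipsychotic
        gives augmentation; a single adequate class gives its standard
        state; antidepressants only give antidepressant monotherapy; no
        use at all gives lack of treatment. The antidepressant flag is
        ignored whenever any adequate class is present.
    """
    if li and (ms or ap):
        return LI_AUGMENT
    if li:
        return LITHIUM
    if ms and ap:
        return AUGMENT
    if ms:
        return MOOD_STAB
    if ap:
        return ANTIPSYCH
    if ad:
        return AD_MONO
    return LACK
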