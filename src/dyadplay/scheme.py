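"""The dimensional coding scheme: dimensions, sub-code legality, and the
social-state taxonomy.

Behavior is coded frame-by-frame on three binary dimensions:

* ``SE`` (socioemotional): 1 = positive/neutral affect, 0 = negative affect.
* ``SM`` (sensorimotor): 1 = voluntary physical contact with the object,
  0 = no or passive contact.
* ``C`` (cognitive): 1 = visual attention on the object or partner,
  0 = attention elsewhere.

A main code of 1 marks play-congruent activity on that dimension. Each main
code may carry an integer sub-code refining the level/type of activity; the
legal sub-codes per (dimension, main code) are fixed by the scheme and
enforced everywhere (see :data:`LEGAL_SUBCODES`).

The per-frame triple of main codes defines one of eight *social states*,
numbered 1..8 in the scheme's canonical order (:data:`STATE_CODES`). State 1,
``[1 1 1]``, is the unique play-congruent state: positive/neutral affect,
contact, and attention all at once.
"""

from __future__ import annotations

import numpy as np

#: Dimension order used throughout the package.
DIMENSIONS = ("SE", "SM", "C")

#: Index of each dimension in code arrays.
DIM_INDEX = {d: i for i, d in enumerate(DIMENSIONS)}

#: Legal sub-codes per (dimension, main code). An empty tuple means the main
#: code takes no sub-code (the sub-code must be absent).
LEGAL_SUBCODES = {
    ("SE", 1): (1, 2),   # 1 neutral affect, 2 positive affect display
    ("SE", 0): (1, 2),   # 1 negative affect, 2 affect unclear
    ("SM", 1): (1, 2, 3),  # holding / circular-repetitive action / other action
    ("SM", 0): (),
    ("C", 1): (1, 2, 3, 4, 5),  # attention only / object-general / object-
    ("C", 0): (),               # specific / pretense / rule-based
}

#: Sentinel stored where a sub-code is absent.
NO_SUBCODE = -1

#: Social-state taxonomy: state index -> (SE, SM, C) main codes, in the
#: scheme's canonical printed order (not binary-value order).
STATE_CODES = {
    1: (1, 1, 1),  # play-congruent: positive/neutral affect, contact, attention
    2: (1, 0, 1),
    3: (0, 1, 1),
    4: (0, 0, 1),
    5: (1, 1, 0),
    6: (1, 0, 0),
    7: (0, 1, 0),
    8: (0, 0, 0),
}

#: The play-congruent state.
PLAY_STATE = 1

#: Number of individual social states (2**3 code triples).
N_STATES = len(STATE_CODES)

#: Inverse map (SE, SM, C) -> state index.
CODES_TO_STATE = {codes: s for s, codes in STATE_CODES.items()}

# Lookup table for vectorized derivation: position 4*(1-C)+2*(1-SE)+(1-SM)
# holds the state index. Built from STATE_CODES so the explicit taxonomy
# remains the single source of truth.
_STATE_LUT = np.zeros(8, dtype=np.int64)
for _s, (_se, _sm, _c) in STATE_CODES.items():
    _STATE_LUT[4 * (1 - _c) + 2 * (1 - _se) + (1 - _sm)] = _s


def state_from_codes(se: int, sm: int, c: int) -> int:
    """Map one (SE, SM, C) main-code triple to its social-state index."""
    try:
        return CODES_TO_STATE[(se, sm, c)]
    except KeyError:
        raise ValueError(f"main codes must be binary, got {(se, sm, c)}") from None


def codes_from_state(state: int) -> tuple[int, int, int]:
    """Inverse of :func:`state_from_codes`."""
    try:
        return STATE_CODES[state]
    except KeyError:
        raise ValueError(f"social state must be in 1..8, got {state}") from None


def states_from_code_array(main: np.ndarray) -> np.ndarray:
    """Vectorized state derivation from an ``(n, 3)`` array of main codes
    with columns ordered (SE, SM, C)."""
    main = np.asarray(main)
    if main.ndim != 2 or main.shape[1] != 3:
        raise ValueError("expected an (n, 3) main-code array")
    if not np.isin(main, (0, 1)).all():
        raise ValueError("main codes must be binary")
    se, sm, c = main[:, 0], main[:, 1], main[:, 2]
    return _STATE_LUT[4 * (1 - c) + 2 * (1 - se) + (1 - sm)]


def code_array_from_states(states: np.ndarray) -> np.ndarray:
    """Vectorized inverse: state indices -> ``(n, 3)`` main-code array."""
    states = np.asarray(states)
    if not np.isin(states, np.arange(1, 9)).all():
        raise ValueError("state indices must be in 1..8")
    table = np.array([STATE_CODES[s] for s in range(1, 9)], dtype=np.int8)
    return table[states - 1]


def validate_subcode(dimension: str, main_code: int, sub_code: int | None) -> None:
    """Raise ``ValueError`` unless ``sub_code`` is legal for the
    (dimension, main code) pair.

    SE takes sub-codes {1,2} for both main codes; SM main 1 takes {1,2,3} and
    SM main 0 none; C main 1 takes {1..5} and C main 0 none.
    """
    if dimension not in DIMENSIONS:
        raise ValueError(f"unknown dimension {dimension!r}; expected one of {DIMENSIONS}")
    if main_code not in (0, 1):
        raise ValueError(f"main code must be 0 or 1, got {main_code!r}")
    legal = LEGAL_SUBCODES[(dimension, main_code)]
    if sub_code is None or sub_code == NO_SUBCODE:
        if legal:
            raise ValueError(
                f"{dimension} main code {main_code} requires a sub-code in {legal}"
            )
        return
    if not legal:
        raise ValueError(
            f"{dimension} main code {main_code} takes no sub-code, got {sub_code}"
        )
    if sub_code not in legal:
        raise ValueError(
            f"sub-code {sub_code} illegal for {dimension} main code {main_code}; "
            f"legal sub-codes are {legal}"
        )
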