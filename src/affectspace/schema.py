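"""Column-name conventions and validation for the long-format trial table.

A trial table holds one row per (participant, stimulus) presentation with the
subjective ratings, the three autonomic features, stimulus metadata and the
brightness covariate.  All modules address columns through the constants below
so the layout is defined in exactly one place.
"""

from __future__ import annotations

from collections.abc import Iterable

import pandas as pd

PARTICIPANT = "participant"
STIMULUS = "stimulus"
VALENCE_CATEGORY = "valence_category"
AROUSAL_CATEGORY = "arousal_category"

#: Active quantitative variables, in canonical order.
SUBJECTIVE_VARS = ("valence", "arousal")
AUTONOMIC_VARS = ("pupil", "scr", "hr")
ACTIVE_VARS = SUBJECTIVE_VARS + AUTONOMIC_VARS

BRIGHTNESS = "brightness"

#: Columns a trial table must always carry.
REQUIRED_COLUMNS = (
    PARTICIPANT,
    STIMULUS,
    VALENCE_CATEGORY,
    AROUSAL_CATEGORY,
    *ACTIVE_VARS,
    BRIGHTNESS,
)

VALENCE_LEVELS = ("negative", "neutral", "positive")
AROUSAL_LEVELS = ("low", "medium", "high")


class TrialTableError(ValueError):
    """Raised when a table violates the trial-table contract."""


def validate_trial_table(table: pd.DataFrame, *, allow_missing: bool = True) -> None:
    """Check the structural invariants of a trial table.

    Parameters
    ----------
    table:
        Candidate long-format table.
    allow_missing:
        When False, any NaN in an active column is an error.

    Raises
    ------
    TrialTableError
        Naming the first violated invariant (missing column, duplicated
        participant-stimulus key, negative SCR, out-of-range rating).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise TrialTableError(f"trial table missing required column(s): {missing}")
    dup = table.duplicated(subset=[PARTICIPANT, STIMULUS])
    if dup.any():
        keys = table.loc[dup, [PARTICIPANT, STIMULUS]].head(5).to_dict("records")
        raise TrialTableError(f"duplicated (participant, stimulus) keys, e.g. {keys}")
    scr = table["scr"].dropna()
    if (scr < 0).any():
        raise TrialTableError("scr column contains negative amplitudes")
    for col in ("valence", "arousal"):
        vals = table[col].dropna()
        if ((vals < -10) | (vals > 10)).any():
            raise TrialTableError(f"{col} ratings outside the [-10, 10] slider range")
    if not allow_missing:
        bad = [c for c in ACTIVE_VARS if table[c].isna().any()]
        if bad:
            raise TrialTableError(f"missing values not allowed in column(s): {bad}")


def complete_cases(table: pd.DataFrame, columns: Iterable[str]) -> tuple[pd.DataFrame, int]:
    """Drop rows with a missing value in *columns*; return (kept, n_dropped)."""
    cols = list(columns)
    mask = table[cols].notna().all(axis=1)
    return table.loc[mask], int((~mask).sum())
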