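"""Scoring: response sheets -> the nine output measures.

One point per correctly recognized syllable; a fully recognized word is
worth two points, which coincides with the syllable sum.  Primary measures
RH/NR/UnSc (0-32) total each condition; secondary measures RH1..UnSc2
(0-16) split them by syllable position.
"""

from __future__ import annotations

import unicodedata

import numpy as np
import pandas as pd

from .listener import Cohort, ResponseSheet
from .stimulus import CONDITIONS

__all__ = [
    "SCORE_COLUMNS",
    "score_word",
    "score_session",
    "score_cohort",
    "normalize_transcript",
]

SCORE_COLUMNS = [
    "listener_id",
    "sex",
    "RH",
    "RH1",
    "RH2",
    "NR",
    "NR1",
    "NR2",
    "UnSc",
    "UnSc1",
    "UnSc2",
]


def score_word(syll1_correct: bool, syll2_correct: bool) -> int:
    """0, 1 or 2 points: one per correct syllable."""
    return int(bool(syll1_correct)) + int(bool(syll2_correct))


def score_session(sheet: ResponseSheet) -> dict[str, int]:
    """Sum points per condition and per condition x syllable position."""
    conds = np.asarray(sheet.conditions)
    out: dict[str, int] = {}
    for c in CONDITIONS:
        mask = conds == c
        s1 = int(np.sum(sheet.syll1[mask]))
        s2 = int(np.sum(sheet.syll2[mask]))
        out[c] = s1 + s2
        out[f"{c}1"] = s1
        out[f"{c}2"] = s2
    return out


def score_cohort(cohort: Cohort) -> pd.DataFrame:
    """Fixed 11-column score table, one row per listener."""
    rows = []
    for lid, prof, sheet in zip(cohort.listener_ids, cohort.profiles, cohort.sheets):
        row = {"listener_id": lid, "sex": prof.sex}
        row.update(score_session(sheet))
        rows.append(row)
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def normalize_transcript(text: str) -> str:
    """Case-fold and strip diacritics — for optional free-text answer input."""
    decomposed = unicodedata.normalize("NFD", text.strip().casefold())
    return "".join(ch for ch in decomposed if not unicodedata.combining(ch))
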