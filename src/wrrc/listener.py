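"""Synthetic listener cohort with a condition x syllable x sex effect structure.

Each listener's probability of recognizing a syllable is additive on the
logit scale: a baseline, a condition-by-syllable-position term, and (for
females on the synchronized condition's second syllable) an extra sex term.
The default calibration targets the reference median score profile: totals
of 24.5/32 (RH), 22/32 (NR) and 22/32 (UnSc), with the synchronized-rhythm
advantage weighted toward the first syllable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stimulus import CONDITIONS, plan_session

__all__ = [
    "ListenerProfile",
    "ResponseSheet",
    "Cohort",
    "DEFAULT_CELL_PROBS",
    "default_effects",
    "syllable_prob",
    "simulate_listener",
    "simulate_cohort",
]


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _inv_logit(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


#: per-cell recognition probabilities implied by the reference median table
#: (per-syllable medians, rescaled within condition so the two syllables sum
#: to the condition's total-score target: RH 24.5, NR 22, UnSc 22 of 32)
DEFAULT_CELL_PROBS: dict[tuple[str, int], float] = {
    ("RH", 1): (13 / 16) * (24.5 / 24.0),
    ("RH", 2): (11 / 16) * (24.5 / 24.0),
    ("NR", 1): 12 / 16,
    ("NR", 2): 10 / 16,
    ("UnSc", 1): (12 / 16) * (22.0 / 21.0),
    ("UnSc", 2): (9 / 16) * (22.0 / 21.0),
}

#: baseline = NR per-syllable mean (22/32)
DEFAULT_BASE_LOGIT = _logit(22.0 / 32.0)


def default_effects() -> dict[tuple[str, int], float]:
    """Logit offsets from baseline reproducing ``DEFAULT_CELL_PROBS``."""
    return {
        cell: _logit(p) - DEFAULT_BASE_LOGIT for cell, p in DEFAULT_CELL_PROBS.items()
    }


@dataclass
class ListenerProfile:
    base_logit: float = DEFAULT_BASE_LOGIT
    effects: dict[tuple[str, int], float] = field(default_factory=default_effects)
    sex: str = "male"
    sex_rh2_logit: float = 0.3  # applied to (RH, syllable 2) for females
    lapse: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        if not 0.0 <= self.lapse < 0.5:
            raise ValueError("lapse must be in [0, 0.5)")


@dataclass
class ResponseSheet:
    """Per-trial, per-syllable correctness for one listener (48 trials)."""

    word_ids: list[str]
    conditions: list[str]
    syll1: np.ndarray  # bool, length 48
    syll2: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.conditions)
        if n != 48:
            raise ValueError("a response sheet has exactly 48 trials")
        for c in CONDITIONS:
            if self.conditions.count(c) != 16:
                raise ValueError("each condition must appear on 16 trials")
        if len(self.syll1) != n or len(self.syll2) != n:
            raise ValueError("per-syllable arrays must match trial count")


@dataclass
class Cohort:
    profiles: list[ListenerProfile]
    sheets: list[ResponseSheet]
    listener_ids: list[str]


def syllable_prob(profile: ListenerProfile, condition: str, syllable: int) -> float:
    """Recognition probability for one condition x syllable cell (lapse-free)."""
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    if syllable not in (1, 2):
        raise ValueError("syllable must be 1 or 2")
    x = profile.base_logit + profile.effects.get((condition, syllable), 0.0)
    if profile.sex == "female" and condition == "RH" and syllable == 2:
        x += profile.sex_rh2_logit
    return _inv_logit(x)


def simulate_listener(
    profile: ListenerProfile, plan: list[dict], seed: int | None = None
) -> ResponseSheet:
    """Independent Bernoulli outcome per syllable per trial.

    A lapse mixes the cell probability toward chance:
    p_eff = (1 - lapse) * p + lapse / 2.
    """
    if len(plan) != 48:
        raise ValueError("plan must contain 48 trials")
    rng = np.random.default_rng(profile.seed if seed is None else seed)
    conds = [t["condition"] for t in plan]
    p1 = np.array([syllable_prob(profile, c, 1) for c in conds])
    p2 = np.array([syllable_prob(profile, c, 2) for c in conds])
    p1 = (1 - profile.lapse) * p1 + profile.lapse / 2.0
    p2 = (1 - profile.lapse) * p2 + profile.lapse / 2.0
    u = rng.random((2, len(plan)))
    return ResponseSheet(
        word_ids=[t.get("word_id", f"w{t['word_index']:02d}") for t in plan],
        conditions=conds,
        syll1=u[0] < p1,
        syll2=u[1] < p2,
    )


def simulate_cohort(
    n_male: int = 10,
    n_female: int = 16,
    effects: dict[tuple[str, int], float] | None = None,
    seed: int = 0,
    base_logit: float = DEFAULT_BASE_LOGIT,
    base_logit_sd: float = 0.2,
    sex_rh2_logit: float = 0.3,
    lapse: float = 0.02,
    plan: list[dict] | None = None,
) -> Cohort:
    """Independent listeners sharing one session plan, with between-subject
    variation of the baseline logit."""
    if n_male < 0 or n_female < 0:
        raise ValueError("counts must be non-negative")
    if effects is None:
        effects = default_effects()
    rng = np.random.default_rng(seed)
    if plan is None:
        plan = plan_session(int(rng.integers(0, 2**31 - 1)))
    profiles, sheets, ids = [], [], []
    sexes = ["male"] * n_male + ["female"] * n_female
    for i, sex in enumerate(sexes):
        prof = ListenerProfile(
            base_logit=base_logit + base_logit_sd * rng.standard_normal(),
            effects=dict(effects),
            sex=sex,
            sex_rh2_logit=sex_rh2_logit,
            lapse=lapse,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        profiles.append(prof)
        sheets.append(simulate_listener(prof, plan))
        ids.append(f"{'m' if sex == 'male' else 'f'}{i:02d}")
    return Cohort(profiles=profiles, sheets=sheets, listener_ids=ids)
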