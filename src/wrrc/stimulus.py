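"""Per-trial timelines and mixed waveforms for the three priming conditions.

Conditions (beat grid relative to the word's first P-center P1, with the
first beat anchoring time zero and IPI the word's inter-P-center interval):

* ``RH``   — isochronous and synchronized: four beats one IPI apart, last
  beat one IPI before P1, so beats and P-centers share one pulse.
* ``NR``   — the four intervals (three inter-beat + last-beat-to-P1) are
  each distorted +/-30% in one of six fixed sign patterns (two ``+`` and
  two ``-`` each), which leaves the four-interval total, and hence P1, at
  exactly 4 IPI.
* ``UnSc`` — isochronous but unsynchronized: inter-beat intervals shrink to
  0.9 IPI while the word stays put, so the last-beat gap grows to 1.3 IPI
  and no extrapolated beat lands on a P-center.

Babble geometry in every condition: onset 1.5 IPI before P1, linear fade-in
lasting 1 IPI (so the ramp ends 0.5 IPI before P1), constant plateau, and
an abrupt stop a short tail after the word ends.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .audio import (
    AudioBuffer,
    BabbleTrack,
    InvalidParameterError,
    WordList,
    WordToken,
    synth_babble,
    synth_beat,
    write_wav,
)

__all__ = [
    "CONDITIONS",
    "NR_PATTERNS",
    "ConditionSpec",
    "StimulusTimeline",
    "Stimulus",
    "RenderingError",
    "build_timeline",
    "assign_nr_type",
    "mix_stimulus",
    "measure_sbr",
    "plan_session",
    "export_session",
]

CONDITIONS = ("RH", "NR", "UnSc")

#: sign patterns of the +/-30% distortion applied to the four intervals
NR_PATTERNS: dict[str, tuple[int, int, int, int]] = {
    "A": (-1, -1, +1, +1),
    "B": (-1, +1, -1, +1),
    "C": (-1, +1, +1, -1),
    "D": (+1, -1, -1, +1),
    "E": (+1, -1, +1, -1),
    "F": (+1, +1, -1, -1),
}

NR_DISTORTION = 0.30
DEFAULT_SBR_DB = 1.3
DEFAULT_BABBLE_TAIL_S = 0.250
HEADROOM_DB = 3.0


class RenderingError(RuntimeError):
    pass


@dataclass
class ConditionSpec:
    condition: str
    nr_type: str | None = None
    unsc_factor: float = 0.9

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise InvalidParameterError(f"condition must be one of {CONDITIONS}")
        if (self.condition == "NR") != (self.nr_type is not None):
            raise InvalidParameterError("nr_type must be given iff condition is NR")
        if self.nr_type is not None and self.nr_type not in NR_PATTERNS:
            raise InvalidParameterError("nr_type must be A..F")


@dataclass
class StimulusTimeline:
    """All event times (seconds from stimulus start) for one trial."""

    beat_onsets: tuple[float, float, float, float]
    p_centers: tuple[float, float]
    intervals: tuple[float, float, float, float]  # 3 inter-beat + last-beat-to-P1
    babble_on: float
    ramp_end: float
    babble_off: float
    word_start: float
    word_end: float
    word_id: str
    condition: str
    nr_type: str | None = None
    ipi: float = 0.0

    def __post_init__(self) -> None:
        b = self.beat_onsets
        if not all(b[i] < b[i + 1] for i in range(3)):
            raise InvalidParameterError("beat onsets must be strictly increasing")
        if self.p_centers[0] <= b[-1]:
            raise InvalidParameterError("P-centers must follow the beats")
        if self.babble_off <= self.word_end:
            raise InvalidParameterError("babble must outlast the word")

    @property
    def last_beat_gap(self) -> float:
        """Distance from the last beat to the first P-center (a logged
        per-trial confound: it differs across conditions by design)."""
        return self.p_centers[0] - self.beat_onsets[-1]


@dataclass
class Stimulus:
    audio: AudioBuffer
    timeline: StimulusTimeline
    sbr_db: float
    # scaled component tracks kept for SBR verification
    word_track: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    babble_track: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


def build_timeline(
    word: WordToken,
    spec: ConditionSpec,
    babble_tail_s: float = DEFAULT_BABBLE_TAIL_S,
) -> StimulusTimeline:
    """Compute all event times for one word under one condition."""
    ipi = word.ipi
    if spec.condition == "RH":
        intervals = (ipi, ipi, ipi, ipi)
    elif spec.condition == "NR":
        signs = NR_PATTERNS[spec.nr_type]  # type: ignore[index]
        intervals = tuple(ipi * (1.0 + NR_DISTORTION * s) for s in signs)
    else:  # UnSc
        ibi = spec.unsc_factor * ipi
        intervals = (ibi, ibi, ibi, 4.0 * ipi - 3.0 * ibi)
    beats = (0.0, intervals[0], intervals[0] + intervals[1], intervals[0] + intervals[1] + intervals[2])
    p1 = 4.0 * ipi  # conserved across conditions by construction
    p2 = p1 + ipi
    word_start = p1 - word.p1
    word_end = word_start + word.audio.duration
    return StimulusTimeline(
        beat_onsets=beats,
        p_centers=(p1, p2),
        intervals=intervals,  # type: ignore[arg-type]
        babble_on=p1 - 1.5 * ipi,
        ramp_end=p1 - 0.5 * ipi,
        babble_off=word_end + babble_tail_s,
        word_start=word_start,
        word_end=word_end,
        word_id=word.word_id,
        condition=spec.condition,
        nr_type=spec.nr_type,
        ipi=ipi,
    )


def assign_nr_type(nr_trial_index: int) -> str:
    """Ordinal type assignment: first NR presentation A, second B, ... cycling."""
    if nr_trial_index < 0:
        raise InvalidParameterError("index must be >= 0")
    return "ABCDEF"[nr_trial_index % 6]


def measure_sbr(word_track: np.ndarray, babble_track: np.ndarray, timeline: StimulusTimeline, rate: int) -> float:
    """Signal-to-babble ratio in dB, measured on rendered component tracks:
    word RMS over the word extent vs. babble RMS over its plateau."""
    w0, w1 = int(round(timeline.word_start * rate)), int(round(timeline.word_end * rate))
    p0, p1 = int(round(timeline.ramp_end * rate)), int(round(timeline.babble_off * rate))
    word_rms = np.sqrt(np.mean(word_track[w0:w1] ** 2))
    plateau_rms = np.sqrt(np.mean(babble_track[p0:p1] ** 2))
    return float(20.0 * np.log10(word_rms / plateau_rms))


def mix_stimulus(
    timeline: StimulusTimeline,
    word: WordToken,
    babble: BabbleTrack,
    beat: AudioBuffer,
    sbr_db: float = DEFAULT_SBR_DB,
) -> Stimulus:
    """Render beats, word and ramped babble into one peak-normalized mixture.

    The babble gain is set from the word's RMS over its extent so that the
    measured SBR equals ``sbr_db``; peak normalization (3 dB headroom)
    scales all components equally and leaves the SBR untouched.
    """
    rate = word.audio.rate
    if babble.audio.rate != rate or beat.rate != rate:
        raise InvalidParameterError("sampling rates must match")
    n = int(round(timeline.babble_off * rate))
    need = n - int(round(timeline.babble_on * rate))
    if len(babble.audio) < need:
        raise InvalidParameterError("babble track too short for this timeline")

    word_track = np.zeros(n)
    i0 = int(round(timeline.word_start * rate))
    word_track[i0 : i0 + len(word.audio)] = word.audio.samples

    beat_track = np.zeros(n)
    for t in timeline.beat_onsets:
        j = int(round(t * rate))
        beat_track[j : j + len(beat)] += beat.samples

    b_on = int(round(timeline.babble_on * rate))
    r_end = int(round(timeline.ramp_end * rate))
    babble_track = np.zeros(n)
    babble_track[b_on:n] = babble.audio.samples[: n - b_on]
    ramp = np.ones(n - b_on)
    ramp[: r_end - b_on] = np.linspace(0.0, 1.0, r_end - b_on, endpoint=False)
    babble_track[b_on:] *= ramp

    w0, w1 = i0, i0 + len(word.audio)
    word_rms = np.sqrt(np.mean(word_track[w0:w1] ** 2))
    # gain against the local plateau RMS of the placed slice, not the track's
    # nominal plateau: short excerpts fluctuate a few percent around it
    local_plateau = np.sqrt(np.mean(babble_track[r_end:n] ** 2))
    gain = word_rms / (local_plateau * 10 ** (sbr_db / 20.0))
    babble_track *= gain

    mix = word_track + beat_track + babble_track
    target_peak = 10 ** (-HEADROOM_DB / 20.0)
    peak = np.max(np.abs(mix))
    scale = target_peak / peak
    mix *= scale
    word_track = word_track * scale
    babble_track = babble_track * scale
    if np.max(np.abs(mix)) > 1.0:
        raise RenderingError("mixture clips after normalization")
    measured = measure_sbr(word_track, babble_track, timeline, rate)
    return Stimulus(
        audio=AudioBuffer(mix, rate),
        timeline=timeline,
        sbr_db=measured,
        word_track=word_track,
        babble_track=babble_track,
    )


# ---------------------------------------------------------------------------
# sessions


def plan_session(
    seed: int,
    n_per_condition: int = 16,
    conditions: tuple[str, ...] = CONDITIONS,
) -> list[dict]:
    """Randomized presentation order of 48 trials (16 per condition), with
    NR types assigned ordinally in presentation order."""
    rng = np.random.default_rng(seed)
    trials = [
        {"condition": c, "word_index": i}
        for c in conditions
        for i in range(n_per_condition)
    ]
    order = rng.permutation(len(trials))
    plan = []
    nr_count = 0
    for pos, k in enumerate(order):
        t = dict(trials[int(k)])
        t["trial"] = pos
        if t["condition"] == "NR":
            t["nr_type"] = assign_nr_type(nr_count)
            nr_count += 1
        else:
            t["nr_type"] = None
        plan.append(t)
    return plan


def export_session(
    lists: tuple[WordList, WordList, WordList],
    seed: int,
    out_dir,
    condition_map: tuple[str, ...] = CONDITIONS,
    sbr_db: float = DEFAULT_SBR_DB,
    babble_tail_s: float = DEFAULT_BABBLE_TAIL_S,
    write_audio: bool = True,
) -> dict:
    """Build all 48 stimuli of a session, write WAVs and a manifest.

    One word list serves each condition (default list order RH, NR, UnSc);
    presentation order is shuffled by ``seed`` and the manifest records the
    full per-trial timeline plus ground truth.
    """
    if len(lists) != 3:
        raise InvalidParameterError("need exactly three word lists")
    rate = lists[0].tokens[0].audio.rate
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    by_condition = dict(zip(condition_map, lists))
    plan = plan_session(seed, conditions=condition_map)
    beat = synth_beat(rate=rate)
    rng = np.random.default_rng(seed + 1)
    rows = []
    for t in plan:
        word = by_condition[t["condition"]].tokens[t["word_index"]]
        spec = ConditionSpec(condition=t["condition"], nr_type=t["nr_type"])
        tl = build_timeline(word, spec, babble_tail_s=babble_tail_s)
        babble = synth_babble(
            tl.babble_off - tl.babble_on + 0.05,
            seed=int(rng.integers(0, 2**31 - 1)),
            rate=rate,
        )
        stim = mix_stimulus(tl, word, babble, beat, sbr_db=sbr_db)
        fname = f"trial{t['trial']:02d}_{t['condition']}_{word.word_id}.wav"
        if write_audio:
            write_wav(out / fname, stim.audio)
        rows.append(
            {
                "trial": t["trial"],
                "file": fname,
                "word_id": word.word_id,
                "condition": t["condition"],
                "nr_type": t["nr_type"] or "",
                "stress": word.stress,
                "ipi": tl.ipi,
                "p1": tl.p_centers[0],
                "p2": tl.p_centers[1],
                "beat_onsets": list(tl.beat_onsets),
                "babble_on": tl.babble_on,
                "ramp_end": tl.ramp_end,
                "babble_off": tl.babble_off,
                "last_beat_gap": tl.last_beat_gap,
                "sbr_db": stim.sbr_db,
            }
        )
    manifest = {
        "seed": seed,
        "rate": rate,
        "sbr_db": sbr_db,
        "condition_map": {c: wl.list_id for c, wl in by_condition.items()},
        "trials": rows,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    flat = pd.DataFrame(rows).drop(columns=["beat_onsets"])
    flat.to_csv(out / "manifest.csv", index=False)
    return manifest
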