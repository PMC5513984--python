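"""Two-stage adaptive staircase for P-center estimation.

A simulated musician judges each presentation of a word against a beat grid
derived from the current P-value (the running P-center estimate).  The
engine adjusts the P-value in fixed sample steps — coarse stage (1,000
samples, 22.7 ms at 44.1 kHz) then fine stage (500 samples) — reversing
direction after two consecutive opposite-category responses, for four runs
per stage.  The stage estimate is the mean of the border values of the two
final runs; the fine-stage estimate is the final P-center estimate.

Response semantics here: a presented P-value *later* than the word's true
P-center makes the syllable sound "delayed", so the staircase moves the
P-value earlier; "early" moves it later.  This is the same reversal
schedule as the behavioral procedure, stated in the presented-value frame.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .audio import WordToken

__all__ = [
    "StaircaseConfig",
    "SimulatedMusician",
    "Trial",
    "StaircaseResult",
    "ConvergenceError",
    "respond",
    "run_stage",
    "estimate_pcenter",
    "export_trial_log",
]

Response = str  # "early" | "delayed" | "good"


class ConvergenceError(RuntimeError):
    """Staircase failed to complete its runs within the trial cap."""


@dataclass
class StaircaseConfig:
    rate: int = 44_100
    coarse_step: int = 1_000  # samples
    fine_step: int = 500  # samples
    runs_per_stage: int = 4
    reversal_criterion: int = 2  # consecutive opposite responses ending a run
    trial_cap: int = 200  # per stage
    visual_offset_ms: float = 60.0  # half-range of the initial "visual" estimate

    def __post_init__(self) -> None:
        if self.coarse_step <= 0 or self.fine_step <= 0:
            raise ValueError("steps must be positive")
        if self.fine_step >= self.coarse_step:
            raise ValueError("fine step must be smaller than coarse step")

    def step_ms(self, step_samples: int) -> float:
        """Step duration in milliseconds (1,000 samples -> 22.7 ms)."""
        return step_samples / self.rate * 1000.0


@dataclass
class SimulatedMusician:
    """Oracle listener: accepts presentations within ``window_ms`` of the
    true P-center, otherwise reports the direction of the misalignment.

    ``lapse_rate`` is the probability that a response is replaced by a
    uniformly random one.  ``bias_ms`` is the SD of a seeded per-word
    perceptual bias: real listeners' internal P-centers deviate
    idiosyncratically from any fixed envelope landmark, and without such a
    term two independent oracles agree to within step quantization (a few
    ms), far tighter than human inter-judge differences.
    """

    true_p: float
    window_ms: float = 10.0
    lapse_rate: float = 0.0
    bias_ms: float = 0.0
    seed: int = 0
    rng: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.window_ms < 0:
            raise ValueError("window_ms must be >= 0")
        if not 0.0 <= self.lapse_rate <= 0.2:
            raise ValueError("lapse_rate must be in [0, 0.2]")
        if self.bias_ms < 0:
            raise ValueError("bias_ms must be >= 0")
        self.rng = np.random.default_rng(self.seed)


@dataclass
class Trial:
    index: int
    presented_p: float
    response: Response
    run: int
    stage: int


@dataclass
class StaircaseResult:
    estimate: float
    trial_log: list[Trial]
    stage_boundaries: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if not self.trial_log:
            raise ValueError("trial log must be non-empty")
        presented = [t.presented_p for t in self.trial_log]
        if not (min(presented) <= self.estimate <= max(presented)):
            raise ValueError("estimate outside the range of presented values")


def respond(musician: SimulatedMusician, presented_p: float) -> Response:
    """One judgment: good within the window, else early/delayed by sign."""
    window_s = musician.window_ms / 1000.0
    if musician.lapse_rate > 0 and musician.rng.random() < musician.lapse_rate:
        return str(musician.rng.choice(["early", "delayed", "good"]))
    if presented_p > musician.true_p + window_s:
        return "delayed"
    if presented_p < musician.true_p - window_s:
        return "early"
    return "good"


def _terminating(direction: int) -> Response:
    # moving the P-value up, it eventually sounds delayed; moving down, early
    return "delayed" if direction > 0 else "early"


def run_stage(
    start_p: float,
    step_samples: int,
    musician: SimulatedMusician,
    config: StaircaseConfig,
    stage: int = 1,
    trial_offset: int = 0,
) -> tuple[tuple[float, float], list[Trial]]:
    """Execute one staircase stage and return the last two runs' border values.

    The first response fixes the initial direction (good -> seeded random
    direction).  A run ends when ``reversal_criterion`` consecutive
    opposite-category responses occur; the border value of the run is the
    presented value of the first response of that terminating pair.  After
    ``runs_per_stage`` runs the borders of the final two runs bracket the
    acceptance region.
    """
    if step_samples <= 0:
        raise ValueError("step must be positive")
    step = step_samples / config.rate
    log: list[Trial] = []
    p = start_p
    r = respond(musician, p)
    log.append(Trial(trial_offset, p, r, 1, stage))
    if r == "delayed":
        direction = -1
    elif r == "early":
        direction = 1
    else:
        direction = int(musician.rng.choice([-1, 1]))
    run = 1
    consec = 0
    pending: list[float] = []  # presented values of the current opposite streak
    borders: list[float] = []
    while run <= config.runs_per_stage:
        if len(log) >= config.trial_cap:
            raise ConvergenceError(
                f"stage {stage} did not finish {config.runs_per_stage} runs "
                f"within {config.trial_cap} trials"
            )
        p = p + direction * step
        r = respond(musician, p)
        log.append(Trial(trial_offset + len(log), p, r, run, stage))
        if r == _terminating(direction):
            consec += 1
            pending.append(p)
        else:
            consec = 0
            pending = []
        if consec >= config.reversal_criterion:
            borders.append(pending[0])
            run += 1
            direction = -direction
            consec = 0
            pending = []
    lo, hi = sorted(borders[-2:])
    return (lo, hi), log


def estimate_pcenter(
    word: WordToken,
    syllable: int,
    musician: SimulatedMusician,
    config: StaircaseConfig | None = None,
) -> StaircaseResult:
    """Full two-stage estimate of one syllable's P-center.

    The musician's ``true_p`` is set to the word's ground truth for the
    requested syllable.  Stage 1 starts from a seeded "visual estimate"
    (true P-center + uniform offset within +/- ``visual_offset_ms``); the
    mean of its border pair seeds stage 2, whose border mean is the final
    estimate.
    """
    if syllable not in (1, 2):
        raise ValueError("syllable must be 1 or 2")
    if config is None:
        config = StaircaseConfig()
    truth = word.p1 if syllable == 1 else word.p2
    musician.true_p = truth
    if musician.bias_ms > 0:
        musician.true_p = truth + musician.rng.normal(0.0, musician.bias_ms / 1000.0)
    off = musician.rng.uniform(-config.visual_offset_ms, config.visual_offset_ms) / 1000.0
    start = truth + off
    (b1_lo, b1_hi), log1 = run_stage(start, config.coarse_step, musician, config, stage=1)
    mid = 0.5 * (b1_lo + b1_hi)
    (b2_lo, b2_hi), log2 = run_stage(
        mid, config.fine_step, musician, config, stage=2, trial_offset=len(log1)
    )
    return StaircaseResult(
        estimate=0.5 * (b2_lo + b2_hi),
        trial_log=log1 + log2,
        stage_boundaries=[(b1_lo, b1_hi), (b2_lo, b2_hi)],
    )


def export_trial_log(result: StaircaseResult, path, rate: int = 44_100) -> None:
    """Trial log as CSV: index, presented value (samples and s), response, run, stage."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["trial", "presented_samples", "presented_s", "response", "run", "stage"])
        for t in result.trial_log:
            w.writerow(
                [t.index, int(round(t.presented_p * rate)), f"{t.presented_p:.6f}", t.response, t.run, t.stage]
            )
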