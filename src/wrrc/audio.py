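"""Synthetic audio materials: beat tones, bisyllabic word tokens and babble.

Word tokens are fully synthetic stand-ins for recorded bisyllabic words.
Each syllable is a vowel-like tone under a gamma-shaped rise-fall envelope,
and its perceptual center (P-center) is *defined* as the time at which the
syllable envelope first reaches 50% of its peak.  That landmark is computed
on the discrete sample grid at synthesis time, so every token carries an
exact ground-truth ``p1``/``p2`` that downstream staircase and timeline code
can be validated against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile
from scipy.ndimage import gaussian_filter1d
from scipy.signal import butter, hilbert, sosfiltfilt

__all__ = [
    "DEFAULT_RATE",
    "AudioBuffer",
    "WordToken",
    "WordList",
    "BabbleTrack",
    "synth_beat",
    "synth_word_token",
    "make_word_list",
    "sample_ipis",
    "synth_babble",
    "measure_pcenters",
    "write_wav",
    "read_wav",
    "save_token",
    "load_token",
    "IPI_MEAN_S",
    "IPI_SD_S",
    "IPI_BOUNDS_S",
]

DEFAULT_RATE = 44_100

#: inter-P-center interval distribution of the emulated word material (s)
IPI_MEAN_S = 0.329
IPI_SD_S = 0.055
IPI_BOUNDS_S = (0.224, 0.434)


class InvalidParameterError(ValueError):
    """Raised when a synthesis parameter violates its contract."""


@dataclass
class AudioBuffer:
    """Mono audio: float samples in [-1, 1] at a fixed sampling rate."""

    samples: np.ndarray
    rate: int = DEFAULT_RATE

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise InvalidParameterError("audio must be a non-empty 1-D array")
        if self.rate <= 0:
            raise InvalidParameterError("sampling rate must be positive")
        peak = float(np.max(np.abs(self.samples)))
        if peak > 1.0 + 1e-9:
            raise InvalidParameterError(f"amplitudes exceed [-1, 1] (peak {peak:.3f})")

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.samples.size / self.rate

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class WordToken:
    """A synthetic bisyllabic word with exact ground-truth P-centers.

    ``p1``/``p2`` are seconds relative to token start; ``stress`` is the
    index (1 or 2) of the stressed syllable.  ``syllable_spans`` records the
    (onset, offset) of each syllable in seconds, used by the P-center
    re-measurement routine and by SBR windowing.
    """

    audio: AudioBuffer
    p1: float
    p2: float
    stress: int
    word_id: str
    syllable_spans: tuple[tuple[float, float], tuple[float, float]] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.stress not in (1, 2):
            raise InvalidParameterError("stress must be 1 or 2")
        if not (0.0 < self.p1 < self.p2 < self.audio.duration):
            raise InvalidParameterError("need 0 < p1 < p2 < duration")
        lo, hi = IPI_BOUNDS_S
        one_sample = 1.0 / self.audio.rate
        if not (lo - one_sample <= self.ipi <= hi + one_sample):
            raise InvalidParameterError(f"IPI {self.ipi:.3f}s outside [{lo}, {hi}]s")

    @property
    def ipi(self) -> float:
        """Inter-P-center interval, seconds."""
        return self.p2 - self.p1


@dataclass
class WordList:
    """Exactly 16 tokens, 11 stressed on the first syllable, 5 on the second."""

    tokens: list[WordToken]
    list_id: str = "list1"

    def __post_init__(self) -> None:
        if len(self.tokens) != 16:
            raise InvalidParameterError("a word list holds exactly 16 tokens")
        n1 = sum(1 for t in self.tokens if t.stress == 1)
        if n1 != 11:
            raise InvalidParameterError(f"need 11 first-syllable-stressed tokens, got {n1}")


@dataclass
class BabbleTrack:
    """Stationary multitalker-like noise with a known plateau RMS."""

    audio: AudioBuffer
    plateau_rms: float

    def __post_init__(self) -> None:
        if self.plateau_rms <= 0:
            raise InvalidParameterError("plateau_rms must be positive")


# ---------------------------------------------------------------------------
# beats


def synth_beat(
    duration_ms: float = 15.0,
    freq_hz: float = 1000.0,
    rate: int = DEFAULT_RATE,
    peak: float = 0.79,
    ramp_ms: float = 2.0,
) -> AudioBuffer:
    """Render a brief pure-tone beat (default 15 ms, 1 kHz).

    A raised-cosine onset/offset ramp (default 2 ms) avoids clicks; the
    beat's nominal time in any timeline is its onset sample.
    """
    if duration_ms <= 0:
        raise InvalidParameterError("duration must be positive")
    if freq_hz <= 0 or freq_hz >= rate / 2:
        raise InvalidParameterError("frequency must be in (0, rate/2)")
    n = int(round(duration_ms / 1000.0 * rate))
    t = np.arange(n) / rate
    x = np.sin(2 * np.pi * freq_hz * t)
    nr = min(int(round(ramp_ms / 1000.0 * rate)), n // 2)
    if nr > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
        x[:nr] *= ramp
        x[-nr:] *= ramp[::-1]
    x *= peak / np.max(np.abs(x))
    return AudioBuffer(x, rate)


# ---------------------------------------------------------------------------
# word tokens

_STRESS_GAIN_DB = 4.0  # stressed syllable peak boost
_STRESS_DUR_FACTOR = 1.3


def _syllable(
    dur_s: float, peak: float, f0_hz: float, rate: int
) -> tuple[np.ndarray, int]:
    """One syllable burst; returns (samples, index of the 50% envelope crossing).

    Envelope is gamma-like, (t/tr)^2 exp(2(1 - t/tr)) with rise time tr =
    dur/4, faded to zero over the final 20% so bursts end silently.  The
    carrier is a single vowel-range tone: its Hilbert envelope tracks the
    synthesis envelope closely enough for sample-exact landmark recovery.
    """
    n = int(round(dur_s * rate))
    t = np.arange(n) / rate
    tr = dur_s / 4.0
    env = (t / tr) ** 2 * np.exp(2.0 * (1.0 - t / tr))
    nf = max(int(0.2 * n), 2)
    fade = 0.5 * (1 + np.cos(np.pi * np.arange(nf) / (nf - 1)))
    env[-nf:] *= fade
    env *= peak / env.max()
    cross = int(np.argmax(env >= 0.5 * env.max()))
    x = env * np.sin(2 * np.pi * f0_hz * t)
    return x, cross


def synth_word_token(
    ipi_s: float,
    stress: int,
    seed: int,
    rate: int = DEFAULT_RATE,
    base_peak: float = 0.5,
    base_dur_s: float = 0.18,
    word_id: str | None = None,
) -> WordToken:
    """Synthesize a bisyllabic token whose P-centers are exact by construction.

    The second syllable is placed so that the two 50%-envelope landmarks are
    exactly ``round(ipi_s * rate)`` samples apart; the stressed syllable gets
    a +4 dB peak and a 1.3x duration.
    """
    lo, hi = IPI_BOUNDS_S
    if not (lo <= ipi_s <= hi):
        raise InvalidParameterError(f"ipi_s must lie in [{lo}, {hi}] s")
    if stress not in (1, 2):
        raise InvalidParameterError("stress must be 1 or 2")
    rng = np.random.default_rng(seed)
    gain = 10 ** (_STRESS_GAIN_DB / 20.0)
    peaks = (base_peak * gain, base_peak) if stress == 1 else (base_peak, base_peak * gain)
    durs = (
        (base_dur_s * _STRESS_DUR_FACTOR, base_dur_s)
        if stress == 1
        else (base_dur_s, base_dur_s * _STRESS_DUR_FACTOR)
    )
    f0s = rng.uniform(180.0, 360.0, size=2)

    s1, c1 = _syllable(durs[0], peaks[0], f0s[0], rate)
    s2, c2 = _syllable(durs[1], peaks[1], f0s[1], rate)

    lead = int(round(0.05 * rate))  # silence before syllable 1
    ipi_n = int(round(ipi_s * rate))
    on1 = lead
    on2 = lead + c1 + ipi_n - c2
    if on2 < on1 + len(s1) // 2:
        raise InvalidParameterError("ipi_s too short for the syllable durations")
    total = on2 + len(s2) + int(round(0.03 * rate))
    x = np.zeros(total)
    x[on1 : on1 + len(s1)] += s1
    x[on2 : on2 + len(s2)] += s2
    if word_id is None:
        word_id = f"w{seed:06d}"
    return WordToken(
        audio=AudioBuffer(x, rate),
        p1=(on1 + c1) / rate,
        p2=(on2 + c2) / rate,
        stress=stress,
        word_id=word_id,
        syllable_spans=(
            (on1 / rate, (on1 + len(s1)) / rate),
            (on2 / rate, (on2 + len(s2)) / rate),
        ),
    )


def measure_pcenters(token: WordToken, smooth_ms: float = 0.5) -> tuple[float, float]:
    """Re-measure both P-centers from the rendered audio.

    Takes the magnitude of the analytic signal, smooths it with a zero-phase
    Gaussian, and finds the first 50%-of-peak crossing within each syllable's
    span.  Under the synthesis conventions this recovers ``p1``/``p2`` to
    within one sample.
    """
    rate = token.audio.rate
    env = np.abs(hilbert(token.audio.samples))
    env = gaussian_filter1d(env, sigma=smooth_ms / 1000.0 * rate)
    out = []
    for start_s, end_s in token.syllable_spans:
        i0, i1 = int(round(start_s * rate)), int(round(end_s * rate))
        seg = env[i0:i1]
        cross = int(np.argmax(seg >= 0.5 * seg.max()))
        out.append((i0 + cross) / rate)
    return out[0], out[1]


def sample_ipis(
    n: int,
    mean_s: float = IPI_MEAN_S,
    sd_s: float = IPI_SD_S,
    bounds_s: tuple[float, float] = IPI_BOUNDS_S,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw IPIs from a truncated normal by rejection sampling."""
    if rng is None:
        rng = np.random.default_rng()
    lo, hi = bounds_s
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean_s, sd_s, size=2 * (n - filled) + 8)
        keep = draw[(draw >= lo) & (draw <= hi)][: n - filled]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def make_word_list(
    seed: int,
    n_words: int = 16,
    n_stress1: int = 11,
    ipi_mean_s: float = IPI_MEAN_S,
    ipi_sd_s: float = IPI_SD_S,
    ipi_bounds_s: tuple[float, float] = IPI_BOUNDS_S,
    rate: int = DEFAULT_RATE,
    list_id: str = "list1",
) -> WordList:
    """Build a 16-word list (11 first-syllable stressed, 5 second) with
    truncated-normal IPIs; the seed governs IPIs, stress order and tokens."""
    if n_stress1 > n_words:
        raise InvalidParameterError("n_stress1 cannot exceed n_words")
    rng = np.random.default_rng(seed)
    ipis = sample_ipis(n_words, ipi_mean_s, ipi_sd_s, ipi_bounds_s, rng)
    stresses = np.array([1] * n_stress1 + [2] * (n_words - n_stress1))
    rng.shuffle(stresses)
    token_seeds = rng.integers(0, 2**31 - 1, size=n_words)
    tokens = [
        synth_word_token(
            float(ipi), int(st), int(ts), rate=rate, word_id=f"{list_id}_w{i:02d}"
        )
        for i, (ipi, st, ts) in enumerate(zip(ipis, stresses, token_seeds))
    ]
    return WordList(tokens=tokens, list_id=list_id)


# ---------------------------------------------------------------------------
# babble


def synth_babble(
    duration_s: float,
    n_streams: int = 8,
    seed: int = 0,
    rate: int = DEFAULT_RATE,
    plateau_rms: float = 0.05,
    band_hz: tuple[float, float] = (100.0, 8000.0),
    mod_band_hz: tuple[float, float] = (2.0, 8.0),
    mod_depth: float = 0.5,
) -> BabbleTrack:
    """Stationary multitalker-like babble.

    Sum of independent speech-band noise streams, each amplitude-modulated
    at syllabic rates (2-8 Hz), normalized to ``plateau_rms``.  The high band
    edge is clipped below Nyquist so low-rate renderings stay valid.
    """
    if duration_s <= 0:
        raise InvalidParameterError("duration must be positive")
    if n_streams < 2:
        raise InvalidParameterError("need at least 2 streams")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate))
    lo = band_hz[0]
    hi = min(band_hz[1], 0.45 * rate)
    sos_carrier = butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    sos_mod = butter(2, list(mod_band_hz), btype="bandpass", fs=rate, output="sos")
    pad = rate  # discard 1 s per edge: low-rate bandpass edge transients
    total = np.zeros(n)
    for _ in range(n_streams):
        noise = sosfiltfilt(sos_carrier, rng.standard_normal(n))
        mod = sosfiltfilt(sos_mod, rng.standard_normal(n + 2 * pad))[pad:-pad]
        mod /= max(np.std(mod), 1e-12)
        env = np.clip(1.0 + mod_depth * mod, 0.05, None)
        total += noise * env
    total *= plateau_rms / np.sqrt(np.mean(total**2))
    peak = np.max(np.abs(total))
    if peak > 1.0:
        total /= peak * 1.01
    return BabbleTrack(audio=AudioBuffer(total, rate), plateau_rms=float(np.sqrt(np.mean(total**2))))


# ---------------------------------------------------------------------------
# I/O


def write_wav(path, buf: AudioBuffer, dtype: str = "float32") -> None:
    """Write mono WAV (float32 by default, or 16-bit PCM)."""
    if dtype == "float32":
        wavfile.write(path, buf.rate, buf.samples.astype(np.float32))
    elif dtype == "pcm16":
        wavfile.write(path, buf.rate, np.round(buf.samples * 32767).astype(np.int16))
    else:
        raise InvalidParameterError("dtype must be 'float32' or 'pcm16'")


def read_wav(path) -> AudioBuffer:
    rate, data = wavfile.read(path)
    if data.dtype == np.int16:
        data = data / 32767.0
    return AudioBuffer(np.asarray(data, dtype=np.float64), int(rate))


def save_token(token: WordToken, directory) -> None:
    """WAV plus JSON sidecar carrying the ground-truth metadata."""
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_wav(d / f"{token.word_id}.wav", token.audio)
    meta = {
        "word_id": token.word_id,
        "p1": token.p1,
        "p2": token.p2,
        "stress": token.stress,
        "syllable_spans": token.syllable_spans,
        "rate": token.audio.rate,
    }
    (d / f"{token.word_id}.json").write_text(json.dumps(meta, indent=2))


def load_token(directory, word_id: str) -> WordToken:
    from pathlib import Path

    d = Path(directory)
    meta = json.loads((d / f"{word_id}.json").read_text())
    audio = read_wav(d / f"{word_id}.wav")
    spans = tuple(tuple(s) for s in meta["syllable_spans"])
    return WordToken(
        audio=audio,
        p1=meta["p1"],
        p2=meta["p2"],
        stress=meta["stress"],
        word_id=meta["word_id"],
        syllable_spans=spans,  # type: ignore[arg-type]
    )
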