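"""Auditory stimulus construction and adaptive threshold procedures.

This module builds the acoustic side of a continuous speech-in-noise
detection experiment:

* RMS normalisation and Hann on/off ramps for 1-s speech snippets,
* speech-shaped noise (SSN) whose long-term magnitude spectrum matches the
  snippet ensemble but whose phases are randomised,
* pseudo-random inter-stimulus-interval (ISI) schedules in which an
  identical 50-s sub-block pattern — short ISIs first, long ISIs last — is
  tiled across the session,
* an individual-hearing-level (IHL) bracketing procedure (descend in 2-dB
  steps to "not hearing", drop 10 dB, ascend to "hearing again", repeated
  three times),
* a transformed up-down (1-up/2-down) staircase converging on the 70.7%
  detection point of the observer's psychometric function,
* assembly of the full session audio with ground-truth event tables.

Simulated observers stand in for participants: any callable mapping a
stimulus level in dB to a detection probability can drive the adaptive
procedures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Waveform",
    "ISIScheduleConfig",
    "ISISchedule",
    "StaircaseConfig",
    "StaircaseRun",
    "IHLConfig",
    "Observer",
    "rms_normalize",
    "hann_ramp",
    "make_ssn",
    "build_isi_schedule",
    "run_staircase",
    "estimate_ihl",
    "assemble_session",
]

STIMULUS_RATE = 50_000.0  # Hz; playback-hardware rate for all stimuli


@dataclass(frozen=True)
class Waveform:
    """A mono waveform in arbitrary amplitude units."""

    samples: np.ndarray
    rate: float = STIMULUS_RATE

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ValueError("Waveform samples must be 1-D")
        if not np.all(np.isfinite(samples)):
            raise ValueError("Waveform contains non-finite samples")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))


def rms_normalize(wave: Waveform, target_rms: float) -> Waveform:
    """Scale ``wave`` so its root-mean-square amplitude equals ``target_rms``."""
    if target_rms <= 0:
        raise ValueError("target_rms must be positive")
    rms = wave.rms()
    if rms == 0.0:
        raise ValueError("cannot RMS-normalize an all-zero waveform")
    return replace(wave, samples=wave.samples * (target_rms / rms))


def hann_ramp(wave: Waveform, ramp_ms: float = 100.0) -> Waveform:
    """Smooth onset and offset with raised-cosine (Hann) ramps.

    The first sample is scaled to 0, the gain reaches 0.5 at the ramp
    midpoint and 1 at the end of the ramp; the interior is untouched.
    """
    n_ramp = int(round(ramp_ms / 1000.0 * wave.rate))
    if wave.samples.size < 2 * n_ramp:
        raise ValueError("waveform shorter than two ramps")
    gain = np.ones(wave.samples.size)
    # rising half of a Hann window: sin^2(pi/2 * t/ramp)
    t = np.arange(n_ramp) / n_ramp
    ramp = np.sin(0.5 * np.pi * t) ** 2
    gain[:n_ramp] = ramp
    gain[-n_ramp:] = ramp[::-1]
    return replace(wave, samples=wave.samples * gain)


def _ensemble_magnitude(snippets: Sequence[Waveform], n_fft: int) -> np.ndarray:
    """Mean magnitude spectrum of the snippet ensemble on an ``n_fft`` grid."""
    mags = np.zeros(n_fft // 2 + 1)
    for sn in snippets:
        mags += np.abs(np.fft.rfft(sn.samples, n=n_fft))
    return mags / len(snippets)


def make_ssn(
    snippets: Sequence[Waveform],
    duration: float,
    seed: int,
    rms: float | None = None,
) -> Waveform:
    """Speech-shaped noise: the ensemble magnitude spectrum with random phases.

    The magnitude spectra of all snippets (zero-padded to a common length)
    are averaged; segments of that length are synthesised with fresh
    uniform-random phases each, tiled, and cropped to ``duration``. Hermitian
    symmetry of the spectrum is implicit in the use of the real inverse FFT,
    so the output is exactly real-valued.
    """
    if not snippets:
        raise ValueError("need at least one speech snippet")
    rate = snippets[0].rate
    if any(sn.rate != rate for sn in snippets):
        raise ValueError("snippets must share a common sampling rate")
    if duration <= 0:
        raise ValueError("duration must be positive")
    n_fft = max(sn.samples.size for sn in snippets)
    mag = _ensemble_magnitude(snippets, n_fft)
    rng = np.random.default_rng(seed)
    n_out = int(round(duration * rate))
    pieces = []
    produced = 0
    while produced < n_out:
        phases = rng.uniform(0.0, 2.0 * np.pi, mag.size)
        spec = mag * np.exp(1j * phases)
        spec[0] = mag[0]  # DC must stay real
        if n_fft % 2 == 0:
            spec[-1] = mag[-1]  # Nyquist bin real for even lengths
        piece = np.fft.irfft(spec, n=n_fft)
        pieces.append(piece)
        produced += piece.size
    out = np.concatenate(pieces)[:n_out]
    wave = Waveform(out, rate)
    if rms is not None:
        wave = rms_normalize(wave, rms)
    return wave


# ---------------------------------------------------------------------------
# ISI schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ISIScheduleConfig:
    """Layout of the pseudo-random stimulus schedule.

    Defaults give three 10-min blocks of twelve 50-s sub-blocks each, with
    5 stimuli per sub-block (180 total) at 3-19 s ISI; within a sub-block
    the ISIs increase from short to long, and the identical onset pattern
    repeats in every sub-block.
    """

    block_length: float = 600.0
    n_blocks: int = 3
    subblock_length: float = 50.0
    subblocks_per_block: int = 12
    stimuli_per_subblock: int = 5
    isi_min: float = 3.0
    isi_max: float = 19.0

    def __post_init__(self):
        if self.subblock_length * self.subblocks_per_block != self.block_length:
            raise ValueError("sub-blocks must tile the block exactly")
        if not 0 < self.isi_min < self.isi_max:
            raise ValueError("need 0 < isi_min < isi_max")
        if self.stimuli_per_subblock * self.isi_min > self.subblock_length:
            raise ValueError("ISIs cannot fit in the sub-block")

    @property
    def n_stimuli(self) -> int:
        return self.stimuli_per_subblock * self.subblocks_per_block * self.n_blocks

    @property
    def duration(self) -> float:
        return self.block_length * self.n_blocks


@dataclass(frozen=True)
class ISISchedule:
    """Stimulus onset times for a whole session."""

    onsets: np.ndarray  # seconds, ascending
    config: ISIScheduleConfig

    def __post_init__(self):
        object.__setattr__(self, "onsets", np.asarray(self.onsets, float))

    @property
    def subblock_pattern(self) -> np.ndarray:
        """Onset offsets relative to the sub-block start (first sub-block)."""
        return self.onsets[: self.config.stimuli_per_subblock].copy()


def build_isi_schedule(
    config: ISIScheduleConfig | None = None, seed: int = 0
) -> ISISchedule:
    """Draw one sub-block ISI pattern and tile it across the session.

    The within-sub-block gaps are drawn once from ``[isi_min, isi_max]``,
    sorted ascending (short ISIs first, long last), and accepted only if the
    wrap-around gap into the next sub-block also lies in the ISI range; the
    frozen pattern then repeats in all sub-blocks, so every consecutive
    onset difference in the session respects the ISI bounds.
    """
    config = config or ISIScheduleConfig()
    rng = np.random.default_rng(seed)
    k = config.stimuli_per_subblock
    sub = config.subblock_length
    for _ in range(10_000):
        gaps = np.sort(rng.uniform(config.isi_min, config.isi_max, k - 1))
        wrap = sub - gaps.sum()  # gap from last onset to next sub-block's first
        if config.isi_min <= wrap <= config.isi_max:
            break
    else:
        raise ValueError("could not fit an ISI pattern into the sub-block")
    # place the first onset so the pattern ends isi-consistently at the wrap
    first = float(rng.uniform(0.0, min(wrap - config.isi_min, sub - gaps.sum())))
    offsets = first + np.concatenate(([0.0], np.cumsum(gaps)))
    n_sub = config.subblocks_per_block * config.n_blocks
    starts = np.arange(n_sub) * sub
    onsets = (starts[:, None] + offsets[None, :]).ravel()
    return ISISchedule(onsets=onsets, config=config)


# ---------------------------------------------------------------------------
# Observers
# ---------------------------------------------------------------------------


@dataclass
class Observer:
    """Simulated participant for the adaptive procedures.

    ``psychometric`` maps stimulus level (dB) to detection probability and
    must be monotonically non-decreasing; ``rt_sampler`` draws a response
    latency (s) given an RNG; ``fa_rate`` is the spontaneous false-alarm
    rate in responses/s used by the session simulator.
    """

    psychometric: Callable[[float], float]
    # RT truncated strictly inside the 0.3-1.8 s hit window (an RT exactly
    # on the boundary is ambiguous under floating-point classification)
    rt_sampler: Callable[[np.random.Generator], float] = field(
        default=lambda rng: float(
            np.clip(rng.lognormal(np.log(0.7), 0.3), 0.301, 1.799)
        )
    )
    fa_rate: float = 0.0

    def detects(self, level_db: float, rng: np.random.Generator) -> bool:
        p = float(self.psychometric(level_db))
        if not 0.0 <= p <= 1.0:
            raise ValueError("psychometric returned a probability outside [0, 1]")
        return bool(rng.random() < p)


def logistic_observer(midpoint_db: float = 0.0, slope_per_db: float = 1.0, **kw) -> Observer:
    """Observer with a logistic psychometric function."""

    def psychometric(level: float) -> float:
        return 1.0 / (1.0 + np.exp(-slope_per_db * (level - midpoint_db)))

    return Observer(psychometric=psychometric, **kw)


def step_observer(threshold_db: float, **kw) -> Observer:
    """Deterministic observer that detects iff level >= threshold."""
    return Observer(psychometric=lambda lv: 1.0 if lv >= threshold_db else 0.0, **kw)


# ---------------------------------------------------------------------------
# 1-up / 2-down staircase
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StaircaseConfig:
    """Transformed up-down staircase targeting 70.7% detection.

    One miss raises the level by the current step; two consecutive
    detections lower it (the two-down counter resets after every level
    change, Levitt-style). The step starts at 1 dB and halves to 0.5 dB
    after four reversals; the run stops after nine reversals and the
    threshold is the mean level at the last five reversal points.
    """

    step_initial: float = 1.0
    step_reduced: float = 0.5
    reversals_to_reduce: int = 4
    reversals_to_stop: int = 9
    reversals_averaged: int = 5
    max_trials: int = 200

    def __post_init__(self):
        if self.reversals_averaged > self.reversals_to_stop:
            raise ValueError("cannot average more reversals than are collected")
        if self.step_initial <= 0 or self.step_reduced <= 0:
            raise ValueError("step sizes must be positive")


@dataclass
class StaircaseRun:
    """Full trace of one staircase run."""

    levels: list[float]
    detected: list[bool]
    reversal_levels: list[float]
    threshold: float


def run_staircase(
    observer: Observer,
    cfg: StaircaseConfig | None = None,
    start_level: float = 0.0,
    seed: int = 0,
    return_run: bool = False,
):
    """Run a 1-up/2-down staircase against ``observer``; return the threshold.

    ``start_level`` should be the experimenter's rough prior estimate of
    the threshold. Starting inside the threshold region makes the first
    reversal's direction random; with a clearly audible start the track
    always descends first, and because an odd number of reversal levels is
    averaged, that parity biases the returned threshold toward the
    valleys of the staircase (about 2 percentage points below the 70.7%
    tracking target of the up-down rule).

    With ``return_run=True`` the full trial/reversal trace is returned
    instead, for diagnostics and verification.
    """
    cfg = cfg or StaircaseConfig()
    rng = np.random.default_rng(seed)
    level = float(start_level)
    step = cfg.step_initial
    down_count = 0
    direction = 0  # -1 descending, +1 ascending, 0 undetermined
    levels: list[float] = []
    detected: list[bool] = []
    reversal_levels: list[float] = []

    for _ in range(cfg.max_trials):
        det = observer.detects(level, rng)
        levels.append(level)
        detected.append(det)
        if det:
            down_count += 1
            move = -step if down_count == 2 else 0.0
        else:
            move = +step
        if move != 0.0:
            down_count = 0
            new_direction = -1 if move < 0 else +1
            if direction != 0 and new_direction != direction:
                reversal_levels.append(level)
                if len(reversal_levels) == cfg.reversals_to_reduce:
                    step = cfg.step_reduced
                if len(reversal_levels) >= cfg.reversals_to_stop:
                    break
            direction = new_direction
            level += move
    else:
        raise RuntimeError(
            f"staircase did not terminate within {cfg.max_trials} trials; "
            f"trace tail: levels={levels[-10:]}, detected={detected[-10:]}"
        )

    threshold = float(np.mean(reversal_levels[-cfg.reversals_averaged:]))
    if return_run:
        return StaircaseRun(levels, detected, reversal_levels, threshold)
    return threshold


# ---------------------------------------------------------------------------
# Individual hearing level
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IHLConfig:
    """Bracketing procedure on 400-ms noise bursts."""

    burst_ms: float = 400.0
    step_db: float = 2.0
    drop_db: float = 10.0
    repeats: int = 3
    max_steps: int = 500

    def __post_init__(self):
        if min(self.burst_ms, self.step_db, self.drop_db, self.repeats) <= 0:
            raise ValueError("all IHL parameters must be positive")


def estimate_ihl(
    observer: Observer,
    cfg: IHLConfig | None = None,
    start_level: float = 40.0,
    seed: int = 0,
) -> float:
    """Bracket the hearing level: descend to silence, drop, ascend to audibility.

    The level descends from ``start_level`` in ``step_db`` steps until the
    observer stops hearing, drops ``drop_db`` further, then ascends in
    ``step_db`` steps until the observer hears again. Both report levels are
    recorded; after ``repeats`` passes the mean of all report levels is the
    individual hearing level.
    """
    cfg = cfg or IHLConfig()
    rng = np.random.default_rng(seed)
    reports: list[float] = []
    for _ in range(cfg.repeats):
        level = float(start_level)
        for _ in range(cfg.max_steps):
            if not observer.detects(level, rng):
                break
            level -= cfg.step_db
        else:
            raise RuntimeError("observer never reported 'not hearing'")
        reports.append(level)
        level -= cfg.drop_db
        for _ in range(cfg.max_steps):
            if observer.detects(level, rng):
                break
            level += cfg.step_db
        else:
            raise RuntimeError("observer never reported 'hearing again'")
        reports.append(level)
    return float(np.mean(reports))


# ---------------------------------------------------------------------------
# Session assembly
# ---------------------------------------------------------------------------


def assemble_session(
    ssn: Waveform,
    snippets: Sequence[Waveform],
    schedule: ISISchedule | np.ndarray,
    threshold_db: float,
    mode: str = "main",
    seed: int = 0,
    bp_n_stimuli: int = 60,
    bp_period: float = 10.0,
    bp_jitter: float = 1.0,
):
    """Embed speech snippets in the noise bed with per-trial level roving.

    In ``main`` mode the snippets are placed at the schedule onsets with
    levels drawn uniformly in ``threshold_db`` +/- 1.5 dB. In
    ``button_press`` mode 60 snippets are placed every 10 +/- 1 s at levels
    uniform in ``threshold_db`` + [5, 6] dB (clearly audible).

    Levels are expressed relative to a unit-RMS snippet: a snippet presented
    at level L is scaled to RMS ``10**(L/20)`` in the units of the noise bed.

    Returns ``(audio: Waveform, events: list[dict])`` where each event has
    keys ``onset_s``, ``type`` and ``level_db``.
    """
    rng = np.random.default_rng(seed)
    rate = ssn.rate
    if any(sn.rate != rate for sn in snippets):
        raise ValueError("snippet rate must match the noise rate")
    if mode == "main":
        onsets = schedule.onsets if isinstance(schedule, ISISchedule) else np.asarray(schedule, float)
        levels = rng.uniform(threshold_db - 1.5, threshold_db + 1.5, onsets.size)
    elif mode == "button_press":
        gaps = rng.uniform(bp_period - bp_jitter, bp_period + bp_jitter, bp_n_stimuli)
        onsets = np.cumsum(gaps) - gaps[0] + bp_period / 2.0
        levels = rng.uniform(threshold_db + 5.0, threshold_db + 6.0, onsets.size)
    else:
        raise ValueError("mode must be 'main' or 'button_press'")

    audio = ssn.samples.copy()
    events = []
    last_end = -np.inf
    for onset, level in zip(onsets, levels):
        sn = snippets[rng.integers(len(snippets))]
        i0 = int(round(onset * rate))
        i1 = i0 + sn.samples.size
        if i1 > audio.size:
            raise ValueError(f"snippet at {onset:.2f} s exceeds the noise bed")
        if i0 < last_end:
            raise ValueError(f"snippet at {onset:.2f} s overlaps the previous one")
        last_end = i1
        rms = sn.rms()
        gain = 10.0 ** (level / 20.0) / rms if rms > 0 else 0.0
        audio[i0:i1] += sn.samples * gain
        events.append({"onset_s": float(onset), "type": "stim", "level_db": float(level)})
    return Waveform(audio, rate), events
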