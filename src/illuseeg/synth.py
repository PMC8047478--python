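"""Synthetic behavioral and EEG data with full ground truth.

The generator emulates the statistical structure the analysis chain
assumes, so every stage can be exercised and validated without recorded
data:

* spatially correlated 1/f ("pink") background EEG,
* an early centro-parietal negativity (EN) and a late centro-parietal
  positivity (LP) added to perceived trials as Gaussian-windowed
  deflections,
* a 1-4 Hz (slow cortical potential, SCP) power enhancement and alpha/beta
  event-related desynchronisation (ERD) around responses, implemented as
  band-limited amplitude modulation of the background noise,
* a simulated observer producing hits, misses, FAs and CRs on the session's
  ISI schedule.

Condition defaults encode the qualitative result pattern of the task: hits
and FAs carry EN + LP + SCP (the FA deflections scaled down), misses and
CRs are noise only, and button presses carry only motor ERD. Effect
amplitudes default to the magnitudes reported for this paradigm
(response-aligned LP about 7.5 µV in hits and 4.2 µV in FAs, EN about
-2.7 to -2.9 µV).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import channels as _channels
from .classify import EventStream
from .preprocess import EpochSet
from .stimulus import ISISchedule, Observer

__all__ = [
    "EffectSpec",
    "GroundTruth",
    "pink_noise",
    "topography_template",
    "add_component",
    "simulate_subject",
    "simulate_dataset",
    "simulate_observer_session",
    "default_ground_truth",
    "DEFAULT_TRIALS",
]

CONDITIONS = ("hit_stim", "hit_resp", "miss", "fa", "cr", "bp")

#: Default trials per condition: the study's mean clean trial counts
#: (hits 107.9, FAs 66.9, misses 56.9, 60 button presses); correct
#: rejections have no defined trial count in a continuous design, so they
#: default to the button-press count.
DEFAULT_TRIALS = {
    "hit_stim": 108,
    "hit_resp": 108,
    "miss": 57,
    "fa": 67,
    "cr": 60,
    "bp": 60,
}


@dataclass(frozen=True)
class EffectSpec:
    """One planted effect.

    ``kind='erp'`` adds ``amplitude * exp(-(t - latency)^2 / (2 width^2))``
    times the topography to every trial. ``kind='band'`` multiplies the
    band-limited part of the noise by ``sqrt(1 + amplitude * envelope(t))``
    so the band power changes by ``amplitude`` (relative) at the envelope
    peak — positive for the SCP enhancement, negative for ERDs.
    """

    name: str
    kind: str  # 'erp' | 'band'
    amplitude: float  # µV (erp) or relative power change (band)
    latency: float  # s, envelope/bump center
    width: float  # s, Gaussian std (erp) or envelope half-duration (band)
    topography: np.ndarray  # per-channel weights in [0, 1]
    band: tuple[float, float] | None = None  # Hz, for kind='band'

    def __post_init__(self):
        if self.kind not in ("erp", "band"):
            raise ValueError("kind must be 'erp' or 'band'")
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.kind == "band" and self.band is None:
            raise ValueError("band effects need a frequency band")
        topo = np.asarray(self.topography, float)
        if not np.all(np.isfinite(topo)):
            raise ValueError("topography must be finite")
        object.__setattr__(self, "topography", topo)


@dataclass(frozen=True)
class NoiseModel:
    exponent: float = 1.0  # PSD ~ f^-exponent
    sigma: float = 20.0  # µV per channel
    spatial_mix: float = 0.5  # fraction of variance shared across channels


@dataclass(frozen=True)
class GroundTruth:
    """Planted effects per condition plus the noise and observer models."""

    effects: dict[str, tuple[EffectSpec, ...]]
    noise: NoiseModel = NoiseModel()
    channel_labels: tuple[str, ...] = _channels.LAYOUT_64
    rate: float = 200.0
    window: tuple[float, float] = (-4.6, 1.9)  # response-aligned epoch, s
    between_subject_sd: float = 0.15  # relative amplitude variability
    fa_scale: float = 0.6  # LP/SCP scaling in FAs relative to hits


def topography_template(
    labels, centers=("Pz", "CPz"), falloff: float = 0.7
) -> np.ndarray:
    """Cosine falloff from the nearest center electrode, clipped at zero.

    ``falloff`` is the unit-head distance at which the weight reaches zero;
    weights are 1 at a center and decay as ``cos(pi/2 * d / falloff)``.
    """
    pos = _channels.channel_positions(tuple(labels))
    cpos = _channels.channel_positions(tuple(centers))
    d = np.linalg.norm(pos[:, None, :] - cpos[None, :, :], axis=2).min(axis=1)
    w = np.cos(np.clip(d / falloff, 0.0, 1.0) * np.pi / 2.0)
    return np.clip(w, 0.0, None)


def default_ground_truth(
    labels=_channels.LAYOUT_64,
    rate: float = 200.0,
    window: tuple[float, float] = (-4.6, 1.9),
    noise: NoiseModel | None = None,
) -> GroundTruth:
    """Ground truth encoding the qualitative result pattern of the task.

    Response-aligned timings: LP peaks at -25 ms (hits) / -15 ms (FAs),
    EN troughs at -250 ms / -415 ms; alpha and beta ERD center on the
    response. Stimulus-aligned hits place the LP at 800 ms and the EN at
    345 ms.
    """
    labels = tuple(labels)
    cp = topography_template(labels, centers=("Pz", "CPz"))
    motor = topography_template(labels, centers=("C3", "C4"), falloff=0.5)

    def erp_fx(name, amp, lat, width, topo=cp):
        return EffectSpec(name, "erp", amp, lat, width, topo)

    def band_fx(name, rel, lat, width, band, topo):
        return EffectSpec(name, "band", rel, lat, width, topo, band=band)

    scp = band_fx("SCP", 0.5, -0.2, 0.5, (1.0, 4.0), cp)
    alpha_erd = band_fx("alphaERD", -0.4, 0.0, 0.6, (8.0, 12.0), motor)
    beta_erd = band_fx("betaERD", -0.3, -0.1, 0.5, (15.0, 25.0), motor)

    resp_hit = (
        erp_fx("EN", -2.7, -0.25, 0.12),
        erp_fx("LP", 7.5, -0.025, 0.15),
        scp,
        alpha_erd,
        beta_erd,
    )
    resp_fa = (
        erp_fx("EN", -2.9, -0.415, 0.12),
        erp_fx("LP", 4.2, -0.015, 0.15),
        replace(scp, amplitude=scp.amplitude * 0.6),
        alpha_erd,
        beta_erd,
    )
    stim_hit = (
        erp_fx("EN", -2.1, 0.345, 0.12),
        erp_fx("LP", 2.5, 0.8, 0.25),
        replace(scp, latency=0.6),
        replace(alpha_erd, latency=0.8),
        replace(beta_erd, latency=0.7),
    )
    effects = {
        "hit_stim": stim_hit,
        "hit_resp": resp_hit,
        "miss": (),
        "fa": resp_fa,
        "cr": (),
        "bp": (alpha_erd, beta_erd),
    }
    return GroundTruth(
        effects=effects,
        noise=noise or NoiseModel(),
        channel_labels=labels,
        rate=rate,
        window=window,
    )


def pink_noise(
    n_samples: int,
    n_channels: int,
    exponent: float = 1.0,
    sigma: float = 20.0,
    seed: int | np.random.Generator = 0,
    spatial_mix: float = 0.0,
) -> np.ndarray:
    """Zero-mean 1/f noise, channels x samples, std ``sigma`` per channel.

    The PSD falls as ``f^-exponent``; ``spatial_mix`` is the fraction of
    variance contributed by a component shared across all channels, giving
    spatially correlated background activity.
    """
    if not 0.5 <= exponent <= 2.0:
        raise ValueError("exponent must be in [0.5, 2]")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_src = n_channels + 1 if spatial_mix > 0 else n_channels
    freqs = np.fft.rfftfreq(n_samples)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    white = rng.standard_normal((n_src, n_samples))
    spec = np.fft.rfft(white, axis=1) * shaping[None, :]
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    x -= x.mean(axis=1, keepdims=True)
    x /= x.std(axis=1, keepdims=True)
    if spatial_mix > 0:
        shared, own = x[-1], x[:-1]
        x = np.sqrt(spatial_mix) * shared[None, :] + np.sqrt(1 - spatial_mix) * own
    return sigma * x


def _band_mask(n: int, rate: float, band: tuple[float, float]) -> np.ndarray:
    f = np.fft.rfftfreq(n, 1.0 / rate)
    return (f >= band[0]) & (f <= band[1])


def add_component(epochs: EpochSet, spec: EffectSpec, scale: float = 1.0) -> EpochSet:
    """Plant ``spec`` (scaled by ``scale``) into every trial of ``epochs``."""
    t = epochs.times
    if not (t[0] <= spec.latency <= t[-1]):
        raise ValueError(f"effect {spec.name!r} latency outside the epoch")
    topo = spec.topography[: epochs.n_channels]
    if spec.kind == "erp":
        bump = spec.amplitude * scale * np.exp(-((t - spec.latency) ** 2) / (2 * spec.width**2))
        return replace(epochs, data=epochs.data + topo[None, :, None] * bump[None, None, :])
    # band-limited amplitude modulation: split each trial into band + rest,
    # scale the band part so power changes by amplitude*envelope at the peak.
    # The modulated band is widened by the Morlet spectral FWHM at its edges:
    # the analysis wavelets integrate over that width, so a sharp-edged
    # modulation would read out diluted.
    from .ersp import spectral_fwhm

    env = np.exp(-((t - spec.latency) ** 2) / (2 * (spec.width / 2.0) ** 2))
    lo, hi = spec.band
    wide = (max(lo - float(spectral_fwhm(lo)), 0.0), hi + float(spectral_fwhm(hi)))
    mask = _band_mask(t.size, epochs.rate, wide)
    spec_data = np.fft.rfft(epochs.data, axis=2)
    band_part = np.fft.irfft(spec_data * mask[None, None, :], n=t.size, axis=2)
    rest = epochs.data - band_part
    gain = np.sqrt(np.clip(1.0 + spec.amplitude * scale * env, 0.0, None))
    # interpolate the gain between 1 (topography weight 0) and full effect
    g = 1.0 + topo[None, :, None] * (gain[None, None, :] - 1.0)
    return replace(epochs, data=rest + band_part * g)


def _pink_batch(n_samples, n_rows, exponent, rng) -> np.ndarray:
    """Unit-variance 1/f rows, generated in one batched FFT."""
    freqs = np.fft.rfftfreq(n_samples)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = np.fft.rfft(rng.standard_normal((n_rows, n_samples)), axis=1)
    x = np.fft.irfft(spec * shaping[None, :], n=n_samples, axis=1)
    x -= x.mean(axis=1, keepdims=True)
    x /= x.std(axis=1, keepdims=True)
    return x


def _make_epochs(gt: GroundTruth, n_trials, rng, condition, alignment) -> EpochSet:
    pre, post = gt.window
    n_t = int(round((post - pre) * gt.rate)) + 1
    times = pre + np.arange(n_t) / gt.rate
    n_ch = len(gt.channel_labels)
    mix = gt.noise.spatial_mix
    # one shared + n_ch independent 1/f sources per trial, batched
    rows = _pink_batch(n_t, n_trials * (n_ch + 1), gt.noise.exponent, rng)
    rows = rows.reshape(n_trials, n_ch + 1, n_t)
    shared, own = rows[:, :1, :], rows[:, 1:, :]
    data = gt.noise.sigma * (
        np.sqrt(mix) * shared + np.sqrt(1.0 - mix) * own
    )
    return EpochSet(
        data=data,
        times=times,
        rate=gt.rate,
        alignment=alignment,
        condition=condition,
        channel_labels=gt.channel_labels,
        channel_positions=_channels.channel_positions(gt.channel_labels),
    )


_ALIGNMENT = {
    "hit_stim": "stimulus",
    "hit_resp": "response",
    "miss": "stimulus",
    "fa": "response",
    "cr": "none",
    "bp": "response",
}


def simulate_subject(
    gt: GroundTruth,
    n_trials: dict[str, int] | int | None = None,
    seed: int = 0,
    amplitude_scale: float = 1.0,
    conditions=CONDITIONS,
) -> dict[str, EpochSet]:
    """Epoch sets for one subject, one per requested condition.

    ``amplitude_scale`` multiplies every planted effect (used for
    between-subject variability); noise is freshly drawn per condition.
    """
    rng = np.random.default_rng(seed)
    if n_trials is None:
        n_trials = DEFAULT_TRIALS
    elif isinstance(n_trials, int):
        n_trials = {c: n_trials for c in conditions}
    out = {}
    for cond in conditions:
        ep = _make_epochs(gt, n_trials[cond], rng, cond, _ALIGNMENT[cond])
        for spec in gt.effects.get(cond, ()):
            ep = add_component(ep, spec, scale=amplitude_scale)
        out[cond] = ep
    return out


def simulate_dataset(
    gt: GroundTruth,
    n_subjects: int = 16,
    n_trials: dict[str, int] | int | None = None,
    seed: int = 0,
    conditions=CONDITIONS,
) -> list[dict[str, EpochSet]]:
    """A group dataset: ``n_subjects`` independent subjects.

    Each subject receives an amplitude scale drawn from
    ``Normal(1, between_subject_sd)`` (truncated at 0.1) applied to all
    planted effects, and an independent noise stream; everything is a
    deterministic function of ``seed``.
    """
    root = np.random.default_rng(seed)
    subjects = []
    for _ in range(n_subjects):
        sub_seed = int(root.integers(2**31 - 1))
        scale = float(np.clip(root.normal(1.0, gt.between_subject_sd), 0.1, None))
        subjects.append(
            simulate_subject(gt, n_trials, seed=sub_seed, amplitude_scale=scale,
                             conditions=conditions)
        )
    return subjects


def simulate_observer_session(
    observer: Observer,
    schedule: ISISchedule | np.ndarray,
    levels: np.ndarray | float = 0.0,
    seed: int = 0,
    fa_lockout: float = 3.6,
) -> tuple[EventStream, dict]:
    """Behavioral event stream for an observer run on a stimulus schedule.

    Each stimulus is detected with the psychometric probability at its
    level; detected stimuli get a response at onset + RT (RT drawn from the
    observer's sampler, truncated to the hit window). Spontaneous false
    alarms arrive as a Poisson process at ``observer.fa_rate`` per second,
    suppressed within ``fa_lockout`` seconds after any stimulus onset.

    Returns the stream and the generating truth
    (``{'stim_truth': [...], 'fa_times': [...]}``).
    """
    rng = np.random.default_rng(seed)
    onsets = schedule.onsets if isinstance(schedule, ISISchedule) else np.asarray(schedule, float)
    duration = (
        schedule.config.duration
        if isinstance(schedule, ISISchedule)
        else float(onsets[-1] + 10.0)
    )
    levels = np.broadcast_to(np.asarray(levels, float), onsets.shape)
    responses = []
    stim_truth = []
    for onset, level in zip(onsets, levels):
        if observer.detects(level, rng):
            rt = float(observer.rt_sampler(rng))
            responses.append(onset + rt)
            stim_truth.append("hit")
        else:
            stim_truth.append("miss")
    fa_times = []
    if observer.fa_rate > 0:
        t = 0.0
        while True:
            t += rng.exponential(1.0 / observer.fa_rate)
            if t >= duration:
                break
            since_stim = t - onsets[onsets <= t]
            if since_stim.size and since_stim.min() <= fa_lockout:
                continue
            # keep FAs clear of upcoming stimuli as well
            until_stim = onsets[onsets > t] - t
            if until_stim.size and until_stim.min() < 0.5:
                continue
            fa_times.append(t)
    responses = np.unique(np.asarray(responses + fa_times))
    stream = EventStream(
        stim_onsets=onsets, responses=responses, duration=duration
    )
    return stream, {"stim_truth": stim_truth, "fa_times": np.asarray(fa_times)}
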