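"""Morlet wavelet time-frequency analysis and event-related spectral
perturbations (ERSP).

The wavelet bank spans 1-45 Hz with the number of cycles ``n`` increasing
linearly from 3 at 1 Hz to 10 at 45 Hz. Each wavelet is a complex sine
tapered by a Gaussian with envelope std ``sigma_t = n / (2 pi f)``, giving
the closed-form widths

* temporal FDHM (full-duration at half-maximum of the envelope)
  ``n * sqrt(2 ln 2) / (pi f)`` — from 1.124 s at 1 Hz down to 83 ms at
  45 Hz,
* spectral FWHM ``2 sqrt(2 ln 2) * f / n`` — from 0.78 Hz up to 10.60 Hz,

whose product is the constant ``4 ln 2 / pi``. Power is evaluated on a
10-ms time grid and a 0.2-Hz frequency grid (the wavelets are evaluated
directly on that grid rather than interpolated). The ERSP is the trial
average of wavelet power, and baseline normalisation keeps a per-frequency
margin of one FDHM between baseline and activation so that temporal
smearing of the wavelet cannot leak activation power into the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import fftconvolve

from .preprocess import EpochSet

__all__ = [
    "WaveletBank",
    "TFR",
    "cycles_at",
    "fdhm",
    "spectral_fwhm",
    "make_wavelet",
    "tfr_transform",
    "ersp",
    "relative_baseline",
    "band_trace",
    "BANDS",
]

#: Analysis bands in Hz: slow cortical potentials, alpha, beta.
BANDS = {"scp": (1.0, 4.0), "alpha": (8.0, 12.0), "beta": (15.0, 25.0)}

_F_LO, _F_HI = 1.0, 45.0
_N_LO, _N_HI = 3.0, 10.0


def cycles_at(f: float, f_range=(_F_LO, _F_HI), n_range=(_N_LO, _N_HI)) -> float:
    """Cycle count at frequency ``f``: linear from 3 at 1 Hz to 10 at 45 Hz."""
    f = np.asarray(f, float)
    lo, hi = f_range
    if np.any(f < lo) or np.any(f > hi):
        raise ValueError(f"frequency outside the bank range [{lo}, {hi}] Hz")
    n_lo, n_hi = n_range
    return n_lo + (n_hi - n_lo) * (f - lo) / (hi - lo)


def fdhm(f, n=None) -> float:
    """Temporal full-duration at half-maximum, ``n sqrt(2 ln 2) / (pi f)`` s."""
    f = np.asarray(f, float)
    n = cycles_at(f) if n is None else np.asarray(n, float)
    return n * np.sqrt(2.0 * np.log(2.0)) / (np.pi * f)


def spectral_fwhm(f, n=None) -> float:
    """Spectral full-width at half-maximum, ``2 sqrt(2 ln 2) f / n`` Hz."""
    f = np.asarray(f, float)
    n = cycles_at(f) if n is None else np.asarray(n, float)
    return 2.0 * np.sqrt(2.0 * np.log(2.0)) * f / n


def sigma_t(f, n=None) -> float:
    """Gaussian envelope standard deviation, ``n / (2 pi f)`` s."""
    f = np.asarray(f, float)
    n = cycles_at(f) if n is None else np.asarray(n, float)
    return n / (2.0 * np.pi * f)


def make_wavelet(f: float, rate: float, n: float | None = None) -> np.ndarray:
    """Complex Morlet taps ``exp(i 2 pi f t) exp(-t^2 / (2 sigma_t^2))``.

    Truncated at +/- 4 envelope standard deviations and normalised to unit
    total energy (``sum |w|^2 = 1``) so power is comparable across
    frequencies.
    """
    if rate <= 2 * f:
        raise ValueError("sampling rate must exceed twice the wavelet frequency")
    st = float(sigma_t(f, n))
    half = int(np.ceil(4.0 * st * rate))
    t = np.arange(-half, half + 1) / rate
    taps = np.exp(2j * np.pi * f * t) * np.exp(-(t**2) / (2.0 * st**2))
    return taps / np.sqrt(np.sum(np.abs(taps) ** 2))


@dataclass(frozen=True)
class WaveletBank:
    """Frequency grid, per-frequency cycle counts, and output grids."""

    freqs: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(_F_LO, _F_HI + 1e-9, 0.2), 10)
    )
    rate: float = 200.0
    time_step: float = 0.010  # s, output grid
    f_range: tuple[float, float] = (_F_LO, _F_HI)
    n_range: tuple[float, float] = (_N_LO, _N_HI)

    def __post_init__(self):
        object.__setattr__(self, "freqs", np.asarray(self.freqs, float))

    @property
    def cycles(self) -> np.ndarray:
        return cycles_at(self.freqs, self.f_range, self.n_range)

    @property
    def fdhm_of_f(self) -> np.ndarray:
        return fdhm(self.freqs, self.cycles)

    @property
    def fwhm_of_f(self) -> np.ndarray:
        return spectral_fwhm(self.freqs, self.cycles)

    def wavelet(self, f: float) -> np.ndarray:
        n = float(cycles_at(f, self.f_range, self.n_range))
        return make_wavelet(f, self.rate, n)


@dataclass(frozen=True)
class TFR:
    """Time-frequency power, channels x freqs x times."""

    power: np.ndarray
    times: np.ndarray  # s
    freqs: np.ndarray  # Hz
    valid: np.ndarray  # freqs x times boolean; False near epoch edges
    kind: str = "raw"  # 'raw' | 'relative'
    channel_labels: tuple[str, ...] = ()
    baseline_end_of_f: np.ndarray | None = None

    def __post_init__(self):
        for name in ("power", "times", "freqs", "valid"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))


def tfr_transform(epochs: EpochSet, bank: WaveletBank | None = None) -> tuple[np.ndarray, TFR]:
    """Single-trial wavelet coefficients on the (time_step, 0.2 Hz) grid.

    Returns ``(coeffs, template)`` where ``coeffs`` has shape
    ``(trials, channels, freqs, times)`` (complex) and ``template`` is a
    :class:`TFR` carrying the grids and the edge-validity mask (samples
    within half the wavelet length of an epoch edge are flagged invalid and
    must not enter any statistic).
    """
    bank = bank or WaveletBank(rate=epochs.rate)
    if bank.rate != epochs.rate:
        raise ValueError("bank rate must match the epoch sampling rate")
    step = max(int(round(bank.time_step * epochs.rate)), 1)
    out_idx = np.arange(0, epochs.times.size, step)
    out_times = epochs.times[out_idx]
    n_trials, n_ch, n_t = epochs.data.shape
    coeffs = np.empty((n_trials, n_ch, bank.freqs.size, out_idx.size), complex)
    valid = np.zeros((bank.freqs.size, out_idx.size), bool)
    flat = epochs.data.reshape(n_trials * n_ch, n_t)
    for fi, f in enumerate(bank.freqs):
        w = bank.wavelet(float(f))
        if w.size > n_t:
            raise ValueError(
                f"epoch ({n_t} samples) shorter than the {f:g} Hz wavelet ({w.size})"
            )
        conv = fftconvolve(flat, w[None, ::-1].conj(), mode="same")
        coeffs[:, :, fi, :] = conv[:, out_idx].reshape(n_trials, n_ch, -1)
        half = w.size // 2
        valid[fi] = (out_idx >= half) & (out_idx < n_t - half)
    template = TFR(
        power=np.zeros((n_ch, bank.freqs.size, out_idx.size)),
        times=out_times,
        freqs=bank.freqs,
        valid=valid,
        channel_labels=tuple(epochs.channel_labels),
    )
    return coeffs, template


def ersp(coeffs: np.ndarray, template: TFR, measure: str = "power") -> TFR:
    """Trial-average spectral estimate.

    ``measure='power'`` averages ``|W|^2`` (the default, consistent with the
    downstream use of power values); ``measure='magnitude'`` averages
    ``|W|``.
    """
    if coeffs.shape[0] < 1:
        raise ValueError("need at least one trial")
    if measure == "power":
        est = np.mean(np.abs(coeffs) ** 2, axis=0)
    elif measure == "magnitude":
        est = np.mean(np.abs(coeffs), axis=0)
    else:
        raise ValueError("measure must be 'power' or 'magnitude'")
    return replace(template, power=est, kind="raw")


def relative_baseline(
    tfr: TFR,
    baseline: tuple[float, float],
    activation_start: float | None = None,
    enforce_margin: bool = True,
) -> TFR:
    """Express power as change relative to a pre-event baseline.

    ``relative(t, f) = (P(t, f) - mean_base P(f)) / mean_base P(f)`` with
    the per-frequency baseline ending at ``baseline[1] - FDHM(f)``: the
    activation and baseline periods are separated by a margin of one
    temporal FDHM per frequency, so wavelet smearing from the activation
    (starting at ``activation_start``, by default ``baseline[1]``) cannot
    contaminate the baseline estimate.
    """
    if tfr.kind != "raw":
        raise ValueError("baseline correction expects a raw-power TFR")
    b0, b1 = baseline
    act0 = b1 if activation_start is None else activation_start
    margins = fdhm(tfr.freqs)
    base_end = act0 - margins  # per-frequency baseline end
    rel = np.empty_like(tfr.power)
    for fi, f in enumerate(tfr.freqs):
        mask = (tfr.times >= b0) & (tfr.times <= base_end[fi]) & tfr.valid[fi]
        if enforce_margin and not mask.any():
            raise ValueError(
                f"no valid baseline samples at {f:g} Hz: the {margins[fi]:.3f} s "
                "FDHM margin consumed the whole baseline window"
            )
        base = tfr.power[:, fi, mask].mean(axis=1, keepdims=True)
        rel[:, fi, :] = tfr.power[:, fi, :] / base - 1.0
    return replace(tfr, power=rel, kind="relative", baseline_end_of_f=base_end)


def band_trace(tfr: TFR, band: tuple[float, float]) -> np.ndarray:
    """Mean over the frequency bins inside ``band`` -> channels x time."""
    lo, hi = band
    mask = (tfr.freqs >= lo - 1e-9) & (tfr.freqs <= hi + 1e-9)
    if not mask.any():
        raise ValueError(f"band {band} contains no frequency bins")
    return tfr.power[:, mask, :].mean(axis=1)
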