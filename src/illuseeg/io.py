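"""File formats: HDF5 containers, TSV event tables, and EEG readers.

HDF5 layout for an :class:`~illuseeg.preprocess.EpochSet`: datasets
``data`` (trials x channels x time), ``times``, ``channel_labels`` and
optional ``channel_positions``; attributes ``rate``, ``alignment`` and
``condition``. Recordings and TFRs use the analogous layout. Event tables
are tab-separated with columns ``onset_s``, ``type`` and optional
``level_db`` / ``label``.

Continuous EEG in EDF or BrainVision format is read through MNE.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .erp import ERP
from .ersp import TFR
from .preprocess import EpochSet, Recording

__all__ = [
    "save_epochs",
    "load_epochs",
    "save_recording",
    "load_recording",
    "save_erp",
    "load_erp",
    "save_tfr",
    "load_tfr",
    "write_events",
    "read_events",
    "read_raw",
]

_STR = h5py.string_dtype(encoding="utf-8")


def _write_labels(g, labels):
    g.create_dataset("channel_labels", data=np.array(list(labels), dtype=_STR), track_times=False)


def _read_labels(g):
    return tuple(s.decode() if isinstance(s, bytes) else s for s in g["channel_labels"][()])


def save_epochs(path, epochs: EpochSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, track_times=False)
        f.create_dataset("times", data=epochs.times, track_times=False)
        _write_labels(f, epochs.channel_labels)
        if epochs.channel_positions is not None:
            f.create_dataset("channel_positions", data=epochs.channel_positions, track_times=False)
        f.attrs["rate"] = epochs.rate
        f.attrs["alignment"] = epochs.alignment
        f.attrs["condition"] = epochs.condition


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["data"][()],
            times=f["times"][()],
            rate=float(f.attrs["rate"]),
            alignment=str(f.attrs["alignment"]),
            condition=str(f.attrs["condition"]),
            channel_labels=_read_labels(f),
            channel_positions=f["channel_positions"][()]
            if "channel_positions" in f
            else None,
        )


def save_recording(path, rec: Recording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data, track_times=False)
        _write_labels(f, rec.channel_labels)
        if rec.channel_positions is not None:
            f.create_dataset("channel_positions", data=rec.channel_positions, track_times=False)
        f.attrs["rate"] = rec.rate


def load_recording(path) -> Recording:
    with h5py.File(path, "r") as f:
        return Recording(
            data=f["data"][()],
            rate=float(f.attrs["rate"]),
            channel_labels=_read_labels(f),
            channel_positions=f["channel_positions"][()]
            if "channel_positions" in f
            else None,
        )


def save_erp(path, erp: ERP) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("mean", data=erp.mean, track_times=False)
        f.create_dataset("sem", data=erp.sem, track_times=False)
        f.create_dataset("times", data=erp.times, track_times=False)
        _write_labels(f, erp.channel_labels)
        f.attrs["rate"] = erp.rate
        f.attrs["n_trials"] = erp.n_trials
        if erp.baseline_window is not None:
            f.attrs["baseline_window"] = erp.baseline_window


def load_erp(path) -> ERP:
    with h5py.File(path, "r") as f:
        bw = f.attrs.get("baseline_window")
        return ERP(
            mean=f["mean"][()],
            sem=f["sem"][()],
            times=f["times"][()],
            n_trials=int(f.attrs["n_trials"]),
            rate=float(f.attrs["rate"]),
            channel_labels=_read_labels(f),
            baseline_window=tuple(bw) if bw is not None else None,
        )


def save_tfr(path, tfr: TFR) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("power", data=tfr.power, track_times=False)
        f.create_dataset("times", data=tfr.times, track_times=False)
        f.create_dataset("freqs", data=tfr.freqs, track_times=False)
        f.create_dataset("valid", data=tfr.valid, track_times=False)
        _write_labels(f, tfr.channel_labels)
        f.attrs["kind"] = tfr.kind
        if tfr.baseline_end_of_f is not None:
            f.create_dataset("baseline_end_of_f", data=tfr.baseline_end_of_f, track_times=False)


def load_tfr(path) -> TFR:
    with h5py.File(path, "r") as f:
        return TFR(
            power=f["power"][()],
            times=f["times"][()],
            freqs=f["freqs"][()],
            valid=f["valid"][()],
            kind=str(f.attrs["kind"]),
            channel_labels=_read_labels(f),
            baseline_end_of_f=f["baseline_end_of_f"][()]
            if "baseline_end_of_f" in f
            else None,
        )


def write_events(path, events) -> None:
    """Events as a TSV table; accepts a list of dicts or a DataFrame."""
    df = pd.DataFrame(events)
    df.to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_wav(path, wave) -> None:
    """Waveform to 32-bit float PCM WAV."""
    from scipy.io import wavfile

    wavfile.write(path, int(wave.rate), wave.samples.astype(np.float32))


def read_wav(path):
    """WAV file to a stimulus Waveform."""
    from scipy.io import wavfile

    from .stimulus import Waveform

    rate, samples = wavfile.read(path)
    return Waveform(np.asarray(samples, float), float(rate))


def read_raw(path) -> Recording:
    """Read continuous EEG from EDF or BrainVision (.vhdr) into a Recording."""
    import mne

    path = Path(path)
    if path.suffix.lower() == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    elif path.suffix.lower() == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported raw EEG format: {path.suffix}")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return Recording(
        data=data,
        rate=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
    )
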