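"""Channel geometry helpers for a 64-channel 10-10 EasyCap layout.

Positions come from MNE's bundled ``easycap-M1`` template montage and are
normalised to the unit sphere, so all distance thresholds in the package are
expressed in unit-head coordinates.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

#: 64-channel subset of the EasyCap M1 layout (10-10 system); the outer
#: 9/10-row electrodes and Iz are not part of the recording set.
LAYOUT_64 = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T7", "T8", "P7", "P8", "Fz", "Cz", "Pz",
    "F1", "F2", "FC1", "FC2", "C1", "C2", "CP1", "CP2", "P1", "P2",
    "AF3", "AF4", "FC3", "FC4", "CP3", "CP4", "PO3", "PO4",
    "F5", "F6", "FC5", "FC6", "C5", "C6", "CP5", "CP6", "P5", "P6",
    "AF7", "AF8", "FT7", "FT8", "TP7", "TP8", "PO7", "PO8",
    "Fpz", "AFz", "FCz", "CPz", "POz", "Oz",
    "O9", "O10", "Iz",
)[:64]

#: Default frontal channels excluded from the liberal pre-cleaning
#: peak-to-peak screen (to keep trials that merely contain eye blinks).
FRONTAL_CHANNELS = ("Fp1", "Fp2", "Fpz", "AF7", "AF8", "AF3", "AF4", "AFz")


@lru_cache(maxsize=8)
def _montage_positions() -> dict[str, np.ndarray]:
    import mne

    montage = mne.channels.make_standard_montage("easycap-M1")
    return {k: np.asarray(v, float) for k, v in montage.get_positions()["ch_pos"].items()}


def channel_positions(labels=LAYOUT_64) -> np.ndarray:
    """Unit-sphere 3D positions for ``labels``, shape ``(n_channels, 3)``."""
    pos_map = _montage_positions()
    pos = np.stack([pos_map[lab] for lab in labels])
    return pos / np.linalg.norm(pos, axis=1, keepdims=True)


def subset_layout(n_channels: int) -> tuple[tuple[str, ...], np.ndarray]:
    """First ``n_channels`` of the 64-channel layout with their positions.

    The layout is ordered so that small subsets still span the scalp
    (the first 19 labels are the classic 10-20 set).
    """
    if not 1 <= n_channels <= len(LAYOUT_64):
        raise ValueError(f"n_channels must be in [1, {len(LAYOUT_64)}]")
    labels = LAYOUT_64[:n_channels]
    return labels, channel_positions(labels)
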