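"""Default electrode montage of the simulated recordings.

The emulated setup is a 64-electrode active-cap recording in the
international 10-20/10-10 system: 62 scalp electrodes, one electrode on the
right mastoid (for later linked-mastoid re-referencing against the left
mastoid reference) and one electrooculogram (EOG) electrode below the left
eye.  Spatio-temporal classification features are taken from the 62 scalp
channels only.
"""

from __future__ import annotations

import functools

import numpy as np

#: 62 scalp electrodes (10-10 names), roughly front-to-back.
SCALP_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "AF7", "AF3", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT9", "FT7", "FC5", "FC3", "FC1", "FC2", "FC4", "FC6", "FT8", "FT10",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO9", "PO7", "PO3", "POz", "PO4", "PO8", "PO10",
    "O1", "Oz", "O2",
)

LEFT_MASTOID = "M1"
RIGHT_MASTOID = "M2"
MASTOIDS: tuple[str, str] = (LEFT_MASTOID, RIGHT_MASTOID)
EOG_CHANNEL = "EOG"

#: All channels present in a simulated recording (64 EEG + 1 EOG).
ALL_CHANNELS: tuple[str, ...] = SCALP_CHANNELS + MASTOIDS + (EOG_CHANNEL,)

assert len(SCALP_CHANNELS) == 62
assert len(ALL_CHANNELS) == 65


@functools.lru_cache(maxsize=1)
def _standard_positions() -> dict[str, np.ndarray]:
    """3-D head-surface positions (meters) from mne's built-in 10-05 montage."""
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            mont = mne.channels.make_standard_montage("colin27_1005")
        except ValueError:  # older naming
            mont = mne.channels.make_standard_montage("standard_1005")
    return {k: np.asarray(v, dtype=float) for k, v in mont.get_positions()["ch_pos"].items()}


def channel_positions(names: tuple[str, ...] | list[str] | None = None) -> dict[str, np.ndarray]:
    """Return 3-D positions (m) for the requested channels.

    The EOG channel, which has no montage position, is placed just below
    Fp1 so that distance-based computations (blink leakage, spatially
    correlated noise) remain well defined.
    """
    if names is None:
        names = ALL_CHANNELS
    std = _standard_positions()
    out: dict[str, np.ndarray] = {}
    for name in names:
        if name == EOG_CHANNEL:
            out[name] = std["Fp1"] + np.array([0.0, 0.01, -0.03])
        else:
            out[name] = std[name]
    return out


def positions_2d(names: tuple[str, ...] | list[str]) -> np.ndarray:
    """Top-view (x, y) projection for scalp maps, nose pointing up."""
    pos = channel_positions(tuple(names))
    return np.array([pos[n][:2] for n in names])


def gaussian_topography(center: str, sigma_m: float,
                        channels: tuple[str, ...] = SCALP_CHANNELS) -> dict[str, float]:
    """Unit-peak spatial weight map decaying with distance from a named electrode.

    Parameters
    ----------
    center
        Electrode at which the map attains 1.
    sigma_m
        Spatial standard deviation in meters (on the head surface chord).
    """
    pos = channel_positions(tuple(channels) + (center,))
    c = pos[center]
    return {
        name: float(np.exp(-np.sum((pos[name] - c) ** 2) / (2.0 * sigma_m**2)))
        for name in channels
    }
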