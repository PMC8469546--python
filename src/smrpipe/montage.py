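"""The 30-channel sensorimotor montage used throughout the pipeline.

Electrodes cover the sensorimotor strip in the 10-10 system.  Channel
positions (for building smooth synthetic topographies) come from MNE's
``standard_1005`` template montage, flattened to the 2D head plane.
"""
from __future__ import annotations

from functools import lru_cache

import numpy as np

#: The canonical 30 channel labels, in recording order.
CHANNELS: tuple[str, ...] = (
    "F3", "F4", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
    "P5", "P3", "P1", "Pz", "P2", "P4", "P6",
)

N_CHANNELS = len(CHANNELS)

_CANONICAL = {name.lower(): name for name in CHANNELS}


def validate_channels(names) -> list[str]:
    """Map channel labels (case-insensitive) onto the canonical montage.

    Raises ``ValueError`` for any label outside the 30-channel montage.
    """
    out = []
    for name in names:
        key = str(name).strip().lower()
        if key not in _CANONICAL:
            raise ValueError(
                f"unknown channel {name!r}; expected one of the 30 "
                f"sensorimotor montage labels {CHANNELS}"
            )
        out.append(_CANONICAL[key])
    return out


@lru_cache(maxsize=1)
def channel_positions() -> np.ndarray:
    """(30, 2) array of head-plane electrode coordinates (azimuthal projection)."""
    import warnings

    import mne

    with warnings.catch_warnings():
        # template name being renamed upstream; either resolves identically
        warnings.simplefilter("ignore", FutureWarning)
        montage = mne.channels.make_standard_montage("standard_1005")
    pos3d = montage.get_positions()["ch_pos"]
    lookup = {k.lower(): v for k, v in pos3d.items()}
    xyz = np.array([lookup[ch.lower()] for ch in CHANNELS])
    # azimuthal equidistant projection onto the x/y plane
    x, y, z = xyz.T
    r = np.linalg.norm(xyz, axis=1)
    theta = np.arccos(np.clip(z / r, -1, 1))
    phi = np.arctan2(y, x)
    return np.column_stack([theta * np.cos(phi), theta * np.sin(phi)])


def dipolar_topography(center: str, sigma: float = 0.35) -> np.ndarray:
    """Smooth dipole-like scalp pattern centred on ``center``, unit norm.

    A Gaussian bump at the named electrode with a weaker opposite-sign
    lobe posterior to it; only the unit norm matters to the downstream
    algebra, the shape is cosmetic.
    """
    pos = channel_positions()
    c = pos[CHANNELS.index(validate_channels([center])[0])]
    d2 = np.sum((pos - c) ** 2, axis=1)
    lobe = c + np.array([-0.5, 0.0])  # posterior, x points to nasion
    d2b = np.sum((pos - lobe) ** 2, axis=1)
    topo = np.exp(-d2 / (2 * sigma**2)) - 0.4 * np.exp(-d2b / (2 * sigma**2))
    return topo / np.linalg.norm(topo)
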