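"""Standard 10-10 electrode labels, positions and region-prefix matching.

The 10-10 naming convention encodes the cortical region in the leading
letters of a label (``PO7`` → parieto-occipital) and the lateral position in
the trailing number or midline ``z``.  Region matching therefore operates on
the *letter part* of a label (``POz`` → ``PO``, ``Fp1`` → ``Fp``) and is
case sensitive: ``Fp1``/``FC1`` do not match the ``P``/``C`` regions.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

#: The simulator's 64-channel extended 10-10 cap: the 61 standard scalp
#: labels plus FT9/FT10/Iz.  Under the posterior/central region prefixes
#: {O, PO, P, TP, T, CP, C} this cap retains exactly 35 channels.
STANDARD_64 = (
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2",
    "FT9", "FT10", "Iz",
)

_LABEL_RE = re.compile(r"^([A-Za-z]+?)(?:z|\d+)$")


def letter_part(label: str) -> str:
    """Region letters of a 10-10 label (``CP5`` → ``CP``, ``POz`` → ``PO``)."""
    m = _LABEL_RE.match(label)
    return m.group(1) if m else label


def match_prefix(label: str, prefixes) -> str | None:
    """Longest region prefix matching ``label``'s letter part, or None."""
    lp = letter_part(label)
    best = None
    for p in prefixes:
        if lp.startswith(p) and (best is None or len(p) > len(best)):
            best = p
    return best


@dataclass
class ChannelMontage:
    """Ordered electrode labels with 2-D scalp coordinates and bad channels."""

    channel_names: tuple
    positions: np.ndarray  # (n, 2)
    bad_channels: tuple = ()

    def __post_init__(self):
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("duplicate channel names in montage")
        for b in self.bad_channels:
            if b not in self.channel_names:
                raise ValueError(f"unknown bad-channel name: {b!r}")

    def __len__(self):
        return len(self.channel_names)

    def good_channels(self):
        return tuple(c for c in self.channel_names if c not in self.bad_channels)


def _standard_positions(names):
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        std = mne.channels.make_standard_montage("standard_1005")
    pos3d = std.get_positions()["ch_pos"]
    out = np.zeros((len(names), 2))
    for i, n in enumerate(names):
        out[i] = pos3d[n][:2]
    return out


def make_montage(n_channels: int = 64, bad_channels=()) -> ChannelMontage:
    """The default 64-channel extended 10-10 montage.

    Parameters
    ----------
    n_channels
        Must be 64; the simulator models the full cap of the emulated study.
    bad_channels
        Labels to flag as bad; unknown labels raise ``ValueError``.
    """
    if n_channels != 64:
        raise ValueError(
            f"only the standard 64-channel montage is supported, got {n_channels}"
        )
    names = STANDARD_64
    return ChannelMontage(
        channel_names=names,
        positions=_standard_positions(names),
        bad_channels=tuple(bad_channels),
    )


#: Region weighting of evoked components over the scalp: the face-evoked
#: potentials modelled here are strongest over occipito-temporal cortex.
POSTERIOR_PREFIXES = ("O", "PO", "P", "TP", "T")
CENTRAL_PREFIXES = ("CP", "C")


def spatial_weight(label: str) -> float:
    if match_prefix(label, POSTERIOR_PREFIXES) is not None:
        return 1.0
    if match_prefix(label, CENTRAL_PREFIXES) is not None:
        return 0.5
    return 0.1
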