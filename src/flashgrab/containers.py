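"""In-memory containers for multi-subject EEG epoch data.

Epochs are stored per subject as a dense ``(n_channels, n_times, n_trials)``
array in microvolts, together with per-trial condition and side labels.  The
study-level container additionally carries one perceptual illusion size per
subject (degrees), which the inter-subject correlation analysis consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["SubjectEpochs", "EEGStudy"]


#: 64-electrode Neuroscan-style montage (10-10 scalp labels plus the two
#: ocular channels used for artifact rejection).
DEFAULT_CHANNELS: tuple[str, ...] = (
    "FP1", "FPZ", "FP2", "AF3", "AF4",
    "F7", "F5", "F3", "F1", "FZ", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCZ", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "CZ", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "PZ", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POZ", "PO4", "PO6", "PO8",
    "CB1", "O1", "OZ", "O2", "CB2",
    "VEO", "HEO",
)

#: Default homologous left/right posterior electrode pairing used for
#: contralateral-minus-ipsilateral difference waves.
DEFAULT_PAIRS: tuple[tuple[str, str], ...] = (
    ("P3", "P4"), ("P5", "P6"), ("PO5", "PO6"), ("PO7", "PO8"), ("O1", "O2"),
)


@dataclass
class SubjectEpochs:
    """Epoched EEG data for a single subject.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_times, n_trials)
        Epoch voltages in microvolts.
    times : ndarray, shape (n_times,)
        Sample times in milliseconds relative to flash onset; strictly
        increasing.
    srate : float
        Sampling rate in Hz.
    channel_names : list of str
        One label per channel row.
    condition : ndarray of str, shape (n_trials,)
        Condition label per trial (e.g. ``illusory``, ``background``,
        ``retinal``).
    side : ndarray of str, shape (n_trials,)
        Stimulus/percept side per trial, ``left`` or ``right``.
    subject : str
        Subject identifier.
    """

    data: np.ndarray
    times: np.ndarray
    srate: float
    channel_names: list[str]
    condition: np.ndarray
    side: np.ndarray
    subject: str = "s00"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.times = np.asarray(self.times, dtype=float)
        self.condition = np.asarray(self.condition)
        self.side = np.asarray(self.side)
        n_ch, n_t, n_tr = self.data.shape
        if len(self.channel_names) != n_ch:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {n_ch} channels"
            )
        if self.times.shape != (n_t,):
            raise ValueError("times length does not match data time axis")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for name, labels in (("condition", self.condition), ("side", self.side)):
            if labels.shape != (n_tr,):
                raise ValueError(
                    f"{name} labels ({labels.shape}) do not match "
                    f"trial count ({n_tr})"
                )
        if self.srate <= 0:
            raise ValueError("srate must be positive")

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not present") from None

    def pick_trials(self, mask: np.ndarray) -> "SubjectEpochs":
        """Return a copy restricted to trials where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return SubjectEpochs(
            data=self.data[:, :, mask],
            times=self.times,
            srate=self.srate,
            channel_names=list(self.channel_names),
            condition=self.condition[mask],
            side=self.side[mask],
            subject=self.subject,
        )


@dataclass
class EEGStudy:
    """Multi-subject EEG study: epochs plus per-subject illusion sizes."""

    subjects: list[SubjectEpochs]
    illusion_sizes: np.ndarray
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.illusion_sizes = np.asarray(self.illusion_sizes, dtype=float)
        if len(self.subjects) != len(self.illusion_sizes):
            raise ValueError("one illusion size per subject required")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def times(self) -> np.ndarray:
        return self.subjects[0].times

    @property
    def channel_names(self) -> list[str]:
        return self.subjects[0].channel_names


def posterior_channels(names: Sequence[str]) -> list[str]:
    """Posterior scalp subset (parietal/parieto-occipital/occipital rows)."""
    out = []
    for n in names:
        u = n.upper()
        if u in ("VEO", "HEO"):
            continue
        if u.startswith(("P", "PO", "O", "CB")):
            out.append(n)
    return out
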