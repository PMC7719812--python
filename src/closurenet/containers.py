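"""In-memory containers for epoched EEG and condition averages.

``EpochSet`` holds single-trial epoched EEG as a trials x channels x time
array in microvolts, with times in milliseconds relative to stimulus
onset, a condition label per trial, and subject/group metadata.  On disk
an EpochSet is a ``.npy`` array next to a JSON sidecar carrying the
header (sampling rate, channel names, window, labels).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["EpochSet", "Evoked", "save_epochs", "load_epochs"]


@dataclass
class EpochSet:
    data: np.ndarray            # (n_trials, n_channels, n_times), microvolts
    times: np.ndarray           # (n_times,), ms relative to stimulus onset
    ch_names: list[str]
    conditions: list[str]       # one label per trial
    sfreq: float
    subject: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x time")
        nt, nc, ns = self.data.shape
        if nc != len(self.ch_names) or ns != len(self.times):
            raise ValueError("data shape inconsistent with ch_names/times")
        if nt != len(self.conditions):
            raise ValueError("one condition label per trial required")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def pick_trials(self, idx) -> "EpochSet":
        idx = np.asarray(idx)
        return replace(
            self,
            data=self.data[idx],
            conditions=[self.conditions[i] for i in np.atleast_1d(idx)],
        )

    def time_mask(self, lo_ms: float, hi_ms: float) -> np.ndarray:
        return (self.times >= lo_ms) & (self.times <= hi_ms)


@dataclass
class Evoked:
    """Condition average: channels x time, microvolts."""

    data: np.ndarray
    times: np.ndarray
    ch_names: list[str]
    condition: str
    n_trials: int = 0
    subject: str = ""
    group: str = ""


def save_epochs(epochs: EpochSet, stem: str | Path) -> None:
    """Write `<stem>.npy` (data) and `<stem>.json` (header)."""
    stem = Path(stem)
    np.save(stem.with_suffix(".npy"), epochs.data)
    header = {
        "sfreq": epochs.sfreq,
        "ch_names": epochs.ch_names,
        "times_ms": epochs.times.tolist(),
        "conditions": epochs.conditions,
        "subject": epochs.subject,
        "group": epochs.group,
    }
    with open(stem.with_suffix(".json"), "w") as fh:
        json.dump(header, fh)


def load_epochs(stem: str | Path) -> EpochSet:
    stem = Path(stem)
    data = np.load(stem.with_suffix(".npy"))
    with open(stem.with_suffix(".json")) as fh:
        header = json.load(fh)
    return EpochSet(
        data=data,
        times=np.asarray(header["times_ms"], dtype=float),
        ch_names=list(header["ch_names"]),
        conditions=list(header["conditions"]),
        sfreq=float(header["sfreq"]),
        subject=header.get("subject", ""),
        group=header.get("group", ""),
    )
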