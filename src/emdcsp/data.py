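"""Core data containers shared across the pipeline stages.

The labeled trial tensor (:class:`EEGTrialSet`) is the common currency: the
synthetic generator produces one, the EDF epoching path produces one, and the
decomposition / spatial-filtering stages consume one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "EEGTrialSet",
    "DataError",
    "save_dataset",
    "load_dataset",
]

CLASS_LABELS = ("L", "R")


class DataError(ValueError):
    """Raised when input data violates a structural contract."""


@dataclass
class EEGTrialSet:
    """Labeled multichannel trial tensor.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Real-valued trial tensor (microvolt-scale arbitrary units).
    labels : ndarray of str, shape (n_trials,)
        Per-trial class label, one of ``{"L", "R"}``.
    channel_names : list of str
        Ordered channel identifiers.
    fs : float
        Sampling rate in Hz.
    """

    data: np.ndarray
    labels: np.ndarray
    channel_names: list[str]
    fs: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=str)
        self.channel_names = list(self.channel_names)
        if self.data.ndim != 3:
            raise DataError(
                f"trial tensor must be 3-D (trial, channel, sample); got {self.data.shape}"
            )
        if self.labels.shape[0] != self.data.shape[0]:
            raise DataError(
                f"{self.labels.shape[0]} labels for {self.data.shape[0]} trials"
            )
        if len(self.channel_names) != self.data.shape[1]:
            raise DataError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[1]} channels"
            )
        if self.fs <= 0:
            raise DataError("sampling rate must be positive")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def class_indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    def require_both_classes(self) -> None:
        present = set(np.unique(self.labels))
        if not set(CLASS_LABELS) <= present:
            raise DataError(
                f"both classes {CLASS_LABELS} required for fitting; found {sorted(present)}"
            )

    def select(self, trial_idx: Sequence[int]) -> "EEGTrialSet":
        idx = np.asarray(trial_idx, dtype=int)
        return EEGTrialSet(
            data=self.data[idx],
            labels=self.labels[idx],
            channel_names=self.channel_names,
            fs=self.fs,
        )


def save_dataset(
    path: str | Path,
    trials: EEGTrialSet,
    config_yaml: str = "",
    ground_truth: dict[str, np.ndarray] | None = None,
) -> Path:
    """Serialize a trial set (plus optional config echo and ground truth) to
    a single ``.npz`` container."""
    path = Path(path)
    payload: dict[str, np.ndarray] = {
        "data": trials.data,
        "labels": trials.labels.astype("U1"),
        "channel_names": np.asarray(trials.channel_names, dtype="U16"),
        "fs": np.asarray(trials.fs, dtype=float),
        "config_yaml": np.asarray(config_yaml, dtype="U"),
    }
    if ground_truth:
        for key, value in ground_truth.items():
            payload[f"gt_{key}"] = np.asarray(value)
    np.savez(path, **payload)
    return path


def load_dataset(path: str | Path) -> tuple[EEGTrialSet, str, dict[str, np.ndarray]]:
    """Load a container written by :func:`save_dataset`.

    Returns the trial set, the config echo string, and any ground-truth
    arrays keyed without their ``gt_`` prefix.
    """
    with np.load(path, allow_pickle=False) as npz:
        trials = EEGTrialSet(
            data=npz["data"],
            labels=npz["labels"],
            channel_names=[str(c) for c in npz["channel_names"]],
            fs=float(npz["fs"]),
        )
        config_yaml = str(npz["config_yaml"])
        gt = {k[3:]: npz[k] for k in npz.files if k.startswith("gt_")}
    return trials, config_yaml, gt
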