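"""Continuous-signal conditioning and trial segmentation.

The conditioning chain mirrors standard cue-locked EEG practice: amplitude
thresholding marks artifact samples, a zero-phase Butterworth band-pass
removes out-of-band components without shifting cue-locked latencies, epochs
are cut around each cue (2 s of rest context, 4 s of imagery), the mean of a
pre-cue baseline window is subtracted per trial and channel, and the ten
experimental rounds are split 8/2 into train/test folds for 5-fold
cross-validation.

Containers
----------
:class:`Recording`   continuous channels x samples matrix in microvolts.
:class:`EpochSet`    trials x channels x samples tensor with class labels,
                     per-trial round ids and the cue sample index.
:class:`ArtifactMask` boolean channels x samples matrix marking artifacts.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import signal

__all__ = [
    "CLASSES",
    "Recording",
    "EpochSet",
    "ArtifactMask",
    "mark_artifacts",
    "bandpass",
    "bandpass_array",
    "baseline_correct",
    "split_rounds",
    "epoch_trials",
    "concatenate_epochs",
    "read_recording_csv",
    "write_recording_csv",
    "read_recording_edf",
    "read_epochs_dir",
    "write_epochs_dir",
]

#: canonical motor-imagery class order (left, right, tongue, foot)
CLASSES = ("left_hand", "right_hand", "tongue", "foot")


@dataclass(frozen=True)
class Recording:
    """Continuous EEG: ``data[channel, sample]`` in microvolts."""

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))
        if data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if not np.all(np.isfinite(data)):
            raise ValueError("data contains non-finite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_labels) != data.shape[0]:
            raise ValueError("channel_labels length != channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def pick(self, idx0) -> "Recording":
        """Sub-recording with channels *idx0* (0-based), preserving order."""
        idx0 = np.asarray(idx0, dtype=int)
        return Recording(
            data=self.data[idx0],
            fs=self.fs,
            channel_labels=tuple(self.channel_labels[i] for i in idx0),
        )


@dataclass(frozen=True)
class EpochSet:
    """Cue-aligned trials: ``data[trial, channel, sample]`` in microvolts."""

    data: np.ndarray
    labels: np.ndarray  # per-trial class name
    fs: float
    cue_sample: int
    round_ids: np.ndarray  # per-trial experimental round, 1..10
    channel_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        labels = np.asarray(self.labels)
        rounds = np.asarray(self.round_ids, dtype=int)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "round_ids", rounds)
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))
        if data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if len(labels) != data.shape[0] or len(rounds) != data.shape[0]:
            raise ValueError("labels/round_ids length != trial count")
        unknown = set(labels.tolist()) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown class labels: {sorted(unknown)}")
        if not 0 <= self.cue_sample < data.shape[2]:
            raise ValueError("cue_sample outside epoch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def pick(self, idx0) -> "EpochSet":
        idx0 = np.asarray(idx0, dtype=int)
        labels = (
            tuple(self.channel_labels[i] for i in idx0) if self.channel_labels else ()
        )
        return replace(self, data=self.data[:, idx0], channel_labels=labels)

    def select_trials(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        return replace(
            self,
            data=self.data[mask],
            labels=self.labels[mask],
            round_ids=self.round_ids[mask],
        )


@dataclass(frozen=True)
class ArtifactMask:
    """Boolean channels x samples matrix; True marks artifact samples."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))
        if self.mask.ndim != 2:
            raise ValueError("mask must be channels x samples")

    @property
    def any_per_sample(self) -> np.ndarray:
        return self.mask.any(axis=0)


def mark_artifacts(rec: Recording, threshold_uV: float) -> ArtifactMask:
    """Mark samples whose absolute amplitude exceeds *threshold_uV*."""
    if threshold_uV <= 0:
        raise ValueError("threshold must be positive")
    return ArtifactMask(mask=np.abs(rec.data) > threshold_uV)


def _band_sos(lo_hz: float, hi_hz: float, fs: float, order: int):
    if not 0 < lo_hz < hi_hz < fs / 2:
        raise ValueError(
            f"band edges must satisfy 0 < lo < hi < fs/2, got ({lo_hz}, {hi_hz}) at fs={fs}"
        )
    return signal.butter(order, [lo_hz, hi_hz], btype="bandpass", fs=fs, output="sos")


def bandpass_array(x: np.ndarray, lo_hz: float, hi_hz: float, fs: float,
                   order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    sos = _band_sos(lo_hz, hi_hz, fs, order)
    return signal.sosfiltfilt(sos, x, axis=-1)


def bandpass(rec: Recording, lo_hz: float, hi_hz: float, order: int = 4) -> Recording:
    """Zero-phase band-pass per channel (forward-backward Butterworth).

    The forward-backward pass doubles the effective order and cancels the
    filter's phase delay, so cue-locked epoch timing is unchanged.
    """
    return replace(rec, data=bandpass_array(rec.data, lo_hz, hi_hz, rec.fs, order))


def baseline_correct(epochs: EpochSet, window_ms=(-200.0, 0.0)) -> EpochSet:
    """Subtract the per-trial, per-channel mean of the pre-cue baseline window.

    *window_ms* is relative to the cue; the conventional choice (-200, 0) ms
    gives a 50-sample window at 250 Hz.
    """
    lo = epochs.cue_sample + int(round(window_ms[0] * epochs.fs / 1000.0))
    hi = epochs.cue_sample + int(round(window_ms[1] * epochs.fs / 1000.0))
    if not (0 <= lo < hi <= epochs.data.shape[2]):
        raise ValueError(f"baseline window {window_ms} ms outside epoch")
    base = epochs.data[:, :, lo:hi].mean(axis=2, keepdims=True)
    return replace(epochs, data=epochs.data - base)


def split_rounds(epochs: EpochSet, fold: int) -> tuple[EpochSet, EpochSet]:
    """8/2 round split for 5-fold cross-validation.

    Fold ``k`` (1-based) reserves experimental rounds ``{2k-1, 2k}`` for
    testing and trains on the other eight, so the five test sets partition
    the ten rounds.
    """
    if not 1 <= fold <= 5:
        raise ValueError("fold must be in 1..5")
    present = set(np.unique(epochs.round_ids).tolist())
    if not present <= set(range(1, 11)) or not present:
        raise ValueError("round_ids must lie in 1..10")
    test_rounds = {2 * fold - 1, 2 * fold}
    is_test = np.isin(epochs.round_ids, sorted(test_rounds))
    return epochs.select_trials(~is_test), epochs.select_trials(is_test)


def epoch_trials(rec: Recording, cue_samples, labels, round_ids,
                 pre_s: float = 2.0, post_s: float = 4.0) -> EpochSet:
    """Cut cue-aligned epochs ``[cue - pre_s, cue + post_s)`` from *rec*."""
    n_pre = int(round(pre_s * rec.fs))
    n_post = int(round(post_s * rec.fs))
    if n_pre + n_post < 1:
        raise ValueError("epoch must contain at least one sample")
    trials = []
    for cue in cue_samples:
        lo, hi = cue - n_pre, cue + n_post
        if lo < 0 or hi > rec.n_samples:
            raise ValueError(f"epoch window [{lo}, {hi}) exceeds recording bounds")
        trials.append(rec.data[:, lo:hi])
    return EpochSet(
        data=np.stack(trials),
        labels=np.asarray(labels),
        fs=rec.fs,
        cue_sample=n_pre,
        round_ids=np.asarray(round_ids, dtype=int),
        channel_labels=rec.channel_labels,
    )


def concatenate_epochs(epochs: EpochSet) -> Recording:
    """Lay the trials end to end as one continuous recording.

    Useful for window-based training on trial data: with a window length
    that divides the trial length, windows never straddle trial boundaries.
    """
    n_tr, n_ch, n_s = epochs.data.shape
    data = np.transpose(epochs.data, (1, 0, 2)).reshape(n_ch, n_tr * n_s)
    labels = epochs.channel_labels or tuple(f"ch{i+1}" for i in range(n_ch))
    return Recording(data=data, fs=epochs.fs, channel_labels=labels)


# ---------------------------------------------------------------------------
# readers / writers

def write_recording_csv(rec: Recording, path) -> None:
    """CSV dialect: a ``# fs=<Hz>`` comment line, then one row per channel
    (label followed by the sample values)."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# fs={rec.fs!r}\n")
        writer = csv.writer(fh)
        for label, row in zip(rec.channel_labels, rec.data):
            writer.writerow([label] + [repr(float(v)) for v in row])


def read_recording_csv(path) -> Recording:
    with open(path, newline="") as fh:
        first = fh.readline().strip()
        if not first.startswith("# fs="):
            raise ValueError(f"{path}: missing '# fs=' header line")
        fs = float(first.split("=", 1)[1])
        labels, rows = [], []
        for row in csv.reader(fh):
            if not row:
                continue
            labels.append(row[0])
            rows.append([float(v) for v in row[1:]])
    return Recording(data=np.array(rows), fs=fs, channel_labels=tuple(labels))


def read_recording_edf(path) -> Recording:
    """Read an EDF file (requires the optional ``mne`` dependency).

    EDF stores volts; values are converted to microvolts.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF reading requires mne: pip install eegdense[edf]") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return Recording(
        data=raw.get_data() * 1e6,
        fs=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
    )


def write_epochs_dir(epochs: EpochSet, directory) -> None:
    """Serialize an EpochSet as per-trial CSVs plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "fs": epochs.fs,
        "cue_sample": int(epochs.cue_sample),
        "channel_labels": list(epochs.channel_labels),
        "trials": [],
    }
    for t in range(epochs.n_trials):
        name = f"trial_{t:04d}.csv"
        rec = Recording(
            data=epochs.data[t], fs=epochs.fs,
            channel_labels=epochs.channel_labels
            or tuple(f"ch{i+1}" for i in range(epochs.data.shape[1])),
        )
        write_recording_csv(rec, directory / name)
        manifest["trials"].append(
            {"file": name, "label": str(epochs.labels[t]),
             "round": int(epochs.round_ids[t])}
        )
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def read_epochs_dir(directory) -> EpochSet:
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    data, labels, rounds = [], [], []
    for entry in manifest["trials"]:
        rec = read_recording_csv(directory / entry["file"])
        data.append(rec.data)
        labels.append(entry["label"])
        rounds.append(entry["round"])
    return EpochSet(
        data=np.stack(data),
        labels=np.asarray(labels),
        fs=float(manifest["fs"]),
        cue_sample=int(manifest["cue_sample"]),
        round_ids=np.asarray(rounds, dtype=int),
        channel_labels=tuple(manifest["channel_labels"]),
    )
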