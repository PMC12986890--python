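"""Loading continuous EEG recordings and cutting labelled trial epochs.

The canonical on-disk format is a plain ``.npz`` archive with named arrays
(``data``, ``fs``, ``events``, ``channel_labels``), which round-trips through
:func:`save_recording` / :func:`load_recording` and is what the synthetic
generator writes.  GDF files (the BCI Competition IV-2a distribution format)
are supported through :mod:`mne` when it is installed; nothing else in the
package depends on it.

Epoching follows the standard cue-locked scheme for motor-imagery protocols:
for every event at sample ``e`` the window ``[e + round(t_start*fs),
e + round(t_end*fs))`` is cut (half-open, 0-based), so a 2–6 s window at
250 Hz yields exactly 1000 samples.  No re-referencing, artifact handling or
resampling is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "EEGRecording",
    "EpochedTrial",
    "EpochSet",
    "load_recording",
    "save_recording",
    "extract_epochs",
]


@dataclass
class EEGRecording:
    """A continuous multichannel recording with cue events.

    Parameters
    ----------
    data : ndarray, shape (C, n_samples)
        Channel-by-time signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        Electrode names in row order of ``data``.
    events : list of (int, int)
        ``(sample_index, class_label)`` pairs, sample indices into ``data``.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    events: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("recording data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.data.shape[0] < 2:
            raise ValueError("a recording needs at least 2 channels")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels for "
                f"{self.data.shape[0]} data rows"
            )
        n = self.data.shape[1]
        for sample, _label in self.events:
            if not 0 <= sample < n:
                raise ValueError(
                    f"event at sample {sample} outside recording of {n} samples"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochedTrial:
    """One cue-locked EEG window (C x T, microvolts) with its class label."""

    data: np.ndarray
    label: int
    fs: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("trial data must be 2-D (channels x samples)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochSet:
    """An ordered collection of epochs sharing shape and sampling rate."""

    trials: list[EpochedTrial]
    subject_id: str = "S0"
    session_id: str = "0"
    class_names: list[str] | None = None

    def __post_init__(self):
        if self.trials:
            c, t = self.trials[0].data.shape
            fs = self.trials[0].fs
            for k, trial in enumerate(self.trials):
                if trial.data.shape != (c, t) or trial.fs != fs:
                    raise ValueError(f"trial {k} breaks the shared (C, T, fs) contract")

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    @property
    def labels(self) -> np.ndarray:
        return np.array([t.label for t in self.trials], dtype=int)


def save_recording(path: str | Path, rec: EEGRecording) -> None:
    """Write a recording to the canonical npz container."""
    events = np.asarray(rec.events, dtype=np.int64).reshape(-1, 2)
    np.savez(
        path,
        data=rec.data,
        fs=np.float64(rec.fs),
        events=events,
        channel_labels=np.array(rec.channel_labels, dtype="U32"),
    )


def _load_npz(path: Path) -> EEGRecording:
    with np.load(path, allow_pickle=False) as archive:
        required = {"data", "fs", "events"}
        missing = required - set(archive.files)
        if missing:
            raise ValueError(f"{path} is missing required arrays: {sorted(missing)}")
        data = archive["data"]
        fs = float(archive["fs"])
        events_arr = archive["events"].reshape(-1, 2)
        if "channel_labels" in archive.files:
            labels = [str(x) for x in archive["channel_labels"]]
        else:
            labels = [f"ch{i}" for i in range(data.shape[0])]
    events = [(int(s), int(l)) for s, l in events_arr]
    return EEGRecording(data=data, fs=fs, channel_labels=labels, events=events)


def _load_gdf(path: Path) -> EEGRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError(
            "reading GDF files requires the optional 'mne' dependency "
            "(pip install sfegat[gdf])"
        ) from exc
    raw = mne.io.read_raw_gdf(str(path), preload=True, verbose="error")
    picks = mne.pick_types(raw.info, eeg=True, eog=False, stim=False)
    data = raw.get_data(picks=picks) * 1e6  # volts -> microvolts
    labels = [raw.ch_names[i] for i in picks]
    events_arr, event_id = mne.events_from_annotations(raw, verbose="error")
    # Cue annotations 769..772 are the four motor-imagery classes.
    cue_codes = {"769": 0, "770": 1, "771": 2, "772": 3}
    code_map = {v: cue_codes[k] for k, v in event_id.items() if k in cue_codes}
    events = [
        (int(sample), code_map[code])
        for sample, _, code in events_arr
        if code in code_map
    ]
    if not events:
        raise ValueError(f"no motor-imagery cue events found in {path}")
    return EEGRecording(
        data=data, fs=float(raw.info["sfreq"]), channel_labels=labels, events=events
    )


def load_recording(
    path: str | Path,
    dialect: str = "npz",
    expected_montage: list[str] | None = None,
) -> EEGRecording:
    """Load a continuous recording.

    Parameters
    ----------
    path : path
        File to read.
    dialect : {"npz", "gdf"}
        ``"npz"`` reads the package's canonical array container; ``"gdf"``
        reads a BCI Competition IV-2a style GDF file (requires mne).
    expected_montage : list of str, optional
        If given, the loaded channel labels must match it exactly (order
        included); a mismatch raises ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "npz":
        rec = _load_npz(path)
    elif dialect == "gdf":
        rec = _load_gdf(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'npz' or 'gdf'")
    if expected_montage is not None:
        if list(rec.channel_labels) != list(expected_montage):
            raise ValueError(
                f"channel montage mismatch: recording has {rec.channel_labels}, "
                f"expected {list(expected_montage)}"
            )
    return rec


def extract_epochs(
    rec: EEGRecording,
    t_start: float,
    t_end: float,
    subject_id: str = "S0",
    session_id: str = "0",
    class_names: list[str] | None = None,
) -> EpochSet:
    """Cut one epoch per event, ``[event + t_start, event + t_end)`` seconds.

    The window is a half-open sample interval of length
    ``round((t_end - t_start) * fs)``; an event whose window would run past
    either end of the recording raises ``ValueError`` naming that event.
    """
    if t_end <= t_start:
        raise ValueError(f"empty or inverted window: t_start={t_start}, t_end={t_end}")
    if not rec.events:
        raise ValueError("recording has no events to epoch")
    offset_start = int(round(t_start * rec.fs))
    offset_end = int(round(t_end * rec.fs))
    trials = []
    for k, (sample, label) in enumerate(rec.events):
        lo = sample + offset_start
        hi = sample + offset_end
        if lo < 0 or hi > rec.n_samples:
            raise ValueError(
                f"event {k} at sample {sample}: window [{lo}, {hi}) exceeds "
                f"recording bounds [0, {rec.n_samples})"
            )
        trials.append(EpochedTrial(data=rec.data[:, lo:hi].copy(), label=label, fs=rec.fs))
    return EpochSet(
        trials=trials,
        subject_id=subject_id,
        session_id=session_id,
        class_names=class_names,
    )
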