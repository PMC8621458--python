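"""On-disk formats for recordings, stimulus markers and questionnaires.

A *recording bundle* is one subject's synchronized session: 8-channel EEG at
250 Hz, the auditory-oddball marker table, the wristband streams (BVP, EDA,
TEMP, HR, IBI at their native rates) and, when available, the FAS
questionnaire result.  On disk a bundle is a directory of plain CSV files plus
a JSON manifest; wristband streams follow the Empatica export convention
(first line UTC start timestamp, second line sampling rate, then one value per
line).
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np

logger = logging.getLogger(__name__)

EEG_RATE = 250.0
#: channel order of the 8-electrode dry headset (10-20 positions)
CHANNELS: tuple[str, ...] = ("FP2", "FP1", "C4", "C3", "P8", "P7", "O1", "O2")

#: session layout: 30 s eyes-closed, 30 s eyes-open, 4 min auditory oddball,
#: as half-open [start, end) sample intervals at 250 Hz
SEGMENTS: dict[str, tuple[int, int]] = {
    "EC": (0, 7500),
    "EO": (7500, 15000),
    "AO": (15000, 75000),
}

WRISTBAND_RATES = {"BVP": 64.0, "EDA": 4.0, "TEMP": 4.0, "HR": 1.0, "IBI": 1.0}
WRISTBAND_STREAMS = tuple(WRISTBAND_RATES)

FREQUENT = "frequent"
NONFREQUENT = "nonfrequent"

NO_FATIGUE = "no_fatigue"
SUBSTANTIAL = "substantial"
EXTREME = "extreme"
FATIGUE_CLASSES = (NO_FATIGUE, SUBSTANTIAL, EXTREME)


class Stream(NamedTuple):
    """One wristband stream: sampling rate in Hz and its sample values."""

    rate: float
    values: np.ndarray


@dataclass(frozen=True)
class MarkerTable:
    """Stimulus onsets (samples at the EEG rate, absolute) and labels."""

    onsets: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=np.int64)
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(onsets) != len(self.labels):
            raise ValueError("onsets and labels must have equal length")
        if len(onsets) > 1 and not np.all(np.diff(onsets) > 0):
            raise ValueError("marker onsets must be strictly increasing")
        bad = {lb for lb in self.labels if lb not in (FREQUENT, NONFREQUENT)}
        if bad:
            raise ValueError(f"unknown marker labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.onsets)

    def where(self, label: str) -> np.ndarray:
        return self.onsets[np.array([lb == label for lb in self.labels], bool)]


@dataclass(frozen=True)
class FASResult:
    """Scored fatigue assessment scale questionnaire (10 items, 1-5 each)."""

    items: tuple[int, ...]
    total: int
    fatigue_class: str

    def __post_init__(self) -> None:
        if len(self.items) != 10:
            raise ValueError("FAS has exactly 10 items")
        if not 10 <= self.total <= 50:
            raise ValueError("FAS total must lie in [10, 50]")
        if self.fatigue_class not in FATIGUE_CLASSES:
            raise ValueError(f"unknown fatigue class {self.fatigue_class!r}")


def fatigue_class_of_total(total: float) -> str:
    """Three-class binning of an integer FAS total: <=21 / 22-35 / >=36."""
    if total <= 21:
        return NO_FATIGUE
    if total <= 35:
        return SUBSTANTIAL
    return EXTREME


def score_fas(items: Sequence[int], reverse_items: Iterable[int] = ()) -> FASResult:
    """Score a 10-item FAS questionnaire.

    Parameters
    ----------
    items
        The ten raw answers, each in 1-5.
    reverse_items
        0-based indices of reverse-scored items (mapped ``x -> 6 - x``).
        Defaults to none; the standard instrument reverses items 4 and 10
        (indices 3 and 9), pass ``(3, 9)`` for that behaviour.
    """
    items = tuple(int(x) for x in items)
    if len(items) != 10:
        raise ValueError("FAS has exactly 10 items")
    if any(not 1 <= x <= 5 for x in items):
        raise ValueError("each FAS item must be an integer in 1-5")
    rev = set(reverse_items)
    if any(i not in range(10) for i in rev):
        raise ValueError("reverse_items must be 0-based indices in 0-9")
    scored = tuple(6 - x if i in rev else x for i, x in enumerate(items))
    total = int(sum(scored))
    return FASResult(items=items, total=total, fatigue_class=fatigue_class_of_total(total))


@dataclass
class RecordingBundle:
    """One subject's synchronized multi-modal session."""

    eeg: np.ndarray  # (n_channels, n_samples), microvolts
    markers: MarkerTable
    wristband: dict[str, Stream] = field(default_factory=dict)
    channel_names: tuple[str, ...] = CHANNELS
    rate: float = EEG_RATE
    segments: dict[str, tuple[int, int]] = field(default_factory=lambda: dict(SEGMENTS))
    fas: FASResult | None = None
    fas_total: float | None = None
    subject_id: str = "S00"
    start_time: str = "0"

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        if self.eeg.ndim != 2 or self.eeg.shape[0] != len(self.channel_names):
            raise ValueError("eeg must be a (channels, samples) matrix")
        n = self.eeg.shape[1]
        prev_end = 0
        for name in ("EC", "EO", "AO"):
            if name not in self.segments:
                raise ValueError(f"missing segment {name}")
            start, end = self.segments[name]
            if not (prev_end <= start < end <= n):
                raise ValueError(f"segment {name} [{start}, {end}) invalid for {n} samples")
            prev_end = end
        ao = self.segments["AO"]
        if len(self.markers) and not (
            np.all(self.markers.onsets >= ao[0]) and np.all(self.markers.onsets < ao[1])
        ):
            raise ValueError("all marker onsets must lie inside the AO segment")
        for name, stream in self.wristband.items():
            if stream.rate <= 0:
                raise ValueError(f"stream {name} has non-positive rate")
        if self.fas is not None and self.fas_total is None:
            self.fas_total = float(self.fas.total)

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]


# ---------------------------------------------------------------------------
# on-disk dialect
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"


def write_bundle(bundle: RecordingBundle, path: str | Path) -> Path:
    """Write a bundle as a directory of CSV files plus ``manifest.json``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    np.savetxt(
        path / "eeg.csv",
        bundle.eeg.T,
        delimiter=",",
        fmt=_FLOAT_FMT,
        header=",".join(bundle.channel_names),
        comments="",
    )
    with open(path / "markers.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["onset_sample", "label"])
        for onset, label in zip(bundle.markers.onsets, bundle.markers.labels):
            writer.writerow([int(onset), label])
    for name, stream in bundle.wristband.items():
        with open(path / f"{name}.csv", "w") as fh:
            fh.write(f"{bundle.start_time}\n")
            fh.write(f"{stream.rate:.6f}\n")
            for v in stream.values:
                fh.write(_FLOAT_FMT % v + "\n")
    if bundle.fas is not None:
        with open(path / "fas.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["item", "score"])
            for i, score in enumerate(bundle.fas.items, start=1):
                writer.writerow([i, score])
    manifest = {
        "subject_id": bundle.subject_id,
        "rate": bundle.rate,
        "channel_names": list(bundle.channel_names),
        "segments": {k: list(v) for k, v in bundle.segments.items()},
        "start_time": bundle.start_time,
        "fas_total": bundle.fas_total,
    }
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path


def _read_stream(path: Path) -> tuple[str, Stream]:
    with open(path) as fh:
        start_time = fh.readline().strip()
        rate = float(fh.readline().strip())
        values = np.array([float(line) for line in fh if line.strip()], dtype=float)
    return start_time, Stream(rate=rate, values=values)


def read_bundle(path: str | Path) -> RecordingBundle:
    """Read a bundle directory.

    A missing ``eeg.csv`` is fatal; a missing wristband stream file only
    drops that stream (with a logged warning) so the subject can later be
    flagged incomplete by the feature-extraction stage.
    """
    path = Path(path)
    eeg_path = path / "eeg.csv"
    if not eeg_path.exists():
        raise FileNotFoundError(f"missing EEG file {eeg_path}")
    with open(eeg_path) as fh:
        header = fh.readline().strip().split(",")
    eeg = np.loadtxt(eeg_path, delimiter=",", skiprows=1).T
    if eeg.ndim == 1:
        eeg = eeg[None, :]

    onsets, labels = [], []
    with open(path / "markers.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            onsets.append(int(row["onset_sample"]))
            labels.append(row["label"])
    markers = MarkerTable(onsets=np.array(onsets, dtype=np.int64), labels=tuple(labels))

    manifest: dict = {}
    manifest_path = path / "manifest.json"
    if manifest_path.exists():
        with open(manifest_path) as fh:
            manifest = json.load(fh)

    wristband: dict[str, Stream] = {}
    start_time = str(manifest.get("start_time", "0"))
    for name in WRISTBAND_STREAMS:
        stream_path = path / f"{name}.csv"
        if not stream_path.exists():
            logger.warning("subject %s: wristband stream %s missing",
                           manifest.get("subject_id", path.name), name)
            continue
        start_time, wristband[name] = _read_stream(stream_path)

    fas = None
    fas_path = path / "fas.csv"
    if fas_path.exists():
        with open(fas_path, newline="") as fh:
            items = [int(row["score"]) for row in csv.DictReader(fh)]
        fas = score_fas(items)

    segments = {k: (int(v[0]), int(v[1])) for k, v in manifest.get(
        "segments", {k: list(v) for k, v in SEGMENTS.items()}).items()}
    fas_total = manifest.get("fas_total")
    return RecordingBundle(
        eeg=eeg,
        markers=markers,
        wristband=wristband,
        channel_names=tuple(manifest.get("channel_names", header)),
        rate=float(manifest.get("rate", EEG_RATE)),
        segments=segments,
        fas=fas,
        fas_total=None if fas_total is None else float(fas_total),
        subject_id=str(manifest.get("subject_id", path.name)),
        start_time=start_time,
    )


def with_eeg(bundle: RecordingBundle, eeg: np.ndarray) -> RecordingBundle:
    """Copy of *bundle* with the EEG matrix replaced (markers untouched)."""
    return replace(bundle, eeg=np.asarray(eeg, dtype=float))
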