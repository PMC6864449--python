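"""WAV recording and manifest I/O.

A phonocardiogram (PCG) recording is a mono amplitude sequence with a
sampling rate, an identifier and an optional class label.  The pipeline
assumes 4 kHz mono audio; files at other rates are polyphase-resampled to
4 kHz on read unless resampling is disabled, in which case they are
rejected.  Labelled datasets are described by a manifest CSV with header
``path,label`` whose paths are resolved relative to the manifest's
directory.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from enum import IntEnum
from math import floor
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = [
    "PIPELINE_RATE",
    "ClassLabel",
    "Recording",
    "Manifest",
    "read_wav",
    "write_wav",
    "duration_seconds",
    "load_manifest",
    "save_manifest",
]

#: Sampling rate (Hz) the pipeline operates at.
PIPELINE_RATE = 4000


class ClassLabel(IntEnum):
    """The three heartbeat sound categories, with a fixed integer encoding
    so confusion matrices are comparable across runs."""

    NORMAL = 0
    MURMUR = 1
    EXTRASYSTOLE = 2

    @classmethod
    def parse(cls, text: str) -> "ClassLabel":
        """Parse a label string case-insensitively, accepting the historical
        spelling variants found in heart-sound challenge manifests."""
        key = text.strip().lower().replace("-", "").replace("_", "").replace(" ", "")
        try:
            return _LABEL_ALIASES[key]
        except KeyError:
            raise ValueError(
                f"unknown class label {text!r}; expected one of "
                "normal / murmur / extrasystole"
            ) from None


# "extrastole" is the spelling used by the original challenge file names.
_LABEL_ALIASES = {
    "normal": ClassLabel.NORMAL,
    "murmur": ClassLabel.MURMUR,
    "extrasystole": ClassLabel.EXTRASYSTOLE,
    "extrastole": ClassLabel.EXTRASYSTOLE,
}


@dataclass(frozen=True)
class Recording:
    """A mono heart-sound recording.

    Parameters
    ----------
    samples : ndarray of float
        Amplitudes, any real scale, one channel.
    rate : int
        Sampling rate in Hz, positive.
    id : str
        Opaque identifier (usually the file stem).
    label : ClassLabel, optional
        Ground-truth category if known.
    """

    samples: np.ndarray
    rate: int
    id: str = ""
    label: ClassLabel | None = None

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError(f"recording must be mono 1-D, got shape {samples.shape}")
        if samples.size == 0:
            raise ValueError("recording has no samples")
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    def with_samples(self, samples: np.ndarray) -> "Recording":
        return replace(self, samples=samples)


def duration_seconds(rec: Recording, *, ndigits: int | None = None) -> float:
    """Duration of a recording in seconds, ``len(samples) / rate``.

    With ``ndigits`` the value is rounded half-away-from-zero, matching the
    one-decimal presentation conventional for heart-sound datasets
    (26,551 samples at 4 kHz reports as 6.6 s).
    """
    value = len(rec) / rec.rate
    if ndigits is None:
        return value
    shift = 10**ndigits
    return floor(abs(value) * shift + 0.5) / shift * (1 if value >= 0 else -1)


def read_wav(
    path: str | Path,
    *,
    target_rate: int | None = PIPELINE_RATE,
    resample: bool = True,
    label: ClassLabel | None = None,
) -> Recording:
    """Read a mono PCM/float WAV file into a :class:`Recording`.

    Integer PCM is scaled to ``[-1, 1)``; float WAV is taken as-is.  Files
    whose header rate differs from ``target_rate`` are polyphase-resampled,
    or rejected when ``resample=False``.  Multi-channel input is rejected
    rather than silently mixed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(
            f"{path}: expected mono audio, got {data.shape[1]} channels"
        )
    if data.size == 0:
        raise ValueError(f"{path}: zero-length audio")
    if data.dtype.kind == "i":
        samples = data.astype(np.float64) / float(2 ** (8 * data.dtype.itemsize - 1))
    elif data.dtype.kind == "u":  # 8-bit WAV is unsigned
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:
        samples = data.astype(np.float64)
    if target_rate is not None and rate != target_rate:
        if not resample:
            raise ValueError(
                f"{path}: rate {rate} Hz != required {target_rate} Hz "
                "and resampling is disabled"
            )
        from math import gcd

        g = gcd(target_rate, rate)
        samples = resample_poly(samples, target_rate // g, rate // g)
        rate = target_rate
    return Recording(samples=samples, rate=rate, id=path.stem, label=label)


def write_wav(rec: Recording, path: str | Path, *, clip: bool = False) -> Path:
    """Write a recording as 16-bit PCM WAV.

    Samples must lie in ``[-1, 1]``; out-of-range amplitudes raise unless
    ``clip=True``, which hard-clips them first.
    """
    path = Path(path)
    samples = rec.samples
    peak = float(np.max(np.abs(samples))) if len(samples) else 0.0
    if peak > 1.0:
        if not clip:
            raise ValueError(
                f"samples exceed |1| (peak {peak:.4g}); pass clip=True to clip"
            )
        samples = np.clip(samples, -1.0, 1.0)
    # scale by 2^15 (clipping the one unrepresentable code at +1.0) so the
    # read scaling 1/2^15 round-trips within half a quantization step
    pcm = np.clip(np.round(samples * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(str(path), rec.rate, pcm)
    return path


@dataclass
class Manifest:
    """An ordered mapping of WAV paths to class labels."""

    entries: list[tuple[Path, ClassLabel]] = field(default_factory=list)
    root: Path = Path(".")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def paths(self) -> list[Path]:
        return [p for p, _ in self.entries]

    @property
    def labels(self) -> np.ndarray:
        return np.array([int(lab) for _, lab in self.entries], dtype=np.int64)

    def class_counts(self) -> dict[ClassLabel, int]:
        counts = {lab: 0 for lab in ClassLabel}
        for _, lab in self.entries:
            counts[lab] += 1
        return counts

    def resolve(self, path: Path) -> Path:
        return path if path.is_absolute() else self.root / path

    def subset(self, indices) -> "Manifest":
        return Manifest([self.entries[i] for i in indices], root=self.root)


def load_manifest(path: str | Path) -> Manifest:
    """Load a ``path,label`` CSV manifest.

    Labels are parsed case-insensitively through the alias table; unknown
    labels and duplicate paths are hard errors (silent label corruption is
    worse than failure).
    """
    path = Path(path)
    entries: list[tuple[Path, ClassLabel]] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"path", "label"} <= set(reader.fieldnames):
            raise ValueError(f"{path}: manifest must have header columns path,label")
        for row in reader:
            p = row["path"].strip()
            if p in seen:
                raise ValueError(f"{path}: duplicate path {p!r}")
            seen.add(p)
            entries.append((Path(p), ClassLabel.parse(row["label"])))
    return Manifest(entries, root=path.parent)


def save_manifest(manifest: Manifest, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "label"])
        for p, lab in manifest.entries:
            writer.writerow([str(p), lab.name.lower()])
    return path
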