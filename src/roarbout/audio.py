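"""WAV audio and Raven-style selection-table I/O.

Field recordings arrive as long (often quadraphonic) WAV files at 16 kHz,
annotated in Raven Pro with tight bounding boxes around each vocalisation.
Raven exports those boxes as tab-separated "selection tables"; this module
reads them into :class:`CallAnnotation` records and slices the annotated
calls out of the audio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "AudioClip",
    "CallAnnotation",
    "CALL_TYPES",
    "read_wav",
    "write_wav",
    "read_selection_table",
    "write_selection_table",
    "slice_call",
]

#: Canonical call-type labels of a roaring bout, in bout order.
CALL_TYPES = ("moan", "full_throated_roar", "intermediary_roar", "grunt")

# Raven 1.6 default column headers; a column_map overrides these.
_DEFAULT_COLUMNS = {
    "begin": "Begin Time (s)",
    "end": "End Time (s)",
    "max_freq": "Max Freq (Hz)",
    "duration": "Delta Time (s)",
    "label": "Annotation",
    "bout": "Bout",
    "source": "Source",
}


class FormatError(ValueError):
    """Raised when a file payload does not match the expected format."""


class SchemaError(ValueError):
    """Raised when a required selection-table column cannot be resolved."""


@dataclass(frozen=True)
class AudioClip:
    """A sampled waveform.

    Parameters
    ----------
    samples : ndarray
        Amplitudes, shape ``(n,)`` for mono or ``(n, channels)`` for
        multi-channel audio. Stored as float64 internally.
    rate : int
        Sampling rate in Hz.
    """

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=np.float64)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.ndim != 2 or arr.shape[0] < 1:
            raise ValueError("samples must be a non-empty 1-D or 2-D array")
        if not np.all(np.isfinite(arr)):
            raise ValueError("samples must be finite")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        object.__setattr__(self, "samples", arr)

    @property
    def channel_count(self) -> int:
        return self.samples.shape[1]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def channel(self, index: int = 0) -> "AudioClip":
        """Return a mono clip holding one channel."""
        if not 0 <= index < self.channel_count:
            raise IndexError(f"channel {index} out of range (clip has {self.channel_count})")
        return AudioClip(self.samples[:, index], self.rate)

    @property
    def mono(self) -> np.ndarray:
        """The single channel as a 1-D array; errors on multi-channel clips."""
        if self.channel_count != 1:
            raise ValueError("clip is not mono; select a channel first")
        return self.samples[:, 0]


@dataclass(frozen=True)
class CallAnnotation:
    """One vocalisation's bounding-box annotation.

    ``duration_s`` normally equals ``end_s - begin_s``; Raven's Delta Time
    column is authoritative when present, and a mismatch beyond 1e-6 s is
    rejected.
    """

    begin_s: float
    end_s: float
    max_freq_hz: float
    duration_s: float = field(default=None)  # type: ignore[assignment]
    call_type: str | None = None
    bout_id: str = ""
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.begin_s < 0:
            raise ValueError("begin_s must be >= 0")
        if self.end_s <= self.begin_s:
            raise ValueError("end_s must exceed begin_s")
        if self.max_freq_hz <= 0:
            raise ValueError("max_freq_hz must be positive")
        if self.duration_s is None:
            object.__setattr__(self, "duration_s", self.end_s - self.begin_s)
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if abs(self.duration_s - (self.end_s - self.begin_s)) > 1e-6:
            raise ValueError(
                f"duration_s {self.duration_s} disagrees with end-begin "
                f"{self.end_s - self.begin_s} beyond 1e-6"
            )
        if self.call_type is not None and self.call_type not in CALL_TYPES:
            raise ValueError(f"unknown call_type {self.call_type!r}; expected one of {CALL_TYPES}")

    def relabel(self, call_type: str | None) -> "CallAnnotation":
        return replace(self, call_type=call_type)


def read_wav(path: str | Path) -> AudioClip:
    """Read a PCM or float WAV file into an :class:`AudioClip`.

    All channels are preserved; integer PCM is rescaled to [-1, 1).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        rate, data = wavfile.read(path)
    except ValueError as exc:
        raise FormatError(f"{path} is not a readable WAV file: {exc}") from exc
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max) + 1.0
        data = data.astype(np.float64) / scale
    return AudioClip(np.asarray(data, dtype=np.float64), int(rate))


def write_wav(path: str | Path, clip: AudioClip) -> None:
    """Write a clip as 32-bit float WAV (the field recorders' bit depth)."""
    data = clip.samples.astype(np.float32)
    if data.shape[1] == 1:
        data = data[:, 0]
    wavfile.write(Path(path), clip.rate, data)


def _resolve_columns(columns: list[str], column_map: dict[str, str] | None) -> dict[str, str]:
    mapping = dict(_DEFAULT_COLUMNS)
    if column_map:
        mapping.update(column_map)
    return {key: name for key, name in mapping.items() if name in columns}


def read_selection_table(
    path: str | Path, column_map: dict[str, str] | None = None
) -> list[CallAnnotation]:
    """Read a Raven-style tab-separated selection table.

    Required columns (resolvable via Raven 1.6 defaults or ``column_map``):
    begin time, end time and max frequency. Duration is taken from the
    Delta Time column when present, else computed as end - begin. Label,
    bout and source columns are optional.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str)
    resolved = _resolve_columns(list(table.columns), column_map)
    for key in ("begin", "end", "max_freq"):
        if key not in resolved:
            wanted = (column_map or {}).get(key, _DEFAULT_COLUMNS[key])
            raise SchemaError(f"required column {wanted!r} ({key}) not found in {path.name}")

    annotations: list[CallAnnotation] = []
    for i, row in table.iterrows():
        def num(key: str) -> float:
            cell = row[resolved[key]]
            try:
                return float(cell)
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"{path.name} row {i + 1}: non-numeric value {cell!r} in column "
                    f"{resolved[key]!r}"
                ) from exc

        begin, end = num("begin"), num("end")
        duration = num("duration") if "duration" in resolved else end - begin
        label = row[resolved["label"]] if "label" in resolved else None
        if isinstance(label, float) and math.isnan(label):
            label = None
        annotations.append(
            CallAnnotation(
                begin_s=begin,
                end_s=end,
                max_freq_hz=num("max_freq"),
                duration_s=duration,
                call_type=label if label else None,
                bout_id=str(row[resolved["bout"]]) if "bout" in resolved else "",
                source_id=str(row[resolved["source"]]) if "source" in resolved else "",
            )
        )
    return annotations


def write_selection_table(path: str | Path, annotations: list[CallAnnotation]) -> None:
    """Write annotations as a Raven-style tab-separated table (round-trips
    with :func:`read_selection_table`)."""
    frame = pd.DataFrame(
        {
            _DEFAULT_COLUMNS["begin"]: [a.begin_s for a in annotations],
            _DEFAULT_COLUMNS["end"]: [a.end_s for a in annotations],
            _DEFAULT_COLUMNS["duration"]: [a.duration_s for a in annotations],
            _DEFAULT_COLUMNS["max_freq"]: [a.max_freq_hz for a in annotations],
            _DEFAULT_COLUMNS["label"]: [a.call_type or "" for a in annotations],
            _DEFAULT_COLUMNS["bout"]: [a.bout_id for a in annotations],
            _DEFAULT_COLUMNS["source"]: [a.source_id for a in annotations],
        }
    )
    frame.to_csv(Path(path), sep="\t", index=False, float_format="%.9g")


def slice_call(clip: AudioClip, ann: CallAnnotation, channel: int = 0) -> AudioClip:
    """Cut one annotated call out of a longer recording.

    The interval is half-open [begin, end): the slice starts at
    ``floor(begin_s * rate)`` and holds ``round(duration * rate)`` samples,
    so adjacent annotations never share a sample.
    """
    if not 0 <= channel < clip.channel_count:
        raise IndexError(f"channel {channel} out of range")
    start = int(math.floor(ann.begin_s * clip.rate))
    length = int(round((ann.end_s - ann.begin_s) * clip.rate))
    if start >= clip.n_samples or start + length > clip.n_samples:
        raise ValueError(
            f"annotation [{ann.begin_s}, {ann.end_s}) s lies outside the clip "
            f"({clip.duration_s:.3f} s)"
        )
    return AudioClip(clip.samples[start : start + length, channel], clip.rate)
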