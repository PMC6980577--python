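"""Reading and windowing RR-interval data.

Two input shapes are supported: plain RR exports (one interval per line,
or a CSV with an ``rr_ms`` column) as produced from consumer chest-strap
loggers, and PhysioNet-style beat-annotation tables where rhythm tags
such as ``(AFIB`` mark the start of an episode that persists until the
next tag.  Labeled series are cut into non-overlapping 60-beat windows;
a window keeps its label only if all 60 intervals carry the same one.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "RhythmLabel",
    "RRSeries",
    "Window",
    "DEFAULT_LABEL_MAP",
    "map_rhythm_label",
    "read_rr_text",
    "read_annotated_record",
    "segment_windows",
]

#: Physiological sanity bounds for a single RR interval, in milliseconds.
RR_MIN_MS = 0.0
RR_MAX_MS = 5000.0

WINDOW_LENGTH = 60


class RhythmLabel(Enum):
    """Binary rhythm class with AF as the positive class."""

    AF = "AF"
    NON_AF = "NON_AF"


#: Default mapping from database rhythm tags to the binary label.
#: Only "AFIB" maps to AF; atrial flutter ("AFL") and everything else
#: count as non-AF because flutter is annotated as a separate rhythm
#: in the source databases.  Pass a custom mapping to override.
DEFAULT_LABEL_MAP: Mapping[str, RhythmLabel] = {"AFIB": RhythmLabel.AF}


class RRParseError(ValueError):
    """Malformed RR input (non-numeric payload, bad annotation row)."""


class RRValidationError(ValueError):
    """Structurally valid input with physiologically impossible values."""


@dataclass(frozen=True)
class RRSeries:
    """An ordered sequence of RR intervals in milliseconds.

    ``labels`` when present are raw rhythm tags (e.g. ``"AFIB"``,
    ``"N"``) aligned 1:1 with ``intervals``.
    """

    intervals: np.ndarray
    labels: tuple[str, ...] | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "intervals", arr)
        if arr.ndim != 1:
            raise RRValidationError("intervals must be one-dimensional")
        bad = np.flatnonzero(~((arr > RR_MIN_MS) & (arr < RR_MAX_MS)))
        if bad.size:
            i = int(bad[0])
            raise RRValidationError(
                f"interval {arr[i]!r} at position {i} outside "
                f"({RR_MIN_MS:g}, {RR_MAX_MS:g}) ms"
            )
        if self.labels is not None:
            labels = tuple(self.labels)
            object.__setattr__(self, "labels", labels)
            if len(labels) != arr.size:
                raise RRValidationError(
                    f"{len(labels)} labels for {arr.size} intervals"
                )

    def __len__(self) -> int:
        return int(self.intervals.size)


@dataclass(frozen=True)
class Window:
    """Exactly 60 consecutive RR intervals, optionally labeled."""

    intervals: np.ndarray
    label: RhythmLabel | None = None
    origin: tuple[str, int] = ("", 0)
    length: int = field(default=WINDOW_LENGTH, repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "intervals", arr)
        if arr.shape != (self.length,):
            raise RRValidationError(
                f"window needs exactly {self.length} intervals, got {arr.shape}"
            )


def map_rhythm_label(
    raw_tag: str,
    label_map: Mapping[str, RhythmLabel] = DEFAULT_LABEL_MAP,
) -> RhythmLabel:
    """Map a raw database rhythm tag to the binary AF / non-AF label.

    Leading ``(`` from the annotation aux string is stripped, so both
    ``"AFIB"`` and ``"(AFIB"`` are accepted.
    """
    tag = raw_tag.strip().lstrip("(").strip()
    if not tag:
        raise RRParseError("empty rhythm tag")
    return label_map.get(tag, RhythmLabel.NON_AF)


def read_rr_text(
    stream: io.TextIOBase | str | Iterable[str],
    *,
    seconds: bool = False,
    source_id: str = "",
) -> RRSeries:
    """Parse a plain RR export into an :class:`RRSeries`.

    Accepts one numeric value per line, or a delimited table whose header
    names an ``rr_ms`` (or ``rr_s``) column.  Blank lines and lines
    starting with ``#`` are skipped.  ``seconds=True`` converts values
    from seconds to milliseconds on ingest.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in stream]

    content = [
        (i + 1, ln.strip()) for i, ln in enumerate(lines)
        if ln.strip() and not ln.strip().startswith("#")
    ]
    if not content:
        return RRSeries(np.empty(0), source_id=source_id)

    header = content[0][1]
    rr_col = _find_rr_column(header)
    if rr_col is not None:
        col, delim, col_seconds = rr_col
        values = []
        reader = csv.reader((ln for _, ln in content), delimiter=delim)
        next(reader)  # header
        for (lineno, _), row in zip(content[1:], reader):
            try:
                values.append(float(row[col]))
            except (ValueError, IndexError):
                raise RRParseError(
                    f"line {lineno}: cannot read RR value from {row!r}"
                ) from None
        scale = 1000.0 if (seconds or col_seconds) else 1.0
    else:
        values = []
        for lineno, ln in content:
            try:
                values.append(float(ln))
            except ValueError:
                raise RRParseError(
                    f"line {lineno}: non-numeric RR value {ln!r}"
                ) from None
        scale = 1000.0 if seconds else 1.0

    arr = np.asarray(values) * scale
    bad = np.flatnonzero(~((arr > RR_MIN_MS) & (arr < RR_MAX_MS)))
    if bad.size:
        i = int(bad[0])
        lineno = content[i + (1 if rr_col is not None else 0)][0]
        raise RRValidationError(
            f"line {lineno}: RR value {arr[i]:g} ms outside "
            f"({RR_MIN_MS:g}, {RR_MAX_MS:g}) ms"
        )
    return RRSeries(arr, source_id=source_id)


def _find_rr_column(header: str) -> tuple[int, str, bool] | None:
    """Return (column index, delimiter, values-in-seconds) if the first
    line looks like a table header with an RR column, else None."""
    for delim in (",", "\t", ";"):
        if delim in header:
            names = [c.strip().lower() for c in header.split(delim)]
            for name, in_seconds in (("rr_ms", False), ("rr_s", True)):
                if name in names:
                    return names.index(name), delim, in_seconds
            return None
    return None


def read_annotated_record(
    beat_times_s: Sequence[float] | np.ndarray,
    annotations: Sequence[tuple[float, str]],
    *,
    source_id: str = "",
) -> RRSeries:
    """Build a labeled RRSeries from beat times and rhythm annotations.

    ``beat_times_s`` are beat (R-wave) timestamps in seconds; the
    annotated intervals are their successive differences, no QRS
    detection is involved.  ``annotations`` is a sequence of
    ``(time_s, rhythm_tag)`` pairs in the PhysioNet convention: a tag
    such as ``"(AFIB"`` starts an episode that stays in force until the
    next tag.  Each interval is labeled with the rhythm in force at its
    terminating beat.
    """
    beats = np.asarray(beat_times_s, dtype=float)
    if beats.size < 2:
        raise RRValidationError("need at least two beats to form an interval")
    if np.any(np.diff(beats) <= 0):
        raise RRValidationError("beat times must be strictly increasing")
    if not annotations:
        raise RRParseError("record carries no rhythm annotations")

    ann = sorted(((float(t), tag.strip()) for t, tag in annotations),
                 key=lambda p: p[0])
    for _, tag in ann:
        if not tag.lstrip("("):
            raise RRParseError("empty rhythm tag in annotations")

    intervals = np.diff(beats) * 1000.0
    ann_times = np.asarray([t for t, _ in ann])
    tags = [tag.lstrip("(") for _, tag in ann]
    # rhythm in force at the interval's terminating beat
    idx = np.searchsorted(ann_times, beats[1:], side="right") - 1
    if np.any(idx < 0):
        raise RRParseError(
            "beats occur before the first rhythm annotation"
        )
    labels = tuple(tags[i] for i in idx)
    return RRSeries(intervals, labels=labels, source_id=source_id)


def read_annotation_table(
    stream: io.TextIOBase | str | Iterable[str],
    *,
    source_id: str = "",
) -> RRSeries:
    """Parse a text beat-annotation table (``rdann -v``-style layout).

    Each non-comment line is whitespace-delimited:
    ``time_s  symbol  [aux]`` where ``symbol`` is a beat or annotation
    code and ``aux``, when present and starting with ``(``, is a rhythm
    tag.  Lines whose symbol is ``+`` are pure rhythm-change markers and
    contribute no beat.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = list(stream)
    beats: list[float] = []
    anns: list[tuple[float, str]] = []
    for raw in lines:
        ln = raw.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split()
        if len(parts) < 2:
            raise RRParseError(f"malformed annotation line: {ln!r}")
        t = float(parts[0])
        symbol = parts[1]
        if symbol != "+":
            beats.append(t)
        if len(parts) > 2 and parts[2].startswith("("):
            anns.append((t, parts[2]))
    return read_annotated_record(beats, anns, source_id=source_id)


def segment_windows(
    series: RRSeries,
    length: int = WINDOW_LENGTH,
    stride: int | None = None,
    label_map: Mapping[str, RhythmLabel] = DEFAULT_LABEL_MAP,
) -> list[Window]:
    """Cut a series into fixed-length windows of consecutive intervals.

    Windows start at 0, stride, 2*stride, ...; a trailing remainder
    shorter than ``length`` is dropped.  For labeled series, a window is
    emitted only if all its intervals map to the same binary label
    (purity rule); windows that span a rhythm change are discarded.
    Unlabeled series yield unlabeled windows.
    """
    if length < 2:
        raise ValueError("window length must be >= 2")
    if stride is None:
        stride = length
    if stride < 1:
        raise ValueError("stride must be >= 1")

    n = len(series)
    mapped: list[RhythmLabel] | None = None
    if series.labels is not None:
        mapped = [map_rhythm_label(t, label_map) for t in series.labels]

    windows: list[Window] = []
    for start in range(0, n - length + 1, stride):
        chunk = series.intervals[start:start + length]
        if mapped is None:
            windows.append(Window(chunk, None,
                                  (series.source_id, start), length))
            continue
        chunk_labels = mapped[start:start + length]
        first = chunk_labels[0]
        if all(lb is first for lb in chunk_labels):
            windows.append(Window(chunk, first,
                                  (series.source_id, start), length))
    return windows
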