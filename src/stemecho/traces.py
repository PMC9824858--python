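"""Data model and I/O for ultrasonic A-scan traces and echo picks.

An A-scan is a single pulse-echo RF record: amplitude versus sample index at
a fixed sampling rate (default 10 MHz, 2000 samples per pulse on the
reference acquisition system). Onsets are reported on three scales:

* 1-based sample index — the native coordinate of the trace;
* display units (du) — the acquisition display axis, ``1 du = 100 samples``
  (sample 153 reads 1.53 du);
* physical seconds — ``index / sampling_rate``.

Trace files are plain delimited text (comma or tab, auto-detected), one
amplitude column per trace, with an optional single header row naming the
traces. The sampling rate comes from an optional YAML/JSON sidecar
(``<file>.yaml`` / ``<file>.json``) with key ``sampling_rate_hz``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "DEFAULT_SAMPLING_RATE_HZ",
    "SAMPLES_PER_DISPLAY_UNIT",
    "UltrasonicTrace",
    "EchoPick",
    "index_to_display",
    "display_to_index",
    "index_to_seconds",
    "read_traces",
    "write_picks",
    "read_picks",
]

#: Acquisition default: 10 MHz sampling.
DEFAULT_SAMPLING_RATE_HZ = 1.0e7

#: Display-axis convention: one display unit spans 100 samples.
SAMPLES_PER_DISPLAY_UNIT = 100

#: Picker minimum support (the two-segment variance model needs headroom).
MIN_TRACE_LENGTH = 16

PICK_COLUMNS = (
    "trace_id",
    "onset_index",
    "onset_du",
    "classic_min_index",
    "mixed_peak_value",
)


@dataclass(frozen=True)
class UltrasonicTrace:
    """One A-scan: an amplitude sequence with its sampling rate."""

    samples: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE_HZ
    trace_id: str = "trace"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise ValueError("trace samples must be one-dimensional")
        if samples.size < MIN_TRACE_LENGTH:
            raise ValueError(
                f"trace '{self.trace_id}' has {samples.size} samples; "
                f"at least {MIN_TRACE_LENGTH} are required"
            )
        if not np.all(np.isfinite(samples)):
            raise ValueError(f"trace '{self.trace_id}' contains non-finite samples")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    def __len__(self) -> int:
        return int(self.samples.size)


def index_to_display(index: int) -> float:
    """Convert a 1-based sample index to display units (index / 100)."""
    if index < 1:
        raise ValueError(f"sample index must be >= 1, got {index}")
    return index / SAMPLES_PER_DISPLAY_UNIT


def display_to_index(value: float) -> int:
    """Inverse of :func:`index_to_display` (exact on integer indices)."""
    if value < 0:
        raise ValueError(f"display time must be >= 0, got {value}")
    return int(round(value * SAMPLES_PER_DISPLAY_UNIT))


def index_to_seconds(index: int, sampling_rate: float = DEFAULT_SAMPLING_RATE_HZ) -> float:
    """Physical time of a 1-based sample index, in seconds."""
    if index < 1:
        raise ValueError(f"sample index must be >= 1, got {index}")
    if not sampling_rate > 0:
        raise ValueError("sampling_rate must be positive")
    return index / sampling_rate


@dataclass(frozen=True)
class EchoPick:
    """A picked primary-echo onset with its diagnostics.

    ``onset_index`` is the 1-based sample of the mixed-curve maximum;
    ``classic_min_index`` is the global minimum of the plain AIC curve (on
    stem-like traces this sits at the excitation/noise junction, not at the
    echo); ``mixed_peak_value`` is the mixed-curve value at the pick.
    """

    trace_id: str
    onset_index: int
    classic_min_index: int
    mixed_peak_value: float
    onset_du: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.onset_du is None:
            object.__setattr__(self, "onset_du", index_to_display(self.onset_index))
        if not 1 <= self.classic_min_index <= self.onset_index:
            raise ValueError(
                f"inconsistent pick: classic_min_index={self.classic_min_index}, "
                f"onset_index={self.onset_index}"
            )
        expected = index_to_display(self.onset_index)
        if abs(self.onset_du - expected) > 1e-9:
            raise ValueError("onset_du does not equal onset_index / 100")


def _detect_delimiter(line: str) -> str | None:
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    return None  # single column / whitespace


def _split(line: str, delim: str | None) -> list[str]:
    return line.split(delim) if delim else line.split()


def _sidecar_sampling_rate(path: Path) -> float | None:
    for suffix in (".yaml", ".yml", ".json"):
        sidecar = path.with_suffix(suffix)
        if sidecar == path or not sidecar.exists():
            continue
        text = sidecar.read_text()
        if suffix == ".json":
            meta = json.loads(text)
        else:
            import yaml

            meta = yaml.safe_load(text)
        if isinstance(meta, dict) and "sampling_rate_hz" in meta:
            return float(meta["sampling_rate_hz"])
    return None


def read_traces(
    path: str | Path,
    sampling_rate: float | None = None,
) -> list[UltrasonicTrace]:
    """Read one trace per column from a delimited text file.

    The delimiter (tab or comma; otherwise whitespace) is auto-detected. A
    first row that does not parse as numbers is taken as a header naming the
    traces. Lines starting with ``#`` are ignored. The sampling rate is, in
    order of precedence: the ``sampling_rate`` argument, a YAML/JSON sidecar
    (key ``sampling_rate_hz``), or 10 MHz.
    """
    path = Path(path)
    lines = [
        (i + 1, line)
        for i, line in enumerate(path.read_text().splitlines())
        if line.strip() and not line.lstrip().startswith("#")
    ]
    if not lines:
        raise ValueError(f"{path}: empty trace file")

    delim = _detect_delimiter(lines[0][1])
    first = _split(lines[0][1], delim)
    names: list[str] | None = None
    try:
        [float(cell) for cell in first]
    except ValueError:
        names = [cell.strip() for cell in first]
        lines = lines[1:]
        if not lines:
            raise ValueError(f"{path}: header but no data rows")

    ncol = len(_split(lines[0][1], delim))
    columns: list[list[float]] = [[] for _ in range(ncol)]
    for lineno, line in lines:
        cells = _split(line, delim)
        if len(cells) != ncol:
            raise ValueError(f"{path}: line {lineno} has {len(cells)} cells, expected {ncol}")
        for col, cell in enumerate(cells):
            try:
                value = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} at line {lineno}, column {col + 1}"
                ) from None
            if not np.isfinite(value):
                raise ValueError(
                    f"{path}: non-finite value {cell!r} at line {lineno}, column {col + 1}"
                )
            columns[col].append(value)

    if names is None:
        stem = path.stem
        names = [stem if ncol == 1 else f"{stem}-{c + 1}" for c in range(ncol)]
    if len(names) != ncol:
        raise ValueError(f"{path}: header names {len(names)} columns, data has {ncol}")

    rate = sampling_rate if sampling_rate is not None else _sidecar_sampling_rate(path)
    if rate is None:
        rate = DEFAULT_SAMPLING_RATE_HZ
    return [
        UltrasonicTrace(np.asarray(col), sampling_rate=rate, trace_id=name)
        for name, col in zip(names, columns)
    ]


def write_picks(
    picks: Sequence[EchoPick],
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Write picks as CSV (columns: trace_id, onset_index, onset_du,
    classic_min_index, mixed_peak_value)."""
    if not picks:
        raise ValueError("no picks to write")
    path = Path(path)
    out = []
    if header_comment:
        out.append(f"# {header_comment}")
    out.append(",".join(PICK_COLUMNS))
    for p in picks:
        out.append(
            f"{p.trace_id},{p.onset_index},{p.onset_du:.2f},"
            f"{p.classic_min_index},{p.mixed_peak_value!r}"
        )
    path.write_text("\n".join(out) + "\n")


def read_picks(path: str | Path) -> list[EchoPick]:
    """Read a pick table written by :func:`write_picks`."""
    path = Path(path)
    rows = [
        line
        for line in path.read_text().splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
    if not rows:
        raise ValueError(f"{path}: empty pick file")
    header = tuple(cell.strip() for cell in rows[0].split(","))
    if header != PICK_COLUMNS:
        raise ValueError(f"{path}: unexpected pick columns {header}")
    picks = []
    for row in rows[1:]:
        trace_id, onset, du, cmin, peak = row.split(",")
        picks.append(
            EchoPick(
                trace_id=trace_id,
                onset_index=int(onset),
                onset_du=float(du),
                classic_min_index=int(cmin),
                mixed_peak_value=float(peak),
            )
        )
    return picks
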