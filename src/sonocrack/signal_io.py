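"""Reading and writing per-seed ultrasound waveform CSV files.

Each seed's A-scan is stored as a single-column CSV: one amplitude per
line, with an optional trailing class-label line ("1" = normal kernel,
"0" = slight crack).  A dataset is a flat directory of such files, one
file per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "UltrasoundRecord",
    "SignalFormatError",
    "DatasetError",
    "read_signal_csv",
    "write_signal_csv",
    "load_dataset",
]


class SignalFormatError(ValueError):
    """A waveform file (or record) violates the expected layout."""


class DatasetError(ValueError):
    """A dataset directory is empty or internally inconsistent."""


@dataclass
class UltrasoundRecord:
    """One seed's A-scan amplitude trace with an optional binary label.

    Parameters
    ----------
    sample_id : str
        Identifier, by convention the source file stem.
    amplitudes : np.ndarray
        Digitised voltage trace (arbitrary units), 1-D, finite.
    label : int or None
        1 = normal kernel, 0 = slight crack; ``None`` if unlabelled.
    """

    sample_id: str
    amplitudes: np.ndarray = field(repr=False)
    label: int | None = None

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.ndim != 1 or self.amplitudes.size == 0:
            raise SignalFormatError("amplitudes must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.amplitudes)):
            raise SignalFormatError("amplitudes contain non-finite values")
        if self.label is not None and self.label not in (0, 1):
            raise SignalFormatError(f"label must be 0 or 1, got {self.label!r}")

    def __len__(self) -> int:
        return int(self.amplitudes.size)


def _parse_value(text: str, path: Path, lineno: int) -> float:
    try:
        value = float(text)
    except ValueError:
        raise SignalFormatError(
            f"{path}: line {lineno}: cannot parse {text!r} as a number"
        ) from None
    if not math.isfinite(value):
        raise SignalFormatError(f"{path}: line {lineno}: non-finite value {text!r}")
    return value


def read_signal_csv(path: str | Path, *, expect_label: bool = True) -> UltrasoundRecord:
    """Read one waveform CSV file.

    The file holds one amplitude per line; when ``expect_label`` is true
    the final line must be the class label (exactly 0 or 1) and is split
    off from the trace.
    """
    path = Path(path)
    lines = [
        (i, s) for i, s in enumerate(path.read_text().splitlines(), start=1)
        if s.strip()
    ]
    if not lines:
        raise SignalFormatError(f"{path}: file contains no values")
    values = [_parse_value(s.strip(), path, i) for i, s in lines]

    label: int | None = None
    if expect_label:
        if len(values) < 2:
            raise SignalFormatError(f"{path}: no amplitudes before the label line")
        last = values[-1]
        if last not in (0.0, 1.0):
            raise SignalFormatError(
                f"{path}: final line must be the class label 0 or 1, got {last!r}"
            )
        label = int(last)
        values = values[:-1]

    return UltrasoundRecord(sample_id=path.stem, amplitudes=np.array(values), label=label)


def write_signal_csv(record: UltrasoundRecord, path: str | Path) -> None:
    """Write ``record`` as a single-column CSV; a read-back round-trips exactly.

    Amplitudes are serialised with :func:`repr` (shortest exact float
    representation), the label — when present — as a bare final ``0``/``1``.
    """
    path = Path(path)
    lines = [repr(float(v)) for v in record.amplitudes]
    if record.label is not None:
        lines.append(str(int(record.label)))
    path.write_text("\n".join(lines) + "\n")


def load_dataset(directory: str | Path, *, expect_label: bool = True) -> list[UltrasoundRecord]:
    """Load every ``*.csv`` file in ``directory`` (non-recursive).

    Records are returned in lexicographic filename order regardless of
    filesystem enumeration order; all traces must share one length.
    """
    directory = Path(directory)
    paths = sorted(directory.glob("*.csv"), key=lambda p: p.name)
    if not paths:
        raise DatasetError(f"{directory}: no CSV files found")
    records = [read_signal_csv(p, expect_label=expect_label) for p in paths]
    lengths = {len(r) for r in records}
    if len(lengths) != 1:
        raise DatasetError(
            f"{directory}: inconsistent trace lengths {sorted(lengths)}"
        )
    return records
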