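"""Reading and writing single-channel signals.

Two plain-text formats are supported: the one-value-per-line segment layout
in which single-channel EEG excerpts (e.g. the Bonn epilepsy corpus,
173.61 Hz, ~4096 samples per segment) are customarily distributed, and CSV
with a header row.  The in-memory container is :class:`TimeSeries`.

All user-facing sample indices are 1-based and inclusive: "samples 476 to
480" means the 476th through 480th values of the segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeries",
    "read_segment",
    "read_csv_column",
    "write_segment",
    "write_forecast",
]


class SignalIOError(ValueError):
    """Raised for malformed or empty signal files."""


@dataclass
class TimeSeries:
    """An ordered sequence of real-valued samples.

    Parameters
    ----------
    values
        The samples, in time order.  Stored as a float64 array; must be
        non-empty and finite.
    sampling_rate_hz
        Optional sampling rate in Hz (e.g. 173.61 for the Bonn corpus).
    label
        Free-text identifier, typically subject/electrode or a file stem.
    """

    values: np.ndarray
    sampling_rate_hz: Optional[float] = None
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("TimeSeries values must be one-dimensional")
        if self.values.size < 1:
            raise SignalIOError("TimeSeries must contain at least one sample")
        if not np.all(np.isfinite(self.values)):
            raise SignalIOError("TimeSeries samples must be finite (no NaN/Inf)")
        if self.sampling_rate_hz is not None and not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")

    def __len__(self) -> int:
        return int(self.values.size)

    def sample(self, index: int) -> float:
        """Return the sample at a 1-based index."""
        if not 1 <= index <= len(self):
            raise IndexError(f"sample index {index} outside 1..{len(self)}")
        return float(self.values[index - 1])

    def slice(self, first: int, last: int) -> np.ndarray:
        """Samples from 1-based ``first`` through ``last``, inclusive."""
        if not 1 <= first <= last <= len(self):
            raise IndexError(f"slice {first}..{last} outside 1..{len(self)}")
        return self.values[first - 1 : last]


def read_segment(
    path: Union[str, Path],
    sampling_rate_hz: Optional[float] = None,
) -> TimeSeries:
    """Read a one-value-per-line plain-text segment.

    Blank lines and lines starting with ``#`` are ignored; leading and
    trailing whitespace (including CR from Windows line endings) is
    tolerated.  Values are parsed as double-precision reals.

    Raises
    ------
    SignalIOError
        If a line does not parse as a finite real number (the message names
        the offending 1-based line number) or if no samples are found.
    """
    path = Path(path)
    values: list[float] = []
    with open(path, "r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                v = float(line)
            except ValueError:
                raise SignalIOError(
                    f"{path}: line {lineno}: cannot parse {line!r} as a number"
                ) from None
            if not math.isfinite(v):
                raise SignalIOError(
                    f"{path}: line {lineno}: non-finite value {line!r}"
                )
            values.append(v)
    if not values:
        raise SignalIOError(f"{path}: no samples found")
    return TimeSeries(np.array(values), sampling_rate_hz, label=path.stem)


def write_segment(
    series: TimeSeries,
    path: Union[str, Path],
    header_lines: Sequence[str] = (),
) -> None:
    """Write a series in the one-value-per-line segment format.

    Values are written with :func:`repr` precision (17 significant digits)
    so that a write/read round trip is exact.  ``header_lines`` are emitted
    first, each prefixed with ``"# "``.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for v in series.values:
            fh.write(f"{float(v)!r}\n")


def read_csv_column(path: Union[str, Path], column: Union[str, int]) -> TimeSeries:
    """Read one column of a CSV file (header row expected) as a TimeSeries.

    ``column`` may be a header name or a 0-based positional index.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    if isinstance(column, int):
        if not 0 <= column < df.shape[1]:
            raise SignalIOError(
                f"{path}: column index {column} out of range; "
                f"available columns: {list(df.columns)}"
            )
        series = df.iloc[:, column]
        name = str(df.columns[column])
    else:
        if column not in df.columns:
            raise SignalIOError(
                f"{path}: no column {column!r}; available columns: "
                f"{sorted(map(str, df.columns))}"
            )
        series = df[column]
        name = column
    series = series.dropna()
    if series.empty:
        raise SignalIOError(f"{path}: column {name!r} holds no values")
    vals = pd.to_numeric(series, errors="coerce").to_numpy(dtype=float)
    if np.isnan(vals).any():
        bad = int(np.flatnonzero(np.isnan(vals))[0])
        raise SignalIOError(
            f"{path}: column {name!r} row {bad + 1} is not numeric"
        )
    return TimeSeries(vals, label=f"{path.stem}:{name}")


def write_forecast(result, path: Union[str, Path]) -> None:
    """Write a forecast as CSV: step_index, predicted, actual, error.

    ``step_index`` is the 1-based absolute sample index of each forecast
    step.  ``actual`` and ``error`` are left blank when the observed value
    is unknown.  The ``predicted`` column round-trips through
    :func:`read_csv_column`.
    """
    n = len(result.predicted)
    if n < 1:
        raise ValueError("forecast result holds no steps")
    if isinstance(path, (str, Path)):
        path = Path(path)
    steps = np.arange(result.origin, result.origin + n)
    actual = result.actual if result.actual is not None else [None] * n
    errors = result.errors if result.errors is not None else [None] * n
    df = pd.DataFrame(
        {
            "step_index": steps,
            "predicted": np.asarray(result.predicted, dtype=float),
            "actual": pd.array(actual, dtype="Float64"),
            "error": pd.array(errors, dtype="Float64"),
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
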