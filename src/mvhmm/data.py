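"""Balanced four-way data container and long-format text serialization.

The observation unit is a P x R real matrix (e.g. a two-factor measurement:
P row levels by R column levels), recorded for I units at T common
occasions, i.e. an I x T x P x R array.  On disk the same data live in a
five-column delimited long table: unit_id, time, row_level, col_level,
value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import BalanceError

__all__ = ["FourWayData", "LONG_COLUMNS", "read_long_table", "write_long_table"]

LONG_COLUMNS = ("unit_id", "time", "row_level", "col_level", "value")


@dataclass
class FourWayData:
    """A balanced four-way panel: I units x T occasions of P x R matrices."""

    values: np.ndarray
    unit_ids: list = field(default_factory=list)
    time_ids: list = field(default_factory=list)
    row_names: list = field(default_factory=list)
    col_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4:
            raise BalanceError(
                f"values must be a 4-way (I, T, P, R) array, got ndim={self.values.ndim}"
            )
        if not np.all(np.isfinite(self.values)):
            raise BalanceError("values contain non-finite entries")
        I, T, P, R = self.values.shape
        if not self.unit_ids:
            self.unit_ids = list(range(1, I + 1))
        if not self.time_ids:
            self.time_ids = list(range(1, T + 1))
        if not self.row_names:
            self.row_names = [f"r{p}" for p in range(1, P + 1)]
        if not self.col_names:
            self.col_names = [f"c{r}" for r in range(1, R + 1)]
        if (len(self.unit_ids), len(self.time_ids), len(self.row_names),
                len(self.col_names)) != (I, T, P, R):
            raise BalanceError("label vectors do not match the array shape")

    @property
    def I(self) -> int:  # noqa: E743 - field-standard symbol
        return self.values.shape[0]

    @property
    def T(self) -> int:
        return self.values.shape[1]

    @property
    def P(self) -> int:
        return self.values.shape[2]

    @property
    def R(self) -> int:
        return self.values.shape[3]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.values.shape


def read_long_table(path, delimiter: str = ",") -> FourWayData:
    """Read a balanced five-column long table into a :class:`FourWayData`.

    Ordering is deterministic: units by first appearance, times ascending,
    row/column levels by first appearance.  Raises :class:`BalanceError` on
    missing or duplicated cells and ``ValueError`` (with a line number) on
    non-numeric values.
    """
    df = pd.read_csv(path, sep=delimiter, dtype={"value": object})
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise BalanceError(
            f"long table must have columns {list(LONG_COLUMNS)}; missing {missing}"
        )
    # float() is correctly rounded, so written values read back bit-exactly
    raw = df["value"].to_numpy()
    values = np.empty(len(raw))
    for i, v in enumerate(raw):
        try:
            values[i] = float(v)
        except (TypeError, ValueError):
            raise ValueError(
                f"non-numeric value in long table at line {i + 2}"
            ) from None
    if np.isnan(values).any():
        line = int(np.argmax(np.isnan(values))) + 2
        raise ValueError(f"non-numeric value in long table at line {line}")
    df = df.assign(value=values)

    units = list(pd.unique(df["unit_id"]))
    times = sorted(pd.unique(df["time"]))
    rows = list(pd.unique(df["row_level"]))
    cols = list(pd.unique(df["col_level"]))

    dup = df.duplicated(subset=["unit_id", "time", "row_level", "col_level"])
    if dup.any():
        rec = df.loc[dup.idxmax()]
        raise BalanceError(
            f"duplicated cell (unit {rec['unit_id']}, time {rec['time']}, "
            f"{rec['row_level']} x {rec['col_level']})"
        )

    idx = pd.MultiIndex.from_product(
        [units, times, rows, cols], names=["unit_id", "time", "row_level", "col_level"]
    )
    series = df.set_index(["unit_id", "time", "row_level", "col_level"])["value"]
    full = series.reindex(idx)
    if full.isna().any():
        u, t, r, c = full.index[int(np.argmax(full.isna().to_numpy()))]
        raise BalanceError(f"unbalanced panel: missing cell (unit {u}, time {t})")
    arr = full.to_numpy().reshape(len(units), len(times), len(rows), len(cols))
    return FourWayData(arr, units, times, rows, cols)


def write_long_table(data: FourWayData, path, delimiter: str = ",") -> None:
    """Write a :class:`FourWayData` as a five-column delimited long table."""
    I, T, P, R = data.shape
    idx = pd.MultiIndex.from_product(
        [data.unit_ids, data.time_ids, data.row_names, data.col_names],
        names=["unit_id", "time", "row_level", "col_level"],
    )
    df = pd.DataFrame({"value": data.values.reshape(-1)}, index=idx).reset_index()
    df.to_csv(path, sep=delimiter, index=False)
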