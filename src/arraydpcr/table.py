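"""PartitionTable: the per-partition record shared across pipeline stages.

Column schema (CSV, matched by name, order-free):

====================  =======  =====================================================
column                dtype    meaning
====================  =======  =====================================================
row, col              int      grid index of the partition
qc_pass               bool     partition carries analyzable reagent (ROX QC)
rox_post_mean         float    illumination-corrected ROX post-cycling patch mean
<ch>_delta            float    corrected post − pre patch mean, probe channel <ch>
<ch>_call             bool     positive call for channel <ch> (implies qc_pass)
====================  =======  =====================================================
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import pandas as pd

from .errors import InvalidInputError, SchemaError

BASE_COLUMNS = ("row", "col", "qc_pass", "rox_post_mean")


class PartitionCounts(NamedTuple):
    k_positive: int
    n_valid: int
    n_total: int


@dataclass
class PartitionTable:
    """Per-partition calls for one array run, one row per grid position."""

    data: pd.DataFrame
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        missing = [c for c in self.expected_columns(self.channels)
                   if c not in self.data.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")

    @staticmethod
    def expected_columns(channels: tuple[str, ...]) -> list[str]:
        cols = list(BASE_COLUMNS)
        for ch in channels:
            cols += [f"{ch}_delta", f"{ch}_call"]
        return cols

    @property
    def n_total(self) -> int:
        return len(self.data)

    @property
    def n_valid(self) -> int:
        return int(self.data["qc_pass"].sum())

    @property
    def n_rejected(self) -> int:
        return self.n_total - self.n_valid

    def counts(self, channel: str) -> PartitionCounts:
        """(k_positive, n_valid, n_total) for one probe channel.

        Rejected partitions are excluded from both numerator and denominator:
        they contain no analyzable reagent.
        """
        if channel not in self.channels:
            raise InvalidInputError(f"unknown channel {channel!r}")
        calls = self.data[f"{channel}_call"] & self.data["qc_pass"]
        return PartitionCounts(int(calls.sum()), self.n_valid, self.n_total)

    def write_csv(self, path: str | Path) -> None:
        cols = self.expected_columns(self.channels)
        self.data.loc[:, cols].to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "PartitionTable":
        """Read a table, validating the schema by column name (order-free)."""
        df = pd.read_csv(path)
        missing = [c for c in BASE_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        channels, extra = [], []
        for c in df.columns:
            if c in BASE_COLUMNS:
                continue
            if c.endswith("_delta"):
                channels.append(c[: -len("_delta")])
            elif not c.endswith("_call"):
                extra.append(c)
        for ch in channels:
            if f"{ch}_call" not in df.columns:
                raise SchemaError(f"missing columns: ['{ch}_call']")
        for c in df.columns:
            if c.endswith("_call") and c[: -len("_call")] not in channels:
                extra.append(c)
        if extra:
            raise SchemaError(f"unexpected columns: {sorted(extra)}")
        df = df.astype({"row": int, "col": int, "qc_pass": bool})
        for ch in channels:
            df = df.astype({f"{ch}_delta": float, f"{ch}_call": bool})
        order = cls.expected_columns(tuple(channels))
        return cls(df.loc[:, order], tuple(channels))
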