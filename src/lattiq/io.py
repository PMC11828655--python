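"""Reading and validating plot-level trait tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import SchemaError
from .simulate import PlotTable

__all__ = ["read_plot_table"]

REQUIRED = ("accession", "replication", "block")


def read_plot_table(
    path,
    traits: list[str] | None = None,
    strip_thousands: bool = False,
) -> PlotTable:
    """Load a plot-level CSV with columns accession, replication, block, traits.

    Duplicate (accession, replication) rows are an error, never silently
    averaged.  With ``strip_thousands`` accession ids like ``243,599``
    have the separator removed before being parsed as integers; by
    default ids must already be clean integers.
    """
    frame = pd.read_csv(path, dtype={"accession": str})
    missing = [c for c in REQUIRED if c not in frame.columns]
    if missing:
        raise SchemaError(f"input is missing required column(s): {missing}")
    if traits is None:
        traits = [c for c in frame.columns if c not in REQUIRED]
    else:
        absent = [t for t in traits if t not in frame.columns]
        if absent:
            raise SchemaError(f"input is missing trait column(s): {absent}")
    if not traits:
        raise SchemaError("input has no trait columns")

    acc = frame["accession"].astype(str)
    if strip_thousands:
        acc = acc.str.replace(",", "", regex=False)
    try:
        frame["accession"] = acc.astype(int)
    except ValueError as exc:
        raise SchemaError(f"non-integer accession id: {exc}") from None

    for col in ("replication", "block"):
        if not np.issubdtype(frame[col].dtype, np.integer):
            try:
                frame[col] = frame[col].astype(int)
            except (ValueError, TypeError):
                raise SchemaError(f"column {col!r} is not integer-valued") from None

    for t in traits:
        coerced = pd.to_numeric(frame[t], errors="coerce")
        bad = frame.index[coerced.isna() & frame[t].notna()]
        if len(bad):
            # +2: header line plus 1-based file rows
            raise SchemaError(
                f"non-numeric value(s) in trait {t!r} at file row(s) "
                f"{[int(i) + 2 for i in bad[:5]]}"
            )
        frame[t] = coerced

    dup = frame.duplicated(subset=["accession", "replication"], keep=False)
    if dup.any():
        rows = [int(i) + 2 for i in frame.index[dup]]
        pairs = frame.loc[dup, ["accession", "replication"]].drop_duplicates()
        raise SchemaError(
            f"duplicate (accession, replication) cells "
            f"{[tuple(x) for x in pairs.to_numpy()]} at file rows {rows}"
        )
    return PlotTable(data=frame, traits=tuple(traits))
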