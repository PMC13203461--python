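"""Reading, cleaning and AOI-labeling of fixation tables.

The canonical fixation table is delimited text (tab or comma) with one
row per fixation and the columns ``participant, item, trial, event_type,
t_onset_ms, duration_ms, x_px, y_px, valid``.  Vendor exports with other
header names are mapped through a *dialect* — a ``{source: canonical}``
column-name mapping.

Cleaning keeps only valid fixations with complete numeric coordinates
and durations; dropped counts are logged.  Labeled sequences are built
per participant x item x trial x event in temporal order, with
``OUTSIDE`` fixations either dropped (sequence stitched across the gap,
the default) or used to break the sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .layout import OUTSIDE, AOILayout

__all__ = [
    "FormatError",
    "AOISequence",
    "read_fixations",
    "clean_fixations",
    "build_sequences",
    "target_sequences",
]

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = [
    "participant",
    "item",
    "trial",
    "event_type",
    "t_onset_ms",
    "duration_ms",
    "x_px",
    "y_px",
    "valid",
]
_NUMERIC = ["t_onset_ms", "duration_ms", "x_px", "y_px"]
_GROUP_KEY = ["participant", "item", "trial", "event_type"]
_TRUE_STRINGS = {"true", "1", "yes", "y", "t"}


class FormatError(ValueError):
    """Input table does not match the expected schema."""


@dataclass
class AOISequence:
    """Temporally ordered AOI labels for one participant/item/trial/event."""

    participant_id: str
    item_id: str
    trial_index: int
    event_type: str
    labels: list[str]
    points: list[tuple[float, float, float]]  # (x, y, duration_ms)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.points):
            raise ValueError("labels and points must have equal length")

    def __len__(self) -> int:
        return len(self.labels)


def _coerce_valid(col: pd.Series) -> pd.Series:
    if col.dtype == bool:
        return col
    return col.astype(str).str.strip().str.lower().isin(_TRUE_STRINGS)


def read_fixations(path, dialect: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a delimited fixation table into typed records.

    Unparseable numeric fields become missing values (they are retained
    until :func:`clean_fixations`); missing mandatory columns raise a
    :class:`FormatError` naming the first absent column.  The delimiter
    (tab or comma) is sniffed from the header line.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if dialect:
        df = df.rename(columns=dialect)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column: {col!r}")
    out = pd.DataFrame(
        {
            "participant": df["participant"].astype(str),
            "item": df["item"].astype(str),
            "trial": pd.to_numeric(df["trial"], errors="coerce").astype("Int64"),
            "event_type": df["event_type"].astype(str),
            "valid": _coerce_valid(df["valid"]),
        }
    )
    for col in _NUMERIC:
        out[col] = pd.to_numeric(df[col].replace("", np.nan), errors="coerce")
    return out[MANDATORY_COLUMNS]


def clean_fixations(table: pd.DataFrame) -> pd.DataFrame:
    """Keep valid fixations with complete coordinates and durations.

    Records with any missing coordinate/duration/trial, a negative
    duration, or ``valid == False`` are removed; counts are logged.  The
    result is re-sorted by onset within each participant/item/trial/event
    group.  An empty result logs a warning rather than raising.
    """
    n0 = len(table)
    complete = table[_NUMERIC + ["trial"]].notna().all(axis=1)
    nonneg = table["duration_ms"].fillna(-1) >= 0
    keep = complete & nonneg & table["valid"].astype(bool)
    out = table.loc[keep].copy()
    n_missing = int((~(complete & nonneg)).sum())
    n_invalid = int((complete & nonneg & ~table["valid"].astype(bool)).sum())
    logger.info(
        "clean_fixations: kept %d/%d records (%d incomplete, %d invalid)",
        len(out), n0, n_missing, n_invalid,
    )
    if len(out) == 0:
        logger.warning("clean_fixations: no records survived cleaning")
    out["trial"] = out["trial"].astype(np.int64)
    out = out.sort_values(_GROUP_KEY + ["t_onset_ms"], kind="mergesort")
    return out.reset_index(drop=True)


def build_sequences(
    records: pd.DataFrame,
    layouts: AOILayout | dict[str, AOILayout],
    drop_outside: bool = True,
    break_at_outside: bool = False,
) -> list[AOISequence]:
    """Assemble labeled AOI sequences from cleaned records.

    One sequence per participant x item x trial x event, fixations in
    temporal order and repeated same-zone fixations kept as distinct
    elements.  ``OUTSIDE`` fixations are dropped and the sequence
    stitched across the gap (default); with ``break_at_outside`` each
    maximal in-zone run becomes its own sequence instead.  Empty groups
    emit no sequence.

    ``layouts`` is a single layout shared by all items or a mapping
    ``{item_id: AOILayout}``.
    """

    def layout_for(item: str) -> AOILayout:
        if isinstance(layouts, AOILayout):
            return layouts
        try:
            return layouts[item]
        except KeyError:
            raise KeyError(f"no AOI layout for item {item!r}") from None

    sequences: list[AOISequence] = []
    recs = records.sort_values(_GROUP_KEY + ["t_onset_ms"], kind="mergesort")
    for (pid, item, trial, event), grp in recs.groupby(_GROUP_KEY, sort=True):
        lay = layout_for(item)
        labels = [lay.assign(x, y) for x, y in zip(grp["x_px"], grp["y_px"])]
        points = list(zip(grp["x_px"], grp["y_px"], grp["duration_ms"]))

        def make(labs, pts):
            if labs:
                sequences.append(
                    AOISequence(pid, item, int(trial), event, list(labs), list(pts))
                )

        if break_at_outside:
            run_l: list[str] = []
            run_p: list[tuple] = []
            for lab, pt in zip(labels, points):
                if lab == OUTSIDE:
                    make(run_l, run_p)
                    run_l, run_p = [], []
                else:
                    run_l.append(lab)
                    run_p.append(pt)
            make(run_l, run_p)
        elif drop_outside:
            kept = [(lab, pt) for lab, pt in zip(labels, points) if lab != OUTSIDE]
            make([k[0] for k in kept], [k[1] for k in kept])
        else:
            make(labels, points)
    return sequences


def target_sequences(
    records: pd.DataFrame,
    layouts: AOILayout | dict[str, AOILayout],
    **kwargs,
) -> list[AOISequence]:
    """Sequences restricted to target-face events (the scanpath analyses' input)."""
    return build_sequences(
        records[records["event_type"] == "target"], layouts, **kwargs
    )
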