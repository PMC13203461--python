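"""Inter-participant concordance of spatial gaze allocation (Kendall's W).

Participants each rank a set of spatial units (the three facial zones
by default, optionally a uniform grid over the face box) by cumulative
fixation duration; Kendall's coefficient of concordance

    W = 12 S / (m^2 (n^3 - n)),   S = sum_i (R_i - Rbar)^2,

with m participants, n units and R_i the rank sum of unit i, measures
agreement (1 = identical rankings).  Mid-ranks are used for tied dwell
values; no tie correction is applied to W itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .layout import AOILayout, LABELS

__all__ = ["ConcordanceResult", "dwell_ranks", "kendall_w"]

logger = logging.getLogger(__name__)


def _grid_units(layout: AOILayout, rows: int, cols: int):
    x0, y0, x1, y1 = layout.face_box
    xs = np.linspace(x0, x1, cols + 1)
    ys = np.linspace(y0, y1, rows + 1)
    return xs, ys


def dwell_ranks(
    records: pd.DataFrame,
    layouts: AOILayout | dict[str, AOILayout],
    units: str | tuple[int, int] = "three_zones",
) -> pd.DataFrame:
    """Participants x units matrix of dwell-duration ranks.

    Target-face fixations only.  ``units`` is ``"three_zones"`` (dwell
    per UFZ/CFZ/LFZ) or ``(rows, cols)`` for a uniform grid over the
    face box (grid cells indexed row-major, fixations outside the box
    ignored; a shared layout is required for the grid).  Ranks are
    mid-ranked ascending per participant (rank 1 = least dwell).
    Participants with zero total dwell are excluded with a log entry.
    """
    from .ingest import target_sequences

    if units == "three_zones":
        unit_labels = list(LABELS)

        def unit_of(lab, x, y):
            return lab if lab in LABELS else None

    else:
        rows_n, cols_n = units
        if isinstance(layouts, dict):
            raise ValueError("grid units require a single shared layout")
        xs, ys = _grid_units(layouts, rows_n, cols_n)
        unit_labels = [f"r{r}c{c}" for r in range(rows_n) for c in range(cols_n)]

        def unit_of(lab, x, y):
            c = np.searchsorted(xs, x, side="right") - 1
            r = np.searchsorted(ys, y, side="right") - 1
            if 0 <= r < rows_n and 0 <= c < cols_n:
                return f"r{r}c{c}"
            return None

    dwell: dict[str, dict[str, float]] = {}
    for seq in target_sequences(records, layouts, drop_outside=False):
        row = dwell.setdefault(seq.participant_id, dict.fromkeys(unit_labels, 0.0))
        for lab, (x, y, dur) in zip(seq.labels, seq.points):
            u = unit_of(lab, x, y)
            if u is not None:
                row[u] += dur

    kept, excluded = {}, []
    for pid in sorted(dwell):
        values = np.array([dwell[pid][u] for u in unit_labels])
        if values.sum() <= 0:
            excluded.append(pid)
            continue
        kept[pid] = stats.rankdata(values)  # ascending mid-ranks
    if excluded:
        logger.info("dwell_ranks: excluded zero-dwell participant(s): %s", excluded)
    if len(kept) < 2 or len(unit_labels) < 2:
        raise ValueError("need >= 2 participants and >= 2 units")
    return pd.DataFrame.from_dict(kept, orient="index", columns=unit_labels)


@dataclass
class ConcordanceResult:
    """Kendall's W with its building blocks."""

    w: float
    s: float
    m: int
    n: int
    rank_matrix: pd.DataFrame


def kendall_w(rank_matrix: pd.DataFrame | np.ndarray) -> ConcordanceResult:
    """Kendall's coefficient of concordance from a participants x units rank matrix."""
    ranks = (
        rank_matrix
        if isinstance(rank_matrix, pd.DataFrame)
        else pd.DataFrame(np.asarray(rank_matrix, dtype=float))
    )
    m, n = ranks.shape
    if m < 2 or n < 2:
        raise ValueError("need >= 2 participants and >= 2 units")
    col_sums = ranks.to_numpy(dtype=float).sum(axis=0)
    s = float(((col_sums - col_sums.mean()) ** 2).sum())
    w = 12.0 * s / (m**2 * (n**3 - n))
    return ConcordanceResult(w=float(w), s=s, m=int(m), n=int(n), rank_matrix=ranks)
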