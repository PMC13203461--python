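"""Cross-event repositioning distances, path length and gaze stability.

The *anchor-based* repositioning analysis measures the Euclidean
displacement between the last fixation of the event preceding a target
face (the anchor: the within-trial context image in the pre-context
procedure, the previous trial's response screen in the post-context
procedure) and the first fixation on that face, grouped by the facial
zone the first fixation lands in.

The *gaze stability index* for a participant x zone cell is
``total fixation duration / within-zone path length`` (ms per px):
higher values mean more dwell per unit of gaze travel.  Path length
within a zone sums the distances of consecutive same-zone fixation
pairs inside each target-face presentation; pairs spanning two zones
contribute to neither.

Zone differences are tested with Kruskal-Wallis (effect size
epsilon^2 = H / (n - 1)) followed by pairwise two-sided rank-sum tests
with Holm correction (effect size r = |Z| / sqrt(n_pair)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .layout import OUTSIDE, AOILayout

__all__ = [
    "RankTestResult",
    "euclidean",
    "path_length",
    "anchor_transitions",
    "stability_table",
    "kruskal_wallis",
    "pairwise_wilcoxon_holm",
]

logger = logging.getLogger(__name__)

_EVENT_BEFORE_TARGET = {"pre_context": "context", "post_context": "response"}


def euclidean(p1, p2) -> float:
    """Euclidean distance between two screen points (px)."""
    (x1, y1), (x2, y2) = p1, p2
    return float(np.hypot(x2 - x1, y2 - y1))


def path_length(points) -> float:
    """Cumulative Euclidean distance along an ordered point list (0 for n=1)."""
    pts = np.asarray([(p[0], p[1]) for p in points], dtype=float)
    if len(pts) == 0:
        raise ValueError("path_length needs at least one point")
    if len(pts) < 2:
        return 0.0
    steps = np.diff(pts, axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum())


def anchor_transitions(
    records: pd.DataFrame,
    layouts: AOILayout | dict[str, AOILayout],
    condition: str,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Anchor-to-first-target-fixation displacements for one condition.

    ``records`` are cleaned fixations from a group run under
    ``condition`` (``pre_context`` or ``post_context``).  For each
    target-face presentation with both an anchor fixation and at least
    one target fixation, emits the anchor point, the landing point, the
    distance between them, and the landing zone.  Presentations without
    an anchor (e.g. the first trial of a block in the post-context
    condition, which has no preceding response screen) are skipped and
    counted in the returned skip dictionary.
    """
    if condition not in _EVENT_BEFORE_TARGET:
        raise ValueError(f"unknown condition {condition!r}")
    anchor_event = _EVENT_BEFORE_TARGET[condition]

    def layout_for(item):
        return layouts if isinstance(layouts, AOILayout) else layouts[item]

    rows = []
    skipped = {"no_anchor": 0, "no_target": 0}
    recs = records.sort_values(["participant", "t_onset_ms"], kind="mergesort")
    for pid, prt in recs.groupby("participant", sort=True):
        for trial, tgrp in prt.groupby("trial", sort=True):
            tgt = tgrp[tgrp["event_type"] == "target"]
            if len(tgt) == 0:
                skipped["no_target"] += 1
                continue
            first = tgt.iloc[0]
            if condition == "pre_context":
                anc = tgrp[
                    (tgrp["event_type"] == anchor_event)
                    & (tgrp["t_onset_ms"] < first["t_onset_ms"])
                ]
            else:
                anc = prt[
                    (prt["trial"] == trial - 1) & (prt["event_type"] == anchor_event)
                ]
            if len(anc) == 0:
                skipped["no_anchor"] += 1
                continue
            last = anc.iloc[-1]
            anchor = (float(last["x_px"]), float(last["y_px"]))
            landing = (float(first["x_px"]), float(first["y_px"]))
            zone = layout_for(first["item"]).assign(*landing)
            rows.append(
                {
                    "participant": pid,
                    "item": first["item"],
                    "trial": int(trial),
                    "condition": condition,
                    "anchor_x": anchor[0],
                    "anchor_y": anchor[1],
                    "landing_x": landing[0],
                    "landing_y": landing[1],
                    "distance_px": euclidean(anchor, landing),
                    "landing_zone": zone,
                }
            )
    if skipped["no_anchor"] or skipped["no_target"]:
        logger.info("anchor_transitions(%s): skipped %s", condition, skipped)
    return pd.DataFrame(rows), skipped


def stability_table(
    records: pd.DataFrame,
    layouts: AOILayout | dict[str, AOILayout],
    level: str = "participant_aoi",
    condition: str | None = None,
) -> pd.DataFrame:
    """Long-format gaze stability table from target-face fixations.

    ``level="participant_aoi"`` aggregates over all of a participant's
    target presentations (one row per participant x zone);
    ``level="participant_aoi_event"`` keeps one row per participant x
    zone x target-face presentation (trial), the grain used by the
    event-type mixed model.  ``total_duration_ms`` sums every fixation
    duration in the zone; ``path_length_px`` sums distances of
    consecutive same-zone fixation pairs within a presentation.  Groups
    with zero path length (e.g. a single fixation in a zone) are
    excluded and their count logged.  ``condition``, when given, is
    attached as a constant column.
    """
    if level not in ("participant_aoi", "participant_aoi_event"):
        raise ValueError(f"unknown level {level!r}")
    from .ingest import target_sequences

    acc: dict[tuple, list[float]] = {}
    for seq in target_sequences(records, layouts):
        for i, (lab, pt) in enumerate(zip(seq.labels, seq.points)):
            if lab == OUTSIDE:
                continue
            key = (
                (seq.participant_id, lab)
                if level == "participant_aoi"
                else (seq.participant_id, lab, seq.trial_index)
            )
            dur, path = acc.setdefault(key, [0.0, 0.0])
            acc[key][0] = dur + pt[2]
            if i > 0 and seq.labels[i - 1] == lab:
                prev = seq.points[i - 1]
                acc[key][1] = path + euclidean(prev[:2], pt[:2])

    rows = []
    n_zero_path = 0
    for key in sorted(acc):
        dur, path = acc[key]
        if path <= 0:
            n_zero_path += 1
            continue
        row = {"participant": key[0], "zone": key[1]}
        if level == "participant_aoi_event":
            row["trial"] = key[2]
        row.update(
            total_duration_ms=dur, path_length_px=path, stability=dur / path
        )
        rows.append(row)
    if n_zero_path:
        logger.info(
            "stability_table(%s): excluded %d zero-path group(s)", level, n_zero_path
        )
    out = pd.DataFrame(rows)
    if condition is not None and len(out):
        out["condition"] = condition
    return out


@dataclass
class RankTestResult:
    """One rank-based test with its effect size.

    ``statistic`` is the Kruskal-Wallis H (chi-square approximated) or
    the rank-sum Z; ``effect_size`` is epsilon^2 for Kruskal-Wallis and
    r = |Z|/sqrt(n) for pairwise tests.  ``p_adjusted`` is Holm-adjusted
    within the pairwise family (equals ``p_raw`` for a lone test).
    """

    test: str
    statistic: float
    p_raw: float
    p_adjusted: float
    effect_size: float
    groups: tuple[str, ...]
    n: dict[str, int] = field(default_factory=dict)


def kruskal_wallis(groups: dict[str, np.ndarray | list]) -> RankTestResult:
    """Kruskal-Wallis test across zone groups with epsilon^2 effect size.

    ``groups`` maps group label -> values.  Empty groups are ignored;
    fewer than two non-empty groups or a total n < 5 is an error.
    epsilon^2 = H / (n - 1).
    """
    named = {k: np.asarray(v, dtype=float) for k, v in groups.items() if len(v) > 0}
    if len(named) < 2:
        raise ValueError("need >= 2 non-empty groups")
    n = sum(len(v) for v in named.values())
    if n < 5:
        raise ValueError(f"need total n >= 5, got {n}")
    h, p = stats.kruskal(*named.values())
    return RankTestResult(
        test="kruskal_wallis",
        statistic=float(h),
        p_raw=float(p),
        p_adjusted=float(p),
        effect_size=float(h / (n - 1)),
        groups=tuple(named),
        n={k: len(v) for k, v in named.items()},
    )


def pairwise_wilcoxon_holm(groups: dict[str, np.ndarray | list]) -> list[RankTestResult]:
    """All pairwise two-sided rank-sum tests with Holm-adjusted p-values.

    Group observations are independent (trial-level values, unequal
    group sizes), so the Mann-Whitney/rank-sum form is used with the
    tie-corrected normal approximation; r = |Z| / sqrt(n1 + n2) with
    |Z| recovered from the two-sided p-value.
    """
    named = {k: np.asarray(v, dtype=float) for k, v in groups.items() if len(v) > 0}
    if len(named) < 2:
        raise ValueError("need >= 2 non-empty groups")
    results = []
    p_raws = []
    for a, b in combinations(sorted(named), 2):
        res = stats.mannwhitneyu(named[a], named[b], alternative="two-sided",
                                 method="asymptotic")
        p = float(res.pvalue)
        z = float(stats.norm.isf(min(p, 1.0) / 2))
        n_pair = len(named[a]) + len(named[b])
        results.append(
            RankTestResult(
                test="wilcoxon_rank",
                statistic=z,
                p_raw=p,
                p_adjusted=np.nan,
                effect_size=z / np.sqrt(n_pair),
                groups=(a, b),
                n={a: len(named[a]), b: len(named[b])},
            )
        )
        p_raws.append(p)
    adjusted = multipletests(p_raws, method="holm")[1]
    for r, p_adj in zip(results, adjusted):
        r.p_adjusted = float(p_adj)
    return results
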