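"""Markov transition estimation and entropy over AOI label sequences.

First-order models estimate P(X_t = j | X_{t-1} = i), second-order
models P(X_t = k | X_{t-2} = i, X_{t-1} = j), with transitions counted
strictly within each sequence (never across participant/item/event
boundaries).  Estimates are plain maximum likelihood (row-normalized
counts, no pseudocounts); contexts never observed carry NaN
probabilities and are flagged.

Entropy is reported in bits and normalized by log2(3) — the number of
possible destination zones — for both model orders, so 0 means a fully
predictable next fixation and 1 a uniform one.  The global value is the
occupancy-weighted mean of per-context entropies, i.e. the plug-in
conditional entropy H(X_t | context).

Model orders are compared on per-participant global entropies with a
Wilcoxon signed-rank test and a participant-level bootstrap of the
median entropy difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import AOISequence
from .simulate import STATES

__all__ = [
    "LOG2_3",
    "EstimationError",
    "TransitionModel",
    "EntropySummary",
    "OrderComparison",
    "estimate_transitions",
    "row_entropy",
    "normalized_from_bits",
    "global_entropy",
    "participant_entropies",
    "compare_orders",
]

logger = logging.getLogger(__name__)

_IDX = {s: i for i, s in enumerate(STATES)}

#: Normalization constant: log2 of the number of destination zones.
LOG2_3 = float(np.log2(3))


class EstimationError(ValueError):
    """No usable data for the requested model order."""


@dataclass
class TransitionModel:
    """Counts and conditional probabilities of an order-k chain over AOIs.

    ``counts`` has shape ``(3,) * order + (3,)`` (context axes oldest
    first, destination last); ``probabilities`` are the row-normalized
    counts, NaN for unobserved contexts.
    """

    order: int
    states: tuple[str, ...]
    counts: np.ndarray
    probabilities: np.ndarray
    n_transitions: int

    @property
    def contexts(self) -> list[tuple[str, ...]]:
        return [tuple(c) for c in product(self.states, repeat=self.order)]

    def context_counts(self, context: tuple[str, ...]) -> np.ndarray:
        return self.counts[tuple(_IDX[s] for s in context)]

    def prob(self, context: tuple[str, ...] | str, dest: str) -> float:
        """P(next = dest | context); context may be a single label for order 1."""
        if isinstance(context, str):
            context = (context,)
        idx = tuple(_IDX[s] for s in context) + (_IDX[dest],)
        return float(self.probabilities[idx])

    def observed(self, context: tuple[str, ...]) -> bool:
        return self.context_counts(context).sum() > 0


def _label_arrays(sequences) -> list[np.ndarray]:
    arrs = []
    for seq in sequences:
        labels = seq.labels if isinstance(seq, AOISequence) else list(seq)
        arrs.append(np.array([_IDX[s] for s in labels], dtype=np.int64))
    return arrs


def estimate_transitions(sequences, order: int) -> TransitionModel:
    """Maximum-likelihood transition model from labeled sequences.

    ``sequences`` is a list of :class:`~gazeseq.ingest.AOISequence` or of
    plain label lists.  A sequence of length L contributes
    ``max(L - order, 0)`` transitions.  Raises :class:`EstimationError`
    when no sequence is longer than ``order``.
    """
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order}")
    counts = np.zeros((3,) * order + (3,), dtype=np.int64)
    total = 0
    for arr in _label_arrays(sequences):
        if len(arr) <= order:
            continue
        if order == 1:
            np.add.at(counts, (arr[:-1], arr[1:]), 1)
        else:
            np.add.at(counts, (arr[:-2], arr[1:-1], arr[2:]), 1)
        total += len(arr) - order
    if total == 0:
        raise EstimationError(f"no sequence longer than order {order}")
    row_sums = counts.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(row_sums > 0, counts / row_sums, np.nan)
    return TransitionModel(
        order=order,
        states=STATES,
        counts=counts,
        probabilities=probs,
        n_transitions=total,
    )


def row_entropy(probabilities) -> tuple[float, float]:
    """Shannon entropy of one destination distribution.

    Returns ``(H_bits, H_norm)`` with ``H_bits = -sum p log2 p``
    (0 log 0 := 0) and ``H_norm = H_bits / log2(3)``.
    """
    p = np.asarray(probabilities, dtype=float)
    if np.any(p < 0):
        raise ValueError("negative probability")
    if not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError(f"probabilities must sum to 1, got {p.sum()}")
    nz = p[p > 0]
    h_bits = float(-(nz * np.log2(nz)).sum())
    return h_bits, h_bits / LOG2_3


def normalized_from_bits(h_bits: float) -> float:
    """Convert entropy in bits to the normalized scale H_bits / log2(3)."""
    return h_bits / LOG2_3


@dataclass
class EntropySummary:
    """Per-context and global transition entropy of one model.

    ``per_context`` maps each observed context to
    ``(H_bits, H_norm, weight)`` where the weight is the context's
    empirical occupancy share among counted transitions; weights sum
    to 1 and the global entropies are the weighted means.
    """

    order: int
    per_context: dict[tuple[str, ...], tuple[float, float, float]]
    global_h_bits: float
    global_h_norm: float
    unobserved: list[tuple[str, ...]]


def global_entropy(model: TransitionModel) -> EntropySummary:
    """Occupancy-weighted entropy summary of a fitted transition model.

    Unobserved contexts get weight 0 and are excluded (listed in
    ``unobserved``); the normalization constant is log2(3) regardless of
    model order.
    """
    per: dict[tuple[str, ...], tuple[float, float, float]] = {}
    unobserved: list[tuple[str, ...]] = []
    total = model.counts.sum()
    g_bits = 0.0
    for ctx in model.contexts:
        row = model.context_counts(ctx)
        n = row.sum()
        if n == 0:
            unobserved.append(ctx)
            continue
        h_bits, h_norm = row_entropy(row / n)
        w = float(n / total)
        per[ctx] = (h_bits, h_norm, w)
        g_bits += w * h_bits
    return EntropySummary(
        order=model.order,
        per_context=per,
        global_h_bits=g_bits,
        global_h_norm=g_bits / LOG2_3,
        unobserved=unobserved,
    )


def participant_entropies(sequences: list[AOISequence], order: int) -> pd.Series:
    """Global normalized entropy per participant.

    Fits a separate transition model on each participant's sequences.
    Participants with no sequence longer than ``order`` are excluded
    with a log entry; raises :class:`EstimationError` if none remain.
    """
    by_pid: dict[str, list[AOISequence]] = {}
    for s in sequences:
        by_pid.setdefault(s.participant_id, []).append(s)
    values = {}
    excluded = []
    for pid in sorted(by_pid):
        try:
            model = estimate_transitions(by_pid[pid], order)
        except EstimationError:
            excluded.append(pid)
            continue
        values[pid] = global_entropy(model).global_h_norm
    if excluded:
        logger.info(
            "participant_entropies(order=%d): excluded %d participant(s) "
            "with no usable sequence: %s", order, len(excluded), excluded,
        )
    if not values:
        raise EstimationError("no participant with usable sequences")
    return pd.Series(values, name=f"h_norm_order{order}")


@dataclass
class OrderComparison:
    """Participant-level comparison of first- vs second-order entropy."""

    h1: pd.Series
    h2: pd.Series
    median_diff: float
    ci_low: float
    ci_high: float
    wilcoxon_v: float
    p_value: float
    n_boot: int
    seed: int | None


def signed_rank_v(d: np.ndarray) -> float:
    """Sum of positive signed ranks (zeros dropped, mid-ranks for ties)."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    if len(d) == 0:
        return 0.0
    ranks = stats.rankdata(np.abs(d))
    return float(ranks[d > 0].sum())


def compare_orders(
    h1: pd.Series,
    h2: pd.Series,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> OrderComparison:
    """Paired comparison of per-participant entropies H1 vs H2.

    Computes d_i = H1_i - H2_i on the participants present in both
    series, a two-sided Wilcoxon signed-rank test on d (zeros dropped;
    V = sum of positive ranks), and a percentile 95% bootstrap interval
    of the median difference obtained by resampling participants with
    replacement.  The point estimate is the median of the observed d.
    """
    h1, h2 = h1.align(h2, join="inner")
    d = (h1 - h2).to_numpy(dtype=float)
    n = len(d)
    if n < 5:
        raise ValueError(f"need >= 5 paired participants, got {n}")
    v = signed_rank_v(d)
    nz = d[d != 0]
    if len(nz) == 0:
        p_value = 1.0
    else:
        p_value = float(stats.wilcoxon(nz, alternative="two-sided").pvalue)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_medians = np.median(d[idx], axis=1)
    ci_low, ci_high = np.percentile(boot_medians, [2.5, 97.5])
    return OrderComparison(
        h1=h1,
        h2=h2,
        median_diff=float(np.median(d)),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        wilcoxon_v=v,
        p_value=p_value,
        n_boot=n_boot,
        seed=seed,
    )
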