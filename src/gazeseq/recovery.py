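"""Parameter-recovery simulations: sample from a fixture chain, refit.

These helpers close the loop between the simulator and the estimator:
generate AOI sequences under a bundled fixture transition matrix, then
re-estimate the transition model and compare entries against the
generating values.  Under maximum-likelihood estimation the recovered
entries converge to the generating ones at binomial rate
sqrt(p(1-p)/n_context), so the simulation sizes below are chosen to put
several standard errors inside the published-entry tolerances.
"""

from __future__ import annotations

import numpy as np

from .ingest import clean_fixations, target_sequences
from .markov import TransitionModel, estimate_transitions
from .simulate import SynthConfig, build_fixture_matrix, generate_fixations, sample_markov_sequence

__all__ = ["recover_via_pipeline", "recover_from_sequences"]


def recover_via_pipeline(
    order: int,
    min_transitions: int,
    seed: int,
    n_participants: int = 27,
    n_items: int = 24,
    fixations_mean: float = 10.0,
) -> TransitionModel:
    """Recover a fixture matrix through the full fixation pipeline.

    Generates a synthetic cohort large enough to contain at least
    ``min_transitions`` target-face transitions (scaling the number of
    presentations per item), runs it through cleaning, AOI assignment
    and sequence building, and fits an order-``order`` model.
    """
    per_seq = max(fixations_mean - order, 1.0)
    per_rep = n_participants * n_items * per_seq
    reps = int(np.ceil(1.1 * min_transitions / per_rep))
    cfg = SynthConfig(
        n_participants=n_participants,
        n_items=n_items,
        trials_per_item=reps,
        order=order,
        fixations_mean=fixations_mean,
        fixations_min=order + 1,
        seed=seed,
    )
    df = generate_fixations(cfg)
    seqs = target_sequences(clean_fixations(df), cfg.layout)
    model = estimate_transitions(seqs, order)
    if model.n_transitions < min_transitions:
        raise RuntimeError(
            f"pipeline produced {model.n_transitions} < {min_transitions} transitions"
        )
    return model


def recover_from_sequences(
    order: int,
    min_transitions: int,
    seed: int,
    n_sequences: int = 50,
) -> TransitionModel:
    """Recover a fixture matrix from directly sampled label sequences.

    Skips the spatial layer: samples ``n_sequences`` long label
    sequences straight from the order-``order`` fixture chain and refits.
    """
    matrix = build_fixture_matrix(order)
    rng = np.random.default_rng(seed)
    length = int(np.ceil(min_transitions / n_sequences)) + order
    seqs = [sample_markov_sequence(matrix, length, rng) for _ in range(n_sequences)]
    return estimate_transitions(seqs, order)
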