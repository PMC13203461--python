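import numpy as np
import pandas as pd
import pytest

import gazeseq as gz


@pytest.fixture(scope="session")
def layout():
    return gz.default_face_layout("shared")


@pytest.fixture(scope="session")
def small_cohort():
    """Small pre-context cohort: 6 participants x 6 items, seeded."""
    cfg = gz.SynthConfig(n_participants=6, n_items=6, seed=11)
    return cfg, gz.generate_fixations(cfg)


@pytest.fixture(scope="session")
def small_clean(small_cohort):
    cfg, df = small_cohort
    return cfg, gz.clean_fixations(df)


def make_records(rows):
    """Build a typed fixation table from (pid, item, trial, event, t, dur, x, y, valid) tuples."""
    cols = ["participant", "item", "trial", "event_type", "t_onset_ms",
            "duration_ms", "x_px", "y_px", "valid"]
    return pd.DataFrame(rows, columns=cols)
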