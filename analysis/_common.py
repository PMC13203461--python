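"""Shared study configuration for the analysis drivers.

The emulated study: 27 participants, 13 run with the post-context
procedure (face -> context -> response; the anchor for a face is the
previous trial's response screen) and 14 with the pre-context procedure
(context -> face -> response), 24 face items each, first-order fixture
scanpaths.  Every driver regenerates the cohorts deterministically if
the cached tables are absent, so each can be run on its own from the
repository root.
"""

from pathlib import Path

import gazeseq as gz

ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"

STUDY_SEED = 20_26

CONDITIONS = ("post_context", "pre_context")


def study_configs() -> dict[str, gz.SynthConfig]:
    return {
        "post_context": gz.SynthConfig(
            n_participants=13, procedure="post_context",
            participant_start=1, seed=STUDY_SEED,
        ),
        "pre_context": gz.SynthConfig(
            n_participants=14, procedure="pre_context",
            participant_start=14, seed=STUDY_SEED + 1,
        ),
    }


def load_cohorts() -> dict[str, "object"]:
    """Cleaned fixation tables per condition, generated (and cached) on demand."""
    DATA_DIR.mkdir(parents=True, exist_ok=True)
    out = {}
    for cond, cfg in study_configs().items():
        path = DATA_DIR / f"fixations_{cond}.tsv"
        if not path.exists():
            gz.write_fixations(gz.generate_fixations(cfg), path)
        out[cond] = gz.clean_fixations(gz.read_fixations(path))
    return out


def shared_layout() -> gz.AOILayout:
    return gz.default_face_layout("shared")
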