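"""Generate the synthetic study cohorts and persist them with their configs.

Writes one fixation TSV per procedural condition to scratch/data/, plus
the generator configs and the AOI layout, and prints basic counts.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import gazeseq as gz
from _common import DATA_DIR, shared_layout, study_configs


def main() -> None:
    DATA_DIR.mkdir(parents=True, exist_ok=True)
    gz.save_layouts([shared_layout()], DATA_DIR / "layout.yaml")
    for cond, cfg in study_configs().items():
        df = gz.generate_fixations(cfg)
        gz.write_fixations(df, DATA_DIR / f"fixations_{cond}.tsv")
        gz.simulate.save_config(cfg, DATA_DIR / f"config_{cond}.yaml")
        tgt = df[df.event_type == "target"]
        print(
            f"{cond}: {cfg.n_participants} participants, "
            f"{tgt.groupby(['participant', 'trial']).ngroups} face presentations, "
            f"{len(df)} fixations ({len(tgt)} on faces), "
            f"median fixation {df.duration_ms.median():.0f} ms"
        )
    print(f"written to {DATA_DIR}")


if __name__ == "__main__":
    main()
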