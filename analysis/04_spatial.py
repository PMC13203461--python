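"""Spatial repositioning and gaze stability analysis.

For each procedural condition: anchor-based Euclidean distances from
the preceding event's last fixation to the first fixation on the face,
compared across landing zones with Kruskal-Wallis (epsilon^2) and
pairwise Holm-corrected rank-sum tests; plus the participant x zone
gaze stability tables used by the mixed models.

Writes anchor-transition and stability tables and a JSON of test
results to results/.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd

import gazeseq as gz
from _common import RESULTS, load_cohorts, shared_layout


def main() -> None:
    layout = shared_layout()
    cohorts = load_cohorts()
    RESULTS.mkdir(exist_ok=True)

    anchor_tables, stab_tables, trial_tables, tests = [], [], [], {}
    for cond, clean in cohorts.items():
        table, skipped = gz.anchor_transitions(clean, layout, cond)
        anchor_tables.append(table)
        groups = {
            z: table.loc[table.landing_zone == z, "distance_px"].to_numpy()
            for z in gz.STATES
        }
        kw = gz.kruskal_wallis(groups)
        pairwise = gz.pairwise_wilcoxon_holm(groups)
        tests[cond] = {
            "n_transitions": len(table),
            "skipped": skipped,
            "kruskal_wallis": {
                "chi2": kw.statistic, "p": kw.p_raw, "epsilon2": kw.effect_size,
                "n": kw.n,
            },
            "pairwise": [
                {"pair": list(r.groups), "z": r.statistic, "p_raw": r.p_raw,
                 "p_holm": r.p_adjusted, "r": r.effect_size}
                for r in pairwise
            ],
        }
        print(
            f"{cond}: {len(table)} anchor transitions "
            f"(skipped {sum(skipped.values())}); KW chi2 = {kw.statistic:.2f}, "
            f"p = {kw.p_raw:.3g}, eps^2 = {kw.effect_size:.3f}"
        )
        for r in pairwise:
            print(
                f"    {r.groups[0]} vs {r.groups[1]}: p_holm = {r.p_adjusted:.3g}, "
                f"r = {r.effect_size:.2f}"
            )
        stab_tables.append(
            gz.stability_table(clean, layout, level="participant_aoi",
                               condition=cond)
        )
        trial_tables.append(
            gz.stability_table(clean, layout, level="participant_aoi_event",
                               condition=cond)
        )

    pd.concat(anchor_tables).to_csv(RESULTS / "anchor_transitions.tsv",
                                    sep="\t", index=False)
    stab = pd.concat(stab_tables)
    stab.to_csv(RESULTS / "stability_participant_aoi.tsv", sep="\t", index=False)
    pd.concat(trial_tables).to_csv(RESULTS / "stability_trial_level.tsv",
                                   sep="\t", index=False)
    med = stab.groupby("zone")["stability"].median()
    print("median stability (ms/px): "
          + ", ".join(f"{z}={med[z]:.2f}" for z in gz.STATES if z in med))
    with open(RESULTS / "spatial_tests.json", "w") as fh:
        json.dump(tests, fh, indent=2)
    print(f"tables -> {RESULTS}")


if __name__ == "__main__":
    main()
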