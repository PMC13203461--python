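"""Path-based visualization of gaze on a single item.

Renders the temporally ordered fixation scatter and density heatmap for
the first item of the pre-context cohort into results/figures/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import gazeseq as gz
from _common import RESULTS, load_cohorts, shared_layout


def main() -> None:
    layout = shared_layout()
    clean = load_cohorts()["pre_context"]
    fig_dir = RESULTS / "figures"
    fig_dir.mkdir(parents=True, exist_ok=True)
    out = gz.render_paths(clean, layout, "I01", fig_dir / "item01_paths.png")
    total = out.density.sum()
    cz = layout["CFZ"]
    centers = 0.5 * (out.y_edges[:-1] + out.y_edges[1:])
    central = out.density[(centers >= cz.y_min) & (centers < cz.y_max), :].sum()
    print(f"figure -> {out.path}")
    print(f"share of item I01 fixation density in the central band: "
          f"{central / total:.2f}")


if __name__ == "__main__":
    main()
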