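"""Synthetic fixation-sequence generator for facial-expression-viewing data.

Emulates a face-viewing eye-tracking study: each trial presents either
a contextual image then a target face (pre-context procedure) or the
target face first (post-context procedure), always followed by a
response screen.  Fixations on the target face follow a first- or
second-order Markov chain over the three facial zones (UFZ/CFZ/LFZ);
fixation coordinates are placed inside the corresponding zone band with
truncated Gaussian jitter, and durations are log-normal.

The bundled *fixture* transition matrices encode the published
aggregate transition structure of face viewing (central-zone dominance:
strong CFZ self-transitions and frequent UFZ/LFZ -> CFZ shifts); entries
not fixed by that structure are filled by a documented rule and tagged
``"filled"`` so downstream recovery checks can restrict themselves to
the ``"printed"`` entries.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
import yaml

from .layout import LABELS, AOILayout, default_face_layout

__all__ = [
    "STATES",
    "FixtureMatrix",
    "SynthConfig",
    "build_fixture_matrix",
    "stationary_distribution",
    "sample_markov_sequence",
    "generate_fixations",
    "write_fixations",
    "save_config",
    "load_config",
    "synthetic_stability_table",
]

#: Markov states = the three facial zones, top of the face first.
STATES = LABELS
_IDX = {s: i for i, s in enumerate(STATES)}

#: TSV columns of a written fixation table.
TABLE_COLUMNS = [
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


class ConfigurationError(ValueError):
    """Inconsistent simulator configuration (e.g. matrix/layout mismatch)."""


@dataclass(frozen=True)
class FixtureMatrix:
    """Row-stochastic transition tensor over the three facial zones.

    ``probabilities`` has shape ``(3,) * order + (3,)``: the leading
    axes index the conditioning context (oldest state first), the last
    axis the destination.  ``provenance`` has the same shape with
    entries ``"printed"`` (fixed by the published aggregate structure)
    or ``"filled"`` (completed by the fill rule).
    """

    order: int
    states: tuple[str, ...]
    probabilities: np.ndarray
    provenance: np.ndarray

    def __post_init__(self) -> None:
        p = self.probabilities
        if p.shape != (3,) * self.order + (3,):
            raise ValueError(f"bad tensor shape {p.shape} for order {self.order}")
        rows = p.reshape(-1, 3)
        if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition rows must sum to 1")
        if np.any(p < 0):
            raise ValueError("negative transition probability")

    def row(self, context: tuple[str, ...]) -> np.ndarray:
        """Conditional distribution over destinations for a context."""
        idx = tuple(_IDX[s] for s in context)
        return self.probabilities[idx]

    def prob(self, context: tuple[str, ...] | str, dest: str) -> float:
        """P(next = dest | context); context may be a single label for order 1."""
        if isinstance(context, str):
            context = (context,)
        return float(self.row(tuple(context))[_IDX[dest]])

    def tag(self, context: tuple[str, ...] | str, dest: str) -> str:
        """Provenance of one entry: ``"printed"`` or ``"filled"``."""
        if isinstance(context, str):
            context = (context,)
        idx = tuple(_IDX[s] for s in context) + (_IDX[dest],)
        return str(self.provenance[idx])


# Published aggregate entries (probability of the destination zone given
# the context).  Everything else is completed by the fill rule below.
_PRINTED_ORDER1 = {
    ("UFZ", "CFZ"): 0.694,
    ("LFZ", "CFZ"): 0.692,
    ("CFZ", "CFZ"): 0.920,
}
_PRINTED_ORDER2 = {
    ("UFZ", "CFZ", "CFZ"): 0.902,
    ("CFZ", "CFZ", "CFZ"): 0.926,
    ("LFZ", "CFZ", "CFZ"): 0.830,
    ("LFZ", "LFZ", "LFZ"): 0.535,
}
#: Cross-band hop probability used when filling first-order rows
#: ("infrequent direct transitions between the upper and lower zones").
_CROSS_HOP = 0.030


def _order1_matrix() -> tuple[np.ndarray, np.ndarray]:
    p = np.zeros((3, 3))
    prov = np.full((3, 3), "filled", dtype=object)
    for (src, dst), val in _PRINTED_ORDER1.items():
        p[_IDX[src], _IDX[dst]] = val
        prov[_IDX[src], _IDX[dst]] = "printed"
    # UFZ / LFZ rows: rare direct hop to the opposite band, remainder to self.
    for src, opposite in (("UFZ", "LFZ"), ("LFZ", "UFZ")):
        i = _IDX[src]
        p[i, _IDX[opposite]] = _CROSS_HOP
        p[i, i] = 1.0 - p[i].sum()
    # CFZ row: residual mass split symmetrically between the outer bands.
    c = _IDX["CFZ"]
    resid = 1.0 - p[c, c]
    p[c, _IDX["UFZ"]] = resid / 2
    p[c, _IDX["LFZ"]] = resid / 2
    return p, prov


def _order2_matrix() -> tuple[np.ndarray, np.ndarray]:
    base, _ = _order1_matrix()
    p = np.zeros((3, 3, 3))
    prov = np.full((3, 3, 3), "filled", dtype=object)
    printed_rows: dict[tuple[int, int], tuple[int, float]] = {}
    for (s0, s1, dst), val in _PRINTED_ORDER2.items():
        printed_rows[(_IDX[s0], _IDX[s1])] = (_IDX[dst], val)
    for i, j in product(range(3), range(3)):
        row = base[j].copy()  # first-order row of the most recent state
        if (i, j) in printed_rows:
            k, val = printed_rows[(i, j)]
            # renormalize the remaining first-order mass around the
            # printed entry
            others = np.delete(np.arange(3), k)
            rest = row[others]
            row[k] = val
            row[others] = (1.0 - val) * rest / rest.sum()
            prov[i, j, k] = "printed"
        p[i, j] = row
    return p, prov


def build_fixture_matrix(order: int) -> FixtureMatrix:
    """Bundled transition matrix of the given order (1 or 2).

    Order 1 fixes P(UFZ->CFZ)=0.694, P(LFZ->CFZ)=0.692, P(CFZ->CFZ)=0.920;
    order 2 fixes (U,C)->C=0.902, (C,C)->C=0.926, (L,C)->C=0.830 and
    (L,L)->L=0.535.  Remaining mass is completed by the fill rule (see
    the methods note) and tagged ``"filled"``.
    """
    if order == 1:
        p, prov = _order1_matrix()
    elif order == 2:
        p, prov = _order2_matrix()
    else:
        raise ValueError(f"order must be 1 or 2, got {order}")
    return FixtureMatrix(order=order, states=STATES, probabilities=p, provenance=prov)


def stationary_distribution(p: np.ndarray) -> np.ndarray:
    """Stationary distribution of a first-order row-stochastic matrix."""
    vals, vecs = np.linalg.eig(p.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def _initial_distribution(matrix: FixtureMatrix) -> np.ndarray:
    """First-state distribution: stationary law of the first-order chain.

    For an order-2 matrix the marginal chain is not exactly first-order
    Markov; the stationary law of the bundled first-order matrix is used
    as a consistent starting law (sequences begin near steady state).
    """
    if matrix.order == 1:
        return stationary_distribution(matrix.probabilities)
    return stationary_distribution(_order1_matrix()[0])


def sample_markov_sequence(
    matrix: FixtureMatrix, length: int, rng: np.random.Generator
) -> list[str]:
    """Sample one AOI label sequence from the chain.

    The first state is drawn from the stationary distribution of the
    first-order fixture; for order 2 the second state is then drawn from
    the first-order fixture row of the first state, after which the
    order-2 conditionals take over.
    """
    if length < matrix.order + 1:
        raise ValueError(
            f"length must be >= order + 1 = {matrix.order + 1}, got {length}"
        )
    cum1 = np.cumsum(_order1_matrix()[0], axis=1)
    u = rng.random(length)
    seq = np.empty(length, dtype=np.int64)
    seq[0] = np.searchsorted(np.cumsum(_initial_distribution(matrix)), u[0])
    if matrix.order == 1:
        cum = np.cumsum(matrix.probabilities, axis=1)
        for t in range(1, length):
            seq[t] = np.searchsorted(cum[seq[t - 1]], u[t])
    else:
        seq[1] = np.searchsorted(cum1[seq[0]], u[1])
        cum = np.cumsum(matrix.probabilities, axis=2)
        for t in range(2, length):
            seq[t] = np.searchsorted(cum[seq[t - 2], seq[t - 1]], u[t])
    return [STATES[i] for i in seq]


@dataclass
class SynthConfig:
    """Generative parameters for one simulated participant group.

    Defaults reflect the emulated study: 27 participants viewing 24 face
    items once each, ~10 fixations per 3000 ms face presentation,
    log-normal fixation durations (median 250 ms, sigma 0.4 on the log
    scale), a 1920x1080 screen with a centered 600x800 px face box.
    ``procedure`` controls event order within a trial:
    ``pre_context`` = context (500 ms), face (3000 ms), response screen;
    ``post_context`` = face, context, response screen (the anchor event
    for the face is then the *previous* trial's response screen).
    """

    n_participants: int = 27
    n_items: int = 24
    trials_per_item: int = 1
    procedure: str = "pre_context"
    fixations_mean: float = 10.0
    fixations_min: int = 2
    order: int = 1
    duration_median_ms: float = 250.0
    duration_sigma: float = 0.4
    spatial_jitter_sd: float = 45.0
    screen: tuple[int, int] = (1920, 1080)
    seed: int = 0
    participant_start: int = 1
    matrix: FixtureMatrix | None = None
    layout: AOILayout | None = None
    #: saccade gap inserted between consecutive fixation onsets, ms
    saccade_gap_ms: float = 30.0

    def __post_init__(self) -> None:
        if self.procedure not in ("pre_context", "post_context"):
            raise ConfigurationError(f"unknown procedure {self.procedure!r}")
        if min(self.n_participants, self.n_items, self.trials_per_item) < 1:
            raise ConfigurationError("counts must be >= 1")
        if self.fixations_min < self.order + 1:
            raise ConfigurationError(
                "fixations_min must allow at least one transition "
                f"(>= order + 1 = {self.order + 1})"
            )
        if self.duration_median_ms <= 0:
            raise ConfigurationError("duration median must be positive")
        if self.matrix is None:
            self.matrix = build_fixture_matrix(self.order)
        if self.matrix.order != self.order:
            raise ConfigurationError(
                f"matrix order {self.matrix.order} != configured order {self.order}"
            )
        if self.layout is None:
            self.layout = default_face_layout("shared", screen=self.screen)
        if tuple(self.matrix.states) != tuple(LABELS):
            raise ConfigurationError("matrix states do not match the AOI layout zones")


def _truncated_normal(
    rng: np.random.Generator,
    center: np.ndarray,
    sd: float,
    lo: np.ndarray,
    hi: np.ndarray,
    max_tries: int = 50,
) -> np.ndarray:
    """Gaussian jitter rejection-sampled into [lo, hi); clips as last resort."""
    x = rng.normal(center, sd)
    bad = (x < lo) | (x >= hi)
    tries = 0
    while bad.any() and tries < max_tries:
        x[bad] = rng.normal(center[bad] if np.ndim(center) else center, sd, bad.sum())
        bad = (x < lo) | (x >= hi)
        tries += 1
    return np.clip(x, lo, np.nextafter(hi, -np.inf) - 1e-6)


def generate_fixations(config: SynthConfig) -> pd.DataFrame:
    """Simulate a full fixation table for one participant group.

    Returns a long table with one row per fixation and the columns of
    :data:`TABLE_COLUMNS` plus ``aoi_true`` — the generating zone label
    for target-face fixations (``NA`` for context/response fixations),
    kept in memory for round-trip checks but not written to disk.

    Deterministic: the same config (including seed) yields an identical
    table.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    layout = cfg.layout
    assert layout is not None and cfg.matrix is not None
    zone_lo_x = {z.label: z.x_min for z in layout.zones}
    zone_hi_x = {z.label: z.x_max for z in layout.zones}
    zone_lo_y = {z.label: z.y_min for z in layout.zones}
    zone_hi_y = {z.label: z.y_max for z in layout.zones}
    zone_cx = {z.label: z.center[0] for z in layout.zones}
    zone_cy = {z.label: z.center[1] for z in layout.zones}
    sw, sh = cfg.screen
    # Response screen shows four emoji options in a centered horizontal band.
    emoji_x = np.linspace(sw * 0.25, sw * 0.75, 4)
    emoji_y = sh * 0.5
    mu_log = np.log(cfg.duration_median_ms)

    cols: dict[str, list] = {c: [] for c in TABLE_COLUMNS + ["aoi_true"]}

    def emit(pid, item, trial, event, t0, durations, xs, ys, labels):
        n = len(durations)
        cols["participant"].extend([pid] * n)
        cols["item"].extend([item] * n)
        cols["trial"].extend([trial] * n)
        cols["event_type"].extend([event] * n)
        onsets = t0 + np.concatenate(
            ([0.0], np.cumsum(durations[:-1] + cfg.saccade_gap_ms))
        )
        cols["t_onset_ms"].extend(np.round(onsets, 3))
        cols["duration_ms"].extend(np.round(durations, 3))
        cols["x_px"].extend(np.round(xs, 3))
        cols["y_px"].extend(np.round(ys, 3))
        cols["valid"].extend([True] * n)
        cols["aoi_true"].extend(labels if labels is not None else [pd.NA] * n)
        return onsets[-1] + durations[-1] + cfg.saccade_gap_ms

    if cfg.procedure == "pre_context":
        event_order = ("context", "target", "response")
    else:
        event_order = ("target", "context", "response")

    items = [f"I{k:02d}" for k in range(1, cfg.n_items + 1)]
    for p in range(cfg.n_participants):
        pid = f"P{cfg.participant_start + p:02d}"
        clock = 0.0
        trial = 0
        for _rep in range(cfg.trials_per_item):
            for item in items:
                trial += 1
                for event in event_order:
                    if event == "target":
                        n_fix = max(cfg.fixations_min, int(rng.poisson(cfg.fixations_mean)))
                        labels = sample_markov_sequence(cfg.matrix, n_fix, rng)
                        cx = np.array([zone_cx[s] for s in labels])
                        cy = np.array([zone_cy[s] for s in labels])
                        lox = np.array([zone_lo_x[s] for s in labels])
                        hix = np.array([zone_hi_x[s] for s in labels])
                        loy = np.array([zone_lo_y[s] for s in labels])
                        hiy = np.array([zone_hi_y[s] for s in labels])
                        xs = _truncated_normal(rng, cx, cfg.spatial_jitter_sd * 2, lox, hix)
                        ys = _truncated_normal(rng, cy, cfg.spatial_jitter_sd, loy, hiy)
                    elif event == "context":
                        # 1-2 fixations around screen center
                        n_fix = int(rng.integers(1, 3))
                        xs = rng.normal(sw / 2, 60.0, n_fix)
                        ys = rng.normal(sh / 2, 60.0, n_fix)
                        labels = None
                    else:  # response screen: gaze near one of the four emojis
                        n_fix = int(rng.integers(1, 4))
                        choice = rng.integers(0, 4, n_fix)
                        xs = rng.normal(emoji_x[choice], 50.0)
                        ys = rng.normal(emoji_y, 50.0, n_fix)
                        labels = None
                    durs = rng.lognormal(mu_log, cfg.duration_sigma, n_fix)
                    clock = emit(pid, item, trial, event, clock, durs, xs, ys, labels)
                clock += 500.0  # inter-trial interval

    df = pd.DataFrame(cols)
    df["trial"] = df["trial"].astype(np.int64)
    df["valid"] = df["valid"].astype(bool)
    return df


def write_fixations(df: pd.DataFrame, path) -> None:
    """Write a fixation table as UTF-8 TSV with the canonical columns."""
    df.loc[:, TABLE_COLUMNS].to_csv(path, sep="\t", index=False, encoding="utf-8")


def save_config(config: SynthConfig, path) -> None:
    """Persist a config (scalar fields and the layout) as YAML."""
    scalars = {
        f.name: getattr(config, f.name)
        for f in dataclasses.fields(config)
        if f.name not in ("matrix", "layout")
    }
    scalars["screen"] = list(config.screen)
    assert config.layout is not None
    doc = {
        "config": scalars,
        "layout": {
            "item_id": config.layout.item_id,
            "zones": {
                z.label: [z.x_min, z.y_min, z.x_max, z.y_max]
                for z in config.layout.zones
            },
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_config(path) -> SynthConfig:
    from .layout import Zone

    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    scalars = doc["config"]
    scalars["screen"] = tuple(scalars["screen"])
    lay = doc["layout"]
    layout = AOILayout(
        item_id=lay["item_id"],
        zones=tuple(Zone(lab, *map(float, lay["zones"][lab])) for lab in LABELS),
    )
    return SynthConfig(layout=layout, **scalars)


def synthetic_stability_table(
    n_participants: int,
    zone_means: dict[str, float],
    participant_sd: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Participant x zone stability table with known ground truth.

    ``stability = zone mean + participant intercept + residual``, the
    intercept ~ N(0, participant_sd^2) shared across a participant's
    zones and the residual ~ N(0, noise_sd^2) per cell.  Used for
    mixed-model parameter-recovery checks.
    """
    rows = []
    for p in range(n_participants):
        intercept = rng.normal(0.0, participant_sd)
        pid = f"P{p + 1:02d}"
        for zone in LABELS:
            rows.append(
                {
                    "participant": pid,
                    "zone": zone,
                    "stability": zone_means[zone] + intercept + rng.normal(0.0, noise_sd),
                }
            )
    return pd.DataFrame(rows)
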