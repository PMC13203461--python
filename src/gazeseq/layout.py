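"""Screen-space area-of-interest (AOI) layouts for face stimuli.

A face stimulus is segmented into three stacked horizontal bands —
Upper (UFZ), Central (CFZ) and Lower (LFZ) Facial Zone — defined as
axis-aligned rectangles in screen pixels.  The screen coordinate
convention is origin top-left with y increasing downward, so the UFZ
has the *smallest* y values.

Membership uses half-open rectangles ``[x_min, x_max) x [y_min, y_max)``:
a point on the shared boundary of two vertically adjacent zones belongs
to the lower zone, whose top edge is closed.  Points in no zone map to
``OUTSIDE``.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

__all__ = [
    "LABELS",
    "OUTSIDE",
    "Zone",
    "AOILayout",
    "assign_aoi",
    "default_face_layout",
    "save_layouts",
    "load_layouts",
]

#: Zone labels, top of the face first.
LABELS = ("UFZ", "CFZ", "LFZ")

#: Label for points falling in no zone.
OUTSIDE = "OUTSIDE"


@dataclass(frozen=True)
class Zone:
    """Axis-aligned rectangle in screen pixels (origin top-left)."""

    label: str
    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(f"degenerate zone rectangle: {self}")

    def contains(self, x: float, y: float) -> bool:
        """Half-open point-in-rectangle test."""
        return (self.x_min <= x < self.x_max) and (self.y_min <= y < self.y_max)

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))


@dataclass(frozen=True)
class AOILayout:
    """Three-band facial AOI layout for one stimulus item.

    Zones are stored top-to-bottom (UFZ, CFZ, LFZ) and must be pairwise
    non-overlapping and vertically ordered: the bottom edge of each band
    may at most touch the top edge of the band below it.
    """

    item_id: str
    zones: tuple[Zone, Zone, Zone]

    def __post_init__(self) -> None:
        labels = tuple(z.label for z in self.zones)
        if labels != LABELS:
            raise ValueError(f"zone labels must be {LABELS} top-to-bottom, got {labels}")
        for upper, lower in zip(self.zones, self.zones[1:]):
            if upper.y_max > lower.y_min:
                raise ValueError(
                    f"zones {upper.label} and {lower.label} overlap vertically"
                )

    def __getitem__(self, label: str) -> Zone:
        for z in self.zones:
            if z.label == label:
                return z
        raise KeyError(label)

    def assign(self, x: float, y: float) -> str:
        for z in self.zones:
            if z.contains(x, y):
                return z.label
        return OUTSIDE

    @property
    def face_box(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max) of the union bounding box."""
        return (
            min(z.x_min for z in self.zones),
            min(z.y_min for z in self.zones),
            max(z.x_max for z in self.zones),
            max(z.y_max for z in self.zones),
        )


def assign_aoi(x: float, y: float, layout: AOILayout) -> str:
    """Map a screen coordinate to a zone label or ``OUTSIDE``."""
    return layout.assign(x, y)


def default_face_layout(
    item_id: str,
    screen: tuple[int, int] = (1920, 1080),
    face_size: tuple[int, int] = (600, 800),
    fractions: tuple[float, float, float] = (0.30, 0.40, 0.30),
) -> AOILayout:
    """Centered face box split into three horizontal bands.

    The face box is centered on the screen; ``fractions`` gives the
    height share of the upper, central and lower band (top to bottom),
    mimicking supraorbital-ridge / subnasale boundary lines.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("band fractions must sum to 1")
    sw, sh = screen
    fw, fh = face_size
    x0 = (sw - fw) / 2
    y0 = (sh - fh) / 2
    bounds = [y0]
    for f in fractions:
        bounds.append(bounds[-1] + f * fh)
    zones = tuple(
        Zone(lab, x0, bounds[i], x0 + fw, bounds[i + 1]) for i, lab in enumerate(LABELS)
    )
    return AOILayout(item_id=item_id, zones=zones)


def save_layouts(layouts: list[AOILayout], path) -> None:
    """Write layouts as a YAML file, one block per item."""
    doc = {
        lay.item_id: {
            z.label: [z.x_min, z.y_min, z.x_max, z.y_max] for z in lay.zones
        }
        for lay in layouts
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_layouts(path) -> dict[str, AOILayout]:
    """Read layouts written by :func:`save_layouts`, keyed by item id."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    layouts = {}
    for item_id, zones in doc.items():
        layouts[item_id] = AOILayout(
            item_id=str(item_id),
            zones=tuple(Zone(lab, *map(float, zones[lab])) for lab in LABELS),
        )
    return layouts
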