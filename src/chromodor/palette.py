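"""The 36-color choice palette.

The palette used in the study is the Berkeley Color Project set of 32
chromatic colors (8 hues x 4 cuts: saturated, light, muted, dark) extended
with white, light gray, dark gray and black, for 36 choices in total.
Every statistic in this package depends only on the integer ``color_id``
(1..36); the RGB coordinates exist purely so figures can render the
choices, and approximate sRGB renderings are sufficient for that purpose.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .errors import ValidationError

N_COLORS = 36

# (name, (r, g, b)) in canonical order: saturated, light, muted, dark cuts
# over the hues red, orange, yellow, chartreuse, green, cyan, blue, purple,
# then the four achromatic additions.  sRGB values are approximate
# renderings of the published set; they never enter any statistic.
_DEFAULT_COLORS: tuple[tuple[str, tuple[int, int, int]], ...] = (
    ("saturated_red", (227, 0, 34)),
    ("saturated_orange", (255, 117, 0)),
    ("saturated_yellow", (255, 222, 0)),
    ("saturated_chartreuse", (160, 222, 0)),
    ("saturated_green", (0, 163, 71)),
    ("saturated_cyan", (0, 172, 223)),
    ("saturated_blue", (0, 64, 255)),
    ("saturated_purple", (150, 0, 229)),
    ("light_red", (255, 154, 160)),
    ("light_orange", (255, 189, 126)),
    ("light_yellow", (255, 248, 153)),
    ("light_chartreuse", (206, 242, 139)),
    ("light_green", (146, 224, 163)),
    ("light_cyan", (157, 227, 243)),
    ("light_blue", (152, 183, 255)),
    ("light_purple", (220, 159, 245)),
    ("muted_red", (184, 84, 95)),
    ("muted_orange", (212, 148, 81)),
    ("muted_yellow", (227, 213, 106)),
    ("muted_chartreuse", (152, 184, 84)),
    ("muted_green", (79, 163, 113)),
    ("muted_cyan", (84, 163, 196)),
    ("muted_blue", (86, 119, 201)),
    ("muted_purple", (161, 93, 193)),
    ("dark_red", (139, 0, 23)),
    ("dark_orange", (160, 80, 0)),
    ("dark_yellow", (162, 143, 0)),
    ("dark_chartreuse", (92, 125, 0)),
    ("dark_green", (0, 98, 45)),
    ("dark_cyan", (0, 104, 135)),
    ("dark_blue", (0, 40, 128)),
    ("dark_purple", (84, 0, 134)),
    ("white", (255, 255, 255)),
    ("light_gray", (200, 200, 200)),
    ("dark_gray", (90, 90, 90)),
    ("black", (0, 0, 0)),
)


@dataclass(frozen=True)
class PaletteColor:
    color_id: int
    name: str
    rgb: tuple[int, int, int]


@dataclass(frozen=True)
class ColorPalette:
    """Ordered set of exactly 36 selectable colors with ids 1..36."""

    entries: tuple[PaletteColor, ...]

    def __post_init__(self) -> None:
        if len(self.entries) != N_COLORS:
            raise ValidationError(
                f"expected {N_COLORS} colors, got {len(self.entries)}"
            )
        ids = [e.color_id for e in self.entries]
        if ids != list(range(1, N_COLORS + 1)):
            raise ValidationError(
                "color_ids must be exactly 1..36 in order; "
                f"got {ids[:5]}... (duplicates or gaps)"
            )
        for e in self.entries:
            if not all(0 <= c <= 255 for c in e.rgb):
                raise ValidationError(
                    f"color_id {e.color_id} ({e.name}): RGB out of range {e.rgb}"
                )

    @property
    def color_ids(self) -> tuple[int, ...]:
        return tuple(e.color_id for e in self.entries)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.entries)

    def rgb_float(self) -> list[tuple[float, float, float]]:
        """RGB triples scaled to [0, 1] for matplotlib (rendering only)."""
        return [tuple(c / 255.0 for c in e.rgb) for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "color_id": [e.color_id for e in self.entries],
                "name": [e.name for e in self.entries],
                "r": [e.rgb[0] for e in self.entries],
                "g": [e.rgb[1] for e in self.entries],
                "b": [e.rgb[2] for e in self.entries],
            }
        )


def default_palette() -> ColorPalette:
    """The built-in 36-color palette (32 chromatic + 4 achromatic)."""
    return ColorPalette(
        entries=tuple(
            PaletteColor(i + 1, name, rgb)
            for i, (name, rgb) in enumerate(_DEFAULT_COLORS)
        )
    )


def load_palette(source: Optional[str] = None) -> ColorPalette:
    """Load a palette from a delimited table, or return the default.

    Parameters
    ----------
    source
        Path to a comma-delimited table with columns
        ``color_id,name,r,g,b``.  When omitted, the built-in palette is
        returned.

    Raises
    ------
    ValidationError
        If the table is malformed, has a wrong color count, duplicate or
        out-of-range ids; the message names the offending row.
    """
    if source is None:
        return default_palette()
    try:
        df = pd.read_csv(source)
    except Exception as exc:  # malformed file
        raise ValidationError(f"cannot parse palette table {source!r}: {exc}")
    required = {"color_id", "name", "r", "g", "b"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"palette table missing columns: {sorted(missing)}")
    if len(df) != N_COLORS:
        raise ValidationError(f"expected {N_COLORS} colors, got {len(df)} rows")
    seen: set[int] = set()
    entries = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            cid = int(row.color_id)
        except (TypeError, ValueError):
            raise ValidationError(f"row {row_no}: non-integer color_id {row.color_id!r}")
        if cid in seen:
            raise ValidationError(f"row {row_no}: duplicate color_id {cid}")
        if not 1 <= cid <= N_COLORS:
            raise ValidationError(f"row {row_no}: color_id {cid} outside 1..{N_COLORS}")
        seen.add(cid)
        entries.append((cid, str(row.name).strip(), (int(row.r), int(row.g), int(row.b))))
    entries.sort(key=lambda t: t[0])
    return ColorPalette(
        entries=tuple(PaletteColor(cid, name, rgb) for cid, name, rgb in entries)
    )
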