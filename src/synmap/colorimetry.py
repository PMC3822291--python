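"""CIE colorimetry for the named-colour palette.

All colour arithmetic in the pipeline happens in CIE L*a*b* (D65 white
point, 2-degree standard observer), obtained from nominal sRGB decoding of
the palette's 8-bit triplets. Euclidean distance in L*a*b* serves as the
colour-difference measure; the cylindrical L*C*h transform supplies
separate luminance (|dL*|), saturation (|dC*|) and hue (dh) components.

The packaged palette is the set of 138 distinct sRGB values among the
classic browser-supported named colours (the gray/grey, aqua/cyan and
fuchsia/magenta spelling duplicates collapse the 147-name list to 138
unique colours).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from skimage.color import rgb2lab

__all__ = [
    "NamedColor",
    "LabColor",
    "LChColor",
    "Palette",
    "srgb_to_lab",
    "lab_to_lch",
    "color_distance",
    "circular_hue_difference",
    "component_distances",
    "palette_chance_statistics",
    "load_default_palette",
]

#: chroma below which a colour is treated as achromatic (hue undefined -> 0)
ACHROMATIC_CHROMA = 1e-9

HueMode = Literal["circular", "linear"]


@dataclass(frozen=True)
class NamedColor:
    """A palette entry: a colour name and its 8-bit sRGB triplet."""

    name: str
    rgb: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.rgb) != 3 or any(
            not (0 <= c <= 255) or int(c) != c for c in self.rgb
        ):
            raise ValueError(f"rgb channels must be integers in [0, 255]: {self.rgb}")


@dataclass(frozen=True)
class LabColor:
    """CIE L*a*b* coordinates (D65, 2-degree observer)."""

    L: float
    a: float
    b: float

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.a, self.b], dtype=float)


@dataclass(frozen=True)
class LChColor:
    """Cylindrical CIE L*C*h coordinates: chroma C* >= 0, hue h in [0, 360)."""

    L: float
    C: float
    h: float


def srgb_to_lab(rgb: Iterable[int]) -> LabColor:
    """Convert an 8-bit sRGB triplet to CIE L*a*b*.

    Uses standard sRGB decoding (gamma companding), the D65 white point and
    the 2-degree standard observer. Deterministic; a nominal conversion
    standing in for display-side colorimeter measurement.
    """
    rgb = tuple(rgb)
    if len(rgb) != 3 or any(not (0 <= c <= 255) for c in rgb):
        raise ValueError(f"rgb channels must lie in [0, 255]: {rgb}")
    arr = np.asarray(rgb, dtype=float).reshape(1, 1, 3) / 255.0
    L, a, b = rgb2lab(arr).reshape(3)
    return LabColor(float(L), float(a), float(b))


def srgb_array_to_lab(rgb: np.ndarray) -> np.ndarray:
    """Vectorised sRGB->Lab for an (n, 3) integer array in [0, 255]."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 2 or rgb.shape[1] != 3:
        raise ValueError("expected an (n, 3) array of sRGB triplets")
    if rgb.min() < 0 or rgb.max() > 255:
        raise ValueError("rgb channels must lie in [0, 255]")
    return rgb2lab((rgb / 255.0).reshape(-1, 1, 3)).reshape(-1, 3)


def lab_to_lch(lab: LabColor) -> LChColor:
    """Cylindrical transform: C* = sqrt(a*^2 + b*^2), h = atan2(b*, a*).

    The hue angle is mapped to [0, 360) degrees; achromatic colours
    (C* < 1e-9) take h = 0 by convention.
    """
    C = math.hypot(lab.a, lab.b)
    if C < ACHROMATIC_CHROMA:
        return LChColor(lab.L, C, 0.0)
    h = math.degrees(math.atan2(lab.b, lab.a)) % 360.0
    if h == 360.0:  # fp: tiny negative angles wrap to exactly 360
        h = 0.0
    return LChColor(lab.L, C, h)


def lab_array_to_lch(lab: np.ndarray) -> np.ndarray:
    """Vectorised Lab->LCh for an (n, 3) array; returns (n, 3) [L, C, h]."""
    lab = np.asarray(lab, dtype=float)
    C = np.hypot(lab[:, 1], lab[:, 2])
    h = np.degrees(np.arctan2(lab[:, 2], lab[:, 1])) % 360.0
    h = np.where((C < ACHROMATIC_CHROMA) | (h == 360.0), 0.0, h)
    return np.column_stack([lab[:, 0], C, h])


def color_distance(x: LabColor, y: LabColor) -> float:
    """Euclidean distance in CIE L*a*b* (Delta E 1976)."""
    return float(np.linalg.norm(x.as_array() - y.as_array()))


def circular_hue_difference(h1: float, h2: float) -> float:
    """Shortest angular separation of two hue angles, in [0, 180] degrees."""
    d = abs(h1 - h2) % 360.0
    return min(d, 360.0 - d)


def component_distances(
    x: LChColor, y: LChColor, hue_mode: HueMode = "circular"
) -> tuple[float, float, float]:
    """Per-dimension colour differences in L*C*h.

    Returns ``(luminance_distance, saturation_distance, hue_distance)``
    where luminance and saturation distances are absolute differences of
    L* and C*. The hue distance is the circular (wraparound) angular
    separation by default; ``hue_mode="linear"`` uses the plain absolute
    difference of the stored angles instead.
    """
    dL = abs(x.L - y.L)
    dC = abs(x.C - y.C)
    if hue_mode == "circular":
        dh = circular_hue_difference(x.h, y.h)
    elif hue_mode == "linear":
        dh = abs(x.h - y.h)
    else:
        raise ValueError(f"unknown hue_mode: {hue_mode!r}")
    return dL, dC, dh


class Palette:
    """An ordered named-colour palette with precomputed Lab/LCh coordinates.

    Parameters
    ----------
    colors
        Sequence of :class:`NamedColor`. Names and sRGB triplets must both
        be unique.
    """

    def __init__(self, colors: Iterable[NamedColor]):
        self.colors: list[NamedColor] = list(colors)
        names = [c.name for c in self.colors]
        if len(set(names)) != len(names):
            raise ValueError("duplicate colour names in palette")
        triplets = [c.rgb for c in self.colors]
        if len(set(triplets)) != len(triplets):
            raise ValueError("duplicate sRGB triplets in palette")
        self.names: list[str] = names
        self._index = {n: i for i, n in enumerate(names)}
        self.rgb = np.array(triplets, dtype=int)
        self.lab = srgb_array_to_lab(self.rgb)
        self.lch = lab_array_to_lch(self.lab)

    def __len__(self) -> int:
        return len(self.colors)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def index_of(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"colour {name!r} is not in the palette") from None

    def lab_of(self, name: str) -> LabColor:
        L, a, b = self.lab[self.index_of(name)]
        return LabColor(float(L), float(a), float(b))

    def lch_of(self, name: str) -> LChColor:
        L, C, h = self.lch[self.index_of(name)]
        return LChColor(float(L), float(C), float(h))

    @property
    def n_achromatic(self) -> int:
        """Number of palette entries with chroma below the achromatic cut."""
        return int((self.lch[:, 1] < ACHROMATIC_CHROMA).sum())

    @classmethod
    def from_csv(cls, path: str | Path) -> "Palette":
        df = pd.read_csv(path)
        required = {"name", "r", "g", "b"}
        if not required.issubset(df.columns):
            raise ValueError(f"palette CSV needs columns {sorted(required)}")
        return cls(
            NamedColor(str(row["name"]), (int(row["r"]), int(row["g"]), int(row["b"])))
            for _, row in df.iterrows()
        )

    def to_json(self, path: str | Path) -> None:
        """Audit dump: every entry with its sRGB, Lab and LCh coordinates."""
        records = []
        for i, c in enumerate(self.colors):
            records.append(
                {
                    "name": c.name,
                    "rgb": list(c.rgb),
                    "lab": [round(v, 6) for v in self.lab[i]],
                    "lch": [round(v, 6) for v in self.lch[i]],
                }
            )
        Path(path).write_text(json.dumps(records, indent=1))


def palette_chance_statistics(palette: Palette) -> tuple[float, float]:
    """Chance-level colour distance: mean and SD over all unordered pairs.

    Exhaustive enumeration of the n(n-1)/2 distinct colour pairs (no
    sampling), so the result is deterministic and equals the expectation
    of uniform random pair draws. The SD uses the n-1 denominator; for a
    two-colour palette (a single pair) it is reported as 0.0 with a
    warning.
    """
    if len(palette) < 2:
        raise ValueError("chance statistics need at least 2 palette entries")
    d = pdist(palette.lab)
    mean = float(d.mean())
    if d.size < 2:
        warnings.warn(
            "only one colour pair: chance SD is undefined, reporting 0.0",
            stacklevel=2,
        )
        return mean, 0.0
    return mean, float(d.std(ddof=1))


def load_default_palette() -> Palette:
    """Load the packaged 138-colour named palette."""
    with resources.as_file(
        resources.files("synmap.data").joinpath("palette.csv")
    ) as path:
        return Palette.from_csv(path)
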