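"""Per-image fruit contour data model and cleaning rules.

A fruit image is reduced by the upstream segmentation to a polar contour:
360 radii, one per integer degree, measured from the contour centroid.
Degree 0 points right (+x) and degree 90 points up (+y); on side views the
stalk end of the fruit points up, so the "upper quarter" of the contour is
the degree range [45, 135).

Sections of the contour are named anatomically: top (A) and bottom (B)
halves, left (L) and right (R) halves, their intersections (quarters A.L,
A.R, B.L, B.R) and unions (AB, LR = the full contour).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_DEGREES = 360

TOP_VIEW = "Top"
SIDE_VIEWS = ("Side1", "Side2", "Side3", "Side4")
ALL_VIEWS = (TOP_VIEW,) + SIDE_VIEWS

#: Degree range [45, 135) holding the stalk on side views.
UPPER_QUARTER = np.arange(45, 135)

#: Minimum Cartesian extent (pixels) below which a side view is discarded.
MIN_DIMENSION_PX = 150.0

#: Multiplier of the interquartile range in the stalk-removal fence.
STALK_IQR_K = 1.5

_DEG = np.arange(N_DEGREES)
_COS = np.cos(np.deg2rad(_DEG))
_SIN = np.sin(np.deg2rad(_DEG))

# Quarters partition the circle; halves and the full contour are unions.
SECTION_DEGREES: dict[str, np.ndarray] = {
    "A.R": np.arange(0, 90),
    "A.L": np.arange(90, 180),
    "B.L": np.arange(180, 270),
    "B.R": np.arange(270, 360),
}
SECTION_DEGREES["A"] = np.concatenate([SECTION_DEGREES["A.R"], SECTION_DEGREES["A.L"]])
SECTION_DEGREES["B"] = np.concatenate([SECTION_DEGREES["B.L"], SECTION_DEGREES["B.R"]])
SECTION_DEGREES["L"] = np.concatenate([SECTION_DEGREES["A.L"], SECTION_DEGREES["B.L"]])
SECTION_DEGREES["R"] = np.concatenate([SECTION_DEGREES["B.R"], SECTION_DEGREES["A.R"]])
SECTION_DEGREES["AB"] = np.arange(N_DEGREES)
SECTION_DEGREES["LR"] = np.arange(N_DEGREES)

SECTION_CODES = ("A", "B", "L", "R", "A.L", "A.R", "B.L", "B.R", "AB", "LR")

#: Section codes valid in feature names (adds the cross-section pseudo codes).
FEATURE_SECTION_CODES = SECTION_CODES + ("A.LR", "B.LR", "AB.LR")


def section_degrees(code: str) -> np.ndarray:
    """Degrees belonging to a contour section.

    Quarters are half-open degree intervals (A.R = [0, 90), A.L = [90, 180),
    B.L = [180, 270), B.R = [270, 360)); halves and full sections are unions
    of quarters, so no degree is double-counted.
    """
    try:
        return SECTION_DEGREES[code]
    except KeyError:
        raise ValueError(f"unknown section code: {code!r}") from None


@dataclass(frozen=True)
class FruitImageKey:
    """Identity of one fruit image: tree (genotype x replicate x year),
    fruit number on the tree (1..5) and camera view."""

    genotype_id: str
    year: int
    tree_id: str
    fruit_index: int
    camera: str

    def __post_init__(self) -> None:
        if self.camera not in ALL_VIEWS:
            raise ValueError(f"camera must be one of {ALL_VIEWS}, got {self.camera!r}")

    @property
    def tree(self) -> tuple[str, int, str]:
        return (self.genotype_id, self.year, self.tree_id)

    @property
    def fruit(self) -> tuple[str, int, str, int]:
        return (self.genotype_id, self.year, self.tree_id, self.fruit_index)


@dataclass
class PolarContour:
    """One fruit image as 360 degree-indexed radii.

    ``valid`` marks degrees retained after cleaning (stalk removal); masked
    degrees keep their stored radius but are excluded from every statistic.
    """

    radii: np.ndarray
    view: str = TOP_VIEW
    center: tuple[float, float] = (0.0, 0.0)
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        if self.radii.shape != (N_DEGREES,):
            raise ValueError(f"radii must have shape (360,), got {self.radii.shape}")
        if self.valid is None:
            self.valid = np.ones(N_DEGREES, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != (N_DEGREES,):
                raise ValueError("valid mask must have shape (360,)")
        if np.any(self.radii[self.valid] <= 0):
            raise ValueError("retained radii must be strictly positive")

    @property
    def x(self) -> np.ndarray:
        """Signed x coordinate per degree, relative to the polar origin."""
        return self.radii * _COS

    @property
    def y(self) -> np.ndarray:
        """Signed y coordinate per degree, relative to the polar origin."""
        return self.radii * _SIN

    def section_mask(self, code: str) -> np.ndarray:
        mask = np.zeros(N_DEGREES, dtype=bool)
        mask[section_degrees(code)] = True
        return mask & self.valid


def remove_stalk(contour: PolarContour) -> PolarContour:
    """Mask stalk points on a side-view contour.

    Within the upper quarter (degrees [45, 135)), radii strictly above the
    upper Tukey fence Q3 + 1.5*IQR of that quarter's stored radii are
    masked.  Strict inequality leaves constant contours untouched, degrees
    outside the upper quarter are never masked, and because the fence is
    computed from the stored radii the operation is exactly idempotent.
    """
    valid = contour.valid.copy()
    r = contour.radii[UPPER_QUARTER]
    q1, q3 = np.quantile(r, [0.25, 0.75])
    fence = q3 + STALK_IQR_K * (q3 - q1)
    valid[UPPER_QUARTER[r > fence]] = False
    return PolarContour(contour.radii, contour.view, contour.center, valid)


def min_dimension_ok(contour: PolarContour, threshold: float = MIN_DIMENSION_PX) -> bool:
    """True iff the maximum Cartesian extent (x-range or y-range over
    retained degrees) reaches ``threshold`` pixels."""
    x = contour.x[contour.valid]
    y = contour.y[contour.valid]
    if x.size == 0:
        return False
    extent = max(x.max() - x.min(), y.max() - y.min())
    return bool(extent >= threshold)


CONTOUR_COLUMNS = [
    "genotype_id", "year", "tree_id", "fruit_index", "camera",
    "degree", "radius_px", "x_px", "y_px",
]


def read_contours(path) -> dict[FruitImageKey, PolarContour]:
    """Read a long-format contour table (one row per degree).

    Images missing any of the 360 degrees are dropped with a logged
    warning; a non-numeric radius anywhere is a hard error.
    """
    df = pd.read_csv(path)
    missing = [c for c in CONTOUR_COLUMNS[:7] if c not in df.columns]
    if missing:
        raise ValueError(f"contour table missing columns: {missing}")
    radius = pd.to_numeric(df["radius_px"], errors="raise")
    df = df.assign(radius_px=radius)
    return contours_from_frame(df)


def contours_from_frame(df: pd.DataFrame) -> dict[FruitImageKey, PolarContour]:
    """Build contours from an in-memory long-format table."""
    out: dict[FruitImageKey, PolarContour] = {}
    dropped = 0
    keys = ["genotype_id", "year", "tree_id", "fruit_index", "camera"]
    for key_vals, grp in df.groupby(keys, sort=True):
        degrees = grp["degree"].to_numpy(int)
        if len(np.unique(degrees)) != N_DEGREES or degrees.min() != 0 or degrees.max() != N_DEGREES - 1:
            dropped += 1
            logger.warning("dropping incomplete image %s (%d degree rows)", key_vals, len(degrees))
            continue
        radii = np.empty(N_DEGREES)
        radii[degrees] = grp["radius_px"].to_numpy(float)
        key = FruitImageKey(str(key_vals[0]), int(key_vals[1]), str(key_vals[2]),
                            int(key_vals[3]), str(key_vals[4]))
        out[key] = PolarContour(radii, view=key.camera)
    if dropped:
        logger.warning("dropped %d incomplete images", dropped)
    return out


def write_contours(contours: dict[FruitImageKey, PolarContour] | Iterable, path) -> None:
    """Write contours back to the long-format table (round-trips radii)."""
    items = contours.items() if isinstance(contours, dict) else contours
    frames = []
    for key, c in items:
        frames.append(pd.DataFrame({
            "genotype_id": key.genotype_id,
            "year": key.year,
            "tree_id": key.tree_id,
            "fruit_index": key.fruit_index,
            "camera": key.camera,
            "degree": _DEG,
            "radius_px": c.radii,
            "x_px": c.x,
            "y_px": c.y,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")
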