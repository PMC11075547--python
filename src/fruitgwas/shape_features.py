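"""Shape and size features from polar fruit contours.

Feature names are six underscore-joined tokens::

    <tree level>_<fruit level>_<data type>_<calculation>_<section>_<feature type>

e.g. ``Av_SSD_Pol_Abs_B.L_SD``: per side-view image, the SD of radii in
quarter B.L; then the SD over the four side views of a fruit (SSD); then
the mean over the up-to-five fruits of a tree (Av).

The grammar is block-structured: which calculations, sections and feature
types combine is fixed by an explicit inclusion table (``SHAPE_BLOCKS``),
which is the single source of truth for the feature-column set used by all
downstream stages.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .contours import PolarContour, section_degrees

logger = logging.getLogger(__name__)

TREE_LEVELS = ("Av", "SD")
FRUIT_LEVELS = ("Top", "SAv", "SSD")
COLOR_FRUIT_LEVELS = ("SAv", "SSD")

#: Statistics defined on a vector of radii / coordinates.
POLAR_STATS = ("Av", "SD", "Max", "Min", "Q25", "Q50", "Q75", "Area", "RatM")
CARTESIAN_STATS = ("Av", "SD", "Max", "Min", "Q25", "Q50", "Q75", "RatM", "MaxR")


@dataclass(frozen=True)
class Fragment:
    """The image-level part of a feature name (data type, calculation,
    section, feature type)."""

    data_type: str
    calculation: str
    section: str
    feature_type: str

    def __str__(self) -> str:
        return f"{self.data_type}_{self.calculation}_{self.section}_{self.feature_type}"


@dataclass(frozen=True)
class FeatureName:
    tree_level: str
    fruit_level: str
    fragment: Fragment

    def __str__(self) -> str:
        return f"{self.tree_level}_{self.fruit_level}_{self.fragment}"


# Inclusion table for the shape/size grammar.  Each block:
# (data_type, calculations, sections, feature_types).
SHAPE_BLOCKS: tuple[tuple[str, tuple[str, ...], tuple[str, ...], tuple[str, ...]], ...] = (
    # Per-quarter absolute statistics.
    ("Pol", ("Abs",), ("A.L", "A.R", "B.L", "B.R"), POLAR_STATS),
    # Statistic per quarter, then mean/SD over the two quarters of a half.
    ("Pol", ("Av", "SD"), ("A.LR", "B.LR"), POLAR_STATS),
    # Full-contour absolute statistics.
    ("Pol", ("Abs",), ("AB",), POLAR_STATS),
    # Sum / ratio of top vs bottom quarters, then mean/SD over left/right.
    ("Pol", ("Sum.Av", "Sum.SD", "Rat.Av", "Rat.SD"), ("AB.LR",), POLAR_STATS),
    # Whole-contour mirror symmetry (left/right and top/bottom).
    ("Pol", ("Av", "SD"), ("LR", "AB"), ("Sym.abs",)),
    # Half-section symmetry between the two constituent quarters; the
    # relative variant is normalised by the section area.
    ("Pol", ("Av", "SD"), ("A", "B", "L", "R"), ("Sym.abs", "Sym.rel")),
    # Signed Cartesian coordinates on the top/bottom halves.
    ("X", ("Abs",), ("A", "B"), CARTESIAN_STATS),
    ("Y", ("Abs",), ("A", "B"), CARTESIAN_STATS),
    # Cross-axis combinations: statistic over y combined with statistic
    # over x (Sum = y-stat + x-stat, Rat = y-stat / x-stat).
    ("XY", ("Sum", "Rat"), ("A", "B"), CARTESIAN_STATS),
)

# Color grammar (full-fruit histogram features; see color_features).
COLOR_BLOCKS: tuple[tuple[str, tuple[str, ...], tuple[str, ...], tuple[str, ...]], ...] = (
    ("Hue", ("Abs",), ("AB",), ("Red", "Yellow", "Brown")),
    ("Sat", ("Abs",), ("AB",), ("Low", "Medium", "High")),
)


def enumerate_shape_fragments() -> list[Fragment]:
    """All image-level shape fragments, in stable block order."""
    out = []
    for data_type, calcs, sections, ftypes in SHAPE_BLOCKS:
        for calc, section, ftype in itertools.product(calcs, sections, ftypes):
            out.append(Fragment(data_type, calc, section, ftype))
    return out


def enumerate_color_fragments() -> list[Fragment]:
    out = []
    for data_type, calcs, sections, ftypes in COLOR_BLOCKS:
        for calc, section, ftype in itertools.product(calcs, sections, ftypes):
            out.append(Fragment(data_type, calc, section, ftype))
    return out


def enumerate_feature_grammar() -> list[FeatureName]:
    """The full ordered feature list: shape fragments crossed with tree
    level {Av, SD} x fruit level {Top, SAv, SSD}, then color fragments
    crossed with {Av, SD} x {SAv, SSD} (color has no top-view-only level:
    all five images enter SAv/SSD)."""
    names = [
        FeatureName(tree, fruit, frag)
        for frag in enumerate_shape_fragments()
        for tree in TREE_LEVELS
        for fruit in FRUIT_LEVELS
    ]
    names += [
        FeatureName(tree, fruit, frag)
        for frag in enumerate_color_fragments()
        for tree in TREE_LEVELS
        for fruit in COLOR_FRUIT_LEVELS
    ]
    return names


def feature_name_strings() -> list[str]:
    return [str(n) for n in enumerate_feature_grammar()]


# ---------------------------------------------------------------------------
# Sectional statistics

def sectional_statistic(values: np.ndarray, feature_type: str) -> float:
    """One summary statistic of a value vector.

    Quantiles use linear interpolation at rank h = (n-1)p; SD is the
    sample (n-1) standard deviation.  RatM = Max/Min (NaN when Min <= 0),
    MaxR = Max/Av (NaN when Av = 0).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty value vector")
    if feature_type == "Av":
        return float(v.mean())
    if feature_type == "SD":
        return float(v.std(ddof=1)) if v.size > 1 else np.nan
    if feature_type == "Min":
        return float(v.min())
    if feature_type == "Max":
        return float(v.max())
    if feature_type in ("Q25", "Q50", "Q75"):
        p = {"Q25": 0.25, "Q50": 0.50, "Q75": 0.75}[feature_type]
        return float(np.quantile(v, p))
    if feature_type == "RatM":
        mn = v.min()
        return float(v.max() / mn) if mn > 0 else np.nan
    if feature_type == "MaxR":
        av = v.mean()
        return float(v.max() / av) if av != 0 else np.nan
    raise ValueError(f"unknown feature type: {feature_type!r}")


def section_area(contour: PolarContour, section: str) -> float:
    """Sector-sum area of a section: sum over retained degrees of
    (1/2) r^2 (pi/180), the area of a 1-degree circular sector."""
    mask = contour.section_mask(section)
    if not mask.any():
        raise ValueError(f"section {section} has no retained degrees")
    r = contour.radii[mask]
    return float(0.5 * np.sum(r * r) * np.pi / 180.0)


# Mirror maps: vertical axis (left<->right) pairs degree d with 180-d;
# horizontal axis (top<->bottom) pairs d with 360-d.
_VERTICAL_MIRROR = (180 - np.arange(360)) % 360
_HORIZONTAL_MIRROR = (360 - np.arange(360)) % 360

#: Which mirror a symmetry section uses.
_SYMMETRY_MIRROR = {
    "LR": _VERTICAL_MIRROR,   # left half vs right half
    "A": _VERTICAL_MIRROR,    # quarter A.L vs A.R
    "B": _VERTICAL_MIRROR,    # quarter B.L vs B.R
    "AB": _HORIZONTAL_MIRROR,  # top half vs bottom half
    "L": _HORIZONTAL_MIRROR,  # quarter A.L vs B.L
    "R": _HORIZONTAL_MIRROR,  # quarter A.R vs B.R
}


def _matched_pairs(contour: PolarContour, section: str) -> tuple[np.ndarray, np.ndarray]:
    try:
        mirror = _SYMMETRY_MIRROR[section]
    except KeyError:
        raise ValueError(f"no symmetry defined for section {section!r}") from None
    mask = contour.section_mask(section)
    d = np.arange(360)
    p = mirror[d]
    keep = mask[d] & mask[p] & (d < p)
    return d[keep], p[keep]


def symmetry_statistic(contour: PolarContour, section: str, calc: str,
                       kind: str = "Sym.abs") -> float:
    """Mirror-symmetry measure of a section.

    Matched degree pairs are mirror images within the section; the
    statistic is the mean (calc="Av") or sample SD (calc="SD") of the
    absolute radius differences.  ``Sym.rel`` divides by the section area.
    """
    d, p = _matched_pairs(contour, section)
    if d.size == 0:
        raise ValueError(f"no retained matched pairs in section {section}")
    diff = np.abs(contour.radii[d] - contour.radii[p])
    if calc == "Av":
        value = float(diff.mean())
    elif calc == "SD":
        value = float(diff.std(ddof=1)) if diff.size > 1 else np.nan
    else:
        raise ValueError(f"symmetry calc must be Av or SD, got {calc!r}")
    if kind == "Sym.rel":
        return value / section_area(contour, section)
    if kind != "Sym.abs":
        raise ValueError(f"unknown symmetry kind {kind!r}")
    return value


# ---------------------------------------------------------------------------
# Per-image evaluation

_HALF_QUARTERS = {"A.LR": ("A.L", "A.R"), "B.LR": ("B.L", "B.R")}


def _stat(contour: PolarContour, data_type: str, section: str, ftype: str,
          cache: dict) -> float:
    """Statistic of one data type over one concrete section (with cache)."""
    key = (data_type, section, ftype)
    if key in cache:
        return cache[key]
    mask = contour.section_mask(section)
    if not mask.any():
        cache[key] = np.nan
        return np.nan
    if data_type == "Pol":
        if ftype == "Area":
            value = section_area(contour, section)
        else:
            value = sectional_statistic(contour.radii[mask], ftype)
    elif data_type == "X":
        value = sectional_statistic(contour.x[mask], ftype)
    elif data_type == "Y":
        value = sectional_statistic(contour.y[mask], ftype)
    else:
        raise ValueError(f"unknown data type {data_type!r}")
    cache[key] = value
    return value


def _pair_combine(values: Sequence[float], calc: str) -> float:
    v = np.asarray(values, dtype=float)
    if np.any(np.isnan(v)):
        return np.nan
    if calc == "Av":
        return float(v.mean())
    if calc == "SD":
        return float(v.std(ddof=1))
    raise ValueError(calc)


def image_features(contour: PolarContour) -> dict[Fragment, float]:
    """Evaluate every shape fragment of the grammar on one cleaned contour.

    Fragments whose precondition fails (e.g. RatM over signed coordinates
    crossing zero) yield NaN, which downstream stages treat as missing.
    """
    cache: dict = {}
    out: dict[Fragment, float] = {}
    for frag in _SHAPE_FRAGMENTS:
        dt, calc, sect, ftype = frag.data_type, frag.calculation, frag.section, frag.feature_type
        if ftype in ("Sym.abs", "Sym.rel"):
            try:
                out[frag] = symmetry_statistic(contour, sect, calc, ftype)
            except ValueError:
                out[frag] = np.nan
        elif sect in _HALF_QUARTERS:  # A.LR / B.LR: combine the two quarters
            q1, q2 = _HALF_QUARTERS[sect]
            out[frag] = _pair_combine(
                [_stat(contour, dt, q1, ftype, cache), _stat(contour, dt, q2, ftype, cache)],
                calc)
        elif sect == "AB.LR":  # top-vs-bottom sum/ratio, per left and right side
            op, combine = calc.split(".")
            sides = []
            for top_q, bot_q in (("A.L", "B.L"), ("A.R", "B.R")):
                top = _stat(contour, dt, top_q, ftype, cache)
                bot = _stat(contour, dt, bot_q, ftype, cache)
                if np.isnan(top) or np.isnan(bot):
                    sides.append(np.nan)
                elif op == "Sum":
                    sides.append(top + bot)
                else:  # Rat: top over bottom
                    sides.append(top / bot if bot != 0 else np.nan)
            out[frag] = _pair_combine(sides, combine)
        elif dt == "XY":
            sx = _stat(contour, "X", sect, ftype, cache)
            sy = _stat(contour, "Y", sect, ftype, cache)
            if np.isnan(sx) or np.isnan(sy):
                out[frag] = np.nan
            elif calc == "Sum":
                out[frag] = sx + sy
            else:  # Rat: y (length axis) over x (diameter axis)
                out[frag] = sy / sx if sx != 0 else np.nan
        else:  # plain Abs
            out[frag] = _stat(contour, dt, sect, ftype, cache)
    return out


_SHAPE_FRAGMENTS = enumerate_shape_fragments()


# ---------------------------------------------------------------------------
# Aggregation across views and fruits

def aggregate_views(values_by_camera: Mapping[str, float],
                    fruit_levels: Sequence[str] = FRUIT_LEVELS) -> dict[str, float]:
    """Collapse one fragment's camera-corrected values for one fruit.

    Top = the top-view value; SAv = mean over side views; SSD = sample SD
    over side views (NaN when fewer than two).  For color fragments pass
    ``fruit_levels=("SAv", "SSD")`` with all five cameras as "side" values.
    """
    from .contours import SIDE_VIEWS, TOP_VIEW

    out: dict[str, float] = {}
    if "Top" in fruit_levels:
        side = np.array([values_by_camera[c] for c in SIDE_VIEWS if c in values_by_camera],
                        dtype=float)
        out["Top"] = float(values_by_camera.get(TOP_VIEW, np.nan))
    else:
        side = np.array(list(values_by_camera.values()), dtype=float)
    side = side[~np.isnan(side)]
    if "SAv" in fruit_levels:
        out["SAv"] = float(side.mean()) if side.size >= 1 else np.nan
    if "SSD" in fruit_levels:
        out["SSD"] = float(side.std(ddof=1)) if side.size >= 2 else np.nan
    return out


def aggregate_tree(fruit_values: Sequence[float]) -> dict[str, float]:
    """Mean (Av) and sample SD (SD) of a per-fruit value across the up-to-
    five fruits of a tree; SD is NaN for a single fruit."""
    v = np.asarray(fruit_values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return {"Av": np.nan, "SD": np.nan}
    return {"Av": float(v.mean()),
            "SD": float(v.std(ddof=1)) if v.size > 1 else np.nan}


# ---------------------------------------------------------------------------
# Table-level driver

def image_fragment_table(contours: Mapping) -> pd.DataFrame:
    """Per-image fragment values for a set of contours.

    Index: (genotype_id, year, tree_id, fruit_index, camera); one column
    per shape fragment string.
    """
    rows = []
    index = []
    for key, contour in contours.items():
        feats = image_features(contour)
        rows.append([feats[f] for f in _SHAPE_FRAGMENTS])
        index.append((key.genotype_id, key.year, key.tree_id, key.fruit_index, key.camera))
    idx = pd.MultiIndex.from_tuples(
        index, names=["genotype_id", "year", "tree_id", "fruit_index", "camera"])
    return pd.DataFrame(rows, index=idx, columns=[str(f) for f in _SHAPE_FRAGMENTS])


def aggregate_fragment_table(image_table: pd.DataFrame,
                             fruit_levels: Sequence[str] = FRUIT_LEVELS) -> pd.DataFrame:
    """Aggregate a per-image fragment table to tree-level feature records.

    Applies the fruit-level collapse (Top/SAv/SSD across cameras) followed
    by the tree-level collapse (Av/SD across fruits).  Returns a frame
    indexed by (genotype_id, year, tree_id) with full feature-name columns.
    """
    from .contours import SIDE_VIEWS, TOP_VIEW

    cam = image_table.index.get_level_values("camera")
    per_fruit = {}
    if "Top" in fruit_levels:
        top = image_table[cam == TOP_VIEW].droplevel("camera")
        side = image_table[cam != TOP_VIEW]
        per_fruit["Top"] = top
    else:
        side = image_table
    grp = side.groupby(["genotype_id", "year", "tree_id", "fruit_index"], sort=True)
    if "SAv" in fruit_levels:
        per_fruit["SAv"] = grp.mean()
    if "SSD" in fruit_levels:
        sd = grp.std(ddof=1)
        counts = grp.count()
        per_fruit["SSD"] = sd.where(counts >= 2)
    pieces = []
    for flevel, table in per_fruit.items():
        tg = table.groupby(["genotype_id", "year", "tree_id"], sort=True)
        for tlevel, agg in (("Av", tg.mean()), ("SD", tg.std(ddof=1))):
            agg = agg.rename(columns={c: f"{tlevel}_{flevel}_{c}" for c in agg.columns})
            pieces.append(agg)
    out = pd.concat(pieces, axis=1)
    order = [f"{t}_{f}_{frag}" for frag in image_table.columns
             for t in TREE_LEVELS for f in fruit_levels]
    return out[order]
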