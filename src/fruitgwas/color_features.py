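"""Skin-color phenotyping from hue and saturation histograms.

Each fruit image carries two 36-bin histograms over the [0, 1] color space
(bin centers at (b + 0.5)/36).  Feature extraction is a two-step
procedure: (1) genotype-average histograms are hierarchically clustered
into three groups per channel and the peak (maximum-mass bin center) of
each cluster-average histogram is located; (2) for every image, the mean
mass of the bins within +-0.05 of each frozen peak becomes a feature.

Hue is circular: red sits at the 0/1 seam, so hue windows and peak
distances wrap.  Hue peaks are labelled Red, Brown, Yellow by ascending
circular distance from 0; saturation peaks Low, Medium, High by ascending
position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

logger = logging.getLogger(__name__)

N_BINS = 36
BIN_CENTERS = (np.arange(N_BINS) + 0.5) / N_BINS
WINDOW = 0.05
HUE_LABELS = ("Red", "Brown", "Yellow")
SAT_LABELS = ("Low", "Medium", "High")


def normalize(mass: np.ndarray) -> np.ndarray:
    mass = np.asarray(mass, dtype=float)
    total = mass.sum()
    if total <= 0:
        raise ValueError("histogram mass must be positive")
    return mass / total


@dataclass(frozen=True)
class ColorPeakSet:
    """Frozen per-channel peak positions with their labels."""

    channel: str  # "Hue" or "Sat"
    positions: tuple[float, float, float]
    labels: tuple[str, str, str]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.labels, self.positions))


def genotype_average_histogram(histograms: np.ndarray) -> np.ndarray:
    """Bin-wise mean of the (renormalized) histograms of one genotype's
    side-view images, renormalized to unit mass."""
    h = np.atleast_2d(np.asarray(histograms, dtype=float))
    if h.shape[0] == 0:
        raise ValueError("need at least one histogram")
    h = h / h.sum(axis=1, keepdims=True)
    return normalize(h.mean(axis=0))


def cluster_histograms(genotype_histograms: np.ndarray, k: int = 3) -> np.ndarray:
    """Ward-linkage agglomerative clustering of genotype-average
    histograms (Euclidean distance on the 36-vector), cut at ``k``
    clusters.  Returns integer labels (1..k); deterministic given the
    input values (scipy's ordering is input-order independent up to
    distance ties)."""
    h = np.atleast_2d(np.asarray(genotype_histograms, dtype=float))
    if h.shape[0] < k:
        raise ValueError(f"need at least {k} genotypes, got {h.shape[0]}")
    Z = linkage(h, method="ward")
    labels = fcluster(Z, t=k, criterion="maxclust")
    # degenerate (tied-distance) trees can cut into fewer than k clusters;
    # split off singletons from the lowest indices to restore the count
    deficit = k - len(set(labels))
    if deficit > 0:
        logger.warning("degenerate clustering; splitting %d singleton(s)", deficit)
        free = int(labels.max()) + 1
        for i in range(deficit):
            labels[i] = free + i
    return labels


def circular_distance(a: np.ndarray, b: float) -> np.ndarray:
    d = np.abs(np.asarray(a) - b)
    return np.minimum(d, 1.0 - d)


def locate_peaks(cluster_averages: np.ndarray, channel: str) -> ColorPeakSet:
    """Peak position (maximum-mass bin center) of each of the three
    cluster-average histograms, labelled by position.

    Ties for the maximum take the lower bin index (logged).  Hue labels
    order by ascending circular distance from 0 (Red, Brown, Yellow);
    saturation labels by ascending position (Low, Medium, High).
    """
    h = np.atleast_2d(np.asarray(cluster_averages, dtype=float))
    if h.shape[0] != 3:
        raise ValueError("expected exactly 3 cluster-average histograms")
    positions = []
    for row in h:
        idx = int(np.argmax(row))
        if np.sum(row == row[idx]) > 1:
            logger.warning("tie for histogram maximum; taking lower bin index %d", idx)
        positions.append(float(BIN_CENTERS[idx]))
    positions = np.array(positions)
    if channel == "Hue":
        order = np.argsort(circular_distance(positions, 0.0), kind="stable")
        labels = HUE_LABELS
    elif channel == "Sat":
        order = np.argsort(positions, kind="stable")
        labels = SAT_LABELS
    else:
        raise ValueError(f"channel must be Hue or Sat, got {channel!r}")
    return ColorPeakSet(channel, tuple(positions[order]), labels)


def window_bins(peak: float, channel: str, window: float = WINDOW) -> np.ndarray:
    """Indices of bins whose centers lie within [peak - w, peak + w]
    (circular for hue)."""
    if channel == "Hue":
        dist = circular_distance(BIN_CENTERS, peak)
    else:
        dist = np.abs(BIN_CENTERS - peak)
    idx = np.flatnonzero(dist <= window + 1e-12)
    assert idx.size > 0, "a 0.05 window always covers at least one of 36 bins"
    return idx


def extract_color_features(histogram: np.ndarray, peaks: ColorPeakSet,
                           window: float = WINDOW) -> dict[str, float]:
    """Mean in-window bin mass for each labelled peak of one image
    histogram (invariant to the histogram's normalization scale)."""
    mass = normalize(histogram)
    out = {}
    for label, peak in zip(peaks.labels, peaks.positions):
        idx = window_bins(peak, peaks.channel, window)
        out[label] = float(mass[idx].mean())
    return out


# ---------------------------------------------------------------------------
# Table-level driver

COLOR_COLUMNS = ["genotype_id", "year", "tree_id", "fruit_index", "camera",
                 "channel", "bin", "value"]

_CHANNEL_NAMES = {"hue": "Hue", "sat": "Sat"}


def read_color_histograms(path) -> pd.DataFrame:
    """Read the long-format color table into a wide per-image frame.

    Index (genotype_id, year, tree_id, fruit_index, camera, channel);
    columns bin 0..35.
    """
    df = pd.read_csv(path)
    missing = [c for c in COLOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"color table missing columns: {missing}")
    return color_table_from_frame(df)


def color_table_from_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = df.assign(channel=df["channel"].str.lower().map(_CHANNEL_NAMES))
    wide = df.pivot_table(
        index=["genotype_id", "year", "tree_id", "fruit_index", "camera", "channel"],
        columns="bin", values="value", aggfunc="first")
    if wide.shape[1] != N_BINS or wide.isna().any().any():
        raise ValueError("every image needs all 36 bins per channel")
    return wide


def fit_color_peaks(wide: pd.DataFrame) -> dict[str, ColorPeakSet]:
    """Training pass: genotype-average side-view histograms, clustering,
    cluster averages, peak localization -- per channel."""
    from .contours import TOP_VIEW

    peaks = {}
    cams = wide.index.get_level_values("camera")
    side = wide[cams != TOP_VIEW]
    for channel in ("Hue", "Sat"):
        sub = side.xs(channel, level="channel")
        norm = sub.div(sub.sum(axis=1), axis=0)
        geno_avg = norm.groupby("genotype_id", sort=True).mean()
        geno_avg = geno_avg.div(geno_avg.sum(axis=1), axis=0)
        labels = cluster_histograms(geno_avg.to_numpy())
        cluster_avgs = np.vstack([
            normalize(geno_avg.to_numpy()[labels == c].mean(axis=0))
            for c in sorted(set(labels))])
        peaks[channel] = locate_peaks(cluster_avgs, channel)
    return peaks


def image_color_fragment_table(wide: pd.DataFrame,
                               peaks: dict[str, ColorPeakSet],
                               window: float = WINDOW) -> pd.DataFrame:
    """Per-image color fragment values (columns like ``Hue_Abs_AB_Red``)
    for all images, using frozen peaks."""
    pieces = []
    for channel, labels in (("Hue", HUE_LABELS), ("Sat", SAT_LABELS)):
        sub = wide.xs(channel, level="channel")
        mass = sub.div(sub.sum(axis=1), axis=0).to_numpy()
        cols = {}
        pk = peaks[channel].as_dict()
        for label in labels:
            idx = window_bins(pk[label], channel, window)
            cols[f"{channel}_Abs_AB_{label}"] = mass[:, idx].mean(axis=1)
        pieces.append(pd.DataFrame(cols, index=sub.index))
    return pd.concat(pieces, axis=1)
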