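"""Multilocus genotypes from associated SNPs, averaged fruit contours per
multilocus genotype, and co-localization with published loci.

A multilocus genotype is the concatenated allele-dosage string (one digit
in {0,1,2} per SNP, genome order) of a defined SNP group for one
individual.  Groups are either per-trait (all SNPs associated with one
phenotype) or physical-linkage groups: SNPs on one chromosome chained
together whenever consecutive positions lie within 0.1 Mbp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contours import N_DEGREES

logger = logging.getLogger(__name__)

LINKAGE_WINDOW_BP = 100_000


@dataclass(frozen=True)
class SnpGroup:
    group_id: str
    marker_ids: tuple[str, ...]  # genome order
    rule: str = "physical-linkage"  # or "per-trait"


def _sorted_markers(marker_ids, marker_map: pd.DataFrame) -> list[str]:
    sub = marker_map.loc[list(marker_ids)]
    return list(sub.sort_values(["chrom", "pos_bp"]).index)


def group_linked_snps(marker_ids, marker_map: pd.DataFrame,
                      window: int = LINKAGE_WINDOW_BP) -> list[SnpGroup]:
    """Single-linkage chaining of markers within ``window`` bp on the same
    chromosome; only groups of two or more markers are returned.

    ``marker_map`` is indexed by marker id with columns chrom, pos_bp.
    """
    sub = marker_map.loc[list(dict.fromkeys(marker_ids))]
    groups = []
    for chrom, chrom_df in sub.groupby("chrom"):
        chrom_df = chrom_df.sort_values("pos_bp")
        pos = chrom_df["pos_bp"].to_numpy()
        ids = chrom_df.index.to_numpy()
        start = 0
        for i in range(1, len(pos) + 1):
            if i == len(pos) or pos[i] - pos[i - 1] >= window:
                if i - start >= 2:
                    members = tuple(ids[start:i])
                    groups.append(SnpGroup(
                        group_id=f"chr{chrom}_{pos[start]}", marker_ids=members))
                start = i
    return groups


@dataclass
class MultilocusGenotypeTable:
    group: SnpGroup
    assignments: pd.Series          # genotype_id -> dosage string
    census: pd.Series               # dosage string -> count

    @property
    def n_multilocus_genotypes(self) -> int:
        return len(self.census)


def collapse_multilocus(G: pd.DataFrame, group: SnpGroup,
                        marker_map: pd.DataFrame | None = None) -> MultilocusGenotypeTable:
    """Concatenate each genotype's dosages over the group's markers (in
    genome order when a map is given) and census the distinct strings."""
    ids = list(group.marker_ids)
    if marker_map is not None:
        ids = _sorted_markers(ids, marker_map)
    dosage = G[ids].to_numpy()
    if not np.isin(dosage, (0, 1, 2)).all():
        raise ValueError("dosages must be 0/1/2")
    strings = pd.Series(
        ["".join(str(int(d)) for d in row) for row in dosage],
        index=G.index, name="dosage_string")
    census = strings.value_counts().sort_index()
    return MultilocusGenotypeTable(group=group, assignments=strings, census=census)


@dataclass
class AverageContour:
    label: str                      # dosage string
    mode: str                       # "absolute" or "relative"
    mean: np.ndarray                # 360 radii
    sd: np.ndarray                  # per-degree SD
    n_fruits: int


def _relative_profile(radii: np.ndarray) -> np.ndarray | None:
    """Standardize one contour to mean 0 / SD 1 and shift its minimum to
    zero; degenerate (constant) contours are skipped."""
    sd = radii.std(ddof=1)
    if sd == 0:
        return None
    z = (radii - radii.mean()) / sd
    return z - z.min()


def average_contours(table: MultilocusGenotypeTable,
                     contours: dict, mode: str = "absolute") -> list[AverageContour]:
    """Per-degree mean and SD of side-view contours pooled over all fruits
    of all genotypes sharing each multilocus genotype.

    In relative mode each contributing contour is standardized (mean 0,
    SD 1 across its 360 radii) and shifted so its minimum is 0 first, so
    the profile is invariant to per-fruit affine radius transforms.
    """
    if mode not in ("absolute", "relative"):
        raise ValueError(f"mode must be absolute or relative, got {mode!r}")
    from .contours import TOP_VIEW

    by_geno: dict[str, list[np.ndarray]] = {}
    for key, c in contours.items():
        if key.camera == TOP_VIEW:
            continue
        by_geno.setdefault(key.genotype_id, []).append(c.radii)
    out = []
    for label in table.census.index:
        genos = table.assignments[table.assignments == label].index
        profiles = []
        for g in genos:
            for radii in by_geno.get(g, []):
                if mode == "relative":
                    prof = _relative_profile(radii)
                    if prof is None:
                        logger.warning("skipping constant contour of %s in relative mode", g)
                        continue
                    profiles.append(prof)
                else:
                    profiles.append(radii)
        if not profiles:
            logger.warning("multilocus genotype %s has no fruit contours; omitted", label)
            continue
        stack = np.vstack(profiles)
        out.append(AverageContour(
            label=label, mode=mode,
            mean=stack.mean(axis=0),
            sd=stack.std(axis=0, ddof=1) if len(profiles) > 1 else np.zeros(N_DEGREES),
            n_fruits=len(profiles)))
    return out


def chromosome_segment(pos_bp: float, chrom_length_bp: float) -> str:
    """Assign a position to the top / center / bottom third of its
    chromosome; the chromosome length is the last marker's position.
    Boundary points escalate to the later segment."""
    third = chrom_length_bp / 3.0
    if pos_bp < third:
        return "top"
    if pos_bp < 2.0 * third:
        return "center"
    return "bottom"


def chromosome_lengths(marker_map: pd.DataFrame) -> pd.Series:
    return marker_map.groupby("chrom")["pos_bp"].max()


def colocalize(hits: pd.DataFrame, catalog: pd.DataFrame,
               marker_map: pd.DataFrame | None = None,
               window: int = LINKAGE_WINDOW_BP) -> pd.DataFrame:
    """Match study hits against a published-loci catalog.

    ``hits`` needs columns marker, chrom, pos_bp; ``catalog`` columns
    study, trait_group, chrom and either pos_bp or segment.  Positioned
    catalog entries match when on the same chromosome within ``window``
    bp; segment-only entries match on chromosome-segment identity (the
    segment of the hit computed against the chromosome length from
    ``marker_map`` when given, else from the hits themselves).
    """
    lengths = chromosome_lengths(marker_map if marker_map is not None
                                 else hits.set_index("marker"))
    rows = []
    for _, hit in hits.iterrows():
        seg = chromosome_segment(hit["pos_bp"], lengths.loc[hit["chrom"]])
        for _, cat in catalog.iterrows():
            if cat["chrom"] != hit["chrom"]:
                continue
            if "pos_bp" in cat and pd.notna(cat.get("pos_bp")):
                if abs(cat["pos_bp"] - hit["pos_bp"]) < window:
                    rows.append((hit["marker"], hit["chrom"], hit["pos_bp"], seg,
                                 cat.get("study"), cat.get("trait_group"),
                                 "position", cat["pos_bp"]))
            elif pd.notna(cat.get("segment")):
                if cat["segment"] == seg:
                    rows.append((hit["marker"], hit["chrom"], hit["pos_bp"], seg,
                                 cat.get("study"), cat.get("trait_group"),
                                 "segment", np.nan))
    return pd.DataFrame(rows, columns=[
        "marker", "chrom", "pos_bp", "segment", "study", "trait_group",
        "match_type", "catalog_pos_bp"])
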