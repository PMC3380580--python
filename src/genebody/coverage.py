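"""Tag densities, CAGE promoter activity and the intron partition.

Density of an assay over a region set is the number of mapped tags whose
start position falls in the set, divided by the total bp of the set.  CAGE
cluster activity is tags per cluster bp.  Introns are partitioned into
transcription-initiation space (intron intersected with CAGE cluster spans)
and silent space (the remainder).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneRegions
from .intervals import intersect_pairs, merge_pairs, subtract_pairs, total_length

__all__ = [
    "TagSet",
    "read_cage_clusters",
    "cage_activity",
    "tag_density",
    "assign_clusters",
    "intronic_cage_level",
    "partition_introns",
    "IntronPartition",
]


class TagSet:
    """Mapped tag start positions for one assay, sorted per chromosome."""

    def __init__(self, assay: str, positions: Mapping[str, np.ndarray]):
        self.assay = assay
        self._pos = {c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in positions.items()}

    @classmethod
    def from_bed(cls, path, assay: str) -> "TagSet":
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            usecols=[0, 1],
            names=["chrom", "start"],
            dtype={"chrom": str},
        )
        return cls(assay, {c: g["start"].to_numpy() for c, g in df.groupby("chrom")})

    @property
    def n_tags(self) -> int:
        return sum(len(p) for p in self._pos.values())

    def count_in(self, regions_by_chrom: Mapping[str, Sequence[tuple[int, int]]]) -> int:
        """Tags whose start lies in the union of the regions (single assignment)."""
        total = 0
        for chrom, pairs in regions_by_chrom.items():
            pos = self._pos.get(chrom)
            if pos is None or not len(pos):
                continue
            for s, e in merge_pairs(pairs):
                total += int(
                    np.searchsorted(pos, e, side="left")
                    - np.searchsorted(pos, s, side="left")
                )
        return total


def tag_density(
    tags: TagSet, regions: Mapping[str, Sequence[tuple[int, int]]] | Sequence
) -> float:
    """Tags-per-bp over a region set (union length denominator)."""
    if not isinstance(regions, Mapping):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in regions:
            by_chrom.setdefault(iv.chrom, []).append(iv.pair)
        regions = by_chrom
    length = sum(total_length(pairs) for pairs in regions.values())
    if length <= 0:
        raise ValueError("tag_density over an empty region set")
    return tags.count_in(regions) / length


def read_cage_clusters(path) -> pd.DataFrame:
    """Read CAGE clusters from BED (score column = tag count)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        usecols=[0, 1, 2, 3, 4],
        names=["chrom", "start", "end", "name", "tag_count"],
        dtype={"chrom": str},
    )
    if len(df) and (df["tag_count"] < 1).any():
        raise ValueError("CAGE cluster with tag count < 1")
    return df


def cage_activity(clusters: pd.DataFrame) -> pd.Series:
    """Promoter activity: tags in the cluster divided by cluster length."""
    return clusters["tag_count"] / (clusters["end"] - clusters["start"])


def assign_clusters(
    clusters: pd.DataFrame,
    regions_per_locus: Sequence[GeneRegions],
    tss_window: int = 1000,
    rule: str = "midpoint",
) -> pd.DataFrame:
    """Attach each CAGE cluster to a locus and classify it.

    A cluster belongs to the locus whose span contains its midpoint
    (``rule='midpoint'``, default) or that fully contains it
    (``rule='contained'``).  Classes: ``canonical`` when the midpoint lies
    within ``tss_window/2`` of the TSS on either side, ``intronic`` when it
    falls in an intron, else ``exonic``.  Unassigned clusters get class
    ``intergenic`` and no locus.
    """
    import bisect

    if rule not in ("midpoint", "contained"):
        raise ValueError(f"unknown assignment rule {rule!r}")
    by_chrom: dict[str, list[tuple[int, int, GeneRegions]]] = {}
    for regs in regions_per_locus:
        lo = min(regs.tss, regs.tts)
        hi = max(regs.tss, regs.tts) + 1
        by_chrom.setdefault(regs.chrom, []).append((lo, hi, regs))
    max_len: dict[str, int] = {}
    for chrom, spans in by_chrom.items():
        spans.sort(key=lambda t: (t[0], t[1]))
        max_len[chrom] = max(hi - lo for lo, hi, _ in spans)
    locus_col = []
    class_col = []
    offset_col = []
    half = tss_window // 2
    for row in clusters.itertuples(index=False):
        mid = (row.start + row.end) // 2
        assigned = None
        spans = by_chrom.get(row.chrom, [])
        # candidates start at or before mid; opposite-strand loci may overlap,
        # so walk back until no earlier span could still reach mid
        k = bisect.bisect_right(spans, (mid, float("inf")))
        reach = mid - max_len.get(row.chrom, 0)
        for idx in range(k - 1, -1, -1):
            span_lo, span_hi, regs = spans[idx]
            if span_lo <= reach:
                break
            if rule == "midpoint":
                inside = span_lo <= mid < span_hi
            else:
                inside = span_lo <= row.start and row.end <= span_hi
            if inside:
                assigned = regs
                break
        if assigned is None:
            locus_col.append(None)
            class_col.append("intergenic")
            offset_col.append(np.nan)
            continue
        locus_col.append(assigned.locus_id)
        # oriented offset of the cluster's 5' edge from the host TSS; an
        # orientation-free cluster address within its gene
        if assigned.strand == "-":
            offset_col.append(assigned.tss - (row.end - 1))
        else:
            offset_col.append(row.start - assigned.tss)
        if abs(mid - assigned.tss) <= half:
            class_col.append("canonical")
        elif any(s <= mid < e for s, e in assigned.introns):
            class_col.append("intronic")
        else:
            class_col.append("exonic")
    out = clusters.copy()
    out["locus_id"] = locus_col
    out["cluster_class"] = class_col
    out["tss_offset"] = offset_col
    out["activity"] = cage_activity(out)
    return out


def intronic_cage_level(
    regions: GeneRegions,
    clusters: pd.DataFrame,
    denominator: str = "intron",
) -> float:
    """Intronic initiation level of one locus in tags per bp.

    Sums tag counts of clusters assigned to this locus with class
    ``intronic`` and divides by total intron bp (default) or whole-locus bp
    (``denominator='locus'``).  NaN for loci without introns.
    """
    intron_bp = total_length(regions.introns)
    if intron_bp == 0:
        return float("nan")
    if denominator == "intron":
        denom = intron_bp
    elif denominator == "locus":
        denom = max(regions.tss, regions.tts) + 1 - min(regions.tss, regions.tts)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    sub = clusters[
        (clusters["locus_id"] == regions.locus_id)
        & (clusters["cluster_class"] == "intronic")
    ]
    return float(sub["tag_count"].sum()) / denom


@dataclass(frozen=True)
class IntronPartition:
    """Intron bp split into initiation (CAGE-covered) and silent space."""

    initiation: tuple[tuple[int, int], ...]
    silent: tuple[tuple[int, int], ...]

    @property
    def fraction_initiation(self) -> float:
        init = total_length(self.initiation)
        total = init + total_length(self.silent)
        return init / total if total else float("nan")


def partition_introns(
    introns: Sequence[tuple[int, int]],
    cluster_spans: Sequence[tuple[int, int]],
) -> IntronPartition:
    """Split intron space at CAGE cluster footprints (union, not sum).

    bp conservation holds exactly: |initiation| + |silent| = |introns|.
    """
    if not introns:
        raise ValueError("partition_introns requires non-empty introns")
    init = intersect_pairs(list(introns), list(cluster_spans))
    silent = subtract_pairs(list(introns), list(cluster_spans))
    return IntronPartition(tuple(init), tuple(silent))
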