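"""Per-CpG percent-methylation aggregation and metagene profiles.

Methylation for a region is the unweighted mean percent methylation of all
covered cytosines falling in the region (read coverage is never used as a
weight; an optional minimum-coverage filter can drop shallow sites at load
time).  Regions with no covered CpG yield a missing value, never zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneLocus, GeneRegions, oriented_window
from .intervals import merge_pairs

__all__ = [
    "RegionMethylation",
    "CpGIndex",
    "region_methylation",
    "metagene_profile",
    "flank_body_summary",
    "genic_vs_intergenic",
]


@dataclass(frozen=True)
class RegionMethylation:
    """Mean percent methylation over a region set plus the site count.

    ``mean_percent`` is NaN exactly when ``n_sites`` is zero.
    """

    mean_percent: float
    n_sites: int

    @property
    def missing(self) -> bool:
        return self.n_sites == 0


class CpGIndex:
    """Sorted per-chromosome index of covered CpG sites.

    Stores positions (record starts), percent methylation and coverage as
    numpy arrays with a prefix sum of percents, so any batch of windows is
    aggregated with two ``searchsorted`` calls.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"chrom", "start", "percent", "coverage"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"methylation table missing columns: {sorted(missing)}")
        if len(df) and not ((df["percent"] >= 0) & (df["percent"] <= 100)).all():
            raise ValueError("percent methylation outside [0, 100]")
        self._chrom: dict[str, dict[str, np.ndarray]] = {}
        for chrom, sub in df.groupby("chrom", sort=True):
            order = np.argsort(sub["start"].to_numpy(), kind="stable")
            pos = sub["start"].to_numpy()[order].astype(np.int64)
            pct = sub["percent"].to_numpy()[order].astype(np.float64)
            cov = sub["coverage"].to_numpy()[order].astype(np.int64)
            self._chrom[str(chrom)] = {
                "pos": pos,
                "pct": pct,
                "cov": cov,
                "cum": np.concatenate([[0.0], np.cumsum(pct)]),
            }

    @classmethod
    def from_tsv(cls, path, min_coverage: int = 1) -> "CpGIndex":
        """Load a bedGraph-like TSV: chrom, start, end, percent, coverage."""
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=["chrom", "start", "end", "percent", "coverage"],
            dtype={"chrom": str},
        )
        if min_coverage > 1:
            df = df[df["coverage"] >= min_coverage]
        return cls(df)

    @property
    def n_sites(self) -> int:
        return sum(len(d["pos"]) for d in self._chrom.values())

    @property
    def chroms(self) -> list[str]:
        return sorted(self._chrom)

    def window_stats(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised (mean percent, site count) per window on one chromosome.

        Windows must not overlap each other if the caller intends to sum the
        counts; means are always correct per window.
        """
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        data = self._chrom.get(chrom)
        if data is None:
            n = np.zeros(len(starts), dtype=np.int64)
            return np.full(len(starts), np.nan), n
        i = np.searchsorted(data["pos"], starts, side="left")
        j = np.searchsorted(data["pos"], ends, side="left")
        n = j - i
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.where(n > 0, (data["cum"][j] - data["cum"][i]) / n, np.nan)
        return means, n

    def percents_in(
        self, regions_by_chrom: Mapping[str, Sequence[tuple[int, int]]]
    ) -> np.ndarray:
        """All per-CpG percents whose position falls in the region set."""
        chunks = []
        for chrom, pairs in regions_by_chrom.items():
            data = self._chrom.get(chrom)
            if data is None:
                continue
            for s, e in merge_pairs(pairs):
                i = np.searchsorted(data["pos"], s, side="left")
                j = np.searchsorted(data["pos"], e, side="left")
                if j > i:
                    chunks.append(data["pct"][i:j])
        if not chunks:
            return np.empty(0)
        return np.concatenate(chunks)


def region_methylation(
    index: CpGIndex, regions: Mapping[str, Sequence[tuple[int, int]]] | Sequence
) -> RegionMethylation:
    """Unweighted mean percent over all CpGs in any of the given regions.

    ``regions`` is either a mapping chrom -> pairs or a sequence of
    :class:`~genebody.intervals.GenomicInterval`.  Overlapping regions are
    unioned first so no site is counted twice.
    """
    if not isinstance(regions, Mapping):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in regions:
            by_chrom.setdefault(iv.chrom, []).append(iv.pair)
        regions = by_chrom
    pct = index.percents_in(regions)
    if len(pct) == 0:
        return RegionMethylation(float("nan"), 0)
    return RegionMethylation(float(pct.mean()), int(len(pct)))


def _anchor_windows(
    regions: GeneRegions,
    anchor: str,
    offsets: np.ndarray,
    window: int,
    chrom_size: int | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Genomic (start, end, valid) arrays for oriented windows at one anchor."""
    pos = regions.tss if anchor == "TSS" else regions.tts
    strand = regions.strand if regions.strand in ("+", "-") else "+"
    starts = np.empty(len(offsets), dtype=np.int64)
    ends = np.empty(len(offsets), dtype=np.int64)
    valid = np.ones(len(offsets), dtype=bool)
    for k, off in enumerate(offsets):
        win = oriented_window(pos, strand, int(off), int(off) + window, chrom_size)
        if win is None or win[1] - win[0] != window:
            valid[k] = False
            starts[k] = ends[k] = 0
        else:
            starts[k], ends[k] = win
    return starts, ends, valid


def metagene_profile(
    regions_per_locus: Sequence[GeneRegions],
    index: CpGIndex,
    bins: Mapping[str, int],
    window: int = 100,
    tss_up: int = 3000,
    tss_down: int = 5000,
    tts_up: int = 5000,
    tts_down: int = 3000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Windowed methylation profile around TSS and TTS, averaged per bin.

    For every locus, fixed-size windows are laid out in transcription
    orientation at offsets ``[-tss_up, tss_down)`` around the TSS and
    ``[-tts_up, tts_down)`` around the TTS.  Per expression bin and window
    the gene-weighted mean (mean of per-gene window means, missing windows
    dropped) is reported.

    Returns a tidy frame: bin, anchor, offset, mean_percent, n_genes.
    """
    anchors = {
        "TSS": np.arange(-tss_up, tss_down, window),
        "TTS": np.arange(-tts_up, tts_down, window),
    }
    rows = []
    per_bin: dict[tuple[str, int], list[np.ndarray]] = {}
    for regs in regions_per_locus:
        b = bins.get(regs.locus_id)
        if b is None:
            continue
        size = chrom_sizes.get(regs.chrom) if chrom_sizes else None
        for anchor, offs in anchors.items():
            starts, ends, valid = _anchor_windows(regs, anchor, offs, window, size)
            means, _ = index.window_stats(regs.chrom, starts, ends)
            means[~valid] = np.nan
            per_bin.setdefault((anchor, int(b)), []).append(means)

    for (anchor, b), stack in sorted(per_bin.items(), key=lambda kv: (kv[0][1], kv[0][0])):
        mat = np.vstack(stack)
        n_genes = np.sum(~np.isnan(mat), axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(
                n_genes > 0, np.nansum(np.nan_to_num(mat), axis=0) / n_genes, np.nan
            )
        offs = anchors[anchor]
        for k, off in enumerate(offs):
            rows.append(
                {
                    "bin": b,
                    "anchor": anchor,
                    "offset": int(off),
                    "mean_percent": float(mean[k]) if n_genes[k] else float("nan"),
                    "n_genes": int(n_genes[k]),
                }
            )
    return pd.DataFrame(rows, columns=["bin", "anchor", "offset", "mean_percent", "n_genes"])


def flank_body_summary(
    regions_per_locus: Sequence[GeneRegions],
    index: CpGIndex,
    bins: Mapping[str, int],
) -> pd.DataFrame:
    """Per-bin overall mean +- SE of per-gene TSS-flank, body and TTS-flank methylation."""
    per_gene: dict[int, dict[str, list[float]]] = {}
    for regs in regions_per_locus:
        b = bins.get(regs.locus_id)
        if b is None:
            continue
        slots = per_gene.setdefault(int(b), {"tss_flank": [], "body": [], "tts_flank": []})
        for name, region in (
            ("tss_flank", regs.tss_flank),
            ("body", regs.body),
            ("tts_flank", regs.tts_flank),
        ):
            if region is None:
                continue
            rm = region_methylation(index, {regs.chrom: [region]})
            if not rm.missing:
                slots[name].append(rm.mean_percent)
    rows = []
    for b in sorted(per_gene):
        for name, values in per_gene[b].items():
            arr = np.asarray(values)
            n = len(arr)
            mean = float(arr.mean()) if n else float("nan")
            se = float(arr.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
            rows.append(
                {"bin": b, "region": name, "mean_percent": mean, "se": se, "n_genes": n}
            )
    return pd.DataFrame(rows, columns=["bin", "region", "mean_percent", "se", "n_genes"])


def genic_vs_intergenic(
    index: CpGIndex,
    loci: Sequence[GeneLocus],
    chrom_sizes: Mapping[str, int],
) -> dict:
    """Per-CpG mean +- standard error over genic vs intergenic space.

    A CpG is genic when its position falls inside any locus span (either
    strand).  Site counts are conserved: genic n + intergenic n = total.
    """
    spans: dict[str, list[tuple[int, int]]] = {}
    for locus in loci:
        spans.setdefault(locus.span.chrom, []).append(locus.span.pair)
    genic = index.percents_in(spans)
    from .intervals import complement_pairs

    inter: dict[str, list[tuple[int, int]]] = {}
    for chrom, size in chrom_sizes.items():
        inter[chrom] = complement_pairs(spans.get(chrom, []), size)
    intergenic = index.percents_in(inter)

    def stats(arr: np.ndarray) -> dict:
        n = int(len(arr))
        if n == 0:
            return {"mean": float("nan"), "se": float("nan"), "n": 0}
        se = float(arr.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
        return {"mean": float(arr.mean()), "se": se, "n": n}

    return {"genic": stats(genic), "intergenic": stats(intergenic)}
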