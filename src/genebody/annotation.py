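"""Transcript models, gene-locus merging and derived gene anatomy.

Transcripts come in as BED12.  Overlapping transcripts are merged into
distinct gene loci spanning from the start of the 5'-most exon to the end
of the 3'-most exon; each locus then yields a TSS, a TTS, oriented flank
windows, a trimmed gene body and the intron set (span minus exon union).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, TextIO

from .intervals import (
    GenomicInterval,
    clip_pair,
    complement_pairs,
    merge_pairs,
    subtract_pairs,
)

__all__ = [
    "TranscriptModel",
    "GeneLocus",
    "GeneRegions",
    "read_transcripts",
    "merge_transcripts",
    "derive_regions",
    "intergenic_complement",
    "oriented_window",
    "write_loci_bed",
    "chrom_sort_key",
]


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: its span plus ordered, disjoint exon blocks."""

    id: str
    span: GenomicInterval
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.id}: transcript must have >= 1 exon")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.span.chrom or ex.strand != self.span.strand:
                raise ValueError(f"{self.id}: exon off-chromosome/strand")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"{self.id}: exons unsorted or overlapping")
            prev_end = ex.end
        if self.exons[0].start != self.span.start or self.exons[-1].end != self.span.end:
            raise ValueError(f"{self.id}: exon blocks do not tile the span ends")


@dataclass(frozen=True)
class GeneLocus:
    """A merged gene locus: bounding span, exon union and member transcripts."""

    id: str
    span: GenomicInterval
    exon_union: tuple[tuple[int, int], ...]
    member_ids: tuple[str, ...]

    @property
    def length(self) -> int:
        return len(self.span)

    @property
    def introns(self) -> list[tuple[int, int]]:
        return subtract_pairs([self.span.pair], list(self.exon_union))


@dataclass(frozen=True)
class GeneRegions:
    """Strand-aware anatomy of one locus.

    ``tss``/``tts`` are single 0-based positions.  ``body`` is the locus span
    trimmed by ``body_trim`` at each end (None for short genes).  Flanks are
    oriented in the transcription direction and clipped at chromosome bounds.
    """

    locus_id: str
    chrom: str
    strand: str
    tss: int
    tts: int
    body: tuple[int, int] | None
    introns: tuple[tuple[int, int], ...]
    tss_flank: tuple[int, int] | None
    tts_flank: tuple[int, int] | None


class BedParseError(ValueError):
    pass


def _parse_int_list(field: str) -> list[int]:
    return [int(x) for x in field.rstrip(",").split(",") if x != ""]


def read_transcripts(stream: TextIO | str) -> list[TranscriptModel]:
    """Parse BED12 text into transcript models.

    Accepts a file-like object or a string of BED12 text.  Comment lines
    (``#``, ``track``, ``browser``) are skipped.  Malformed lines raise
    :class:`BedParseError` naming the offending line number.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    out: list[TranscriptModel] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) == 1:
            fields = line.split()
        if len(fields) < 12:
            raise BedParseError(f"line {lineno}: expected 12 BED fields, got {len(fields)}")
        try:
            chrom = fields[0]
            start, end = int(fields[1]), int(fields[2])
            name = fields[3]
            strand = fields[5]
            n_blocks = int(fields[9])
            sizes = _parse_int_list(fields[10])
            starts = _parse_int_list(fields[11])
        except ValueError as exc:
            raise BedParseError(f"line {lineno}: {exc}") from exc
        if len(sizes) != n_blocks or len(starts) != n_blocks:
            raise BedParseError(
                f"line {lineno}: blockCount={n_blocks} but "
                f"{len(sizes)} sizes / {len(starts)} starts"
            )
        try:
            span = GenomicInterval(chrom, start, end, strand)
            exons = tuple(
                GenomicInterval(chrom, start + bs, start + bs + sz, strand)
                for bs, sz in zip(starts, sizes)
            )
            if exons[-1].end > end:
                raise ValueError(f"blocks exceed span end ({exons[-1].end} > {end})")
            tx = TranscriptModel(name, span, exons)
        except ValueError as exc:
            raise BedParseError(f"line {lineno}: {exc}") from exc
        out.append(tx)
    return out


def chrom_sort_key(chrom: str) -> tuple:
    """Natural ordering for chromosome names (chr2 before chr10)."""
    stem = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if stem.isdigit():
        return (0, int(stem), "")
    return (1, 0, stem)


def merge_transcripts(
    transcripts: Sequence[TranscriptModel], strand_aware: bool = True
) -> list[GeneLocus]:
    """Merge transcripts whose spans overlap into gene loci.

    Loci are the connected components of the span-overlap graph (transitive
    closure; intron-inclusive spans).  With ``strand_aware`` (default) only
    same-strand transcripts are merged and locus strand is preserved;
    otherwise merging ignores strand and loci are unstranded.
    Output is sorted by genomic coordinate and ids are assigned in that order.
    """
    groups: dict[tuple, list[TranscriptModel]] = {}
    for tx in transcripts:
        key = (tx.span.chrom, tx.span.strand) if strand_aware else (tx.span.chrom,)
        groups.setdefault(key, []).append(tx)

    raw: list[tuple[str, str, int, int, list[TranscriptModel]]] = []
    for key, members in groups.items():
        members = sorted(members, key=lambda t: (t.span.start, t.span.end, t.id))
        cluster: list[TranscriptModel] = []
        cur_end = None
        for tx in members:
            if cluster and tx.span.start < cur_end:
                cluster.append(tx)
                cur_end = max(cur_end, tx.span.end)
            else:
                if cluster:
                    raw.append(_close_cluster(cluster, key, strand_aware))
                cluster = [tx]
                cur_end = tx.span.end
        if cluster:
            raw.append(_close_cluster(cluster, key, strand_aware))

    raw.sort(key=lambda r: (chrom_sort_key(r[0]), r[2], r[3], r[1]))
    width = max(5, len(str(len(raw))))
    loci = []
    for i, (chrom, strand, start, end, members) in enumerate(raw, start=1):
        exon_union = merge_pairs(
            [(ex.start, ex.end) for tx in members for ex in tx.exons]
        )
        loci.append(
            GeneLocus(
                id=f"L{i:0{width}d}",
                span=GenomicInterval(chrom, start, end, strand),
                exon_union=tuple(exon_union),
                member_ids=tuple(sorted(tx.id for tx in members)),
            )
        )
    return loci


def _close_cluster(cluster, key, strand_aware):
    chrom = key[0]
    strand = key[1] if strand_aware else "."
    start = min(t.span.start for t in cluster)
    end = max(t.span.end for t in cluster)
    return (chrom, strand, start, end, list(cluster))


def oriented_window(
    anchor: int, strand: str, d0: int, d1: int, chrom_size: int | None = None
) -> tuple[int, int] | None:
    """Genomic window for transcription-oriented offsets ``[d0, d1)``.

    Offset ``d`` addresses the base ``d`` bp downstream of ``anchor`` in the
    transcription direction (negative = upstream).  On the minus strand the
    genomic window for ``[d0, d1)`` is ``[anchor-d1+1, anchor-d0+1)``.
    Clipped at chromosome bounds; None when the window falls entirely outside.
    """
    if strand == "-":
        start, end = anchor - d1 + 1, anchor - d0 + 1
    else:
        start, end = anchor + d0, anchor + d1
    return clip_pair(start, end, chrom_size)


def derive_regions(
    locus: GeneLocus,
    body_trim: int = 1000,
    tss_up: int = 3000,
    tss_down: int = 5000,
    tts_up: int = 5000,
    tts_down: int = 3000,
    chrom_size: int | None = None,
) -> GeneRegions:
    """Derive TSS/TTS, flanks, trimmed body and introns for one locus.

    The body is the span trimmed by ``body_trim`` at both ends (in either
    orientation the same genomic interval) and is None when the locus is
    shorter than ``2 * body_trim`` -- such genes are excluded from gene-body
    statistics.  Unstranded loci are treated as plus-strand.
    """
    span = locus.span
    minus = span.strand == "-"
    tss = span.end - 1 if minus else span.start
    tts = span.start if minus else span.end - 1
    strand = span.strand if span.strand in ("+", "-") else "+"

    body: tuple[int, int] | None = None
    if len(span) > 2 * body_trim:
        body = (span.start + body_trim, span.end - body_trim)

    return GeneRegions(
        locus_id=locus.id,
        chrom=span.chrom,
        strand=span.strand,
        tss=tss,
        tts=tts,
        body=body,
        introns=tuple(locus.introns),
        tss_flank=oriented_window(tss, strand, -tss_up, tss_down, chrom_size),
        tts_flank=oriented_window(tts, strand, -tts_up, tts_down, chrom_size),
    )


def intergenic_complement(
    loci: Sequence[GeneLocus], chrom_sizes: Mapping[str, int]
) -> list[GenomicInterval]:
    """Unstranded complement of the union of locus spans, per chromosome."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for locus in loci:
        chrom = locus.span.chrom
        if chrom not in chrom_sizes:
            raise ValueError(f"no chromosome size for {chrom}")
        if locus.span.end > chrom_sizes[chrom]:
            raise ValueError(
                f"locus {locus.id} ends at {locus.span.end} beyond "
                f"{chrom} size {chrom_sizes[chrom]}"
            )
        by_chrom.setdefault(chrom, []).append(locus.span.pair)
    out: list[GenomicInterval] = []
    for chrom in sorted(chrom_sizes, key=chrom_sort_key):
        pairs = by_chrom.get(chrom, [])
        for s, e in complement_pairs(pairs, chrom_sizes[chrom]):
            out.append(GenomicInterval(chrom, s, e, "."))
    return out


def write_loci_bed(loci: Iterable[GeneLocus], path, header: str | None = None) -> None:
    """Write merged loci as BED6 (name = locus id, score = member count)."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for locus in loci:
            s = locus.span
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{locus.id}\t"
                f"{len(locus.member_ids)}\t{s.strand}\n"
            )


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column chrom<TAB>size table."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    return sizes


__all__.append("read_chrom_sizes")
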