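"""Coordinate mirroring of a simulated dataset.

Mirrors every feature through its chromosome (``x -> L - x``) and swaps
strands.  Transcription orientation is preserved, so every analysis
statistic must be invariant under this transformation; it is used as a
symmetry check on the whole pipeline.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .annotation import merge_transcripts, read_chrom_sizes, read_transcripts

__all__ = ["mirror_dataset"]

_FLIP = {"+": "-", "-": "+", ".": "."}


def _mirror_bed12_line(fields: list[str], size: int) -> str:
    start, end = int(fields[1]), int(fields[2])
    sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
    starts = [int(x) for x in fields[11].rstrip(",").split(",")]
    # mirror each block, then re-sort ascending relative to the new start
    blocks = [
        (size - (start + bs + sz), sz) for bs, sz in zip(starts, sizes)
    ]
    blocks.sort()
    new_start, new_end = size - end, size - start
    out = list(fields)
    out[1], out[2] = str(new_start), str(new_end)
    out[5] = _FLIP[fields[5]]
    out[6] = out[7] = str(new_start)
    out[10] = ",".join(str(sz) for _, sz in blocks)
    out[11] = ",".join(str(s - new_start) for s, _ in blocks)
    return "\t".join(out)


def mirror_dataset(in_dir, out_dir) -> Path:
    """Write a mirrored copy of a simulated dataset.

    All interval files are flipped per chromosome; the expression and truth
    tables are re-keyed to the locus ids the mirrored annotation will
    receive (ids are assigned in coordinate order, which mirroring
    reverses).
    """
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sizes = read_chrom_sizes(in_dir / "sizes.tsv")
    (out_dir / "sizes.tsv").write_text(
        "".join(f"{c}\t{s}\n" for c, s in sorted(sizes.items()))
    )

    # transcripts
    mirrored_lines = []
    with open(in_dir / "transcripts.bed12") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            mirrored_lines.append(_mirror_bed12_line(fields, sizes[fields[0]]))
    (out_dir / "transcripts.bed12").write_text("\n".join(mirrored_lines) + "\n")

    # locus id correspondence: original span [s,e) <-> mirrored [L-e, L-s)
    orig = merge_transcripts(read_transcripts((in_dir / "transcripts.bed12").read_text()))
    mirr = merge_transcripts(read_transcripts("\n".join(mirrored_lines) + "\n"))
    lookup = {(l.span.chrom, l.span.start, l.span.end): l.id for l in mirr}
    id_map = {}
    for locus in orig:
        L = sizes[locus.span.chrom]
        key = (locus.span.chrom, L - locus.span.end, L - locus.span.start)
        id_map[locus.id] = lookup[key]

    # point/interval tracks
    for name, cols in (
        ("meth.tsv", ["chrom", "start", "end", "percent", "coverage"]),
        ("pol2.bed", ["chrom", "start", "end"]),
        ("dhss.bed", ["chrom", "start", "end"]),
        ("cage.bed", ["chrom", "start", "end", "name", "score"]),
    ):
        path = in_dir / name
        if not path.exists():
            continue
        df = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols,
                         dtype={"chrom": str})
        L = df["chrom"].map(sizes)
        start, end = df["start"].copy(), df["end"].copy()
        df["start"] = L - end
        df["end"] = L - start
        df = df.sort_values(["chrom", "start"], kind="stable")
        df.to_csv(out_dir / name, sep="\t", header=False, index=False)

    # tables keyed by locus id
    expr = pd.read_csv(in_dir / "expr.tsv", sep="\t", comment="#")
    expr.iloc[:, 0] = expr.iloc[:, 0].map(id_map)
    expr = expr.sort_values(expr.columns[0], kind="stable")
    expr.to_csv(out_dir / "expr.tsv", sep="\t", index=False)
    truth_path = in_dir / "truth.tsv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t", comment="#")
        truth["locus_id"] = truth["locus_id"].map(id_map)
        L = truth["chrom"].map(sizes)
        start, end = truth["start"].copy(), truth["end"].copy()
        truth["start"] = L - end
        truth["end"] = L - start
        truth["strand"] = truth["strand"].map(_FLIP)
        truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return out_dir
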