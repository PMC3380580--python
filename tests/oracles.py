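"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately naive (per-bp scans, explicit union-find,
textbook formulas) and shares no code with the package internals it checks.
"""

from __future__ import annotations

import math


# ---------------------------------------------------------------------------
# union-find merging over pairwise span overlaps

class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)


def bruteforce_merge(spans, strand_aware: bool = True):
    """Connected components of the pairwise span-overlap graph.

    ``spans`` is a list of (chrom, start, end, strand, tx_id).  Returns a
    sorted list of (chrom, strand_or_dot, start, end, frozenset(member ids)).
    """
    uf = _UnionFind(len(spans))
    for i in range(len(spans)):
        for j in range(i + 1, len(spans)):
            ci, si, ei, ti, _ = spans[i]
            cj, sj, ej, tj, _ = spans[j]
            if ci != cj:
                continue
            if strand_aware and ti != tj:
                continue
            if si < ej and sj < ei:
                uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(len(spans)):
        groups.setdefault(uf.find(i), []).append(i)
    out = []
    for members in groups.values():
        chrom = spans[members[0]][0]
        strand = spans[members[0]][3] if strand_aware else "."
        start = min(spans[i][1] for i in members)
        end = max(spans[i][2] for i in members)
        ids = frozenset(spans[i][4] for i in members)
        out.append((chrom, strand, start, end, ids))
    return sorted(out, key=lambda t: (t[0], t[2], t[3], t[1]))


# ---------------------------------------------------------------------------
# per-bp scans

def naive_region_mean(cpgs, regions) -> tuple[float, int]:
    """Mean percent of CpGs ((chrom, pos, percent)) inside any region.

    ``regions``: list of (chrom, start, end).  Returns (mean, n); mean NaN
    when n == 0.  Membership by site enumeration, one site counted once.
    """
    hit = []
    for chrom, pos, percent in cpgs:
        for rc, rs, re in regions:
            if rc == chrom and rs <= pos < re:
                hit.append(percent)
                break
    if not hit:
        return (float("nan"), 0)
    return (sum(hit) / len(hit), len(hit))


def naive_tag_count(tags, regions) -> int:
    """Tags ((chrom, pos)) whose start lies in any region (counted once)."""
    count = 0
    for chrom, pos in tags:
        for rc, rs, re in regions:
            if rc == chrom and rs <= pos < re:
                count += 1
                break
    return count


def naive_partition(introns, clusters, genome_size: int):
    """Per-bp split of intron space at cluster footprints.

    ``introns``/``clusters``: (start, end) pairs on one chromosome.
    Returns (initiation_bp, silent_bp, initiation membership set).
    """
    in_intron = [False] * genome_size
    for s, e in introns:
        for x in range(s, e):
            in_intron[x] = True
    in_cluster = [False] * genome_size
    for s, e in clusters:
        for x in range(max(s, 0), min(e, genome_size)):
            in_cluster[x] = True
    init = {x for x in range(genome_size) if in_intron[x] and in_cluster[x]}
    silent = {x for x in range(genome_size) if in_intron[x] and not in_cluster[x]}
    return len(init), len(silent), init


def naive_complement(spans, size: int) -> set[int]:
    """bp positions in [0, size) not covered by any span."""
    covered = [False] * size
    for s, e in spans:
        for x in range(s, e):
            covered[x] = True
    return {x for x in range(size) if not covered[x]}


# ---------------------------------------------------------------------------
# statistics

def direct_pearson_r(x, y) -> float:
    """Pearson r straight from the covariance formula (no numpy)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def standard_error(values) -> float:
    """Textbook SE: sample sd over sqrt(n)."""
    n = len(values)
    mean = sum(values) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    return sd / math.sqrt(n)
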