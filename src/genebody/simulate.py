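"""Synthetic genome generator built around an accessibility-interference model.

The generator emits a toy genome (transcripts, chromosome sizes, per-CpG
methylation, per-gene expression, CAGE clusters, Pol2 and DNase tags) whose
statistical structure follows a quantitative stand-in for the
accessibility-interference view of gene-body methylation: closed chromatin
at unexpressed genes blocks the methyltransferase, while very dense
polymerase traffic at highly expressed genes interferes with its
processivity.  Gene-body methylation is therefore modelled as a product of
two Hill terms,

    M(E) = M_max * E^h_open / (E^h_open + K_open^h_open)
                 * K_int^h_int / (K_int^h_int + E^h_int)

which rises with expression E at the low end (chromatin opening,
half-saturation ``K_open``) and falls at the high end (polymerase
interference, half-inhibition ``K_int``).  With equal Hill coefficients the
curve peaks at ``E* = sqrt(K_open * K_int)``.  This product form is the
package's own quantitative model choice, not a measured fact.

Promoter (TSS-flank) methylation decreases monotonically with expression;
intergenic CpGs sit at a low baseline; intronic CAGE cluster activity is
sampled proportional to ``exp(-lambda * local methylation)`` so initiation
anti-correlates with local methylation; Pol2 tag counts are Poisson with
mean linear in expression and DNase counts use a saturating link.

All randomness flows through one numpy Generator keyed by the seed; every
output file carries the seed and a config hash in a header comment.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import merge_transcripts, oriented_window, read_transcripts
from .intervals import subtract_pairs
from .methylation import CpGIndex

__all__ = [
    "SimConfig",
    "SimResult",
    "body_methylation",
    "promoter_methylation",
    "peak_expression",
    "simulate_annotation",
    "simulate_expression",
    "simulate_methylome",
    "simulate_cage_and_tags",
    "simulate_all",
    "read_expression",
]


@dataclass
class SimConfig:
    """Parameters of the synthetic genome.

    Expression is log-normal (natural-log location/scale).  The methylation
    model parameters (``K_open``, ``h_open``, ``K_int``, ``h_int``,
    ``M_max``) are in the same expression units and percent points.  With
    the defaults the bell peaks at E* = sqrt(5 * 80) = 20, the median
    expression level, at about 84% methylation.
    """

    n_genes: int = 2000
    n_chroms: int = 4
    mean_gene_length: float = 8000.0
    gene_length_spread: float = 0.35  # log-sd of gene length
    min_gene_length: int = 3000
    mean_intergenic_gap: float = 7000.0
    min_intergenic_gap: int = 3000
    exons_per_gene: float = 5.0
    overlap_fraction: float = 0.2  # genes that get a second, overlapping transcript

    cpg_spacing: float = 100.0  # mean bp between covered CpGs

    expression_meanlog: float = 3.0
    expression_sdlog: float = 0.45

    K_open: float = 5.0
    h_open: float = 2.0
    K_int: float = 80.0
    h_int: float = 2.0
    M_max: float = 95.0

    tss_meth_max: float = 80.0
    tss_meth_K: float = 20.0
    tss_meth_decay: float = 1.5  # Hill slope of promoter demethylation vs E
    promoter_up: int = 3000
    promoter_down: int = 1000
    body_trim: int = 1000

    intergenic_meth: float = 10.0
    noise_sd: float = 5.0

    cage_rate: float = 3.0  # intronic cluster intensity at saturating E
    cage_expr_K: float = 20.0
    cage_width_min: int = 100
    cage_width_max: int = 300
    cage_activity_scale: float = 8.0  # tags per bp before suppression
    cage_expr_act_K: float = 5.0
    meth_activity_decay: float = 0.05  # lambda in exp(-lambda * percent)
    tss_cluster_width: int = 100
    tss_cage_rate: float = 0.5

    pol2_rate: float = 2e-4  # tags per bp per expression unit
    dhss_rate: float = 0.02
    K_dhss: float = 30.0

    seed: int = 17

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]

    def header(self) -> str:
        return f"genebody simulate seed={self.seed} config={self.config_hash()}"


@dataclass
class SimResult:
    """Paths of the emitted files plus the per-gene truth table."""

    out_dir: Path
    files: dict[str, Path]
    truth: pd.DataFrame
    config: SimConfig


def body_methylation(config: SimConfig, E) -> np.ndarray:
    """True mean gene-body percent methylation at expression level E."""
    E = np.asarray(E, dtype=float)
    opening = E**config.h_open / (E**config.h_open + config.K_open**config.h_open)
    interference = config.K_int**config.h_int / (
        config.K_int**config.h_int + E**config.h_int
    )
    return config.M_max * opening * interference


def promoter_methylation(config: SimConfig, E) -> np.ndarray:
    """True TSS-flank percent methylation: monotone decreasing in E."""
    E = np.asarray(E, dtype=float)
    K = config.tss_meth_K
    h = config.tss_meth_decay
    return config.tss_meth_max * K**h / (K**h + E**h)


def peak_expression(config: SimConfig) -> float:
    """Expression level at which the body-methylation bell peaks.

    Closed form ``sqrt(K_open * K_int)`` when the two Hill coefficients are
    equal; otherwise located numerically on a log grid.
    """
    if config.h_open == config.h_int:
        return math.sqrt(config.K_open * config.K_int)
    grid = np.exp(np.linspace(math.log(config.K_open) - 5, math.log(config.K_int) + 5, 20001))
    return float(grid[int(np.argmax(body_methylation(config, grid)))])


# ---------------------------------------------------------------------------
# annotation

@dataclass
class _Gene:
    index: int
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def introns(self) -> list[tuple[int, int]]:
        return subtract_pairs([(self.start, self.end)], self.exons)


def _gene_structure(rng, config: SimConfig, start: int, length: int) -> list[tuple[int, int]]:
    """Exon blocks tiling [start, start+length) with introns >= 400 bp."""
    min_intron = 400
    k = max(1, int(rng.poisson(config.exons_per_gene)))
    while k > 1:
        exon_lens = rng.integers(100, 301, size=k)
        rest = length - int(exon_lens.sum())
        if rest >= min_intron * (k - 1):
            break
        k -= 1
    if k == 1:
        return [(start, start + length)]
    extra = rest - min_intron * (k - 1)
    weights = rng.dirichlet(np.ones(k - 1))
    intron_lens = min_intron + np.floor(weights * extra).astype(int)
    intron_lens[-1] += extra - int((intron_lens - min_intron).sum())
    exons = []
    pos = start
    for i in range(k):
        exons.append((pos, pos + int(exon_lens[i])))
        pos += int(exon_lens[i])
        if i < k - 1:
            pos += int(intron_lens[i])
    # stretch the last exon so blocks end exactly at the span end
    s_last, _ = exons[-1]
    exons[-1] = (s_last, start + length)
    return exons


def simulate_annotation(
    config: SimConfig, rng: np.random.Generator
) -> tuple[list[str], dict[str, int], list[_Gene]]:
    """Place gene models on chromosomes and render them as BED12 lines.

    A fraction of multi-exon genes gets a second transcript spanning all but
    the first exon, so merging is exercised; the merged locus always equals
    the placed gene.
    """
    per_chrom = math.ceil(config.n_genes / config.n_chroms)
    lines: list[str] = []
    sizes: dict[str, int] = {}
    genes: list[_Gene] = []
    mu_len = math.log(config.mean_gene_length) - 0.5 * config.gene_length_spread**2
    idx = 0
    for c in range(1, config.n_chroms + 1):
        chrom = f"chr{c}"
        cursor = config.min_intergenic_gap + int(
            rng.exponential(config.mean_intergenic_gap - config.min_intergenic_gap)
        )
        n_here = min(per_chrom, config.n_genes - idx)
        for _ in range(n_here):
            length = int(rng.lognormal(mu_len, config.gene_length_spread))
            length = max(length, config.min_gene_length)
            strand = "+" if rng.random() < 0.5 else "-"
            exons = _gene_structure(rng, config, cursor, length)
            gene = _Gene(idx, chrom, cursor, cursor + length, strand, exons)
            genes.append(gene)
            lines.append(_bed12(chrom, exons, f"tx{idx:05d}", strand))
            if len(exons) >= 3 and rng.random() < config.overlap_fraction:
                lines.append(_bed12(chrom, exons[1:], f"tx{idx:05d}b", strand))
            gap = config.min_intergenic_gap + int(
                rng.exponential(config.mean_intergenic_gap - config.min_intergenic_gap)
            )
            cursor += length + gap
            idx += 1
        sizes[chrom] = cursor + config.min_intergenic_gap
        if genes and genes[-1].chrom == chrom and genes[-1].end > sizes[chrom]:
            raise ValueError("gene packing exceeded chromosome size")
    return lines, sizes, genes


def _bed12(chrom: str, exons: list[tuple[int, int]], name: str, strand: str) -> str:
    start = exons[0][0]
    end = exons[-1][1]
    sizes = ",".join(str(e - s) for s, e in exons)
    starts = ",".join(str(s - start) for s, e in exons)
    return (
        f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}\t{start}\t{start}\t0\t"
        f"{len(exons)}\t{sizes}\t{starts}"
    )


def simulate_expression(
    config: SimConfig, rng: np.random.Generator, n: int | None = None
) -> np.ndarray:
    """Log-normal expression levels, one per gene (natural units)."""
    n = config.n_genes if n is None else n
    if config.expression_sdlog == 0:
        return np.full(n, math.exp(config.expression_meanlog))
    return rng.lognormal(config.expression_meanlog, config.expression_sdlog, n)


# ---------------------------------------------------------------------------
# methylome

def simulate_methylome(
    config: SimConfig,
    genes: list[_Gene],
    sizes: dict[str, int],
    E: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-CpG percent methylation over the whole toy genome.

    Gene spans follow the body model M(E); an oriented promoter zone
    (``promoter_up`` upstream through ``promoter_down`` downstream of the
    TSS) is overridden with the monotone promoter model; everything else
    sits at the intergenic baseline.  Gaussian per-CpG noise, clamped to
    [0, 100].
    """
    frames = []
    body_true = body_methylation(config, E)
    prom_true = promoter_methylation(config, E)
    for chrom in sorted(sizes):
        size = sizes[chrom]
        n_exp = int(size / (config.cpg_spacing + 1) * 1.3) + 10
        gaps = 1 + rng.exponential(config.cpg_spacing, n_exp)
        pos = np.cumsum(gaps).astype(np.int64)
        while pos[-1] < size:  # pragma: no cover - spacing draw almost always suffices
            extra = 1 + rng.exponential(config.cpg_spacing, n_exp)
            pos = np.concatenate([pos, pos[-1] + np.cumsum(extra).astype(np.int64)])
        pos = pos[pos < size]
        percent = np.full(len(pos), config.intergenic_meth)
        for gene in genes:
            if gene.chrom != chrom:
                continue
            i, j = np.searchsorted(pos, [gene.start, gene.end])
            percent[i:j] = body_true[gene.index]
            tss = gene.end - 1 if gene.strand == "-" else gene.start
            win = oriented_window(
                tss, gene.strand, -config.promoter_up, config.promoter_down, size
            )
            if win is not None:
                i, j = np.searchsorted(pos, [win[0], win[1]])
                percent[i:j] = prom_true[gene.index]
        if config.noise_sd > 0:
            percent = percent + rng.normal(0.0, config.noise_sd, len(pos))
        percent = np.clip(percent, 0.0, 100.0)
        coverage = rng.integers(5, 51, len(pos))
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": pos,
                    "end": pos + 1,
                    "percent": percent,
                    "coverage": coverage,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# CAGE clusters and tags

def simulate_cage_and_tags(
    config: SimConfig,
    genes: list[_Gene],
    E: np.ndarray,
    meth_index: CpGIndex,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """CAGE clusters plus Pol2 and DNase tag positions.

    Intronic clusters are placed inside body introns with Poisson intensity
    increasing (saturating) in E; their tag counts are suppressed by the
    realized local methylation through ``exp(-meth_activity_decay * m)``.
    A canonical TSS cluster with activity proportional to E is always
    emitted.  Pol2 tag counts are Poisson(length * pol2_rate * E); DNase
    counts use a saturating link in E.
    """
    E_med = math.exp(config.expression_meanlog)
    cage_rows = []
    pol2_rows = {"chrom": [], "start": []}
    dhss_rows = {"chrom": [], "start": []}
    for gene in genes:
        e_i = float(E[gene.index])
        # canonical TSS cluster, activity ~ E; oriented downstream from the
        # TSS so the cluster (and its midpoint) lies strictly inside the span
        tss = gene.end - 1 if gene.strand == "-" else gene.start
        width = config.tss_cluster_width
        win = oriented_window(tss, gene.strand, 0, width)
        lam = width * config.tss_cage_rate * e_i / E_med
        tags = max(1, int(rng.poisson(lam)))
        cage_rows.append((gene.chrom, win[0], win[1], tags))
        # intronic clusters, restricted to introns inside the trimmed body
        body = (gene.start + config.body_trim, gene.end - config.body_trim)
        candidates = [
            (max(s, body[0]), min(e, body[1]))
            for s, e in gene.introns
            if min(e, body[1]) - max(s, body[0]) > config.cage_width_min + 2
        ]
        if candidates and config.cage_rate > 0:
            n_cl = rng.poisson(config.cage_rate * e_i / (e_i + config.cage_expr_K))
            for _ in range(n_cl):
                width = int(rng.integers(config.cage_width_min, config.cage_width_max + 1))
                fits = [(s, e) for s, e in candidates if e - s >= width + 2]
                if not fits:
                    continue
                w_arr = np.array([e - s - width - 1 for s, e in fits], dtype=float)
                pick = fits[rng.choice(len(fits), p=w_arr / w_arr.sum())]
                start = int(pick[0] + 1 + rng.integers(0, pick[1] - pick[0] - width - 1))
                m_local = meth_index.window_stats(
                    gene.chrom, np.array([start]), np.array([start + width])
                )[0][0]
                if np.isnan(m_local):
                    m_local = body_methylation(config, e_i)
                lam = (
                    width
                    * config.cage_activity_scale
                    * e_i
                    / (e_i + config.cage_expr_act_K)
                    * math.exp(-config.meth_activity_decay * float(m_local))
                )
                tags = int(rng.poisson(lam))
                if tags >= 1:
                    cage_rows.append((gene.chrom, start, start + width, tags))
        # Pol2: linear in E
        n_pol2 = rng.poisson(gene.length * config.pol2_rate * e_i)
        if n_pol2:
            pol2_rows["chrom"].extend([gene.chrom] * n_pol2)
            pol2_rows["start"].extend(
                (gene.start + rng.integers(0, gene.length, n_pol2)).tolist()
            )
        # DNase: saturating in E
        n_dhss = rng.poisson(
            gene.length * config.dhss_rate * e_i / (e_i + config.K_dhss)
        )
        if n_dhss:
            dhss_rows["chrom"].extend([gene.chrom] * n_dhss)
            dhss_rows["start"].extend(
                (gene.start + rng.integers(0, gene.length, n_dhss)).tolist()
            )
    cage = pd.DataFrame(cage_rows, columns=["chrom", "start", "end", "tag_count"])
    cage = cage.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
    pol2 = pd.DataFrame(pol2_rows).sort_values(["chrom", "start"], kind="stable")
    dhss = pd.DataFrame(dhss_rows).sort_values(["chrom", "start"], kind="stable")
    return cage, pol2.reset_index(drop=True), dhss.reset_index(drop=True)


# ---------------------------------------------------------------------------
# orchestration

def simulate_all(config: SimConfig, out_dir) -> SimResult:
    """Run every stage in order on one seeded RNG stream and write all files.

    Emits transcripts.bed12, sizes.tsv, meth.tsv, expr.tsv, cage.bed,
    pol2.bed, dhss.bed and truth.tsv into ``out_dir``.  Expression and truth
    are keyed by the merged locus ids the annotation module assigns, so the
    whole bundle round-trips through the analysis pipeline.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    header = config.header()

    lines, sizes, genes = simulate_annotation(config, rng)
    E = simulate_expression(config, rng)
    meth = simulate_methylome(config, genes, sizes, E, rng)
    index = CpGIndex(meth)
    cage, pol2, dhss = simulate_cage_and_tags(config, genes, E, index, rng)

    # locus ids as the analysis pipeline will assign them
    loci = merge_transcripts(read_transcripts("\n".join(lines) + "\n"), strand_aware=True)
    span_to_id = {(l.span.chrom, l.span.start, l.span.end): l.id for l in loci}
    ids = []
    for gene in genes:
        key = (gene.chrom, gene.start, gene.end)
        if key not in span_to_id:
            raise RuntimeError("simulated gene did not survive merging unchanged")
        ids.append(span_to_id[key])

    truth = pd.DataFrame(
        {
            "locus_id": ids,
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "strand": [g.strand for g in genes],
            "expression": E,
            "log2_expression": np.log2(E),
            "body_meth_true": body_methylation(config, E),
            "promoter_meth_true": promoter_methylation(config, E),
            "pol2_density_true": config.pol2_rate * E,
            "dhss_density_true": config.dhss_rate * E / (E + config.K_dhss),
        }
    )

    files: dict[str, Path] = {}

    def write(name: str, renderer) -> None:
        path = out_dir / name
        with open(path, "w") as fh:
            fh.write(f"# {header}\n")
            renderer(fh)
        files[name.split(".")[0]] = path

    write("transcripts.bed12", lambda fh: fh.write("\n".join(lines) + "\n"))
    write(
        "sizes.tsv",
        lambda fh: fh.writelines(f"{c}\t{s}\n" for c, s in sorted(sizes.items())),
    )
    write("meth.tsv", lambda fh: meth.to_csv(fh, sep="\t", header=False, index=False))
    expr = pd.DataFrame({"gene_id": ids, "log2_expression": np.log2(E)})
    expr = expr.sort_values("gene_id", kind="stable")
    write("expr.tsv", lambda fh: expr.to_csv(fh, sep="\t", index=False))
    write(
        "cage.bed",
        lambda fh: pd.DataFrame(
            {
                "chrom": cage["chrom"],
                "start": cage["start"],
                "end": cage["end"],
                "name": [f"cl{i}" for i in range(len(cage))],
                "score": cage["tag_count"],
            }
        ).to_csv(fh, sep="\t", header=False, index=False),
    )
    for name, df in (("pol2.bed", pol2), ("dhss.bed", dhss)):
        write(
            name,
            lambda fh, df=df: pd.DataFrame(
                {"chrom": df["chrom"], "start": df["start"], "end": df["start"] + 1}
            ).to_csv(fh, sep="\t", header=False, index=False),
        )
    write("truth.tsv", lambda fh: truth.to_csv(fh, sep="\t", index=False))
    return SimResult(out_dir=out_dir, files=files, truth=truth, config=config)


def read_expression(path) -> pd.Series:
    """Read a gene-expression TSV (gene_id, log2 signal) into a Series."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise ValueError("expression table needs two columns")
    s = pd.Series(df.iloc[:, 1].to_numpy(dtype=float), index=df.iloc[:, 0].astype(str))
    if s.index.has_duplicates:
        raise ValueError("duplicate gene ids in expression table")
    return s
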