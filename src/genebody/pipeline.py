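"""End-to-end meta-analysis pipeline.

Runs, in order: transcript merging; quintile metagene methylation profiles;
the 100-bin gene-body methylation regression (plus length-stratified
check); promoter-methylation vs CAGE-activity regressions for intronic and
canonical promoters; the intron initiation/silent partition and its
cross-class regression; genic vs intergenic methylation; Pol2/DNase density
vs expression regressions; and the joint body-methylation /
intronic-expression comparison with a low/high expression split.  Every
result lands in tidy tables and one machine-readable summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from contextlib import contextmanager
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import (
    GeneRegions,
    derive_regions,
    intergenic_complement,
    merge_transcripts,
    oriented_window,
    read_chrom_sizes,
    read_transcripts,
    write_loci_bed,
)
from .coverage import (
    TagSet,
    assign_clusters,
    intronic_cage_level,
    partition_introns,
    read_cage_clusters,
)
from .methylation import (
    CpGIndex,
    flank_body_summary,
    genic_vs_intergenic,
    metagene_profile,
    region_methylation,
)
from .simulate import read_expression
from .stats import (
    bin_regress,
    length_stratified,
    peak_bin,
    pearson,
    quantile_bins,
)

logger = logging.getLogger("genebody")

__all__ = ["RunConfig", "RunResult", "run_all", "compare_low_high"]


@dataclass
class RunConfig:
    """Inputs and parameters of one pipeline run."""

    transcripts: str
    meth: str
    expr: str
    chrom_sizes: str
    cage: str | None = None
    pol2: str | None = None
    dhss: str | None = None
    out_dir: str | None = None

    bins: int = 100
    quintiles: int = 5
    window: int = 100
    tss_up: int = 3000
    tss_down: int = 5000
    tts_up: int = 5000
    tts_down: int = 3000
    body_trim: int = 1000
    strand_aware: bool = True
    denominator: str = "intron"
    min_coverage: int = 1
    tss_promoter_halfwidth: int = 1000
    length_fraction: float = 0.2
    split: float = 0.5

    def manifest_hash(self) -> str:
        """Content-addressed run id: parameters plus input file bytes.

        Path strings and the output location are excluded, so the same data
        and parameters hash identically wherever they live on disk.
        """
        payload = asdict(self)
        inputs = ("transcripts", "meth", "expr", "chrom_sizes", "cage", "pol2", "dhss")
        for name in inputs + ("out_dir",):
            payload.pop(name)
        h = hashlib.sha1(json.dumps(payload, sort_keys=True).encode())
        for name in inputs:
            path = getattr(self, name)
            if path and Path(path).exists():
                h.update(name.encode())
                h.update(Path(path).read_bytes())
        return h.hexdigest()[:12]


@dataclass
class RunResult:
    summary: dict
    tables: dict[str, pd.DataFrame]
    per_gene: pd.DataFrame
    manifest: str


@contextmanager
def _stage(name: str):
    logger.info("stage %s", name)
    try:
        yield
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc


def _sanitize(obj):
    """Replace non-finite floats with None for strict-JSON output."""
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return float(obj) if math.isfinite(obj) else None
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def _per_gene_window_means(
    index: CpGIndex, regions: list[GeneRegions], windows: list[tuple[int, int] | None]
) -> np.ndarray:
    """Mean methylation of one window per gene (NaN when empty/None)."""
    out = np.full(len(regions), np.nan)
    by_chrom: dict[str, list[int]] = {}
    for i, (regs, win) in enumerate(zip(regions, windows)):
        if win is not None:
            by_chrom.setdefault(regs.chrom, []).append(i)
    for chrom, idxs in by_chrom.items():
        starts = np.array([windows[i][0] for i in idxs])
        ends = np.array([windows[i][1] for i in idxs])
        means, _ = index.window_stats(chrom, starts, ends)
        out[idxs] = means
    return out


def _tag_counts_per_gene(tags: TagSet, regions: list[GeneRegions]) -> np.ndarray:
    spans = [
        (min(r.tss, r.tts), max(r.tss, r.tts) + 1) for r in regions
    ]
    out = np.zeros(len(regions), dtype=np.int64)
    by_chrom: dict[str, list[int]] = {}
    for i, r in enumerate(regions):
        by_chrom.setdefault(r.chrom, []).append(i)
    for chrom, idxs in by_chrom.items():
        pos = tags._pos.get(chrom)
        if pos is None:
            continue
        starts = np.array([spans[i][0] for i in idxs])
        ends = np.array([spans[i][1] for i in idxs])
        out[idxs] = np.searchsorted(pos, ends, side="left") - np.searchsorted(
            pos, starts, side="left"
        )
    return out


def compare_low_high(
    expr: pd.Series,
    body_meth: pd.Series,
    intronic_cage: pd.Series,
    split: float = 0.5,
) -> pd.DataFrame:
    """Mean +- SE of body methylation and intronic initiation per expression group.

    Genes are ranked on expression and split at the ``split`` quantile
    (rank-based, stable id tie-break); each group needs at least two genes
    and the split must not be degenerate (constant expression).
    """
    if expr.nunique() <= 1:
        raise ValueError("degenerate split: expression is constant")
    ids = expr.index.to_numpy(dtype=object)
    order = np.lexsort((np.asarray([str(i) for i in ids]), expr.to_numpy(dtype=float)))
    n_low = int(len(expr) * split)
    groups = {"low": expr.index[order[:n_low]], "high": expr.index[order[n_low:]]}
    rows = []
    for name, sel in groups.items():
        if len(sel) < 2:
            raise ValueError(f"group '{name}' has fewer than 2 genes")
        row = {"group": name, "n": len(sel), "mean_log2_expression": float(expr.loc[sel].mean())}
        for label, series in (("body_meth", body_meth), ("intronic_cage", intronic_cage)):
            vals = series.reindex(sel).dropna().to_numpy(dtype=float)
            row[f"{label}_mean"] = float(vals.mean()) if len(vals) else float("nan")
            row[f"{label}_se"] = (
                float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else float("nan")
            )
            row[f"{label}_n"] = int(len(vals))
        rows.append(row)
    return pd.DataFrame(rows)


def run_all(config: RunConfig) -> RunResult:
    """Execute the full meta-analysis and (optionally) write every output."""
    summary: dict = {}
    tables: dict[str, pd.DataFrame] = {}
    manifest = config.manifest_hash()
    summary["manifest"] = manifest
    summary["parameters"] = asdict(config)

    with _stage("annotation"):
        transcripts = read_transcripts(Path(config.transcripts).read_text())
        chrom_sizes = read_chrom_sizes(config.chrom_sizes)
        loci = merge_transcripts(transcripts, strand_aware=config.strand_aware)
        regions_all = [
            derive_regions(
                locus,
                body_trim=config.body_trim,
                tss_up=config.tss_up,
                tss_down=config.tss_down,
                tts_up=config.tts_up,
                tts_down=config.tts_down,
                chrom_size=chrom_sizes.get(locus.span.chrom),
            )
            for locus in loci
        ]
        summary["n_transcripts"] = len(transcripts)
        summary["n_loci"] = len(loci)

    with _stage("methylation_index"):
        index = CpGIndex.from_tsv(config.meth, min_coverage=config.min_coverage)
        summary["n_cpg_sites"] = index.n_sites

    with _stage("expression"):
        expr_all = read_expression(config.expr)
        locus_ids = [l.id for l in loci]
        expr = expr_all.reindex(locus_ids).dropna()
        keep = set(expr.index)
        genes = [l for l in loci if l.id in keep]
        regions = [r for r in regions_all if r.locus_id in keep]
        expr = expr.loc[[r.locus_id for r in regions]]
        summary["n_genes_with_expression"] = len(expr)
        if len(expr) < 3:
            raise RuntimeError("fewer than 3 genes with expression data")

    # per-gene quantities reused across stages
    with _stage("per_gene_measures"):
        lengths = pd.Series(
            [l.length for l in genes], index=[l.id for l in genes], dtype=float
        )
        body_meth = pd.Series(
            _per_gene_window_means(index, regions, [r.body for r in regions]),
            index=expr.index,
        )
        prom_windows = [
            oriented_window(
                r.tss,
                r.strand if r.strand in "+-" else "+",
                -config.tss_promoter_halfwidth,
                config.tss_promoter_halfwidth,
                chrom_sizes.get(r.chrom),
            )
            for r in regions
        ]
        prom_meth = pd.Series(
            _per_gene_window_means(index, regions, prom_windows), index=expr.index
        )
        per_gene = pd.DataFrame(
            {
                "locus_id": expr.index,
                "log2_expression": expr.to_numpy(),
                "length": lengths.to_numpy(),
                "body_meth": body_meth.to_numpy(),
                "promoter_meth": prom_meth.to_numpy(),
            }
        ).set_index("locus_id")

    with _stage("figure1_metagene"):
        quint = quantile_bins(expr, config.quintiles)
        profile = metagene_profile(
            regions,
            index,
            quint.to_dict(),
            window=config.window,
            tss_up=config.tss_up,
            tss_down=config.tss_down,
            tts_up=config.tts_up,
            tts_down=config.tts_down,
            chrom_sizes=chrom_sizes,
        )
        tables["fig1_profile"] = profile
        tables["fig1_summary"] = flank_body_summary(regions, index, quint.to_dict())
        summary["figure1"] = {"quintiles": config.quintiles, "n_windows": int(len(profile))}

    with _stage("figure2_body_bell"):
        k2 = min(config.bins, len(expr))
        bins2, corr2 = bin_regress(expr, body_meth, k2)
        tables["fig2_bins"] = bins2.reset_index()
        gene_lvl = per_gene.dropna(subset=["body_meth"])
        summary["figure2"] = {
            "bin_level": corr2.as_dict(),
            "gene_level": pearson(
                gene_lvl["log2_expression"], gene_lvl["body_meth"]
            ).as_dict(),
            "k": k2,
            "peak_bin": peak_bin(bins2),
            "n_genes_with_body": int(body_meth.notna().sum()),
        }
        try:
            strata = length_stratified(
                lengths, expr, body_meth, fraction=config.length_fraction
            )
            summary["figure2"]["length_stratified"] = {
                name: {**corr.as_dict(), "k": k, "peak_bin": peak_bin(df)}
                for name, (df, corr, k) in strata.items()
            }
            for name, (df, _, _) in strata.items():
                tables[f"fig2_{name}"] = df.reset_index()
        except ValueError as exc:
            logger.warning("length stratification skipped: %s", exc)

    with _stage("tss_vs_expression"):
        k_tss = min(config.bins, len(expr))
        bins_t, corr_t = bin_regress(expr, prom_meth, k_tss)
        tables["tss_bins"] = bins_t.reset_index()
        summary["tss_promoter_vs_expression"] = {**corr_t.as_dict(), "k": k_tss}

    clusters = None
    if config.cage:
        with _stage("cage_assignment"):
            clusters = assign_clusters(read_cage_clusters(config.cage), regions)
            vals = np.full(len(clusters), np.nan)
            for chrom, sub in clusters.groupby("chrom"):
                means, _ = index.window_stats(
                    chrom, sub["start"].to_numpy(), sub["end"].to_numpy()
                )
                vals[sub.index.to_numpy()] = means
            clusters["meth"] = vals
    else:
        logger.warning("no CAGE input: skipping promoter, partition and joint stages")

    if clusters is not None:
        with _stage("figure3_promoter_activity"):
            summary["figure3"] = {}
            for cls in ("intronic", "canonical"):
                sub = clusters[
                    (clusters["cluster_class"] == cls) & clusters["meth"].notna()
                ]
                if len(sub) < 3:
                    logger.warning("figure3 %s skipped: %d usable clusters", cls, len(sub))
                    continue
                # tie-break key free of genomic orientation: host expression,
                # oriented TSS offset, width and tag count identify a cluster
                keys = [
                    f"{expr.get(r.locus_id, float('nan'))!r}|{int(r.tss_offset)}|"
                    f"{r.end - r.start}|{r.tag_count}"
                    for r in sub.itertuples(index=False)
                ]
                x = pd.Series(np.log2(sub["activity"].to_numpy(dtype=float)), index=keys)
                y = pd.Series(sub["meth"].to_numpy(), index=keys)
                k3 = min(config.bins, len(sub))
                bins3, corr3 = bin_regress(x, y, k3)
                tables[f"fig3_{cls}"] = bins3.reset_index()
                summary["figure3"][cls] = {
                    **corr3.as_dict(),
                    "k": k3,
                    "n_clusters": int(len(sub)),
                }

        with _stage("figure4_intron_partition"):
            rows = []
            for regs in regions:
                if not regs.introns:
                    continue
                spans = clusters[
                    (clusters["locus_id"] == regs.locus_id)
                    & (clusters["cluster_class"] == "intronic")
                ]
                part = partition_introns(
                    list(regs.introns), list(zip(spans["start"], spans["end"]))
                )
                m_init = region_methylation(index, {regs.chrom: list(part.initiation)})
                m_sil = region_methylation(index, {regs.chrom: list(part.silent)})
                rows.append(
                    {
                        "locus_id": regs.locus_id,
                        "fraction_initiation": part.fraction_initiation,
                        "meth_initiation": m_init.mean_percent,
                        "meth_silent": m_sil.mean_percent,
                        "n_clusters": int(len(spans)),
                    }
                )
            fig4 = pd.DataFrame(rows).set_index("locus_id")
            tables["fig4_genes"] = fig4.reset_index()
            summary["figure4"] = {
                "n_genes_with_introns": int(len(fig4)),
                "fraction_initiation_mean": float(fig4["fraction_initiation"].mean())
                if len(fig4)
                else None,
            }
            both = fig4.dropna(subset=["meth_initiation", "meth_silent"])
            if len(both) >= 3:
                k4 = min(config.bins, len(both))
                bins4, corr4 = bin_regress(
                    both["meth_silent"], both["meth_initiation"], k4
                )
                tables["fig4_bins"] = bins4.reset_index()
                summary["figure4"]["cross_class"] = {**corr4.as_dict(), "k": k4}
            else:
                logger.warning("figure4 cross-class regression skipped: %d genes", len(both))

    with _stage("figure5_genic_intergenic"):
        summary["figure5"] = genic_vs_intergenic(index, loci, chrom_sizes)
        # also expose total intergenic span for context
        inter = intergenic_complement(loci, chrom_sizes)
        summary["figure5"]["intergenic_bp"] = int(sum(len(iv) for iv in inter))

    with _stage("figure6_chromatin"):
        summary["figure6"] = {}
        for name, path in (("pol2", config.pol2), ("dhss", config.dhss)):
            if not path:
                logger.warning("no %s input: skipping its density regression", name)
                continue
            tagset = TagSet.from_bed(path, name)
            counts = _tag_counts_per_gene(tagset, regions)
            density = pd.Series(counts / lengths.to_numpy(), index=expr.index)
            per_gene[f"{name}_density"] = density.to_numpy()
            k6 = min(config.bins, len(expr))
            bins6, corr6 = bin_regress(expr, density, k6)
            tables[f"fig6_{name}"] = bins6.reset_index()
            summary["figure6"][name] = {
                **corr6.as_dict(),
                "k": k6,
                "n_tags": int(tagset.n_tags),
            }

    if clusters is not None:
        with _stage("figure8_joint"):
            icage = pd.Series(
                [
                    intronic_cage_level(regs, clusters, config.denominator)
                    for regs in regions
                ],
                index=expr.index,
            )
            per_gene["intronic_cage"] = icage.to_numpy()
            k8 = min(config.bins, len(expr))
            bins_m, _ = bin_regress(expr, body_meth, k8)
            bins_c, _ = bin_regress(expr, icage, k8)
            joint = pd.DataFrame(
                {
                    "mean_log2_expression": bins_m["mean_x"],
                    "mean_body_meth": bins_m["mean_y"],
                    "mean_intronic_cage": bins_c["mean_y"],
                }
            )
            tables["fig8_bins"] = joint.reset_index()
            groups = compare_low_high(expr, body_meth, icage, split=config.split)
            tables["fig8_groups"] = groups
            summary["figure8"] = {
                "split": config.split,
                "groups": {
                    row["group"]: {k: row[k] for k in row.index if k != "group"}
                    for _, row in groups.iterrows()
                },
            }

    summary = _sanitize(summary)
    result = RunResult(summary=summary, tables=tables, per_gene=per_gene, manifest=manifest)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_loci_bed(loci, out / "loci.bed", header=f"manifest={manifest}")
        for name, df in tables.items():
            with open(out / f"{name}.tsv", "w") as fh:
                fh.write(f"# manifest={manifest}\n")
                df.to_csv(fh, sep="\t", index=False)
        with open(out / "per_gene.tsv", "w") as fh:
            fh.write(f"# manifest={manifest}\n")
            per_gene.to_csv(fh, sep="\t")
        (out / "summary.json").write_text(
            json.dumps(summary, sort_keys=True, indent=2) + "\n"
        )
    return result
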