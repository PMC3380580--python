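"""Quantile binning of genes and Pearson regression on bin means.

Genes are ranked on a scalar (log2 expression, methylation, CAGE activity),
split into k equal-count bins (bin 1 = lowest), per-bin means of a second
variable are taken missing-aware, and the product-moment correlation of the
bin means is reported with a two-sided p-value from the t transform
``t = r * sqrt((n-2) / (1-r^2))`` on n-2 degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "quantile_bins",
    "bin_sizes",
    "bin_aggregate",
    "pearson",
    "bin_regress",
    "length_stratified",
    "peak_bin",
    "bin_containing",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r, two-sided significance and the number of points used."""

    r: float
    p: float
    n: int

    def as_dict(self) -> dict:
        return {"r": self.r, "p": self.p, "n": self.n}


def bin_sizes(n: int, k: int) -> list[int]:
    """Equal-count bin sizes; the remainder goes to the lowest bins."""
    base, rem = divmod(n, k)
    return [base + 1] * rem + [base] * (k - rem)


def quantile_bins(values: pd.Series, k: int) -> pd.Series:
    """Assign each gene to one of k ranked equal-count bins.

    Genes are sorted ascending by value with a stable tie-break on the gene
    id, then cut into k contiguous groups whose sizes differ by at most one
    (bin 1 = lowest values).  The assignment is invariant to input order.
    """
    n = len(values)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot form {k} bins from {n} genes")
    if not np.isfinite(values.to_numpy(dtype=float)).all():
        raise ValueError("non-finite ranking values")
    ids = values.index.to_numpy(dtype=object)
    order = np.lexsort((np.asarray([str(i) for i in ids]), values.to_numpy(dtype=float)))
    assignment = np.empty(n, dtype=np.int64)
    pos = 0
    for b, size in enumerate(bin_sizes(n, k), start=1):
        assignment[order[pos : pos + size]] = b
        pos += size
    return pd.Series(assignment, index=values.index, name="bin")


def bin_aggregate(
    assignment: pd.Series, x: pd.Series, y: pd.Series
) -> pd.DataFrame:
    """Per-bin mean_x (all members) and missing-aware mean_y.

    Returns a frame indexed 1..k with columns n, mean_x, n_y, mean_y;
    mean_y is NaN for bins whose members are all missing in y.
    """
    df = pd.DataFrame(
        {"bin": assignment, "x": x.reindex(assignment.index), "y": y.reindex(assignment.index)}
    )
    g = df.groupby("bin")
    out = pd.DataFrame(
        {
            "n": g["x"].size(),
            "mean_x": g["x"].mean(),
            "n_y": g["y"].count(),
            "mean_y": g["y"].mean(),
        }
    )
    out.index.name = "bin"
    return out


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation with a two-sided t-test p-value.

    Raises on fewer than three points or on constant input (the correlation
    is undefined there, not zero).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 points for a correlation, got {n}")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("undefined correlation: constant input")
    r = float(xc @ yc) / (sx * sy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return CorrelationResult(r=r, p=p, n=n)


def bin_regress(
    x: pd.Series, y: pd.Series, k: int = 100
) -> tuple[pd.DataFrame, CorrelationResult]:
    """Quantile-bin genes on x, then correlate the (mean_x, mean_y) bin means.

    Bins with no non-missing y are skipped; fewer than three usable bins is
    an error.  Returns the per-bin summary and the correlation result.
    """
    assignment = quantile_bins(x, k)
    summary = bin_aggregate(assignment, x, y)
    usable = summary.dropna(subset=["mean_y"])
    if len(usable) < 3:
        raise ValueError(f"only {len(usable)} usable bins (need >= 3)")
    corr = pearson(usable["mean_x"].to_numpy(), usable["mean_y"].to_numpy())
    return summary, corr


def length_stratified(
    lengths: pd.Series,
    x: pd.Series,
    y: pd.Series,
    fraction: float = 0.2,
    min_bins: int = 10,
) -> dict[str, tuple[pd.DataFrame, CorrelationResult, int]]:
    """Re-run the binned regression in the shortest and longest gene strata.

    Takes the bottom and top ``fraction`` of genes by length (stable id
    tie-break) and runs :func:`bin_regress` in each with
    ``k = max(min_bins, n_stratum // 20)``.
    """
    n = len(lengths)
    n_strat = int(n * fraction)
    ids = lengths.index.to_numpy(dtype=object)
    order = np.lexsort((np.asarray([str(i) for i in ids]), lengths.to_numpy(dtype=float)))
    k = max(min_bins, n_strat // 20)
    if n_strat < max(k, 3):
        raise ValueError(f"stratum of {n_strat} genes too small for {k} bins")
    out = {}
    for name, idx in (("short", order[:n_strat]), ("long", order[-n_strat:])):
        sel = lengths.index[idx]
        summary, corr = bin_regress(x.loc[sel], y.loc[sel], k)
        out[name] = (summary, corr, k)
    return out


def peak_bin(summary: pd.DataFrame, column: str = "mean_y", smooth: int = 11) -> int:
    """Bin index at the maximum of a lightly smoothed bin-mean curve.

    A centred moving average (window ``smooth`` bins, NaN-aware, shrinking at
    the edges) suppresses bin-level noise before the argmax; ``smooth=1``
    gives the raw argmax.
    """
    values = summary[column].to_numpy(dtype=float)
    bins = summary.index.to_numpy()
    half = smooth // 2
    smoothed = np.full(len(values), np.nan)
    for i in range(len(values)):
        window = values[max(0, i - half) : i + half + 1]
        if np.any(~np.isnan(window)):
            smoothed[i] = np.nanmean(window)
    if np.all(np.isnan(smoothed)):
        raise ValueError("no usable bins")
    return int(bins[int(np.nanargmax(smoothed))])


def bin_containing(values: pd.Series, v: float, k: int) -> int:
    """Which quantile bin a hypothetical value v would fall into.

    Uses the same size rule as :func:`quantile_bins`; v below/above the data
    range maps to the first/last bin.
    """
    arr = np.sort(values.to_numpy(dtype=float))
    rank = int(np.searchsorted(arr, v, side="left"))
    rank = min(rank, len(arr) - 1)
    cum = 0
    for b, size in enumerate(bin_sizes(len(arr), k), start=1):
        cum += size
        if rank < cum:
            return b
    return k
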