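"""Composition statistics that discriminate transposon traps from reference regions.

Two signals separate a region that silences its carriers (a trap) from a
neutral reference region of equal size: the distribution of per-individual
copy counts is much narrower in traps, and the per-family (per-replicate)
trap abundance is uncorrelated with the abundance in the rest of the genome,
whereas reference-region abundance correlates strongly.

The same operators run on simulated ensembles (one row per individual,
pooled over replicates) and on empirical per-family copy-number tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

__all__ = [
    "TailReport",
    "CorrelationReport",
    "region_counts",
    "tail_fractions",
    "kendall_tau",
    "correlation_report",
    "abundance_histogram",
]

REGIONS = ("trap", "reference")


@dataclass
class TailReport:
    """Fractions of rows below/above count thresholds (strict inequalities)."""

    frac_below_low: float
    frac_above_high: float
    low: float
    high: float
    n: int


@dataclass
class CorrelationReport:
    """Kendall tau-b between a region's counts and the rest of the genome."""

    tau: float
    p_value: float
    n: int
    region: str = ""
    undefined: bool = False


def region_counts(ensemble, arch=None) -> pd.DataFrame:
    """Assemble per-individual diploid counts from an ensemble of replicates.

    Returns one row per individual per replicate with columns
    ``replicate``, ``trap_count``, ``reference_count``, ``genome_count``.
    Counts are diploid; divide by 2 for per-haploid values.
    """
    if not ensemble:
        raise ValueError("ensemble is empty")
    frames = []
    for rep in ensemble:
        frames.append(
            pd.DataFrame(
                {
                    "replicate": rep.replicate_id,
                    "trap_count": rep.trap_counts,
                    "reference_count": rep.reference_counts,
                    "genome_count": rep.genome_counts,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _region_column(matrix: pd.DataFrame, region: str) -> pd.Series:
    col = f"{region}_count"
    if col not in matrix.columns:
        raise KeyError(f"no column {col!r}; region must be one of {REGIONS}")
    return matrix[col]


def tail_fractions(matrix: pd.DataFrame, region: str, low: float = 1, high: float = 14) -> TailReport:
    """Fractions of individuals with fewer than ``low`` / more than ``high``
    insertions in the region (strict inequalities, paper defaults 1 and 14)."""
    if len(matrix) == 0:
        raise ValueError("matrix is empty")
    counts = _region_column(matrix, region).to_numpy()
    return TailReport(
        frac_below_low=float((counts < low).mean()),
        frac_above_high=float((counts > high).mean()),
        low=low,
        high=high,
        n=len(counts),
    )


def kendall_tau(x, y, region: str = "") -> CorrelationReport:
    """Kendall tau-b (tie-corrected) with a two-sided p-value.

    scipy computes the exact null distribution for small untied samples and
    the normal approximation otherwise.  A constant input leaves tau
    undefined; the result is flagged rather than raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationReport(float("nan"), float("nan"), x.size, region, undefined=True)
    res = _scipy_stats.kendalltau(x, y)
    return CorrelationReport(float(res.statistic), float(res.pvalue), x.size, region)


def correlation_report(matrix_or_table: pd.DataFrame, region: str = "trap") -> CorrelationReport:
    """Kendall correlation between region abundance and the rest of the genome.

    For a simulated matrix (columns ``replicate``, ``*_count``,
    ``genome_count``) each replicate contributes one point: its mean
    per-haploid region count against its mean per-haploid count over the rest
    of the genome (genome minus the focal region).  For an empirical family
    table (columns ``cluster_count``, ``non_cluster_count``) each family is
    one point.
    """
    df = matrix_or_table
    if {"cluster_count", "non_cluster_count"}.issubset(df.columns):
        return kendall_tau(df["cluster_count"], df["non_cluster_count"], region="cluster")
    per_rep = df.groupby("replicate")[[f"{region}_count", "genome_count"]].mean()
    region_mean = per_rep[f"{region}_count"] / 2.0
    rest_mean = (per_rep["genome_count"] - per_rep[f"{region}_count"]) / 2.0
    return kendall_tau(region_mean, rest_mean, region=region)


def abundance_histogram(
    matrix_or_values,
    region: str = "trap",
    bin_width: float = 1.0,
    truncate_at: float | None = None,
) -> pd.DataFrame:
    """Histogram of per-haploid copy counts (columns ``bin``, ``mass``).

    Masses are normalised before any truncation, so a truncated histogram
    (a display convenience) sums to less than 1 by the trimmed tail mass.
    Diploid matrix counts are halved; a bare sequence of values is binned
    as given.
    """
    if isinstance(matrix_or_values, pd.DataFrame):
        values = _region_column(matrix_or_values, region).to_numpy() / 2.0
    else:
        values = np.asarray(matrix_or_values, dtype=float)
    if values.size == 0:
        raise ValueError("no values to bin")
    bins = np.floor(values / bin_width) * bin_width
    uniq, counts = np.unique(bins, return_counts=True)
    hist = pd.DataFrame({"bin": uniq, "mass": counts / values.size})
    if truncate_at is not None:
        hist = hist[hist["bin"] <= truncate_at].reset_index(drop=True)
    return hist
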