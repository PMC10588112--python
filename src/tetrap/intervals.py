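"""Interval rules and copy-number tables for piRNA-cluster composition analysis.

Implements the bespoke empirical-side operators: merging and neighbour-joining
of cluster annotations, lift-over of clusters from flanking-sequence hits,
filtering of TE annotations, and conversion of population insertion-frequency
tables into per-family haploid copy numbers inside and outside clusters.

Coordinates are 0-based half-open throughout; GFF-style 1-based closed input
must be shifted on ingest (``read_bed`` reads BED as-is).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "merge_overlapping",
    "join_protrac_neighbors",
    "region_between_flanks",
    "tas_cluster",
    "filter_te_annotations",
    "family_copy_table",
    "freqtable_to_haploid_counts",
    "average_tables",
    "read_bed",
    "write_bed",
    "read_te_table",
    "read_frequency_table",
]

TE_COLUMNS = ["chrom", "start", "end", "strand", "family", "divergence", "consensus_length"]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval."""

    chrom: str
    start: int
    end: int
    name: str = field(default="", compare=False)

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty or inverted interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


def merge_overlapping(intervals) -> list:
    """Minimal sorted set of disjoint intervals covering the same base pairs.

    Overlapping and book-ended intervals are merged (bedtools-merge
    semantics).
    """
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if merged and iv.chrom == merged[-1].chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end, last.name)
        else:
            merged.append(iv)
    return merged


def join_protrac_neighbors(clusters) -> list:
    """Join neighbouring clusters closer than their combined lengths.

    Adjacent clusters a, b on one chromosome are replaced by their span
    whenever ``gap(a, b) < len(a) + len(b)``; the rule is applied repeatedly
    until no pair qualifies.
    """
    current = merge_overlapping(clusters)
    changed = True
    while changed:
        changed = False
        out: list[GenomicInterval] = []
        for iv in current:
            if out and iv.chrom == out[-1].chrom:
                prev = out[-1]
                gap = iv.start - prev.end
                if gap < prev.length + iv.length:
                    out[-1] = GenomicInterval(prev.chrom, prev.start, iv.end, prev.name)
                    changed = True
                    continue
            out.append(iv)
        current = out
    return current


def region_between_flanks(flank_pairs):
    """Annotate clusters as the regions between pairs of aligned flanks.

    Each pair is ``(left, right)`` of :class:`GenomicInterval` alignment hits;
    the cluster spans from the end of the left flank to the start of the
    right flank.  Pairs on different chromosomes or in inverted orientation
    cannot be resolved and are returned separately.

    Returns ``(clusters, unresolved)``.
    """
    clusters, unresolved = [], []
    for left, right in flank_pairs:
        if left.chrom != right.chrom or right.start <= left.end:
            unresolved.append((left, right))
            continue
        name = left.name or right.name
        clusters.append(GenomicInterval(left.chrom, left.end, right.start, name))
    return clusters, unresolved


def tas_cluster(distal_gene: GenomicInterval, contig_length: int) -> GenomicInterval:
    """Telomeric cluster: the region between the most distal gene and the contig end."""
    if distal_gene.end >= contig_length:
        raise ValueError("distal gene reaches the contig end; no region remains")
    return GenomicInterval(distal_gene.chrom, distal_gene.end, contig_length, "TAS")


# ---------------------------------------------------------------------------
# TE annotation tables


def filter_te_annotations(
    tes: pd.DataFrame,
    min_length: int = 100,
    max_divergence: float = 10.0,
    family_whitelist=None,
    full_length_only: bool = False,
    full_length_fraction: float = 0.95,
) -> pd.DataFrame:
    """Filter a TE annotation table.

    Keeps insertions of at least ``min_length`` bp (inclusive) diverged at
    most ``max_divergence`` percent (inclusive) from the family consensus.
    ``family_whitelist`` restricts to germline-active families;
    ``full_length_only`` additionally requires
    ``length >= full_length_fraction * consensus_length``.
    """
    length = tes["end"] - tes["start"]
    keep = (length >= min_length) & (tes["divergence"] <= max_divergence)
    if family_whitelist is not None:
        keep &= tes["family"].isin(set(family_whitelist))
    if full_length_only:
        keep &= length >= full_length_fraction * tes["consensus_length"]
    return tes[keep].reset_index(drop=True)


def _cluster_bounds(clusters) -> dict:
    """Per-chromosome sorted half-open boundary arrays for membership tests."""
    by_chrom: dict[str, list] = {}
    for iv in merge_overlapping(clusters):
        by_chrom.setdefault(iv.chrom, []).extend((iv.start, iv.end))
    return {c: np.asarray(b, dtype=np.int64) for c, b in by_chrom.items()}


def points_in_clusters(chroms, positions, clusters) -> np.ndarray:
    """Boolean membership of (chrom, position) points in cluster intervals."""
    bounds = _cluster_bounds(clusters)
    chroms = np.asarray(chroms)
    positions = np.asarray(positions, dtype=np.int64)
    inside = np.zeros(len(positions), dtype=bool)
    for chrom, b in bounds.items():
        m = chroms == chrom
        if m.any():
            inside[m] = (np.searchsorted(b, positions[m], side="right") & 1) == 1
    return inside


def family_copy_table(tes: pd.DataFrame, clusters) -> pd.DataFrame:
    """Per-family haploid copy counts inside and outside clusters.

    A TE is inside a cluster when its midpoint falls in a cluster interval
    (annotations may straddle cluster edges).  Assembly-derived annotations
    are already per haploid genome.  Families with zero cluster copies stay
    in the table.  Returns a DataFrame indexed by family with columns
    ``cluster_count`` and ``non_cluster_count``.
    """
    mid = (tes["start"] + tes["end"]) // 2
    inside = points_in_clusters(tes["chrom"].to_numpy(), mid.to_numpy(), clusters)
    table = (
        pd.DataFrame({"family": tes["family"], "inside": inside})
        .groupby("family")["inside"]
        .agg(cluster_count="sum", non_cluster_count=lambda s: int((~s).sum()))
    )
    return table.astype(float)


def freqtable_to_haploid_counts(
    records: pd.DataFrame,
    clusters,
    min_frequency: float = 0.3,
    het_cutoff: float = 0.6,
) -> pd.DataFrame:
    """Convert population insertion frequencies to haploid copy numbers.

    Insertions below ``min_frequency`` are discarded as unreliable or
    somatic; frequencies in ``[min_frequency, het_cutoff)`` are taken as
    heterozygous and contribute 0.5 copies; frequencies >= ``het_cutoff`` as
    homozygous contribute 1.0.  Contributions are summed per family inside
    and outside clusters.
    """
    f = records["frequency"].to_numpy(dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    weight = np.where(f < min_frequency, 0.0, np.where(f < het_cutoff, 0.5, 1.0))
    inside = points_in_clusters(records["chrom"].to_numpy(), records["pos"].to_numpy(), clusters)
    df = pd.DataFrame(
        {
            "family": records["family"],
            "cluster_count": np.where(inside, weight, 0.0),
            "non_cluster_count": np.where(inside, 0.0, weight),
        }
    )
    return df.groupby("family")[["cluster_count", "non_cluster_count"]].sum()


def average_tables(tables, absent_as_missing: bool = True) -> pd.DataFrame:
    """Average per-strain family count tables.

    With ``absent_as_missing`` (default) a family absent from a strain's
    table is excluded from that family's mean — only strains where the
    family is actually present contribute — rather than counted as zero.
    """
    if not tables:
        raise ValueError("need at least one table")
    stacked = pd.concat(tables)
    if not absent_as_missing:
        families = stacked.index.unique()
        tables = [t.reindex(families, fill_value=0.0) for t in tables]
        stacked = pd.concat(tables)
    return stacked.groupby(level=0)[["cluster_count", "non_cluster_count"]].mean()


# ---------------------------------------------------------------------------
# readers / writers


def read_bed(path) -> list:
    """Read BED intervals (first three or four columns)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            name = parts[3] if len(parts) > 3 else ""
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]), name))
    return out


def write_bed(intervals, path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")


def read_te_table(path) -> pd.DataFrame:
    """Tab-separated TE annotation table with columns
    chrom, start, end, strand, family, divergence, consensus_length."""
    df = pd.read_csv(path, sep="\t")
    missing = set(TE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"TE table misses columns: {sorted(missing)}")
    return df


def read_frequency_table(path) -> pd.DataFrame:
    """Tab-separated insertion-frequency table: family, chrom, pos, frequency."""
    df = pd.read_csv(path, sep="\t")
    missing = {"family", "chrom", "pos", "frequency"} - set(df.columns)
    if missing:
        raise ValueError(f"frequency table misses columns: {sorted(missing)}")
    return df
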