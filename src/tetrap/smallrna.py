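"""Dispersed piRNA source loci (DSL) and ping-pong signatures from small-RNA reads.

A TE insertion outside piRNA clusters that itself produces piRNAs leaves an
asymmetric footprint: antisense piRNAs upstream of the insertion and sense
piRNAs downstream (both in the insertion's orientation).  ``detect_dsl``
scans TE flanks for that footprint; ``control_dsl_rate`` applies the same
criteria to conserved genes, which should not produce piRNAs, to estimate
the false-positive rate.  Ping-pong amplification is summarised by the
Z-score of the 10-nt 5'-5' overlap between sense and antisense reads mapped
to a family's consensus sequence.

Reads are rows of a DataFrame with columns chrom, start, end (0-based
half-open), strand, length, mapq and ncrna (pre-matched against
miRNA/rRNA/snRNA/snoRNA/tRNA/mRNA references upstream).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "READ_COLUMNS",
    "PingPongResult",
    "filter_pirna_reads",
    "five_prime_positions",
    "flank_signature",
    "detect_dsl",
    "control_dsl_rate",
    "pingpong_overlap_histogram",
    "pingpong_z",
    "read_table",
    "read_sam",
]

READ_COLUMNS = ["chrom", "start", "end", "strand", "length", "mapq", "ncrna"]

OVERLAP_OFFSETS = np.arange(1, 21)


def filter_pirna_reads(
    reads: pd.DataFrame,
    min_len: int = 23,
    max_len: int = 29,
    min_mapq: int = 5,
) -> pd.DataFrame:
    """Keep piRNA-sized (23-29 nt inclusive), uniquely mapping (mapq >= 5),
    non-ncRNA reads."""
    keep = (
        reads["length"].between(min_len, max_len)
        & (reads["mapq"] >= min_mapq)
        & ~reads["ncrna"].astype(bool)
    )
    return reads[keep].reset_index(drop=True)


def five_prime_positions(reads: pd.DataFrame) -> np.ndarray:
    """Genomic position of each read's 5' end (start on +, end-1 on -)."""
    plus = reads["strand"].to_numpy() == "+"
    return np.where(plus, reads["start"].to_numpy(), reads["end"].to_numpy() - 1)


class _ReadIndex:
    """5' positions sorted per (chrom, strand) for fast window counts."""

    def __init__(self, reads: pd.DataFrame):
        reads = reads.reset_index(drop=True)
        p5 = five_prime_positions(reads)
        self._index: dict[tuple, np.ndarray] = {}
        grouped = pd.Series(p5).groupby([reads["chrom"].to_numpy(), reads["strand"].to_numpy()])
        for key, vals in grouped:
            self._index[key] = np.sort(vals.to_numpy())

    def count(self, chrom: str, strand: str, start: int, end: int) -> int:
        """Reads on ``strand`` whose 5' end lies in [start, end)."""
        pos = self._index.get((chrom, strand))
        if pos is None or end <= start:
            return 0
        return int(np.searchsorted(pos, end) - np.searchsorted(pos, start))


def flank_signature(
    feature,
    reads: pd.DataFrame | _ReadIndex,
    flank: int = 500,
    library_size: int | None = None,
) -> tuple[float, float]:
    """(upstream antisense rpm, downstream sense rpm) around an oriented feature.

    Upstream/downstream and sense/antisense are defined in the feature's
    orientation: for a +-strand feature the upstream window is
    ``[start - flank, start)`` counting −-strand reads and the downstream
    window ``[end, end + flank)`` counting +-strand reads; both flip for a
    −-strand feature.  A read belongs to a window when its 5' end lies in it.
    Windows are truncated at position 0; rpm = count * 1e6 / library_size.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    index = reads if isinstance(reads, _ReadIndex) else _ReadIndex(reads)
    if library_size is None:
        raise ValueError("library_size is required for rpm normalisation")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    chrom, start, end, strand = feature["chrom"], feature["start"], feature["end"], feature["strand"]
    if strand == "+":
        up = index.count(chrom, "-", max(0, start - flank), start)
        down = index.count(chrom, "+", end, end + flank)
    elif strand == "-":
        up = index.count(chrom, "+", end, end + flank)
        down = index.count(chrom, "-", max(0, start - flank), start)
    else:
        raise ValueError(f"feature needs a +/- strand, got {strand!r}")
    scale = 1e6 / library_size
    return up * scale, down * scale


def detect_dsl(
    tes: pd.DataFrame,
    clusters,
    reads: pd.DataFrame,
    flank: int = 500,
    min_rpm: float = 5.0,
    library_size: int | None = None,
) -> pd.DataFrame:
    """Call dispersed piRNA source loci among TE insertions.

    A TE is a DSL when its upstream-antisense and downstream-sense flank
    signals each reach ``min_rpm`` reads per million and the TE (by midpoint)
    lies outside every cluster interval.  ``reads`` must already be
    piRNA-filtered; ``library_size`` defaults to the number of those reads.

    Returns the TE table with columns ``upstream_antisense_rpm``,
    ``downstream_sense_rpm``, ``in_cluster`` and ``is_dsl`` appended.
    """
    from .intervals import points_in_clusters

    if library_size is None:
        library_size = len(reads)
    index = _ReadIndex(reads)
    up = np.empty(len(tes))
    down = np.empty(len(tes))
    for i, (_, te) in enumerate(tes.iterrows()):
        up[i], down[i] = flank_signature(te, index, flank=flank, library_size=library_size)
    mid = ((tes["start"] + tes["end"]) // 2).to_numpy()
    in_cluster = points_in_clusters(tes["chrom"].to_numpy(), mid, clusters)
    out = tes.reset_index(drop=True).copy()
    out["upstream_antisense_rpm"] = up
    out["downstream_sense_rpm"] = down
    out["in_cluster"] = in_cluster
    out["is_dsl"] = (up >= min_rpm) & (down >= min_rpm) & ~in_cluster
    return out


def control_dsl_rate(
    genes: pd.DataFrame,
    reads: pd.DataFrame,
    flank: int = 500,
    min_rpm: float = 5.0,
    library_size: int | None = None,
    min_gene_length: int = 100,
) -> float:
    """False-positive DSL rate over conserved genes (>= 100 bp).

    Applies the DSL flank criteria (without the cluster exclusion) to genes
    that should not produce piRNAs; returns the fraction of genes passing.
    """
    if library_size is None:
        library_size = len(reads)
    genes = genes[(genes["end"] - genes["start"]) >= min_gene_length]
    if len(genes) == 0:
        raise ValueError("no genes pass the length filter")
    index = _ReadIndex(reads)
    hits = 0
    for _, gene in genes.iterrows():
        up, down = flank_signature(gene, index, flank=flank, library_size=library_size)
        hits += bool(up >= min_rpm and down >= min_rpm)
    return hits / len(genes)


# ---------------------------------------------------------------------------
# ping-pong signatures


def pingpong_overlap_histogram(sense_reads: pd.DataFrame, antisense_reads: pd.DataFrame) -> np.ndarray:
    """Counts of sense/antisense read pairs at each 5'-5' overlap of 1..20 nt.

    Both tables hold reads mapped to one consensus sequence.  A pair overlaps
    by ``o`` nucleotides when the antisense read's 5' end sits at the sense
    read's 5' end plus ``o - 1`` (so a 10-nt ping-pong overlap places the
    antisense 5' end 9 nt downstream of the sense 5' end).

    Returns an array of length 20; index ``o - 1`` holds the count for
    overlap ``o``.
    """
    hist = np.zeros(len(OVERLAP_OFFSETS), dtype=np.int64)
    if len(sense_reads) == 0 or len(antisense_reads) == 0:
        return hist
    s5, s_mult = np.unique(five_prime_positions(sense_reads), return_counts=True)
    a5, a_mult = np.unique(five_prime_positions(antisense_reads), return_counts=True)
    for i, o in enumerate(OVERLAP_OFFSETS):
        target = s5 + o - 1
        j = np.clip(np.searchsorted(a5, target), 0, len(a5) - 1)
        match = a5[j] == target
        hist[i] = int((s_mult[match] * a_mult[j[match]]).sum())
    return hist


@dataclass
class PingPongResult:
    z10: float
    histogram: np.ndarray
    undefined: bool = False


def pingpong_z(histogram) -> PingPongResult:
    """Z-score of the 10-nt overlap against the other offsets.

    ``z10 = (c10 - mean(background)) / sd(background)`` with the background
    being offsets 1..20 except 10 and sd the sample standard deviation
    (ddof=1).  A constant background leaves the score undefined (flagged).
    """
    hist = np.asarray(histogram, dtype=float)
    if hist.shape != (20,):
        raise ValueError("histogram must cover overlaps 1..20")
    c10 = hist[9]
    background = np.delete(hist, 9)
    sd = background.std(ddof=1)
    if sd == 0:
        if c10 == background.mean():  # flat histogram: no enrichment
            return PingPongResult(0.0, hist)
        return PingPongResult(float("nan"), hist, undefined=True)
    return PingPongResult(float((c10 - background.mean()) / sd), hist)


# ---------------------------------------------------------------------------
# readers


def read_table(path) -> pd.DataFrame:
    """Tab-separated read table with columns chrom, start, end, strand,
    length, mapq, ncrna (0/1)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(READ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"read table misses columns: {sorted(missing)}")
    df["ncrna"] = df["ncrna"].astype(bool)
    return df


def read_sam(path) -> pd.DataFrame:
    """Read aligned small-RNA records from SAM/BAM (mapped primary records).

    The ncRNA flag cannot be carried in a plain alignment file and is set to
    False; pre-filter such reads upstream or supply a read table instead.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            rows.append(
                (
                    rec.reference_name,
                    rec.reference_start,
                    rec.reference_end,
                    "-" if rec.is_reverse else "+",
                    rec.query_length or rec.infer_query_length() or 0,
                    rec.mapping_quality,
                    False,
                )
            )
    return pd.DataFrame(rows, columns=READ_COLUMNS)
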