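"""Synthetic empirical-side data with planted ground truth.

Stand-ins for the processed strain data: TE annotation tables, cluster
intervals, insertion-frequency tables, and strand-resolved small-RNA reads
with planted dispersed-source-locus (DSL) asymmetry and ping-pong overlap
structure.  Every generated record traces to a truth entry, so each pipeline
statistic has a closed-form expected value.

The default genome layout mirrors the simulator's: 5 chromosomes of 10 Mb
with clusters at the chromosome starts.  Coordinates and labels only — no
sequence is generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .smallrna import READ_COLUMNS

__all__ = [
    "SyntheticTruth",
    "default_layout",
    "synth_annotations",
    "synth_freq_table",
    "synth_small_rna",
    "synth_pingpong_reads",
]


@dataclass
class SyntheticTruth:
    """Planted ground truth behind a batch of synthetic records."""

    seed: int
    clusters: list = field(default_factory=list)
    te_annotations: pd.DataFrame | None = None
    family_counts: dict = field(default_factory=dict)  # family -> (inside, outside)
    dsl_flags: pd.Series | None = None  # aligned with te_annotations rows
    library_size: int | None = None
    pingpong_signal: dict = field(default_factory=dict)  # family -> signal fraction


def default_layout(n_chrom: int = 5, chrom_length: int = 10_000_000, cluster_fraction: float = 0.035):
    """Cluster intervals at the start of each chromosome (simulator-like layout)."""
    span = round(cluster_fraction * chrom_length)
    clusters = [GenomicInterval(f"chr{c + 1}", 0, span, f"cluster{c + 1}") for c in range(n_chrom)]
    chrom_sizes = {f"chr{c + 1}": chrom_length for c in range(n_chrom)}
    return clusters, chrom_sizes


def _place_uniform(rng, n, intervals, te_len, chrom_sizes, inside: bool):
    """Uniform placements of midpoints inside (or outside) the intervals."""
    chroms, starts = [], []
    if inside:
        spans = [(iv.chrom, iv.start, iv.end) for iv in intervals]
        weights = np.array([e - s for _, s, e in spans], dtype=float)
        pick = rng.choice(len(spans), size=n, p=weights / weights.sum())
        for k, length in zip(pick, te_len):
            chrom, s, e = spans[k]
            mid = int(rng.integers(s, e))
            chroms.append(chrom)
            starts.append(max(0, mid - int(length) // 2))
    else:
        names = list(chrom_sizes)
        by_chrom = {c: [] for c in names}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for length in te_len:
            for _ in range(1000):  # bounded rejection sampling
                chrom = names[int(rng.integers(len(names)))]
                mid = int(rng.integers(0, chrom_sizes[chrom]))
                if not any(s <= mid < e for s, e in by_chrom.get(chrom, [])):
                    break
            else:
                raise RuntimeError("could not place a TE outside the clusters")
            chroms.append(chrom)
            starts.append(max(0, mid - int(length) // 2))
    return chroms, starts


def synth_annotations(
    family_counts: dict,
    layout=None,
    consensus_length: int = 5000,
    seed: int = 0,
) -> tuple[pd.DataFrame, list, SyntheticTruth]:
    """TE annotation table with planted per-family copies inside/outside clusters.

    ``family_counts`` maps family -> (copies inside clusters, copies outside).
    Divergence is drawn uniformly on [0, 15]% and length on
    [50, consensus_length] bp so that the standard filters (>=100 bp,
    <=10%) have work to do.  Returns (annotations, clusters, truth).
    """
    rng = np.random.default_rng(seed)
    clusters, chrom_sizes = layout if layout is not None else default_layout()
    rows = []
    for family, (n_in, n_out) in sorted(family_counts.items()):
        for inside, n in ((True, n_in), (False, n_out)):
            if n == 0:
                continue
            lengths = rng.integers(50, consensus_length + 1, size=n)
            chroms, starts = _place_uniform(rng, n, clusters, lengths, chrom_sizes, inside)
            divergence = rng.uniform(0.0, 15.0, size=n)
            strands = rng.choice(["+", "-"], size=n)
            for c, s, ln, d, st in zip(chroms, starts, lengths, divergence, strands):
                rows.append((c, s, s + int(ln), st, family, float(d), consensus_length))
    tes = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "family", "divergence", "consensus_length"]
    )
    truth = SyntheticTruth(seed=seed, clusters=clusters, te_annotations=tes, family_counts=dict(family_counts))
    return tes, clusters, truth


def synth_freq_table(
    family_frequencies: dict,
    layout=None,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Insertion-frequency records with exact planted frequencies.

    ``family_frequencies`` maps family -> list of ``(frequency, in_cluster)``
    pairs (or bare frequencies, placed outside clusters).
    """
    rng = np.random.default_rng(seed)
    clusters, chrom_sizes = layout if layout is not None else default_layout()
    rows = []
    for family, entries in sorted(family_frequencies.items()):
        for entry in entries:
            freq, inside = entry if isinstance(entry, tuple) else (entry, False)
            chroms, starts = _place_uniform(rng, 1, clusters, [0], chrom_sizes, inside)
            rows.append((family, chroms[0], starts[0], float(freq)))
    records = pd.DataFrame(rows, columns=["family", "chrom", "pos", "frequency"])
    truth = SyntheticTruth(seed=seed, clusters=clusters)
    return records, truth


def _plant_window_reads(rng, rows, chrom, start, end, strand, n):
    """n reads of piRNA size whose 5' ends fall uniformly in [start, end)."""
    if end <= start or n <= 0:
        return
    p5 = rng.integers(start, end, size=n)
    lengths = rng.integers(23, 30, size=n)
    for p, ln in zip(p5, lengths):
        if strand == "+":
            rows.append((chrom, int(p), int(p) + int(ln), "+", int(ln), 37, False))
        else:
            rows.append((chrom, int(p) - int(ln) + 1, int(p) + 1, "-", int(ln), 37, False))


def synth_small_rna(
    tes: pd.DataFrame,
    clusters,
    dsl_truth,
    library_size: int = 1_000_000,
    flank: int = 500,
    min_rpm: float = 5.0,
    signal_factor: float = 2.0,
    noise_factor: float = 0.5,
    decoy_fraction: float = 0.1,
    genes: pd.DataFrame | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Strand-resolved reads with planted DSL asymmetry around TE insertions.

    Only reads near the features are materialised; ``library_size`` is the
    nominal size of the whole filtered library they are drawn from and is
    the rpm denominator downstream.  Truth-DSL TEs receive
    ``signal_factor * min_rpm`` antisense reads upstream and sense reads
    downstream (in feature orientation); every feature additionally gets
    strand-symmetric background in both flanks, capped at
    ``noise_factor * min_rpm`` so non-DSL features stay below threshold.
    A ``decoy_fraction`` of extra out-of-size-range and low-mapq reads
    exercises the read filters.
    """
    rng = np.random.default_rng(seed)
    dsl_truth = np.asarray(dsl_truth, dtype=bool)
    if len(dsl_truth) != len(tes):
        raise ValueError("dsl_truth must align with the TE table")
    signal_reads = int(np.ceil(signal_factor * min_rpm * library_size / 1e6))
    noise_cap = int(np.floor(noise_factor * min_rpm * library_size / 1e6))
    rows: list = []

    def flanks(feature):
        start, end, strand = feature["start"], feature["end"], feature["strand"]
        upstream = (max(0, start - flank), start)
        downstream = (end, end + flank)
        if strand == "+":
            return upstream, "-", downstream, "+"
        return downstream, "+", upstream, "-"

    features = [tes]
    flags = [dsl_truth]
    if genes is not None:
        features.append(genes)
        flags.append(np.zeros(len(genes), dtype=bool))
    for feat_df, feat_flags in zip(features, flags):
        for (_, feature), is_dsl in zip(feat_df.iterrows(), feat_flags):
            (up_w, up_strand, down_w, down_strand) = flanks(feature)
            chrom = feature["chrom"]
            if is_dsl:
                _plant_window_reads(rng, rows, chrom, *up_w, up_strand, signal_reads)
                _plant_window_reads(rng, rows, chrom, *down_w, down_strand, signal_reads)
            # strand-symmetric background, truncated below threshold
            for window in (up_w, down_w):
                for strand in ("+", "-"):
                    n = min(int(rng.poisson(noise_cap / 2 if noise_cap else 0)), noise_cap)
                    _plant_window_reads(rng, rows, chrom, *window, strand, n)

    reads = pd.DataFrame(rows, columns=READ_COLUMNS)
    # decoys: wrong size or low mapq; removed by filter_pirna_reads
    n_decoy = int(decoy_fraction * len(reads))
    if n_decoy and len(reads):
        picks = reads.sample(n=n_decoy, random_state=int(rng.integers(2**31)), replace=True).copy()
        bad_len = rng.random(n_decoy) < 0.5
        picks.loc[bad_len, "length"] = int(22)
        picks.loc[bad_len, "end"] = picks.loc[bad_len, "start"] + 22
        picks.loc[~bad_len, "mapq"] = 0
        reads = pd.concat([reads, picks], ignore_index=True)
    truth = SyntheticTruth(
        seed=seed,
        clusters=list(clusters),
        te_annotations=tes,
        dsl_flags=pd.Series(dsl_truth),
        library_size=library_size,
    )
    return reads.reset_index(drop=True), truth


def synth_pingpong_reads(
    family: str,
    n_pairs: int,
    signal_fraction: float,
    consensus_length: int = 5000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Consensus-mapped sense/antisense read pairs with a planted 10-nt overlap.

    A ``signal_fraction`` of pairs is placed at exactly 10 nt of 5'-5'
    overlap (the ping-pong signature); the remaining antisense reads are
    placed independently of any sense read, modelling piRNA production
    without amplification, so the expected z10 is null-centred at 0.  Sense
    5' ends sit on a >=40 bp grid (the consensus is virtually extended when
    ``n_pairs`` needs more room), so no incidental cross-pair 5'-5' overlap
    of 20 nt or less can arise.  Returns (sense_reads, antisense_reads) on
    the consensus coordinate system.
    """
    if not (0.0 <= signal_fraction <= 1.0):
        raise ValueError("signal_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    stride = 40
    effective_length = max(consensus_length, stride * (n_pairs + 2))
    slots = rng.choice(effective_length // stride - 2, size=n_pairs, replace=False)
    s5 = slots * stride + stride
    signal = rng.random(n_pairs) < signal_fraction
    a5 = np.where(
        signal,
        s5 + 9,  # 10-nt 5'-5' overlap
        rng.integers(30, effective_length - 30, size=n_pairs),
    )
    s_len = rng.integers(23, 30, size=n_pairs)
    a_len = rng.integers(23, 30, size=n_pairs)
    sense = pd.DataFrame(
        {
            "chrom": family,
            "start": s5,
            "end": s5 + s_len,
            "strand": "+",
            "length": s_len,
            "mapq": 37,
            "ncrna": False,
        }
    )
    antisense = pd.DataFrame(
        {
            "chrom": family,
            "start": a5 - a_len + 1,
            "end": a5 + 1,
            "strand": "-",
            "length": a_len,
            "mapq": 37,
            "ncrna": False,
        }
    )
    return sense, antisense
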