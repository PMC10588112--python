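# Methods

## The trap model and what the simulator computes

Transposable elements (TEs) multiply within genomes; hosts fight back. In
the trap model, a TE invasion ends when a copy jumps into a piRNA cluster —
a genomic region whose transcripts are processed into PIWI-interacting
RNAs — because a single cluster insertion silences every copy of that
family carried by the individual. `tetrap.simulate` implements this as a
forward-in-time Wright–Fisher simulation of diploids with:

- 5 chromosomes of 10 Mb and a uniform recombination rate of 4 cM/Mb
  (crossovers per chromosome per meiosis ~ Poisson(0.4), free assortment
  between chromosomes);
- a *transposon trap* at the start of each chromosome and an equally sized
  *reference region* at the end, each 3.5% of the genome by default. A trap
  insertion silences its carrier; a reference insertion does nothing and
  serves as the null comparator;
- N = 1000 diploids, non-overlapping generations, two parents per offspring
  drawn independently with probability proportional to fitness (selfing
  allowed);
- multiplicative-free fitness `w = 1 − Σ x_i` over all copies, clamped at 0,
  with per-insertion effects assigned by class (a configurable fraction of
  sites is deleterious at a given x; trap insertions are cost-free when
  `traps_neutral`); a run is marked extinct when mean fitness drops below
  0.1;
- transposition at rate u = 0.1 per copy per generation: each copy in a
  non-silenced individual spawns a new copy at a uniformly random genome
  position on a random haplotype of the offspring;
- invasions triggered by 1000 seed insertions, each on one random haplotype
  of one random individual (population frequency 1/2N), and sampled at
  generation 2000 unless configured otherwise. u and the sampling
  generation can instead be per-replicate uniform samplers, emulating TE
  families with family-specific rates or invasion ages.

### Silencing timing

The published description of such simulators leaves open *whose* silencing
status gates transposition: the parent a copy was inherited from, or the
newly formed offspring itself. Both are implemented
(`SimulationConfig.silencing`). The default is `"zygote"` — new copies
arise only in offspring that carry no trap insertion — because in ensemble
pilots the `"parent"` conditioning lets rare trap-free individuals keep
feeding copies into already-silenced genomes late in the invasion, which
inflates the mean trap content per haploid genome to ~3.4, produces a
percent-scale upper tail of trap counts, and leaves a visible fraction of
replicates uncontrolled at generation 2000. Under the zygote conditioning
invasions are controlled in every replicate, traps accumulate ~2–3
insertions per haploid genome, and full silencing is first reached at
around four trap insertions per diploid — the regime the composition
statistics are built on.

### Phases

`classify_phase` is strict: a population is "rapid" while at least one
individual carries no trap insertion, "shotgun" when everyone is silenced
by segregating trap insertions, and "inactive" once some trap insertion is
fixed on all 2N haplotypes. Because segregation continually produces a few
trap-free individuals even in well-controlled invasions, a controlled
population can still classify as "rapid" at a given snapshot; the
trajectory's `fraction_silenced` column is the graded signal.

### Engine

The population lives in flat per-copy arrays (position, haplotype, effect
class), and a generation is advanced with vectorised numpy; the
gamete-formation inner loop optionally runs as a numba kernel. All random
draws happen outside the kernel, so the numpy and numba paths are
bitwise-identical (unit-tested). Positions are discrete base pairs;
haplotypes are position *sets* — a transposition landing on an occupied
position of the same haplotype is redrawn (collision probability ~1e-2 per
generation at 50 Mb). A crossover at position p splits [0, p) | [p, L).
One root generator (numpy PCG64) drives each replicate; replicate i of an
ensemble uses a seed derived from `SeedSequence([base_seed, i])`, so
ensembles are reproducible and replicates independent.

## Composition statistics

`tetrap.stats` computes the two signals that discriminate traps from
reference regions:

- **Tail fractions** of pooled per-individual counts (strictly fewer than
  `low`=1, strictly more than `high`=14 insertions in a region). Traps are
  narrow: nearly every silenced individual has at least one trap insertion,
  and nothing drives counts far above the silencing threshold; reference
  regions inherit the full breadth of invasion sizes.
- **Kendall tau-b** (via scipy, exact small-sample p-values when untied)
  between a region's abundance and the rest of the genome (genome minus the
  focal region), one point per replicate (= TE family), using per-replicate
  mean haploid counts — averaging before rank transformation. Reference
  regions correlate positively with the rest of the genome; traps do not,
  and under strong negative selection the trap correlation turns negative
  (more genomic copies mean more chances to hit a trap early and stop
  small).

Histograms are per-haploid (diploid counts / 2), unit bin width, masses
normalised before any display truncation.

## Empirical operators

`tetrap.intervals` re-implements the bespoke annotation rules: bedtools-style
interval merging (book-ended intervals merge); the de novo cluster
neighbour-join rule (join adjacent clusters when the gap is smaller than
their combined lengths, iterated to a fixed point); cluster lift-over as the
region between two aligned flanking sequences, with the telomeric variant
(distal gene end to contig end) and inverted/cross-contig pairs flagged
unresolvable; TE filters (length ≥ 100 bp and divergence ≤ 10%, both
inclusive; optional germline-active family whitelist; "full-length" =
length ≥ 0.95 × consensus length, configurable); and the haploid conversion
of population insertion frequencies (f < 0.3 discarded as unreliable or
somatic, 0.3 ≤ f < 0.6 heterozygous = 0.5 copies, f ≥ 0.6 homozygous = 1.0).
Cluster membership of an annotation is decided by its midpoint, since
annotations may straddle cluster edges. Per-strain tables are averaged per
family over the strains where the family is present (absence is missing
data, not zero; configurable).

`tetrap.smallrna` detects dispersed piRNA source loci (DSL): piRNA-sized
reads (23–29 nt inclusive), uniquely mapping (mapq ≥ 5), non-ncRNA; a read
belongs to a flank window when its 5′ end (the piRNA-defining coordinate)
lies in it; windows abut the feature (upstream [start−flank, start),
downstream [end, end+flank), flipped for −-strand features, truncated at
position 0, flank = 500 bp); a TE is a DSL when upstream-antisense and
downstream-sense signals both reach 5 reads per million and the TE lies
outside all clusters. The rpm denominator defaults to the filtered read
count. The false-positive rate is estimated by applying the same criteria
to conserved genes ≥ 100 bp. Ping-pong signatures count sense/antisense
5′–5′ overlaps of 1..20 nt (an overlap of o puts the antisense 5′ end at
the sense 5′ end + o − 1); z10 is the 10-nt count standardised against the
other 19 offsets (sample sd, ddof=1); a flat histogram scores 0 and a
zero-variance background with an enriched 10-nt count is flagged undefined
rather than infinite.

## Synthetic data

`tetrap.synth` generates every empirical input with planted truth: TE
tables with per-family copies placed inside/outside clusters (divergence
uniform on [0, 15]%, lengths uniform on [50, consensus], so the standard
filters have work to do); frequency tables with exact planted frequencies;
small-RNA reads in which truth-DSL TEs get 2× the 5-rpm threshold of
antisense-upstream/sense-downstream signal while every feature receives
strand-symmetric background truncated at 0.5× threshold (so the
planted-recovery contract is deterministic), plus out-of-size-range and
low-mapq decoys; and consensus-mapped ping-pong read pairs where a chosen
fraction sits at exactly 10 nt overlap and the rest of the antisense reads
are placed independently of the sense reads (a proper no-amplification
null, centring z10 at 0). Sense 5′ ends sit on a 40-bp grid so no
incidental ≤20-nt cross-pair overlap arises. Only flank-local reads are
materialised; the nominal library size used for rpm normalisation is
carried in the truth object. The default layout mirrors the simulator's
genome (5 × 10 Mb, clusters at chromosome starts).

What the synthetic data does **not** emulate: real sequence content (no
bases, only coordinates), mapping ambiguity, fragmented or nested TE
annotations, cluster annotation error, or biological variation in piRNA
production along a locus. Tests passing on synthetic data therefore
validate the operators' rules and arithmetic, not their robustness to real
alignment artefacts.

## Problem sizes and numerical choices

The packaged ensembles use 30 replicates (test suite) and 40 replicates
(`scripts/acceptance.py`) of the N=1000, 2000-generation scenario — a
deliberate scale-down from 300-replicate production ensembles; pooled tail
percentages at this scale carry binomial noise of a few hundredths of a
percentage point, and the suite's assertions use ±3 binomial standard
errors at the pooled sample size. Mean trap content per haploid genome
lands near the top of the expected 2–3 band (ensemble means 2.6–3.1 across
pilot batches), and the pooled tail percentages under the zygote default
are narrower than the reference values derived from much larger production
ensembles (same order of magnitude; the trap-narrower-than-reference
ordering is robust). Kendall p-values use scipy's exact method for small
untied samples and the normal approximation otherwise. Degenerate inputs
(constant correlation vectors, zero-variance ping-pong backgrounds,
inverted flank pairs) return flagged results instead of raising.
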