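"""Forward-in-time Wright-Fisher simulation of TE invasions under the trap model.

A transposable element (TE) family invades a diploid population of size N.
Each chromosome carries a "transposon trap" (a piRNA-cluster-like region) at
one end and an equally sized "reference region" at the other.  A single TE
insertion anywhere in a trap silences every TE copy carried by that
individual (its copies no longer transpose); insertions in reference regions
have no effect on TE activity and serve as the null comparator.

The life cycle per (non-overlapping) generation is:

1. fitness of each parent: ``w = 1 - sum(x_i)`` over all insertions on both
   haplotypes, clamped at 0 (trap insertions contribute 0 when
   ``traps_neutral``);
2. each offspring draws two parents independently, with probability
   proportional to fitness (selfing allowed);
3. each parent contributes one recombinant gamete (Poisson crossovers at a
   uniform cM/Mb rate, free assortment between chromosomes);
4. every copy inherited from a *non-silenced* parent transposes with
   probability ``u``, placing a new copy at a uniformly random genome
   position on a random haplotype of the offspring.

The population state is held in flat numpy arrays (one row per TE copy) so a
whole generation is advanced with vectorised operations; ``Population``
exposes conventional per-individual views for inspection and small-scale
testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

try:  # the jitted gamete kernel is optional; the numpy path is equivalent
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "GenomeArchitecture",
    "Insertion",
    "Haplotype",
    "Individual",
    "SelectionModel",
    "SimulationConfig",
    "Population",
    "ReplicateSummary",
    "ExtinctionError",
    "build_architecture",
    "standard_architecture",
    "seed_population",
    "fitness",
    "is_silenced",
    "make_gamete",
    "reproduce",
    "classify_phase",
    "count_regions",
    "run_replicate",
    "run_ensemble",
]


class ExtinctionError(RuntimeError):
    """Raised when every individual has fitness zero and no parent can be drawn."""


# ---------------------------------------------------------------------------
# genome architecture


@dataclass
class GenomeArchitecture:
    """Chromosome layout with trap and reference intervals.

    Intervals are ``(chrom, start, end)`` in 0-based half-open base pairs;
    ``recomb_rate`` is a uniform rate in cM/Mb.
    """

    n_chromosomes: int
    chrom_length: int
    recomb_rate: float
    trap_intervals: tuple
    reference_intervals: tuple
    trap_fraction: float
    reference_fraction: float

    def __post_init__(self) -> None:
        for chrom, start, end in (*self.trap_intervals, *self.reference_intervals):
            if not (0 <= start < end <= self.chrom_length):
                raise ValueError(f"interval ({chrom},{start},{end}) outside [0, chrom_length)")
        self._trap_bounds = _interval_bounds(self.trap_intervals, self.chrom_length)
        self._ref_bounds = _interval_bounds(self.reference_intervals, self.chrom_length)
        # pairwise disjointness: sorted by start, each interval must end
        # before the next one starts
        spans = sorted(
            (chrom * self.chrom_length + start, chrom * self.chrom_length + end)
            for chrom, start, end in (*self.trap_intervals, *self.reference_intervals)
        )
        for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
            if s1 < e0:
                raise ValueError("trap and reference intervals overlap")

    @property
    def genome_length(self) -> int:
        return self.n_chromosomes * self.chrom_length

    @property
    def crossover_mean(self) -> float:
        """Expected crossovers per chromosome per meiosis (Morgans)."""
        return self.recomb_rate * (self.chrom_length / 1e6) / 100.0

    def in_trap(self, gpos: np.ndarray) -> np.ndarray:
        return _in_bounds(self._trap_bounds, gpos)

    def in_reference(self, gpos: np.ndarray) -> np.ndarray:
        return _in_bounds(self._ref_bounds, gpos)


def _interval_bounds(intervals: Sequence, chrom_length: int) -> np.ndarray:
    """Flatten intervals to sorted global-coordinate edges for searchsorted tests."""
    edges = []
    for chrom, start, end in intervals:
        g = chrom * chrom_length
        edges.extend((g + start, g + end))
    return np.asarray(sorted(edges), dtype=np.int64)


def _in_bounds(bounds: np.ndarray, gpos: np.ndarray) -> np.ndarray:
    if len(bounds) == 0:
        return np.zeros(np.shape(gpos), dtype=bool)
    return (np.searchsorted(bounds, gpos, side="right") & 1) == 1


def build_architecture(
    n_chrom: int,
    chrom_length: int,
    trap_fraction: float,
    reference_fraction: float,
    recomb_rate: float,
) -> GenomeArchitecture:
    """Place a trap at the start and a reference region at the end of each chromosome.

    Per chromosome the trap occupies ``[0, round(trap_fraction * L))`` and the
    reference region ``[L - round(reference_fraction * L), L)``.
    """
    if trap_fraction < 0 or reference_fraction < 0:
        raise ValueError("fractions must be non-negative")
    if trap_fraction + reference_fraction > 1:
        raise ValueError("trap and reference fractions must not overlap (sum > 1)")
    trap_bp = round(trap_fraction * chrom_length)
    ref_bp = round(reference_fraction * chrom_length)
    traps = tuple((c, 0, trap_bp) for c in range(n_chrom) if trap_bp > 0)
    refs = tuple((c, chrom_length - ref_bp, chrom_length) for c in range(n_chrom) if ref_bp > 0)
    return GenomeArchitecture(
        n_chromosomes=n_chrom,
        chrom_length=chrom_length,
        recomb_rate=recomb_rate,
        trap_intervals=traps,
        reference_intervals=refs,
        trap_fraction=trap_fraction,
        reference_fraction=reference_fraction,
    )


def standard_architecture() -> GenomeArchitecture:
    """5 chromosomes of 10 Mb, 4 cM/Mb, trap and reference each 3.5% of the genome."""
    return build_architecture(5, 10_000_000, 0.035, 0.035, 4.0)


# ---------------------------------------------------------------------------
# individual-level types


@dataclass(frozen=True)
class Insertion:
    chrom: int
    pos: int
    effect_class: int = 0


@dataclass
class Haplotype:
    insertions: list

    def sorted(self) -> "Haplotype":
        return Haplotype(sorted(self.insertions, key=lambda i: (i.chrom, i.pos)))


@dataclass
class Individual:
    hap1: Haplotype
    hap2: Haplotype

    def all_insertions(self):
        return [*self.hap1.insertions, *self.hap2.insertions]


@dataclass
class SelectionModel:
    """Per-copy selection coefficients by effect class.

    ``class_effects`` maps a class label to the fitness cost x per copy;
    ``class_fractions`` gives the fraction of genomic sites (equivalently, of
    new insertions) falling in each class.  With ``traps_neutral`` insertions
    inside trap intervals contribute nothing to the fitness cost.
    """

    class_effects: Mapping[str, float] = field(default_factory=lambda: {"neutral": 0.0})
    class_fractions: Mapping[str, float] = field(default_factory=lambda: {"neutral": 1.0})
    traps_neutral: bool = True

    def __post_init__(self) -> None:
        if set(self.class_effects) != set(self.class_fractions):
            raise ValueError("class_effects and class_fractions must share labels")
        if any(x < 0 for x in self.class_effects.values()):
            raise ValueError("selection coefficients must be >= 0")
        if not math.isclose(sum(self.class_fractions.values()), 1.0, abs_tol=1e-9):
            raise ValueError("class_fractions must sum to 1")
        self.labels = list(self.class_effects)
        self.x = np.array([self.class_effects[l] for l in self.labels], dtype=float)
        self.p = np.array([self.class_fractions[l] for l in self.labels], dtype=float)

    @property
    def is_neutral(self) -> bool:
        return bool(np.all(self.x == 0.0))

    @classmethod
    def neutral(cls) -> "SelectionModel":
        return cls()

    @classmethod
    def site_effects(cls, effects: Mapping[float, float], traps_neutral: bool = True) -> "SelectionModel":
        """Build from a mapping {x: fraction of sites}; the remainder is neutral.

        ``site_effects({0.01: 0.4})`` gives 40% of sites a cost of 0.01 per
        copy and leaves 60% neutral.
        """
        frac = sum(effects.values())
        if frac > 1 + 1e-9:
            raise ValueError("effect fractions sum to more than 1")
        class_effects = {"neutral": 0.0}
        class_fractions = {"neutral": max(0.0, 1.0 - frac)}
        for x, f in effects.items():
            label = f"x={x:g}"
            class_effects[label] = x
            class_fractions[label] = f
        return cls(class_effects, class_fractions, traps_neutral)


UniformRange = tuple  # (low, high) sampled uniformly once per replicate


@dataclass
class SimulationConfig:
    """One invasion scenario.

    ``u`` and ``sample_generation`` may be scalars or ``(low, high)`` tuples;
    a tuple is sampled uniformly once per replicate (continuous for u,
    integer-inclusive for the sampling generation), modelling TE families
    with family-specific transposition rates or invasion ages.

    ``silencing`` selects whose trap status suppresses transposition of a
    copy: "zygote" (default) adds new copies only to offspring that carry no
    trap insertion themselves; "parent" lets every copy inherited from an
    unsilenced parent transpose, regardless of the offspring's own trap
    content.
    """

    architecture: GenomeArchitecture = field(default_factory=standard_architecture)
    N: int = 1000
    u: Union[float, UniformRange] = 0.1
    selection: SelectionModel = field(default_factory=SelectionModel.neutral)
    n_seed_insertions: int = 1000
    max_generations: int = 10_000
    sample_generation: Union[int, UniformRange] = 2000
    extinction_fitness: float = 0.1
    silencing: str = "zygote"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        u_vals = self.u if isinstance(self.u, tuple) else (self.u,)
        if any(not (0.0 <= v <= 1.0) for v in u_vals):
            raise ValueError("u must lie in [0, 1]")
        if not (0.0 < self.extinction_fitness < 1.0):
            raise ValueError("extinction_fitness must lie in (0, 1)")
        if self.silencing not in ("zygote", "parent"):
            raise ValueError("silencing must be 'zygote' or 'parent'")


# ---------------------------------------------------------------------------
# population state


class Population:
    """Diploid population state, stored as flat per-copy arrays.

    ``pos`` holds global genome coordinates (``chrom * chrom_length + bp``),
    ``hap`` the owning haplotype index (individual ``i`` owns haplotypes
    ``2i`` and ``2i+1``) and ``cls`` the effect-class code of each copy.
    Arrays are kept sorted by (haplotype, position).
    """

    def __init__(self, pos: np.ndarray, hap: np.ndarray, cls: np.ndarray, N: int, generation: int = 0):
        # int32 suffices: genome coordinates < 2**31 bp, haplotype indices < 2N
        self.pos = np.asarray(pos, dtype=np.int32)
        self.hap = np.asarray(hap, dtype=np.int32)
        self.cls = np.asarray(cls, dtype=np.int8)
        self.N = int(N)
        self.generation = int(generation)

    @property
    def n_insertions(self) -> int:
        return self.pos.size

    def individuals(self, arch: GenomeArchitecture) -> list:
        """Materialise Individual objects (for inspection; O(copies))."""
        L = arch.chrom_length
        haps: list = [[] for _ in range(2 * self.N)]
        order = np.lexsort((self.pos, self.hap))
        for p, h, c in zip(self.pos[order], self.hap[order], self.cls[order]):
            haps[h].append(Insertion(int(p) // L, int(p) % L, int(c)))
        return [
            Individual(Haplotype(haps[2 * i]), Haplotype(haps[2 * i + 1]))
            for i in range(self.N)
        ]

    @classmethod
    def from_individuals(cls, individuals: Sequence[Individual], arch: GenomeArchitecture, generation: int = 0) -> "Population":
        pos, hap, cc = [], [], []
        for i, ind in enumerate(individuals):
            for h, haplo in enumerate((ind.hap1, ind.hap2)):
                for ins in haplo.insertions:
                    pos.append(ins.chrom * arch.chrom_length + ins.pos)
                    hap.append(2 * i + h)
                    cc.append(ins.effect_class)
        pop = cls(
            np.asarray(pos, dtype=np.int64),
            np.asarray(hap, dtype=np.int64),
            np.asarray(cc, dtype=np.int8),
            N=len(individuals),
            generation=generation,
        )
        pop._sort()
        return pop

    def _sort(self) -> None:
        order = np.lexsort((self.pos, self.hap))
        self.pos = self.pos[order]
        self.hap = self.hap[order]
        self.cls = self.cls[order]

    def copy(self) -> "Population":
        return Population(self.pos.copy(), self.hap.copy(), self.cls.copy(), self.N, self.generation)


# ---------------------------------------------------------------------------
# individual-level operations (reference semantics; the engine is vectorised)


def fitness(individual: Individual, selection: SelectionModel, arch: GenomeArchitecture) -> float:
    """``w = 1 - sum(x_i)`` over all copies on both haplotypes, clamped at 0."""
    cost = 0.0
    for ins in individual.all_insertions():
        if selection.traps_neutral and arch.in_trap(np.int64(ins.chrom * arch.chrom_length + ins.pos)):
            continue
        cost += selection.x[ins.effect_class]
    return max(0.0, 1.0 - cost)


def is_silenced(individual: Individual, arch: GenomeArchitecture) -> bool:
    """True iff any copy on either haplotype lies inside a trap interval."""
    for ins in individual.all_insertions():
        if arch.in_trap(np.int64(ins.chrom * arch.chrom_length + ins.pos)):
            return True
    return False


def make_gamete(individual: Individual, arch: GenomeArchitecture, rng: np.random.Generator) -> Haplotype:
    """One recombinant gamete: Poisson crossovers per chromosome, free assortment.

    A crossover at position p splits the chromosome into [0, p) | [p, L); the
    contributing parental haplotype alternates across breakpoints starting
    from a fair-coin choice per chromosome.
    """
    L = arch.chrom_length
    lam = arch.crossover_mean
    out = []
    for chrom in range(arch.n_chromosomes):
        k = rng.poisson(lam)
        breaks = np.sort(np.floor(rng.random(k) * L).astype(np.int64))
        phase = int(rng.integers(0, 2))
        for h, haplo in enumerate((individual.hap1, individual.hap2)):
            for ins in haplo.insertions:
                if ins.chrom != chrom:
                    continue
                n_before = int(np.searchsorted(breaks, ins.pos, side="right"))
                if (phase + n_before) % 2 == h:
                    out.append(ins)
    return Haplotype(sorted(out, key=lambda i: (i.chrom, i.pos)))


# ---------------------------------------------------------------------------
# vectorised generation step


def _population_state(pop: Population, arch: GenomeArchitecture, selection: SelectionModel):
    """Per-individual fitness and silencing status from the flat arrays."""
    ind = pop.hap >> 1
    in_trap = arch.in_trap(pop.pos)
    silenced = np.bincount(ind[in_trap], minlength=pop.N) > 0
    if selection.is_neutral:
        w = np.ones(pop.N)
    else:
        x = selection.x[pop.cls]
        if selection.traps_neutral:
            x = np.where(in_trap, 0.0, x)
        w = 1.0 - np.bincount(ind, weights=x, minlength=pop.N)
        np.clip(w, 0.0, None, out=w)
    return w, silenced, in_trap


def _form_gametes_numpy(pos, hap, cls, off, parents, cx_pos, cx_off, phase, L, n_chrom):
    """Vectorised gamete formation: gather parental copies, apply the
    crossover mosaic, return the transmitted copies grouped by gamete."""
    n_gam = parents.shape[0]
    lens = (off[parents + 1] - off[parents]).astype(np.int64)
    total = int(lens.sum())
    gid = np.repeat(np.arange(n_gam, dtype=np.int32), lens)
    if total:
        head = np.zeros(n_gam, dtype=np.int64)
        np.cumsum(lens[:-1], out=head[1:])
        idx = np.arange(total, dtype=np.int64) - np.repeat(head, lens) + np.repeat(off[parents], lens)
    else:
        idx = np.empty(0, dtype=np.int64)
    gpos = pos[idx]
    gsrc = hap[idx] & np.int32(1)  # parental haplotype of origin
    gchrom = gpos // np.int32(L)
    iblock = gid * np.int32(n_chrom) + gchrom
    # crossovers in the same (gamete, chromosome) block at positions <= pos
    ikey = iblock.astype(np.int64) * L + (gpos - gchrom * np.int32(L))
    n_before = np.searchsorted(
        np.repeat(np.arange(phase.shape[0], dtype=np.int64), np.diff(cx_off)) * L + cx_pos,
        ikey,
        side="right",
    ).astype(np.int64) - cx_off[iblock]
    keep = ((phase[iblock] + n_before) & 1) == gsrc
    return gpos[keep], gid[keep], cls[idx][keep]


if _HAVE_NUMBA:

    @numba.njit(cache=True)
    def _form_gametes_jit(pos, hap, cls, off, parents, cx_pos, cx_off, phase, L, n_chrom):  # pragma: no cover
        n_gam = parents.shape[0]
        total = 0
        for g in range(n_gam):
            p = parents[g]
            total += off[p + 1] - off[p]
        out_pos = np.empty(total, dtype=np.int32)
        out_hap = np.empty(total, dtype=np.int32)
        out_cls = np.empty(total, dtype=np.int8)
        n = 0
        for g in range(n_gam):
            p = parents[g]
            for j in range(off[p], off[p + 1]):
                pp = pos[j]
                src = hap[j] & 1
                chrom = pp // L
                local = pp - chrom * L
                b = g * n_chrom + chrom
                nb = 0
                for k in range(cx_off[b], cx_off[b + 1]):
                    if cx_pos[k] <= local:
                        nb += 1
                if ((phase[b] + nb) & 1) == src:
                    out_pos[n] = pp
                    out_hap[n] = g
                    out_cls[n] = cls[j]
                    n += 1
        return out_pos[:n], out_hap[:n], out_cls[:n]


def _form_gametes(pos, hap, cls, off, parents, cx_pos, cx_off, phase, L, n_chrom):
    if _HAVE_NUMBA:
        return _form_gametes_jit(pos, hap, cls, off, parents, cx_pos, cx_off, phase, np.int64(L), np.int64(n_chrom))
    return _form_gametes_numpy(pos, hap, cls, off, parents, cx_pos, cx_off, phase, L, n_chrom)


def reproduce(
    population: Population,
    config: SimulationConfig,
    rng: np.random.Generator,
    u: float | None = None,
    _state: tuple | None = None,
) -> Population:
    """Advance one generation: selection, mating, recombination, transposition.

    ``u`` overrides ``config.u`` (used when the rate was sampled per
    replicate).  Raises :class:`ExtinctionError` when all fitnesses are 0.
    """
    arch = config.architecture
    sel = config.selection
    N = population.N
    L = arch.chrom_length
    n_chrom = arch.n_chromosomes
    G = arch.genome_length
    if u is None:
        u = config.u if not isinstance(config.u, tuple) else None
    if u is None:
        raise ValueError("u is a per-replicate sampler; pass the sampled value explicitly")

    if _state is None:
        w, silenced, _ = _population_state(population, arch, sel)
    else:
        w, silenced = _state

    # two independent, fitness-weighted parents per offspring (selfing allowed)
    if np.all(w == w[0]):
        if w[0] == 0.0:
            raise ExtinctionError("all individuals have fitness 0")
        parents = rng.integers(0, N, size=2 * N)
    else:
        cdf = np.cumsum(w)
        if cdf[-1] == 0.0:
            raise ExtinctionError("all individuals have fitness 0")
        parents = np.searchsorted(cdf, rng.random(2 * N) * cdf[-1], side="right")

    # per-individual copy offsets (arrays are grouped by haplotype, hence by
    # individual)
    ind = population.hap >> 1
    cnt = np.bincount(ind, minlength=N)
    off = np.zeros(N + 1, dtype=np.int64)
    np.cumsum(cnt, out=off[1:])

    # crossover mosaic: Poisson(#) breakpoints per (gamete, chromosome) block
    lam = arch.crossover_mean
    n_blocks = 2 * N * n_chrom
    if lam > 0:
        nc = rng.poisson(lam, size=n_blocks)
        C = int(nc.sum())
        ckey = np.repeat(np.arange(n_blocks, dtype=np.int64), nc) * L + np.floor(rng.random(C) * L).astype(np.int64)
        ckey.sort()
    else:
        nc = np.zeros(n_blocks, dtype=np.int64)
        ckey = np.empty(0, dtype=np.int64)
    cx_off = np.zeros(n_blocks + 1, dtype=np.int64)
    np.cumsum(nc, out=cx_off[1:])
    cx_pos = ckey % L
    phase = rng.integers(0, 2, size=n_blocks, dtype=np.int32)

    kpos, khap, kcls = _form_gametes(
        population.pos, population.hap, population.cls, off, parents, cx_pos, cx_off, phase, L, n_chrom
    )

    # transposition: each copy in a non-silenced context spawns a new copy
    # with probability u, anywhere in the genome.  The silencing context is
    # the offspring's own trap status ("zygote") or the trap status of the
    # parent the copy came from ("parent").
    n_new = 0
    if u > 0 and kpos.size:
        if config.silencing == "zygote":
            off_trap = np.bincount((khap >> 1)[arch.in_trap(kpos)], minlength=N) > 0
            active = np.flatnonzero(~off_trap[khap >> 1])
        else:
            active = np.flatnonzero(~silenced[parents][khap])
        if active.size:
            spawn_idx = active[rng.random(active.size) < u]
            n_new = spawn_idx.size
    if n_new:
        npos = rng.integers(0, G, size=n_new, dtype=np.int32)
        nhap = ((khap[spawn_idx] >> 1) << 1) + rng.integers(0, 2, size=n_new, dtype=np.int32)
        if len(sel.x) > 1:
            ncls = rng.choice(len(sel.x), size=n_new, p=sel.p).astype(np.int8)
        else:
            ncls = np.zeros(n_new, dtype=np.int8)
        allpos = np.concatenate([kpos, npos])
        allhap = np.concatenate([khap, nhap])
        allcls = np.concatenate([kcls, ncls])
    else:
        allpos, allhap, allcls = kpos, khap, kcls

    # keep haplotypes as position sets: redraw new copies that landed on an
    # occupied position of the same haplotype (collisions are ~never at 50 Mb)
    key = allhap.astype(np.int64) * G + allpos
    order = np.argsort(key)
    while True:
        k_sorted = key[order]
        dup = np.flatnonzero(k_sorted[1:] == k_sorted[:-1])
        if dup.size == 0:
            break
        redo = order[dup + 1]
        allpos[redo] = rng.integers(0, G, size=redo.size, dtype=np.int32)
        key = allhap.astype(np.int64) * G + allpos
        order = np.argsort(key)

    out = Population(allpos[order], allhap[order], allcls[order], N, population.generation + 1)
    return out


# ---------------------------------------------------------------------------
# seeding, counting, phases


def seed_population(config: SimulationConfig) -> Population:
    """Trigger an invasion: n_seed insertions, each on one random haplotype.

    Every seed segregates at population frequency 1/(2N).  Effect classes are
    drawn from the selection model's class fractions.
    """
    rng = np.random.default_rng(config.rng_seed)
    return _seed_population(config, rng)


def _seed_population(config: SimulationConfig, rng: np.random.Generator) -> Population:
    arch = config.architecture
    n = config.n_seed_insertions
    G = arch.genome_length
    pos = rng.integers(0, G, size=n)
    hap = rng.integers(0, 2 * config.N, size=n)
    if len(config.selection.x) > 1:
        cls = rng.choice(len(config.selection.x), size=n, p=config.selection.p).astype(np.int8)
    else:
        cls = np.zeros(n, dtype=np.int8)
    # haplotypes are position sets: redraw the rare (hap, pos) collision
    while True:
        key = hap * G + pos
        order = np.argsort(key)
        ks = key[order]
        dup = np.flatnonzero(ks[1:] == ks[:-1])
        if dup.size == 0:
            break
        redo = order[dup + 1]
        pos[redo] = rng.integers(0, G, size=redo.size)
    pop = Population(pos[order], hap[order], cls[order], config.N, generation=0)
    return pop


def count_regions(population: Population, arch: GenomeArchitecture):
    """Per-individual diploid copy counts: (trap, reference, genome) arrays."""
    ind = population.hap >> 1
    trap = np.bincount(ind[arch.in_trap(population.pos)], minlength=population.N)
    ref = np.bincount(ind[arch.in_reference(population.pos)], minlength=population.N)
    genome = np.bincount(ind, minlength=population.N)
    return trap, ref, genome


def classify_phase(population: Population, arch: GenomeArchitecture) -> str:
    """Invasion phase: "rapid" while any individual is unsilenced, "shotgun"
    when all are silenced by segregating trap insertions, "inactive" once a
    trap insertion is fixed (present on all 2N haplotypes at one site)."""
    in_trap = arch.in_trap(population.pos)
    ind = population.hap >> 1
    silenced = np.bincount(ind[in_trap], minlength=population.N) > 0
    if not silenced.all():
        return "rapid"
    trap_pos = population.pos[in_trap]
    if trap_pos.size:
        _, counts = np.unique(trap_pos, return_counts=True)
        if counts.max() == 2 * population.N:
            return "inactive"
    return "shotgun"


# ---------------------------------------------------------------------------
# replicates and ensembles


@dataclass
class ReplicateSummary:
    """Per-individual counts and the copy-number trajectory of one invasion."""

    replicate_id: int
    sample_generation: int
    u: float
    phase: str
    extinct: bool
    trap_counts: np.ndarray  # diploid, one entry per individual
    reference_counts: np.ndarray
    genome_counts: np.ndarray
    trajectory: pd.DataFrame  # generation, mean_diploid_copies, fraction_silenced, mean_trap_diploid, mean_fitness

    @property
    def trap_per_haploid(self) -> np.ndarray:
        return self.trap_counts / 2.0

    @property
    def reference_per_haploid(self) -> np.ndarray:
        return self.reference_counts / 2.0

    @property
    def genome_per_haploid(self) -> np.ndarray:
        return self.genome_counts / 2.0

    @property
    def mean_diploid_copies(self) -> float:
        return float(self.genome_counts.mean())

    @property
    def first_all_silenced_generation(self):
        """First generation with every individual silenced, or None."""
        t = self.trajectory
        hit = t.index[t["fraction_silenced"] >= 1.0]
        return int(t.loc[hit[0], "generation"]) if len(hit) else None

    @property
    def mean_trap_at_first_silencing(self) -> float:
        """Mean diploid trap copies in the first all-silenced generation (nan if never)."""
        t = self.trajectory
        hit = t.index[t["fraction_silenced"] >= 1.0]
        return float(t.loc[hit[0], "mean_trap_diploid"]) if len(hit) else float("nan")


def run_replicate(config: SimulationConfig, replicate_id: int = 0) -> ReplicateSummary:
    """Run one invasion to its sampling generation and summarise it.

    Deterministic for a given config (including ``rng_seed``).  The run is
    marked extinct (phase "extinct") when mean fitness drops below
    ``extinction_fitness`` before sampling; counts then reflect the final
    surviving generation.
    """
    rng = np.random.default_rng(config.rng_seed)
    u = float(rng.uniform(*config.u)) if isinstance(config.u, tuple) else float(config.u)
    if isinstance(config.sample_generation, tuple):
        lo, hi = config.sample_generation
        sample_g = int(rng.integers(lo, hi + 1))
    else:
        sample_g = int(config.sample_generation)
    if sample_g > config.max_generations:
        raise ValueError("sample_generation exceeds max_generations")

    pop = _seed_population(config, rng)
    arch = config.architecture
    traj = np.empty((sample_g + 1, 5))
    extinct = False
    g = 0
    while True:
        w, silenced, in_trap = _population_state(pop, arch, config.selection)
        mean_w = float(w.mean())
        trap_per_ind = np.bincount((pop.hap >> 1)[in_trap], minlength=pop.N)
        traj[g] = (
            g,
            pop.n_insertions / pop.N,
            float(silenced.mean()),
            float(trap_per_ind.mean()),
            mean_w,
        )
        if mean_w < config.extinction_fitness:
            extinct = True
            break
        if g >= sample_g:
            break
        pop = reproduce(pop, config, rng, u=u, _state=(w, silenced))
        g += 1

    trajectory = pd.DataFrame(
        traj[: g + 1],
        columns=["generation", "mean_diploid_copies", "fraction_silenced", "mean_trap_diploid", "mean_fitness"],
    )
    trap, ref, genome = count_regions(pop, arch)
    phase = "extinct" if extinct else classify_phase(pop, arch)
    return ReplicateSummary(
        replicate_id=replicate_id,
        sample_generation=pop.generation,
        u=u,
        phase=phase,
        extinct=extinct,
        trap_counts=trap,
        reference_counts=ref,
        genome_counts=genome,
        trajectory=trajectory,
    )


def replicate_seed(base_seed: int, index: int) -> int:
    """Deterministic per-replicate seed derived from (base_seed, index)."""
    return int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0]) % 2**31


def run_ensemble(config: SimulationConfig, n_replicates: int, base_seed: int) -> list:
    """Independent replicates (interpreted as distinct TE families).

    Replicate i runs with a seed derived deterministically from
    ``(base_seed, i)``; per-replicate samplers for u and the sampling
    generation draw within each replicate.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    out = []
    for i in range(n_replicates):
        cfg = replace(config, rng_seed=replicate_seed(base_seed, i))
        out.append(run_replicate(cfg, replicate_id=i))
    return out
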