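"""Founder genomes and genetic transmission.

Genomes are fully synthetic: biallelic 0/1 sites on a genetic map measured in
Morgans. Two site classes are tracked, causal QTN and neutral SNP markers;
nothing outside those sites is ever stored. Transmission follows a Poisson
crossover process with no interference (Haldane model), so a chromosome of
length L Morgans receives on average L crossovers per meiosis.

Founders emulate a maize-like base population: a panmictic base of
``n_founders`` individuals in Hardy-Weinberg equilibrium (coalescent-derived
haplotypes via msprime, or a Beta-distributed allele-frequency fallback),
split into a public and a private pool that then random-mate independently
for ``split_generations`` generations of pure drift.
"""

from __future__ import annotations

import dataclasses
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np

from ._kernels import gamete_fill

__all__ = [
    "GenomeSpec",
    "Individual",
    "Population",
    "simulate_founders",
    "meiosis",
    "make_gametes",
    "cross",
    "cross_pairs",
    "self_pollinate",
    "self_each",
    "make_dh",
    "make_dh_each",
    "write_vcf",
]

PUBLIC = 0
PRIVATE = 1
_POOL_NAMES = {PUBLIC: "public", PRIVATE: "private"}


# --------------------------------------------------------------------------
# genome specification
# --------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class GenomeSpec:
    """Genetic map plus QTN/SNP site coordinates.

    ``qtn_positions`` / ``snp_positions`` hold, per chromosome, sorted map
    positions in Morgans. Positions must be strictly increasing, lie in
    [0, morgans_per_chr], and the two site classes must be disjoint within a
    chromosome.
    """

    n_chromosomes: int = 10
    morgans_per_chr: float = 2.0
    bp_per_chr: float = 2.0e8
    recomb_rate: float = 1.25e-8
    mutation_rate: float = 2.5e-8
    qtn_per_chr: int = 300
    snp_per_chr: int = 3000
    qtn_positions: tuple = None
    snp_positions: tuple = None

    def __post_init__(self):
        if self.qtn_positions is None or self.snp_positions is None:
            raise ValueError(
                "positions are required; use GenomeSpec.create() to draw them"
            )
        qtn = tuple(np.asarray(p, dtype=float) for p in self.qtn_positions)
        snp = tuple(np.asarray(p, dtype=float) for p in self.snp_positions)
        object.__setattr__(self, "qtn_positions", qtn)
        object.__setattr__(self, "snp_positions", snp)
        if len(qtn) != self.n_chromosomes or len(snp) != self.n_chromosomes:
            raise ValueError("one position array per chromosome required")
        for c, (q, s) in enumerate(zip(qtn, snp)):
            if len(q) != self.qtn_per_chr or len(s) != self.snp_per_chr:
                raise ValueError(f"chromosome {c}: site counts do not match "
                                 "the declared per-chromosome numbers")
            for arr in (q, s):
                if arr.size and (np.any(np.diff(arr) <= 0)
                                 or arr[0] < 0 or arr[-1] > self.morgans_per_chr):
                    raise ValueError(
                        f"chromosome {c}: positions must be strictly increasing "
                        f"in [0, {self.morgans_per_chr}]"
                    )
            if np.intersect1d(q, s).size:
                raise ValueError(f"chromosome {c}: QTN and SNP positions overlap")

    @classmethod
    def create(cls, rng=None, *, n_chromosomes=10, morgans_per_chr=2.0,
               qtn_per_chr=300, snp_per_chr=3000, **kwargs):
        """Draw default site coordinates: QTN evenly spaced on the map, SNPs
        uniform-random (resampled to avoid QTN collisions)."""
        rng = np.random.default_rng(rng)
        L = morgans_per_chr
        qtn, snp = [], []
        for _ in range(n_chromosomes):
            grid = (np.arange(qtn_per_chr) + 0.5) * L / qtn_per_chr
            s = rng.uniform(0.0, L, size=snp_per_chr)
            while True:
                s = np.unique(s)
                clash = np.isin(s, grid)
                short = snp_per_chr - s.size + clash.sum()
                if short == 0:
                    break
                s = np.concatenate([s[~clash], rng.uniform(0.0, L, size=short)])
            qtn.append(grid)
            snp.append(np.sort(s))
        return cls(n_chromosomes=n_chromosomes, morgans_per_chr=morgans_per_chr,
                   qtn_per_chr=qtn_per_chr, snp_per_chr=snp_per_chr,
                   qtn_positions=tuple(qtn), snp_positions=tuple(snp), **kwargs)

    # -- derived site map ---------------------------------------------------

    @cached_property
    def _sitemap(self):
        pos, starts, qtn_idx, snp_idx = [], [0], [], []
        off = 0
        for c in range(self.n_chromosomes):
            q, s = self.qtn_positions[c], self.snp_positions[c]
            allp = np.concatenate([q, s])
            order = np.argsort(allp, kind="stable")
            allp = allp[order]
            is_qtn = np.concatenate(
                [np.ones(len(q), bool), np.zeros(len(s), bool)])[order]
            pos.append(allp)
            qtn_idx.append(off + np.flatnonzero(is_qtn))
            snp_idx.append(off + np.flatnonzero(~is_qtn))
            off += allp.size
            starts.append(off)
        return (np.concatenate(pos), np.asarray(starts, dtype=np.int64),
                np.concatenate(qtn_idx), np.concatenate(snp_idx))

    @property
    def site_pos(self) -> np.ndarray:
        return self._sitemap[0]

    @property
    def chrom_starts(self) -> np.ndarray:
        return self._sitemap[1]

    @property
    def qtn_sites(self) -> np.ndarray:
        return self._sitemap[2]

    @property
    def snp_sites(self) -> np.ndarray:
        return self._sitemap[3]

    @property
    def n_sites(self) -> int:
        return self.site_pos.size

    @property
    def n_qtn(self) -> int:
        return self.qtn_per_chr * self.n_chromosomes

    @property
    def n_snp(self) -> int:
        return self.snp_per_chr * self.n_chromosomes

    def chrom_of_site(self) -> np.ndarray:
        return np.searchsorted(self.chrom_starts, np.arange(self.n_sites),
                               side="right") - 1


@dataclasses.dataclass
class Individual:
    """Lightweight per-individual view onto a :class:`Population`."""

    id: int
    haplotypes: np.ndarray  # (2, S) uint8
    mother: int
    father: int
    cohort_tag: str
    birth_year: int
    pool: str


class Population:
    """An ordered collection of diploid individuals over one GenomeSpec.

    Haplotypes live in a single (n, 2, S) uint8 array; ``mother``/``father``
    record pedigree by id (-1 for unknown).
    """

    def __init__(self, genome: GenomeSpec, haplo: np.ndarray, ids: np.ndarray,
                 mother=None, father=None, cohort_tag: str = "founder",
                 birth_year: int = 0, pool=None):
        haplo = np.ascontiguousarray(haplo, dtype=np.uint8)
        if haplo.ndim != 3 or haplo.shape[1] != 2 or haplo.shape[2] != genome.n_sites:
            raise ValueError("haplo must have shape (n, 2, n_sites)")
        if haplo.size and haplo.max() > 1:
            raise ValueError("alleles must be 0/1")
        n = haplo.shape[0]
        ids = np.asarray(ids, dtype=np.int64)
        if ids.shape != (n,) or np.unique(ids).size != n:
            raise ValueError("ids must be unique, one per individual")
        self.genome = genome
        self.haplo = haplo
        self.ids = ids
        self.mother = (np.full(n, -1, np.int64) if mother is None
                       else np.asarray(mother, np.int64))
        self.father = (np.full(n, -1, np.int64) if father is None
                       else np.asarray(father, np.int64))
        self.cohort_tag = cohort_tag
        self.birth_year = birth_year
        self.pool = (np.full(n, PUBLIC, np.int8) if pool is None
                     else np.asarray(pool, np.int8))

    # -- basics -------------------------------------------------------------

    @property
    def n(self) -> int:
        return self.haplo.shape[0]

    def __len__(self):
        return self.n

    def individual(self, row: int) -> Individual:
        return Individual(
            id=int(self.ids[row]), haplotypes=self.haplo[row],
            mother=int(self.mother[row]), father=int(self.father[row]),
            cohort_tag=self.cohort_tag, birth_year=self.birth_year,
            pool=_POOL_NAMES[int(self.pool[row])])

    def __iter__(self) -> Iterable[Individual]:
        return (self.individual(i) for i in range(self.n))

    def subset(self, rows) -> "Population":
        rows = np.asarray(rows)
        return Population(self.genome, self.haplo[rows], self.ids[rows],
                          self.mother[rows], self.father[rows],
                          self.cohort_tag, self.birth_year, self.pool[rows])

    def copy(self) -> "Population":
        return Population(self.genome, self.haplo.copy(), self.ids.copy(),
                          self.mother.copy(), self.father.copy(),
                          self.cohort_tag, self.birth_year, self.pool.copy())

    @classmethod
    def concat(cls, pops: Sequence["Population"]) -> "Population":
        g = pops[0].genome
        return cls(g, np.concatenate([p.haplo for p in pops]),
                   np.concatenate([p.ids for p in pops]),
                   np.concatenate([p.mother for p in pops]),
                   np.concatenate([p.father for p in pops]),
                   pops[0].cohort_tag, pops[0].birth_year,
                   np.concatenate([p.pool for p in pops]))

    # -- genotype summaries ---------------------------------------------------

    def dosage(self, sites=None) -> np.ndarray:
        """Alt-allele count in {0,1,2}, int8, optionally at a site subset."""
        d = self.haplo.sum(axis=1, dtype=np.int8)
        return d if sites is None else d[:, sites]

    def heterozygous(self, sites=None) -> np.ndarray:
        h = self.haplo[:, 0, :] != self.haplo[:, 1, :]
        return h if sites is None else h[:, sites]

    def heterozygosity(self) -> np.ndarray:
        """Per-individual fraction of heterozygous sites."""
        return self.heterozygous().mean(axis=1)

    def allele_freq(self, sites=None) -> np.ndarray:
        return self.dosage(sites).mean(axis=0) / 2.0


# --------------------------------------------------------------------------
# meiosis and crossing
# --------------------------------------------------------------------------

def make_gametes(pop: Population, parent_rows, rng) -> np.ndarray:
    """One independent meiotic gamete per entry of ``parent_rows``.

    Crossovers per chromosome ~ Poisson(length in Morgans), breakpoints
    uniform, no interference; starting haplotype is a fair coin.
    """
    g = pop.genome
    parent_rows = np.asarray(parent_rows, dtype=np.int64)
    k = parent_rows.size
    n_chrom = g.n_chromosomes
    counts = rng.poisson(g.morgans_per_chr, size=k * n_chrom)
    offsets = np.zeros(k * n_chrom + 1, dtype=np.int64)
    np.cumsum(counts, out=offsets[1:])
    co_pos = rng.uniform(0.0, g.morgans_per_chr, size=int(offsets[-1]))
    start = rng.integers(0, 2, size=k * n_chrom, dtype=np.uint8)
    out = np.empty((k, g.n_sites), dtype=np.uint8)
    if k:
        gamete_fill(pop.haplo, parent_rows, g.chrom_starts, g.site_pos,
                    co_pos, offsets, start, out)
    return out


def meiosis(pop: Population, row: int, rng) -> np.ndarray:
    """A single gamete (one haplotype over all sites) from individual ``row``."""
    return make_gametes(pop, [row], rng)[0]


def _progeny(genome, gam_m, gam_f, ids, mid, fid, tag, year, pool):
    haplo = np.stack([gam_m, gam_f], axis=1)
    return Population(genome, haplo, ids, mid, fid, tag, year, pool)


def cross_pairs(pop_m: Population, rows_m, pop_f: Population, rows_f, rng, *,
                n_per_pair: int = 1, cohort_tag: str = "F1",
                birth_year: int = 0, id_start: int = 0) -> Population:
    """One (or ``n_per_pair``) progeny for each (mother, father) row pair."""
    if n_per_pair < 1:
        raise ValueError("n_per_pair must be >= 1")
    rows_m = np.repeat(np.asarray(rows_m, np.int64), n_per_pair)
    rows_f = np.repeat(np.asarray(rows_f, np.int64), n_per_pair)
    if rows_m.size != rows_f.size:
        raise ValueError("mother and father row lists must have equal length")
    gm = make_gametes(pop_m, rows_m, rng)
    gf = make_gametes(pop_f, rows_f, rng)
    n = rows_m.size
    ids = id_start + np.arange(n, dtype=np.int64)
    pool = pop_m.pool[rows_m]
    return _progeny(pop_m.genome, gm, gf, ids, pop_m.ids[rows_m],
                    pop_f.ids[rows_f], cohort_tag, birth_year, pool)


def cross(mother: Population, mrow: int, father: Population, frow: int,
          n_progeny: int, rng, **kw) -> Population:
    """Full-sib family from one mother x father pair."""
    if n_progeny < 1:
        raise ValueError("n_progeny must be >= 1")
    return cross_pairs(mother, [mrow] * n_progeny, father, [frow] * n_progeny,
                       rng, **kw)


def self_each(pop: Population, rows, n_per: int, rng, *,
              cohort_tag: str = "self", birth_year: int = 0,
              id_start: int = 0) -> Population:
    """``n_per`` selfed progeny per row: two independent gametes per progeny."""
    if n_per < 1:
        raise ValueError("n_per must be >= 1")
    rows = np.repeat(np.asarray(rows, np.int64), n_per)
    gm = make_gametes(pop, rows, rng)
    gf = make_gametes(pop, rows, rng)
    ids = id_start + np.arange(rows.size, dtype=np.int64)
    return _progeny(pop.genome, gm, gf, ids, pop.ids[rows], pop.ids[rows],
                    cohort_tag, birth_year, pop.pool[rows])


def self_pollinate(pop: Population, row: int, n_progeny: int, rng, **kw
                   ) -> Population:
    return self_each(pop, [row], n_progeny, rng, **kw)


def make_dh_each(pop: Population, rows, n_per: int, rng, *,
                 birth_year: int = 0, id_start: int = 0) -> Population:
    """Doubled-haploid lines: one gamete per line, duplicated into both
    haplotypes. Heterozygosity is exactly zero by construction."""
    if n_per < 1:
        raise ValueError("n_per must be >= 1")
    rows = np.repeat(np.asarray(rows, np.int64), n_per)
    gam = make_gametes(pop, rows, rng)
    ids = id_start + np.arange(rows.size, dtype=np.int64)
    return _progeny(pop.genome, gam, gam.copy(), ids, pop.ids[rows],
                    pop.ids[rows], "DH", birth_year, pop.pool[rows])


def make_dh(donor: Population, row: int, n_lines: int, rng, **kw) -> Population:
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    return make_dh_each(donor, [row], n_lines, rng, **kw)


# --------------------------------------------------------------------------
# founder simulation
# --------------------------------------------------------------------------

def _coalescent_base(spec: GenomeSpec, n_founders: int, rng):
    """Per-chromosome candidate haplotypes from a neutral coalescent."""
    import msprime

    pos_chr, hap_chr = [], []
    for _ in range(spec.n_chromosomes):
        seed = int(rng.integers(1, 2**31 - 1))
        ts = msprime.sim_ancestry(
            samples=n_founders, ploidy=2, population_size=n_founders,
            sequence_length=spec.bp_per_chr,
            recombination_rate=spec.recomb_rate, random_seed=seed)
        mts = msprime.sim_mutations(
            ts, rate=spec.mutation_rate,
            model=msprime.BinaryMutationModel(), random_seed=seed)
        geno = mts.genotype_matrix()  # (sites, 2n)
        pos_bp = np.array([s.position for s in mts.sites()])
        keep = (geno.max(axis=1) <= 1)
        pos_chr.append(pos_bp[keep] / spec.bp_per_chr * spec.morgans_per_chr)
        hap_chr.append(np.ascontiguousarray(geno[keep].T, dtype=np.uint8))
    return pos_chr, hap_chr


def _beta_base(spec: GenomeSpec, n_founders: int, rng, oversample: float = 3.0):
    """Hardy-Weinberg candidate haplotypes: ancestral frequencies from
    Beta(0.5, 0.5), independent sites. Candidate positions include the even
    QTN grid so post-drift QTN selection can land on it."""
    need = spec.qtn_per_chr + spec.snp_per_chr
    n_cand = max(int(np.ceil(oversample * need)), need + 8)
    pos_chr, hap_chr = [], []
    for c in range(spec.n_chromosomes):
        grid = (np.arange(spec.qtn_per_chr) + 0.5) \
            * spec.morgans_per_chr / spec.qtn_per_chr
        extra = rng.uniform(0.0, spec.morgans_per_chr,
                            size=n_cand - grid.size)
        pos = np.unique(np.concatenate([grid, extra]))
        p = rng.beta(0.5, 0.5, size=pos.size)
        hap = (rng.random((2 * n_founders, pos.size)) < p).astype(np.uint8)
        pos_chr.append(pos)
        hap_chr.append(hap)
    return pos_chr, hap_chr


def _drift_pool(haplo, sitemap_spec, rows, generations, rng):
    """Constant-size Wright-Fisher random mating (selfing allowed) within one
    pool, returning the drifted haplotypes for those rows."""
    pop = Population(sitemap_spec, haplo[rows], np.arange(rows.size))
    for _ in range(generations):
        mothers = rng.integers(0, pop.n, size=pop.n)
        fathers = rng.integers(0, pop.n, size=pop.n)
        gm = make_gametes(pop, mothers, rng)
        gf = make_gametes(pop, fathers, rng)
        pop = Population(sitemap_spec, np.stack([gm, gf], axis=1),
                         np.arange(pop.n))
    return pop.haplo


def _select_sites(spec, pos_chr, hap, starts, rng):
    """Pick QTN (nearest segregating candidate to each even grid point) and
    SNP (random segregating candidates) per chromosome. Returns realized
    position tuples and the global candidate-column indices, or None if a
    chromosome lacks enough segregating sites."""
    dose = hap.sum(axis=0)
    seg = (dose > 0) & (dose < hap.shape[0])
    qtn_pos, snp_pos, cols = [], [], []
    for c in range(spec.n_chromosomes):
        lo, hi = starts[c], starts[c + 1]
        seg_local = np.flatnonzero(seg[lo:hi])
        if seg_local.size < spec.qtn_per_chr + spec.snp_per_chr:
            return None
        pos = pos_chr[c][seg_local]
        grid = (np.arange(spec.qtn_per_chr) + 0.5) \
            * spec.morgans_per_chr / spec.qtn_per_chr
        taken = np.zeros(pos.size, dtype=bool)
        q_idx = np.empty(spec.qtn_per_chr, dtype=np.int64)
        for j, gpos in enumerate(grid):
            i = int(np.argmin(np.where(taken, np.inf, np.abs(pos - gpos))))
            taken[i] = True
            q_idx[j] = i
        free = np.flatnonzero(~taken)
        s_idx = rng.choice(free, size=spec.snp_per_chr, replace=False)
        chosen = np.sort(np.concatenate([q_idx, s_idx]))
        cols.append(lo + seg_local[chosen])
        qtn_pos.append(pos[np.sort(q_idx)])
        snp_pos.append(pos[np.sort(s_idx)])
    return tuple(qtn_pos), tuple(snp_pos), np.concatenate(cols)


def simulate_founders(spec: GenomeSpec, n_founders: int = 100,
                      split_generations: int = 30, rng_seed=None,
                      method: str = "coalescent",
                      max_retries: int = 5) -> Population:
    """Generate the founder population.

    A panmictic Hardy-Weinberg base of ``n_founders`` individuals is split
    into equal public/private pools which random-mate independently for
    ``split_generations`` Wright-Fisher generations (pure drift, no further
    mutation). QTN/SNP sites are then selected among sites still segregating
    in the combined founder set; the returned Population's ``genome`` carries
    the realized coordinates.

    method: "coalescent" (msprime) or "beta" (Beta(0.5, 0.5) frequencies).
    Raises RuntimeError if, after ``max_retries`` fresh attempts, some
    chromosome lacks enough segregating sites.
    """
    if n_founders < 2 or n_founders % 2:
        raise ValueError("n_founders must be even and >= 2")
    if split_generations < 0:
        raise ValueError("split_generations must be >= 0")
    if method not in ("coalescent", "beta"):
        raise ValueError(f"unknown founder method: {method!r}")
    rng = np.random.default_rng(rng_seed)

    for _ in range(max_retries):
        if method == "coalescent":
            pos_chr, hap_chr = _coalescent_base(spec, n_founders, rng)
        else:
            pos_chr, hap_chr = _beta_base(spec, n_founders, rng)
        starts = np.zeros(spec.n_chromosomes + 1, dtype=np.int64)
        np.cumsum([p.size for p in pos_chr], out=starts[1:])
        # temporary spec over the candidate sites (QTN bookkeeping unused)
        cand_spec = _candidate_spec(spec, pos_chr)
        hap = np.ascontiguousarray(
            np.concatenate(hap_chr, axis=1).reshape(n_founders, 2, -1))
        if split_generations > 0:
            half = n_founders // 2
            hap = hap.copy()
            hap[:half] = _drift_pool(hap, cand_spec, np.arange(half),
                                     split_generations, rng)
            hap[half:] = _drift_pool(hap, cand_spec,
                                     np.arange(half, n_founders),
                                     split_generations, rng)
        flat = hap.reshape(2 * n_founders, -1)
        picked = _select_sites(spec, pos_chr, flat, starts, rng)
        if picked is None:
            continue
        qtn_pos, snp_pos, cols = picked
        genome = dataclasses.replace(spec, qtn_positions=qtn_pos,
                                     snp_positions=snp_pos)
        pool = np.repeat([PUBLIC, PRIVATE], n_founders // 2).astype(np.int8)
        return Population(genome, hap[:, :, cols],
                          ids=np.arange(n_founders, dtype=np.int64),
                          cohort_tag="founder", birth_year=0, pool=pool)
    raise RuntimeError(
        f"could not obtain {spec.qtn_per_chr + spec.snp_per_chr} segregating "
        f"sites per chromosome after {max_retries} attempts")


class _SiteMap:
    """Bare genetic map over candidate sites (duck-types the GenomeSpec
    attributes used by Population and make_gametes)."""

    def __init__(self, spec, pos_chr):
        self.n_chromosomes = spec.n_chromosomes
        self.morgans_per_chr = spec.morgans_per_chr
        self.site_pos = np.concatenate(pos_chr)
        starts = np.zeros(len(pos_chr) + 1, dtype=np.int64)
        np.cumsum([p.size for p in pos_chr], out=starts[1:])
        self.chrom_starts = starts
        self.n_sites = self.site_pos.size


def _candidate_spec(spec, pos_chr):
    return _SiteMap(spec, pos_chr)


# --------------------------------------------------------------------------
# VCF export
# --------------------------------------------------------------------------

def write_vcf(pop: Population, path, site_class: str = "snp",
              sample_prefix: str = "ind") -> None:
    """Write genotypes as a minimal diploid VCF (one contig per chromosome).

    Coordinates are synthetic: 1-based round(map position in Morgans x 1e6),
    nudged upward where rounding would collide. REF/ALT are placeholder A/T
    since sites are abstract biallelic 0/1.
    """
    g = pop.genome
    if site_class == "snp":
        sites = g.snp_sites
    elif site_class == "qtn":
        sites = g.qtn_sites
    elif site_class == "all":
        sites = np.arange(g.n_sites)
    else:
        raise ValueError("site_class must be 'snp', 'qtn' or 'all'")
    chrom = g.chrom_of_site()[sites]
    rel_pos = g.site_pos[sites]
    contig_len = int(round(g.morgans_per_chr * 1e6)) + g.n_sites + 1
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweetsim\n")
        for c in range(g.n_chromosomes):
            fh.write(f"##contig=<ID=chr{c + 1},length={contig_len}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(f"{sample_prefix}{i}" for i in pop.ids)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + samples + "\n")
        h = pop.haplo[:, :, sites]
        last = {}
        for j in range(sites.size):
            c = int(chrom[j])
            p = int(round(rel_pos[j] * 1e6)) + 1
            if p <= last.get(c, 0):
                p = last[c] + 1
            last[c] = p
            gts = "\t".join(f"{h[i, 0, j]}|{h[i, 1, j]}" for i in range(pop.n))
            fh.write(f"chr{c + 1}\t{p}\tsite{sites[j]}\tA\tT\t.\t.\t.\tGT\t"
                     + gts + "\n")
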