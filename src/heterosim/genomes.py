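"""Founder genomes, genetic maps, and marker/QTL panels.

The study species is an outbred clonal crop. Founders are drawn as a panel
of phased biallelic haplotypes over a multi-chromosome genetic map, with
derived-allele frequencies following the neutral site-frequency spectrum
(P(count = i) proportional to 1/i over haploid copies) and alleles assigned
to haplotypes exchangeably, i.e. at linkage equilibrium. An optional
coalescent backend (msprime) generates founders with realistic linkage
disequilibrium instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GenomeMap",
    "Population",
    "make_genome_map",
    "simulate_founder_haplotypes",
    "sample_qtl_and_markers",
    "draw_and_split",
    "write_vcf",
]

FOUNDER = -1  # pedigree sentinel for unknown/founder parent


@dataclass(frozen=True)
class GenomeMap:
    """Genetic map: loci at genetic positions (Morgans) on linear chromosomes.

    ``positions`` holds one sorted array per chromosome; locus indices are
    global (concatenated across chromosomes in order). ``qtl_index`` and
    ``marker_index`` are global index arrays designating the trait loci and
    the SNP-chip panel; they may overlap.
    """

    positions: tuple[np.ndarray, ...]
    qtl_index: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    marker_index: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self):
        for pos in self.positions:
            if len(pos) and (np.any(np.diff(pos) <= 0) or pos[0] < 0):
                raise ValueError("positions must be strictly increasing and non-negative")
        n = self.n_loci
        for idx in (self.qtl_index, self.marker_index):
            if len(idx) and (idx.min() < 0 or idx.max() >= n):
                raise ValueError("locus index out of range")

    @property
    def n_chromosomes(self) -> int:
        return len(self.positions)

    @property
    def n_loci(self) -> int:
        return sum(len(p) for p in self.positions)

    @property
    def chrom_lengths(self) -> np.ndarray:
        """Chromosome map lengths in Morgans (end position of each)."""
        return np.array([p[-1] if len(p) else 0.0 for p in self.positions])

    def chrom_slices(self) -> list[slice]:
        """Global-index slice per chromosome."""
        out, start = [], 0
        for p in self.positions:
            out.append(slice(start, start + len(p)))
            start += len(p)
        return out

    def chrom_of(self) -> np.ndarray:
        """Chromosome id per global locus."""
        return np.repeat(np.arange(self.n_chromosomes), [len(p) for p in self.positions])


@dataclass
class Population:
    """A set of individuals with phased haplotypes.

    ``haplotypes`` has shape (n_individuals, ploidy, n_loci), uint8 in {0, 1}
    ("1" is the alternate allele). ``pedigree`` has shape (n, 2) with parent
    ids or the FOUNDER sentinel. ``family`` labels full-sib families (the
    cross an individual came from); -1 when not applicable.
    """

    haplotypes: np.ndarray
    ids: np.ndarray
    pedigree: np.ndarray
    pool: str = "single"  # one of {"A", "B", "hybrid", "single"}
    cycle: int = 0
    family: np.ndarray | None = None

    def __post_init__(self):
        if self.haplotypes.ndim != 3:
            raise ValueError("haplotypes must be (n, ploidy, loci)")
        if self.ploidy % 2 != 0:
            raise ValueError(f"ploidy must be even, got {self.ploidy}")
        if len(self.ids) != len(self.haplotypes) or len(self.pedigree) != len(self.ids):
            raise ValueError("ids/pedigree/haplotypes length mismatch")
        if self.family is None:
            self.family = np.full(len(self.ids), -1, dtype=np.int64)

    def __len__(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def ploidy(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[2]

    def dosages(self, loci: np.ndarray | slice | None = None) -> np.ndarray:
        """Alternate-allele dosage matrix (n, loci), values in 0..ploidy."""
        h = self.haplotypes if loci is None else self.haplotypes[:, :, loci]
        return h.sum(axis=1, dtype=np.int64)

    def allele_freq(self, loci: np.ndarray | slice | None = None) -> np.ndarray:
        """Per-locus alternate-allele frequency."""
        return self.dosages(loci).mean(axis=0) / self.ploidy

    def subset(self, idx: np.ndarray) -> "Population":
        return Population(
            haplotypes=self.haplotypes[idx],
            ids=self.ids[idx],
            pedigree=self.pedigree[idx],
            pool=self.pool,
            cycle=self.cycle,
            family=self.family[idx],
        )


def make_genome_map(
    n_chromosomes: int = 10,
    n_loci_per_chr: int = 1000,
    morgans_per_chr: float = 1.0,
    rng_seed: int | np.random.Generator = 0,
) -> GenomeMap:
    """Uniform-random locus positions on equal-length chromosomes."""
    rng = np.random.default_rng(rng_seed)
    positions = []
    for _ in range(n_chromosomes):
        pos = np.sort(rng.uniform(0.0, morgans_per_chr, size=n_loci_per_chr))
        # enforce strict ordering in the (measure-zero) event of ties
        while np.any(np.diff(pos) <= 0):
            pos = np.sort(rng.uniform(0.0, morgans_per_chr, size=n_loci_per_chr))
        positions.append(pos)
    return GenomeMap(positions=tuple(positions))


def _sfs_frequencies(n_loci: int, n_haplotypes: int, rng: np.random.Generator) -> np.ndarray:
    """Derived-allele counts under the neutral SFS, P(i) ~ 1/i, i in 1..n-1."""
    classes = np.arange(1, n_haplotypes)
    w = 1.0 / classes
    return rng.choice(classes, size=n_loci, p=w / w.sum())


def simulate_founder_haplotypes(
    n_founders: int,
    ploidy: int,
    genome_map: GenomeMap,
    rng_seed: int | np.random.Generator = 0,
    backend: str = "sfs",
) -> Population:
    """Draw an outbred founder population over the map's loci.

    Default backend assigns, per locus, a derived-allele count from the
    neutral frequency spectrum and scatters the copies exchangeably over
    the n_founders * ploidy haplotypes, so every locus segregates and the
    panel is at linkage equilibrium. ``backend="coalescent"`` simulates
    haplotypes with msprime instead (mutation/recombination on the map's
    chromosome lengths) and resamples loci to the map's density.
    """
    if ploidy % 2 != 0 or ploidy <= 0:
        raise ValueError(f"ploidy must be a positive even integer, got {ploidy}")
    n_hap = n_founders * ploidy
    if n_hap < 2:
        raise ValueError("need at least 2 haplotypes for segregating loci")
    rng = np.random.default_rng(rng_seed)
    n_loci = genome_map.n_loci
    if backend == "coalescent":
        haps = _coalescent_haplotypes(n_hap, genome_map, rng)
    elif backend == "sfs":
        counts = _sfs_frequencies(n_loci, n_hap, rng)
        haps = np.zeros((n_hap, n_loci), dtype=np.uint8)
        # exchangeable placement: random permutation of haplotypes per locus
        for j in range(n_loci):
            carriers = rng.choice(n_hap, size=counts[j], replace=False)
            haps[carriers, j] = 1
    else:
        raise ValueError(f"unknown backend {backend!r}")
    ac = haps.sum(axis=0)
    bad = int(np.sum((ac == 0) | (ac == n_hap)))
    if bad:
        raise RuntimeError(f"{bad} of {n_loci} loci are not segregating")
    haplotypes = haps.reshape(n_founders, ploidy, n_loci)
    ids = np.arange(n_founders, dtype=np.int64)
    pedigree = np.full((n_founders, 2), FOUNDER, dtype=np.int64)
    return Population(haplotypes=haplotypes, ids=ids, pedigree=pedigree)


def _coalescent_haplotypes(n_hap: int, genome_map: GenomeMap, rng: np.random.Generator) -> np.ndarray:
    """msprime-backed founder haplotypes with realistic LD (optional backend)."""
    import msprime

    cols = []
    for chrom, pos in enumerate(genome_map.positions):
        L = float(pos[-1]) if len(pos) else 1.0
        seq_len = 1e6 * max(L, 1e-3)  # 1 Mb per Morgan convention
        ts = msprime.sim_ancestry(
            samples=n_hap,
            ploidy=1,
            sequence_length=seq_len,
            recombination_rate=L / seq_len,
            population_size=100,
            random_seed=int(rng.integers(1, 2**31 - 1)),
        )
        mts = msprime.sim_mutations(
            ts, rate=2.5e-8 * 50, random_seed=int(rng.integers(1, 2**31 - 1))
        )
        G = mts.genotype_matrix().T.astype(np.uint8)  # (n_hap, sites)
        G = G[:, (G.sum(0) > 0) & (G.sum(0) < n_hap)]
        if G.shape[1] < len(pos):
            raise RuntimeError(
                f"coalescent backend produced {G.shape[1]} segregating sites on "
                f"chromosome {chrom}, fewer than the {len(pos)} requested"
            )
        keep = np.sort(rng.choice(G.shape[1], size=len(pos), replace=False))
        cols.append(G[:, keep])
    return np.concatenate(cols, axis=1)


def sample_qtl_and_markers(
    genome_map: GenomeMap,
    n_qtl_per_chr: int,
    n_markers_per_chr: int,
    rng_seed: int | np.random.Generator = 0,
) -> GenomeMap:
    """Designate QTL and SNP-chip marker loci, uniformly per chromosome.

    QTL and markers are sampled independently without replacement within a
    chromosome, so the two panels may overlap (as on a real chip).
    """
    rng = np.random.default_rng(rng_seed)
    qtl, markers = [], []
    for sl, pos in zip(genome_map.chrom_slices(), genome_map.positions):
        n_avail = len(pos)
        if n_qtl_per_chr > n_avail or n_markers_per_chr > n_avail:
            raise ValueError(
                f"requested {n_qtl_per_chr} QTL / {n_markers_per_chr} markers "
                f"but only {n_avail} loci on chromosome"
            )
        qtl.append(np.sort(rng.choice(n_avail, size=n_qtl_per_chr, replace=False)) + sl.start)
        markers.append(
            np.sort(rng.choice(n_avail, size=n_markers_per_chr, replace=False)) + sl.start
        )
    return replace(
        genome_map,
        qtl_index=np.concatenate(qtl) if qtl else np.empty(0, dtype=np.int64),
        marker_index=np.concatenate(markers) if markers else np.empty(0, dtype=np.int64),
    )


def draw_and_split(
    pop: Population,
    n: int,
    n_pools: int = 1,
    rng_seed: int | np.random.Generator = 0,
) -> tuple[Population, ...]:
    """Sample n individuals without replacement; optionally split into 2 pools.

    The two-pool case returns disjoint pools of n/2 labelled "A" and "B",
    the starting germplasm of a reciprocal recurrent selection program.
    """
    if n > len(pop):
        raise ValueError(f"cannot draw {n} from population of {len(pop)}")
    if n_pools not in (1, 2):
        raise ValueError("n_pools must be 1 or 2")
    if n % n_pools:
        raise ValueError("n must be divisible by n_pools")
    rng = np.random.default_rng(rng_seed)
    idx = rng.choice(len(pop), size=n, replace=False)
    if n_pools == 1:
        sub = pop.subset(idx)
        sub.pool = "single"
        return (sub,)
    a, b = pop.subset(idx[: n // 2]), pop.subset(idx[n // 2 :])
    a.pool, b.pool = "A", "B"
    return (a, b)


def write_vcf(path: str, pop: Population, genome_map: GenomeMap) -> None:
    """Export genotypes as an uncompressed VCF (phased GT with ploidy alleles).

    Physical positions follow a 1 Mb per Morgan convention, noted in the
    header. Diploids produce standard two-allele GT fields.
    """
    chrom = genome_map.chrom_of()
    pos_m = np.concatenate(genome_map.positions)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=heterosim\n")
        fh.write("##positions=genetic_Morgans_x_1e6 (1 Mb per Morgan convention)\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c, p in enumerate(genome_map.positions):
            fh.write(f"##contig=<ID=chr{c + 1},length={int(1e6 * (p[-1] + 1))}>\n")
        samples = "\t".join(f"ind{i}" for i in pop.ids)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for j in range(genome_map.n_loci):
            gts = "\t".join(
                "|".join(str(int(a)) for a in pop.haplotypes[i, :, j]) for i in range(len(pop))
            )
            fh.write(
                f"chr{chrom[j] + 1}\t{int(pos_m[j] * 1e6) + 1}\tlocus{j}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n"
            )
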