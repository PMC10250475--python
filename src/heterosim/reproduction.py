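"""Meiosis, crossing, doubled haploids, and mating-plan construction.

Meiosis assumes bivalent pairing at all ploidies: the phi homologues of a
chromosome pair at random into phi/2 bivalents, each bivalent recombines
with a Poisson number of crossovers (mean = map length in Morgans, no
interference, no obligate chiasma), and the gamete receives one recombinant
chromatid per bivalent. There is no double reduction, matching the
fixed assumption of the simulated species. The diploid case reduces to
standard meiosis.

Mating plans implement maximum avoidance of inbreeding (Kimura & Crow):
two full sibs are kept per family and each sib pair is mated to the sib
pair of the family least related to it by pedigree kinship (Wright's path
counting, depth-limited), ties broken by lowest family index. With 2^k
families this realises the circular design in which no common ancestor
recurs for k generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomes import FOUNDER, GenomeMap, Population

__all__ = [
    "CrossPlan",
    "PedigreeBook",
    "make_gamete",
    "cross",
    "make_crosses",
    "make_dh",
    "make_dh_population",
    "random_plan",
    "max_avoidance_plan",
    "testcross_plan",
]


@dataclass
class CrossPlan:
    """List of (mother id, father id, n_progeny) with a plan kind tag."""

    crosses: list[tuple[int, int, int]]
    kind: str = "explicit"  # {"random", "max_avoidance", "testcross", "explicit"}

    def __post_init__(self):
        for m, f, n in self.crosses:
            if n < 1:
                raise ValueError("n_progeny must be >= 1")
            if m == f:
                raise ValueError("selfing is excluded from all plans")

    def __len__(self) -> int:
        return len(self.crosses)

    @property
    def total_progeny(self) -> int:
        return sum(n for _, _, n in self.crosses)

    def to_csv(self, path: str) -> None:
        pd.DataFrame(self.crosses, columns=["mother", "father", "n_progeny"]).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str, kind: str = "explicit") -> "CrossPlan":
        df = pd.read_csv(path)
        return cls([(int(m), int(f), int(n)) for m, f, n in df.to_numpy()], kind=kind)


class PedigreeBook:
    """Global id -> (mother, father) registry with depth-limited kinship."""

    def __init__(self):
        self._parents: dict[int, tuple[int, int]] = {}
        self._next_id = 0

    def register_founders(self, pop: Population) -> None:
        for i in pop.ids:
            self._parents[int(i)] = (FOUNDER, FOUNDER)
        if len(pop.ids):
            self._next_id = max(self._next_id, int(pop.ids.max()) + 1)

    def new_ids(self, parents: list[tuple[int, int]]) -> np.ndarray:
        ids = np.arange(self._next_id, self._next_id + len(parents), dtype=np.int64)
        for i, (m, f) in zip(ids, parents):
            self._parents[int(i)] = (int(m), int(f))
        self._next_id += len(parents)
        return ids

    def parents_of(self, i: int) -> tuple[int, int]:
        return self._parents.get(int(i), (FOUNDER, FOUNDER))

    def kinship(self, i: int, j: int, depth: int = 5) -> float:
        """Wright's kinship coefficient, truncating ancestry at `depth`."""
        return self._kin(int(i), int(j), depth, {})

    def _kin(self, i: int, j: int, depth: int, memo: dict) -> float:
        if i == FOUNDER or j == FOUNDER:
            return 0.0
        if i > j:
            i, j = j, i
        key = (i, j, depth)
        if key in memo:
            return memo[key]
        if i == j:
            if depth <= 0:
                val = 0.5
            else:
                m, f = self.parents_of(i)
                val = 0.5 * (1.0 + self._kin(m, f, depth - 1, memo))
        elif depth <= 0:
            val = 0.0
        else:
            # recurse on the younger (larger-id) individual's parents
            m, f = self.parents_of(j)
            val = 0.5 * (self._kin(i, m, depth - 1, memo) + self._kin(i, f, depth - 1, memo))
        memo[key] = val
        return val


def _recombinant(
    hap_a: np.ndarray, hap_b: np.ndarray, pos: np.ndarray, length: float, rng: np.random.Generator
) -> np.ndarray:
    """One recombinant chromatid from a bivalent of two homologues."""
    n_xo = rng.poisson(length)
    start = rng.integers(2)
    if n_xo == 0:
        return (hap_a if start == 0 else hap_b).copy()
    xo = np.sort(rng.uniform(0.0, length, size=n_xo))
    # parity of crossovers passed before each locus selects the strand
    strand = (start + np.searchsorted(xo, pos)) % 2
    return np.where(strand == 0, hap_a, hap_b)


def make_gamete(
    parent_haplotypes: np.ndarray, genome_map: GenomeMap, rng: np.random.Generator
) -> np.ndarray:
    """Sample one gamete (phi/2 haploid chromosome sets, concatenated loci).

    parent_haplotypes: (phi, n_loci). Returns (phi/2, n_loci).
    """
    phi = parent_haplotypes.shape[0]
    if phi % 2:
        raise ValueError("odd ploidy cannot undergo bivalent meiosis")
    half = phi // 2
    out = np.empty((half, parent_haplotypes.shape[1]), dtype=parent_haplotypes.dtype)
    lengths = genome_map.chrom_lengths
    for c, (sl, pos) in enumerate(zip(genome_map.chrom_slices(), genome_map.positions)):
        pairing = rng.permutation(phi)
        for b in range(half):
            ia, ib = pairing[2 * b], pairing[2 * b + 1]
            out[b, sl] = _recombinant(
                parent_haplotypes[ia, sl], parent_haplotypes[ib, sl], pos, lengths[c], rng
            )
    return out


def cross(
    mother: np.ndarray,
    father: np.ndarray,
    n_progeny: int,
    genome_map: GenomeMap,
    rng: np.random.Generator,
) -> np.ndarray:
    """Progeny haplotypes (n_progeny, phi, n_loci) from two parents."""
    if mother.shape != father.shape:
        raise ValueError("parents must share ploidy and locus set")
    phi = mother.shape[0]
    out = np.empty((n_progeny, phi, mother.shape[1]), dtype=mother.dtype)
    for k in range(n_progeny):
        out[k, : phi // 2] = make_gamete(mother, genome_map, rng)
        out[k, phi // 2 :] = make_gamete(father, genome_map, rng)
    return out


def make_crosses(
    pop: Population,
    plan: CrossPlan,
    genome_map: GenomeMap,
    book: PedigreeBook,
    rng: np.random.Generator,
    pool: str | None = None,
    cycle: int | None = None,
) -> Population:
    """Execute a CrossPlan against a parent population, one family per cross."""
    id_to_row = {int(i): r for r, i in enumerate(pop.ids)}
    haps, parents, family = [], [], []
    for fam, (m, f, n) in enumerate(plan.crosses):
        prog = cross(
            pop.haplotypes[id_to_row[m]], pop.haplotypes[id_to_row[f]], n, genome_map, rng
        )
        haps.append(prog)
        parents.extend([(m, f)] * n)
        family.extend([fam] * n)
    ids = book.new_ids(parents)
    return Population(
        haplotypes=np.concatenate(haps, axis=0),
        ids=ids,
        pedigree=np.array(parents, dtype=np.int64),
        pool=pool if pool is not None else pop.pool,
        cycle=pop.cycle + 1 if cycle is None else cycle,
        family=np.array(family, dtype=np.int64),
    )


def make_dh(
    parent_haplotypes: np.ndarray, genome_map: GenomeMap, rng: np.random.Generator
) -> np.ndarray:
    """Doubled haploid of a diploid: one gamete, duplicated. Fully homozygous."""
    if parent_haplotypes.shape[0] != 2:
        raise ValueError("Strategies with doubled haploids were only run for ploidy = 2")
    gam = make_gamete(parent_haplotypes, genome_map, rng)
    return np.concatenate([gam, gam], axis=0)


def make_dh_population(
    pop: Population, genome_map: GenomeMap, book: PedigreeBook, rng: np.random.Generator
) -> Population:
    """One DH line per individual; family labels carry over from the donors."""
    haps = np.stack([make_dh(pop.haplotypes[i], genome_map, rng) for i in range(len(pop))])
    parents = [(int(i), int(i)) for i in pop.ids]
    ids = book.new_ids(parents)
    return Population(
        haplotypes=haps,
        ids=ids,
        pedigree=np.array(parents, dtype=np.int64),
        pool=pop.pool,
        cycle=pop.cycle,
        family=pop.family.copy(),
    )


def random_plan(
    pop: Population, n_progeny_per_cross: int, rng: np.random.Generator
) -> CrossPlan:
    """Random pairing into len(pop)/2 crosses (first-cycle mating)."""
    if len(pop) % 2:
        raise ValueError("need an even number of parents")
    order = rng.permutation(len(pop))
    crosses = [
        (int(pop.ids[order[2 * k]]), int(pop.ids[order[2 * k + 1]]), n_progeny_per_cross)
        for k in range(len(pop) // 2)
    ]
    return CrossPlan(crosses, kind="random")


def max_avoidance_plan(
    selected: Population,
    book: PedigreeBook,
    n_progeny_per_cross: int,
    kinship_depth: int = 5,
) -> CrossPlan:
    """Pair sib-pairs across least-related families (maximum avoidance).

    ``selected`` must hold exactly two individuals per family and an even
    number of families. Families are walked in index order; each unpaired
    family is matched with the least-related unpaired family (mean pairwise
    pedigree kinship between the two sib pairs; ties to the lowest family
    index), and the two sib pairs are mated one-to-one, so every individual
    enters exactly one cross.
    """
    fams = np.unique(selected.family)
    if len(fams) % 2:
        raise ValueError("maximum avoidance requires an even number of families")
    members: dict[int, list[int]] = {}
    for fam in fams:
        rows = np.where(selected.family == fam)[0]
        if len(rows) != 2:
            raise ValueError(f"family {fam} has {len(rows)} members; exactly 2 required")
        members[int(fam)] = [int(selected.ids[r]) for r in rows]
    unpaired = [int(f) for f in fams]
    crosses: list[tuple[int, int, int]] = []
    while unpaired:
        f1 = unpaired.pop(0)
        best, best_kin = None, np.inf
        for f2 in unpaired:
            kin = np.mean(
                [
                    book.kinship(i, j, depth=kinship_depth)
                    for i in members[f1]
                    for j in members[f2]
                ]
            )
            if kin < best_kin - 1e-12:
                best, best_kin = f2, kin
        unpaired.remove(best)
        (a1, a2), (b1, b2) = members[f1], members[best]
        crosses.append((a1, b1, n_progeny_per_cross))
        crosses.append((a2, b2, n_progeny_per_cross))
    return CrossPlan(crosses, kind="max_avoidance")


def max_avoidance_family_pairs(
    selected: Population, book: PedigreeBook, kinship_depth: int = 5
) -> list[tuple[int, int]]:
    """The family pairing underlying max_avoidance_plan, without the crosses."""
    plan = max_avoidance_plan(selected, book, 1, kinship_depth)
    id_to_fam = {int(i): int(f) for i, f in zip(selected.ids, selected.family)}
    pairs = []
    for m, f, _ in plan.crosses[::2]:
        pairs.append((id_to_fam[m], id_to_fam[f]))
    return pairs


def testcross_plan(candidates: Population, testers: Population) -> CrossPlan:
    """Cross every candidate to both opposite-pool testers, one progeny each."""
    if len(testers) != 2:
        raise ValueError("exactly two testers are used per pool")
    if testers.pool == candidates.pool:
        raise ValueError("testers must come from the opposite pool")
    crosses = [
        (int(c), int(t), 1) for c in candidates.ids for t in testers.ids
    ]
    return CrossPlan(crosses, kind="testcross")
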