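"""Trait architectures with additive and digenic dominance effects.

A trait is controlled by QTL with additive effects ``a`` and dominance
effects ``d = DD * |a|``, where the dominance degree DD is drawn per locus
from Normal(meanDD, varDD). Genetic values use the genotypic
parameterisation for arbitrary even ploidy phi:

    GV(x) = mu + sum_j a_j xA_j + sum_j d_j xD_j,
    xA = (x - phi/2) * (2/phi),       in [-1, 1]
    xD = x (phi - x) * (2/phi)^2,     in [0, 1], zero at both homozygotes

which restricts polyploid dominance to digenic (pairwise within-locus)
interactions. Architectures are scaled so the founder population has mean
genetic value 0 and additive variance 1; the phenotypic error variance is
then fixed at the founders' total genetic variance, giving an initial
broad-sense heritability of 0.5.

Closed-form population summaries assume binomial(phi, p) dosages (HWE):
E[x] = phi p and E[x(phi - x)] = phi(phi - 1)p(1 - p), from which the HWE
mean, the fully-inbred mean, baseline heterosis and the standardized
initial heterosis H0 = (P0_HWE - P0_I) / sigma_G0 follow.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genomes import GenomeMap, Population

__all__ = [
    "TraitArchitecture",
    "additive_code",
    "dominance_code",
    "sample_architecture",
    "scale_architecture",
    "genetic_value",
    "population_means_hwe_inbred",
    "initial_heterosis",
    "architecture_to_csv",
    "architecture_from_csv",
]


def additive_code(x: np.ndarray, ploidy: int) -> np.ndarray:
    """Additive dosage code xA = (x - phi/2)(2/phi), in [-1, 1]."""
    return (np.asarray(x, dtype=float) - ploidy / 2.0) * (2.0 / ploidy)


def dominance_code(x: np.ndarray, ploidy: int) -> np.ndarray:
    """Digenic dominance code xD = x(phi - x)(2/phi)^2, in [0, 1]."""
    x = np.asarray(x, dtype=float)
    return x * (ploidy - x) * (2.0 / ploidy) ** 2


@dataclass
class TraitArchitecture:
    """QTL effects and the population constants recorded at scaling time."""

    qtl_index: np.ndarray
    a: np.ndarray  # additive effect per QTL
    dd: np.ndarray  # dominance degree per QTL
    mu: float  # intercept
    ploidy: int
    mean_dd: float
    var_dd: float
    sigma_g0: float | None = None  # founder genetic SD, set by scale_architecture
    sigma_e2: float | None = None  # phenotypic error variance, fixed at scaling
    d_explicit: np.ndarray | None = None  # overrides DD*|a| (hand-built traits)

    @property
    def d(self) -> np.ndarray:
        """Dominance effects d_j = DD_j * |a_j| (or an explicit override)."""
        if self.d_explicit is not None:
            return self.d_explicit
        return self.dd * np.abs(self.a)

    @property
    def n_qtl(self) -> int:
        return len(self.a)


def sample_architecture(
    genome_map: GenomeMap,
    mean_dd: float,
    var_dd: float,
    ploidy: int,
    rng_seed: int | np.random.Generator = 0,
) -> TraitArchitecture:
    """Draw raw (unscaled) QTL effects for the map's designated QTL.

    Additive effects are standard normal; dominance degrees are
    Normal(meanDD, varDD). With varDD = 0 every locus has the same degree
    of dominance (0 = additive, 1 = complete dominance, >1 overdominant).
    """
    if var_dd < 0:
        raise ValueError("varDD must be non-negative")
    if len(genome_map.qtl_index) == 0:
        raise ValueError("genome map has no QTL designated")
    rng = np.random.default_rng(rng_seed)
    n = len(genome_map.qtl_index)
    a = rng.standard_normal(n)
    dd = mean_dd + np.sqrt(var_dd) * rng.standard_normal(n)
    return TraitArchitecture(
        qtl_index=genome_map.qtl_index.copy(),
        a=a,
        dd=dd,
        mu=0.0,
        ploidy=ploidy,
        mean_dd=mean_dd,
        var_dd=var_dd,
    )


def _breeding_values(arch: TraitArchitecture, dos: np.ndarray, p: np.ndarray) -> np.ndarray:
    """True breeding values: gamete-share weighted derivative of the mean.

    BV_i = sum_j (x_ij - phi p_j) * alpha_j / (phi/2) with average effect
    alpha_j = a_j + 2 d_j (phi - 1)(1 - 2 p_j) / phi on the xA/xD scale.
    """
    phi = arch.ploidy
    alpha = 2.0 * arch.a / phi + 4.0 * arch.d * (phi - 1) * (1.0 - 2.0 * p) / phi**2
    return (dos - phi * p) @ alpha


def scale_architecture(arch: TraitArchitecture, founders: Population) -> TraitArchitecture:
    """Rescale effects to founder mean GV = 0 and additive variance = 1.

    Both a and d are multiplied by a common constant (preserving every
    dominance degree), mu absorbs the mean, sigma_G0 is recorded as the
    empirical SD of founder genetic values, and the error variance is fixed
    at sigma_G0^2 so that cycle-0 broad-sense heritability is 0.5.
    """
    if len(founders) == 0:
        raise ValueError("founder population is empty")
    dos = founders.dosages(arch.qtl_index)
    p = dos.mean(axis=0) / arch.ploidy
    bv = _breeding_values(arch, dos, p)
    va = bv.var()
    if va <= 0:
        raise ValueError("founder additive variance is zero (all QTL fixed?)")
    c = 1.0 / np.sqrt(va)
    scaled = replace(
        arch,
        a=arch.a * c,
        dd=arch.dd.copy(),
        d_explicit=None if arch.d_explicit is None else arch.d_explicit * c,
    )
    gv, _, _ = genetic_value(scaled, dos)
    scaled.mu = float(scaled.mu - gv.mean())
    gv = gv - gv.mean()
    scaled.sigma_g0 = float(gv.std())
    scaled.sigma_e2 = float(gv.var())
    return scaled


def genetic_value(
    arch: TraitArchitecture, dosages: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """True genetic values GV = mu + A(x) + D(x) for a QTL dosage matrix.

    Returns (GV, A, D) so the additive and dominance components can be
    tracked separately over breeding cycles.
    """
    dosages = np.atleast_2d(dosages)
    if dosages.min() < 0 or dosages.max() > arch.ploidy:
        raise ValueError("dosage outside [0, ploidy]")
    A = additive_code(dosages, arch.ploidy) @ arch.a
    D = dominance_code(dosages, arch.ploidy) @ arch.d
    return arch.mu + A + D, A, D


def population_means_hwe_inbred(
    arch: TraitArchitecture, freqs: np.ndarray
) -> tuple[float, float]:
    """Closed-form population means at HWE and fully inbred, at given freqs.

    P_HWE = mu + sum a(2p - 1) + sum d * 4(phi-1) p q / phi  (digenic E[xD])
    P_I   = mu + sum a(2p - 1)                               (no heterozygotes)
    """
    p = np.asarray(freqs, dtype=float)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("allele frequencies outside [0, 1]")
    phi = arch.ploidy
    add = float(arch.a @ (2.0 * p - 1.0))
    dom = float(arch.d @ (4.0 * (phi - 1) * p * (1.0 - p) / phi))
    return arch.mu + add + dom, arch.mu + add


def initial_heterosis(arch: TraitArchitecture, founders: Population) -> float:
    """Standardized baseline heterosis of the founders.

    H0 = (P0_HWE - P0_I) / sigma_G0 at founder allele frequencies. Negative
    values occur when sampled dominance degrees are net-negative (seen with
    meanDD = 0, varDD > 0); they are legitimate architectures, not errors.
    """
    if arch.sigma_g0 is None or arch.sigma_g0 == 0:
        raise ValueError("architecture not scaled (sigma_G0 unset or zero)")
    p = founders.allele_freq(arch.qtl_index)
    p_hwe, p_i = population_means_hwe_inbred(arch, p)
    return (p_hwe - p_i) / arch.sigma_g0


def architecture_to_csv(arch: TraitArchitecture, genome_map: GenomeMap, path: str) -> None:
    """Flat-table serialization; scalar constants ride in '#' header lines."""
    chrom = genome_map.chrom_of()[arch.qtl_index]
    pos = np.concatenate(genome_map.positions)[arch.qtl_index]
    df = pd.DataFrame(
        {
            "locus": arch.qtl_index,
            "chromosome": chrom,
            "position_morgans": pos,
            "a": arch.a,
            "DD": arch.dd,
            "d": arch.d,
        }
    )
    with open(path, "w") as fh:
        fh.write(
            f"# mu={arch.mu!r} ploidy={arch.ploidy} meanDD={arch.mean_dd!r} "
            f"varDD={arch.var_dd!r} sigma_g0={arch.sigma_g0!r} sigma_e2={arch.sigma_e2!r}\n"
        )
        df.to_csv(fh, index=False)


def architecture_from_csv(path: str) -> TraitArchitecture:
    with open(path) as fh:
        header = fh.readline().lstrip("# ").split()
        meta = {k: v for k, v in (kv.split("=") for kv in header)}
        df = pd.read_csv(io.StringIO(fh.read()))
    none_or = lambda v: None if v == "None" else float(v)
    return TraitArchitecture(
        qtl_index=df["locus"].to_numpy(),
        a=df["a"].to_numpy(),
        dd=df["DD"].to_numpy(),
        mu=float(meta["mu"]),
        ploidy=int(meta["ploidy"]),
        mean_dd=float(meta["meanDD"]),
        var_dd=float(meta["varDD"]),
        sigma_g0=none_or(meta["sigma_g0"]),
        sigma_e2=none_or(meta["sigma_e2"]),
    )
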