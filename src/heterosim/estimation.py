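"""Phenotypes, genomic prediction, and progeny-value calculators.

Three estimation methods drive selection decisions:

* true values — genetic values, breeding values, GCA and cross performance
  computed from the (normally unknowable) QTL effects;
* phenotypic values — a single plot value P = GV + e per entry, with the
  error variance fixed at cycle 0 so heritability erodes as genetic
  variance is consumed;
* genomic estimates — ridge-regression BLUP of SNP-chip marker effects on
  a rolling training window, either with a directional-dominance model
  (RRBLUP_D: fixed inbreeding covariate b plus random additive and
  dominance marker effects) or a paired-pool GCA model (RRBLUP_GCA:
  hybrid phenotypes regressed on maternal- and paternal-pool marker
  dosages with independent additive effect vectors).

Variance components are estimated by REML: the restricted likelihood is
profiled over the residual variance and maximised over log variance
ratios with Nelder-Mead on the n-by-n observation covariance (tolerance
1e-6, bounded iterations), after which marker effects are the usual BLUP
back-solutions.

The closed-form calculators treat loci as independent (expectation over a
single meiosis depends only on the marginal gamete-dosage distribution per
locus, hypergeometric phi/2-of-phi without double reduction).
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .genomes import Population
from .traits import TraitArchitecture, additive_code, dominance_code, genetic_value

__all__ = [
    "PhenotypeRecord",
    "MarkerModelFit",
    "TrainingWindow",
    "phenotype",
    "build_design_matrices",
    "fit_rrblup_d",
    "predict_rrblup_d",
    "fit_rrblup_gca",
    "predict_gca_score",
    "breeding_value",
    "cross_performance",
    "gca_true",
]


# ---------------------------------------------------------------------------
# phenotypes


def phenotype(
    pop: Population, arch: TraitArchitecture, rng: np.random.Generator
) -> np.ndarray:
    """One phenotypic value per individual: P = GV + N(0, sigma_e^2).

    sigma_e^2 was fixed when the architecture was scaled (cycle-0 H^2 = 0.5)
    and never changes, emulating constant phenotyping effort.
    """
    if arch.sigma_e2 is None:
        raise ValueError("architecture not scaled; sigma_e2 unset")
    gv, _, _ = genetic_value(arch, pop.dosages(arch.qtl_index))
    return gv + rng.normal(0.0, np.sqrt(arch.sigma_e2), size=len(pop))


@dataclass
class PhenotypeRecord:
    individual_id: int
    value: float
    cycle: int


# ---------------------------------------------------------------------------
# design matrices and the training window


def build_design_matrices(
    dosages: np.ndarray, ploidy: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(Z, W, f): additive codes, dominance codes, marker inbreeding.

    Z_ij = (x_ij - phi/2)(2/phi), W_ij = x_ij(phi - x_ij)(2/phi)^2, and
    f_i = 1 - rowsum(W)/N with N the marker count, so a fully homozygous
    individual has f = 1 and a fully heterozygous diploid f = 0.
    """
    dosages = np.atleast_2d(dosages)
    if dosages.min() < 0 or dosages.max() > ploidy:
        raise ValueError("dosage outside [0, ploidy]")
    Z = additive_code(dosages, ploidy)
    W = dominance_code(dosages, ploidy)
    f = 1.0 - W.sum(axis=1) / W.shape[1]
    return Z, W, f


class TrainingWindow:
    """Rolling buffer of the most recently evaluated individuals.

    Holds marker dosages, phenotypes and (for GCA training) both parents'
    marker dosages; at capacity the oldest records are evicted.
    """

    def __init__(self, capacity: int = 2000):
        if capacity < 1:
            raise ValueError("capacity must be positive")
        self.capacity = capacity
        self._buf: deque = deque(maxlen=capacity)
        self.n_dropped = 0

    def add(
        self,
        dosage: np.ndarray,
        value: float,
        mother_dosage: np.ndarray | None = None,
        father_dosage: np.ndarray | None = None,
    ) -> None:
        self._buf.append((dosage, float(value), mother_dosage, father_dosage))

    def add_population(
        self,
        pop: Population,
        values: np.ndarray,
        marker_index: np.ndarray,
        parent_lookup: dict[int, np.ndarray] | None = None,
    ) -> None:
        """Append a whole evaluated cohort; parent_lookup maps id -> marker dosage."""
        dos = pop.dosages(marker_index)
        for r in range(len(pop)):
            mom = dad = None
            if parent_lookup is not None:
                m, f = pop.pedigree[r]
                mom, dad = parent_lookup.get(int(m)), parent_lookup.get(int(f))
                if mom is None or dad is None:
                    self.n_dropped += 1
                    continue
            self.add(dos[r], values[r], mom, dad)

    def __len__(self) -> int:
        return len(self._buf)

    def genotypes(self) -> np.ndarray:
        return np.stack([r[0] for r in self._buf])

    def phenotypes(self) -> np.ndarray:
        return np.array([r[1] for r in self._buf])

    def parent_genotypes(self) -> tuple[np.ndarray, np.ndarray]:
        if any(r[2] is None or r[3] is None for r in self._buf):
            raise ValueError("training window lacks parental genotypes")
        return (
            np.stack([r[2] for r in self._buf]),
            np.stack([r[3] for r in self._buf]),
        )


# ---------------------------------------------------------------------------
# REML core


def _reml_kernels(
    y: np.ndarray,
    X: np.ndarray,
    kernels: list[np.ndarray],
    tol: float = 1e-6,
    max_iter: int = 200,
    fixed_theta: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """REML for y = X beta + sum_k g_k + e, g_k ~ N(0, s2_k K_k).

    Profiles the residual variance out and maximises the restricted
    log-likelihood over log variance ratios theta_k = s2_k / s2_e.
    Returns (beta, s2 per kernel, s2_e, Hinv_r) where Hinv_r = H^{-1}(y - X beta)
    lets callers back-solve marker effects cheaply. ``fixed_theta`` skips the
    optimisation and solves at the given variance ratios (frozen components).
    """
    n, p = X.shape
    Ks = [np.asarray(K) for K in kernels]

    def _gls(theta: np.ndarray):
        """One Cholesky of H = I + sum theta_k K_k; GLS pieces from it."""
        H = np.eye(n)
        for t, K in zip(theta, Ks):
            H += t * K
        c, low = cho_factor(H, lower=True)
        logdetH = 2.0 * np.log(np.diag(c)).sum()
        Hi_y = cho_solve((c, low), y)
        Hi_X = cho_solve((c, low), X)
        XtHiX = X.T @ Hi_X
        XtHi_y = X.T @ Hi_y
        beta = np.linalg.solve(XtHiX, XtHi_y)
        quad = float(y @ Hi_y - beta @ XtHi_y)  # = r' H^-1 r at the GLS beta
        return logdetH, XtHiX, beta, quad, (c, low)

    def deviance(log_theta: np.ndarray) -> float:
        try:
            logdetH, XtHiX, _, quad, _ = _gls(np.exp(np.clip(log_theta, -30, 30)))
        except np.linalg.LinAlgError:
            return 1e12
        sign, logdetXtHiX = np.linalg.slogdet(XtHiX)
        if sign <= 0 or quad <= 0:
            return 1e12
        s2e = quad / (n - p)
        return (n - p) * np.log(s2e) + logdetH + logdetXtHiX

    if fixed_theta is not None:
        theta = np.asarray(fixed_theta, dtype=float)
    else:
        x0 = np.zeros(len(Ks))
        res = minimize(
            deviance,
            x0,
            method="Nelder-Mead",
            options={"xatol": tol, "fatol": tol, "maxiter": max_iter * max(1, len(Ks))},
        )
        theta = np.exp(np.clip(res.x, -30, 30))
    _, _, beta, quad, chol = _gls(theta)
    Hi_r = cho_solve(chol, y - X @ beta)
    s2e = quad / (n - p)
    return beta, theta * s2e, s2e, Hi_r


@dataclass
class MarkerModelFit:
    """Fitted marker-effect model (RRBLUP_D or RRBLUP_GCA)."""

    kind: str  # {"RRBLUP_D", "RRBLUP_GCA"}
    ploidy: int
    beta: float  # fixed intercept
    b: float | None = None  # inbreeding-depression fixed effect (RRBLUP_D)
    a: np.ndarray | None = None  # additive marker effects (RRBLUP_D)
    d_star: np.ndarray | None = None  # dominance marker effects (RRBLUP_D)
    a_m: np.ndarray | None = None  # maternal-pool effects (RRBLUP_GCA)
    a_p: np.ndarray | None = None  # paternal-pool effects (RRBLUP_GCA)
    varcomp: dict = field(default_factory=dict)


def fit_rrblup_d(
    window: TrainingWindow,
    ploidy: int,
    tol: float = 1e-6,
    max_iter: int = 200,
    fixed_theta: np.ndarray | None = None,
) -> MarkerModelFit:
    """RRBLUP with directional dominance: y = Xb + f b + Z a + W d* + e.

    The fixed covariate f (marker inbreeding) absorbs directional dominance
    so the random d* stay zero-mean; b estimates inbreeding depression.
    If f is constant in the training set, b is dropped with a warning.
    """
    if len(window) < 2:
        raise ValueError("need at least 2 training records")
    M = window.genotypes()
    y = window.phenotypes()
    Z, W, f = build_design_matrices(M, ploidy)
    if Z.std(axis=0).sum() == 0:
        raise ValueError("no marker variation in training set")
    use_b = f.std() > 1e-10
    if not use_b:
        warnings.warn("inbreeding covariate f is constant; dropping b", stacklevel=2)
    X = np.column_stack([np.ones(len(y)), f]) if use_b else np.ones((len(y), 1))
    kernels = [Z @ Z.T, W @ W.T]
    beta, s2, s2e, Hi_r = _reml_kernels(
        y, X, kernels, tol=tol, max_iter=max_iter, fixed_theta=fixed_theta
    )
    theta = s2 / s2e
    a_hat = theta[0] * (Z.T @ Hi_r)
    d_hat = theta[1] * (W.T @ Hi_r)
    return MarkerModelFit(
        kind="RRBLUP_D",
        ploidy=ploidy,
        beta=float(beta[0]),
        b=float(beta[1]) if use_b else 0.0,
        a=a_hat,
        d_star=d_hat,
        varcomp={"s2_a": float(s2[0]), "s2_d": float(s2[1]), "s2_e": s2e},
    )


def predict_rrblup_d(fit: MarkerModelFit, dosages: np.ndarray) -> np.ndarray:
    """Estimated total genetic merit beta + f b + Z a + W d* per individual."""
    if fit.kind != "RRBLUP_D":
        raise ValueError("fit is not an RRBLUP_D model")
    Z, W, f = build_design_matrices(dosages, fit.ploidy)
    return fit.beta + f * fit.b + Z @ fit.a + W @ fit.d_star


def _gca_code(dosages: np.ndarray, ploidy: int) -> np.ndarray:
    """Parental dosage code (x - phi/4)(4/phi) for the half genome contributed."""
    return (np.asarray(dosages, dtype=float) - ploidy / 4.0) * (4.0 / ploidy)


def fit_rrblup_gca(
    window: TrainingWindow,
    ploidy: int,
    tol: float = 1e-6,
    max_iter: int = 200,
    fixed_theta: np.ndarray | None = None,
) -> MarkerModelFit:
    """Paired-pool GCA model: y = Xb + Z_M a_M + Z_P a_P + e.

    y are hybrid phenotypes; Z_M/Z_P carry the maternal/paternal parents'
    marker dosages with the (x - phi/4)(4/phi) scaling that accounts for
    each parent contributing half of the hybrid genome. The two pools get
    independent additive effect vectors.
    """
    if len(window) < 2:
        raise ValueError("need at least 2 training records")
    y = window.phenotypes()
    Gm, Gp = window.parent_genotypes()
    Zm, Zp = _gca_code(Gm, ploidy), _gca_code(Gp, ploidy)
    X = np.ones((len(y), 1))
    beta, s2, s2e, Hi_r = _reml_kernels(
        y, X, [Zm @ Zm.T, Zp @ Zp.T], tol=tol, max_iter=max_iter, fixed_theta=fixed_theta
    )
    theta = s2 / s2e
    return MarkerModelFit(
        kind="RRBLUP_GCA",
        ploidy=ploidy,
        beta=float(beta[0]),
        a_m=theta[0] * (Zm.T @ Hi_r),
        a_p=theta[1] * (Zp.T @ Hi_r),
        varcomp={"s2_m": float(s2[0]), "s2_p": float(s2[1]), "s2_e": s2e},
    )


def predict_gca_score(
    fit: MarkerModelFit, dosages: np.ndarray, role: str
) -> np.ndarray:
    """Genomic GCA score of candidates playing the maternal or paternal role."""
    if fit.kind != "RRBLUP_GCA":
        raise ValueError("fit is not an RRBLUP_GCA model")
    eff = fit.a_m if role == "M" else fit.a_p
    return _gca_code(dosages, fit.ploidy) @ eff


# ---------------------------------------------------------------------------
# closed-form progeny-value calculators


def breeding_value(
    a: np.ndarray,
    d: np.ndarray,
    dosages: np.ndarray,
    freqs: np.ndarray,
    ploidy: int,
) -> np.ndarray:
    """Breeding values within the candidate's own pool.

    BV_i = sum_j (x_ij - phi p_j) [2 a_j + 4 d_j (phi-1)(1 - 2 p_j)/phi]/phi:
    the expected deviation of progeny mean under random mating within the
    pool (gamete-share-weighted derivative of the population mean in p).
    The population mean of BV is zero by construction.
    """
    p = np.asarray(freqs, dtype=float)
    alpha = (2.0 * np.asarray(a) + 4.0 * np.asarray(d) * (ploidy - 1) * (1.0 - 2.0 * p) / ploidy) / ploidy
    return (np.atleast_2d(dosages) - ploidy * p) @ alpha


def _gamete_moments(dosages: np.ndarray, ploidy: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean and variance of gamete dosage per locus for one parent.

    Bivalent meiosis without double reduction draws phi/2 of the phi allele
    copies without replacement (hypergeometric): E[g] = x/2 and
    Var[g] = x(phi - x) / (4 (phi - 1)).
    """
    x = np.asarray(dosages, dtype=float)
    return x / 2.0, x * (ploidy - x) / (4.0 * (ploidy - 1.0))


def _expected_gv_from_moments(
    arch_mu: float,
    a: np.ndarray,
    d: np.ndarray,
    e_x: np.ndarray,
    var_x: np.ndarray,
    ploidy: int,
) -> float:
    """E[GV] of progeny whose dosage has per-locus mean e_x and variance var_x."""
    e_xa = (e_x - ploidy / 2.0) * (2.0 / ploidy)
    e_xd = (ploidy * e_x - (var_x + e_x**2)) * (2.0 / ploidy) ** 2
    return float(arch_mu + a @ e_xa + d @ e_xd)


def cross_performance(
    arch: TraitArchitecture,
    dosages1: np.ndarray,
    dosages2: np.ndarray,
    a: np.ndarray | None = None,
    d: np.ndarray | None = None,
) -> float:
    """Expected progeny mean GV of a specific cross, loci independent.

    Progeny dosage is the sum of two independent gamete dosages, so its
    per-locus mean and variance follow from the parents' gamete moments;
    E[xD] then needs only these two moments because xD is quadratic in x.
    Estimated effects may be passed to score crosses on marker effects.
    """
    if len(dosages1) != len(dosages2):
        raise ValueError("parents must share the locus set (same ploidy and loci)")
    a = arch.a if a is None else a
    d = arch.d if d is None else d
    e1, v1 = _gamete_moments(dosages1, arch.ploidy)
    e2, v2 = _gamete_moments(dosages2, arch.ploidy)
    return _expected_gv_from_moments(arch.mu, a, d, e1 + e2, v1 + v2, arch.ploidy)


def cross_performance_genomic(
    fit: MarkerModelFit, dosages1: np.ndarray, dosages2: np.ndarray
) -> float:
    """Expected progeny merit of a cross under a fitted RRBLUP_D model.

    Same gamete-moment algebra as cross_performance, applied to estimated
    marker effects; the inbreeding covariate contributes b * E[f].
    """
    if fit.kind != "RRBLUP_D":
        raise ValueError("fit is not an RRBLUP_D model")
    phi = fit.ploidy
    e1, v1 = _gamete_moments(dosages1, phi)
    e2, v2 = _gamete_moments(dosages2, phi)
    e_x, var_x = e1 + e2, v1 + v2
    e_xa = (e_x - phi / 2.0) * (2.0 / phi)
    e_xd = (phi * e_x - (var_x + e_x**2)) * (2.0 / phi) ** 2
    e_f = 1.0 - e_xd.mean()
    return float(fit.beta + fit.b * e_f + fit.a @ e_xa + fit.d_star @ e_xd)


def gca_true(
    arch: TraitArchitecture,
    candidate_dosages: np.ndarray,
    opposite_pool: Population,
) -> float:
    """True GCA: expected progeny GV vs a random opposite-pool mate.

    The opposite pool's gamete-dosage distribution is the mixture over its
    members; its mean and variance come from the law of total variance.
    """
    if len(opposite_pool) == 0:
        raise ValueError("opposite pool is empty")
    phi = arch.ploidy
    e_c, v_c = _gamete_moments(candidate_dosages, phi)
    pool_dos = opposite_pool.dosages(arch.qtl_index).astype(float)
    e_per, v_per = _gamete_moments(pool_dos, phi)
    e_o = e_per.mean(axis=0)
    v_o = v_per.mean(axis=0) + e_per.var(axis=0)
    return _expected_gv_from_moments(arch.mu, arch.a, arch.d, e_c + e_o, v_c + v_o, phi)
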