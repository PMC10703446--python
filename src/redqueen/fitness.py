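"""DSB placement, symmetric DSBs, and genotype fitness.

A fixed number D of programmed double-strand breaks per meiosis is spread
uniformly over all PRDM9-bound chromatid sites, so the probability that any
given bound site is broken is c = D / P_B (capped at one). Fitness is the
probability that the smallest chromosome (a proportion r of the genome)
receives at least one *symmetric* DSB — a break at a locus where each
homolog carries at least one PRDM9-bound sister chromatid. Symmetric
binding is what couples DSB formation to efficient repair and homolog
pairing; asymmetric breaks do not count toward fitness.

Homozygotes run a single binding system at the full PRDM9 dose; a
heterozygote's two alleles each express half the dose and bind disjoint
site sets, coupled only through the shared DSB pool.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np

from .binding import BindingSolution, InvalidParameterError, SiteClass, solve_free_prdm9


class DegenerateGenotypeError(ValueError):
    """No PRDM9 is bound anywhere in the genotype: DSB placement undefined."""


class ConsistencyError(ValueError):
    """Frequencies or fitness matrices violate their contracts."""


class DsbCapWarning(RuntimeWarning):
    """Fewer bound sites than DSBs; the per-site DSB probability was capped."""


def dsb_probability(total_bound: float, dsb_count: float) -> float:
    """Probability that a given bound site experiences a DSB, D / P_B.

    The model assumes more bound sites than DSBs; if a heavily eroded state
    transiently violates that, the probability is capped at one and a
    warning is issued.
    """
    if not (dsb_count > 0):
        raise InvalidParameterError(f"DSB count must be > 0, got {dsb_count!r}")
    if total_bound <= 0:
        raise DegenerateGenotypeError(
            "no PRDM9-bound sites in this genotype; DSB placement undefined")
    if total_bound < dsb_count:
        warnings.warn(
            f"bound sites ({total_bound:.3g}) < DSBs ({dsb_count:.3g}); "
            "capping per-site DSB probability at 1", DsbCapWarning,
            stacklevel=2)
        return 1.0
    return dsb_count / total_bound


def _check_unit_interval(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 1):
        raise InvalidParameterError(f"{name} must lie in [0, 1], got {value!r}")
    return arr


def symmetric_dsb_prob(H, c):
    """Probability that a site experiences a symmetric DSB.

    This is the model's defining approximation,

        alpha = 1 - (1 - c H^2 (2 - H) (2 - c H))^2,

    applied per site class within a genotype. It slightly over-counts
    relative to the exact four-chromatid enumeration
    (:func:`exact_symmetric_dsb_prob`) at interior heats.
    """
    H = _check_unit_interval("H", H)
    c = _check_unit_interval("c", c)
    x = np.clip(c * H * H * (2.0 - H) * (2.0 - c * H), 0.0, 1.0)
    alpha = x * (2.0 - x)  # == 1 - (1 - x)^2, in [0, 1] by construction
    if alpha.ndim == 0:
        return float(alpha)
    return alpha


def exact_symmetric_dsb_prob(H: float, c: float) -> float:
    """Exact symmetric-DSB probability by enumeration.

    Enumerates the 2^4 binding configurations of the four chromatids (each
    bound independently with probability H, chromatids 0-1 on one homolog,
    2-3 on the other) and, conditional on b bound chromatids, uses
    1 - (1 - c)^b for the probability that at least one bound chromatid is
    broken. The event requires each homolog to carry at least one bound
    chromatid. Serves as the independent oracle and lower bound for
    :func:`symmetric_dsb_prob`.
    """
    H = float(_check_unit_interval("H", H))
    c = float(_check_unit_interval("c", c))
    total = 0.0
    for config in product((0, 1), repeat=4):
        if not (config[0] or config[1]) or not (config[2] or config[3]):
            continue
        p_config = 1.0
        for bit in config:
            p_config *= H if bit else (1.0 - H)
        b = sum(config)
        total += p_config * (1.0 - (1.0 - c) ** b)
    return total


def _log_survival(alphas: Sequence[float], counts: Sequence[float],
                  r: float) -> float:
    """log of the probability that no site on the smallest chromosome
    experiences a symmetric DSB: sum_i r n_i log(1 - alpha_i)."""
    total = 0.0
    for alpha, n in zip(alphas, counts):
        if n == 0.0:
            continue
        if alpha >= 1.0:
            return -math.inf
        total += r * n * math.log1p(-alpha)
    return total


def fitness_from_alphas(alphas: Sequence[Sequence[float]],
                        site_counts: Sequence[Sequence[float]],
                        r: float) -> float:
    """Fitness given per-class symmetric-DSB probabilities.

    ``W = 1 - prod (1 - alpha_i)^(r n_i)`` with the product over every
    class of every allele system present in the genotype; exponents are
    real-valued and the product is evaluated in log space.
    """
    if not (0.0 < r <= 1.0):
        raise InvalidParameterError(f"r must lie in (0, 1], got {r!r}")
    log_surv = sum(_log_survival(a, n, r)
                   for a, n in zip(alphas, site_counts))
    return -math.expm1(log_surv)


@dataclass(frozen=True)
class GenotypeContext:
    """Solved molecular state of one PRDM9 genotype.

    ``bindings`` holds one equilibrium per distinct allele: a single system
    at full dose for homozygotes, two half-dose systems for heterozygotes.
    ``alphas`` mirrors that structure with per-class symmetric-DSB
    probabilities, all sharing the genotype-wide DSB probability ``dsb_prob``.
    """

    bindings: tuple[BindingSolution, ...]
    site_counts: tuple[tuple[float, ...], ...]
    total_bound: float
    dsb_prob: float
    alphas: tuple[tuple[float, ...], ...]
    fitness: float


def solve_genotype(allele_sites: Sequence[Sequence[SiteClass]],
                   P_T: float, D: float, r: float) -> GenotypeContext:
    """Solve binding, DSB and fitness for a genotype.

    ``allele_sites`` holds the site classes of each *distinct* allele: one
    entry for a homozygote (dose ``P_T``), two for a heterozygote (dose
    ``P_T / 2`` each; the alleles bind disjoint site sets and interact only
    through the shared pool of D DSBs).
    """
    if not (0.0 < r <= 1.0):
        raise InvalidParameterError(f"r must lie in (0, 1], got {r!r}")
    n_alleles = len(allele_sites)
    if n_alleles not in (1, 2):
        raise InvalidParameterError(
            f"a genotype has one or two distinct alleles, got {n_alleles}")
    dose = P_T if n_alleles == 1 else P_T / 2.0
    bindings = tuple(solve_free_prdm9(sites, dose) for sites in allele_sites)
    total_bound = sum(b.bound_total for b in bindings)
    c = dsb_probability(total_bound, D)
    alphas = tuple(
        tuple(float(symmetric_dsb_prob(h, c)) for h in b.heats)
        for b in bindings)
    site_counts = tuple(tuple(sc.count for sc in sites)
                        for sites in allele_sites)
    fitness = fitness_from_alphas(alphas, site_counts, r)
    return GenotypeContext(bindings, site_counts, total_bound, c, alphas,
                           fitness)


def genotype_fitness(allele_sites: Sequence[Sequence[SiteClass]],
                     P_T: float, D: float, r: float) -> float:
    """Fitness of a homozygote (one allele entry) or heterozygote (two).

    Homozygote: W = 1 - prod_i (1 - alpha_i)^(r n_i); heterozygote: the
    product additionally runs over the second allele's classes. Products
    are evaluated in log space.
    """
    return solve_genotype(allele_sites, P_T, D, r).fitness


def marginal_fitness(frequencies, fitness_matrix):
    """Per-allele marginal fitness and population mean fitness.

    ``W_j = sum_k f_k W_{j,k}`` (the frequency-weighted row average of the
    symmetric genotype-fitness matrix, homozygotes entering through the
    diagonal) and ``Wbar = sum_j f_j W_j``.
    """
    f = np.asarray(frequencies, dtype=float)
    W = np.asarray(fitness_matrix, dtype=float)
    if abs(f.sum() - 1.0) > 1e-9:
        raise ConsistencyError(f"allele frequencies sum to {f.sum()!r}, not 1")
    if W.shape != (f.size, f.size):
        raise ConsistencyError(f"fitness matrix shape {W.shape} does not "
                               f"match {f.size} alleles")
    if not np.allclose(W, W.T, rtol=0.0, atol=1e-12):
        raise ConsistencyError("fitness matrix must be symmetric")
    Wj = W @ f
    return Wj, float(f @ Wj)
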