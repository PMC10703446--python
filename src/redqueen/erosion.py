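"""Deterministic erosion of binding sites by biased gene conversion.

A hot site allele that is bound and broken during meiosis is repaired off
the homolog; when a conversion tract spans the binding motif (probability
B), the hot allele is overwritten. Gene conversion therefore acts like
selection against hot site alleles with coefficient equal to the meiotic
conversion rate g, so newly arising cold mutants (input 2N mu per site per
generation) fix with probability 2g, giving the deterministic per-class
loss

    delta n_ij = 4 N mu g_i^j n_ij

applied instantaneously. Because the number of DSBs (and hence conversions)
per meiosis is fixed, the total loss per generation across all classes and
alleles is the constant N mu B D whenever the DSB-probability cap is not
engaged.
"""

from __future__ import annotations

import numpy as np

from .binding import InvalidParameterError


def meiotic_conversion_rate(H, c, B):
    """Per-meiosis conversion rate of a site: g = B * c * H."""
    H = np.asarray(H, dtype=float)
    if np.any(H < 0) or np.any(H > 1):
        raise InvalidParameterError("H must lie in [0, 1]")
    if not (0.0 <= np.min(c) and np.max(c) <= 1.0):
        raise InvalidParameterError("c must lie in [0, 1]")
    if not 0.0 <= B <= 1.0:
        raise InvalidParameterError(f"B must lie in [0, 1], got {B!r}")
    out = B * np.asarray(c, dtype=float) * H
    return float(out) if out.ndim == 0 else out


def population_conversion_rate(frequencies, per_genotype_rates):
    """Population conversion rate of one site class of each allele.

    ``per_genotype_rates[j, k]`` is the rate for allele j's class in a
    genotype carrying alleles j and k. Genotypes are weighted at their
    Hardy-Weinberg frequencies built from the (post-selection) allele
    frequencies:

        g_i^j = 2 f_j sum_k f_k g_i^{j,k} - f_j^2 g_i^{j,j}.
    """
    f = np.asarray(frequencies, dtype=float)
    g = np.asarray(per_genotype_rates, dtype=float)
    if abs(f.sum() - 1.0) > 1e-9:
        raise InvalidParameterError(
            f"frequencies sum to {f.sum()!r}, not 1")
    out = 2.0 * f * (g @ f) - f * f * np.diagonal(g)
    return out


def erode_sites(site_counts, population_rates, N: int, mu: float):
    """One generation of deterministic site loss, clipped at zero.

    ``site_counts`` and ``population_rates`` are matched arrays (any shape,
    typically classes x alleles); returns the updated counts
    ``n * max(0, 1 - 4 N mu g)``.
    """
    n = np.asarray(site_counts, dtype=float)
    g = np.asarray(population_rates, dtype=float)
    factor = np.clip(1.0 - 4.0 * N * mu * g, 0.0, None)
    return n * factor
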