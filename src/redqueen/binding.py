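"""Competitive PRDM9 binding equilibrium.

A meiotic cell expresses a fixed dose of PRDM9 molecules of a given allele,
which partition among that allele's genomic binding-site classes under
Michaelis-Menten kinetics. At equilibrium the occupancy ("heat") of a site
with dissociation constant ``k`` is

    H = P_F / (P_F + k),

and the number of free molecules ``P_F`` balances the dose against the
molecules sequestered on the four chromatid copies of each genomic site:

    P_F + sum_i 4 n_i * P_F / (P_F + k_i) = dose.

The left-hand side is strictly increasing and concave in ``P_F``, so the
balance has a unique root in ``[0, dose]``; Newton iteration started at zero
converges to it monotonically from below. The factor of four (chromatid
multiplicity) is applied here and nowhere else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq


class InvalidParameterError(ValueError):
    """A numeric input is non-finite or outside its allowed range."""


class UnsupportedCaseError(ValueError):
    """The closed-form solver only covers one or two site classes."""


class InfeasibleTargetError(ValueError):
    """The requested bound count/fraction cannot be reached at saturation."""


@dataclass(frozen=True)
class SiteClass:
    """A class of genomic binding sites sharing one affinity.

    ``count`` is the number of genomic sites (real-valued: erosion is
    deterministic and continuous); each contributes four chromatid copies
    to the binding equilibrium. ``dissociation_constant`` is k in
    molecule-count units; lower k means stronger binding.
    """

    count: float
    dissociation_constant: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.count) and self.count >= 0):
            raise InvalidParameterError(f"site count must be finite and >= 0, "
                                        f"got {self.count!r}")
        if not (math.isfinite(self.dissociation_constant)
                and self.dissociation_constant > 0):
            raise InvalidParameterError(
                f"dissociation constant must be finite and > 0, "
                f"got {self.dissociation_constant!r}")


@dataclass(frozen=True)
class BindingSolution:
    """Equilibrium of one PRDM9 binding system (one allele, one dose)."""

    free_molecules: float
    heats: tuple[float, ...]
    bound_total: float
    dose: float


def _validate_dose(dose: float) -> float:
    if not (math.isfinite(dose) and dose >= 0):
        raise InvalidParameterError(f"dose must be finite and >= 0, got {dose!r}")
    return float(dose)


def free_molecules_newton(four_n: np.ndarray, ks: np.ndarray,
                          dose: np.ndarray | float,
                          rtol: float = 1e-13, max_iter: int = 200) -> np.ndarray:
    """Vectorized Newton solve of the free-molecule balance.

    ``four_n`` and ``ks`` have shape (..., m) — chromatid-copy counts (4n)
    and dissociation constants per class; ``dose`` broadcasts against the
    leading axes. Returns ``P_F`` with the leading shape.
    """
    four_n = np.asarray(four_n, dtype=float)
    ks = np.asarray(ks, dtype=float)
    dose_arr = np.asarray(dose, dtype=float)
    shape = np.broadcast_shapes(four_n.shape[:-1], dose_arr.shape)
    x = np.zeros(shape)
    scale = np.maximum(dose_arr, 1.0)
    for _ in range(max_iter):
        denom = x[..., None] + ks
        f = x + np.sum(four_n * x[..., None] / denom, axis=-1) - dose_arr
        if np.all(np.abs(f) <= rtol * scale):
            break
        fp = 1.0 + np.sum(four_n * ks / (denom * denom), axis=-1)
        step = f / fp
        if np.all(np.abs(step) <= 1e-16 * (np.abs(x) + 1.0)):
            break  # at the floating-point noise floor
        x = np.maximum(x - step, 0.0)
    return np.asarray(x)


def _free_two_class_scalar(fn1: float, k1: float, fn2: float, k2: float,
                           dose: float) -> float:
    """Pure-scalar Newton for the two-class balance (hot loop of the
    simulator at low PRDM9 diversity)."""
    if dose <= 0.0:
        return 0.0
    x = 0.0
    tol = 1e-13 * (dose if dose > 1.0 else 1.0)
    for _ in range(100):
        d1 = x + k1
        d2 = x + k2
        f = x + fn1 * x / d1 + fn2 * x / d2 - dose
        if -tol <= f <= tol:
            break
        fp = 1.0 + fn1 * k1 / (d1 * d1) + fn2 * k2 / (d2 * d2)
        step = f / fp
        if abs(step) <= 1e-16 * (x + 1.0):
            break  # floating-point noise floor
        x -= step
        if x < 0.0:
            x = 0.0
    return x


def solve_free_prdm9(site_classes: Sequence[SiteClass],
                     dose: float) -> BindingSolution:
    """Solve the competitive-binding equilibrium for one allele.

    Returns the unique root ``P_F`` in ``[0, dose]`` of the free-molecule
    balance, together with the per-class heats ``H_i = P_F / (P_F + k_i)``
    and the total bound ``sum_i 4 n_i H_i``.
    """
    dose = _validate_dose(dose)
    classes = list(site_classes)
    if not classes:
        return BindingSolution(dose, (), 0.0, dose)
    four_n = np.array([4.0 * sc.count for sc in classes])
    ks = np.array([sc.dissociation_constant for sc in classes])
    if dose == 0.0:
        return BindingSolution(0.0, (0.0,) * len(classes), 0.0, dose)
    pf = float(free_molecules_newton(four_n, ks, dose))
    heats = pf / (pf + ks)
    bound = float(np.sum(four_n * heats))
    return BindingSolution(pf, tuple(float(h) for h in heats), bound, dose)


def closed_form_free_prdm9(site_classes: Sequence[SiteClass],
                           dose: float) -> float:
    """Algebraic root of the balance for one (quadratic) or two (cubic)
    site classes; the independent oracle for :func:`solve_free_prdm9`."""
    dose = _validate_dose(dose)
    classes = list(site_classes)
    if len(classes) not in (1, 2):
        raise UnsupportedCaseError(
            f"closed form covers 1 or 2 site classes, got {len(classes)}")
    if dose == 0.0:
        return 0.0
    if len(classes) == 1:
        fn = 4.0 * classes[0].count
        k = classes[0].dissociation_constant
        # x^2 + (fn + k - dose) x - k dose = 0, positive root
        b = fn + k - dose
        c = k * dose
        if b >= 0.0:
            return 2.0 * c / (b + math.sqrt(b * b + 4.0 * c))
        return (-b + math.sqrt(b * b + 4.0 * c)) / 2.0
    (n1, k1), (n2, k2) = [(sc.count, sc.dissociation_constant)
                          for sc in classes]
    fn1, fn2 = 4.0 * n1, 4.0 * n2
    coeffs = [
        1.0,
        k1 + k2 + fn1 + fn2 - dose,
        k1 * k2 + fn1 * k2 + fn2 * k1 - dose * (k1 + k2),
        -dose * k1 * k2,
    ]
    roots = np.roots(coeffs)
    real = roots[np.abs(roots.imag) <= 1e-9 * (1.0 + np.abs(roots.real))].real
    tol = 1e-9 * dose
    candidates = real[(real >= -tol) & (real <= dose + tol)]
    if candidates.size == 0:  # pragma: no cover - cubic always has this root
        raise RuntimeError("no cubic root found in [0, dose]")
    return float(np.clip(candidates[0], 0.0, dose))


def bound_total(site_classes: Sequence[SiteClass], dose: float) -> float:
    """Total number of PRDM9 molecules bound at equilibrium."""
    return solve_free_prdm9(site_classes, dose).bound_total


def calibrate_dose(site_classes: Sequence[SiteClass],
                   target_bound: float) -> float:
    """Dose at which ``target_bound`` molecules are bound at equilibrium.

    The bound total is strictly increasing in the dose and saturates at
    ``4 * sum(n_i)`` (every chromatid copy occupied), so the solution is
    unique whenever ``target_bound`` lies below saturation.
    """
    if not (math.isfinite(target_bound) and target_bound >= 0):
        raise InvalidParameterError(
            f"target_bound must be finite and >= 0, got {target_bound!r}")
    if target_bound == 0.0:
        return 0.0
    saturation = 4.0 * sum(sc.count for sc in site_classes)
    if target_bound >= saturation:
        raise InfeasibleTargetError(
            f"target_bound={target_bound} exceeds the saturation bound "
            f"{saturation} (4x total genomic sites)")
    lo = target_bound  # bound < dose strictly, so f(lo) < 0
    hi = 2.0 * target_bound
    while bound_total(site_classes, hi) < target_bound:
        hi *= 2.0
    return float(brentq(
        lambda d: bound_total(site_classes, d) - target_bound,
        lo, hi, xtol=1e-12, rtol=1e-14))


def calibrate_dissociation(count: float, dose: float,
                           target_bound_fraction: float) -> float:
    """Dissociation constant at which a single site class binds the given
    fraction of the dose at equilibrium.

    The bound fraction is strictly decreasing in k, and the solution has a
    closed form: with ``bound = fraction * dose`` the heat must be
    ``H = bound / (4 count)`` and ``k = P_F (1 - H) / H`` with
    ``P_F = dose - bound``.
    """
    if not (math.isfinite(count) and count > 0):
        raise InvalidParameterError(f"count must be finite and > 0, got {count!r}")
    dose = _validate_dose(dose)
    if dose == 0.0:
        raise InvalidParameterError("dose must be positive to calibrate k")
    frac = target_bound_fraction
    limit = min(1.0, 4.0 * count / dose)
    if not (0.0 < frac < limit):
        raise InfeasibleTargetError(
            f"target bound fraction must lie in (0, {limit}) "
            f"(saturation limit), got {frac!r}")
    bound = frac * dose
    heat = bound / (4.0 * count)
    free = dose - bound
    return free * (1.0 - heat) / heat
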