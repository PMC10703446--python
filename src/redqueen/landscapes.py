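"""Static fitness-landscape analyses.

Two families of analyses, neither involving evolutionary dynamics:

* One-heat comparisons of model variants as binding sites erode — what
  happens to fitness when DSB number tracks binding (``proportional_dsb``),
  when DSBs are fixed but PRDM9 is non-limiting
  (``fixed_dsb_noncompetitive``), and when both PRDM9 and DSBs are limiting
  (``fixed_dsb_competitive``).

* Two-heat landscapes of fitness against the hotspot count for homozygotes
  and for heterozygotes carrying two same-count alleles, their optima, and
  the resident hotspot counts at which a homozygote is susceptible to
  invasion by a heterozygote with an optimal challenger allele.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .binding import SiteClass, calibrate_dose, free_molecules_newton
from .params import ModelParams

ONE_HEAT_VARIANTS = ("proportional_dsb", "fixed_dsb_noncompetitive",
                     "fixed_dsb_competitive")


def _heats_two_class(n1_grid: np.ndarray, k1: float, n2: float, k2: float,
                     dose: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized equilibrium over a grid of hotspot counts: returns
    (H1, H2, bound_total) for one allele's binding system at ``dose``."""
    fn = np.stack([4.0 * n1_grid, np.full_like(n1_grid, 4.0 * n2)], axis=-1)
    ks = np.array([k1, k2])
    pf = free_molecules_newton(fn, ks, dose)
    H1 = pf / (pf + k1)
    H2 = pf / (pf + k2)
    bound = fn[..., 0] * H1 + fn[..., 1] * H2
    return H1, H2, bound


def _log_survival(n: np.ndarray, x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        out = n * (2.0 * np.log1p(-x))
    return np.where(np.asarray(n) == 0.0, 0.0, out)


def _alpha(H: np.ndarray, c: np.ndarray) -> np.ndarray:
    x = np.clip(c * H * H * (2.0 - H) * (2.0 - c * H), 0.0, 1.0)
    return x


def _hom_fitness(n1, params: ModelParams) -> np.ndarray:
    """Homozygote fitness over an array of hotspot counts (full dose)."""
    n1 = np.asarray(n1, dtype=float)
    H1, H2, bound = _heats_two_class(n1, params.k1, params.n2, params.k2,
                                     params.P_T)
    c = np.clip(params.D / bound, None, 1.0)
    x1 = _alpha(H1, c)
    x2 = _alpha(H2, c)
    logs = params.r * (_log_survival(n1, x1)
                       + _log_survival(params.n2, x2))
    return -np.expm1(logs)


def _het_fitness(n1_res, n1_chal, params: ModelParams) -> np.ndarray:
    """Heterozygote fitness for resident/challenger hotspot counts
    (broadcasting); each allele runs a half-dose binding system."""
    n1_res = np.asarray(n1_res, dtype=float)
    n1_chal = np.asarray(n1_chal, dtype=float)
    shape = np.broadcast_shapes(n1_res.shape, n1_chal.shape)
    out_res = np.broadcast_to(n1_res, shape)
    out_chal = np.broadcast_to(n1_chal, shape)
    H1r, H2r, br = _heats_two_class(out_res, params.k1, params.n2, params.k2,
                                    params.P_T / 2.0)
    H1c, H2c, bc = _heats_two_class(out_chal, params.k1, params.n2, params.k2,
                                    params.P_T / 2.0)
    c = np.clip(params.D / (br + bc), None, 1.0)
    logs = params.r * (
        _log_survival(out_res, _alpha(H1r, c))
        + _log_survival(params.n2, _alpha(H2r, c))
        + _log_survival(out_chal, _alpha(H1c, c))
        + _log_survival(params.n2, _alpha(H2c, c)))
    return -np.expm1(logs)


def _refine_optimum(fun, grid: np.ndarray, values: np.ndarray) -> float:
    """Golden-section refinement around the grid argmax (ties resolve to
    the smaller hotspot count via the first argmax)."""
    i = int(np.argmax(values))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    if hi <= lo:
        return float(grid[i])
    res = minimize_scalar(lambda v: -fun(v), bounds=(lo, hi),
                          method="bounded", options={"xatol": 1e-3})
    return float(res.x) if res.fun <= -values[i] else float(grid[i])


@dataclass(frozen=True)
class FitnessCurve:
    """Two-heat fitness landscape over a hotspot-count grid."""

    hotspot_grid: np.ndarray
    fitness_hom: np.ndarray
    fitness_het: np.ndarray          # both alleles at the same count
    het_challenger_best: np.ndarray  # max over challenger counts, per resident
    optimum_hom: float
    optimum_het: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n1": self.hotspot_grid,
                             "W_hom": self.fitness_hom,
                             "W_het": self.fitness_het})


def fitness_landscape(params: ModelParams,
                      n1_grid: np.ndarray | None = None) -> FitnessCurve:
    """Fitness against hotspot count for homozygotes and same-count
    heterozygotes, with grid-argmax optima refined by golden section.

    The challenger curve pairs each resident count with the best possible
    heterozygous partner, the quantity that defines invasion susceptibility.
    """
    if n1_grid is None:
        n1_grid = np.arange(10.0, params.n1_max + 1.0, 10.0)
    grid = np.asarray(n1_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("hotspot grid must be non-empty")
    w_hom = _hom_fitness(grid, params)
    w_het = _het_fitness(grid, grid, params)
    # full resident x challenger matrix; best challenger per resident
    w_pairs = _het_fitness(grid[:, None], grid[None, :], params)
    het_best = w_pairs.max(axis=1)
    opt_hom = _refine_optimum(lambda v: _hom_fitness(v, params), grid, w_hom)
    opt_het = _refine_optimum(lambda v: _het_fitness(v, v, params),
                              grid, w_het)
    return FitnessCurve(grid, w_hom, w_het, het_best,
                        optimum_hom=opt_hom, optimum_het=opt_het)


def invasion_region(curve: FitnessCurve) -> list[tuple[float, float]]:
    """Contiguous intervals of resident hotspot counts where the resident
    homozygote is beaten by the best challenger heterozygote."""
    mask = curve.fitness_hom < curve.het_challenger_best
    grid = curve.hotspot_grid
    intervals: list[tuple[float, float]] = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = grid[i]
        elif not m and start is not None:
            intervals.append((float(start), float(grid[i - 1])))
            start = None
    if start is not None:
        intervals.append((float(start), float(grid[-1])))
    return intervals


def one_heat_trajectory(variant: str, n_grid: np.ndarray, k: float,
                        D: float = 300.0, r: float = 1.0 / 40.0,
                        dose: float | None = None,
                        calibration: tuple[float, float] = (20_000.0, 5_000.0),
                        ) -> pd.DataFrame:
    """Fitness along an erosion grid of site counts, under one of three
    single-heat model variants.

    Fitness here is one minus the probability of no symmetric DSB on the
    smallest chromosome, ``1 - exp(-r * D_eff * H (2 - H))``: of the
    ``D_eff`` DSBs (all at bound chromatids), each is symmetric when the
    other homolog carries at least one bound chromatid, probability
    ``1 - (1 - H)^2``.

    * ``proportional_dsb`` — binding non-competitive (H fixed at its value
      at the top of the grid) and DSBs proportional to binding:
      ``D_eff = D * n / n0``; fitness falls as sites are lost.
    * ``fixed_dsb_noncompetitive`` — H fixed, ``D_eff = D``; fitness is
      exactly constant.
    * ``fixed_dsb_competitive`` — H solved from the competitive equilibrium
      at every n, ``D_eff = D``; fitness rises as sites are lost.

    The PRDM9 dose defaults to the value binding ``calibration[1]``
    molecules when ``calibration[0]`` sites are present.
    """
    if variant not in ONE_HEAT_VARIANTS:
        raise ValueError(f"unknown one-heat variant {variant!r}; "
                         f"expected one of {ONE_HEAT_VARIANTS}")
    grid = np.asarray(n_grid, dtype=float)
    if dose is None:
        dose = calibrate_dose([SiteClass(calibration[0], k)], calibration[1])
    n0 = float(grid.max())
    pf0 = float(free_molecules_newton(np.array([4.0 * n0]), np.array([k]),
                                      dose))
    H0 = pf0 / (pf0 + k)
    if variant == "fixed_dsb_competitive":
        pf = free_molecules_newton(4.0 * grid[:, None], np.array([k]), dose)
        H = pf / (pf + k)
        d_eff = np.full_like(grid, D)
    elif variant == "fixed_dsb_noncompetitive":
        H = np.full_like(grid, H0)
        d_eff = np.full_like(grid, D)
    else:  # proportional_dsb
        H = np.full_like(grid, H0)
        d_eff = D * grid / n0
    fitness = -np.expm1(-r * d_eff * H * (2.0 - H))
    return pd.DataFrame({"n": grid, "H": H, "fitness": fitness})


def binding_symmetry_curves(k: float, n_grid: np.ndarray,
                            dose: float | None = None,
                            calibration: tuple[float, float]
                            = (20_000.0, 5_000.0)) -> pd.DataFrame:
    """Per-site occupancy H and per-locus symmetric-binding probability
    ``(H (2 - H))^2`` (each homolog has a bound chromatid) along a grid of
    site counts, for a single affinity class."""
    grid = np.asarray(n_grid, dtype=float)
    if dose is None:
        dose = calibrate_dose([SiteClass(calibration[0], k)], calibration[1])
    pf = free_molecules_newton(4.0 * grid[:, None], np.array([k]), dose)
    H = pf / (pf + k)
    sym = (H * (2.0 - H)) ** 2
    return pd.DataFrame({"n": grid, "H": H, "symmetric_binding": sym})
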