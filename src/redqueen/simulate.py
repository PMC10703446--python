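"""Forward-time Wright-Fisher dynamics of PRDM9 alleles.

Each generation executes, in order: (1) the genotype-fitness matrix over
all segregating alleles (Hardy-Weinberg genotype frequencies) and marginal
fitnesses; (2) expected post-selection frequencies; (3) deterministic
erosion of every allele's binding-site classes, weighted by the
post-selection frequencies; (4) multinomial resampling of 2N gene copies;
(5) recurrent PRDM9 mutation, each new allele entering at frequency 1/(2N)
with a fresh, un-eroded set of binding sites; (6) recording of the mean
hotspot count, mean fitness and PRDM9 diversity.

Binding equilibria are solved once per allele per generation (full dose for
the homozygous system, half dose for the heterozygous one) and every
genotype's fitness is assembled from those solutions, since alleles bind
disjoint site sets and interact only through the shared DSB pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .binding import _free_two_class_scalar, free_molecules_newton
from .params import ModelParams


class ExtinctionError(RuntimeError):
    """Mean fitness reached zero: every genotype is inviable."""

    def __init__(self, generation: int):
        super().__init__(f"population mean fitness is 0 at generation "
                         f"{generation}")
        self.generation = generation


@dataclass
class LedgerEntry:
    """Lifetime summary of one PRDM9 allele."""

    allele_id: int
    birth_generation: int
    exit_generation: int | None
    initial_hotspots: int
    final_hotspots: float
    sojourn_time: int
    mean_frequency: float
    max_frequency: float
    fixed: bool
    censored: bool


@dataclass
class PopulationState:
    """Mutable simulation state: segregating alleles and bookkeeping.

    Parallel arrays/lists indexed by segregating allele: ``n1``/``n2`` are
    the (real-valued, eroding) hotspot and weak-site counts, ``freq`` the
    current frequencies (summing to one), ``sum_freq``/``max_freq``
    running accumulators for the ledger.
    """

    generation: int
    ids: list[int]
    birth: list[int]
    init_n1: list[int]
    n1: np.ndarray
    n2: np.ndarray
    freq: np.ndarray
    sum_freq: np.ndarray
    max_freq: np.ndarray
    rng: np.random.Generator
    next_id: int
    ledger: list[LedgerEntry] = field(default_factory=list)
    fixation_events: list[tuple[int, int]] = field(default_factory=list)
    last_fixed_id: int | None = None
    cap_generations: int = 0
    #: total binding sites lost to gene conversion in the last step
    #: (equals N mu B D whenever the DSB cap is not engaged)
    last_site_loss: float = 0.0
    #: exited non-founder alleles whose peak frequency reached >= 0.5
    dominant_exits: int = 0


def draw_initial_hotspots(params: ModelParams, rng: np.random.Generator) -> int:
    """Hotspot count of a newly arising PRDM9 allele."""
    if params.n1_distribution == "uniform":
        return int(rng.integers(params.n1_min, params.n1_max + 1))
    n1 = int(round(rng.normal(params.n1_center, params.n1_sd)))
    return int(min(max(n1, params.n1_min), params.n1_max))


def initial_state(params: ModelParams,
                  rng: np.random.Generator | None = None) -> PopulationState:
    """A single founder allele fixed in the population, with a hotspot
    count drawn from the mutational distribution unless ``founder_n1`` is
    set."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n1 = (params.founder_n1 if params.founder_n1 is not None
          else draw_initial_hotspots(params, rng))
    return PopulationState(
        generation=0, ids=[0], birth=[0], init_n1=[int(n1)],
        n1=np.array([float(n1)]), n2=np.array([float(params.n2)]),
        freq=np.array([1.0]), sum_freq=np.array([1.0]),
        max_freq=np.array([1.0]), rng=rng, next_id=1)


def selection_update(frequencies: np.ndarray, marginal: np.ndarray,
                     mean_fitness: float, generation: int = -1) -> np.ndarray:
    """Expected frequencies after viability selection, f'_j = f_j W_j / Wbar."""
    if mean_fitness <= 0.0:
        raise ExtinctionError(generation)
    return frequencies * marginal / mean_fitness


def wright_fisher_sample(expected: np.ndarray, two_N: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Multinomial sample of 2N gene copies at the expected frequencies."""
    p = np.asarray(expected, dtype=float)
    return rng.multinomial(two_N, p / p.sum())


def mutate_prdm9(counts: np.ndarray, params: ModelParams,
                 rng: np.random.Generator) -> tuple[np.ndarray, list[int]]:
    """PRDM9 mutation: Binomial(2N, nu) new alleles, each replacing one
    uniformly chosen pre-existing gene copy.

    Returns the updated counts of pre-existing alleles and the hotspot
    counts of the new alleles (each holding one copy).
    """
    two_N = int(counts.sum())
    n_mut = int(rng.binomial(two_N, params.nu))
    if n_mut == 0:
        return counts, []
    counts = counts.copy()
    total = two_N
    new_n1 = []
    for _ in range(n_mut):
        u = int(rng.integers(total))
        victim = int(np.searchsorted(np.cumsum(counts), u, side="right"))
        counts[victim] -= 1
        total -= 1
        new_n1.append(draw_initial_hotspots(params, rng))
    return counts, new_n1


def _weighted_log_survival(n: np.ndarray, x: np.ndarray) -> np.ndarray:
    """r-free part of the no-symmetric-DSB log probability, n * 2 log1p(-x),
    with the 0 * -inf indeterminacy resolved to 0 (no sites, no DSBs)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = n * (2.0 * np.log1p(-x))
    return np.where(n == 0.0, 0.0, out)


def step_generation(state: PopulationState, params: ModelParams
                    ) -> tuple[int, float, float, float]:
    """Advance the population by one generation in place.

    Returns the trajectory record ``(generation, n1_mean, W_mean, pi)``
    describing the state after the step: the frequency-weighted mean
    hotspot count, this generation's population mean fitness, and PRDM9
    heterozygosity.
    """
    p = params
    two_N = 2 * p.N
    K = state.freq.size
    k1, k2, P_T, D, B, r = p.k1, p.k2, p.P_T, p.D, p.B, p.r
    four_N_mu = 4.0 * p.N * p.mu

    if p.neutral and p.mu == 0.0:
        # pure-drift diagnostic: no selection, no erosion
        Wbar = 1.0
        state.last_site_loss = 0.0
        counts = (None if K == 1
                  else wright_fisher_sample(state.freq, two_N, state.rng))
    elif K == 1:
        # Monomorphic fast path: one binding system, no sampling noise.
        fn1 = 4.0 * state.n1[0]
        fn2 = 4.0 * state.n2[0]
        pf = _free_two_class_scalar(fn1, k1, fn2, k2, P_T)
        H1 = pf / (pf + k1)
        H2 = pf / (pf + k2)
        PB = fn1 * H1 + fn2 * H2
        c = D / PB if PB > 0.0 else math.inf
        if c > 1.0:
            c = 1.0
            state.cap_generations += 1
        if p.neutral:
            Wbar = 1.0
        else:
            x1 = min(c * H1 * H1 * (2.0 - H1) * (2.0 - c * H1), 1.0)
            x2 = min(c * H2 * H2 * (2.0 - H2) * (2.0 - c * H2), 1.0)
            log_surv = 0.0
            for n, x in ((state.n1[0], x1), (state.n2[0], x2)):
                if n > 0.0:
                    log_surv += (-math.inf if x >= 1.0
                                 else r * n * 2.0 * math.log1p(-x))
            Wbar = -math.expm1(log_surv)
        # erosion (monomorphic: population rate is the homozygote rate)
        g1 = B * c * H1
        g2 = B * c * H2
        state.last_site_loss = four_N_mu * (g1 * state.n1[0]
                                            + g2 * state.n2[0])
        state.n1[0] *= max(0.0, 1.0 - four_N_mu * g1)
        state.n2[0] *= max(0.0, 1.0 - four_N_mu * g2)
        counts = None
    else:
        fn1 = 4.0 * state.n1
        fn2 = 4.0 * state.n2
        counts_k = np.stack([fn1, fn2], axis=-1)
        ks = np.array([k1, k2])
        pf_hom = free_molecules_newton(counts_k, ks, P_T)
        pf_het = free_molecules_newton(counts_k, ks, P_T / 2.0)
        H1hom = pf_hom / (pf_hom + k1)
        H2hom = pf_hom / (pf_hom + k2)
        H1het = pf_het / (pf_het + k1)
        H2het = pf_het / (pf_het + k2)
        PBhom = fn1 * H1hom + fn2 * H2hom
        PBhet = fn1 * H1het + fn2 * H2het
        # DSB probability per genotype; heterozygotes pool both alleles' bound sites
        with np.errstate(divide="ignore"):
            C = D / (PBhet[:, None] + PBhet[None, :])
            np.fill_diagonal(C, D / PBhom)
        if np.any(C > 1.0):
            np.clip(C, None, 1.0, out=C)
            state.cap_generations += 1
        H1 = np.repeat(H1het[:, None], K, axis=1)
        H2 = np.repeat(H2het[:, None], K, axis=1)
        np.fill_diagonal(H1, H1hom)
        np.fill_diagonal(H2, H2hom)
        x1 = np.clip(C * H1 * H1 * (2.0 - H1) * (2.0 - C * H1), 0.0, 1.0)
        x2 = np.clip(C * H2 * H2 * (2.0 - H2) * (2.0 - C * H2), 0.0, 1.0)
        # row j = allele j's log survival contribution in genotype (j, k)
        Lrow = r * (_weighted_log_survival(state.n1[:, None], x1)
                    + _weighted_log_survival(state.n2[:, None], x2))
        M = Lrow + Lrow.T
        np.fill_diagonal(M, np.diagonal(Lrow))
        W = -np.expm1(M)
        if p.neutral:
            W = np.ones_like(W)
        Wj = W @ state.freq
        Wbar = float(state.freq @ Wj)
        fprime = selection_update(state.freq, Wj, Wbar, state.generation)
        fprime /= fprime.sum()
        # erosion uses post-selection Hardy-Weinberg genotype frequencies
        g1jk = B * C * H1
        g2jk = B * C * H2
        g1 = 2.0 * fprime * (g1jk @ fprime) - fprime * fprime * np.diagonal(g1jk)
        g2 = 2.0 * fprime * (g2jk @ fprime) - fprime * fprime * np.diagonal(g2jk)
        state.last_site_loss = four_N_mu * float(g1 @ state.n1
                                                 + g2 @ state.n2)
        state.n1 *= np.clip(1.0 - four_N_mu * g1, 0.0, None)
        state.n2 *= np.clip(1.0 - four_N_mu * g2, 0.0, None)
        counts = wright_fisher_sample(fprime, two_N, state.rng)

    # PRDM9 mutation (binomial draw happens every generation)
    if counts is None:
        n_mut = int(state.rng.binomial(two_N, p.nu))
        new_n1 = [draw_initial_hotspots(p, state.rng) for _ in range(n_mut)]
        if n_mut:
            counts = np.array([two_N - n_mut])
    else:
        counts, new_n1 = mutate_prdm9(counts, p, state.rng)

    gen_next = state.generation + 1
    if counts is not None:
        _apply_composition(state, counts, new_n1, gen_next, params)
    state.generation = gen_next

    # accumulate ledger statistics and detect fixation
    state.sum_freq += state.freq
    np.maximum(state.max_freq, state.freq, out=state.max_freq)
    if state.freq.size == 1 and state.ids[0] != state.last_fixed_id:
        state.last_fixed_id = state.ids[0]
        state.fixation_events.append((gen_next, state.ids[0]))

    n1_mean = float(state.freq @ state.n1)
    pi = 1.0 - float(state.freq @ state.freq)
    return gen_next, n1_mean, float(Wbar), pi


def _apply_composition(state: PopulationState, counts: np.ndarray,
                       new_n1: list[int], gen_next: int,
                       params: ModelParams) -> None:
    """Rebuild the allele arrays after sampling/mutation, closing ledger
    entries for exited alleles and appending newborns."""
    two_N = 2 * params.N
    alive = counts > 0
    if alive.all() and not new_n1:
        state.freq = counts / two_N
        return
    for j in np.flatnonzero(~alive):
        j = int(j)
        sojourn = gen_next - state.birth[j]
        state.ledger.append(LedgerEntry(
            allele_id=state.ids[j], birth_generation=state.birth[j],
            exit_generation=gen_next, initial_hotspots=state.init_n1[j],
            final_hotspots=float(state.n1[j]), sojourn_time=sojourn,
            mean_frequency=float(state.sum_freq[j]) / sojourn,
            max_frequency=float(state.max_freq[j]),
            fixed=bool(state.max_freq[j] >= 1.0), censored=False))
        if state.max_freq[j] >= 0.5 and state.birth[j] > 0:
            state.dominant_exits += 1
    n_new = len(new_n1)
    keep = np.flatnonzero(alive)
    state.ids = [state.ids[int(j)] for j in keep] + list(
        range(state.next_id, state.next_id + n_new))
    state.birth = [state.birth[int(j)] for j in keep] + [gen_next] * n_new
    state.init_n1 = ([state.init_n1[int(j)] for j in keep]
                     + [int(v) for v in new_n1])
    state.next_id += n_new
    new_n1_arr = np.array(new_n1, dtype=float)
    state.n1 = np.concatenate([state.n1[keep], new_n1_arr])
    state.n2 = np.concatenate(
        [state.n2[keep], np.full(n_new, float(params.n2))])
    state.freq = np.concatenate(
        [counts[keep], np.ones(n_new)]) / two_N
    state.sum_freq = np.concatenate(
        [state.sum_freq[keep], np.zeros(n_new)])
    state.max_freq = np.concatenate(
        [state.max_freq[keep], np.zeros(n_new)])


class _TrajectoryBuffer:
    """Chunked column store for per-generation records."""

    _CHUNK = 1 << 16

    def __init__(self) -> None:
        self._chunks: list[np.ndarray] = []
        self._cur = np.empty((self._CHUNK, 4))
        self._i = 0

    def append(self, rec: tuple[int, float, float, float]) -> None:
        if self._i == self._CHUNK:
            self._chunks.append(self._cur)
            self._cur = np.empty((self._CHUNK, 4))
            self._i = 0
        self._cur[self._i] = rec
        self._i += 1

    def to_frame(self) -> pd.DataFrame:
        parts = self._chunks + [self._cur[:self._i]]
        data = np.concatenate(parts, axis=0)
        return pd.DataFrame({
            "generation": data[:, 0].astype(np.int64),
            "n1": data[:, 1], "W": data[:, 2], "pi": data[:, 3]})


@dataclass
class SimulationResult:
    """Trajectory, allele ledger and bookkeeping of one run."""

    params: ModelParams
    trajectory: pd.DataFrame
    ledger: pd.DataFrame
    fixation_events: list[tuple[int, int]]
    cap_generations: int
    final_state: PopulationState


def _close_ledger(state: PopulationState) -> list[LedgerEntry]:
    entries = list(state.ledger)
    for j in range(state.freq.size):
        sojourn = max(state.generation - state.birth[j], 1)
        entries.append(LedgerEntry(
            allele_id=state.ids[j], birth_generation=state.birth[j],
            exit_generation=None, initial_hotspots=state.init_n1[j],
            final_hotspots=float(state.n1[j]), sojourn_time=sojourn,
            mean_frequency=float(state.sum_freq[j]) / sojourn,
            max_frequency=float(state.max_freq[j]),
            fixed=bool(state.max_freq[j] >= 1.0), censored=True))
    return entries


def _ledger_frame(entries: list[LedgerEntry]) -> pd.DataFrame:
    return pd.DataFrame({
        "allele_id": [e.allele_id for e in entries],
        "birth_generation": [e.birth_generation for e in entries],
        "exit_generation": [math.nan if e.exit_generation is None
                            else e.exit_generation for e in entries],
        "initial_hotspots": [e.initial_hotspots for e in entries],
        "final_hotspots": [e.final_hotspots for e in entries],
        "sojourn_time": [e.sojourn_time for e in entries],
        "mean_frequency": [e.mean_frequency for e in entries],
        "max_frequency": [e.max_frequency for e in entries],
        "fixed": [e.fixed for e in entries],
        "censored": [e.censored for e in entries],
    }).sort_values("birth_generation", kind="stable").reset_index(drop=True)


def run_simulation(params: ModelParams,
                   generations: int | None = None,
                   rng: np.random.Generator | None = None,
                   stop_when: Callable[[PopulationState], bool] | None = None,
                   ) -> SimulationResult:
    """Run the model for a fixed number of generations (default
    ``params.generations``), optionally stopping early once ``stop_when``
    returns True. Fully reproducible given ``params.seed``."""
    if generations is None:
        generations = params.generations
    state = initial_state(params, rng)
    buf = _TrajectoryBuffer()
    every = params.record_every
    for g in range(generations):
        rec = step_generation(state, params)
        if (g + 1) % every == 0:
            buf.append(rec)
        if stop_when is not None and stop_when(state):
            break
    return SimulationResult(
        params=params, trajectory=buf.to_frame(),
        ledger=_ledger_frame(_close_ledger(state)),
        fixation_events=list(state.fixation_events),
        cap_generations=state.cap_generations, final_state=state)


def run_until_turnovers(params: ModelParams, min_turnovers: int,
                        max_generations: int,
                        rng: np.random.Generator | None = None,
                        ) -> SimulationResult:
    """Run until at least ``min_turnovers`` non-founder alleles that once
    dominated the population (peak frequency >= 0.5) have exited, or
    ``max_generations`` elapse. Used to size turnover-time estimates."""

    def enough(state: PopulationState) -> bool:
        return state.dominant_exits >= min_turnovers

    return run_simulation(params, generations=max_generations, rng=rng,
                          stop_when=enough)
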