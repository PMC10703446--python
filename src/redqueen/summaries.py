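"""Summary statistics and run outputs.

Allele-level distributions are weighted by sojourn time x mean frequency,
which equals the probability of drawing that allele when sampling a random
gene copy from a random generation of the run; the same weighting defines
the mean turnover time (the weighted mean allele lifetime, right-censored
alleles excluded).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .params import ModelParams
from .simulate import SimulationResult

TRAJECTORY_COLUMNS = ["generation", "n1", "W", "pi"]


def diversity(frequencies) -> float:
    """Expected heterozygosity at the PRDM9 locus, pi = 1 - sum f_j^2."""
    f = np.asarray(frequencies, dtype=float)
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError(f"frequencies sum to {f.sum()!r}, not 1")
    return float(1.0 - f @ f)


def filter_ledger(ledger: pd.DataFrame, burn_in: int = 0,
                  exclude_founder: bool = True,
                  exclude_censored: bool = True) -> pd.DataFrame:
    """Restrict a ledger to alleles usable for stationary summaries."""
    keep = pd.Series(True, index=ledger.index)
    if exclude_founder:
        keep &= ledger["birth_generation"] > 0
    if burn_in:
        keep &= ledger["birth_generation"] >= burn_in
    if exclude_censored:
        keep &= ~ledger["censored"]
    return ledger[keep]


def _binned_distribution(values: np.ndarray, weights: np.ndarray,
                         bin_width: int, upper: float) -> pd.DataFrame:
    edges = np.arange(0.0, upper + bin_width, bin_width)
    hist, _ = np.histogram(values, bins=edges, weights=weights)
    total = hist.sum()
    density = hist / total if total > 0 else hist
    return pd.DataFrame({"bin_start": edges[:-1] + 1, "bin_end": edges[1:],
                         "weight": density})


@dataclass(frozen=True)
class AlleleDistributions:
    """Sojourn-and-frequency-weighted allele summaries."""

    initial: pd.DataFrame
    final: pd.DataFrame
    mean_turnover_time: float
    mean_initial_hotspots: float
    mean_final_hotspots: float


def weighted_allele_distributions(ledger: pd.DataFrame,
                                  initial_bin: int = 100,
                                  final_bin: int = 50,
                                  n1_max: int = 5_000) -> AlleleDistributions:
    """Distributions of initial and final hotspot counts among segregating
    alleles, each allele weighted by sojourn_time x mean_frequency, plus
    the weighted mean turnover time.

    Right-censored alleles (still segregating at the end of the run) must
    be removed beforehand (see :func:`filter_ledger`); their final state
    and sojourn are not observed.
    """
    if len(ledger) == 0:
        raise ValueError("empty allele ledger")
    if ledger["censored"].any():
        ledger = ledger[~ledger["censored"]]
        if len(ledger) == 0:
            raise ValueError("ledger contains only censored alleles")
    w = (ledger["sojourn_time"] * ledger["mean_frequency"]).to_numpy(float)
    w = w / w.sum()
    init = ledger["initial_hotspots"].to_numpy(float)
    final = ledger["final_hotspots"].to_numpy(float)
    sojourn = ledger["sojourn_time"].to_numpy(float)
    return AlleleDistributions(
        initial=_binned_distribution(init, w, initial_bin, n1_max),
        final=_binned_distribution(final, w, final_bin, n1_max),
        mean_turnover_time=float(w @ sojourn),
        mean_initial_hotspots=float(w @ init),
        mean_final_hotspots=float(w @ final))


def mean_turnover_time(ledger: pd.DataFrame, burn_in: int = 0) -> float:
    """Weighted mean allele lifetime after burn-in (founder and censored
    alleles excluded)."""
    usable = filter_ledger(ledger, burn_in=burn_in)
    if len(usable) == 0:
        raise ValueError("no exited non-founder alleles in the ledger")
    w = (usable["sojourn_time"] * usable["mean_frequency"]).to_numpy(float)
    return float(w @ usable["sojourn_time"].to_numpy(float) / w.sum())


def trajectory_summary(trajectory: pd.DataFrame,
                       burn_in: int = 0) -> dict[str, float]:
    """Time-averaged mean and interquartile range of diversity and fitness.

    Percentiles use linear interpolation between order statistics.
    """
    traj = trajectory[trajectory["generation"] > burn_in]
    if len(traj) == 0:
        raise ValueError("empty trajectory after burn-in")
    out: dict[str, float] = {}
    for col in ("pi", "W"):
        values = traj[col].to_numpy(float)
        out[f"{col}_mean"] = float(values.mean())
        out[f"{col}_q25"] = float(np.percentile(values, 25))
        out[f"{col}_q75"] = float(np.percentile(values, 75))
    out["n1_mean"] = float(traj["n1"].to_numpy(float).mean())
    return out


def write_run_outputs(result: SimulationResult, out_dir: str | Path,
                      code_version: str | None = None) -> dict[str, Path]:
    """Write trajectory.csv, ledger.csv and manifest.json for one run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "trajectory": out / "trajectory.csv",
        "ledger": out / "ledger.csv",
        "manifest": out / "manifest.json",
    }
    result.trajectory.to_csv(paths["trajectory"], index=False,
                             columns=TRAJECTORY_COLUMNS,
                             float_format="%.10g")
    result.ledger.to_csv(paths["ledger"], index=False, float_format="%.10g")
    if code_version is None:
        from . import __version__ as code_version
    manifest = {
        "config": result.params.to_dict(),
        "seed": result.params.seed,
        "code_version": code_version,
        "generations_run": int(result.final_state.generation),
        "fixation_events": len(result.fixation_events),
        "dsb_cap_generations": result.cap_generations,
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")
    return paths


def summarize_run(trajectory: pd.DataFrame, ledger: pd.DataFrame,
                  params: ModelParams | None = None,
                  burn_in: int = 0) -> dict:
    """Aggregate one run into the standard summary tables and scalars."""
    usable = filter_ledger(ledger, burn_in=burn_in)
    summary = dict(trajectory_summary(trajectory, burn_in=burn_in))
    if len(usable):
        n1_max = params.n1_max if params is not None else 5_000
        dists = weighted_allele_distributions(usable, n1_max=n1_max)
        summary.update({
            "mean_turnover_time": dists.mean_turnover_time,
            "mean_initial_hotspots": dists.mean_initial_hotspots,
            "mean_final_hotspots": dists.mean_final_hotspots,
        })
    return summary
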