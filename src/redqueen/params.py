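"""Model parameters and run configuration.

The defaults are the two-heat baseline of the model: a diploid panmictic
population in which each PRDM9 allele recognizes a small class of strong
binding sites ("hotspots", dissociation constant ``k1``) plus a large
backdrop of weak sites (``n2`` sites at ``k2``) calibrated so that ~99% of
expressed PRDM9 molecules are bound even in the absence of hotspots.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any


class ConfigError(ValueError):
    """A configuration key is unknown or its value is out of range."""


@dataclass(frozen=True)
class ModelParams:
    """All global constants of the model plus run controls.

    Attributes
    ----------
    N : diploid population size.
    mu : mutation rate from hot to cold alleles per binding site per
        generation (per gamete).
    nu : mutation rate at the PRDM9 locus per gamete per generation.
    D : number of double-strand breaks initiated per meiosis (fixed,
        independent of PRDM9).
    P_T : total number of PRDM9 molecules expressed per meiosis for a
        homozygote; each allele of a heterozygote expresses ``P_T / 2``.
    B : probability that a gene-conversion tract spans the binding motif.
    r : proportion of the genome on the smallest chromosome.
    k1 : dissociation constant of the hotspot (strong) site class.
    k2, n2 : dissociation constant and initial count of the weak backdrop.
    n1_min, n1_max : support of the uniform distribution of hotspot counts
        for newly arising PRDM9 alleles.
    n1_distribution : "uniform" for Uniform{n1_min..n1_max}; "unimodal" for
        a tight rounded-normal alternative centred at ``n1_center``.
    generations : number of generations to simulate.
    seed : RNG seed.
    record_every : cadence (in generations) of trajectory records.
    burn_in : number of leading generations excluded by the summary helpers.
    neutral : diagnostic switch forcing every genotype fitness to 1
        (pure drift); used to validate the Wright-Fisher machinery.
    """

    N: int = 1_000
    mu: float = 1.25e-7
    nu: float = 1e-5
    D: float = 300.0
    P_T: float = 5_000.0
    B: float = 0.7
    r: float = 1.0 / 40.0
    k1: float = 50.0
    k2: float = 8_030.0
    n2: float = 200_000.0
    n1_min: int = 1
    n1_max: int = 5_000
    n1_distribution: str = "uniform"
    n1_center: float = 1_000.0
    n1_sd: float = 100.0
    founder_n1: int | None = None
    generations: int = 10_000
    seed: int = 1
    record_every: int = 1
    burn_in: int = 0

    neutral: bool = False

    def __post_init__(self) -> None:
        checks = [
            ("N", self.N >= 1),
            ("mu", 0.0 <= self.mu <= 1.0),
            ("nu", 0.0 <= self.nu <= 1.0),
            ("D", self.D > 0),
            ("P_T", self.P_T > 0),
            ("B", 0.0 <= self.B <= 1.0),
            ("r", 0.0 < self.r <= 1.0),
            ("k1", self.k1 > 0),
            ("k2", self.k2 > 0),
            ("n2", self.n2 >= 0),
            ("n1_min", 1 <= self.n1_min <= self.n1_max),
            ("n1_max", self.n1_max >= self.n1_min),
            ("n1_distribution", self.n1_distribution in ("uniform", "unimodal")),
            ("generations", self.generations >= 0),
            ("record_every", self.record_every >= 1),
            ("burn_in", self.burn_in >= 0),
        ]
        for key, ok in checks:
            if not ok:
                raise ConfigError(f"invalid value for parameter {key!r}: "
                                  f"{getattr(self, key)!r}")

    def replace(self, **kwargs: Any) -> "ModelParams":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


_FIELDS = {f.name for f in dataclasses.fields(ModelParams)}

#: Named parameter presets for the regimes explored in the dynamics analyses
#: and for the lower PRDM9-expression variants.
SCENARIOS: dict[str, dict[str, Any]] = {
    "fig4-weak-largeN": {"N": 1_000_000, "k1": 50.0},
    "fig4-weak-smallN": {"N": 1_000, "k1": 50.0},
    "fig4-strong-largeN": {"N": 1_000_000, "k1": 5.0},
    "fig4-strong-smallN": {"N": 1_000, "k1": 5.0},
    "appendix4-PT500": {"P_T": 500.0},
    "appendix4-PT1000": {"P_T": 1_000.0},
    "appendix4-PT2500": {"P_T": 2_500.0},
}


def params_from_dict(data: dict[str, Any], **overrides: Any) -> ModelParams:
    """Build :class:`ModelParams`, rejecting unknown keys by name."""
    merged = dict(data)
    merged.update({k: v for k, v in overrides.items() if v is not None})
    unknown = set(merged) - _FIELDS
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
    return ModelParams(**merged)


def load_config(path: str | Path, **overrides: Any) -> ModelParams:
    """Read a TOML or JSON configuration file into :class:`ModelParams`."""
    path = Path(path)
    text = path.read_bytes()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = tomllib.loads(text.decode())
    if not isinstance(data, dict):
        raise ConfigError(f"configuration root must be a table/object: {path}")
    return params_from_dict(data, **overrides)
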