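"""Synthetic country tables with the statistical shape of worldwide well-being data.

National mean life evaluations on the 0–10 Cantril Ladder span roughly 2.4
(lowest-ranked countries) to 7.8 (highest), with within-country SDs of a few
ladder points and heavily right-skewed population sizes.  These generators
emulate that structure so every downstream stage is testable without any
external download.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from twinworld.country_data import CountryRecord, CountryTable

#: Default calendar year attached to generated records.
DEFAULT_YEAR = 2019


@dataclass(frozen=True)
class WorldGenParams:
    """Parameters of the synthetic world generator.

    Means are uniform on [mean_low, mean_high] (defaults span the 2.4–7.8
    range of published national means), SDs uniform on [sd_low, sd_high]
    (defaults bracket typical national SDs of 1.7–2.7 ladder points), and
    populations log-normal (default median ≈ 9 million with a heavy right
    tail, realistic for UN country estimates).
    """

    n_countries: int = 157
    mean_low: float = 2.4
    mean_high: float = 7.8
    sd_low: float = 1.5
    sd_high: float = 3.0
    population_log_mean: float = 16.0
    population_log_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_countries < 1:
            raise ValueError("n_countries must be >= 1")
        if not 0.0 <= self.mean_low < self.mean_high <= 10.0:
            raise ValueError("require 0 <= mean_low < mean_high <= 10")
        if not 0.0 < self.sd_low < self.sd_high:
            raise ValueError("require 0 < sd_low < sd_high")


def _country_stream(seed: int, name: str) -> np.random.Generator:
    """Named RNG substream: independent of country iteration order."""
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([seed, tag]))


def generate_world(params: WorldGenParams) -> CountryTable:
    """Draw a synthetic country table, fully reproducible from ``params.seed``."""
    records = []
    width = len(str(params.n_countries))
    for i in range(params.n_countries):
        name = f"C{i + 1:0{width}d}"
        rng = _country_stream(params.seed, name)
        mean = rng.uniform(params.mean_low, params.mean_high)
        sd = rng.uniform(params.sd_low, params.sd_high)
        population = float(
            np.ceil(rng.lognormal(params.population_log_mean, params.population_log_sd))
        )
        records.append(
            CountryRecord(
                name=name,
                mean=mean,
                sd=sd,
                population=population,
                yearly={DEFAULT_YEAR: (mean, sd)},
            )
        )
    return CountryTable(tuple(records), frozenset({DEFAULT_YEAR}))


def homogeneous_world(n_countries: int, mean: float, sd: float) -> CountryTable:
    """A null world: ``n_countries`` identical records with equal populations.

    With zero between-country variance the worldwide shared-environment
    component equals the within-country one, so this table is the reference
    for parameter-recovery checks.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    width = len(str(n_countries))
    records = tuple(
        CountryRecord(
            name=f"C{i + 1:0{width}d}",
            mean=mean,
            sd=sd,
            population=1_000_000.0,
            yearly={DEFAULT_YEAR: (mean, sd)},
        )
        for i in range(n_countries)
    )
    return CountryTable(records, frozenset({DEFAULT_YEAR}))


def calibrated_world(
    n_countries: int = 157,
    between_share: float = 0.19,
    grand_mean: float = 5.0,
    sd: float = 2.0,
) -> CountryTable:
    """Deterministic table whose between-country variance share is exact.

    Country means are evenly spaced and standardized so that the (equal-weight)
    variance of the means is ``between_share / (1 - between_share) * sd**2``,
    i.e. between-country variance accounts for exactly ``between_share`` of the
    total pooled variance.  All within-country SDs equal ``sd`` and populations
    are equal.  Useful for mirroring a target worldwide shared-environment
    share without external data.
    """
    if not 0.0 <= between_share < 1.0:
        raise ValueError("between_share must be in [0, 1)")
    if sd <= 0:
        raise ValueError("sd must be positive")
    if n_countries < 2 and between_share > 0:
        raise ValueError("need >= 2 countries for a positive between share")
    z = np.linspace(-1.0, 1.0, n_countries)
    if between_share > 0:
        z = (z - z.mean()) / z.std()  # population SD; weights are equal
        spread = sd * np.sqrt(between_share / (1.0 - between_share))
    else:
        z = np.zeros(n_countries)
        spread = 0.0
    means = grand_mean + spread * z
    if means.min() < 0 or means.max() > 10:
        raise ValueError("calibrated means leave the 0-10 ladder; reduce the spread")
    width = len(str(n_countries))
    records = tuple(
        CountryRecord(
            name=f"C{i + 1:0{width}d}",
            mean=float(m),
            sd=sd,
            population=1_000_000.0,
            yearly={DEFAULT_YEAR: (float(m), sd)},
        )
        for i, m in enumerate(means)
    )
    return CountryTable(records, frozenset({DEFAULT_YEAR}))
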