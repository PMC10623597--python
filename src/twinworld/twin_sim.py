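"""Bivariate-normal twin-pair simulation per country, pooled worldwide.

Each country contributes MZ pairs correlated at r_MZ and DZ pairs correlated
at r_DZ, with both margins set to the country's well-being mean and SD.  Under
Falconer's model r_MZ = a² + c² and r_DZ = a²/2 + c², so within-country ACE
inputs map directly to target twin correlations.  Pooling countries with
different means adds between-country variance that loads identically on both
members of every pair — the mechanism by which national differences surface
as a worldwide shared-environment component.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from twinworld.country_data import CountryRecord, CountryTable, SamplingPlan

#: Column layout of a twin dataset (a pandas DataFrame).
TWIN_COLUMNS = ("country", "zygosity", "twin1", "twin2")


@dataclass(frozen=True)
class TwinCorrelations:
    """Target twin–cotwin correlations for MZ and DZ pairs."""

    r_mz: float
    r_dz: float

    def __post_init__(self) -> None:
        if not (-1.0 <= self.r_mz <= 1.0 and -1.0 <= self.r_dz <= 1.0):
            raise ValueError("twin correlations must lie in [-1, 1]")


def ace_to_twin_correlations(a2: float, c2: float) -> TwinCorrelations:
    """Invert Falconer's equations: (a², c²) -> (r_MZ, r_DZ).

    MZ twins share all additive-genetic variance and the shared environment
    (r_MZ = a² + c²); DZ twins share on average half the additive-genetic
    variance (r_DZ = a²/2 + c²).
    """
    if a2 < 0 or c2 < 0 or a2 + c2 > 1:
        raise ValueError("(a2, c2) must lie in the unit simplex")
    return TwinCorrelations(r_mz=a2 + c2, r_dz=a2 / 2.0 + c2)


def _correlated_pairs(
    rng: np.random.Generator, n: int, r: float
) -> tuple[np.ndarray, np.ndarray]:
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    return z1, r * z1 + np.sqrt(max(0.0, 1.0 - r * r)) * z2


def _match_moments(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Affine-rescale so the sample mean and SD (ddof=1) hit the targets exactly.

    Pearson correlations are invariant under per-variable affine maps, so
    rescaling each twin column separately leaves the realized twin correlation
    untouched while making the country moments exact.
    """
    s = x.std(ddof=1)
    if s == 0:
        raise ValueError("degenerate sample: zero variance, cannot moment-match")
    return (x - x.mean()) / s * sd + mean


def simulate_country(
    record: CountryRecord,
    n_mz: int,
    n_dz: int,
    corr: TwinCorrelations,
    seed: int | np.random.SeedSequence,
    moment_match: bool = True,
) -> pd.DataFrame:
    """Simulate one country's MZ and DZ twin pairs.

    Pairs are drawn from a bivariate normal with both margins at
    (record.mean, record.sd) and the requested zygosity correlation.  With
    ``moment_match`` each twin column within each zygosity group is linearly
    rescaled so its sample mean and SD equal the record's values exactly; the
    realized correlation keeps its sampling noise.
    """
    if n_mz < 2 or n_dz < 2:
        raise ValueError("need at least 2 pairs per zygosity")
    rng = np.random.default_rng(seed)
    frames = []
    for zygosity, n, r in (("MZ", n_mz, corr.r_mz), ("DZ", n_dz, corr.r_dz)):
        t1, t2 = _correlated_pairs(rng, n, r)
        if moment_match:
            t1 = _match_moments(t1, record.mean, record.sd)
            t2 = _match_moments(t2, record.mean, record.sd)
        else:
            t1 = record.mean + record.sd * t1
            t2 = record.mean + record.sd * t2
        frames.append(
            pd.DataFrame(
                {
                    "country": record.name,
                    "zygosity": zygosity,
                    "twin1": t1,
                    "twin2": t2,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_world(
    table: CountryTable,
    plan: SamplingPlan,
    corr: TwinCorrelations,
    seed: int,
    moment_match: bool = True,
) -> pd.DataFrame:
    """Simulate every country in ``plan`` and pool into one worldwide dataset.

    Each country runs on a named RNG substream derived from ``seed`` and the
    country name, so results do not depend on iteration order.
    """
    missing = [r.name for r in table if r.name not in plan.counts]
    if missing:
        raise ValueError(f"sampling plan missing countries: {missing[:5]}")
    frames = []
    for record in table:
        n_mz, n_dz = plan.counts[record.name]
        sub = np.random.SeedSequence([seed, zlib.crc32(record.name.encode("utf-8"))])
        frames.append(
            simulate_country(record, n_mz, n_dz, corr, sub, moment_match=moment_match)
        )
    return pd.concat(frames, ignore_index=True)
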