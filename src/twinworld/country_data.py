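"""Country-level well-being tables and per-country twin sampling plans.

A country table holds, for each country, the mean and standard deviation of
subjective well-being on the 0–10 Cantril Ladder (optionally per year) plus a
population count.  Sampling plans assign monozygotic (MZ) and dizygotic (DZ)
twin-pair counts to each country, either uniformly or proportionally to
population.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: CSV header used by both the reader and the writer.
CSV_COLUMNS = ("country", "year", "mean", "sd", "population")


@dataclass(frozen=True)
class CountryRecord:
    """One country's well-being summary statistics.

    Parameters
    ----------
    name
        Country identifier (unique within a table).
    mean
        Well-being mean, ladder units, in [0, 10].
    sd
        Well-being standard deviation, ladder units, > 0.
    population
        Person count, > 0.
    yearly
        Optional mapping year -> (mean, sd); when present, ``mean`` and ``sd``
        are the unweighted averages of the yearly entries.
    """

    name: str
    mean: float
    sd: float
    population: float
    yearly: Mapping[int, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean <= 10.0:
            raise ValueError(
                f"country {self.name!r}: mean {self.mean} outside the 0-10 ladder"
            )
        if not self.sd > 0.0:
            raise ValueError(f"country {self.name!r}: sd must be positive, got {self.sd}")
        if not self.population > 0:
            raise ValueError(
                f"country {self.name!r}: population must be positive, got {self.population}"
            )
        if self.yearly is not None:
            agg_mean, agg_sd = aggregate_years(self.yearly)
            if not (
                math.isclose(agg_mean, self.mean, abs_tol=1e-9)
                and math.isclose(agg_sd, self.sd, abs_tol=1e-9)
            ):
                raise ValueError(
                    f"country {self.name!r}: (mean, sd) inconsistent with yearly entries"
                )


@dataclass(frozen=True)
class CountryTable:
    """Ordered collection of :class:`CountryRecord` with unique names."""

    records: tuple[CountryRecord, ...]
    years: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("country table must be non-empty")
        names = [r.name for r in self.records]
        if len(set(names)) != len(names):
            raise ValueError("country names must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def names(self) -> list[str]:
        return [r.name for r in self.records]

    def subset_year(self, year: int) -> "CountryTable":
        """Table restricted to one year's (mean, sd), dropping countries without it."""
        recs = []
        for r in self.records:
            if r.yearly and year in r.yearly:
                m, s = r.yearly[year]
                recs.append(
                    CountryRecord(r.name, m, s, r.population, yearly={year: (m, s)})
                )
        if not recs:
            raise ValueError(f"no country has data for year {year}")
        return CountryTable(tuple(recs), frozenset({year}))


@dataclass(frozen=True)
class SamplingPlan:
    """Per-country MZ/DZ pair counts: mapping name -> (n_mz, n_dz)."""

    counts: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        for name, (n_mz, n_dz) in self.counts.items():
            if n_mz < 1 or n_dz < 1:
                raise ValueError(f"country {name!r}: pair counts must be >= 1")

    @property
    def total_mz(self) -> int:
        return sum(n for n, _ in self.counts.values())

    @property
    def total_dz(self) -> int:
        return sum(n for _, n in self.counts.values())

    @property
    def total_pairs(self) -> int:
        return self.total_mz + self.total_dz


def aggregate_years(
    record_years: Mapping[int, tuple[float, float]],
) -> tuple[float, float]:
    """Average yearly (mean, sd) pairs into one summary.

    Unweighted arithmetic mean of the available yearly means, and of the
    available yearly SDs.  Permutation-invariant and idempotent on constant
    series.
    """
    if not record_years:
        raise ValueError("no yearly entries to aggregate")
    means = [m for m, _ in record_years.values()]
    sds = [s for _, s in record_years.values()]
    return sum(means) / len(means), sum(sds) / len(sds)


def read_country_table(path: str | Path, years: Iterable[int] | None = None) -> CountryTable:
    """Read a country table CSV (columns ``country,year,mean,sd,population``).

    Each country keeps the years with valid (non-missing) mean and sd; its
    summary (mean, sd) is the unweighted average across those years.  Countries
    with no valid year (after the optional ``years`` filter) are dropped with a
    logged warning.  Rows with sd <= 0 or mean outside [0, 10] raise.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    if "population" not in df.columns:
        df["population"] = 1.0

    if years is not None:
        keep = frozenset(int(y) for y in years)
        df = df[df["year"].isin(keep)]

    records: list[CountryRecord] = []
    years_seen: set[int] = set()
    for name, grp in df.groupby("country", sort=False):
        yearly: dict[int, tuple[float, float]] = {}
        population = None
        for idx, row in grp.iterrows():
            m, s = row["mean"], row["sd"]
            if pd.isna(m) or pd.isna(s):
                continue  # missing year for this country
            if s <= 0:
                raise ValueError(f"{path} row {idx}: sd must be positive, got {s}")
            if not 0.0 <= m <= 10.0:
                raise ValueError(f"{path} row {idx}: mean {m} outside the 0-10 ladder")
            yearly[int(row["year"])] = (float(m), float(s))
            if not pd.isna(row["population"]):
                population = float(row["population"])
        if not yearly:
            logger.warning("dropping country %r: no valid year", name)
            continue
        mean, sd = aggregate_years(yearly)
        records.append(
            CountryRecord(
                name=str(name),
                mean=mean,
                sd=sd,
                population=population if population is not None else 1.0,
                yearly=yearly,
            )
        )
        years_seen.update(yearly)
    if not records:
        raise ValueError(f"{path}: no country has valid data")
    logger.info(
        "read %d countries over years %s from %s", len(records), sorted(years_seen), path
    )
    return CountryTable(tuple(records), frozenset(years_seen))


def write_country_table(table: CountryTable, path: str | Path) -> None:
    """Write a table in the same CSV dialect the reader accepts."""
    rows = []
    for r in table:
        yearly = r.yearly or {0: (r.mean, r.sd)}
        for year, (m, s) in sorted(yearly.items()):
            rows.append((r.name, year, m, s, r.population))
    pd.DataFrame(rows, columns=list(CSV_COLUMNS)).to_csv(path, index=False)


def build_sampling_plan(
    table: CountryTable,
    mode: str,
    pairs_per_zygosity: int,
) -> SamplingPlan:
    """Assign MZ/DZ pair counts to every country.

    ``mode='equal'``: every country gets ``pairs_per_zygosity`` MZ pairs and
    the same number of DZ pairs.

    ``mode='population_weighted'``: ``pairs_per_zygosity`` is the per-zygosity
    TOTAL, split proportionally to population by the largest-remainder
    (Hamilton) method with a floor of one pair per country; ties broken by
    descending population, then name order.  Totals are conserved exactly.
    """
    n = len(table)
    if mode == "equal":
        if pairs_per_zygosity < 1:
            raise ValueError("pairs_per_zygosity must be >= 1")
        counts = {r.name: (pairs_per_zygosity, pairs_per_zygosity) for r in table}
    elif mode == "population_weighted":
        if pairs_per_zygosity < n:
            raise ValueError(
                f"pairs_per_zygosity ({pairs_per_zygosity}) must be >= number of "
                f"countries ({n}) so every country gets at least one pair"
            )
        alloc = _largest_remainder(table, pairs_per_zygosity)
        counts = {name: (k, k) for name, k in alloc.items()}
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")
    return SamplingPlan(counts)


def _largest_remainder(table: CountryTable, total: int) -> dict[str, int]:
    """Hamilton apportionment of ``total`` pairs proportionally to population."""
    pop_total = sum(r.population for r in table)
    quotas = {r.name: total * r.population / pop_total for r in table}
    base = {name: max(1, math.floor(q)) for name, q in quotas.items()}
    remainder = {name: quotas[name] - math.floor(quotas[name]) for name in quotas}
    pop = {r.name: r.population for r in table}
    leftover = total - sum(base.values())
    # order: largest fractional remainder, then largest population, then name
    order = sorted(base, key=lambda c: (-remainder[c], -pop[c], c))
    if leftover >= 0:
        for name in order[:leftover]:
            base[name] += 1
    else:
        # the min-1 floor overshot; take back from smallest remainders first
        while leftover < 0:
            progressed = False
            for name in reversed(order):
                if leftover == 0:
                    break
                if base[name] > 1:
                    base[name] -= 1
                    leftover += 1
                    progressed = True
            if not progressed:
                raise ValueError("total too small to give every country one pair")
    assert sum(base.values()) == total
    return base
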