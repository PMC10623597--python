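"""Closed-form expectations for pooled correlations and worldwide ACE.

Pooling countries mixes within-country variation with between-country mean
differences.  By the law of total covariance, with country weights w_c,
within-country SDs σ_c, a common within-country twin correlation r, and
between-country mean variance V_b = Σ w_c (μ_c − μ̄)²:

    E[r_pooled] = (Σ w_c σ_c² · r  +  V_b) / (Σ w_c σ_c²  +  V_b)

because the country mean loads identically on both twins of a pair.  Applying
Falconer's equations to the expected pooled MZ and DZ correlations gives the
expected worldwide components in closed form: with within share
W = V_w / (V_w + V_b) and between share B = 1 − W,

    A_world = a² · W,   C_world = c² · W + B,   E_world = e² · W.

These are large-sample expectations (exact for moment-matched simulations up
to within-country correlation noise); they are the verification surface for
the Monte Carlo pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from twinworld.ace import ACEEstimate, falconer
from twinworld.country_data import CountryTable
from twinworld.twin_sim import TwinCorrelations


@dataclass(frozen=True)
class PooledMoments:
    """Variance decomposition of the pooled worldwide sample."""

    within_var: float  # Σ w_c σ_c², squared ladder units
    between_var: float  # Σ w_c (μ_c − μ̄)², squared ladder units

    @property
    def total_var(self) -> float:
        return self.within_var + self.between_var

    @property
    def between_share(self) -> float:
        return self.between_var / self.total_var


def country_weights(table: CountryTable, mode: str = "equal") -> np.ndarray:
    """Per-country sampling proportions: uniform or population-proportional."""
    n = len(table)
    if mode == "equal":
        return np.full(n, 1.0 / n)
    if mode == "population_weighted":
        pops = np.array([r.population for r in table], dtype=float)
        return pops / pops.sum()
    raise ValueError(f"unknown weighting mode {mode!r}")


def _check_weights(table: CountryTable, weights: Sequence[float]) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.shape != (len(table),):
        raise ValueError("need exactly one weight per country")
    if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must be nonnegative and sum to 1")
    return w


def pooled_moments(table: CountryTable, weights: Sequence[float]) -> PooledMoments:
    """Within- and between-country variance of the pooled mixture."""
    w = _check_weights(table, weights)
    mu = np.array([r.mean for r in table])
    sigma2 = np.array([r.sd**2 for r in table])
    mu_bar = float(w @ mu)
    return PooledMoments(
        within_var=float(w @ sigma2),
        between_var=float(w @ (mu - mu_bar) ** 2),
    )


def expected_pooled_correlation(
    table: CountryTable, weights: Sequence[float], r_within: float
) -> float:
    """Expected worldwide twin correlation for a common within-country r."""
    m = pooled_moments(table, weights)
    return (m.within_var * r_within + m.between_var) / m.total_var


def expected_worldwide_ace(
    table: CountryTable, weights: Sequence[float], corr: TwinCorrelations
) -> ACEEstimate:
    """Falconer decomposition of the expected pooled correlations.

    The between-country share B inflates both expected correlations equally,
    so it lands entirely in C (2B − B = B) while A and E shrink by the within
    share: A_world = a²·(1 − B), E_world = e²·(1 − B).
    """
    r_mz = expected_pooled_correlation(table, weights, corr.r_mz)
    r_dz = expected_pooled_correlation(table, weights, corr.r_dz)
    return falconer(TwinCorrelations(r_mz=r_mz, r_dz=r_dz))
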