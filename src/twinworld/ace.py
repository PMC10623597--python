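"""ACE variance decomposition from pooled twin correlations.

Falconer's equations turn the MZ and DZ twin–cotwin correlations into the
three classical variance components:

    A = a² = 2 (r_MZ − r_DZ)        additive genetic
    C = c² = 2 r_DZ − r_MZ          shared environment
    E = e² = 1 − r_MZ               nonshared environment (+ measurement error)

The three sum to one identically.  Estimates are reported raw — C may be
slightly negative under sampling noise; nothing is truncated at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from twinworld.twin_sim import TwinCorrelations


@dataclass(frozen=True)
class ACEEstimate:
    """A/C/E variance proportions with optional 95% confidence intervals."""

    a2: float
    c2: float
    e2: float
    ci_a2: tuple[float, float] | None = None
    ci_c2: tuple[float, float] | None = None
    ci_e2: tuple[float, float] | None = None

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.a2, self.c2, self.e2)


@dataclass(frozen=True)
class RepSummary:
    """Per-repetition estimates and pooled correlations of a Monte Carlo run."""

    estimates: tuple[ACEEstimate, ...]
    r_mz: tuple[float, ...]
    r_dz: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.estimates:
            raise ValueError("need at least one repetition")
        if not len(self.estimates) == len(self.r_mz) == len(self.r_dz):
            raise ValueError("repetition lists must have equal length")

    @property
    def n_reps(self) -> int:
        return len(self.estimates)


def pair_correlation(data: pd.DataFrame, zygosity: str) -> float:
    """Pearson twin–cotwin correlation over pooled raw scores of one zygosity.

    Scores are NOT standardized within country: the pooled correlation must
    keep the between-country signal, which is what the worldwide design
    measures.
    """
    sub = data.loc[data["zygosity"] == zygosity]
    if len(sub) < 2:
        raise ValueError(f"need >= 2 pairs of zygosity {zygosity!r}")
    t1 = sub["twin1"].to_numpy()
    t2 = sub["twin2"].to_numpy()
    if t1.std() == 0 or t2.std() == 0:
        raise ValueError("zero variance in a twin column")
    return float(np.corrcoef(t1, t2)[0, 1])


def falconer(corr: TwinCorrelations) -> ACEEstimate:
    """Apply Falconer's equations to a pair of twin correlations."""
    a2 = 2.0 * (corr.r_mz - corr.r_dz)
    c2 = 2.0 * corr.r_dz - corr.r_mz
    e2 = 1.0 - corr.r_mz
    return ACEEstimate(a2=a2, c2=c2, e2=e2)


def adjust_for_reliability(est: ACEEstimate, rho: float) -> ACEEstimate:
    """Disattenuate for measurement error with reliability ``rho``.

    Random error variance (1 − rho) sits inside E; it is subtracted and the
    remaining true-score components renormalized by rho so they again sum to
    one.  Confidence intervals, when present, are mapped through the same
    affine transformation.
    """
    if not 0.0 < rho <= 1.0:
        raise ValueError("reliability must lie in (0, 1]")
    if est.e2 < (1.0 - rho) - 1e-12:
        raise ValueError(
            f"infeasible reliability: E = {est.e2} is smaller than the error "
            f"share 1 - rho = {1 - rho}"
        )

    def scale(x: float) -> float:
        return x / rho

    def scale_e(x: float) -> float:
        return (x - (1.0 - rho)) / rho

    return ACEEstimate(
        a2=scale(est.a2),
        c2=scale(est.c2),
        e2=scale_e(est.e2),
        ci_a2=tuple(map(scale, est.ci_a2)) if est.ci_a2 else None,
        ci_c2=tuple(map(scale, est.ci_c2)) if est.ci_c2 else None,
        ci_e2=tuple(map(scale_e, est.ci_e2)) if est.ci_e2 else None,
    )


def summarize_reps(
    reps: RepSummary, ci: bool = True, percentile: bool = False
) -> ACEEstimate:
    """Point estimates and 95% CIs across Monte Carlo repetitions.

    The point estimate is the mean across repetitions.  Normal-theory CIs are
    mean ± 1.96 × SD of the repetition estimates; ``percentile=True`` uses the
    empirical 2.5/97.5 percentiles instead.
    """
    arr = np.array([e.as_tuple() for e in reps.estimates])  # (n_reps, 3)
    point = arr.mean(axis=0)
    if not ci:
        return ACEEstimate(*map(float, point))
    if reps.n_reps < 2:
        raise ValueError("need >= 2 repetitions for confidence intervals")
    if percentile:
        lo = np.percentile(arr, 2.5, axis=0)
        hi = np.percentile(arr, 97.5, axis=0)
    else:
        sd = arr.std(axis=0, ddof=1)
        lo, hi = point - 1.96 * sd, point + 1.96 * sd
    return ACEEstimate(
        a2=float(point[0]),
        c2=float(point[1]),
        e2=float(point[2]),
        ci_a2=(float(lo[0]), float(hi[0])),
        ci_c2=(float(lo[1]), float(hi[1])),
        ci_e2=(float(lo[2]), float(hi[2])),
    )
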