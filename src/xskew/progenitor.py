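"""Estimating the progenitor pool size at X inactivation.

If each of N progenitor cells independently inactivates the paternal X
with probability p, the per-individual maternal-active fraction f = K/N
has among-individual variance p(1-p)/N.  The pool size is therefore read
off the observed among-individual variance: simulate the sampling
variance of f over a grid of N, then invert the simulated curve at the
observed value.

The observed variance comes from the fitted nested ANOVA via the
expected-mean-square identity sigma^2_ind = (MS_individual - MS_residual)/c
(c = observations per individual), so measurement noise is subtracted
before matching — the matched quantity is the variance of f itself.

Interpolation is linear in 1/N, where the binomial variance law is exact.
The 95% CI inverts the 2.5th/97.5th percentile curves of the simulated
replicate variances, i.e. the set of N whose replicate-variance
distribution is compatible with the observed value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .anova import AnovaResult
from .errors import ParameterError

DEFAULT_GRID = tuple(range(30, 151))
DEFAULT_REPS = 1000


def observed_sampling_variance(result: AnovaResult) -> float:
    """Among-individual variance of f from the ANOVA strata.

    (MS_individual - MS_residual) / c with c the average observations per
    individual (genes x replicates); clamped at zero with a warning when
    the individual stratum falls below the residual.
    """
    ms_ind = float(result.table.loc["individual(mother)", "mean_sq"])
    ms_res = float(result.table.loc["residual", "mean_sq"])
    c = float(result.meta["obs_per_individual"])
    var = (ms_ind - ms_res) / c
    if var < 0:
        warnings.warn(
            "individual mean square below residual; sampling variance clamped to 0",
            stacklevel=2,
        )
        return 0.0
    return var


@dataclass
class VarianceCurve:
    """Simulated among-individual variance of f over a grid of pool sizes.

    ``replicate_variances`` has shape (reps, len(grid)): each entry is the
    pooled within-cross sample variance of one simulated cohort.
    """

    grid: np.ndarray
    mean_variance: np.ndarray
    replicate_variances: np.ndarray
    p: float
    n_individuals: int
    n_crosses: int

    def quantile(self, q: float) -> np.ndarray:
        return np.quantile(self.replicate_variances, q, axis=0)


def simulate_variance_curve(
    grid: Sequence[int] = DEFAULT_GRID,
    *,
    n_individuals: int = 18,
    p: float = 0.53,
    reps: int = DEFAULT_REPS,
    n_crosses: int = 2,
    rng: np.random.Generator | int | None = None,
) -> VarianceCurve:
    """Monte-Carlo curve of among-individual variance of f against N.

    For each pool size N on the grid, each replicate draws
    ``n_individuals`` binomial fractions per cross for ``n_crosses``
    crosses and records the mean of the within-cross sample variances —
    the same estimand as the ANOVA's individual-within-mother stratum.
    """
    grid = np.asarray(sorted(grid), dtype=int)
    if grid.size == 0:
        raise ParameterError("grid must be non-empty")
    if (grid < 1).any():
        raise ParameterError("grid values must be >= 1")
    if n_individuals < 2:
        raise ParameterError("need >= 2 individuals per cross to form a variance")
    if reps < 1:
        raise ParameterError("reps must be >= 1")
    rng = np.random.default_rng(rng)

    var = np.empty((reps, grid.size))
    for j, N in enumerate(grid):
        draws = rng.binomial(N, p, size=(reps, n_crosses, n_individuals)) / N
        var[:, j] = draws.var(axis=2, ddof=1).mean(axis=1)
    return VarianceCurve(
        grid=grid,
        mean_variance=var.mean(axis=0),
        replicate_variances=var,
        p=p,
        n_individuals=n_individuals,
        n_crosses=n_crosses,
    )


@dataclass
class CellNumberEstimate:
    n_hat: float
    ci95: tuple[float, float]
    observed_variance: float
    extrapolated: bool
    meta: dict = field(default_factory=dict)

    def __repr__(self) -> str:
        lo, hi = self.ci95
        tag = " (extrapolated)" if self.extrapolated else ""
        return f"CellNumberEstimate(N={self.n_hat:.1f}, 95% CI [{lo:.1f}, {hi:.1f}]){tag}"


def _invert_curve(values: np.ndarray, grid: np.ndarray, observed: float) -> tuple[float, bool]:
    """Invert a variance-vs-N curve at ``observed``, interpolating in 1/N.

    Variance decreases in N, so it increases in x = 1/N; minor Monte-Carlo
    non-monotonicity is ironed out with an isotonic (running-max) pass
    before :func:`numpy.interp`.  Outside the grid the exact c/N scaling
    extends the curve, and the result is flagged extrapolated.
    """
    x = 1.0 / grid[::-1].astype(float)  # ascending in x
    v = values[::-1].astype(float)
    v_iso = np.maximum.accumulate(v)
    if observed < v_iso[0] or observed > v_iso[-1]:
        slope = float(np.dot(v, x) / np.dot(x, x))  # lsq fit of v = slope / N
        return slope / observed, True
    x_hat = float(np.interp(observed, v_iso, x))
    return 1.0 / x_hat, False


def estimate_cell_number(
    observed_variance: float,
    curve: VarianceCurve,
    *,
    allow_extrapolation: bool = True,
) -> CellNumberEstimate:
    """Match an observed among-individual variance to the simulated curve.

    The point estimate inverts the mean curve; the 95% CI inverts the
    2.5th and 97.5th percentile curves of the per-replicate variances.
    """
    if observed_variance <= 0:
        raise ParameterError("observed variance must be positive")
    n_hat, extra = _invert_curve(curve.mean_variance, curve.grid, observed_variance)
    if extra and not allow_extrapolation:
        raise ParameterError(
            f"observed variance {observed_variance:.4g} outside the simulated range "
            f"for grid [{curve.grid[0]}, {curve.grid[-1]}]"
        )
    lo_curve = curve.quantile(0.025)
    hi_curve = curve.quantile(0.975)
    # variance decreases with N: the upper quantile curve bounds N above
    n_low, extra_lo = _invert_curve(lo_curve, curve.grid, observed_variance)
    n_high, extra_hi = _invert_curve(hi_curve, curve.grid, observed_variance)
    n_low, n_high = min(n_low, n_hat), max(n_high, n_hat)
    return CellNumberEstimate(
        n_hat=float(n_hat),
        ci95=(float(n_low), float(n_high)),
        observed_variance=float(observed_variance),
        extrapolated=bool(extra),
        meta={
            "ci_extrapolated": bool(extra_lo or extra_hi),
            "grid": (int(curve.grid[0]), int(curve.grid[-1])),
            "reps": int(curve.replicate_variances.shape[0]),
            "n_individuals": curve.n_individuals,
            "n_crosses": curve.n_crosses,
            "p": curve.p,
        },
    )
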