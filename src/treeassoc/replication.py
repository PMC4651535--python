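"""Standardisation of per-plot curves onto the null band and replicate pooling.

Replicate plots yield one envelope each for a species pair.  To pool them,
every plot's empirical curve is mapped by the affine transform that sends
the plot's own null band to exactly [-1, 1]:

    F_st(d) = a(d) + b(d) F(d),   b(d) = 2 / (N_sup(d) - N_inf(d)),
                                  a(d) = 1 - b(d) N_sup(d)

so that the upper bound maps to +1 and the lower to -1.  The pooled curve
is the per-lag mean of the standardised replicates; lags where a replicate's
band is degenerate (N_sup == N_inf) or its statistic undefined are carried
as missing and excluded from the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .null_models import EnvelopeResult
from .spatial_stats import DistanceGrid

__all__ = ["StandardizedCurve", "standardize", "pool", "pooled_null"]


@dataclass
class StandardizedCurve:
    """Per-replicate standardised curves and their pooled mean on a shared grid."""

    grid: DistanceGrid
    per_replicate: np.ndarray  # (n_rep, n_lags), NaN = undefined
    pooled: np.ndarray  # (n_lags,)
    n_contributing: np.ndarray  # replicates contributing per lag
    replicate_ids: list = field(default_factory=list)
    statistic: str = ""


def standardize(env: EnvelopeResult) -> np.ndarray:
    """Map one envelope's empirical curve so its null band becomes [-1, 1].

    Returns the standardised curve with NaN at lags where the band is
    degenerate (upper == lower) or the statistic undefined.  Strictly
    monotone in the empirical value at every defined lag.
    """
    width = env.upper - env.lower
    with np.errstate(invalid="ignore", divide="ignore"):
        b = 2.0 / width
        a = 1.0 - b * env.upper
        out = a + b * env.empirical
    out = np.where(width > 0, out, np.nan)
    return np.where(np.isnan(env.empirical), np.nan, out)


def pooled_null(envs: list[EnvelopeResult]) -> EnvelopeResult:
    """Null ensemble for the pooled standardised curve.

    Each plot's simulated curves are standardised by that plot's own band and
    averaged across plots simulation-by-simulation (plots are independent, so
    the pairing of simulation indices is arbitrary).  The result is an
    :class:`EnvelopeResult` whose empirical curve is the pooled standardised
    empirical and whose simulations are pooled standardised nulls — the basis
    for a rank quasi-p of the replicated analysis.  With a single plot this
    reduces to a monotone per-lag transform of the original envelope, leaving
    every rank (hence the quasi-p) unchanged.
    """
    from .null_models import _rank_bounds

    if len(envs) == 0:
        raise ValueError("at least one envelope is required")
    n_sim = envs[0].sims.shape[0]
    if any(e.sims.shape[0] != n_sim for e in envs):
        raise ValueError("all replicate envelopes must use the same number of simulations")
    std_sims = []
    for env in envs:
        width = env.upper - env.lower
        with np.errstate(invalid="ignore", divide="ignore"):
            b = 2.0 / width
            a = 1.0 - b * env.upper
            s = a + b * env.sims
        std_sims.append(np.where(width > 0, s, np.nan))
    stack = np.stack(std_sims)  # (n_env, n_sim, n_lag)
    defined = ~np.isnan(stack)
    n_def = defined.sum(axis=0)
    pooled_sims = np.where(
        n_def > 0,
        np.where(defined, stack, 0.0).sum(axis=0) / np.where(n_def > 0, n_def, 1),
        np.nan,
    )
    pooled_emp = pool(envs).pooled
    lower, upper = _rank_bounds(pooled_sims, envs[0].alpha)
    return EnvelopeResult(
        grid=envs[0].grid,
        empirical=pooled_emp,
        lower=lower,
        upper=upper,
        sims=pooled_sims,
        statistic=envs[0].statistic,
        alpha=envs[0].alpha,
        meta={"n_replicates": len(envs)},
    )


def pool(
    replicates: list[np.ndarray] | list[EnvelopeResult],
    grid: DistanceGrid | None = None,
    replicate_ids: list | None = None,
    statistic: str = "",
) -> StandardizedCurve:
    """Per-lag mean of standardised replicate curves.

    Accepts either already-standardised arrays or EnvelopeResults (which are
    standardised first).  Permutation-invariant in replicate order; lags with
    no defined replicate are NaN in the pooled curve.
    """
    if len(replicates) == 0:
        raise ValueError("at least one replicate is required")
    curves = []
    for r in replicates:
        if isinstance(r, EnvelopeResult):
            if grid is None:
                grid = r.grid
            elif len(grid.lags) != len(r.grid.lags) or not np.allclose(grid.lags, r.grid.lags):
                raise ValueError("replicates must share one distance grid")
            curves.append(standardize(r))
        else:
            curves.append(np.asarray(r, dtype=float))
    if grid is None:
        raise ValueError("a DistanceGrid is required when pooling raw arrays")
    mat = np.vstack(curves)
    if mat.shape[1] != len(grid.lags):
        raise ValueError("replicate curves do not match the grid length")
    defined = ~np.isnan(mat)
    n_contrib = defined.sum(axis=0)
    with np.errstate(invalid="ignore"):
        pooled = np.where(n_contrib > 0, np.nansum(np.where(defined, mat, 0.0), axis=0), np.nan)
        pooled = pooled / np.where(n_contrib > 0, n_contrib, 1)
    return StandardizedCurve(
        grid=grid,
        per_replicate=mat,
        pooled=pooled,
        n_contributing=n_contrib,
        replicate_ids=replicate_ids or list(range(mat.shape[0])),
        statistic=statistic,
    )
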