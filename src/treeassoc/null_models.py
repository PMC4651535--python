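"""Monte Carlo null models, simulation envelopes and quasi p-values.

Independence between two species' stem patterns is tested with the toroidal
shift: one pattern is rigidly translated by a uniform random vector with the
plot treated as a torus, which preserves each marginal pattern's internal
second-order structure while destroying any cross-structure.  Independence
of the DBH marks from the cross arrangement is tested with random marking:
stem positions stay fixed and marks are permuted within each species.

An envelope is the pointwise rank-based quantile band of the statistic over
``n_sim`` null simulations (with 399 simulations and alpha = 0.05, the
10th-lowest and 10th-highest simulated values per lag).  The quasi p-value
at a lag is the Monte Carlo rank p: (1 + number of simulations as or more
extreme than the empirical value, on the empirical deviation's side) /
(n_sim + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .spatial_stats import (
    DistanceGrid,
    MarkedPattern,
    PairGeometry,
    _standardised_marks,
)

__all__ = [
    "EnvelopeResult",
    "toroidal_shift",
    "random_marking",
    "envelope",
    "quasi_p",
    "pair_seed",
]


@dataclass
class EnvelopeResult:
    """Empirical curve plus per-lag null quantile bounds for one species pair."""

    grid: DistanceGrid
    empirical: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    sims: np.ndarray  # (n_sim, n_lags); NaN where a simulated curve is undefined
    statistic: str
    alpha: float
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_sim(self) -> int:
        return self.sims.shape[0]


def toroidal_shift(pattern: MarkedPattern, shift: tuple[float, float]) -> MarkedPattern:
    """Rigidly translate a pattern on the torus defined by its window.

    Every stem moves by the same vector; coordinates wrap at the plot edges
    and marks travel with their stems.
    """
    dx, dy = shift
    pts = pattern.points.copy()
    pts[:, 0] = np.mod(pts[:, 0] + dx, pattern.window.width)
    pts[:, 1] = np.mod(pts[:, 1] + dy, pattern.window.height)
    return replace(pattern, points=pts)


def random_marking(
    a: MarkedPattern, b: MarkedPattern, rng: np.random.Generator
) -> tuple[MarkedPattern, MarkedPattern]:
    """Permute marks uniformly at random within each species; positions fixed."""
    return (
        replace(a, marks=rng.permutation(a.marks)),
        replace(b, marks=rng.permutation(b.marks)),
    )


def _rank_bounds(sims: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise rank-based alpha/2 and 1-alpha/2 bounds, NaN-aware per lag."""
    n_sim, n_lag = sims.shape
    k = max(int(np.floor(alpha / 2 * (n_sim + 1))), 1)
    lower = np.full(n_lag, np.nan)
    upper = np.full(n_lag, np.nan)
    for j in range(n_lag):
        col = sims[:, j]
        col = col[~np.isnan(col)]
        if len(col) == 0:
            continue
        srt = np.sort(col)
        kk = min(k, len(srt))
        lower[j] = srt[kk - 1]
        upper[j] = srt[len(srt) - kk]
    return lower, upper


def pair_seed(seed: int, *key) -> np.random.SeedSequence:
    """Derive a deterministic per-pair substream from a run seed and a key.

    The key (species labels, plot id, statistic, ...) is hashed into
    SeedSequence entropy so any single pair can be re-run in isolation
    bit-identically, independent of scheduling order.
    """
    import zlib

    tag = zlib.crc32("|".join(str(k) for k in key).encode())
    return np.random.SeedSequence(entropy=[int(seed), tag])


def envelope(
    a: MarkedPattern,
    b: MarkedPattern,
    statistic: str = "lrs",
    n_sim: int = 399,
    alpha: float = 0.05,
    seed: int | np.random.SeedSequence | None = None,
    grid: DistanceGrid | None = None,
    corr: str = "ripley_isotropic",
) -> EnvelopeResult:
    """Simulation envelope for one species pair.

    The null model is the toroidal shift for ``statistic='lrs'`` (the pattern
    with fewer stems is shifted) and random marking for ``statistic='kmm'``.
    Bounds are the pointwise rank quantiles of the simulated curves;
    simulated curves undefined at a lag are excluded from that lag's bounds.
    Deterministic under a fixed seed.
    """
    if n_sim < 19:
        raise ValueError("n_sim must be at least 19")
    if statistic not in ("lrs", "kmm"):
        raise ValueError(f"unknown statistic {statistic!r}")
    grid = grid or DistanceGrid()
    rng = np.random.default_rng(seed)

    sims = np.empty((n_sim, len(grid.lags)))
    shift_b = b.n <= a.n  # shift the sparser pattern
    if statistic == "lrs":
        emp = PairGeometry(a, b, grid, corr).lrs_values()
        for i in range(n_sim):
            shift = (
                rng.uniform(0, a.window.width),
                rng.uniform(0, a.window.height),
            )
            aa, bb = (a, toroidal_shift(b, shift)) if shift_b else (toroidal_shift(a, shift), b)
            sims[i] = PairGeometry(aa, bb, grid, corr).lrs_values()
    else:
        # positions are fixed under random marking: reuse the pair geometry
        # and permute the standardised marks (permutation commutes with
        # per-species standardisation)
        geom = PairGeometry(a, b, grid, corr)
        z_a, z_b = _standardised_marks(a), _standardised_marks(b)
        emp = geom.kmm_values(z_a, z_b)
        for i in range(n_sim):
            sims[i] = geom.kmm_values(rng.permutation(z_a), rng.permutation(z_b))
    lower, upper = _rank_bounds(sims, alpha)
    return EnvelopeResult(
        grid=grid,
        empirical=emp,
        lower=lower,
        upper=upper,
        sims=sims,
        statistic=statistic,
        alpha=alpha,
        seed=None if isinstance(seed, np.random.SeedSequence) else seed,
        meta={
            "n_sim": n_sim,
            "edge_mode": corr,
            "shifted": (b.label if shift_b else a.label) if statistic == "lrs" else None,
            "pair": (a.label, b.label),
        },
    )


def quasi_p(env: EnvelopeResult, at: float) -> float:
    """Monte Carlo rank p-value of the empirical statistic at one grid lag.

    One-sided on the side of the empirical deviation from the null median:
    p = (1 + #{sims as or more extreme}) / (n_sim + 1).  Bounded below by
    1/(n_sim + 1).
    """
    j = env.grid.index_of(at)
    emp = env.empirical[j]
    col = env.sims[:, j]
    col = col[~np.isnan(col)]
    if np.isnan(emp) or len(col) == 0:
        raise ValueError(f"statistic undefined at lag {at}")
    med = np.median(col)
    if emp >= med:
        extreme = int(np.sum(col >= emp))
    else:
        extreme = int(np.sum(col <= emp))
    return (1 + extreme) / (len(col) + 1)
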