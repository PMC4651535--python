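"""Intertype second-order estimators on marked point patterns.

Two statistics drive the pairwise analysis of a stem map:

* the intertype L function ``lrs_hat`` — a bivariate Ripley-type summary of
  how often stems of two species occur within distance *d* of each other,
  relative to the product of their intensities.  For two independent
  homogeneous patterns its expectation is ``d**2 / (n_r + n_s)``;
* the intertype mark-correlation function ``kmm_hat`` — the mean product of
  per-species standardised DBH marks over inter-species stem pairs within
  *d*.  Positive values mean similarly sized (similar-stage) individuals of
  the two species co-occur; negative values mean large stems of one species
  sit near small stems of the other.

Both support Ripley's isotropic boundary correction for a rectangular
window: each pair's indicator is divided by the fraction of the circle
centred on the focal stem, with radius the pair distance, that lies inside
the window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .io_census import Window

__all__ = [
    "MarkedPattern",
    "DistanceGrid",
    "CurveResult",
    "EDGE_MODES",
    "PairGeometry",
    "circle_in_rectangle_fraction",
    "cross_pair_weights",
    "lrs_hat",
    "kmm_hat",
]

EDGE_MODES = ("none", "ripley_isotropic")


@dataclass(frozen=True)
class MarkedPattern:
    """One species' mapped stems with DBH marks inside a rectangular window."""

    points: np.ndarray  # (n, 2) metres
    marks: np.ndarray  # (n,) DBH, centimetres
    window: Window
    label: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        mks = np.asarray(self.marks, dtype=float).ravel()
        if len(pts) != len(mks):
            raise ValueError(f"{self.label or 'pattern'}: {len(pts)} points but {len(mks)} marks")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "marks", mks)

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def intensity(self) -> float:
        """Stems per square metre, lambda = n / A."""
        return self.n / self.window.area


@dataclass(frozen=True)
class DistanceGrid:
    """Ordered distance lags (metres); defaults to 0.5 m steps up to 50 m."""

    lags: np.ndarray = field(default_factory=lambda: 0.5 * np.arange(1, 101))

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float).ravel()
        if len(lags) == 0 or np.any(lags <= 0) or np.any(np.diff(lags) <= 0):
            raise ValueError("lags must be strictly increasing and positive")
        object.__setattr__(self, "lags", lags)

    @property
    def max_d(self) -> float:
        return float(self.lags[-1])

    def index_of(self, d: float) -> int:
        idx = np.searchsorted(self.lags, d)
        if idx >= len(self.lags) or not np.isclose(self.lags[idx], d):
            raise ValueError(f"distance {d} is not a grid lag")
        return int(idx)


@dataclass
class CurveResult:
    """One statistic evaluated on a distance grid.

    ``values`` holds NaN at lags where the statistic is undefined (mark
    correlation with no inter-type pair within the lag).
    """

    grid: DistanceGrid
    values: np.ndarray
    statistic: str  # "lrs" | "kmm"
    edge_mode: str = "ripley_isotropic"
    meta: dict = field(default_factory=dict)


def circle_in_rectangle_fraction(centers: np.ndarray, radii: np.ndarray, window: Window) -> np.ndarray:
    """Fraction of each circle's perimeter inside the window.

    Closed form by inclusion–exclusion: subtract the arc outside each edge
    half-plane (2·arccos(d_edge/r)), add back the arc beyond each corner
    (arccos(dx/r) + arccos(dy/r) − π/2 where positive).  Valid while the
    circle cannot reach two opposite edges at once, i.e. r ≤ min(width,
    height); the pairwise analysis caps distances at half the short side.
    """
    centers = np.asarray(centers, dtype=float)
    r = np.asarray(radii, dtype=float)
    x, y = centers[..., 0], centers[..., 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.zeros(np.broadcast_shapes(x.shape, r.shape), dtype=float)
        dists_x = (x, window.width - x)
        dists_y = (y, window.height - y)
        for d in (*dists_x, *dists_y):
            out += 2.0 * np.arccos(np.clip(np.minimum(d / np.where(r > 0, r, np.inf), 1.0), -1.0, 1.0))
        for dx in dists_x:
            for dy in dists_y:
                corner = (
                    np.arccos(np.clip(np.minimum(dx / np.where(r > 0, r, np.inf), 1.0), -1.0, 1.0))
                    + np.arccos(np.clip(np.minimum(dy / np.where(r > 0, r, np.inf), 1.0), -1.0, 1.0))
                    - 0.5 * np.pi
                )
                out -= np.maximum(corner, 0.0)
    return 1.0 - out / (2.0 * np.pi)


def _pair_weights(focal: MarkedPattern, other: MarkedPattern, corr: str) -> tuple[np.ndarray, np.ndarray]:
    """Distances and per-pair weights with the focal species' stems as circle centres."""
    d = cdist(focal.points, other.points)
    if corr == "none":
        w = np.ones_like(d)
    elif corr == "ripley_isotropic":
        frac = circle_in_rectangle_fraction(focal.points[:, None, :], d, focal.window)
        w = 1.0 / np.maximum(frac, 1e-12)
    else:
        raise ValueError(f"unknown edge mode {corr!r}; expected one of {EDGE_MODES}")
    return d, w


def _check_pair(a: MarkedPattern, b: MarkedPattern) -> None:
    if a.window != b.window:
        raise ValueError("patterns must share one observation window")
    for p in (a, b):
        if p.n == 0:
            raise ValueError(f"empty pattern for species {p.label!r}")


class PairGeometry:
    """Precomputed inter-type distances, edge weights and lag bins for one pair.

    Random-marking simulations leave stem positions fixed, so the geometry
    (distances, edge weights, sort order) can be computed once and reused
    across simulated mark assignments.
    """

    def __init__(self, a: MarkedPattern, b: MarkedPattern, grid: DistanceGrid, corr: str):
        _check_pair(a, b)
        self.a, self.b, self.grid, self.corr = a, b, grid, corr
        d_ab, w_ab = _pair_weights(a, b, corr)
        _, w_ba = _pair_weights(b, a, corr)
        flat = d_ab.ravel()
        self.order = np.argsort(flat, kind="stable")
        self.idx = np.searchsorted(flat[self.order], grid.lags, side="right")
        # both directions share the indicator (d_ba = d_ab.T); combine weights
        self.w_both = (w_ab + w_ba.T).ravel()[self.order]
        self.w_lrs = (w_ab / a.n + w_ba.T / b.n).ravel()[self.order]
        self.den = np.concatenate(([0.0], np.cumsum(self.w_both)))[self.idx]

    def lrs_values(self) -> np.ndarray:
        s = np.concatenate(([0.0], np.cumsum(self.w_lrs)))[self.idx]
        norm = (self.a.intensity + self.b.intensity) * (self.a.n + self.b.n) * np.pi
        return s / norm

    def kmm_values(self, z_a: np.ndarray, z_b: np.ndarray) -> np.ndarray:
        prod = np.outer(z_a, z_b).ravel()[self.order]
        num = np.concatenate(([0.0], np.cumsum(self.w_both * prod)))[self.idx]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.den > 0, num / np.where(self.den > 0, self.den, 1.0), np.nan)


def cross_pair_weights(a: MarkedPattern, b: MarkedPattern, d: float, corr: str = "ripley_isotropic"):
    """Directional edge-corrected pair-weight sums at a single distance.

    Returns ``(sum_ab, sum_ba)``: the sum over ordered inter-type pairs
    within ``d`` of the edge weight, first with species *a* stems focal,
    then with species *b* stems focal.  With ``corr='none'`` these are plain
    pair counts and the two directions coincide.
    """
    _check_pair(a, b)
    if d <= 0:
        raise ValueError("d must be positive")
    dd, w_ab = _pair_weights(a, b, corr)
    _, w_ba = _pair_weights(b, a, corr)
    inside = dd <= d
    return float(w_ab[inside].sum()), float(w_ba.T[inside].sum())


def lrs_hat(
    a: MarkedPattern,
    b: MarkedPattern,
    grid: DistanceGrid | None = None,
    corr: str = "ripley_isotropic",
) -> CurveResult:
    """Intertype L function of two species' stem patterns.

    L(d) = [S_ab(d)/n_r + S_ba(d)/n_s] / [(lambda_r + lambda_s)(n_r + n_s) pi]

    where S_ab is the edge-weighted count of inter-type pairs within d with
    species-a stems focal, and S_ba the reverse direction.  Symmetric in its
    two arguments; with ``corr='none'`` it is non-decreasing in d.
    """
    grid = grid or DistanceGrid()
    values = PairGeometry(a, b, grid, corr).lrs_values()
    return CurveResult(grid, values, "lrs", corr, meta={"n_r": a.n, "n_s": b.n})


def _standardised_marks(p: MarkedPattern) -> np.ndarray:
    s = p.marks.std(ddof=1) if p.n > 1 else 0.0
    if not s > 0:
        raise ValueError(f"marks constant for species {p.label!r}")
    return (p.marks - p.marks.mean()) / s


def kmm_hat(
    a: MarkedPattern,
    b: MarkedPattern,
    grid: DistanceGrid | None = None,
    corr: str = "ripley_isotropic",
) -> CurveResult:
    """Intertype mark-correlation function.

    Edge-weighted average, over ordered inter-type pairs within each lag, of
    the product of per-species standardised marks (sample SD, ddof=1).  Lags
    with no inter-type pair are NaN (undefined), not zero.  Invariant under
    positive affine transforms of either species' marks.
    """
    grid = grid or DistanceGrid()
    geom = PairGeometry(a, b, grid, corr)
    values = geom.kmm_values(_standardised_marks(a), _standardised_marks(b))
    return CurveResult(grid, values, "kmm", corr, meta={"n_r": a.n, "n_s": b.n})
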