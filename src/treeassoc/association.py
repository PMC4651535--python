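"""From standardised curves to association records, matrices and guild tables.

An association for a species pair is a maximal run of distance lags where
the (pooled) standardised curve exits the [-1, 1] null band on one side.
Each pair contributes at most one record per statistic, anchored at a single
representative distance: the lag with the greatest exceedance beyond the
band (the standardised scale already normalises by band width), ties broken
toward the smallest distance.

Records are summarised the way field studies report them: a species-by-
species matrix with the plain spatial statistic in one triangle and the
mark-correlation statistic in the other (entries are signed representative
distances), cross-tabulations of associated pairs by shared versus different
guild traits, and concordance counts against an externally supplied
species-habitat table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import groupby

import numpy as np
import pandas as pd

from .io_census import TraitTable
from .replication import StandardizedCurve
from .spatial_stats import DistanceGrid

__all__ = [
    "AssociationRecord",
    "AssociationMatrix",
    "GuildCrossTab",
    "significant_intervals",
    "representative_distance",
    "build_matrix",
    "guild_crosstab",
    "habitat_concordance",
]

GUILD_TRAITS = ("life_form", "shade_tolerance", "dispersal")


@dataclass(frozen=True)
class AssociationRecord:
    """One detected pairwise association.

    ``sign`` is '+' when the curve exits above the upper bound and '-' below
    the lower.  For the plain spatial statistic that reads as attraction /
    repulsion of stems; for the mark correlation it reads as similar-stage
    versus opposite-stage attraction.
    """

    species_a: str
    species_b: str
    statistic: str  # "lrs" | "kmm"
    sign: str  # "+" | "-"
    d_min: float
    d_max: float
    representative_d: float
    quasi_p: float

    def __post_init__(self) -> None:
        if not (self.d_min <= self.representative_d <= self.d_max):
            raise ValueError("representative distance must lie inside the interval")
        if self.sign not in "+-":
            raise ValueError(f"sign must be '+' or '-', got {self.sign!r}")


def _curve_and_mask(curve, rule: str) -> tuple[np.ndarray, DistanceGrid]:
    if isinstance(curve, StandardizedCurve):
        vals = curve.pooled.copy()
        if rule == "strict" and curve.per_replicate.shape[0] > 1:
            # every usable replicate must exit the band on the pooled side
            rep = curve.per_replicate
            defined = ~np.isnan(rep)
            above = np.where(defined, rep > 1, True).all(axis=0) & (defined.any(axis=0))
            below = np.where(defined, rep < -1, True).all(axis=0) & (defined.any(axis=0))
            coincident = np.where(vals > 1, above, np.where(vals < -1, below, False))
            with np.errstate(invalid="ignore"):
                non_coincident_exit = ((vals > 1) | (vals < -1)) & ~coincident
            vals = np.where(non_coincident_exit, np.clip(vals, -1.0, 1.0), vals)
        return vals, curve.grid
    raise TypeError("expected a StandardizedCurve; pass arrays through pool() first")


def significant_intervals(
    curve: StandardizedCurve,
    max_d: float | None = None,
    rule: str = "pooled",
) -> list[tuple[float, float, str]]:
    """Maximal signed runs of lags where the curve exits the [-1, 1] band.

    ``rule='pooled'`` uses the pooled curve alone; ``rule='strict'`` demands
    in addition that every usable replicate deviates on the same side at the
    lag (the coincidence requirement for replicated designs).  Returns
    ``(d_min, d_max, sign)`` triples; empty list when the curve stays inside.
    """
    if rule not in ("pooled", "strict"):
        raise ValueError(f"unknown rule {rule!r}")
    vals, grid = _curve_and_mask(curve, rule)
    lags = grid.lags
    if max_d is not None:
        keep = lags <= max_d
        vals, lags = vals[keep], lags[keep]
    state = np.where(np.isnan(vals), 0, np.where(vals > 1, 1, np.where(vals < -1, -1, 0)))
    out = []
    for s, run in groupby(range(len(state)), key=lambda k: state[k]):
        idx = list(run)
        if s != 0:
            out.append((float(lags[idx[0]]), float(lags[idx[-1]]), "+" if s > 0 else "-"))
    return out


def representative_distance(
    curve: StandardizedCurve,
    intervals: list[tuple[float, float, str]],
    rule: str = "pooled",
) -> tuple[float, float]:
    """Single distance where the association is strongest.

    The representative distance is the in-interval lag maximising the
    exceedance |standardised value| - 1 beyond the band; the standardised
    scale already weighs the raw deviation by the local width of the null
    acceptance band.  Ties break toward the smallest distance.  Returns
    ``(d_star, exceedance)``.
    """
    if not intervals:
        raise ValueError("no significant intervals to choose from")
    vals, grid = _curve_and_mask(curve, rule)
    best = None
    for d_min, d_max, _sign in intervals:
        sel = (grid.lags >= d_min) & (grid.lags <= d_max)
        for lag, v in zip(grid.lags[sel], vals[sel]):
            if np.isnan(v):
                continue
            exc = abs(v) - 1.0
            if exc <= 0:
                continue
            if best is None or exc > best[1] + 1e-12:
                best = (float(lag), float(exc))
    if best is None:
        raise ValueError("intervals contain no lag outside the band")
    return best


@dataclass
class AssociationMatrix:
    """Species-by-species table: lrs records in the lower triangle, kmm in the upper.

    Entries are signed representative distances (metres); ``counts`` gives
    per-species association counts for each statistic.
    """

    species: list[str]
    table: pd.DataFrame
    counts: pd.DataFrame

    def entry(self, a: str, b: str, statistic: str) -> float:
        i, j = self.species.index(a), self.species.index(b)
        lo, hi = min(i, j), max(i, j)
        r, c = (hi, lo) if statistic == "lrs" else (lo, hi)
        return self.table.iat[r, c]


def build_matrix(records: list[AssociationRecord], species: list[str]) -> AssociationMatrix:
    """Assemble the signed-distance association matrix from one run's records."""
    n = len(species)
    idx = {sp: i for i, sp in enumerate(species)}
    table = pd.DataFrame(np.full((n, n), np.nan), index=species, columns=species)
    seen = set()
    for rec in records:
        if rec.species_a not in idx or rec.species_b not in idx:
            raise ValueError(f"record references unknown species {rec.species_a}/{rec.species_b}")
        key = (frozenset((rec.species_a, rec.species_b)), rec.statistic)
        if key in seen:
            raise ValueError(
                f"duplicate record for pair {rec.species_a}-{rec.species_b} ({rec.statistic})"
            )
        seen.add(key)
        i, j = idx[rec.species_a], idx[rec.species_b]
        lo, hi = min(i, j), max(i, j)
        r, c = (hi, lo) if rec.statistic == "lrs" else (lo, hi)
        table.iat[r, c] = rec.representative_d * (1 if rec.sign == "+" else -1)
    counts = pd.DataFrame(0, index=species, columns=["lrs", "kmm"])
    for rec in records:
        counts.loc[rec.species_a, rec.statistic] += 1
        counts.loc[rec.species_b, rec.statistic] += 1
    return AssociationMatrix(species=list(species), table=table, counts=counts)


@dataclass
class GuildCrossTab:
    """Associated-pair counts by trait x same/different x sign.

    ``counts`` is indexed by (trait, 'same'|'different', '+'|'-');
    ``excluded`` lists, per trait, the pairs dropped because a species lacks
    that trait value.
    """

    counts: pd.Series
    excluded: dict[str, list[tuple[str, str]]] = field(default_factory=dict)


def guild_crosstab(records: list[AssociationRecord], traits: TraitTable) -> GuildCrossTab:
    """Cross-tabulate associated pairs by shared versus different guild traits."""
    index = pd.MultiIndex.from_product(
        [GUILD_TRAITS, ["same", "different"], ["+", "-"]],
        names=["trait", "match", "sign"],
    )
    counts = pd.Series(0, index=index)
    excluded: dict[str, list[tuple[str, str]]] = {t: [] for t in GUILD_TRAITS}
    for rec in records:
        for trait in GUILD_TRAITS:
            va = traits.get(rec.species_a, trait)
            vb = traits.get(rec.species_b, trait)
            if va is None or vb is None:
                excluded[trait].append((rec.species_a, rec.species_b))
                continue
            match = "same" if va == vb else "different"
            counts.loc[(trait, match, rec.sign)] += 1
    return GuildCrossTab(counts=counts, excluded=excluded)


def habitat_concordance(
    records: list[AssociationRecord], habitat_table: pd.DataFrame
) -> tuple[int, float, list[AssociationRecord]]:
    """Count records concordant with an external species-habitat table.

    ``habitat_table`` has columns (species, habitat, relation) with relation
    'associated' or 'avoided'; a species may have several rows.  A positive
    record is concordant when both species are associated with a common
    habitat; a negative record when one species is associated with and the
    other avoids the same habitat.  Species absent from the table count as
    having no habitat relation.  Returns (count, fraction of all records,
    concordant records).
    """
    for col in ("species", "habitat", "relation"):
        if col not in habitat_table.columns:
            raise ValueError(f"habitat table missing column {col!r}")
    assoc: dict[str, set[str]] = {}
    avoid: dict[str, set[str]] = {}
    for _, row in habitat_table.iterrows():
        target = assoc if str(row["relation"]).lower().startswith("assoc") else avoid
        target.setdefault(str(row["species"]), set()).add(str(row["habitat"]))
    concordant = []
    for rec in records:
        a_assoc = assoc.get(rec.species_a, set())
        b_assoc = assoc.get(rec.species_b, set())
        a_avoid = avoid.get(rec.species_a, set())
        b_avoid = avoid.get(rec.species_b, set())
        if rec.sign == "+":
            hit = bool(a_assoc & b_assoc)
        else:
            hit = bool(a_assoc & b_avoid) or bool(b_assoc & a_avoid)
        if hit:
            concordant.append(rec)
    frac = len(concordant) / len(records) if records else 0.0
    return len(concordant), frac, concordant
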