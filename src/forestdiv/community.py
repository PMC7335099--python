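"""Functional and taxonomic diversity of plot censuses.

Communities are weighted by relative basal area: each stem contributes
pi*(dbh/200)**2 m^2 and a species' weight is its share of the plot total.
Functional dispersion (FDis) is the abundance-weighted mean distance of
species to the community's weighted centroid in trait space; with mixed
numeric/categorical traits the space is a principal-coordinates embedding
of Gower dissimilarities.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PlotCensus",
    "CommunityAbundance",
    "TraitTable",
    "EmptyCommunityError",
    "basal_area_weights",
    "stem_basal_area",
    "simpson_index",
    "hill_simpson",
    "gower_distance",
    "pcoa_embedding",
    "fdis",
    "rao_q",
    "trait_coverage",
]

MIN_DBH_CM = 10.0


class EmptyCommunityError(ValueError):
    """Raised when a metric is requested for a community with no stems."""


@dataclass
class PlotCensus:
    """Stem records of one plot at one census.

    Parameters
    ----------
    plot_id : str
    census_date : float
        Decimal year of the census.
    plot_area : float
        Plot area in hectares (> 0).
    stems : list of (species, dbh_cm)
        Every stem has diameter at breast height >= 10 cm.
    """

    plot_id: str
    census_date: float
    plot_area: float
    stems: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.plot_area <= 0:
            raise ValueError(f"plot_area must be > 0, got {self.plot_area}")
        for sp, dbh in self.stems:
            if not sp:
                raise ValueError("empty species identifier in census")
            if dbh < MIN_DBH_CM:
                raise ValueError(
                    f"stem of {sp} has dbh {dbh} cm < minimum {MIN_DBH_CM} cm"
                )


@dataclass
class CommunityAbundance:
    """Relative basal-area weights of one plot census.

    ``weights`` maps species to its share of total basal area (sums to 1);
    ``total_ba`` is the plot total in m^2.
    """

    plot_id: str
    census_date: float
    weights: dict[str, float]
    total_ba: float

    @property
    def species(self) -> list[str]:
        return list(self.weights)

    def weight_array(self, order: list[str] | None = None) -> np.ndarray:
        order = self.species if order is None else order
        return np.array([self.weights[s] for s in order], dtype=float)


class TraitTable:
    """Species x trait matrix with per-trait numeric/categorical kinds.

    Parameters
    ----------
    data : pandas.DataFrame
        Indexed by species; one column per trait. NaN marks missing values.
    kinds : dict
        Maps trait name to ``"numeric"`` or ``"categorical"``.
    """

    def __init__(self, data: pd.DataFrame, kinds: dict[str, str]):
        unknown = set(kinds) - set(data.columns)
        if unknown:
            raise ValueError(f"kinds refer to unknown traits: {sorted(unknown)}")
        missing = set(data.columns) - set(kinds)
        if missing:
            raise ValueError(f"traits without declared kind: {sorted(missing)}")
        for t, k in kinds.items():
            if k not in ("numeric", "categorical"):
                raise ValueError(f"unknown trait kind {k!r} for {t!r}")
        self.data = data
        self.kinds = dict(kinds)

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def traits(self) -> list[str]:
        return list(self.data.columns)

    def subset(self, species: list[str]) -> pd.DataFrame:
        absent = [s for s in species if s not in self.data.index]
        if absent:
            raise KeyError(f"species missing from trait table: {absent}")
        return self.data.loc[species]

    def to_csv(self, path) -> None:
        out = self.data.copy()
        # header row after the species column declares the kind of each trait
        kinds_row = pd.DataFrame(
            [[self.kinds[t] for t in out.columns]], columns=out.columns, index=["#kind"]
        )
        pd.concat([kinds_row, out]).to_csv(path, index_label="species")

    @classmethod
    def from_csv(cls, path) -> "TraitTable":
        raw = pd.read_csv(path, index_col="species")
        kinds = {t: raw.loc["#kind", t] for t in raw.columns}
        data = raw.drop(index="#kind")
        for t, k in kinds.items():
            if k == "numeric":
                data[t] = pd.to_numeric(data[t])
        return cls(data, kinds)


def stem_basal_area(dbh_cm: float | np.ndarray) -> float | np.ndarray:
    """Basal area in m^2 of a stem of the given diameter (cm)."""
    return np.pi * (np.asarray(dbh_cm, dtype=float) / 200.0) ** 2


def basal_area_weights(census: PlotCensus) -> CommunityAbundance:
    """Relative basal-area abundance of each species in a census."""
    if not census.stems:
        raise EmptyCommunityError(f"census of plot {census.plot_id} has no stems")
    ba: dict[str, float] = {}
    for sp, dbh in census.stems:
        ba[sp] = ba.get(sp, 0.0) + float(stem_basal_area(dbh))
    total = math.fsum(ba.values())
    weights = {sp: v / total for sp, v in ba.items()}
    return CommunityAbundance(census.plot_id, census.census_date, weights, total)


def _check_proportions(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("proportions must be non-negative")
    s = p.sum()
    if s <= 0:
        raise ValueError("proportions sum to zero")
    return p / s


def simpson_index(proportions) -> float:
    """Simpson diversity 1 - sum(p_i^2); accepts proportions or counts."""
    p = _check_proportions(proportions)
    return float(1.0 - np.sum(p**2))


def hill_simpson(proportions) -> float:
    """Inverse Simpson concentration: the effective number of species at q=2."""
    p = _check_proportions(proportions)
    return float(1.0 / np.sum(p**2))


def gower_distance(
    traits: TraitTable, species: list[str] | None = None
) -> pd.DataFrame:
    """Pairwise Gower dissimilarity between species on mixed traits.

    Numeric traits are range-normalized within the requested subset and
    contribute |x_i - x_j| / range; categorical traits contribute a 0/1
    mismatch. Pairwise-missing traits are excluded with renormalization.
    Zero-range numeric traits are skipped with a warning.
    """
    species = traits.species if species is None else list(species)
    if len(species) < 2:
        raise ValueError("Gower distance needs at least 2 species")
    sub = traits.subset(species)
    n = len(species)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for t in traits.traits:
        col = sub[t]
        if traits.kinds[t] == "numeric":
            x = col.to_numpy(dtype=float)
            ok = np.isfinite(x)
            if ok.sum() < 2:
                continue
            rng = np.nanmax(x[ok]) - np.nanmin(x[ok])
            if rng == 0:
                logger.warning("trait %r has zero range in subset; skipped", t)
                continue
            d = np.abs(x[:, None] - x[None, :]) / rng
            valid = ok[:, None] & ok[None, :]
        else:
            vals = col.to_numpy(dtype=object)
            ok = np.array([v is not None and v == v for v in vals])
            d = (vals[:, None] != vals[None, :]).astype(float)
            valid = ok[:, None] & ok[None, :]
        num += np.where(valid, d, 0.0)
        den += valid.astype(float)
    with np.errstate(invalid="ignore"):
        dist = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=species, columns=species)


def pcoa_embedding(dist: np.ndarray, sqrt_correction: bool = True) -> np.ndarray:
    """Principal-coordinates embedding of a dissimilarity matrix.

    With ``sqrt_correction`` the square root of the dissimilarities is
    embedded, which renders Gower dissimilarities Euclidean in practice and
    avoids sizeable negative eigenvalues. Axes with eigenvalues <= 0 (up to
    numerical jitter) are dropped.
    """
    d = np.sqrt(dist) if sqrt_correction else np.asarray(dist, dtype=float)
    n = d.shape[0]
    a = -0.5 * d**2
    centered = a - a.mean(0) - a.mean(1)[:, None] + a.mean()
    vals, vecs = np.linalg.eigh(centered)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(1e-12, 1e-10 * max(vals.max(), 1.0))
    keep = vals > tol
    if not keep.any():
        return np.zeros((n, 1))
    return vecs[:, keep] * np.sqrt(vals[keep])


def _standardized_numeric_matrix(sub: pd.DataFrame, numeric: list[str]) -> np.ndarray:
    cols = []
    for t in numeric:
        x = sub[t].to_numpy(dtype=float)
        sd = np.std(x, ddof=1)
        if sd == 0 or not np.isfinite(sd):
            logger.warning("trait %r constant in community; skipped", t)
            continue
        cols.append((x - x.mean()) / sd)
    if not cols:
        return np.zeros((len(sub), 1))
    return np.column_stack(cols)


def fdis(traits: TraitTable, community: CommunityAbundance) -> float:
    """Functional dispersion of a community.

    The abundance-weighted mean distance of species to the weighted centroid:
    ``FDis = sum(a_j z_j) / sum(a_j)`` with ``z_j = ||x_j - c||`` and
    ``c = sum(a_j x_j)``. Numeric-only trait sets use z-scored Euclidean
    space (sample sd); mixed trait sets use the PCoA embedding of Gower
    dissimilarities with the square-root correction.
    """
    sp = community.species
    if not sp:
        raise EmptyCommunityError("empty community")
    if len(sp) == 1:
        return 0.0
    traits.subset(sp)  # validates coverage
    # trait space is built over the whole table (the species pool) so that
    # FDis does not depend on which other species co-occur in the community
    pool = traits.species
    numeric = [t for t in traits.traits if traits.kinds[t] == "numeric"]
    if len(numeric) == len(traits.traits):
        all_coords = _standardized_numeric_matrix(traits.data, numeric)
    else:
        all_coords = pcoa_embedding(gower_distance(traits, pool).to_numpy())
    idx = [pool.index(s) for s in sp]
    coords = all_coords[idx]
    a = community.weight_array(sp)
    c = a @ coords
    z = np.linalg.norm(coords - c, axis=1)
    return float(np.sum(a * z) / np.sum(a))


def rao_q(dist: pd.DataFrame | np.ndarray, community: CommunityAbundance) -> float:
    """Rao's quadratic entropy: expected dissimilarity of two random draws."""
    sp = community.species
    if not sp:
        raise EmptyCommunityError("empty community")
    if len(sp) == 1:
        return 0.0
    if isinstance(dist, pd.DataFrame):
        d = dist.loc[sp, sp].to_numpy()
    else:
        d = np.asarray(dist, dtype=float)
    a = community.weight_array(sp)
    return float(a @ d @ a)


def trait_coverage(
    traits: TraitTable,
    community: CommunityAbundance,
    warn_threshold: float = 0.9,
) -> dict[str, float]:
    """Fraction of basal area held by species with data, per trait.

    Species absent from the trait table count as missing for every trait.
    Coverage below ``warn_threshold`` logs a warning; metrics are still
    computed downstream.
    """
    cov: dict[str, float] = {}
    present = set(traits.species)
    for t in traits.traits:
        have = 0.0
        for sp, w in community.weights.items():
            if sp in present:
                v = traits.data.at[sp, t]
                if v is not None and v == v:
                    have += w
        cov[t] = have
        if have < warn_threshold:
            logger.warning(
                "trait %r covers %.1f%% of basal area in plot %s (< %.0f%%)",
                t, 100 * have, community.plot_id, 100 * warn_threshold,
            )
    return cov
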