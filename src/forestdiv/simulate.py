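"""Synthetic study worlds with known ground truth.

Generates every input the analysis pipeline consumes: a pure-birth
ultrametric phylogeny, traits with configurable phylogenetic-signal regimes,
two-census stem tables for 21 plots spanning a wet-dry water-deficit
gradient, 50 years of monthly climate with a drying trend, and a soil table
with a three-factor latent structure. True per-plot diversity-change rates
are engineered by rank-preserving abundance reallocation and stored in a
:class:`GroundTruth` object that analysis stages never read.
"""

from __future__ import annotations

import hashlib
import json
import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import climate as clim
from .community import (
    CommunityAbundance,
    PlotCensus,
    TraitTable,
    basal_area_weights,
    gower_distance,
    pcoa_embedding,
    stem_basal_area,
)
from .phylo import Phylogeny

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "StudyData",
    "InfeasibleTargetError",
    "substream",
    "generate_phylogeny",
    "generate_traits",
    "generate_climate",
    "generate_community_pair",
    "generate_soils",
    "generate_study",
    "DEFAULT_TRAIT_REGIMES",
]

# per-trait phylogenetic-signal regime; categorical traits mirror the
# qualitative leaf-habit / guild / nitrogen-fixing descriptors
DEFAULT_TRAIT_REGIMES: dict[str, object] = {
    "wood_density": "BM",
    "sla": "BM",
    "leaf_area": "BM",
    "height_max": "BM",
    "leaf_n": "BM",
    "deciduousness": ("categorical", 2),
    "guild": ("categorical", 3),
    "n_fixing": ("categorical", 2),
}


class InfeasibleTargetError(ValueError):
    """A prescribed diversity-change target cannot be realized."""


def substream(seed: int, name: str) -> np.random.Generator:
    """Named deterministic substream of the top-level seed."""
    h = int.from_bytes(hashlib.sha256(name.encode()).digest()[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([seed, h]))


@dataclass
class SimulationConfig:
    """Study-design parameters of a synthetic world.

    Defaults emulate the study design: 21 one-hectare plots censused around
    1989 and again around 2011 (interval >= 10 yr), a baseline MCWD gradient
    from -320 to -150 mm straddling the -250 mm dry/wet split, per-plot
    drying of -27.5 mm (driest) to -7.5 mm (wettest) between the two 30-yr
    climatologies, and positive couplings from drying to the true annual
    diversity-change rates so drier plots decline.
    """

    n_plots: int = 21
    n_species_pool: int = 140
    n_species_per_plot: int = 80
    n_stems_per_plot: int = 500
    census_years: tuple[float, float] = (1989.5, 2011.5)
    census_jitter: float = 1.5
    mcwd_gradient: tuple[float, float] = (-320.0, -150.0)
    dmcwd_range: tuple[float, float] = (-27.5, -7.5)
    # true rate = intercept + slope * dMCWD_abs + N(0, noise); slopes > 0
    # make drier (more negative dMCWD) plots decline
    rate_intercept: dict[str, float] = field(default_factory=lambda: {
        "fdis": 3.0e-4, "simpson": 3.0e-4, "mpd": -5.0e-4,
    })
    drying_effect: dict[str, float] = field(default_factory=lambda: {
        "fdis": 2.0e-5, "simpson": 2.0e-5, "mpd": 1.0e-4,
    })
    rate_noise_sd: dict[str, float] = field(default_factory=lambda: {
        "fdis": 8.0e-5, "simpson": 8.0e-5, "mpd": 4.0e-4,
    })
    trait_bm_sigma2: float = 1.0
    climate_noise: float = 0.08
    climate_trend: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_plots < 2:
            raise ValueError("n_plots must be >= 2")
        if self.census_years[1] - self.census_years[0] < 10:
            raise ValueError("census interval must be >= 10 years")


@dataclass
class GroundTruth:
    """What the generator actually did; never consumed by analysis stages."""

    true_rates: pd.DataFrame        # plot x facet true annual rates
    coefficients: dict              # intercept/slope/noise per facet
    trait_regimes: dict             # trait -> regime label
    dmcwd_targets: dict             # plot -> targeted MCWD change (mm)
    mcwd_targets: dict              # plot -> targeted baseline MCWD (mm)

    def to_json(self, path) -> None:
        payload = {
            "true_rates": self.true_rates.to_dict(orient="index"),
            "coefficients": self.coefficients,
            "trait_regimes": {
                k: list(v) if isinstance(v, tuple) else v
                for k, v in self.trait_regimes.items()
            },
            "dmcwd_targets": self.dmcwd_targets,
            "mcwd_targets": self.mcwd_targets,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------

def generate_phylogeny(n_tips: int, seed: int = 0) -> Phylogeny:
    """Pure-birth (Yule) ultrametric tree rescaled to unit height.

    Only relative branch lengths matter for the diversity metrics, so the
    speciation rate is 1 and the tree height is normalized to 1.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    taxa = dendropy.TaxonNamespace(
        [f"sp{i + 1:04d}" for i in range(n_tips)]
    )
    py_rng = random.Random(seed)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        taxon_namespace=taxa,
        rng=py_rng,
    )
    tree.seed_node.edge.length = 0.0
    # the simulator stops at the n-th speciation, leaving two zero-length
    # pendant edges; run the clock one further exponential waiting time
    extra = py_rng.expovariate(float(n_tips))
    for lf in tree.leaf_node_iter():
        lf.edge.length = (lf.edge.length or 0.0) + extra
    # normalize to unit height and force exact ultrametry on pendant edges
    depths = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        depths[id(node)] = (
            0.0 if parent is None
            else depths[id(parent)] + (node.edge.length or 0.0)
        )
    height = max(depths[id(lf)] for lf in tree.leaf_node_iter())
    for node in tree.preorder_node_iter():
        if node.edge.length:
            node.edge.length = node.edge.length / height
    depths = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        depths[id(node)] = (
            0.0 if parent is None
            else depths[id(parent)] + (node.edge.length or 0.0)
        )
    for lf in tree.leaf_node_iter():
        lf.edge.length += 1.0 - depths[id(lf)]
    return Phylogeny(tree)


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def _brownian_tips(tree: Phylogeny, sigma2: float,
                   rng: np.random.Generator) -> pd.Series:
    """One Brownian-motion trait realization along the tree."""
    t = tree.dendropy_tree
    values: dict[int, float] = {}
    out = {}
    for node in t.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            values[id(node)] = 0.0
        else:
            el = node.edge.length or 0.0
            values[id(node)] = values[id(parent)] + rng.normal(
                0.0, np.sqrt(sigma2 * el)
            )
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    return pd.Series(out).loc[tree.tip_labels]


def generate_traits(
    tree: Phylogeny,
    regimes: dict[str, object] | None = None,
    seed: int = 0,
    bm_sigma2: float = 1.0,
) -> TraitTable:
    """Simulate a complete trait table under per-trait signal regimes.

    ``regimes`` maps trait name to ``"BM"`` (Brownian motion along the
    branches), ``"white_noise"`` (iid normal, no signal) or
    ``("categorical", k)`` (a latent Brownian trait thresholded into k
    equal-frequency classes, giving categorical traits phylogenetic
    structure too).
    """
    regimes = DEFAULT_TRAIT_REGIMES if regimes is None else regimes
    rng = np.random.default_rng(seed)
    data = {}
    kinds = {}
    for trait, regime in regimes.items():
        if regime == "BM":
            data[trait] = _brownian_tips(tree, bm_sigma2, rng)
            kinds[trait] = "numeric"
        elif regime == "white_noise":
            data[trait] = pd.Series(
                rng.normal(size=tree.n_tips), index=tree.tip_labels
            )
            kinds[trait] = "numeric"
        elif (
            isinstance(regime, tuple) and len(regime) == 2
            and regime[0] == "categorical"
        ):
            k = int(regime[1])
            latent = _brownian_tips(tree, bm_sigma2, rng)
            qs = np.quantile(latent, np.linspace(0, 1, k + 1)[1:-1])
            labels = np.searchsorted(qs, latent.to_numpy())
            data[trait] = pd.Series(
                [f"{trait}_{c}" for c in labels], index=tree.tip_labels
            )
            kinds[trait] = "categorical"
        else:
            raise ValueError(f"unknown regime {regime!r} for trait {trait!r}")
    return TraitTable(pd.DataFrame(data), kinds)


# ---------------------------------------------------------------------------
# climate
# ---------------------------------------------------------------------------

_YEARS = (1964, 2013)
_PET_MEAN = 100.0
_PET_AMP = 15.0
_WET_PEAK_MONTH = 9
_P_AMP = 0.9


def _monthly_pet(months: np.ndarray) -> np.ndarray:
    return _PET_MEAN + _PET_AMP * np.cos(2 * np.pi * (months - 3) / 12.0)


def _monthly_precip_shape(months: np.ndarray) -> np.ndarray:
    return 1.0 + _P_AMP * np.cos(2 * np.pi * (months - _WET_PEAK_MONTH) / 12.0)


def _stationary_mcwd(base: float) -> float:
    """Noise-free one-year MCWD for a given mean monthly precipitation."""
    months = np.arange(1, 13)
    p = base * _monthly_precip_shape(months)
    pet = _monthly_pet(months)
    anchor = int(months[np.argmax(p)])
    order = np.concatenate([months[anchor - 1:], months[: anchor - 1]])
    wd, worst = 0.0, 0.0
    for m in order:
        wd = min(0.0, wd + p[m - 1] - pet[m - 1])
        worst = min(worst, wd)
    return worst


def _solve_precip_base(target_mcwd: float) -> float:
    lo, hi = 1.0, 500.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _stationary_mcwd(mid) < target_mcwd:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _solve_trend(base: float, target_dmcwd: float) -> float:
    """Linear fractional precipitation slope producing the wanted MCWD change.

    Evaluated at the centers of the two 30-yr windows (1978.5 vs 1998.5).
    """
    if target_dmcwd == 0:
        return 0.0

    def dmcwd(g):
        f1 = 1.0 + g * (1978.5 - 1988.5)
        f2 = 1.0 + g * (1998.5 - 1988.5)
        return _stationary_mcwd(base * f2) - _stationary_mcwd(base * f1)

    lo, hi = -5e-3, 0.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if dmcwd(mid) < target_dmcwd:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_climate(
    config: SimulationConfig,
) -> tuple[dict[str, clim.ClimateSeries], dict[str, float], dict[str, float]]:
    """Monthly P / PET / VPD series per plot for 1964-2013.

    Each plot gets a seasonal sinusoid calibrated so its stationary MCWD
    matches a point on the configured gradient, a linear drying trend
    calibrated to the configured per-plot MCWD change (strongest at the dry
    end), multiplicative lognormal precipitation noise and a warming VPD.
    Returns the series plus the targeted baseline MCWD and MCWD change of
    every plot.
    """
    rng = substream(config.seed, "climate")
    n = config.n_plots
    plot_ids = [f"P{i + 1:02d}" for i in range(n)]
    mcwd_targets = np.linspace(*config.mcwd_gradient, n)
    # drier plots (more negative MCWD) get the stronger drying
    dmcwd_targets = np.linspace(*config.dmcwd_range, n)
    if not config.climate_trend:
        dmcwd_targets = np.zeros(n)
    years = np.arange(_YEARS[0], _YEARS[1] + 1)
    months = np.arange(1, 13)
    grid_year = np.repeat(years, 12)
    grid_month = np.tile(months, len(years))
    pet = _monthly_pet(grid_month)
    series: dict[str, clim.ClimateSeries] = {}
    for i, pid in enumerate(plot_ids):
        base = _solve_precip_base(mcwd_targets[i])
        g = _solve_trend(base, dmcwd_targets[i])
        factor = 1.0 + g * (grid_year + (grid_month - 0.5) / 12.0 - 1988.5)
        p = base * _monthly_precip_shape(grid_month) * np.maximum(factor, 0.05)
        if config.climate_noise > 0:
            p = p * np.exp(rng.normal(0.0, config.climate_noise, len(p)))
        # drier plots start with higher atmospheric demand; drying raises it
        vpd_base = 0.8 + 0.8 * (i / max(n - 1, 1))
        vpd_trend = -g * 4.0  # precip decline fraction maps to VPD rise
        vpd = (
            vpd_base
            * (1.0 + 0.25 * np.cos(2 * np.pi * (grid_month - 3) / 12.0))
            * (1.0 + vpd_trend * (grid_year - 1988.5))
        )
        if config.climate_noise > 0:
            vpd = vpd * np.exp(
                rng.normal(0.0, config.climate_noise / 2, len(vpd))
            )
        frame = pd.DataFrame({
            "year": grid_year, "month": grid_month,
            "precip_mm": p, "pet_mm": pet, "vpd_kpa": vpd,
        })
        series[pid] = clim.ClimateSeries(pid, frame)
    return (
        series,
        dict(zip(plot_ids, mcwd_targets.tolist())),
        dict(zip(plot_ids, dmcwd_targets.tolist())),
    )


# ---------------------------------------------------------------------------
# communities
# ---------------------------------------------------------------------------

def _fdis_from_coords(coords: np.ndarray, w: np.ndarray) -> float:
    c = w @ coords
    return float(w @ np.linalg.norm(coords - c, axis=1))


def _weighted_mpd(d: np.ndarray, w: np.ndarray) -> float:
    num = w @ d @ w
    den = w.sum() ** 2 - np.sum(w**2)
    return float(num / den)


def _simpson(w: np.ndarray) -> float:
    return float(1.0 - np.sum(w**2))


def _reallocate(w1, theta, eta_f, eta_p, u_f, u_p):
    logw = theta * np.log(w1) + eta_f * u_f + eta_p * u_p
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def _stems_for_weights(
    species: list[str], ba: np.ndarray, rng: np.random.Generator
) -> list[tuple[str, float]]:
    """Stem list realizing the given per-species basal areas (m^2) exactly.

    Each species gets equal-diameter stems; the count targets a typical
    20 cm diameter and is reduced until the implied diameter clears the
    10 cm census threshold. Species below the single-10-cm-stem floor keep
    one minimal stem (a small, unavoidable discretization).
    """
    ba = np.asarray(ba, dtype=float)
    ba_min = float(stem_basal_area(10.0))
    ba_typical = float(stem_basal_area(20.0))
    # species under the single-minimal-stem floor get one 10 cm stem; the
    # rest are rescaled so the plot total is conserved exactly (keeps stand
    # basal-area change independent of community structure)
    floored = ba < ba_min
    adj = ba.copy()
    if floored.any() and not floored.all():
        adj[floored] = ba_min
        remaining = ba.sum() - adj[floored].sum()
        if remaining > 0:
            adj[~floored] = ba[~floored] * remaining / ba[~floored].sum()
    stems = []
    for sp, b in zip(species, adj):
        count = max(1, int(round(b / ba_typical)))
        dbh = 200.0 * np.sqrt(b / (count * np.pi))
        while dbh < 10.0 and count > 1:
            count -= 1
            dbh = 200.0 * np.sqrt(b / (count * np.pi))
        if dbh < 10.0:
            dbh = 10.0
        stems.extend([(sp, float(dbh))] * count)
    rng.shuffle(stems)
    return stems


def generate_community_pair(
    tree: Phylogeny,
    traits: TraitTable,
    dmcwd_abs: dict[str, float],
    config: SimulationConfig,
) -> tuple[list[PlotCensus], list[PlotCensus], GroundTruth]:
    """Two-census stem tables whose realized change rates track ground truth.

    The first census draws a lognormal basal-area community per plot; the
    second reallocates abundance with the rank-preserving transform
    ``w2 ~ w1^theta * exp(eta_f u_f + eta_p u_p)`` (u_f: trait distance to
    the community centroid, u_p: mean phylogenetic distance to the rest),
    solving (theta, eta_f, eta_p) so the realized annual changes of Simpson,
    FDis and weighted MPD match the true rates implied by the plot's MCWD
    change. Infeasible targets (e.g. Simpson above 1 - 1/S) raise
    :class:`InfeasibleTargetError`.
    """
    rng = substream(config.seed, "communities")
    pool = tree.tip_labels
    if not set(pool) <= set(traits.species):
        raise ValueError("species pool not covered by trait table")
    coords_pool = pcoa_embedding(gower_distance(traits, pool).to_numpy())
    pool_index = {s: i for i, s in enumerate(pool)}
    plot_ids = sorted(dmcwd_abs)
    facets = ("simpson", "fdis", "mpd")
    t1_list, t2_list = [], []
    truth_rows = {}
    for pid in plot_ids:
        # census dates
        j1, j2 = rng.uniform(-config.census_jitter, config.census_jitter, 2)
        t1 = config.census_years[0] + j1
        t2 = config.census_years[1] + j2
        if t2 - t1 < 10:
            t2 = t1 + 10.0
        area = float(rng.choice([1.0, 1.0, 1.0, 0.96, 0.8, 0.64]))
        # first census
        n_sp = min(config.n_species_per_plot, len(pool))
        species = list(rng.choice(pool, size=n_sp, replace=False))
        w_raw = np.exp(rng.normal(0.0, 1.2, n_sp))
        counts = rng.multinomial(
            max(2 * n_sp, int(config.n_stems_per_plot * area)),
            w_raw / w_raw.sum(),
        )
        keep = counts > 0
        species = [s for s, k in zip(species, keep) if k]
        counts = counts[keep]
        dbh1 = [
            10.0 + rng.gamma(2.0, 6.0, c).astype(float) for c in counts
        ]
        stems1 = [
            (sp, float(d)) for sp, ds in zip(species, dbh1) for d in ds
        ]
        census1 = PlotCensus(pid, round(t1, 2), area, stems1)
        com1 = basal_area_weights(census1)
        species = com1.species
        w1 = com1.weight_array()
        idx = [pool_index[s] for s in species]
        coords = coords_pool[idx]
        d = tree._patristic[np.ix_(
            tree.indices(species), tree.indices(species)
        )]
        base = {
            "simpson": _simpson(w1),
            "fdis": _fdis_from_coords(coords, w1),
            "mpd": _weighted_mpd(d, w1),
        }
        # true rates from the drying coupling
        interval = t2 - t1
        rates = {}
        for f in facets:
            rates[f] = (
                config.rate_intercept[f]
                + config.drying_effect[f] * dmcwd_abs[pid]
                + rng.normal(0.0, config.rate_noise_sd[f])
            )
        targets = {f: base[f] + rates[f] * interval for f in facets}
        s_max = 1.0 - 1.0 / len(species)
        if not 0.0 <= targets["simpson"] < s_max:
            raise InfeasibleTargetError(
                f"plot {pid}: Simpson target {targets['simpson']:.4f} outside "
                f"[0, {s_max:.4f})"
            )
        if targets["fdis"] < 0 or targets["mpd"] <= 0:
            raise InfeasibleTargetError(
                f"plot {pid}: negative dispersion target"
            )
        if all(abs(rates[f]) < 1e-15 for f in facets):
            w2 = w1.copy()
        else:
            u_f = np.linalg.norm(coords - w1 @ coords, axis=1)
            u_f = (u_f - u_f.mean()) / max(u_f.std(), 1e-12)
            u_p = d @ w1
            u_p = (u_p - u_p.mean()) / max(u_p.std(), 1e-12)
            # residual scales: the targeted change, floored at ~1% of the
            # metric's own scale so zero-change facets are not over-weighted
            floors = {
                "simpson": 5e-3,
                "fdis": 0.01 * max(base["fdis"], 0.1),
                "mpd": 0.01 * max(base["mpd"], 0.1),
            }
            scale = np.array([
                max(abs(targets[f] - base[f]), floors[f]) for f in facets
            ])

            def resid(x):
                th, ef, ep = x
                w = _reallocate(w1, th, ef, ep, u_f, u_p)
                vals = np.array([
                    _simpson(w),
                    _fdis_from_coords(coords, w),
                    _weighted_mpd(d, w),
                ])
                return (vals - np.array([targets[f] for f in facets])) / scale

            starts = [
                (1.0, 0.0, 0.0), (0.6, 0.0, -0.8), (1.6, 0.0, 0.8),
                (0.8, -0.8, 0.0), (1.2, 0.8, 0.0), (0.5, 0.5, -1.5),
                (2.0, -0.5, 1.0),
            ]
            best = None
            for x0 in starts:
                sol = least_squares(
                    resid, x0=np.array(x0),
                    bounds=([0.05, -5.0, -5.0], [20.0, 5.0, 5.0]),
                    xtol=1e-12, ftol=1e-12, gtol=1e-12,
                )
                if best is None or np.max(np.abs(sol.fun)) < np.max(
                    np.abs(best.fun)
                ):
                    best = sol
                if np.max(np.abs(best.fun)) <= 0.02:
                    break
            if np.max(np.abs(best.fun)) > 0.1:
                raise InfeasibleTargetError(
                    f"plot {pid}: reallocation missed targets by "
                    f"{np.max(np.abs(best.fun)):.2f} (relative)"
                )
            w2 = _reallocate(w1, *best.x, u_f, u_p)
        total_ba2 = com1.total_ba * float(rng.uniform(0.98, 1.12))
        stems2 = _stems_for_weights(species, w2 * total_ba2, rng)
        census2 = PlotCensus(pid, round(t2, 2), area, stems2)
        t1_list.append(census1)
        t2_list.append(census2)
        truth_rows[pid] = {f"d_{f}_r": rates[f] for f in facets}
    truth = GroundTruth(
        true_rates=pd.DataFrame.from_dict(truth_rows, orient="index"),
        coefficients={
            "rate_intercept": dict(config.rate_intercept),
            "drying_effect": dict(config.drying_effect),
            "rate_noise_sd": dict(config.rate_noise_sd),
        },
        trait_regimes={},
        dmcwd_targets=dict(dmcwd_abs),
        mcwd_targets={},
    )
    return t1_list, t2_list, truth


# ---------------------------------------------------------------------------
# soils
# ---------------------------------------------------------------------------

_SOIL_VARS = [
    "ecec_mmol_kg", "mg_mmol_kg", "n_pct", "p_mg_kg",
    "ph", "fe_mmol_kg", "ca_mmol_kg", "clay_pct", "sand_pct",
]

# loadings of the 3 latent factors: F1 nutrients (eCEC, Mg, N, P),
# F2 acidity-calcium (pH-, Fe+, Ca-), F3 texture (clay-, sand+)
_SOIL_LOADINGS = np.array([
    # F1    F2    F3
    [4.0, 0.3, 0.0],    # eCEC
    [1.5, 0.2, 0.0],    # Mg
    [0.08, 0.0, 0.01],  # N
    [20.0, 0.0, 1.0],   # P
    [0.1, -0.5, 0.0],   # pH
    [0.3, 2.0, 0.1],    # Fe
    [-0.5, -3.0, 0.0],  # Ca
    [0.0, 0.5, -6.0],   # clay
    [0.0, -0.5, 8.0],   # sand
])
_SOIL_MEANS = np.array([20.0, 6.0, 0.25, 80.0, 5.5, 8.0, 12.0, 30.0, 45.0])


def generate_soils(
    n_plots: int, seed: int = 0, noise_sd: float = 0.15
) -> pd.DataFrame:
    """Plot-level 0-30 cm soil table driven by 3 latent factors plus noise.

    With ``noise_sd=0`` the table has exactly rank-3 covariance structure
    (up to the clipping of texture percentages, which the default factor
    scales avoid). Clay and sand percentages stay within [0, 100] and sum
    to at most 100.
    """
    if n_plots < 4:
        raise ValueError("n_plots must be >= 4")
    rng = substream(seed, "soils")
    factors = rng.normal(size=(n_plots, 3))
    X = _SOIL_MEANS + factors @ _SOIL_LOADINGS.T
    if noise_sd > 0:
        scales = np.abs(_SOIL_LOADINGS).max(axis=1)
        X = X + rng.normal(0.0, noise_sd, X.shape) * scales
    df = pd.DataFrame(
        X, columns=_SOIL_VARS,
        index=[f"P{i + 1:02d}" for i in range(n_plots)],
    )
    df["clay_pct"] = df["clay_pct"].clip(0.0, 100.0)
    df["sand_pct"] = df["sand_pct"].clip(0.0, 100.0)
    over = df["clay_pct"] + df["sand_pct"] > 100.0
    if over.any():
        tot = df.loc[over, "clay_pct"] + df.loc[over, "sand_pct"]
        df.loc[over, ["clay_pct", "sand_pct"]] = (
            df.loc[over, ["clay_pct", "sand_pct"]].mul(100.0 / tot, axis=0)
        )
    return df


# ---------------------------------------------------------------------------
# whole worlds
# ---------------------------------------------------------------------------

@dataclass
class StudyData:
    """Everything a synthetic world provides to the pipeline."""

    config: SimulationConfig
    tree: Phylogeny
    traits: TraitTable
    climate: dict[str, clim.ClimateSeries]
    census_t1: list[PlotCensus]
    census_t2: list[PlotCensus]
    soils: pd.DataFrame
    ground_truth: GroundTruth


def generate_study(config: SimulationConfig) -> StudyData:
    """Generate one complete synthetic world from a single seed."""
    tree = generate_phylogeny(
        config.n_species_pool, seed=int(substream(config.seed, "tree")
                                        .integers(2**31))
    )
    traits = generate_traits(
        tree, DEFAULT_TRAIT_REGIMES,
        seed=int(substream(config.seed, "traits").integers(2**31)),
        bm_sigma2=config.trait_bm_sigma2,
    )
    climate_series, mcwd_targets, dmcwd_targets = generate_climate(config)
    t1, t2, truth = generate_community_pair(
        tree, traits, dmcwd_targets, config
    )
    truth.trait_regimes = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in DEFAULT_TRAIT_REGIMES.items()
    }
    truth.mcwd_targets = mcwd_targets
    soils = generate_soils(config.n_plots, seed=config.seed)
    return StudyData(
        config=config, tree=tree, traits=traits, climate=climate_series,
        census_t1=t1, census_t2=t2, soils=soils, ground_truth=truth,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_census_csv(censuses: list[PlotCensus], path) -> None:
    rows = []
    for c in censuses:
        for i, (sp, dbh) in enumerate(c.stems):
            rows.append({
                "plot_id": c.plot_id, "census_date": c.census_date,
                "plot_area": c.plot_area, "stem_id": f"{c.plot_id}_{i:05d}",
                "species": sp, "dbh_cm": round(dbh, 4),
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_census_csv(path) -> list[PlotCensus]:
    df = pd.read_csv(path)
    out = []
    for (pid, date), sub in df.groupby(["plot_id", "census_date"], sort=True):
        out.append(PlotCensus(
            str(pid), float(date), float(sub["plot_area"].iloc[0]),
            list(zip(sub["species"], sub["dbh_cm"].astype(float))),
        ))
    return out


def write_climate_csv(series: dict[str, clim.ClimateSeries], path) -> None:
    frames = []
    for pid in sorted(series):
        f = series[pid].frame.copy()
        f.insert(0, "plot_id", pid)
        frames.append(f)
    pd.concat(frames).to_csv(path, index=False, float_format="%.6f")


def read_climate_csv(path) -> dict[str, clim.ClimateSeries]:
    df = pd.read_csv(path)
    return {
        str(pid): clim.ClimateSeries(str(pid), sub.drop(columns="plot_id"))
        for pid, sub in df.groupby("plot_id")
    }
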