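"""End-to-end study pipeline: simulate -> diversity -> climate -> inference.

Every stage reads its inputs from and writes its outputs to a run directory,
so the whole study is reproducible from a config and one seed. A manifest
echoes every stage's effective parameters, the derived stage seeds, input
checksums and any data-quality warnings. Randomness flows from the single
top-level seed through named substreams (one per stage).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import climate as clim
from . import rates as rates_mod
from .bayes import (
    BayesianLinearModel,
    RobustTwoGroupModel,
    enumerate_models,
    loo_compare,
    prune_correlated,
    soil_pca,
)
from .bayes.loo import exact_loo
from .community import (
    TraitTable,
    basal_area_weights,
    fdis,
    gower_distance,
    rao_q,
    simpson_index,
    hill_simpson,
    trait_coverage,
)
from .phylo import (
    Phylogeny,
    faith_pd,
    frequency_null,
    k_significance,
    mntd,
    mpd,
)
from .simulate import (
    SimulationConfig,
    generate_study,
    read_census_csv,
    read_climate_csv,
    substream,
    write_census_csv,
    write_climate_csv,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "report"]

FACETS = ("fdis", "simpson", "mpd")


@dataclasses.dataclass
class RunConfig:
    """Effective parameters of a pipeline run."""

    out_dir: str
    seed: int = 0
    simulate: bool = True
    sim: SimulationConfig | None = None
    dry_wet_threshold: float = rates_mod.DRY_WET_THRESHOLD_MM
    coverage_threshold: float = 0.9
    correlation_cutoff: float = 0.7
    null_iterations: int = 999
    chains: int = 3
    iterations: int = 2000
    loo_chains: int = 2
    loo_iterations: int = 600
    cwd_mode: str = "cumulative"
    responses: tuple[str, ...] = ("d_fdis_r", "d_simpson_r", "d_mpd_r")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.sim = SimulationConfig(**sim)
        return cfg

    def resolved_sim(self) -> SimulationConfig:
        if self.sim is not None:
            return self.sim
        return SimulationConfig(seed=self.seed)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data = {"stages": {}, "warnings": [], "checksums": {}}
        if path.exists():
            self.data = json.loads(path.read_text())

    def record(self, stage: str, params: dict):
        self.data["stages"][stage] = params
        self.save()

    def warn(self, message: str):
        logger.warning(message)
        if message not in self.data["warnings"]:
            self.data["warnings"].append(message)
        self.save()

    def checksum(self, *paths: Path):
        for p in paths:
            self.data["checksums"][p.name] = _checksum(p)
        self.save()

    def save(self):
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True))


def _stage_seed(config: RunConfig, stage: str) -> int:
    return int(substream(config.seed, stage).integers(2**31))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig, out: Path, manifest: _Manifest):
    sim = config.resolved_sim()
    study = generate_study(sim)
    write_census_csv(study.census_t1 + study.census_t2, out / "census.csv")
    study.traits.to_csv(out / "traits.csv")
    study.tree.write_newick(out / "tree.nwk")
    write_climate_csv(study.climate, out / "climate.csv")
    study.soils.to_csv(out / "soils.csv", index_label="plot_id")
    study.ground_truth.to_json(out / "ground_truth.json")
    manifest.record("simulate", dataclasses.asdict(sim))
    manifest.checksum(
        out / "census.csv", out / "traits.csv", out / "tree.nwk",
        out / "climate.csv", out / "soils.csv",
    )


def stage_diversity(config: RunConfig, out: Path, manifest: _Manifest):
    censuses = read_census_csv(out / "census.csv")
    traits = TraitTable.from_csv(out / "traits.csv")
    gower = gower_distance(traits)
    rows = []
    for census in censuses:
        com = basal_area_weights(census)
        cov = trait_coverage(traits, com, config.coverage_threshold)
        low = {t: c for t, c in cov.items() if c < config.coverage_threshold}
        if low:
            manifest.warn(
                f"plot {census.plot_id} @ {census.census_date}: trait "
                f"coverage below {config.coverage_threshold:.0%}: {low}"
            )
        w = com.weight_array()
        rows.append({
            "plot_id": com.plot_id,
            "census_date": com.census_date,
            "plot_area": census.plot_area,
            "total_ba": com.total_ba,
            "fdis": fdis(traits, com),
            "rao_q": rao_q(gower, com),
            "simpson": simpson_index(w),
            "hill_q2": hill_simpson(w),
        })
    pd.DataFrame(rows).to_csv(out / "diversity.csv", index=False)
    manifest.record("diversity", {
        "coverage_threshold": config.coverage_threshold,
        "abundance": "relative basal area",
    })


def stage_phylo(config: RunConfig, out: Path, manifest: _Manifest):
    censuses = read_census_csv(out / "census.csv")
    tree = Phylogeny.from_newick(str(out / "tree.nwk"))
    div = pd.read_csv(out / "diversity.csv")
    rows = []
    by_census: dict[float, dict[str, dict[str, float]]] = {}
    for census in censuses:
        com = basal_area_weights(census)
        rows.append({
            "plot_id": com.plot_id, "census_date": com.census_date,
            "mpd": mpd(com, tree), "mntd": mntd(com, tree),
            "pd": faith_pd(com, tree),
        })
        period = "t1" if com.census_date == min(
            c.census_date for c in censuses if c.plot_id == com.plot_id
        ) else "t2"
        by_census.setdefault(period, {})[com.plot_id] = {
            s: w * com.total_ba for s, w in com.weights.items()
        }
    ph = pd.DataFrame(rows)
    ses_frames = []
    seed = _stage_seed(config, "phylo-null")
    for k, (period, plots) in enumerate(sorted(by_census.items())):
        mat = pd.DataFrame.from_dict(plots, orient="index").fillna(0.0)
        ses = frequency_null(
            mat, tree, n_iter=config.null_iterations, seed=seed + k
        )
        ses["period"] = period
        ses_frames.append(ses)
    pd.concat(ses_frames).to_csv(out / "ses_mpd.csv", index_label="plot_id")
    merged = div.merge(ph, on=["plot_id", "census_date"])
    merged.to_csv(out / "diversity.csv", index=False)
    # phylogenetic signal of each numeric trait (tip-shuffle test)
    traits = TraitTable.from_csv(out / "traits.csv")
    sig_rows = []
    for t in traits.traits:
        if traits.kinds[t] != "numeric":
            continue
        k, p = k_significance(
            traits.data[t].astype(float), tree, n_perm=999, seed=seed,
        )
        sig_rows.append({"trait": t, "blomberg_k": k, "p_value": p})
    pd.DataFrame(sig_rows).to_csv(out / "phylo_signal.csv", index=False)
    manifest.record("phylo", {
        "null_iterations": config.null_iterations, "seed": seed,
        "weighting": "basal area", "pd_convention": "root-inclusive",
    })


def stage_climate(config: RunConfig, out: Path, manifest: _Manifest):
    series = read_climate_csv(out / "climate.csv")
    summaries, changes = [], []
    for pid in sorted(series):
        s = series[pid]
        t1 = clim.summarize(s, clim.WINDOW_T1, mode=config.cwd_mode)
        t2 = clim.summarize(s, clim.WINDOW_T2, mode=config.cwd_mode)
        full = clim.summarize(s, clim.WINDOW_FULL, mode=config.cwd_mode)
        for summ, name in ((t1, "T1"), (t2, "T2"), (full, "Full")):
            summaries.append({
                "plot_id": pid, "window": name, "mcwd": summ.mcwd,
                "vpd_mean": summ.vpd_mean, "spei_mean": summ.spei_mean,
            })
        ch = clim.driver_changes(t1, t2, full)
        changes.append(dataclasses.asdict(ch))
    pd.DataFrame(summaries).to_csv(out / "climate_summary.csv", index=False)
    pd.DataFrame(changes).to_csv(out / "driver_changes.csv", index=False)
    manifest.record("climate", {
        "cwd_mode": config.cwd_mode,
        "windows": {"T1": clim.WINDOW_T1, "T2": clim.WINDOW_T2,
                    "Full": clim.WINDOW_FULL},
    })


def stage_rates(config: RunConfig, out: Path, manifest: _Manifest):
    div = pd.read_csv(out / "diversity.csv")
    summ = pd.read_csv(out / "climate_summary.csv")
    mcwd_t1 = summ[summ["window"] == "T1"].set_index("plot_id")["mcwd"]
    table = rates_mod.rate_table(
        div, mcwd_t1, facets=FACETS, threshold=config.dry_wet_threshold
    )
    # basal-area-change diagnostics: rate changes should not track stand growth
    ba = div.pivot(index="plot_id", columns="census_date", values="total_ba")
    ba_change = ba.apply(
        lambda r: r.dropna().iloc[-1] - r.dropna().iloc[0], axis=1
    )
    diag = rates_mod.ba_change_diagnostics(ba_change, table)
    table.to_csv(out / "rates.csv")
    diag.to_csv(out / "ba_diagnostics.csv")
    manifest.record("rates", {"dry_wet_threshold": config.dry_wet_threshold})


def stage_compare(config: RunConfig, out: Path, manifest: _Manifest):
    table = pd.read_csv(out / "rates.csv").set_index("plot_id")
    seed = _stage_seed(config, "compare")
    results = {}
    for i, facet in enumerate(FACETS):
        col = f"d_{facet}_r"
        model = RobustTwoGroupModel.from_dataframe(
            table.reset_index(), value=col, group="group",
            order=("dry", "wet"),
        )
        res = model.fit(
            chains=config.chains, iterations=config.iterations,
            seed=seed + i,
        )
        if not res.converged:
            manifest.warn(f"compare[{facet}]: MCMC not converged "
                          f"(max Rhat {max(res.rhat.values()):.3f})")
        d = res.diff_draws
        results[facet] = {
            "n_dry": int((table["group"] == "dry").sum()),
            "n_wet": int((table["group"] == "wet").sum()),
            "median_diff": float(np.median(d)),
            "hdi_50": res.hdi(0.50), "hdi_89": res.hdi(0.89),
            "hdi_95": res.hdi(0.95),
            "prob": res.prob,
            "rhat": res.rhat,
            "converged": res.converged,
        }
    (out / "comparison.json").write_text(
        json.dumps(results, indent=1, sort_keys=True)
    )
    manifest.record("compare", {
        "chains": config.chains, "iterations": config.iterations,
        "seed": seed, "groups": "dry (MCWD_T1 <= -250 mm) vs wet",
    })


def _driver_table(out: Path) -> pd.DataFrame:
    table = pd.read_csv(out / "rates.csv").set_index("plot_id")
    changes = pd.read_csv(out / "driver_changes.csv").set_index("plot_id")
    soils = pd.read_csv(out / "soils.csv").set_index("plot_id")
    pca = soil_pca(soils)
    div = pd.read_csv(out / "diversity.csv")
    areas = div.groupby("plot_id")["plot_area"].first()
    data = table.join(changes[["d_mcwd_abs", "d_vpd_abs", "d_spei_abs",
                               "mcwd_full"]])
    data = data.join(pca.scores[pca.selected_axes[:3]])
    data["plot_area"] = areas
    return data


def stage_drivers(config: RunConfig, out: Path, manifest: _Manifest):
    data = _driver_table(out)
    candidates = [c for c in ["d_mcwd_abs", "mcwd_full", "d_vpd_abs",
                              "d_spei_abs", "PC1", "PC2", "PC3"]
                  if c in data.columns]
    incomplete = [c for c in candidates
                  if not np.isfinite(data[c].to_numpy(dtype=float)).all()]
    if incomplete:
        manifest.warn(f"drivers with missing values excluded: {incomplete}")
        candidates = [c for c in candidates if c not in incomplete]
    retained = prune_correlated(
        data[candidates], threshold=config.correlation_cutoff,
        priority=["d_mcwd_abs", "mcwd_full", "d_vpd_abs", "PC1", "PC2",
                  "PC3", "d_spei_abs"],
    )
    climate_terms = tuple(
        t for t in ("d_mcwd_abs", "mcwd_full", "d_vpd_abs", "d_spei_abs")
        if t in retained
    )[:3]
    soil_terms = tuple(t for t in ("PC1", "PC2", "PC3") if t in retained)
    seed = _stage_seed(config, "drivers")
    leaderboards = {}
    coef_tables = []
    for r, response in enumerate(config.responses):
        specs = enumerate_models(response, climate_terms, soil_terms)
        fits, loos = [], []
        for k, spec in enumerate(specs):
            model = BayesianLinearModel.from_spec(spec, data)
            fit = model.fit(chains=config.chains,
                            iterations=config.iterations,
                            seed=seed + 1000 * r + k)
            if not fit.converged:
                manifest.warn(f"drivers[{response}]: {spec.name} flagged "
                              f"non-converged; excluded from selection")
                continue
            loo = exact_loo(model, chains=config.loo_chains,
                            iterations=config.loo_iterations,
                            seed=seed + 1000 * r + k)
            fits.append(fit)
            loos.append(loo)
        board = loo_compare(loos)
        board["r2_adj"] = [
            next(f.r2_adj for f, l in zip(fits, loos) if l.name == nm)
            for nm in board.index
        ]
        leaderboards[response] = board
        best_name = board.index[0]
        best = next(f for f, l in zip(fits, loos) if l.name == best_name)
        tab = best.summary().reset_index()
        tab.insert(0, "model", best_name)
        tab.insert(0, "response", response)
        coef_tables.append(tab)
        board.to_csv(out / f"leaderboard_{response}.csv")
    pd.concat(coef_tables).to_csv(out / "best_model_coefficients.csv",
                                  index=False)
    manifest.record("drivers", {
        "retained_drivers": retained,
        "correlation_cutoff": config.correlation_cutoff,
        "n_candidate_models": len(enumerate_models(
            config.responses[0], climate_terms, soil_terms)),
        "chains": config.chains, "iterations": config.iterations,
        "loo": {"chains": config.loo_chains,
                "iterations": config.loo_iterations, "method": "exact refit"},
        "seed": seed,
    })


STAGES = [
    ("simulate", stage_simulate),
    ("diversity", stage_diversity),
    ("phylo", stage_phylo),
    ("climate", stage_climate),
    ("rates", stage_rates),
    ("compare", stage_compare),
    ("drivers", stage_drivers),
]


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages in dependency order; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json")
    manifest.data["config"] = {
        **{k: v for k, v in dataclasses.asdict(config).items() if k != "sim"},
        "sim": dataclasses.asdict(config.resolved_sim()),
    }
    manifest.save()
    for name, fn in STAGES:
        if name == "simulate" and not config.simulate:
            required = ["census.csv", "traits.csv", "tree.nwk",
                        "climate.csv", "soils.csv"]
            missing = [f for f in required if not (out / f).exists()]
            if missing:
                raise FileNotFoundError(
                    f"simulate disabled and inputs missing: {missing}"
                )
            continue
        try:
            fn(config, out, manifest)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def report(run_dir) -> str:
    """Human-readable summary of a completed run (deterministic text)."""
    out = Path(run_dir)
    missing = [f for f in ("comparison.json", "rates.csv", "manifest.json")
               if not (out / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run; missing {missing}")
    manifest = json.loads((out / "manifest.json").read_text())
    comparison = json.loads((out / "comparison.json").read_text())
    lines = ["# Diversity-change report", ""]
    if manifest.get("warnings"):
        lines.append("## WARNINGS")
        for w in manifest["warnings"]:
            lines.append(f"  !! {w}")
        lines.append("")
    lines.append("## Dry vs wet group comparison (difference = dry - wet)")
    for facet, res in sorted(comparison.items()):
        lo89, hi89 = res["hdi_89"]
        flag = "" if res["converged"] else "  [NOT CONVERGED]"
        lines.append(
            f"  {facet:8s} median diff {res['median_diff']: .3e}  "
            f"89% HDI [{lo89: .3e}, {hi89: .3e}]  "
            f"Prob {res['prob']:.1f}%{flag}"
        )
    lines.append("")
    for f in sorted(out.glob("leaderboard_*.csv")):
        board = pd.read_csv(f, index_col=0)
        response = f.stem.replace("leaderboard_", "")
        lines.append(f"## Model selection for {response} (top 5 by LOOIC)")
        head = board.head(5)
        for name, row in head.iterrows():
            lines.append(
                f"  looic {row['looic']:9.2f}  elpd_diff {row['elpd_diff']:7.3f}"
                f"  r2_adj {row['r2_adj']:6.3f}  {name}"
            )
        lines.append("")
    coef_path = out / "best_model_coefficients.csv"
    if coef_path.exists():
        coefs = pd.read_csv(coef_path)
        lines.append("## Best-model coefficients "
                     "(median, 89% HDI, ROPE, Rhat)")
        for _, row in coefs.iterrows():
            lines.append(
                f"  {row['response']:12s} {row['term']:24s} "
                f"{row['median']: .3e}  [{row['hdi89_l']: .3e}, "
                f"{row['hdi89_h']: .3e}]  ROPE {row['rope']:.2f}  "
                f"Rhat {row['rhat']:.2f}"
            )
        lines.append("")
    diag_path = out / "ba_diagnostics.csv"
    if diag_path.exists():
        diag = pd.read_csv(diag_path, index_col=0)
        lines.append("## Basal-area-change diagnostics (Pearson)")
        for facet, row in diag.iterrows():
            lines.append(f"  {facet:12s} r {row['r']: .3f}  p {row['p']:.3f}")
        lines.append("")
    text = "\n".join(lines) + "\n"
    (out / "report.txt").write_text(text)
    return text
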