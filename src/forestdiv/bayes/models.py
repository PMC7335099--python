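"""Candidate model grammar for the driver regressions.

A model spec names a response (a diversity-change rate), a set of main-effect
drivers and optional interaction terms, each pairing one soil principal
component with one climate driver. The default grammar enumerates 35 specs:
the intercept-only baseline, every single driver, climate-only and soils-only
additive tiers, the full additive model and its interaction extensions up to
the model with all nine PC x climate interactions. Every spec carries the
plot-area covariate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ModelSpec", "enumerate_models", "CLIMATE_TERMS", "SOIL_TERMS"]

CLIMATE_TERMS = ("d_mcwd_abs", "mcwd_full", "d_vpd_abs")
SOIL_TERMS = ("PC1", "PC2", "PC3")


@dataclass(frozen=True)
class ModelSpec:
    """One candidate linear model: response ~ mains + interactions."""

    response: str
    main_terms: tuple[str, ...]
    interaction_terms: tuple[tuple[str, str], ...] = ()

    @property
    def term_names(self) -> list[str]:
        return list(self.main_terms) + [
            f"{a}:{b}" for a, b in self.interaction_terms
        ]

    @property
    def name(self) -> str:
        rhs = " + ".join(self.term_names) or "1"
        return f"{self.response} ~ {rhs}"

    def build_design(self, data: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
        """Response vector and raw (unstandardized) design frame."""
        need = {self.response, *self.main_terms}
        need |= {t for pair in self.interaction_terms for t in pair}
        missing = need - set(data.columns)
        if missing:
            raise KeyError(f"data lacks columns {sorted(missing)}")
        X = data[list(self.main_terms)].astype(float).copy()
        for a, b in self.interaction_terms:
            X[f"{a}:{b}"] = data[a].astype(float) * data[b].astype(float)
        return data[self.response].astype(float), X


def enumerate_models(
    response: str,
    climate_terms: tuple[str, ...] = CLIMATE_TERMS,
    soil_terms: tuple[str, ...] = SOIL_TERMS,
    covariate: str = "plot_area",
) -> list[ModelSpec]:
    """Deterministic, duplicate-free default candidate set (35 specs)."""
    drivers = tuple(climate_terms) + tuple(soil_terms)
    full = drivers

    def spec(mains, inter=()):
        return ModelSpec(
            response,
            tuple(mains) + (covariate,),
            tuple(inter),
        )

    specs: list[ModelSpec] = []
    specs.append(spec(()))                                     # intercept only
    specs.extend(spec((d,)) for d in drivers)                  # single drivers
    specs.extend(spec(p) for p in combinations(climate_terms, 2))
    specs.append(spec(climate_terms))
    specs.extend(spec(p) for p in combinations(soil_terms, 2))
    specs.append(spec(soil_terms))
    specs.extend(spec(climate_terms + (pc,)) for pc in soil_terms)
    specs.append(spec(full))                                   # full additive
    all_inter = [(pc, c) for pc in soil_terms for c in climate_terms]
    specs.extend(spec(full, (pair,)) for pair in all_inter)
    specs.extend(
        spec(full, [(pc, c) for c in climate_terms]) for pc in soil_terms
    )
    specs.extend(
        spec(full, [(pc, c) for pc in soil_terms]) for c in climate_terms
    )
    specs.append(spec(full, all_inter))

    seen, unique = set(), []
    for s in specs:
        key = (s.main_terms, s.interaction_terms)
        if key in seen:
            logger.warning("duplicate model spec dropped: %s", s.name)
            continue
        seen.add(key)
        unique.append(s)
    return unique
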