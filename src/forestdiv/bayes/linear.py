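"""Bayesian Gaussian linear regression for the diversity-change drivers.

Predictors are centred and scaled internally; coefficient priors are
``N(0, 2.5)`` on that standardized scale with ``N(0, 10)`` on the intercept
and an ``Exponential(rate 1/sd(y))`` prior on the residual scale. Sampling
is Gibbs: the coefficient block is conjugate multivariate normal given
``sigma``; ``log sigma`` gets a slice update.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diagnostics import hdi, prob_direction, rope, split_rhat
from .models import ModelSpec
from .samplers import slice_sample

logger = logging.getLogger(__name__)

__all__ = ["BayesianLinearModel", "BayesianLMResults"]

RHAT_LIMIT = 1.05


class BayesianLinearModel:
    """Linear model ``y ~ N(X beta, sigma^2)`` with standardized predictors.

    Parameters
    ----------
    y : array-like
        Response on its own scale (not standardized).
    X : pandas.DataFrame
        Raw predictor columns (no intercept column). Constant columns are
        dropped with a warning.
    spec : ModelSpec, optional
        Provenance of the design; carried into results.
    """

    def __init__(self, y, X: pd.DataFrame, spec: ModelSpec | None = None,
                 coef_prior_sd: float = 2.5, intercept_prior_sd: float = 10.0,
                 sigma_prior_rate: float | None = None):
        y = np.asarray(y, dtype=float).ravel()
        if isinstance(X, pd.DataFrame):
            Xf = X.astype(float)
        else:
            X = np.atleast_2d(np.asarray(X, dtype=float))
            Xf = pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])
        if len(Xf) != len(y):
            raise ValueError("X and y lengths differ")
        if not np.all(np.isfinite(y)):
            raise ValueError("response contains non-finite values")
        if Xf.size and not np.all(np.isfinite(Xf.to_numpy(dtype=float))):
            raise ValueError("predictors contain non-finite values")
        keep, dropped = [], []
        for c in Xf.columns:
            if np.std(Xf[c].to_numpy()) == 0:
                dropped.append(c)
            else:
                keep.append(c)
        if dropped:
            logger.warning("constant predictors dropped: %s", dropped)
        Xf = Xf[keep]
        n, p = len(y), Xf.shape[1]
        if n < p + 2:
            logger.warning(
                "n=%d observations for p=%d terms; posterior will be "
                "prior-dominated", n, p,
            )
        self.y = y
        self.X_raw = Xf
        self.spec = spec
        self.term_names = ["intercept"] + list(Xf.columns)
        self._mean = Xf.to_numpy().mean(axis=0)
        self._sd = Xf.to_numpy().std(axis=0, ddof=1)
        Z = (Xf.to_numpy() - self._mean) / self._sd if p else np.empty((n, 0))
        self.Z = np.column_stack([np.ones(n), Z])
        sd_y = float(np.std(y, ddof=1)) if n > 1 else 1.0
        self.sd_y = sd_y if sd_y > 0 else 1.0
        self.sigma_prior_rate = (
            1.0 / self.sd_y if sigma_prior_rate is None else sigma_prior_rate
        )
        prior_sd = np.full(p + 1, coef_prior_sd)
        prior_sd[0] = intercept_prior_sd
        self._prior_prec = np.diag(1.0 / prior_sd**2)

    @classmethod
    def from_spec(cls, spec: ModelSpec, data: pd.DataFrame, **kw):
        y, X = spec.build_design(data)
        return cls(y, X, spec=spec, **kw)

    # -- sampling ----------------------------------------------------------
    def _run_chain(self, n_iter: int, warmup: int, rng: np.random.Generator):
        Z, y = self.Z, self.y
        n, p1 = Z.shape
        ZtZ = Z.T @ Z
        Zty = Z.T @ y
        ls = math.log(self.sd_y) + rng.normal(0, 0.5)
        # numerical support for log sigma: spans sd_y/400 .. sd_y*3000, so
        # ZtZ/sigma^2 stays well-conditioned against the prior precision
        # even for rank-deficient designs (p close to or above n)
        ls_lo = math.log(self.sd_y) - 6.0
        ls_hi = math.log(self.sd_y) + 8.0
        ls = min(max(ls, ls_lo + 1.0), ls_hi - 1.0)
        beta = np.zeros(p1)
        kept = n_iter - warmup
        out = np.empty((kept, p1 + 1))
        for it in range(n_iter):
            sigma2 = math.exp(2 * ls)
            Q = ZtZ / sigma2 + self._prior_prec
            L = np.linalg.cholesky(Q)
            mean = np.linalg.solve(Q, Zty / sigma2)
            z = rng.standard_normal(p1)
            beta = mean + np.linalg.solve(L.T, z)
            resid = y - Z @ beta
            ssr = float(resid @ resid)
            rate = self.sigma_prior_rate

            def logf(s):
                if s < ls_lo or s > ls_hi:
                    return -np.inf
                return -n * s - ssr / (2.0 * math.exp(2 * s)) - rate * math.exp(s) + s

            ls = slice_sample(ls, logf, rng, w=0.5)
            if it >= warmup:
                out[it - warmup, :p1] = beta
                out[it - warmup, p1] = math.exp(ls)
        return out

    def fit(self, chains: int = 3, iterations: int = 2000,
            warmup: int | None = None, seed: int = 0) -> "BayesianLMResults":
        """Sample the posterior; half of ``iterations`` warms up by default."""
        if warmup is None:
            warmup = iterations // 2
        if chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")
        root = np.random.SeedSequence(seed)
        draws = np.stack([
            self._run_chain(iterations, warmup, np.random.default_rng(s))
            for s in root.spawn(chains)
        ])
        return BayesianLMResults(self, draws)


@dataclass
class BayesianLMResults:
    """Posterior draws and Table-style summaries of a fitted linear model."""

    model: BayesianLinearModel
    chain_draws: np.ndarray  # (chains, kept, p+2): coefs then sigma
    rhat: dict[str, float] = field(init=False)
    converged: bool = field(init=False)

    def __post_init__(self):
        names = self.model.term_names + ["sigma"]
        self.rhat = {
            nm: split_rhat(self.chain_draws[:, :, i])
            for i, nm in enumerate(names)
        }
        self.converged = all(r <= RHAT_LIMIT for r in self.rhat.values())

    # -- draws -------------------------------------------------------------
    def coef_draws(self, term: str) -> np.ndarray:
        """Draws of a coefficient on the standardized-predictor scale."""
        i = self.model.term_names.index(term)
        return self.chain_draws[:, :, i].ravel()

    @property
    def sigma_draws(self) -> np.ndarray:
        return self.chain_draws[:, :, -1].ravel()

    def coef_draws_raw(self, term: str) -> np.ndarray:
        """Coefficient draws back-transformed to the raw predictor scale."""
        if term == "intercept":
            b = self.chain_draws[:, :, 0].ravel().copy()
            for j in range(1, len(self.model.term_names)):
                bj = self.chain_draws[:, :, j].ravel()
                b -= bj * self.model._mean[j - 1] / self.model._sd[j - 1]
            return b
        i = self.model.term_names.index(term)
        return self.chain_draws[:, :, i].ravel() / self.model._sd[i - 1]

    # -- summaries ---------------------------------------------------------
    def rope(self, term: str, rope_range: tuple[float, float] | None = None,
             hdi_mass: float = 0.89) -> float:
        """Fraction of the coefficient HDI inside the negligible-effect band.

        The default band is ``+/- 0.1 * sd(y)``: with standardized predictors
        a coefficient is the response change per predictor standard
        deviation, so the band marks effects smaller than a tenth of the
        response's spread.
        """
        if rope_range is None:
            half = 0.1 * self.model.sd_y
            rope_range = (-half, half)
        return rope(self.coef_draws(term), rope_range, hdi_mass)

    @property
    def r2_adj(self) -> float:
        """Classical adjusted R^2 at the posterior-median coefficients."""
        med = np.median(
            self.chain_draws[:, :, : len(self.model.term_names)], axis=(0, 1)
        )
        fitted = self.model.Z @ med
        y = self.model.y
        ss_res = float(np.sum((y - fitted) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        n = len(y)
        p = len(self.model.term_names) - 1
        if ss_tot == 0 or n - p - 1 <= 0:
            return float("nan")
        r2 = 1.0 - ss_res / ss_tot
        return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)

    def summary(self) -> pd.DataFrame:
        """Per-term median, 50/89/95% HDIs, ROPE and Rhat."""
        rows = []
        for nm in self.model.term_names:
            d = self.coef_draws(nm)
            lo50, hi50 = hdi(d, 0.50)
            lo89, hi89 = hdi(d, 0.89)
            lo95, hi95 = hdi(d, 0.95)
            rows.append({
                "term": nm, "median": float(np.median(d)),
                "hdi50_l": lo50, "hdi50_h": hi50,
                "hdi89_l": lo89, "hdi89_h": hi89,
                "hdi95_l": lo95, "hdi95_h": hi95,
                "rope": self.rope(nm), "pd": prob_direction(d),
                "rhat": self.rhat[nm],
            })
        return pd.DataFrame(rows).set_index("term")

    def loo(self, chains: int = 2, iterations: int = 800, seed: int = 0):
        """Exact leave-one-out cross-validation by refitting (see loo module)."""
        from .loo import exact_loo

        return exact_loo(self.model, chains=chains, iterations=iterations,
                         seed=seed)
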