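"""Phylogenetic diversity of plot censuses and phylogenetic signal of traits.

Communities are scored on an ultrametric tree by mean pairwise patristic
distance (MPD, basal-area weighted), mean nearest-taxon distance (MNTD) and
Faith's PD (root-inclusive). A frequency null model randomizes each species'
abundances across the plots where it occurs to standardize MPD. Blomberg's K
measures phylogenetic signal of a numeric trait against the Brownian-motion
expectation; its significance comes from tip randomization.
"""

from __future__ import annotations

import logging


import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

logger = logging.getLogger(__name__)

__all__ = [
    "Phylogeny",
    "MissingTipError",
    "patristic_matrix",
    "mpd",
    "mntd",
    "faith_pd",
    "frequency_null",
    "blomberg_k",
    "k_significance",
]

ULTRAMETRIC_TOL = 1e-6


class MissingTipError(KeyError):
    """Raised when community species cannot be resolved to tree tips."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(f"species not found among tree tips: {self.missing}")


class Phylogeny:
    """Ultrametric labelled tree with cached distance structures.

    Wraps a :class:`dendropy.Tree`; tip labels must be unique. A warning
    (not an error) is logged when root-to-tip depths differ by more than
    ``1e-6`` relative to tree height.
    """

    def __init__(self, tree: dendropy.Tree):
        tree = tree.clone(depth=1)
        self._tree = tree
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValueError("tip labels are not unique")
        self.tip_labels = labels
        self._index = {lab: i for i, lab in enumerate(labels)}
        self._build_caches()

    # -- construction / serialization -------------------------------------
    @classmethod
    def from_newick(cls, source: str, *, is_path: bool = True) -> "Phylogeny":
        kwargs = {"path" if is_path else "data": source}
        tree = dendropy.Tree.get(schema="newick", **kwargs)
        return cls(tree)

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        )

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick())

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    # -- cached structures -------------------------------------------------
    def _build_caches(self) -> None:
        tree = self._tree
        n = len(self.tip_labels)
        # node depths from the root and the tip sets below each edge
        depths: dict[int, float] = {}
        tipsets: dict[int, np.ndarray] = {}
        self._edges: list[tuple[float, np.ndarray]] = []
        root = tree.seed_node
        depths[id(root)] = 0.0
        for node in tree.preorder_node_iter():
            if node is not root:
                el = node.edge.length or 0.0
                if el < 0:
                    raise ValueError("negative branch length")
                depths[id(node)] = depths[id(node.parent_node)] + el
        vcv = np.zeros((n, n))
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                i = self._index[node.taxon.label]
                mask = np.zeros(n, dtype=bool)
                mask[i] = True
                tipsets[id(node)] = mask
                vcv[i, i] = depths[id(node)]
            else:
                children = node.child_nodes()
                masks = [tipsets[id(c)] for c in children]
                d = depths[id(node)]
                for a in range(len(masks)):
                    for b in range(a + 1, len(masks)):
                        vcv[np.ix_(masks[a], masks[b])] = d
                        vcv[np.ix_(masks[b], masks[a])] = d
                agg = np.logical_or.reduce(masks)
                tipsets[id(node)] = agg
            if node is not root:
                self._edges.append((node.edge.length or 0.0, tipsets[id(node)]))
        self._tip_depths = np.array([vcv[i, i] for i in range(n)])
        self.vcv = vcv
        td = self._tip_depths
        self._patristic = td[:, None] + td[None, :] - 2 * vcv
        np.fill_diagonal(self._patristic, 0.0)
        self.height = float(td.max()) if n else 0.0
        self.total_length = float(sum(el for el, _ in self._edges))
        spread = float(td.max() - td.min()) if n else 0.0
        self.is_ultrametric = spread <= ULTRAMETRIC_TOL * max(self.height, 1.0)
        if not self.is_ultrametric:
            logger.warning(
                "tree is not ultrametric: root-to-tip depths spread %.3g", spread
            )
        self._chol = None

    def indices(self, species) -> np.ndarray:
        missing = [s for s in species if s not in self._index]
        if missing:
            raise MissingTipError(missing)
        return np.array([self._index[s] for s in species], dtype=int)

    def vcv_solve(self, b: np.ndarray) -> np.ndarray:
        """Solve V x = b against the trait variance-covariance matrix."""
        if self._chol is None:
            self._chol = cho_factor(self.vcv)
        return cho_solve(self._chol, b)


def patristic_matrix(tree: Phylogeny, species: list[str]) -> pd.DataFrame:
    """Tip-to-tip path-length distances for a subset of species."""
    idx = tree.indices(species)
    sub = tree._patristic[np.ix_(idx, idx)]
    return pd.DataFrame(sub, index=list(species), columns=list(species))


def _weights_and_dist(community, tree: Phylogeny):
    sp = community.species
    idx = tree.indices(sp)
    d = tree._patristic[np.ix_(idx, idx)]
    a = community.weight_array(sp)
    return a, d


def mpd(community, tree: Phylogeny, abundance_weighted: bool = True) -> float:
    """Mean pairwise patristic distance of a community.

    Self pairs (i = j) are excluded; with weighting the mean is taken with
    weights ``a_i a_j`` renormalized over the included pairs. Communities of
    fewer than 2 species have no pairs: NaN is returned (recorded missing).
    """
    a, d = _weights_and_dist(community, tree)
    n = len(a)
    if n < 2:
        return float("nan")
    if abundance_weighted:
        num = a @ d @ a
        den = a.sum() ** 2 - np.sum(a**2)
        return float(num / den)
    iu = np.triu_indices(n, k=1)
    return float(d[iu].mean())


def mntd(community, tree: Phylogeny, abundance_weighted: bool = True) -> float:
    """Mean distance of each species to its nearest community relative."""
    a, d = _weights_and_dist(community, tree)
    n = len(a)
    if n < 2:
        return float("nan")
    dd = d + np.diag(np.full(n, np.inf))
    nearest = dd.min(axis=1)
    if abundance_weighted:
        return float(np.sum(a * nearest) / np.sum(a))
    return float(nearest.mean())


def faith_pd(community, tree: Phylogeny) -> float:
    """Total branch length of the root-inclusive subtree spanning the community.

    A single-species community scores its root-to-tip path length.
    """
    idx = tree.indices(community.species)
    if len(idx) == 0:
        raise ValueError("empty community")
    mask = np.zeros(tree.n_tips, dtype=bool)
    mask[idx] = True
    total = 0.0
    for el, tipset in tree._edges:
        if np.any(tipset & mask):
            total += el
    return float(total)


def frequency_null(
    community_matrix: pd.DataFrame,
    tree: Phylogeny,
    n_iter: int = 999,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Standardized effect size of weighted MPD under the frequency null.

    ``community_matrix`` holds plots in rows and species abundances (basal
    area) in columns. Each null iteration permutes every species' abundance
    values among the plots where it occurs, leaving the occurrence pattern
    untouched, and recomputes the abundance-weighted MPD of every plot.
    Returns a frame with observed MPD, null mean/sd and
    ``ses = (obs - null_mean) / null_sd`` per plot; plots whose null sd is
    zero get NaN with a warning.
    """
    if community_matrix.shape[0] < 2:
        raise ValueError("frequency null needs at least 2 plots")
    if n_iter < 99:
        raise ValueError("n_iter must be >= 99")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    species = list(community_matrix.columns)
    idx = tree.indices(species)
    d = tree._patristic[np.ix_(idx, idx)]
    A = community_matrix.to_numpy(dtype=float)

    def weighted_mpd_rows(mat: np.ndarray) -> np.ndarray:
        num = np.einsum("ps,st,pt->p", mat, d, mat)
        den = mat.sum(axis=1) ** 2 - np.sum(mat**2, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0, num / den, np.nan)

    obs = weighted_mpd_rows(A)
    occupied = [np.flatnonzero(A[:, j] > 0) for j in range(A.shape[1])]
    nulls = np.empty((n_iter, A.shape[0]))
    for it in range(n_iter):
        perm = A.copy()
        for j, occ in enumerate(occupied):
            if len(occ) > 1:
                perm[occ, j] = A[rng.permutation(occ), j]
        nulls[it] = weighted_mpd_rows(perm)
    null_mean = np.nanmean(nulls, axis=0)
    null_sd = np.nanstd(nulls, axis=0, ddof=1)
    # a null distribution that is constant up to float jitter has no scale
    degenerate = null_sd <= 1e-12 * np.maximum(np.abs(null_mean), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ses = np.where(~degenerate, (obs - null_mean) / null_sd, np.nan)
    if np.any(degenerate):
        logger.warning(
            "null sd is zero for plots %s; ses recorded missing",
            list(community_matrix.index[degenerate]),
        )
    return pd.DataFrame(
        {
            "mpd_obs": obs,
            "null_mean": null_mean,
            "null_sd": null_sd,
            "ses_mpd": ses,
        },
        index=community_matrix.index,
    )


def _k_batch(tree: Phylogeny, X: np.ndarray) -> np.ndarray:
    """Blomberg's K for each column of an (n_tips, B) trait matrix."""
    n = tree.n_tips
    V = tree.vcv
    ones = np.ones(n)
    Vinv_ones = tree.vcv_solve(ones)
    denom = ones @ Vinv_ones
    ahat = (Vinv_ones @ X) / denom
    resid = X - ahat
    mse0 = np.sum(resid**2, axis=0) / (n - 1)
    mse = np.sum(resid * tree.vcv_solve(resid), axis=0) / (n - 1)
    expected = (np.trace(V) - n / denom) / (n - 1)
    return (mse0 / mse) / expected


def blomberg_k(trait: pd.Series | np.ndarray, tree: Phylogeny) -> float:
    """Blomberg's K phylogenetic-signal statistic of a numeric tip trait.

    K compares the observed ratio of trait variance (around the
    phylogenetically corrected mean) to its tree-structured counterpart with
    the ratio expected under Brownian motion: K of about 1 indicates a
    Brownian level of signal, K near 0 the absence of signal.
    """
    x = _trait_vector(trait, tree)
    if np.ptp(x) == 0:
        raise ValueError("trait has zero variance; K is undefined")
    return float(_k_batch(tree, x[:, None])[0])


def _trait_vector(trait, tree: Phylogeny) -> np.ndarray:
    if isinstance(trait, pd.Series):
        missing = [t for t in tree.tip_labels if t not in trait.index]
        if missing:
            raise MissingTipError(missing)
        x = trait.loc[tree.tip_labels].to_numpy(dtype=float)
    else:
        x = np.asarray(trait, dtype=float)
        if x.shape != (tree.n_tips,):
            raise ValueError("trait vector length does not match tip count")
    if not np.all(np.isfinite(x)):
        raise ValueError("trait contains non-finite values")
    return x


def k_significance(
    trait,
    tree: Phylogeny,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Tip-randomization test of Blomberg's K.

    Shuffles trait values across tips ``n_perm`` times;
    ``p = (1 + #{K_perm >= K_obs}) / (1 + n_perm)``. Returns ``(K, p)``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    x = _trait_vector(trait, tree)
    if np.ptp(x) == 0:
        raise ValueError("trait has zero variance; K is undefined")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    k_obs = float(_k_batch(tree, x[:, None])[0])
    perms = np.column_stack([rng.permutation(x) for _ in range(n_perm)])
    k_perm = _k_batch(tree, perms)
    p = (1.0 + np.sum(k_perm >= k_obs)) / (1.0 + n_perm)
    return k_obs, float(p)
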