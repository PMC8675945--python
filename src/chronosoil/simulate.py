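"""Ground-truth synthetic data for every stage of the analysis chain.

Generators cover: birth-death phylogenies; rarefied-depth OTU count tables
assembled under neutral, habitat-filtering or dispersal-limited regimes
(the regimes the null-model stage is designed to tell apart); compositional
counts with planted basis correlations (the sparCC test substrate); and
enzyme-activity profiles with a controllable stoichiometry vector.  All
generators are pure functions of (parameters, seed).

The habitat-filtering regime evolves a habitat optimum for every taxon by
Brownian motion along the tree, so that ecologically similar taxa are
phylogenetically close — the niche conservatism without which a
tip-shuffling phylogenetic null has no power.  Per-sample taxon weights are
Gaussian in the distance between the sample's environment value and the
taxon's optimum.  The default sequencing depth is 6,996 reads per sample,
a typical rarefaction depth for soil 16S surveys.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from dendropy.simulate import treesim
from skbio import TreeNode

from .io import ENZYMES

DEFAULT_DEPTH = 6996

REGIME_MODES = ("neutral", "habitat_filtering", "dispersal_limited")


@dataclass
class AssemblyRegime:
    """Parameters of one community-assembly scenario.

    ``niche_conservatism`` is the Brownian-motion rate (trait variance per
    unit branch length) of habitat-optimum evolution; ``selection_strength``
    is the width (sd) of the Gaussian fitness kernel around each taxon's
    optimum — smaller means stronger environmental filtering.
    ``dispersal_concentration`` is the Dirichlet concentration of per-sample
    metacommunities in the dispersal-limited mode; values far below the
    taxon count give strong local drift.
    """
    mode: str = "neutral"
    n_samples: int = 12
    n_otus: int = 600
    depth: int = DEFAULT_DEPTH
    environment: np.ndarray | None = None
    niche_conservatism: float = 1.0
    selection_strength: float = 0.05
    dispersal_concentration: float = 2.0
    metacommunity_log_sd: float = 2.5
    overdispersion: float | None = None  # Dirichlet-multinomial, off by default

    def __post_init__(self):
        if self.mode not in REGIME_MODES:
            raise ValueError(f"unknown mode {self.mode!r}; one of {REGIME_MODES}")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.n_otus < 4:
            raise ValueError("n_otus must be >= 4")
        if self.mode == "habitat_filtering" and self.selection_strength <= 0:
            raise ValueError("selection_strength must be > 0 for habitat_filtering")


@dataclass
class NetworkTruth:
    """Planted basis-correlation structure for compositional count data."""
    correlation: np.ndarray
    modules: np.ndarray = field(default=None)

    def __post_init__(self):
        c = np.asarray(self.correlation, dtype=float)
        if c.shape[0] != c.shape[1] or not np.allclose(c, c.T, atol=1e-10):
            raise ValueError("correlation matrix must be square and symmetric")
        if not np.allclose(np.diag(c), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(c).min() < -1e-8:
            raise ValueError("correlation matrix is not positive semidefinite")
        self.correlation = c
        if self.modules is None:
            self.modules = np.zeros(c.shape[0], dtype=int)


def simulate_tree(n_otus: int, birth_rate: float = 1.0, death_rate: float = 0.0,
                  seed=None) -> TreeNode:
    """Rooted ultrametric birth-death tree with ``n_otus`` extant tips.

    Tips are labelled OTU0001..; branch lengths are in expected-speciation
    time units.  Deterministic under ``seed``.
    """
    if n_otus < 2:
        raise ValueError("need at least 2 tips")
    if not birth_rate > death_rate >= 0:
        raise ValueError("need birth_rate > death_rate >= 0")
    if seed is None:
        seed_int = None
    elif isinstance(seed, np.random.SeedSequence):
        seed_int = int(seed.generate_state(1)[0])
    else:
        seed_int = int(np.random.SeedSequence(seed).generate_state(1)[0])
    rng = random.Random(seed_int)
    dtree = treesim.birth_death_tree(
        birth_rate=birth_rate, death_rate=death_rate,
        num_extant_tips=n_otus, rng=rng,
    )
    for i, leaf in enumerate(dtree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"OTU{i:04d}"
    newick = dtree.as_string(schema="newick", suppress_rooting=True).strip()
    tree = TreeNode.read([newick])
    if tree.length is None:
        tree.length = 0.0
    return tree


def brownian_traits(tree: TreeNode, rate: float, seed=None) -> pd.Series:
    """Evolve a trait by Brownian motion along the tree; returns tip values.

    Each branch adds a Normal(0, rate * branch_length) increment from the
    root value 0.
    """
    rng = np.random.default_rng(seed)
    values = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        parent_val = values[id(node.parent)]
        bl = node.length or 0.0
        values[id(node)] = parent_val + rng.normal(0.0, np.sqrt(max(rate * bl, 0.0)))
    return pd.Series({t.name: values[id(t)] for t in tree.tips()})


def _multinomial_rows(rng, weights: np.ndarray, depth: int,
                      overdispersion: float | None) -> np.ndarray:
    rows = []
    for w in weights:
        p = w / w.sum()
        if overdispersion is not None:
            p = rng.dirichlet(p * overdispersion)
        rows.append(rng.multinomial(depth, p))
    return np.array(rows, dtype=np.int64)


def simulate_communities(tree: TreeNode, regime: AssemblyRegime,
                         seed=None) -> tuple[pd.DataFrame, pd.Series]:
    """OTU count table (rows sum exactly to depth) plus the environment vector.

    * ``neutral`` — every sample is a multinomial draw from one shared
      metacommunity distribution (log-normal species-abundance shape).
    * ``habitat_filtering`` — habitat optima evolve by Brownian motion on
      the tree; per-sample weights are the metacommunity times a Gaussian
      fitness kernel exp(-(env - optimum)^2 / (2 sd^2)).
    * ``dispersal_limited`` — each sample draws its own metacommunity from
      a low-concentration Dirichlet around the shared one (strong local
      drift), then samples multinomially.
    """
    tips = [t.name for t in tree.tips()]
    if len(tips) < regime.n_otus:
        raise ValueError("tree has fewer tips than regime.n_otus")
    otus = tips[: regime.n_otus]
    rng = np.random.default_rng(seed)

    if regime.environment is not None:
        env = np.asarray(regime.environment, dtype=float)
        if len(env) != regime.n_samples:
            raise ValueError("environment vector length must equal n_samples")
    else:
        env = np.linspace(-1.0, 1.0, regime.n_samples)

    # log-normal metacommunity abundance distribution; the wide default
    # log-sd gives the long rare tail of real soil surveys, so samples
    # share their abundant taxa but differ in which rare taxa they catch
    meta = np.exp(rng.normal(0.0, regime.metacommunity_log_sd, size=regime.n_otus))
    meta /= meta.sum()

    if regime.mode == "neutral":
        weights = np.tile(meta, (regime.n_samples, 1))
    elif regime.mode == "habitat_filtering":
        optima = brownian_traits(
            tree, regime.niche_conservatism,
            seed=rng.integers(2 ** 31),
        )[otus].to_numpy()
        # map optima rank-uniformly onto [-1, 1]: the niche axis then has a
        # fixed scale across trees (Brownian optima are typically bimodal
        # across the root split) while phylogenetic conservatism of the
        # ordering is preserved; selection_strength is the Gaussian kernel
        # sd in units of this axis, so 0.1 admits roughly a tenth of it
        ranks = np.argsort(np.argsort(optima)) + 0.5
        optima = 2.0 * ranks / len(optima) - 1.0
        kernel = np.exp(
            -(env[:, None] - optima[None, :]) ** 2
            / (2.0 * regime.selection_strength ** 2)
        )
        weights = meta[None, :] * kernel
        weights = np.where(weights.sum(axis=1, keepdims=True) > 0, weights,
                           meta[None, :])
    else:  # dispersal_limited
        conc = regime.dispersal_concentration
        weights = np.vstack([
            rng.dirichlet(np.maximum(meta * conc, 1e-8))
            for _ in range(regime.n_samples)
        ])
        weights = np.maximum(weights, 1e-12)

    counts = _multinomial_rows(rng, weights, regime.depth, regime.overdispersion)
    # every community must be non-empty; at these depths it always is
    table = pd.DataFrame(
        counts, columns=otus,
        index=[f"S{i + 1:02d}" for i in range(regime.n_samples)],
    )
    return table, pd.Series(env, index=table.index, name="environment")


def simulate_compositional_counts(truth: NetworkTruth, n_samples: int,
                                  depth: int = 5000, seed=None,
                                  log_sd: float = 1.0,
                                  mean_log_abundance: float = 0.0) -> pd.DataFrame:
    """Compositional counts whose basis correlations follow ``truth``.

    Basis abundances are log-normal with the given correlation structure
    (all log-variances log_sd^2), closed to compositions, then multinomially
    sampled at ``depth`` reads per sample.
    """
    if n_samples < 10:
        raise ValueError("need at least 10 samples")
    c = truth.correlation
    d = c.shape[0]
    cov = c * log_sd ** 2
    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal(np.full(d, mean_log_abundance), cov,
                                size=n_samples, method="svd")
    basis = np.exp(z)
    fracs = basis / basis.sum(axis=1, keepdims=True)
    counts = np.array([rng.multinomial(depth, p) for p in fracs], dtype=np.int64)
    return pd.DataFrame(
        counts,
        index=[f"S{i + 1:02d}" for i in range(n_samples)],
        columns=[f"OTU{j + 1:04d}" for j in range(d)],
    )


def block_correlation_truth(n_otus: int, block_sizes, within: float = 0.8,
                            jitter: float = 0.0, seed=None) -> NetworkTruth:
    """Block-structured basis correlations: ``within`` inside blocks, 0 outside.

    Convenience constructor for module-recovery tests; ``jitter`` adds
    small symmetric noise to the within-block entries.  The result is
    nudged to the nearest positive semidefinite matrix if needed.
    """
    rng = np.random.default_rng(seed)
    c = np.eye(n_otus)
    modules = np.zeros(n_otus, dtype=int)
    start = 0
    for b, size in enumerate(block_sizes):
        idx = np.arange(start, start + size)
        for i in idx:
            for j in idx:
                if i < j:
                    val = within + (rng.uniform(-jitter, jitter) if jitter else 0.0)
                    c[i, j] = c[j, i] = np.clip(val, -0.99, 0.99)
        modules[idx] = b
        start += size
    eigmin = np.linalg.eigvalsh(c).min()
    if eigmin < 1e-8:
        c += np.eye(n_otus) * (1e-6 - eigmin)
        dsqrt = np.sqrt(np.diag(c))
        c = c / np.outer(dsqrt, dsqrt)
    return NetworkTruth(correlation=c, modules=modules)


def simulate_enzymes(n_samples: int, target_vector_angle: float,
                     target_vector_length: float, noise_sd: float = 0.0,
                     seed=None, log_c_activity: float = 2.0) -> pd.DataFrame:
    """Enzyme activity table whose noiseless stoichiometry hits a target vector.

    Solves x = L cos A, y = L sin A, fixes ln(BG+CBH) = ``log_c_activity``,
    and sets ln(AP) = ln(BG+CBH)/x and ln(NAG+LAP) = ln(BG+CBH)/y; the two
    enzymes within each group split their sum evenly.  Multiplicative
    log-normal noise of sd ``noise_sd`` is applied per activity.
    """
    if not 0 < target_vector_angle < 90:
        raise ValueError("target_vector_angle must be in (0, 90) degrees")
    if target_vector_length <= 0:
        raise ValueError("target_vector_length must be positive")
    a_rad = np.radians(target_vector_angle)
    x = target_vector_length * np.cos(a_rad)
    y = target_vector_length * np.sin(a_rad)
    ln_c = log_c_activity
    if ln_c <= 0:
        raise ValueError("log_c_activity must be positive")
    ln_ap = ln_c / x
    ln_n = ln_c / y
    if min(ln_ap, ln_n) <= 0:
        raise ValueError("targets imply activities <= 1 in working units")
    c_sum, n_sum, ap = np.exp(ln_c), np.exp(ln_n), np.exp(ln_ap)
    base = {
        "BG": c_sum / 2, "CBH": c_sum / 2,
        "NAG": n_sum / 2, "LAP": n_sum / 2,
        "AP": ap,
    }
    rng = np.random.default_rng(seed)
    rows = {
        e: base[e] * np.exp(rng.normal(0.0, noise_sd, size=n_samples))
        for e in ENZYMES
    }
    return pd.DataFrame(rows, index=[f"S{i + 1:02d}" for i in range(n_samples)])
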