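"""Co-occurrence network analysis for compositional count data.

The chain is: estimate basis correlations between taxa with the sparCC
procedure (log-ratio variances on Dirichlet-smoothed fractions, basis
variances solved under a sparsity assumption, strongly correlated pairs
iteratively excluded from the system); pick the correlation cutoff with the
random-matrix-theory criterion (smallest cutoff at which the thresholded
matrix's nearest-neighbour eigenvalue spacings are Poisson rather than
Wigner-Dyson, i.e. modular signal rather than noise); keep edges passing
both the cutoff and a significance filter; then characterise the graph:
topology summary, greedy modularity modules, and the within-module degree
z-score / participation coefficient (Zi / Pi) node roles with their
keystone interpretation.
"""

from __future__ import annotations

import itertools
import logging
import warnings
import zlib
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Guimera-Amaral style role thresholds on (Zi, Pi).
ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62
KEYSTONE_ROLES = frozenset({"module_hub", "network_hub", "connector"})


# ---------------------------------------------------------------------------
# sparCC
# ---------------------------------------------------------------------------

def _logratio_variance_matrix(fracs: np.ndarray) -> np.ndarray:
    logf = np.log(fracs)
    # var over samples of log(x_i / x_j), all pairs at once
    diff = logf[:, :, None] - logf[:, None, :]
    return diff.var(axis=0, ddof=1)


def _basis_correlations(t: np.ndarray, n_exclusion_rounds: int,
                        exclusion_threshold: float) -> np.ndarray:
    """Solve basis variances from the log-ratio variance matrix ``t``.

    Under the sparsity assumption the row sums of t are linear in the basis
    variances; pairs whose estimated correlation exceeds the exclusion
    threshold are iteratively removed from the system (strongest first).
    """
    d = t.shape[0]
    include = ~np.eye(d, dtype=bool)
    corr = np.eye(d)
    for _ in range(n_exclusion_rounds + 1):
        # linear system: sum_{j in J_i} t_ij = d_i * w_i + sum_{j in J_i} w_j
        m = include.astype(float)
        a = m + np.diag(m.sum(axis=1))
        rhs = (t * m).sum(axis=1)
        try:
            w = np.linalg.solve(a, rhs)
        except np.linalg.LinAlgError:
            break
        w = np.maximum(w, 1e-12)
        sd = np.sqrt(w)
        corr = (w[:, None] + w[None, :] - t) / (2.0 * np.outer(sd, sd))
        np.clip(corr, -1.0, 1.0, out=corr)
        np.fill_diagonal(corr, 1.0)
        # exclude the most correlated still-included pair above the threshold
        masked = np.where(include, np.abs(corr), 0.0)
        np.fill_diagonal(masked, 0.0)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= exclusion_threshold:
            break
        include[i, j] = include[j, i] = False
    return corr


def _sparcc_point_estimate(counts: np.ndarray, rngs, n_inner_iter: int,
                           n_exclusion_rounds: int,
                           exclusion_threshold: float) -> np.ndarray:
    """``rngs`` holds one generator per sample (row), so the Monte Carlo
    draws attach to samples rather than to row positions and the estimate
    is invariant under sample reordering."""
    ests = []
    for _ in range(n_inner_iter):
        # Dirichlet-posterior fraction draw per sample with pseudocount 1
        fracs = np.vstack([rng.dirichlet(row + 1.0)
                           for rng, row in zip(rngs, counts)])
        t = _logratio_variance_matrix(fracs)
        ests.append(_basis_correlations(t, n_exclusion_rounds, exclusion_threshold))
    return np.median(ests, axis=0)


def sparcc(table: pd.DataFrame, n_inner_iter: int = 20,
           n_exclusion_rounds: int = 10, exclusion_threshold: float = 0.1,
           n_bootstrap: int = 100, seed=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """sparCC basis correlations and two-sided null p-values.

    ``table`` is a samples x OTUs count table (>= 10 samples, >= 4 OTUs;
    with fewer taxa the basis-variance system is underdetermined).  The
    point estimate is the median over ``n_inner_iter`` Dirichlet-posterior
    fraction draws.  P-values come from ``n_bootstrap`` null tables built by
    independently shuffling each OTU's counts across samples (destroying
    all between-taxon association while preserving marginals):
    p = (1 + #{|r_null| >= |r_obs|}) / (n_bootstrap + 1), two-sided.
    """
    counts = table.to_numpy(dtype=float)
    n_samples, n_otus = counts.shape
    if n_samples < 10:
        raise ValueError("sparCC needs at least 10 samples")
    if n_otus < 4:
        raise ValueError("sparCC needs at least 4 OTUs (basis system "
                         "underdetermined below that)")
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    entropy = int(ss.generate_state(1)[0])
    # one substream per sample id: the point estimate is then invariant
    # under permutations of the sample (row) order
    sample_rngs = [
        np.random.default_rng(np.random.SeedSequence(
            entropy=entropy, spawn_key=(zlib.crc32(str(sid).encode()),)))
        for sid in table.index
    ]
    corr = _sparcc_point_estimate(counts, sample_rngs, n_inner_iter,
                                  n_exclusion_rounds, exclusion_threshold)

    rng = np.random.default_rng(np.random.SeedSequence(entropy=entropy,
                                                       spawn_key=(0xB007,)))
    exceed = np.zeros((n_otus, n_otus))
    for _ in range(n_bootstrap):
        null_counts = np.column_stack(
            [rng.permutation(counts[:, j]) for j in range(n_otus)]
        )
        null_corr = _sparcc_point_estimate(
            null_counts, [rng] * n_samples, max(1, n_inner_iter // 4),
            n_exclusion_rounds, exclusion_threshold,
        )
        exceed += np.abs(null_corr) >= np.abs(corr)
    pvals = (exceed + 1.0) / (n_bootstrap + 1.0)
    np.fill_diagonal(pvals, 0.0)

    ids = table.columns
    return (pd.DataFrame(corr, index=ids, columns=ids),
            pd.DataFrame(pvals, index=ids, columns=ids))


# ---------------------------------------------------------------------------
# RMT threshold
# ---------------------------------------------------------------------------

def _unfolded_spacings(eigvals: np.ndarray, poly_degree: int = 5) -> np.ndarray:
    """Nearest-neighbour spacings after polynomial unfolding.

    The cumulative spectral density is smoothed with a polynomial fit; the
    unfolded spacings then have unit mean by construction, making the
    Poisson (exponential) vs Wigner-Dyson comparison scale-free.
    """
    lam = np.sort(eigvals)
    n = len(lam)
    if n < 3 or np.ptp(lam) < 1e-10:
        return np.array([])
    cum = (np.arange(1, n + 1) - 0.5) / n
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rank warnings on degenerate spectra
        coeffs = np.polyfit(lam, cum, deg=min(poly_degree, n - 1))
    smooth = np.polyval(coeffs, lam) * n
    spacings = np.diff(smooth)
    spacings = spacings[spacings > 0]
    if len(spacings) == 0:
        return spacings
    return spacings / spacings.mean()


def _poisson_gof_pvalue(spacings: np.ndarray) -> float:
    """Chi-square goodness of fit of unit-mean spacings to the exponential law."""
    n = len(spacings)
    if n < 10:
        return np.nan
    n_bins = int(np.clip(n // 5, 5, 20))
    # equal-probability bins under Exp(1)
    edges = np.append(-np.log(1.0 - np.arange(n_bins) / n_bins), np.inf)
    observed, _ = np.histogram(spacings, bins=edges)
    expected = np.full(n_bins, n / n_bins)
    chi2 = ((observed - expected) ** 2 / expected).sum()
    # one parameter (the mean) fixed by unfolding
    return float(stats.chi2.sf(chi2, df=n_bins - 2))


def rmt_threshold(corr: pd.DataFrame | np.ndarray, scan_range=(0.3, 0.9),
                  step: float = 0.01, alpha: float = 0.05) -> tuple[float, pd.DataFrame]:
    """Random-matrix-theory correlation cutoff.

    Scans cutoffs from low to high; at each, the adjacency keeps |r| >=
    cutoff (weights retained), eigenvalue spacings are unfolded and tested
    against the Poisson (exponential) law.  Returns the smallest cutoff
    whose spacing distribution is consistent with Poisson (GOF p > alpha),
    together with the full scan table (cutoff, edges, p).
    """
    c = np.asarray(corr, dtype=float)
    if c.shape[0] != c.shape[1] or not np.allclose(c, c.T, atol=1e-8):
        raise ValueError("correlation matrix must be square and symmetric")
    if c.shape[0] < 20:
        raise ValueError("matrix too small for spacing statistics (< 20 nodes)")
    lo, hi = scan_range
    cutoffs = np.arange(lo, hi + step / 2, step)
    rows = []
    chosen = None
    for cutoff in cutoffs:
        adj = np.where(np.abs(c) >= cutoff, c, 0.0)
        np.fill_diagonal(adj, 0.0)
        n_edges = int((np.abs(adj[np.triu_indices_from(adj, k=1)]) > 0).sum())
        eig = np.linalg.eigvalsh(adj)
        spacings = _unfolded_spacings(eig)
        p = _poisson_gof_pvalue(spacings)
        rows.append({"cutoff": float(cutoff), "n_edges": n_edges, "poisson_gof_p": p})
        if chosen is None and np.isfinite(p) and p > alpha:
            chosen = float(cutoff)
    scan = pd.DataFrame(rows)
    if chosen is None:
        raise ValueError(
            "no cutoff in the scan range gives Poisson-consistent spacings; "
            "widen the scan range"
        )
    return chosen, scan


# ---------------------------------------------------------------------------
# Graph construction and description
# ---------------------------------------------------------------------------

def build_network(corr: pd.DataFrame, pvals: pd.DataFrame, threshold: float,
                  alpha: float = 0.05) -> nx.Graph:
    """Signed co-occurrence graph: edge iff |r| >= threshold AND p < alpha.

    Isolated nodes are dropped.  Edge attributes: ``weight`` (the signed
    correlation), ``sign`` (+1/-1) and ``p``.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    g = nx.Graph()
    ids = list(corr.index)
    c = corr.to_numpy()
    p = pvals.to_numpy()
    for i, j in itertools.combinations(range(len(ids)), 2):
        if abs(c[i, j]) >= threshold and p[i, j] < alpha:
            g.add_edge(ids[i], ids[j], weight=float(c[i, j]),
                       sign=1 if c[i, j] > 0 else -1, p=float(p[i, j]))
    if g.number_of_edges() == 0:
        logger.warning("no edge passed |r| >= %.4g and p < %.3g", threshold, alpha)
    return g


def positive_link_fraction(g: nx.Graph) -> float:
    if g.number_of_edges() == 0:
        return np.nan
    signs = [d.get("sign", 1 if d.get("weight", 1.0) > 0 else -1)
             for _, _, d in g.edges(data=True)]
    return float(np.mean([s > 0 for s in signs]))


def sample_subnetwork(g: nx.Graph, sample_otus) -> nx.Graph:
    """Induced subgraph on the OTUs present in one sample."""
    nodes = set(sample_otus) & set(g.nodes)
    return g.subgraph(nodes).copy()


@dataclass
class TopologySummary:
    """Global topology descriptors of one (sub)network."""
    n_nodes: int
    n_links: int
    transitivity: float
    average_degree: float
    mean_betweenness: float
    average_path_length: float
    density: float
    positive_link_fraction: float = field(default=np.nan)

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def topology(g: nx.Graph) -> TopologySummary:
    """Topology summary; paths are unweighted, averaged over reachable pairs.

    Graphs with fewer than 2 nodes get NaN for every metric.
    """
    n = g.number_of_nodes()
    e = g.number_of_edges()
    if n < 2:
        return TopologySummary(n, e, *([np.nan] * 5))
    bet = nx.betweenness_centrality(g, normalized=True)
    total_d, total_pairs = 0.0, 0
    for source, lengths in nx.all_pairs_shortest_path_length(g):
        for target, d in lengths.items():
            if target != source:
                total_d += d
                total_pairs += 1
    apl = total_d / total_pairs if total_pairs else np.nan
    return TopologySummary(
        n_nodes=n,
        n_links=e,
        transitivity=nx.transitivity(g),
        average_degree=2.0 * e / n,
        mean_betweenness=float(np.mean(list(bet.values()))),
        average_path_length=apl,
        density=nx.density(g),
        positive_link_fraction=positive_link_fraction(g),
    )


def detect_modules(g: nx.Graph, seed=None) -> tuple[dict, float]:
    """Greedy modularity modules on absolute edge weights.

    Deterministic (the agglomeration is greedy; ``seed`` is accepted for
    interface uniformity).  Module ids are 0-based, ordered by module size
    descending.  Returns (node -> module id, modularity score).
    """
    if g.number_of_nodes() == 0:
        return {}, np.nan
    h = nx.Graph()
    h.add_nodes_from(g.nodes)
    for u, v, d in g.edges(data=True):
        h.add_edge(u, v, weight=abs(d.get("weight", 1.0)))
    if h.number_of_edges() == 0:
        communities = [{n} for n in h.nodes]
    else:
        communities = list(nx.community.greedy_modularity_communities(h, weight="weight"))
    communities.sort(key=lambda c: (-len(c), sorted(map(str, c))))
    membership = {node: i for i, comm in enumerate(communities) for node in comm}
    score = (nx.community.modularity(h, communities, weight="weight")
             if h.number_of_edges() else np.nan)
    return membership, float(score)


def classify_role(zi: float, pi: float) -> str:
    """Exclusive (Zi, Pi) role partition with strict thresholds 2.5 / 0.62.

    network_hub (Zi > 2.5 and Pi > 0.62), module_hub (Zi > 2.5 only),
    connector (Pi > 0.62 only), peripheral otherwise; boundary equality
    falls to the lower role.
    """
    if zi > ZI_THRESHOLD and pi > PI_THRESHOLD:
        return "network_hub"
    if zi > ZI_THRESHOLD:
        return "module_hub"
    if pi > PI_THRESHOLD:
        return "connector"
    return "peripheral"


def zi_pi(g: nx.Graph, modules: dict) -> pd.DataFrame:
    """Within-module degree z-score (Zi), participation coefficient (Pi), role.

    Zi standardises a node's within-module degree against the nodes of its
    own module (modules whose within-module degrees have zero spread give
    Zi = 0 by convention).  Pi = 1 - sum_s (k_is / k_i)^2 over modules s.
    Roles partition the (Zi, Pi) plane exclusively: network_hub (Zi > 2.5 &
    Pi > 0.62), module_hub (Zi > 2.5 & Pi <= 0.62), connector (Zi <= 2.5 &
    Pi > 0.62), peripheral otherwise; boundary equality falls to the lower
    role.  Module hubs, network hubs and connectors are flagged keystone.
    """
    missing = [n for n in g.nodes if n not in modules]
    if missing:
        raise ValueError(f"nodes without module assignment: {missing[:5]}")
    nodes = list(g.nodes)
    within = {}
    per_module_counts = {}
    for node in nodes:
        counts = {}
        for nbr in g.neighbors(node):
            counts[modules[nbr]] = counts.get(modules[nbr], 0) + 1
        per_module_counts[node] = counts
        within[node] = counts.get(modules[node], 0)

    module_stats = {}
    for m in set(modules[n] for n in nodes):
        ks = np.array([within[n] for n in nodes if modules[n] == m], dtype=float)
        module_stats[m] = (ks.mean(), ks.std(ddof=0))

    rows = []
    for node in nodes:
        k = g.degree(node)
        mean, sd = module_stats[modules[node]]
        if sd > 0:
            zi = (within[node] - mean) / sd
        else:
            zi = 0.0
        if k > 0:
            pi = 1.0 - sum((c / k) ** 2 for c in per_module_counts[node].values())
        else:
            pi = 0.0
        role = classify_role(zi, pi)
        rows.append({"otu": node, "module": modules[node], "Zi": zi, "Pi": pi,
                     "role": role, "keystone": role in KEYSTONE_ROLES})
    columns = ["otu", "module", "Zi", "Pi", "role", "keystone"]
    return pd.DataFrame(rows, columns=columns).set_index("otu")


def write_edge_list(g: nx.Graph, path) -> None:
    rows = [{"source": u, "target": v, "weight": d["weight"],
             "sign": d["sign"], "p": d.get("p", np.nan)}
            for u, v, d in g.edges(data=True)]
    pd.DataFrame(rows, columns=["source", "target", "weight", "sign", "p"]).to_csv(
        path, sep="\t", index=False)


def write_graphml(g: nx.Graph, path) -> None:
    """GraphML export for external visualisers (Gephi, Cytoscape)."""
    nx.write_graphml(g, path)
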