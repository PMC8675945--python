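"""Null-model inference of community assembly processes.

The turnover between each pair of communities is scored twice:

* phylogenetically, by the between-community mean nearest taxon distance
  (betaMNTD) and its z-score against a tip-label-shuffling null, the
  beta nearest taxon index (betaNTI);
* taxonomically, by the Raup-Crick metric on Bray-Curtis distances
  (RC_bray), the probability-rescaled deviation of the observed
  dissimilarity from a stochastic-assembly null, in [-1, 1].

The two indices combine into the five-process classification:
|betaNTI| > 2 flags selection (variable if > +2, homogeneous if < -2);
otherwise RC_bray < -0.95 flags homogenizing dispersal, RC_bray > +0.95
dispersal limitation, and the remainder is undominated.  Boundary values
(betaNTI exactly +/-2, RC exactly +/-0.95) fall on the undominated side,
matching the strict inequalities of the rule.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

PROCESSES = (
    "variable_selection",
    "homogeneous_selection",
    "homogenizing_dispersal",
    "dispersal_limitation",
    "undominated",
)


def patristic_distances(tree: TreeNode, otu_ids) -> np.ndarray:
    """Tip-to-tip branch-length distances, ordered as ``otu_ids``."""
    tips = {t.name for t in tree.tips()}
    missing = [o for o in otu_ids if o not in tips]
    if missing:
        raise ValueError(f"OTUs absent from the tree: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    dm = tree.tip_tip_distances(endpoints=list(otu_ids))
    return dm.data


def _bmntd_pair(dist: np.ndarray, idx_a, w_a, idx_b, w_b) -> float:
    # mean distance from each taxon to its nearest relative in the other
    # community, abundance weighted, averaged over both directions
    sub = dist[np.ix_(idx_a, idx_b)]
    return 0.5 * (sub.min(axis=1) @ w_a + sub.min(axis=0) @ w_b)


def _sample_support(table: pd.DataFrame, weighted: bool):
    """Per-sample (present-OTU index array, relative-abundance weights)."""
    counts = table.to_numpy(dtype=float)
    support = []
    for row in counts:
        idx = np.flatnonzero(row > 0)
        if weighted:
            w = row[idx] / row[idx].sum()
        else:
            w = np.full(len(idx), 1.0 / len(idx))
        support.append((idx, w))
    return support


def bmntd(table: pd.DataFrame, tree: TreeNode, weighted: bool = True) -> pd.DataFrame:
    """Between-community mean nearest taxon distance for all sample pairs.

    ``weighted`` (default) weights each taxon's nearest-relative distance
    by its relative abundance within its own community.
    """
    dist = patristic_distances(tree, table.columns)
    support = _sample_support(table, weighted)
    n = len(support)
    out = np.zeros((n, n))
    for k, l in itertools.combinations(range(n), 2):
        ia, wa = support[k]
        ib, wb = support[l]
        out[k, l] = out[l, k] = _bmntd_pair(dist, ia, wa, ib, wb)
    return pd.DataFrame(out, index=table.index, columns=table.index)


def bnti(table: pd.DataFrame, tree: TreeNode, n_null: int = 999,
         seed=None, weighted: bool = True) -> pd.DataFrame:
    """Beta nearest taxon index: z-score of betaMNTD against a tip-shuffle null.

    The null randomises phylogenetic relationships by shuffling tip labels
    across the entire tree (equivalently, permuting the rows/columns of the
    patristic distance matrix) while holding the abundance table fixed.
    Pairs whose null distribution has zero spread get NaN and a warning.
    """
    if n_null < 99:
        raise ValueError("n_null must be at least 99")
    rng = np.random.default_rng(seed)
    dist = patristic_distances(tree, table.columns)
    support = _sample_support(table, weighted)
    n = len(support)
    pairs = list(itertools.combinations(range(n), 2))

    obs = np.array([_bmntd_pair(dist, *support[k], *support[l]) for k, l in pairs])
    n_otus = dist.shape[0]
    perms = np.vstack([rng.permutation(n_otus) for _ in range(n_null)])
    nulls = np.empty((n_null, len(pairs)))
    chunk = max(1, int(2e7 // max(1, n_otus * n_otus)))  # bound temp memory
    for p, (k, l) in enumerate(pairs):
        ia, wa = support[k]
        ib, wb = support[l]
        for start in range(0, n_null, chunk):
            pr = perms[start:start + chunk]
            sub = dist[pr[:, ia][:, :, None], pr[:, ib][:, None, :]]
            nulls[start:start + chunk, p] = 0.5 * (
                sub.min(axis=2) @ wa + sub.min(axis=1) @ wb
            )

    mean = nulls.mean(axis=0)
    sd = nulls.std(axis=0, ddof=1)
    z = np.full(len(pairs), np.nan)
    ok = sd > 0
    z[ok] = (obs[ok] - mean[ok]) / sd[ok]
    if (~ok).any():
        logger.warning("betaNTI undefined (zero null spread) for %d pair(s)",
                       (~ok).sum())

    out = np.zeros((n, n))
    for p, (k, l) in enumerate(pairs):
        out[k, l] = out[l, k] = z[p]
    np.fill_diagonal(out, 0.0)
    return pd.DataFrame(out, index=table.index, columns=table.index)


def _bray_curtis_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    num = np.abs(x - y).sum(axis=-1)
    den = (x + y).sum(axis=-1)
    return np.divide(num, den, out=np.full(num.shape, np.nan), where=den > 0)


def _null_community(rng, n_otus: int, richness: int, total: int,
                    occ_p: np.ndarray, pool_rel: np.ndarray) -> np.ndarray:
    """One stochastic-assembly null community (richness and total preserved)."""
    out = np.zeros(n_otus, dtype=np.int64)
    chosen = rng.choice(n_otus, size=richness, replace=False, p=occ_p)
    out[chosen] = 1
    extra = total - richness
    if extra > 0:
        p = pool_rel[chosen]
        out[chosen] += rng.multinomial(extra, p / p.sum())
    return out


def stochastic_null_table(table: pd.DataFrame, seed=None,
                          occupancy_weights=None, pool_abundance=None) -> pd.DataFrame:
    """One realisation of the Raup-Crick stochastic-assembly null per sample.

    Useful as a ground-truth generator for calibration checks: data produced
    by the null process (with the same known pool passed to
    :func:`raup_crick_bray`) yields approximately uniform RC values.
    """
    counts = np.round(table.to_numpy()).astype(np.int64)
    rng = np.random.default_rng(seed)
    if occupancy_weights is None:
        occupancy_weights = (counts > 0).sum(axis=0).astype(float)
    if pool_abundance is None:
        pool_abundance = counts.sum(axis=0).astype(float)
    pool_rel = np.asarray(pool_abundance, dtype=float)
    pool_rel = pool_rel / pool_rel.sum()
    occ_p = np.asarray(occupancy_weights, dtype=float)
    occ_p = occ_p / occ_p.sum()
    rows = [
        _null_community(rng, counts.shape[1], int((row > 0).sum()),
                        int(row.sum()), occ_p, pool_rel)
        for row in counts
    ]
    return pd.DataFrame(np.array(rows), index=table.index, columns=table.columns)


def raup_crick_bray(table: pd.DataFrame, n_null: int = 999, seed=None,
                    occupancy_weights=None, pool_abundance=None) -> pd.DataFrame:
    """Raup-Crick metric on Bray-Curtis distances, rescaled to [-1, 1].

    For each sample the null draws its observed richness from the species
    pool with selection probability proportional to occupancy frequency,
    then fills up to the sample's observed total abundance with reads drawn
    proportionally to pool-wide relative abundance (each selected species
    seeded with one read).  RC = 2 * ((#null BC < observed BC) + 0.5 * ties)
    / n_null - 1; ties count half, the standard convention.

    By default the species pool (occupancy and relative abundance per OTU)
    is estimated from ``table`` itself; ``occupancy_weights`` and
    ``pool_abundance`` override it when a larger survey defines the pool.
    """
    if n_null < 99:
        raise ValueError("n_null must be at least 99")
    counts = table.to_numpy()
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("Raup-Crick null model needs integer counts")
    counts = np.round(counts).astype(np.int64)
    rng = np.random.default_rng(seed)

    n_samples, n_otus = counts.shape
    if occupancy_weights is None:
        occupancy_weights = (counts > 0).sum(axis=0).astype(float)
    if pool_abundance is None:
        pool_abundance = counts.sum(axis=0).astype(float)
    pool_rel = np.asarray(pool_abundance, dtype=float)
    pool_rel = pool_rel / pool_rel.sum()
    occ_p = np.asarray(occupancy_weights, dtype=float)
    occ_p = occ_p / occ_p.sum()

    # one set of n_null null communities per sample, shared across pairs
    null_tables = np.zeros((n_samples, n_null, n_otus), dtype=np.int64)
    for s in range(n_samples):
        richness = int((counts[s] > 0).sum())
        total = int(counts[s].sum())
        for r in range(n_null):
            null_tables[s, r] = _null_community(rng, n_otus, richness, total,
                                                occ_p, pool_rel)

    out = np.zeros((n_samples, n_samples))
    for k, l in itertools.combinations(range(n_samples), 2):
        obs = _bray_curtis_rows(counts[k].astype(float), counts[l].astype(float))
        null_bc = _bray_curtis_rows(null_tables[k].astype(float),
                                    null_tables[l].astype(float))
        below = (null_bc < obs).sum()
        ties = np.isclose(null_bc, obs).sum()
        rc = 2.0 * (below + 0.5 * ties) / n_null - 1.0
        out[k, l] = out[l, k] = rc
    return pd.DataFrame(out, index=table.index, columns=table.index)


def classify_assembly(bnti_value: float, rc_value: float) -> str | float:
    """Five-way assembly-process label from one (betaNTI, RC_bray) pair.

    NaN betaNTI propagates to a NaN label.
    """
    if np.isnan(bnti_value):
        return np.nan
    if not -1.0 - 1e-12 <= rc_value <= 1.0 + 1e-12:
        raise ValueError(f"RC_bray outside [-1, 1]: {rc_value}")
    if bnti_value > 2:
        return "variable_selection"
    if bnti_value < -2:
        return "homogeneous_selection"
    if rc_value < -0.95:
        return "homogenizing_dispersal"
    if rc_value > 0.95:
        return "dispersal_limitation"
    return "undominated"


def pairwise_assembly(bnti_matrix: pd.DataFrame, rc_matrix: pd.DataFrame,
                      bmntd_matrix: pd.DataFrame | None = None) -> pd.DataFrame:
    """Long-format per-pair table with betaNTI, RC_bray and the process label."""
    samples = list(bnti_matrix.index)
    rows = []
    for k, l in itertools.combinations(range(len(samples)), 2):
        si, sj = samples[k], samples[l]
        b = bnti_matrix.iloc[k, l]
        r = rc_matrix.iloc[k, l]
        rows.append({
            "sample_i": si,
            "sample_j": sj,
            "bmntd": np.nan if bmntd_matrix is None else bmntd_matrix.iloc[k, l],
            "bnti": b,
            "rc_bray": r,
            "process": classify_assembly(b, r),
        })
    return pd.DataFrame(rows)


def process_fractions(pair_labels: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-group fractions of the five assembly processes over within-group pairs.

    ``pair_labels`` needs columns sample_i, sample_j, process; ``groups``
    maps sample id to group (e.g. stand-age class).  Between-group pairs and
    NaN labels are excluded; groups contributing fewer than one within-group
    pair are skipped with a warning.  Adds the derived columns
    deterministic (= variable + homogeneous selection) and stochastic
    (= homogenizing dispersal + dispersal limitation).
    """
    rows = {}
    for group in pd.unique(groups):
        members = set(groups.index[groups == group])
        if len(members) < 2:
            logger.warning("group %r has < 2 samples; skipped", group)
            continue
        mask = pair_labels["sample_i"].isin(members) & pair_labels["sample_j"].isin(members)
        labels = pair_labels.loc[mask, "process"].dropna()
        if labels.empty:
            logger.warning("group %r has no classified within-group pairs", group)
            continue
        frac = labels.value_counts(normalize=True)
        row = {p: float(frac.get(p, 0.0)) for p in PROCESSES}
        row["deterministic"] = row["variable_selection"] + row["homogeneous_selection"]
        row["stochastic"] = row["homogenizing_dispersal"] + row["dispersal_limitation"]
        row["n_pairs"] = int(labels.size)
        rows[group] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "group"
    return out


def mantel(x: np.ndarray, y: np.ndarray, n_perm: int = 999, seed=None,
           alternative: str = "greater") -> tuple[float, float]:
    """Mantel test: Pearson correlation of two square symmetric matrices.

    The correlation is computed over the lower-triangle entries; the p-value
    permutes rows and columns of ``y`` simultaneously.  ``alternative`` is
    ``greater`` (default, upper tail), ``less`` or ``two-sided``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.shape[0] != x.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    n = x.shape[0]
    tri = np.tril_indices(n, k=-1)
    xv = x[tri]
    if np.std(xv) == 0 or np.std(y[tri]) == 0:
        raise ValueError("zero-variance distance matrix")
    r_obs = np.corrcoef(xv, y[tri])[0, 1]
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm = np.corrcoef(xv, y[np.ix_(perm, perm)][tri])[0, 1]
        if alternative == "greater":
            hits += r_perm >= r_obs
        elif alternative == "less":
            hits += r_perm <= r_obs
        else:
            hits += abs(r_perm) >= abs(r_obs)
    p = (hits + 1) / (n_perm + 1)
    return float(r_obs), float(p)


def mantel_env(bnti_matrix: pd.DataFrame, metadata: pd.DataFrame, variable: str,
               n_perm: int = 999, seed=None) -> tuple[float, float]:
    """Mantel test of betaNTI against the Euclidean distance of one soil variable.

    Samples with a missing value for ``variable`` are dropped (logged).
    """
    if variable not in metadata.columns:
        raise ValueError(f"variable {variable!r} not in metadata")
    values = metadata.loc[bnti_matrix.index, variable].astype(float)
    keep = values.notna()
    if keep.sum() < 4:
        raise ValueError(f"fewer than 4 samples with non-missing {variable!r}")
    if (~keep).any():
        logger.info("dropping %d sample(s) with missing %s", (~keep).sum(), variable)
    v = values[keep].to_numpy()
    env_dist = np.abs(v[:, None] - v[None, :])
    sub = bnti_matrix.loc[keep, keep].to_numpy()
    return mantel(sub, env_dist, n_perm=n_perm, seed=seed, alternative="greater")
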