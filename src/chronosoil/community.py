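"""Community statistics: rarefaction, alpha diversity, ordination, dispersion, RDA.

Distances are Bray-Curtis unless stated otherwise; ordination is classical
principal coordinates (Gower double-centering, negative eigenvalues
reported rather than corrected); group dispersion homogeneity is tested by
the permutational analysis of multivariate dispersions (PERMDISP) around
group centroids, with the standard imaginary-axis correction for
non-Euclidean distances.  Redundancy analysis regresses the (by default
Hellinger-transformed) community matrix on standardised environmental
predictors and scores each predictor by its marginal permutation F-test.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)


def rarefy(table: pd.DataFrame, depth: int, seed=None) -> pd.DataFrame:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` total reads are dropped with a
    warning.  Draws are multivariate hypergeometric, so the expected
    rarefied count of an OTU is depth * count / total.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    counts = table.to_numpy()
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("rarefaction needs integer counts")
    counts = np.round(counts).astype(np.int64)
    rng = np.random.default_rng(seed)
    keep, rows = [], []
    for i, row in enumerate(counts):
        total = int(row.sum())
        if total < depth:
            logger.warning("sample %r has %d < %d reads; dropped",
                           table.index[i], total, depth)
            continue
        keep.append(table.index[i])
        rows.append(row if total == depth
                    else rng.multivariate_hypergeometric(row, depth))
    return pd.DataFrame(np.array(rows, dtype=np.int64), index=keep,
                        columns=table.columns)


def alpha_diversity(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample richness (observed OTUs) and Shannon index (natural log)."""
    counts = table.to_numpy(dtype=float)
    richness = (counts > 0).sum(axis=1).astype(float)
    totals = counts.sum(axis=1)
    shannon = np.full(len(totals), np.nan)
    for i, row in enumerate(counts):
        if totals[i] == 0:
            logger.warning("sample %r is all-zero; alpha diversity NA",
                           table.index[i])
            richness[i] = np.nan
            continue
        p = row[row > 0] / totals[i]
        shannon[i] = float(-(p * np.log(p)).sum())
    return pd.DataFrame({"richness": richness, "shannon": shannon},
                        index=table.index)


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity: sum|x-y| / sum(x+y), in [0, 1]."""
    counts = table.to_numpy(dtype=float)
    if (counts < 0).any():
        raise ValueError("abundances must be non-negative")
    dm = squareform(pdist(counts, metric="braycurtis"))
    return pd.DataFrame(dm, index=table.index, columns=table.index)


def pcoa(distances: pd.DataFrame | np.ndarray, n_axes: int | None = None):
    """Classical principal coordinates analysis (metric MDS).

    Gower double-centering followed by an eigendecomposition.  Coordinates
    are returned for axes with positive eigenvalues (scaled by sqrt of the
    eigenvalue); negative eigenvalues are reported, not corrected.

    Returns (coordinates DataFrame, eigenvalues, proportion_explained),
    with axes ordered by non-increasing eigenvalue.  Proportions are taken
    relative to the sum of positive eigenvalues.
    """
    if isinstance(distances, pd.DataFrame):
        ids = list(distances.index)
        d = distances.to_numpy(dtype=float)
    else:
        d = np.asarray(distances, dtype=float)
        ids = list(range(d.shape[0]))
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    n = d.shape[0]
    a = -0.5 * d ** 2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = centering @ a @ centering
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-10
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    if n_axes is not None:
        coords = coords[:, :n_axes]
    pos_sum = eigvals[pos].sum()
    prop = eigvals / pos_sum if pos_sum > 0 else np.zeros_like(eigvals)
    coords_df = pd.DataFrame(
        coords, index=ids,
        columns=[f"PCo{i + 1}" for i in range(coords.shape[1])],
    )
    return coords_df, eigvals, prop


def _dispersion_embedding(d: np.ndarray):
    """Full-dimension PCoA embedding split into real and imaginary parts.

    Axes with negative eigenvalues contribute imaginary coordinates; squared
    distances on those axes are subtracted (the standard correction for
    non-Euclidean dissimilarities).
    """
    n = d.shape[0]
    a = -0.5 * d ** 2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = centering @ a @ centering
    eigvals, eigvecs = np.linalg.eigh(b)
    pos = eigvals > 1e-9
    neg = eigvals < -1e-9
    real = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    imag = eigvecs[:, neg] * np.sqrt(-eigvals[neg])
    return real, imag


def _centroid_distances(real: np.ndarray, imag: np.ndarray,
                        groups: np.ndarray, centroid: bool = True) -> np.ndarray:
    dists = np.empty(real.shape[0])
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        if centroid:
            c_real = real[idx].mean(axis=0)
            c_imag = imag[idx].mean(axis=0) if imag.size else imag[:0]
        else:  # spatial median location estimate per coordinate
            c_real = np.median(real[idx], axis=0)
            c_imag = np.median(imag[idx], axis=0) if imag.size else imag[:0]
        sq = ((real[idx] - c_real) ** 2).sum(axis=1)
        if imag.size:
            sq = sq - ((imag[idx] - c_imag) ** 2).sum(axis=1)
        dists[idx] = np.sqrt(np.maximum(sq, 0.0))
    return dists


def _anova_f(d: np.ndarray, groups: np.ndarray) -> float:
    grand = d.mean()
    ssb = ssw = 0.0
    k = 0
    for g in np.unique(groups):
        vals = d[groups == g]
        ssb += len(vals) * (vals.mean() - grand) ** 2
        ssw += ((vals - vals.mean()) ** 2).sum()
        k += 1
    n = len(d)
    if ssw == 0:
        return np.inf if ssb > 0 else np.nan
    return (ssb / (k - 1)) / (ssw / (n - k))


def permdisp(distances: pd.DataFrame, groups: pd.Series, n_perm: int = 999,
             seed=None, centroid: bool = True) -> dict:
    """Homogeneity of multivariate dispersions around group centroids.

    F is the one-way ANOVA statistic on the samples' distances to their own
    group centroid; the p-value permutes group labels, recomputing the
    centroids and distances under every relabelling (the statistic is
    recomputed wholly, not approximated by shuffling the observed
    distances).  Returns the F statistic, permutation p, the per-sample
    distances, and the per-group mean centroid distance (the dispersion
    index table commonly reported alongside the test).
    """
    g = groups.loc[distances.index].to_numpy()
    labels, counts = np.unique(g, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        small = labels[counts < 2].tolist()
        raise ValueError(f"group(s) with fewer than 2 samples: {small}")
    d = distances.to_numpy(dtype=float)
    real, imag = _dispersion_embedding(d)
    dist_to_centroid = _centroid_distances(real, imag, g, centroid=centroid)
    f_obs = _anova_f(dist_to_centroid, g)

    rng = np.random.default_rng(seed)
    n = len(dist_to_centroid)
    exceed = 0
    for _ in range(n_perm):
        perm_g = g[rng.permutation(n)]
        perm_d = _centroid_distances(real, imag, perm_g, centroid=centroid)
        if _anova_f(perm_d, perm_g) >= f_obs:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)

    group_means = pd.Series(
        {lab: dist_to_centroid[g == lab].mean() for lab in labels},
        name="mean_centroid_distance",
    )
    return {
        "F": float(f_obs),
        "p": float(p),
        "distances": pd.Series(dist_to_centroid, index=distances.index),
        "group_mean_distances": group_means,
        "n_perm": n_perm,
    }


def hellinger(table: pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform: square root of within-sample relative abundance."""
    counts = table.to_numpy(dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    return pd.DataFrame(np.sqrt(counts / totals), index=table.index,
                        columns=table.columns)


def rda(table: pd.DataFrame, predictors: pd.DataFrame, n_perm: int = 999,
        seed=None, hellinger_transform: bool = True) -> dict:
    """Redundancy analysis of a community table on environmental predictors.

    The community matrix is Hellinger-transformed by default and centred;
    predictors are standardised.  Each predictor gets a marginal F (its
    added explained variance given all others, over the full-model residual
    variance) with a permutation p-value obtained by permuting the rows of
    the response.  Collinear predictors (design condition number > 1e8) are
    rejected.
    """
    samples = table.index.intersection(predictors.index)
    pred = predictors.loc[samples].astype(float).dropna(axis=0)
    y_tab = table.loc[pred.index]
    y = (hellinger(y_tab) if hellinger_transform else y_tab).to_numpy(dtype=float)
    y = y - y.mean(axis=0)
    x = pred.to_numpy()
    if x.size:
        sd = x.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = pred.columns[sd == 0].tolist()
            raise ValueError(f"constant predictor(s): {bad}")
        x = (x - x.mean(axis=0)) / sd
        if np.linalg.cond(x) > 1e8:
            corr = np.corrcoef(x, rowvar=False)
            i, j = max(itertools.combinations(range(x.shape[1]), 2),
                       key=lambda ij: abs(corr[ij]))
            raise ValueError(
                "collinear predictors: "
                f"{pred.columns[i]!r} and {pred.columns[j]!r}"
            )

    total_ss = (y ** 2).sum()
    n, p = y.shape[0], x.shape[1] if x.size else 0

    def explained_ss(design: np.ndarray, resp: np.ndarray) -> float:
        if design.size == 0:
            return 0.0
        beta, *_ = np.linalg.lstsq(design, resp, rcond=None)
        return float(((design @ beta) ** 2).sum())

    full_ss = explained_ss(x, y)
    resid_df = n - p - 1
    resid_ms = (total_ss - full_ss) / resid_df if resid_df > 0 else np.nan

    # constrained ordination axes of the fitted values
    if p:
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        fitted = x @ beta
        u, s, vt = np.linalg.svd(fitted, full_matrices=False)
        eigvals = (s ** 2) / max(n - 1, 1)
        site_scores = pd.DataFrame(
            (u * s)[:, :p], index=pred.index,
            columns=[f"RDA{i + 1}" for i in range(p)],
        )
    else:
        eigvals = np.array([])
        site_scores = pd.DataFrame(index=pred.index)

    rng = np.random.default_rng(seed)
    per_predictor = {}
    for j, name in enumerate(pred.columns):
        reduced = np.delete(x, j, axis=1)
        added = full_ss - explained_ss(reduced, y)
        f_obs = (added / 1.0) / resid_ms
        hits = 0
        for _ in range(n_perm):
            yp = y[rng.permutation(n)]
            full_p = explained_ss(x, yp)
            added_p = full_p - explained_ss(reduced, yp)
            resid_p = (total_ss - full_p) / resid_df
            hits += (added_p / resid_p) >= f_obs
        per_predictor[name] = {"F": float(f_obs), "p": (hits + 1) / (n_perm + 1)}

    return {
        "constrained_ss": full_ss,
        "total_ss": total_ss,
        "proportion_constrained": full_ss / total_ss if total_ss > 0 else np.nan,
        "eigenvalues": eigvals,
        "site_scores": site_scores,
        "per_predictor": pd.DataFrame(per_predictor).T,
        "n_perm": n_perm,
    }
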