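"""Eco-enzymatic stoichiometry: activity ratios, vector analysis, limitation classes.

Five hydrolases summarise microbial investment into resource acquisition:
BG and CBH (carbon), NAG and LAP (nitrogen), AP (phosphorus).  Two summaries
of the same activities are provided:

* the C:N / C:P / N:P activity ratios, plotted as N:P versus C:N to place a
  sample in one of four limitation quadrants (P, N, C&P, N&P);
* the vector representation of the log-transformed activities, where vector
  length indexes C limitation and vector angle discriminates P (> 45 deg)
  from N (< 45 deg) limitation.

The vector coordinates are x = ln(BG+CBH)/ln(AP) and
y = ln(BG+CBH)/ln(NAG+LAP); length is sqrt(x^2 + y^2) and angle is the
polar angle of the point (x, y) in degrees.  Because the coordinates are
ratios of logarithms, activities must be expressed in units in which each
enzyme-group sum exceeds 1, so that every logarithm is strictly positive;
no pseudo-offset is added (an offset would silently change both L and A).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import ENZYMES

LIMITATION_CLASSES = ("P", "N", "C_and_P", "N_and_P")


def enzymatic_ratios(bg, cbh, nag, lap, ap):
    """Return the (C:N, C:P, N:P) enzymatic activity ratios.

    C:N = (BG+CBH):(LAP+NAG), C:P = (BG+CBH):AP, N:P = (LAP+NAG):AP.
    Plain ratios of untransformed activities; exactly invariant under a
    common rescaling of all five activities.
    """
    bg, cbh, nag, lap, ap = map(np.asarray, (bg, cbh, nag, lap, ap))
    if np.any(bg <= 0) or np.any(cbh <= 0) or np.any(nag <= 0) \
            or np.any(lap <= 0) or np.any(ap <= 0):
        raise ValueError("all enzyme activities must be strictly positive")
    c = bg + cbh
    n = lap + nag
    return c / n, c / ap, n / ap


def vector_metrics(bg, cbh, nag, lap, ap, log_transform: bool = True):
    """Return (vector_L, vector_A_degrees) for one or more enzyme profiles.

    With ``log_transform`` (the default, matching the standard formulae)
    x = ln(BG+CBH)/ln(AP) and y = ln(BG+CBH)/ln(NAG+LAP); the untransformed
    variant uses the raw activity ratios instead (offered because vector
    analysis is sometimes run on whichever transform minimises the kurtosis
    of the angle distribution).  L = sqrt(x^2+y^2); A = atan2(y, x) in
    degrees, so A > 45 exactly when AP investment exceeds N-enzyme
    investment (y > x).
    """
    bg, cbh, nag, lap, ap = map(np.asarray, (bg, cbh, nag, lap, ap))
    c = bg + cbh
    n = nag + lap
    if log_transform:
        if np.any(c <= 1) or np.any(n <= 1) or np.any(ap <= 1):
            raise ValueError(
                "vector analysis needs BG+CBH, NAG+LAP and AP all > 1 in "
                "working units (their natural logs must be positive); "
                "check the activity units"
            )
        x = np.log(c) / np.log(ap)
        y = np.log(c) / np.log(n)
    else:
        if np.any(c <= 0) or np.any(n <= 0) or np.any(ap <= 0):
            raise ValueError("activities must be positive")
        x = c / ap
        y = c / n
    length = np.hypot(x, y)
    angle = np.degrees(np.arctan2(y, x))
    return length, angle


def classify_limitation(ratio_cn, ratio_np, bounds=(1.0, 1.0)):
    """Quadrant label on the N:P versus C:N activity-ratio plane.

    With boundaries (cn_boundary, np_boundary), default (1, 1):

    * C:N >  cn and N:P <  np -> ``C_and_P`` (C and P both scarce)
    * C:N <= cn and N:P <  np -> ``P``
    * C:N >  cn and N:P >= np -> ``N_and_P``
    * otherwise               -> ``N``

    Boundary ties fall on the N side by the <= / >= rule above.
    """
    cn_boundary, np_boundary = bounds
    if cn_boundary <= 0 or np_boundary <= 0:
        raise ValueError("quadrant boundaries must be positive")
    ratio_cn = np.asarray(ratio_cn)
    ratio_np = np.asarray(ratio_np)
    high_c = ratio_cn > cn_boundary
    low_p = ratio_np < np_boundary
    out = np.where(
        high_c & low_p, "C_and_P",
        np.where(~high_c & low_p, "P", np.where(high_c, "N_and_P", "N")),
    )
    return out[()] if out.ndim == 0 else out


def stoichiometry_table(enzymes: pd.DataFrame, bounds=(1.0, 1.0),
                        log_transform: bool = True) -> pd.DataFrame:
    """Per-sample stoichiometry summary for an enzyme activity table.

    ``enzymes`` must carry the columns BG, CBH, NAG, LAP, AP indexed by
    sample.  Returns ratios, vector coordinates, vector length/angle and
    the quadrant limitation class for every sample, in input order.
    """
    missing = [e for e in ENZYMES if e not in enzymes.columns]
    if missing:
        raise ValueError(f"enzyme table is missing column(s) {missing}")
    bg, cbh, nag, lap, ap = (enzymes[e].to_numpy(dtype=float) for e in ENZYMES)
    cn, cp, np_ratio = enzymatic_ratios(bg, cbh, nag, lap, ap)
    length, angle = vector_metrics(bg, cbh, nag, lap, ap, log_transform=log_transform)
    return pd.DataFrame(
        {
            "ratio_CN": cn,
            "ratio_CP": cp,
            "ratio_NP": np_ratio,
            "vector_L": length,
            "vector_A": angle,
            "limitation_class": classify_limitation(cn, np_ratio, bounds),
        },
        index=enzymes.index,
    )
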