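"""Readers, writers and validators for the flat-file formats used throughout.

All tabular files are UTF-8 TSV with a header row and "." as the decimal
separator.  OTU tables are held in memory as :class:`pandas.DataFrame` in
samples x OTUs orientation; trees as :class:`skbio.TreeNode`.  Missing
metadata values are encoded as the literal string ``NA``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

#: Accepted stand-age classes, ordered young to old.
AGE_CLASSES = ("young", "near_mature", "mature", "over_mature")

ENZYMES = ("BG", "CBH", "NAG", "LAP", "AP")


class FormatError(ValueError):
    """Structural problem in an input file (duplicate ids, bad tree...)."""


def validate_otu_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a samples x OTUs abundance table.

    Requires unique sample and OTU ids, finite non-negative numeric cells,
    and at least one positive entry per sample.
    """
    if table.shape[0] == 0 or table.shape[1] == 0:
        raise ValueError("empty OTU table")
    if table.index.duplicated().any():
        dups = table.index[table.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample ids: {dups}")
    if table.columns.duplicated().any():
        dups = table.columns[table.columns.duplicated()].unique().tolist()
        raise FormatError(f"duplicate OTU ids: {dups}")
    try:
        values = table.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in OTU table: {exc}") from exc
    if not np.isfinite(values).all():
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"non-finite value at sample {table.index[i]!r}, OTU {table.columns[j]!r}"
        )
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative count {values[i, j]} at sample {table.index[i]!r}, "
            f"OTU {table.columns[j]!r}"
        )
    if (values.sum(axis=1) == 0).any():
        empty = table.index[values.sum(axis=1) == 0].tolist()
        raise ValueError(f"samples with no positive entry: {empty}")
    return table


def read_otu_table(path: str | Path, orientation: str = "samples_in_rows") -> pd.DataFrame:
    """Read a TSV OTU table and return it in samples x OTUs orientation.

    Parameters
    ----------
    path:
        TSV file whose first row and first column hold identifiers.
    orientation:
        ``"samples_in_rows"`` or ``"otus_in_rows"``.  Orientation is never
        guessed from the shape of the table.
    """
    if orientation not in ("samples_in_rows", "otus_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    table = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "otus_in_rows":
        table = table.T
    table = validate_otu_table(table)
    logger.info(
        "read OTU table %s: %d samples x %d OTUs", path, table.shape[0], table.shape[1]
    )
    return table


def write_otu_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="sample_id")


def read_newick(path_or_buffer) -> TreeNode:
    """Read a single rooted Newick tree with branch lengths.

    Every tip must be uniquely labelled and every non-root branch must carry
    an explicit length; missing lengths are rejected rather than defaulted
    to zero.
    """
    tree = TreeNode.read(path_or_buffer, format="newick")
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        seen, dups = set(), set()
        for name in tips:
            (dups if name in seen else seen).add(name)
        raise FormatError(f"duplicate tip labels: {sorted(dups)}")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise FormatError(
                f"branch above {node.name or 'internal node'} has no length"
            )
        if node.length < 0:
            raise ValueError(f"negative branch length above {node.name!r}")
    return tree


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata TSV.

    Required columns: ``sample_id``, ``stand_age_class``, ``pH``.  The soil
    chemistry columns (SOC, TN, TP, Olsen_P) are optional; unknown columns
    are preserved untouched.  ``NA`` encodes a missing value.
    """
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, na_values=["NA"])
    for col in ("sample_id", "stand_age_class", "pH"):
        if col not in meta.columns:
            raise FormatError(f"metadata is missing required column {col!r}")
    if meta["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in metadata")
    bad = set(meta["stand_age_class"].dropna()) - set(AGE_CLASSES)
    if bad:
        raise ValueError(
            f"unknown stand_age_class value(s) {sorted(bad)}; "
            f"accepted tokens: {list(AGE_CLASSES)}"
        )
    meta["stand_age_class"] = pd.Categorical(
        meta["stand_age_class"], categories=AGE_CLASSES, ordered=True
    )
    ph = meta["pH"].astype(float)
    out_of_range = ph.dropna()[(ph.dropna() <= 0) | (ph.dropna() >= 14)]
    if len(out_of_range):
        raise ValueError(f"pH outside (0, 14): {out_of_range.tolist()}")
    return meta.set_index("sample_id")


def read_enzyme_table(path: str | Path) -> pd.DataFrame:
    """Read per-sample activities of the five hydrolases (BG, CBH, NAG, LAP, AP).

    Activities are in nmol g^-1 dry soil h^-1 (or any consistent unit in
    which the vector-analysis preconditions hold); all must be positive.
    """
    enz = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in enz.columns:
        raise FormatError("enzyme table is missing 'sample_id'")
    missing = [e for e in ENZYMES if e not in enz.columns]
    if missing:
        raise FormatError(f"enzyme table is missing column(s) {missing}")
    enz = enz.set_index("sample_id")
    acts = enz[list(ENZYMES)].astype(float)
    if (acts <= 0).any().any():
        bad = acts[(acts <= 0).any(axis=1)].index.tolist()
        raise ValueError(f"non-positive enzyme activity for sample(s) {bad}")
    enz[list(ENZYMES)] = acts
    return enz


def write_distance_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="sample_id")


def write_long_pairwise(table: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format pairwise table (sample_i, sample_j, metrics...)."""
    table.to_csv(path, sep="\t", index=False, na_rep="NA")
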