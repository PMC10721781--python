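"""Expression-matrix container, loading, validation, filtering and transforms.

The pipeline's substrate is a genes x samples matrix of non-negative
FPKM-scale values, with each sample assigned to an ordered tissue group
(e.g. leaves -> roots -> ... -> SAM -> RAM along the de-/re-differentiation
axis). Genes with an excessive fraction of zero values are dropped before
any correlation work; correlations downstream default to log2(FPKM+1).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class ExpressionError(ValueError):
    """Raised for malformed or inconsistent expression inputs."""


@dataclass
class ExpressionMatrix:
    """Genes x samples non-negative expression values with tissue groups.

    Attributes
    ----------
    values : pandas.DataFrame
        Rows are genes, columns samples; all entries >= 0.
    group_of : dict
        Maps every sample id to its tissue-group label.
    group_order : list of str
        Tissue groups in their biological order along the sample axis.
    """

    values: pd.DataFrame
    group_of: dict = field(default_factory=dict)
    group_order: list = field(default_factory=list)

    def __post_init__(self):
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise ExpressionError(f"duplicate gene id: {dup!r}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise ExpressionError(f"duplicate sample id: {dup!r}")
        vals = self.values.to_numpy()
        if vals.size and np.nanmin(vals) < 0:
            gi, si = np.argwhere(vals < 0)[0]
            raise ExpressionError(
                f"negative value at gene {idx[gi]!r}, sample {cols[si]!r}"
            )
        for s in cols:
            if s not in self.group_of:
                raise ExpressionError(f"sample {s!r} missing from group map")
        labels = {self.group_of[s] for s in cols}
        if not labels <= set(self.group_order):
            missing = sorted(labels - set(self.group_order))[0]
            raise ExpressionError(f"group label {missing!r} not in group_order")

    # -- convenience -----------------------------------------------------
    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def groups_in_order(self) -> list:
        """Per-sample group labels, in sample column order."""
        return [self.group_of[s] for s in self.sample_ids]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[list(gene_ids)], dict(self.group_of), list(self.group_order)
        )


def load_expression(matrix_path, groups_path) -> ExpressionMatrix:
    """Load a genes x samples TSV plus a two-column sample->group map TSV.

    The group map's row order defines ``group_order`` (first appearance).
    Raises :class:`ExpressionError` naming the offending record on duplicate
    ids, negative values, or samples absent from the map.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    gmap = pd.read_csv(groups_path, sep="\t", header=0, dtype=str)
    if gmap.shape[1] != 2:
        raise ExpressionError(
            f"group map {groups_path} must have exactly two columns (sample, group)"
        )
    sample_col, group_col = gmap.columns
    group_of = dict(zip(gmap[sample_col], gmap[group_col]))
    group_order = list(dict.fromkeys(gmap[group_col]))
    return ExpressionMatrix(values, group_of, group_order)


def write_expression(X: ExpressionMatrix, matrix_path, groups_path,
                     applied_filters: dict | None = None) -> None:
    """Write matrix + group map TSVs and a sidecar JSON of applied filters."""
    Path(matrix_path).parent.mkdir(parents=True, exist_ok=True)
    X.values.to_csv(matrix_path, sep="\t")
    rows = X.sample_ids  # preserve column order so load -> write round-trips
    pd.DataFrame({"sample": rows, "group": [X.group_of[s] for s in rows]}).to_csv(
        groups_path, sep="\t", index=False
    )
    sidecar = Path(str(matrix_path) + ".filters.json")
    with open(sidecar, "w") as fh:
        json.dump(applied_filters or {}, fh, indent=2, sort_keys=True)
        fh.write("\n")


def filter_sparse_genes(X: ExpressionMatrix, max_zero_frac: float = 0.92) -> ExpressionMatrix:
    """Drop genes whose zero fraction strictly exceeds ``max_zero_frac``.

    A gene is retained iff (#zero entries / #samples) <= max_zero_frac.
    With 78 samples and the default 0.92, a gene with 72 zeros (92.3%) is
    dropped while one with 71 zeros (91.0%) is kept. The zero test is exact
    equality to 0.0 — FPKM tables print literal zeros.
    """
    if not 0 <= max_zero_frac <= 1:
        raise ExpressionError("max_zero_frac must lie in [0, 1]")
    if X.n_genes == 0 or X.n_samples == 0:
        raise ExpressionError("cannot filter an empty matrix")
    zero_frac = (X.values.to_numpy() == 0.0).mean(axis=1)
    keep = zero_frac <= max_zero_frac
    dropped = int((~keep).sum())
    logger.info("filter_sparse_genes: dropped %d of %d genes (> %.0f%% zeros)",
                dropped, X.n_genes, 100 * max_zero_frac)
    return ExpressionMatrix(X.values.loc[keep], dict(X.group_of), list(X.group_order))


def log_transform(X: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Map each value v -> log2(v + pseudocount); monotone, 0 -> 0 at the default."""
    if pseudocount <= 0:
        raise ExpressionError("pseudocount must be positive")
    return ExpressionMatrix(
        np.log2(X.values + pseudocount), dict(X.group_of), list(X.group_order)
    )
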