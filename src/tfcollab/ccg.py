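"""Top-k co-expressed gene (CCG) ranking per TF and the shared
co-expression connectivity matrix (SCCM).

Each transcription factor is characterised by the k genes most correlated
with it (its CCGs; k = 100 by default). The SCCM is the symmetric TF x TF
matrix whose (i, j) entry counts the CCGs shared by TFs i and j; pairs
sharing at least ``min_shared`` CCGs (25 by default) form the edges of the
collaborative network that is later decomposed into subnetworks.

Correlations are computed on whatever scale the caller supplies; the
intended default is log2(FPKM+1). The candidate pool for a TF's CCGs is
every other gene in the matrix — TFs may themselves be CCGs of other TFs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class CCGRanking:
    """Ordered top-k co-expression list for one TF."""

    tf_id: str
    ranked_genes: list
    scores: np.ndarray
    k: int
    constant_tf: bool = False

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.ranked_genes) != len(self.scores):
            raise ValueError("ranked_genes and scores length mismatch")
        if self.tf_id in self.ranked_genes:
            raise ValueError(f"TF {self.tf_id!r} appears in its own CCG list")
        if len(set(self.ranked_genes)) != len(self.ranked_genes):
            raise ValueError("duplicate genes in ranked list")


@dataclass
class SCCM:
    """Symmetric shared-CCG count matrix over an ordered TF list."""

    tf_ids: list
    counts: np.ndarray
    k: int
    min_shared: int = 25

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        n = len(self.tf_ids)
        if self.counts.shape != (n, n):
            raise ValueError("counts shape does not match tf_ids")
        if not np.array_equal(self.counts, self.counts.T):
            raise ValueError("SCCM must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.tf_ids, columns=self.tf_ids)


def _standardize_rows(M: np.ndarray) -> np.ndarray:
    """Center/scale each row to unit norm; constant rows become all-zero
    (so their correlation with anything is 0)."""
    Mc = M - M.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(Mc, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(norm > 0, Mc / norm, 0.0)
    return Z


def rank_ccgs(X: ExpressionMatrix, tf_ids, k: int = 100,
              method: str = "pearson") -> list[CCGRanking]:
    """Rank, for each TF, the k genes most correlated with its profile.

    Sorting is by descending correlation, ties broken by ascending gene id;
    the TF itself is excluded; constant-profile genes score 0. A TF whose
    own profile is constant is flagged and emitted with all-zero scores.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    gene_ids = np.asarray(X.gene_ids)
    missing = [t for t in tf_ids if t not in set(X.gene_ids)]
    if missing:
        raise KeyError(f"TF {missing[0]!r} not present in expression matrix")
    if k >= X.n_genes:
        raise ValueError(f"k={k} must be smaller than the number of genes ({X.n_genes})")

    M = X.values.to_numpy(dtype=float)
    if method == "spearman":
        M = rankdata(M, axis=1)
    Z = _standardize_rows(M)
    pos = {g: i for i, g in enumerate(gene_ids)}
    tf_idx = np.array([pos[t] for t in tf_ids])
    corr = Z[tf_idx] @ Z.T  # |tfs| x n_genes
    np.clip(corr, -1.0, 1.0, out=corr)

    # stable order: descending score, then ascending gene id
    id_order = np.argsort(gene_ids, kind="stable")
    id_rank = np.empty(len(gene_ids), dtype=int)
    id_rank[id_order] = np.arange(len(gene_ids))

    out = []
    for row, tf in zip(corr, tf_ids):
        constant = not np.any(Z[pos[tf]])
        if constant:
            logger.warning("TF %s has a constant profile; scores set to 0", tf)
            row = np.zeros_like(row)
        order = np.lexsort((id_rank, -row))
        order = order[order != pos[tf]][:k]
        out.append(CCGRanking(tf_id=tf, ranked_genes=list(gene_ids[order]),
                              scores=row[order], k=k, constant_tf=constant))
    return out


def build_sccm(rankings: list[CCGRanking], min_shared: int = 25) -> SCCM:
    """Count shared CCGs for every TF pair: counts[i, j] = |list_i ∩ list_j|.

    The diagonal is defined as k. All rankings must share the same k.
    """
    if not rankings:
        raise ValueError("no rankings supplied")
    ks = {r.k for r in rankings}
    if len(ks) != 1:
        raise ValueError(f"rankings disagree on k: {sorted(ks)}")
    k = ks.pop()
    tf_ids = [r.tf_id for r in rankings]
    if len(set(tf_ids)) != len(tf_ids):
        raise ValueError("duplicate TF ids among rankings")

    universe = sorted({g for r in rankings for g in r.ranked_genes})
    pos = {g: i for i, g in enumerate(universe)}
    B = np.zeros((len(rankings), len(universe)), dtype=bool)
    for i, r in enumerate(rankings):
        B[i, [pos[g] for g in r.ranked_genes]] = True
    counts = (B.astype(np.int64) @ B.T.astype(np.int64))
    np.fill_diagonal(counts, k)
    return SCCM(tf_ids=tf_ids, counts=counts, k=k, min_shared=min_shared)


def threshold_edges(S: SCCM, min_shared: int | None = None) -> list[tuple]:
    """Edges (tf_i, tf_j, shared count) for i<j with count >= min_shared
    ("at least" — the boundary value is retained)."""
    ms = S.min_shared if min_shared is None else min_shared
    if ms < 0:
        raise ValueError("min_shared must be non-negative")
    edges = []
    n = len(S.tf_ids)
    for i in range(n):
        for j in range(i + 1, n):
            c = int(S.counts[i, j])
            if c >= ms:
                edges.append((S.tf_ids[i], S.tf_ids[j], c))
    return edges


# -- I/O -----------------------------------------------------------------

def rankings_to_tsv(rankings: list[CCGRanking], path) -> None:
    rows = [(r.tf_id, rank + 1, g, s)
            for r in rankings
            for rank, (g, s) in enumerate(zip(r.ranked_genes, r.scores))]
    pd.DataFrame(rows, columns=["tf", "rank", "gene", "score"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g")


def rankings_from_tsv(path) -> list[CCGRanking]:
    df = pd.read_csv(path, sep="\t", dtype={"tf": str, "gene": str})
    out = []
    for tf, grp in df.groupby("tf", sort=False):
        grp = grp.sort_values("rank")
        out.append(CCGRanking(tf_id=tf, ranked_genes=list(grp["gene"]),
                              scores=grp["score"].to_numpy(), k=len(grp)))
    return out


def sccm_to_tsv(S: SCCM, path) -> None:
    S.to_frame().to_csv(path, sep="\t")


def sccm_from_tsv(path, k: int | None = None, min_shared: int = 25) -> SCCM:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    counts = df.to_numpy(dtype=np.int64)
    if k is None:
        k = int(counts.diagonal().max()) if len(df) else 0
    return SCCM(tf_ids=list(df.index), counts=counts, k=k, min_shared=min_shared)


def edges_to_tsv(edges: list[tuple], path) -> None:
    pd.DataFrame(edges, columns=["tf_a", "tf_b", "shared_ccgs"]).to_csv(
        path, sep="\t", index=False)


def sccm_to_graphml(S: SCCM, path, min_shared: int | None = None) -> None:
    """Export the thresholded collaborative network for external layout
    tools (e.g. force-directed layouts in Cytoscape)."""
    import networkx as nx

    G = nx.Graph()
    G.add_nodes_from(S.tf_ids)
    for a, b, w in threshold_edges(S, min_shared):
        G.add_edge(a, b, weight=w)
    nx.write_graphml(G, path)
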