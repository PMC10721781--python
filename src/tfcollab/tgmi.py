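"""Triple-gene mutual-interaction (TGMI) scoring and TF ranking.

Every triple (TF, G1, G2) — one transcription factor and an unordered
pair of biological-process (BP) genes — is profiled on equal-frequency-
discretised expression by plug-in information measures (bits):

* TF-coupling statistics  I(T;G1) and I(T;G2) — how strongly the TF's
  profile is informative about each BP gene;
* the conditional profile I(T;G1|G2), I(T;G2|G1), I(G1;G2|T) — how the
  dependencies decompose once the third gene is held fixed.

Significance comes from a permutation null that shuffles only the TF's
discretised labels, preserving the G1-G2 joint: the null of interest is
TF-independence. Upper-tail p-values use the add-one estimator
p = (1 + #{null >= observed}) / (1 + n_perm) and Benjamini-Hochberg runs
per component across all triples of a run. A triple is significant when
both TF-coupling statistics pass the adjusted threshold.

The residual pair dependence I(G1;G2|T) and its upper-tail p-value are
reported as a diagnostic but do not gate: under the common-regulator
model (both BP genes driven by the TF), conditioning on the true TF
*removes* G1-G2 dependence while permuting the TF restores it, so that
component sits below its null exactly when the TF is the genuine
regulator (see docs/methods.md for the full argument). Conditioning the
TF-coupling statistics on the partner gene similarly discards shared
signal, which is why the marginal informations are the test statistics.

A TF's interference frequency is the number of distinct BP genes that
appear with it in at least one significant triple — each gene counted
once no matter how many triples repeat it.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix
from ._util import derive_rng

logger = logging.getLogger(__name__)


@dataclass
class TripleRecord:
    tf_id: str
    g1_id: str
    g2_id: str
    mi: tuple           # (I(T;G1), I(T;G2)) in bits — the gating statistics
    cmi: tuple          # (I(T;G1|G2), I(T;G2|G1), I(G1;G2|T)) in bits
    p_values: tuple     # permutation p for (I(T;G1), I(T;G2), I(G1;G2|T))
    adj_p: tuple        # BH-adjusted, per component across the run
    significant: bool   # both TF-coupling adjusted p-values <= alpha


@dataclass
class TFRanking:
    tf_id: str
    interference_frequency: int
    rank: int


def discretize(profile, bins: int = 3) -> np.ndarray:
    """Equal-frequency (quantile) binning into ``bins`` labels 0..bins-1.

    Rank-based, hence invariant under any strictly monotone transform of
    the input; tied values share the lower bin. A constant profile
    collapses to a single label with a warning.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    x = np.asarray(profile, dtype=float)
    n = x.size
    if n == 0:
        raise ValueError("empty profile")
    if np.all(x == x[0]):
        warnings.warn("constant profile: discretization yields a single label")
        return np.zeros(n, dtype=np.int64)
    # min-rank (1-based): ties share the rank of their first occurrence
    order = np.argsort(x, kind="stable")
    xs = x[order]
    first = np.empty(n, dtype=np.int64)
    first[0] = 1
    for i in range(1, n):
        first[i] = first[i - 1] if xs[i] == xs[i - 1] else i + 1
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = first
    return np.ceil(ranks * bins / n).astype(np.int64) - 1


def mutual_information(x, y) -> float:
    """Plug-in mutual information I(X;Y) in bits from two equal-length
    label vectors."""
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D label vectors")
    bx, by = x.max() + 1, y.max() + 1
    counts = np.bincount(x * by + y, minlength=bx * by).reshape(bx, by)
    return float(_mi_from_table(counts))


def conditional_mi(x, y, z) -> float:
    """Plug-in conditional mutual information I(X;Y|Z) in bits from three
    equal-length label vectors. Non-negative by construction (tiny float
    negatives are clipped to 0)."""
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    z = np.asarray(z, dtype=np.int64)
    if not (x.shape == y.shape == z.shape) or x.ndim != 1:
        raise ValueError("x, y, z must be equal-length 1-D label vectors")
    bx, by, bz = x.max() + 1, y.max() + 1, z.max() + 1
    counts = np.bincount((x * by + y) * bz + z,
                         minlength=bx * by * bz).reshape(bx, by, bz)
    return _cmi_from_table(counts)


def _mi_from_table(counts: np.ndarray):
    """I(X;Y) from a (..., X, Y) contingency table; batch-aware."""
    c = np.asarray(counts, dtype=float)
    n = c.sum(axis=(-2, -1), keepdims=True)
    p = c / n
    px = p.sum(axis=-1)
    py = p.sum(axis=-2)
    den = px[..., :, None] * py[..., None, :]
    safe = p > 0
    ratio = np.where(safe, p / np.where(safe, den, 1.0), 1.0)
    out = np.maximum(np.where(safe, p * np.log2(ratio), 0.0).sum(axis=(-2, -1)), 0.0)
    return float(out) if out.ndim == 0 else out


def _cmi_from_table(counts: np.ndarray):
    """I(X;Y|Z) from a (..., X, Y, Z) contingency table; batch-aware."""
    c = np.asarray(counts, dtype=float)
    n = c.sum(axis=(-3, -2, -1), keepdims=True)
    p = c / n
    pz = p.sum(axis=(-3, -2))                        # (..., Z)
    pxz = p.sum(axis=-2)                             # (..., X, Z)
    pyz = p.sum(axis=-3)                             # (..., Y, Z)
    num = p * pz[..., None, None, :]
    den = pxz[..., :, None, :] * pyz[..., None, :, :]
    safe = p > 0
    ratio = np.where(safe, num / np.where(safe, den, 1.0), 1.0)
    terms = np.where(safe, p * np.log2(ratio), 0.0)
    out = np.maximum(terms.sum(axis=(-3, -2, -1)), 0.0)
    return float(out) if out.ndim == 0 else out


def _joint_table(t, g1, g2, bins: int) -> np.ndarray:
    return np.bincount((t * bins + g1) * bins + g2,
                       minlength=bins ** 3).reshape(bins, bins, bins)


def _triple_stats(table: np.ndarray):
    """(I(T;G1), I(T;G2), I(T;G1|G2), I(T;G2|G1), I(G1;G2|T)) from a
    (..., t, g1, g2) table; batch-aware over leading dims."""
    mi1 = _mi_from_table(table.sum(axis=-1))                 # I(T;G1)
    mi2 = _mi_from_table(table.sum(axis=-2))                 # I(T;G2)
    cmi1 = _cmi_from_table(table)                            # I(T;G1|G2)
    cmi2 = _cmi_from_table(np.swapaxes(table, -2, -1))       # I(T;G2|G1)
    cmi3 = _cmi_from_table(np.moveaxis(table, -3, -1))       # I(G1;G2|T)
    return mi1, mi2, cmi1, cmi2, cmi3


def _null_stats(t_perms: np.ndarray, g1, g2, bins: int) -> np.ndarray:
    """Null (I(T;G1), I(T;G2), I(G1;G2|T)) for a batch of permuted TF
    label vectors; returns (n_perm, 3). All joint tables are built with a
    single bincount."""
    n_perm, n = t_perms.shape
    codes = (t_perms * bins + g1[None, :]) * bins + g2[None, :]
    offset = (np.arange(n_perm) * bins ** 3)[:, None]
    flat = np.bincount((codes + offset).ravel(), minlength=n_perm * bins ** 3)
    tables = flat.reshape(n_perm, bins, bins, bins)
    out = np.empty((n_perm, 3))
    out[:, 0] = _mi_from_table(tables.sum(axis=-1))
    out[:, 1] = _mi_from_table(tables.sum(axis=-2))
    out[:, 2] = _cmi_from_table(np.moveaxis(tables, 1, 3))
    return out


def score_triples(X: ExpressionMatrix, tf_ids, bp_genes, n_perm: int = 1000,
                  alpha: float = 0.05, seed: int = 0, bins: int = 3) -> list[TripleRecord]:
    """Score all (TF, {G1, G2}) triples with permutation p-values and BH.

    Discretisation is rank-based, so raw and log-scale inputs give
    identical results. Fresh permutations are drawn per triple from a
    stream derived from ``seed``. Triples where a BP gene coincides with
    the TF are skipped with a warning. The smallest attainable p-value is
    1/(n_perm + 1).
    """
    bp_genes = sorted(set(bp_genes))
    tf_ids = list(tf_ids)
    if len(bp_genes) < 2:
        raise ValueError("need at least two BP genes")
    present = set(X.gene_ids)
    for g in list(tf_ids) + bp_genes:
        if g not in present:
            raise KeyError(f"gene {g!r} not present in expression matrix")

    labels = {g: discretize(X.values.loc[g].to_numpy(), bins=bins)
              for g in set(tf_ids) | set(bp_genes)}

    rng = derive_rng(seed, "tgmi", "permutations")
    triples, mis, cmis, pvals = [], [], [], []
    for tf in tf_ids:
        for g1, g2 in combinations(bp_genes, 2):
            if tf in (g1, g2):
                warnings.warn(f"skipping triple where BP gene equals TF {tf!r}")
                continue
            t, a, b = labels[tf], labels[g1], labels[g2]
            table = _joint_table(t, a, b, bins)
            mi1, mi2, c1, c2, c3 = _triple_stats(table)
            t_perms = np.array([rng.permutation(t) for _ in range(n_perm)])
            null = _null_stats(t_perms, a, b, bins)
            observed = np.array([mi1, mi2, c3])
            ge = (null >= observed[None, :] - 1e-12).sum(axis=0)
            pvals.append((1.0 + ge) / (1.0 + n_perm))
            mis.append((mi1, mi2))
            cmis.append((c1, c2, c3))
            triples.append((tf, g1, g2))

    if not triples:
        return []
    pvals = np.asarray(pvals)
    adj = np.column_stack([multipletests(pvals[:, c], method="fdr_bh")[1]
                           for c in range(3)])

    records = []
    for (tf, g1, g2), mi, cm, pv, ap in zip(triples, mis, cmis, pvals, adj):
        sig = bool(ap[0] <= alpha and ap[1] <= alpha)
        records.append(TripleRecord(
            tf_id=tf, g1_id=g1, g2_id=g2,
            mi=tuple(float(v) for v in mi),
            cmi=tuple(float(v) for v in cm),
            p_values=tuple(float(v) for v in pv),
            adj_p=tuple(float(v) for v in ap),
            significant=sig))
    return records


def rank_tfs(records: list[TripleRecord]) -> list[TFRanking]:
    """Interference frequency per TF: distinct BP genes sharing at least
    one significant triple with it (each counted once); rank by descending
    frequency, ties by ascending TF id."""
    genes_by_tf: dict = {}
    for r in records:
        genes_by_tf.setdefault(r.tf_id, set())
        if r.significant:
            genes_by_tf[r.tf_id] |= {r.g1_id, r.g2_id}
    ordered = sorted(genes_by_tf.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return [TFRanking(tf_id=tf, interference_frequency=len(gs), rank=i + 1)
            for i, (tf, gs) in enumerate(ordered)]


# -- I/O -----------------------------------------------------------------

def triples_to_tsv(records: list[TripleRecord], path) -> None:
    rows = [{"tf": r.tf_id, "g1": r.g1_id, "g2": r.g2_id,
             "mi_t_g1": r.mi[0], "mi_t_g2": r.mi[1],
             "cmi_t_g1": r.cmi[0], "cmi_t_g2": r.cmi[1], "cmi_g1_g2": r.cmi[2],
             "p_t_g1": r.p_values[0], "p_t_g2": r.p_values[1],
             "p_g1_g2": r.p_values[2],
             "adj_t_g1": r.adj_p[0], "adj_t_g2": r.adj_p[1],
             "adj_g1_g2": r.adj_p[2], "significant": r.significant}
            for r in records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def ranking_to_tsv(rankings: list[TFRanking], path) -> None:
    rows = [{"rank": r.rank, "tf": r.tf_id,
             "interference_frequency": r.interference_frequency}
            for r in rankings]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
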