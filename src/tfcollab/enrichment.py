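"""Hypergeometric gene-set enrichment with Benjamini-Hochberg control.

Given a query gene set (e.g. a subnetwork's merged CCGs), an annotation
(term -> gene set, GMT-style) and a background universe, each term is
tested with the upper-tail hypergeometric probability of the observed
overlap; BH adjustment runs across *all* tested terms (terms with zero
overlap stay in the denominator but are dropped from the output table).
Fold enrichment is (k/n)/(K/N).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneSetAnnotation:
    sets: dict                      # term_id -> frozenset of gene ids
    names: dict = field(default_factory=dict)

    def __post_init__(self):
        for term, genes in self.sets.items():
            if not genes:
                raise ValueError(f"term {term!r} has an empty gene set")
            self.sets[term] = frozenset(genes)
        for term in self.sets:
            self.names.setdefault(term, term)


@dataclass
class EnrichmentResult:
    term_id: str
    name: str
    k: int          # overlap
    n: int          # query size
    K: int          # term size (within universe)
    N: int          # universe size
    fold_enrichment: float
    p_value: float
    adj_p: float
    significant: bool


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    k successes drawn in a sample of n from a universe of N containing K
    successes. k = 0 gives exactly 1.0.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(query, ann: GeneSetAnnotation, universe, alpha: float = 0.05) -> list[EnrichmentResult]:
    """Test every annotation term for over-representation in ``query``.

    Results (one per term with overlap >= 1) are sorted by adjusted p then
    term id; the significance flag applies adj_p <= alpha (default 0.05,
    the conventional corrected-P cutoff).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    stray = sorted(query - universe)
    if stray:
        raise ValueError(f"query gene {stray[0]!r} not in universe")
    N, n = len(universe), len(query)

    terms = sorted(ann.sets)
    ks, Ks, ps = [], [], []
    for t in terms:
        term_genes = ann.sets[t] & universe
        K = len(term_genes)
        k = len(term_genes & query)
        ks.append(k)
        Ks.append(K)
        ps.append(hypergeom_tail(k, N, K, n) if K else 1.0)
    adj = multipletests(ps, method="fdr_bh")[1] if ps else np.array([])

    results = []
    for t, k, K, p, ap in zip(terms, ks, Ks, ps, adj):
        if k < 1:
            continue
        fold = (k / n) / (K / N)
        results.append(EnrichmentResult(
            term_id=t, name=ann.names.get(t, t), k=k, n=n, K=K, N=N,
            fold_enrichment=fold, p_value=float(p), adj_p=float(ap),
            significant=bool(ap <= alpha)))
    results.sort(key=lambda r: (r.adj_p, r.term_id))
    return results


# -- I/O -----------------------------------------------------------------

def read_gmt(path) -> GeneSetAnnotation:
    """Read GMT: term <tab> description <tab> gene1 <tab> gene2 ..."""
    sets, names = {}, {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            term, desc, genes = parts[0], parts[1], parts[2:]
            sets[term] = frozenset(g for g in genes if g)
            names[term] = desc or term
    return GeneSetAnnotation(sets=sets, names=names)


def write_gmt(ann: GeneSetAnnotation, path) -> None:
    with open(path, "w") as fh:
        for term in sorted(ann.sets):
            genes = "\t".join(sorted(ann.sets[term]))
            fh.write(f"{term}\t{ann.names.get(term, term)}\t{genes}\n")


def results_to_tsv(results: list[EnrichmentResult], path) -> None:
    rows = [{"term": r.term_id, "name": r.name, "k": r.k, "K": r.K,
             "n": r.n, "N": r.N, "fold_enrichment": r.fold_enrichment,
             "p_value": r.p_value, "adj_p": r.adj_p,
             "significant": r.significant} for r in results]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
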