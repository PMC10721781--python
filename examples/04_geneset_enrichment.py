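"""Hypergeometric gene-set enrichment with BH correction.

A query of 30 genes is tested against 15 annotation terms, one of which
was constructed to overlap the query heavily; the planted term is
reported with its fold enrichment and adjusted p-value.
"""
from tfcollab import enrich, make_annotations

universe = {f"g{i:03d}" for i in range(500)}
query = {f"g{i:03d}" for i in range(30)}
ann = make_annotations(terms=15, genes_per_term=40, enriched_term_overlap=20,
                       query_set=query, universe=universe, seed=5)

results = enrich(query, ann, universe, alpha=0.05)
print(f"{'term':<10} {'k/K':>7} {'fold':>6} {'adj_p':>10}  significant")
for r in results[:5]:
    print(f"{r.term_id:<10} {r.k:>3}/{r.K:<3} {r.fold_enrichment:>6.2f} "
          f"{r.adj_p:>10.3g}  {r.significant}")
# fold = (k/n)/(K/N): how much denser the term is in the query than in
# the background; only the planted term passes the 0.05 corrected cutoff
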