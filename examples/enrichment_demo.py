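"""Fisher's-exact overrepresentation of the cancer-unique gene list.

Builds a small flat annotation in memory (in real use, load a GMT file
with ``read_gmt``) and tests the packaged cancer-unique gene list against
it.  Seven of the 18 genes are ribosomal proteins, so the ribosome term
dominates the ranking.
"""

from baitcall import enrich_all, top_terms
from baitcall.datasets import load_cancer_unique, load_common_core
from baitcall.io import AnnotationMap, AnnotationTerm, GoCategory

unique_genes = set(load_cancer_unique()["gene_name"])
common_genes = set(load_common_core()["gene_name"])
background = unique_genes | common_genes | {f"FILLER{i}" for i in range(400)}

terms = {
    "SET:ribosome": {g for g in background if g.startswith(("RPL", "RPS"))},
    "SET:hnrnp": {g for g in background if g.startswith("HNRNP")},
    "SET:splicing": {g for g in background if g.startswith(("SRSF", "SNR", "SF"))},
    "SET:filler": {f"FILLER{i}" for i in range(100)},
}
annotation = AnnotationMap(
    terms={
        tid: AnnotationTerm(tid, tid, GoCategory.CELLULAR_COMPONENT, frozenset(m))
        for tid, m in terms.items()
    }
)

results = enrich_all(unique_genes, annotation, background, correction="bh")
print(f"query: {len(unique_genes)} genes, background: {len(background)}")
print("top terms (ascending p):")
for r in top_terms(results, n=4):
    print(
        f"  {r.term_id:14s} k={r.k:2d} K={r.K:3d} expected={r.expected:5.2f} "
        f"fold={r.fold_enrichment:5.1f} p={r.p_value:.3g} fdr={r.fdr:.3g}"
    )
# 'fold' is observed/expected hits; p is the one-sided hypergeometric tail,
# fdr the Benjamini-Hochberg adjustment within the ontology category
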