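"""Overlap statistics between a called interactor list and a reference set.

Calls interactors on a simulated experiment and compares one cell line's
list against the planted truth used as a stand-in reference interactome
(in real use, load e.g. a database export with ``read_id_list``).
"""

from baitcall import call_candidates, overlap_stats, study_like_params, simulate_experiment

table, design, truth = simulate_experiment(study_like_params(seed=11))
candidates = call_candidates(table, design)

query = candidates["HeLa"]
reference = truth.true_interactors("HeLa")
stats = overlap_stats(query, reference)
print(f"query (called in HeLa): {stats.n_query} proteins")
print(f"reference (planted interactors): {stats.n_reference} proteins")
print(f"overlap: {stats.count} proteins")
print(f"  {stats.pct_of_query:.1f}% of the query, "
      f"{stats.pct_of_reference:.1f}% of the reference, "
      f"Jaccard {stats.jaccard:.3f}")
# pct_of_reference < 100 because the all-of-3-replicates rule drops true
# interactors that failed detection in at least one replicate
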