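"""Collapse duplicate accessions into a core collection.

Genebank collections often hold the same genotype under several accession
numbers.  Estimated probability of identity (PI-HAT) is 1 for duplicates,
~0.5 for full sibs; single-linkage clustering at PI >= 0.99 groups the
redundant seed lots and one representative per cluster forms the core.
"""

import pigdiv as pg

cfg = pg.PanelConfig(
    n_markers=800, n_chromosomes=12,
    group_spec=(("indica", 60, 0.5), ("japonica", 70, 0.5)),
    selfing_generations=4, n_duplicates=25, missing_rate=0.03, rng_seed=7,
)
gm, truth = pg.simulate_panel(cfg)
print(f"panel holds {gm.n_accessions} accessions, "
      f"{len(truth.duplicate_pairs)} of them planted duplicates")

rel = pg.estimate_pi(gm)
sel = pg.find_duplicates(rel, gm, pi_threshold=0.99)
n_dup = sum(len(c) - 1 for c in sel.duplicate_clusters if len(c) > 1)
print(f"PI >= 0.99 clustering finds {n_dup} redundant accessions "
      f"in {sum(len(c) > 1 for c in sel.duplicate_clusters)} clusters")
print(f"core collection: {len(sel.core_ids)} unique genotypes "
      "(each cluster represented by its best-called accession)")
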