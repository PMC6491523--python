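"""Pairwise Weir-Cockerham FST and hierarchical AMOVA.

FST measures standardized allele-frequency differentiation between groups
(the Balding-Nichols F used by the simulator is exactly the parameter the
Weir-Cockerham estimator targets).  AMOVA partitions total genetic variance
into between-group, among-accession-within-group and within-accession
(residual heterozygosity) strata.
"""

import pigdiv as pg

cfg = pg.PanelConfig(
    n_markers=2000, n_chromosomes=12,
    group_spec=(("indica", 120, 0.5), ("japonica", 140, 0.5), ("admix", 15, 0.1)),
    selfing_generations=4, missing_rate=0.0, rng_seed=9,
)
gm, _ = pg.simulate_panel(cfg)
labels = gm.group_labels("subspecies")

fm = pg.fst_matrix(gm, labels)
print("pairwise FST:")
for i, a in enumerate(fm.group_ids):
    for j in range(i + 1, len(fm.group_ids)):
        print(f"  {a} vs {fm.group_ids[j]}: {fm.theta[i, j]:.4f}")
print(f"mean over pairs: {fm.mean_offdiagonal:.3f}")
print("(the indica-japonica value sits near the generative F = 0.5; a value "
      "near zero would mean free exchange between groups)\n")

res = pg.amova(gm, labels)
print(res.table.round(2))
print("\nDegrees of freedom follow the diploid design (G-1, N-G, N, 2N-1); "
      "percentages say where the variance lives — high between-group % here "
      "mirrors the deep indica/japonica split.")
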