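"""Seed-trait statistics and the Rc-indel colour screen.

Simulated multi-spectral trait tables (geometry + CIE colour appearance)
are summarised, correlated, reduced by PCA and tested for colour-class
effects with the gated one-way ANOVA (Bartlett homoscedasticity check, log
transform on failure, Tukey HSD on the surviving traits).  Binary Rc
deletion calls are cross-tabulated against pericarp colour.
"""

import pigdiv as pg
from pigdiv.syndata import PanelConfig, simulate_panel

cfg = PanelConfig(n_markers=50, group_spec=(("g", 200, 0.0),), rng_seed=4)
_, truth = simulate_panel(cfg)
tt = pg.simulate_traits(truth, rng_seed=20)

desc = pg.describe_traits(tt)
print("trait dispersion (CV):")
print(desc["CV"].round(3).sort_values().to_string())

r, _ = pg.trait_correlations(tt)
print(f"\nr(intensity, lightness) = {r.loc['intensity', 'lightness']:.2f} "
      "(colour-appearance traits move together)")

res = pg.trait_pca(tt)
print(f"trait PCA: PC1 {res.pct_variance[0]:.1f}% (colour axis), "
      f"PC2 {res.pct_variance[1]:.1f}% (geometry axis)")

an = pg.colour_anova(tt, "intensity")
print(f"\nANOVA intensity ~ colour class: F{an.df} = {an.F:.2f}, "
      f"p = {an.p_value:.2e}"
      + (f", log-transformed" if an.transform else "")
      + (", precluded (heterogeneous variances)" if an.precluded else ""))
if an.tukey is not None:
    sig = an.tukey[an.tukey["significant"]]
    print(f"Tukey HSD: {len(sig)}/{len(an.tukey)} class pairs differ")

calls = pg.simulate_indel_calls(truth, concordance=0.9, rng_seed=2)
ct = pg.rc_crosstab(calls, tt["colour_class"])
print(f"\nRc screen: {len(ct.discordant)} discordant accessions "
      "(pigmented despite the 14-bp deletion, or white without it)")
print(ct.table)
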