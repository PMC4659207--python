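"""Effective population size from background LD, and marker-based inbreeding.

Ne is estimated from the mean Burrows composite r-squared among non-syntenic
(cross-chromosome) SNP pairs after removing the 1/S + 3.19/S^2 sampling
contribution.  Inbreeding coefficients F1/F2/F3 (additive-variance,
homozygote-excess and gametic-correlation forms) use within-population allele
frequencies, which is what makes F1 crosses come out negative (outbred).
"""

import flockdiv as fd

gm, smap, truth = fd.simulate_panel(fd.sheep_scenario(seed=17))

ne = fd.ne_table(gm, smap, ["BL", "PD", "MER"], seed=1)
ne["true_ne"] = [truth.ne[p] for p in ne["population"]]
print(ne.round(3).to_string(index=False))
# Ne-hat should track the configured sizes: the bottlenecked meat breeds are
# small, the wool breed several times larger.

co = fd.f_coefficients(gm)
print()
print(fd.inbreeding_summary(co, threshold=0.065).round(4).to_string(index=False))
# Pure breeds hover near zero; the crosses are clearly negative with a 0%
# critical percentage (no individual above 0.065).
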