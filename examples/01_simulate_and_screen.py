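"""Simulate a small birth cohort with planted effects and screen covariates.

The generator plants an extraction-batch effect plus delivery, older-sibling
and stool-consistency effects of decreasing size.  The screen reports each
variable's sequential Bray-Curtis PERMANOVA R-squared after the two
technical confounders (extraction batch, processed reads), with permutation
p, BH-FDR q, and a beta-dispersion flag.
"""

import permapart as pp
from permapart.simulate import GeneratorConfig, demo_truth, simulate_cohort

cfg = GeneratorConfig(n_families=200, seed=1, timepoints=("3w", "3m", "12m"))
ct, md, truth = simulate_cohort(cfg, demo_truth())
print(f"cohort: {ct.n_samples} samples x {ct.n_taxa} taxa, "
      f"{md.table['family_id'].nunique()} families")

genus = pp.aggregate(ct, "genus")
dms = {}
for tp in cfg.timepoints:
    samples = [s for s in genus.sample_ids
               if md.table.loc[s, "role"] == "infant"
               and md.table.loc[s, "timepoint"] == tp]
    dms[tp] = pp.bray_curtis(pp.relative_abundance(genus.select_samples(samples)))

report = pp.screen_all(dms, md,
                       ["delivery3", "older_siblings", "stool_consistency"],
                       confounders=["extraction_batch", "reads"], B=299, seed=1)
print(report.table[["timepoint", "variable", "R2", "p", "q",
                    "significant", "dispersion_uneven"]].round(4).to_string(index=False))
print("\nR2 is the fraction of community variance a covariate explains after"
      " technical adjustment; the planted delivery effect should dominate"
      " early timepoints and the dual rule (p<0.05, q<0.1) flags it.")
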