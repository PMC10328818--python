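"""Per-taxon differential abundance for the delivery variable.

Each genus passing the >10% prevalence filter is fit with the
NB -> Poisson -> quasi-Poisson -> GLS cascade (log processed reads as
offset, extraction batch as adjustment).  Coefficients are log fold-changes
of C-section+antibiotics births against the vaginal-delivery reference.
"""

import permapart as pp
from permapart.simulate import GeneratorConfig, demo_truth, simulate_cohort

cfg = GeneratorConfig(n_families=150, seed=4, timepoints=("3w", "3m"))
ct, md, _ = simulate_cohort(cfg, demo_truth())
genus = pp.aggregate(ct, "genus")
early = [s for s in genus.sample_ids
         if md.table.loc[s, "role"] == "infant"
         and md.table.loc[s, "timepoint"] == "3w"]

res = pp.fit_da(genus.select_samples(early), md, "delivery3",
                adjust="extraction_batch", reference="VD-AB")
sig = res.significant().sort_values("p")
print(f"{len(res.table)} (taxon, contrast) fits; {len(sig)} significant at"
      " p<0.05 & q<0.1")
print(sig[["taxon", "contrast", "family", "coef", "p", "q"]].round(4).to_string(index=False))
print("\nNegative coefficients for Bacteroides-like taxa in the CS+AB"
      " contrast reproduce the planted depletion; 'family' records which"
      " model in the cascade fit each taxon.")
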