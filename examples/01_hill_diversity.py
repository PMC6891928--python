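"""Hill-number diversity profiles and a two-cohort comparison.

Builds a small synthetic two-sex dataset, computes per-sample Hill numbers
at orders q = 0..3 and compares the cohorts with the Wilcoxon rank-sum
test and Cohen's d.
"""

import mgx
from mgx.diversity import profiles_per_sample
from mgx.synthetic import CohortSpec, generate_cohorts

spec = CohortSpec(n_samples=(40, 40), n_shared_taxa=150, n_specific_taxa=(30, 5),
                  lognormal_sd=1.5, seed=1)
table, metadata, taxonomy = generate_cohorts(spec)
# cohorts come back in sorted group-label order: F first, then M
female, male = mgx.split_by_group(table, metadata, "site_1")

print("q    median(M)  median(F)  Wilcoxon p  Cohen's d  call")
for qi, q in enumerate((0, 1, 2, 3)):
    dm = [p.D[qi] for p in profiles_per_sample(male)]
    df = [p.D[qi] for p in profiles_per_sample(female)]
    cmp = mgx.compare_groups(dm, df)
    print(f"{q}    {cmp.medianA:9.1f}  {cmp.medianB:9.1f}  {cmp.wilcoxon_p:10.4f}"
          f"  {cmp.cohens_d:9.2f}  {cmp.direction}")

# The call column reads A~B when the rank-sum test finds no significant
# difference at alpha = 0.05 (A = M here).  The male cohort carries 25
# extra planted taxa, so richness (q=0) favors it; the higher orders weight
# dominance and can point the other way, as in this draw where the male
# community happens to be more uneven.
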