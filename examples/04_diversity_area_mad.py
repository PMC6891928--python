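"""Diversity-area relationship (DAR) and maximal accrual diversity (MAD).

Accumulates subjects in random orders, fits the power law with exponential
cutoff D = c*A^z*exp(dA) to the mean accrual curve, and reports the
theoretical maximum diversity D_max reached at A_max = -z/d subjects.
"""

import mgx
from mgx.synthetic import CohortSpec, generate_cohorts

spec = CohortSpec(n_samples=(60, 1), n_shared_taxa=300, n_specific_taxa=(0, 0),
                  lognormal_sd=2.5, depth_mean=2000.0, seed=9)
table, metadata, _ = generate_cohorts(spec)
cohort = table.select_samples([s for s in table.sample_ids if s.startswith("M")])

for q in (0, 1, 2):
    curve = mgx.dar_curve(cohort, q, n_orders=100, seed=0)
    fit = mgx.fit_dar(curve, "PLEC", q)
    est = mgx.mad(fit)
    print(f"q={q}: z = {fit.z:.3f}, d = {fit.d:.5f}, R^2 = {fit.r_squared:.4f}  "
          f"->  D_max = {est.D_max:.1f} effective species at A_max = {est.A_max:.0f} subjects")

# z is the diversity-scaling exponent; the negative cutoff d makes accrual
# saturate, and D_max estimates the cohort's potential ("dark") diversity
# beyond the subjects actually sampled.
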