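"""Generate a synthetic claims population and inspect its structure.

Draws 20,000 members with the default configuration (age-graded diabetes
risk, age-graded glucose-test ordering, ~53% of lab orders returning a
value) and prints the moments the generator targets.
"""

import cohortperm as cp

cfg = cp.SyntheticConfig(n_members=20_000, seed=1)
ds, truth = cp.generate(cfg)
summary = cp.empirical_summary(ds, truth)

print(f"members: {ds.n_members:,}   claim lines: {ds.n_events:,}")
print(f"latent T2D prevalence:        {summary['p_t2d']:.3f}")
print(f"latent depression prevalence: {summary['p_depression']:.3f}")
print(f"lab value-return fraction:    {summary['value_return_fraction']:.3f} "
      "(claims feeds only pass back a subset of ordered results)")
print(f"mean age, tested members:     {summary['mean_age_tested']:.1f}")
print(f"mean age, untested members:   {summary['mean_age_untested']:.1f} "
      "(testing intensity rises with age -> informative missingness)")
print("\nglucose-test orders per member-year by age decade:")
print(summary["tests_by_decade"].round(3).to_string())
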