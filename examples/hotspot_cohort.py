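"""Integration hot spots across a simulated 27-strain cohort.

Generates 27 strains whose tRNA genes receive integrations at tiered
probabilities (shares 0.02 / 0.05 / 0.11), runs the full per-strain pipeline,
tests the per-gene counts against a uniform expectation, and partitions the
per-gene frequencies into tiers.
"""

from prsmap import pipeline
from prsmap.simulate import generate_cohort

cohort = generate_cohort(n_strains=27, seed=100, length_bp=250_000)
results = [
    pipeline.analyze_strain(chrom, truth.all_features(), truth.probe)
    for chrom, truth in cohort
]

counts, gof, tiers = pipeline.hotspot_analysis(results)
print(f"{sum(counts.values())} integrations in {len(counts)} tRNA genes "
      f"across {len(results)} strains")
print(f"uniformity test: chi2 = {gof.statistic:.1f}, df = {gof.df}, "
      f"P = {gof.p_value:.2e}")
for i, tier in enumerate(tiers.tiers, 1):
    print(f"tier {i}: {len(tier.members)} genes, "
          f"mean frequency {tier.mean:.3f} +- {tier.sem:.3f}")
print("hot spots (top tier):", ", ".join(sorted(tiers.top.members)))
# A tiny uniformity P and a top tier of genes 010/030/039 reproduce the
# planted hot-spot structure: integration is site-specific, not uniform.
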