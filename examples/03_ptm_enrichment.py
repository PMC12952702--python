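"""PTM enrichment in disordered regions.

First reproduces the canonical pooled-count worked example, then runs the
full residue-level analysis on a simulated study with a planted
disordered-vs-ordered PTM odds ratio of 3.
"""

import math

from idrscope import (ContingencyTable2x2, SimConfig, call_regions,
                      density_comparison, fisher_enrichment, partition_ptms,
                      ptm_type_distribution, simulate_proteins,
                      simulate_ptms_and_mutations)

# Pooled counts: 1012 PTM-bearing vs 32068 PTM-free residues in IDRs,
# 831 vs 78059 in ordered regions.
table = ContingencyTable2x2(1012, 32068, 831, 78059)
res = fisher_enrichment(table, alternative="two_sided")
print(f"odds ratio {res.statistic:.3f}, two-sided p = 10^{math.log10(res.p_value):.1f}")
# PTMs are ~3x more likely per residue inside disorder.

# Simulated study: 500 proteins, planted odds ratio 3.
cfg = SimConfig(seed=11, n_proteins=500)
records, profiles, _, truth = simulate_proteins(cfg)
ptms, _, truth = simulate_ptms_and_mutations(cfg, records, truth)
regions = [r for rec in records
           for r in call_regions(profiles[rec.id], 0.5, 1, 0, len(rec))]
part = partition_ptms(ptms, regions)
fisher = fisher_enrichment(part.pooled)
print(f"recovered odds ratio {fisher.statistic:.2f} "
      f"(planted {cfg.ptm_odds_ratio}), p = 10^{math.log10(fisher.p_value):.0f}")

dens = density_comparison(part)
print(f"paired per-protein density test: {dens.method}, "
      f"p = 10^{math.log10(dens.p_value):.0f}")

dist = ptm_type_distribution(ptms, regions, scope="idr_only")
print("\nPTM-type percentages among IDR PTMs:")
for row in dist.itertuples(index=False):
    print(f"  {row.ptm_type:24s} {row.percent:5.1f}%")
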