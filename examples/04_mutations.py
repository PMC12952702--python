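"""Cancer-mutation mapping and the PTM-flanking permutation test.

Simulates a study in which 80% of mutations are placed within +/-5
residues of a PTM, maps mutations to regions, and asks whether the
observed co-location could arise by chance.
"""

from idrscope import (SimConfig, call_regions, flanking_enrichment,
                      flanking_pairs, map_mutations, simulate_dataset)

ds = simulate_dataset(SimConfig(seed=0))
regions = [r for rec in ds.records
           for r in call_regions(ds.disorder_profiles[rec.id], 0.5, 1, 0,
                                 len(rec))]
groups = {rec.id: rec.group for rec in ds.records}

mapping = map_mutations(ds.mutations, regions, groups=groups)
n_idr = int(mapping.table["in_idr"].sum())
print(f"{len(mapping.table)} mutations, {n_idr} inside IDRs")
print("mutated IDR residues per family:")
print(mapping.family_idr_counts.to_string())

pairs = flanking_pairs(ds.mutations, ds.ptms, window=5)
n_prot = len({p.protein_id for p in pairs})
print(f"\n{len(pairs)} (PTM, mutation) flanking pairs "
      f"on {n_prot} proteins (window = 5 residues)")

res = flanking_enrichment(ds.mutations, ds.ptms, regions, window=5,
                          n_perm=999, seed=1)
print(f"permutation test: {res.statistic:.0f} proteins with a flanking "
      f"pair, p = {res.p_value:.3f}")
# p ~ 0.001 (the smallest value 999 permutations can resolve): mutations
# sit near PTM sites far more often than uniform re-placement allows.
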