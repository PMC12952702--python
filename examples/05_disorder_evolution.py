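"""Disorder-to-order transitions (DOTs) over an ortholog family.

Simulates binary disorder characters over a 16-taxon tree, counts
minimum state changes per alignment column by parsimony, and reports the
normalized DOT rate and per-clade net gain of disorder.
"""

from idrscope import (SimConfig, build_character_matrix, dot_summary,
                      per_column_changes, simulate_dataset, ss_idr_site_set,
                      type_regions, call_regions)

ds = simulate_dataset(SimConfig(seed=0))
family = ds.families[0]
matrix = build_character_matrix(family, ds.family_regions[family.family_id])
print(f"family {family.family_id}: {matrix.n_columns} columns, "
      f"{len(matrix.leaf_labels)} orthologs")

changes = per_column_changes(matrix, family.tree)
scored = changes >= 0
print(f"scored columns: {int(scored.sum())}, "
      f"mean changes/column: {changes[scored].mean():.2f}")

ref_regions = [r for r in ds.truth.regions
               if r.protein_id == family.reference_id]
sites = ss_idr_site_set(ref_regions, matrix)
summary = dot_summary(matrix, family.tree, sites)
print(f"changes per node: {summary.changes_per_node:.3f}")
# Empirical DOT rates for conserved disordered proteins fall around
# 0.01-0.08 changes per node; simulated gain/loss of 0.05/edge lands there.

if summary.group_comparison:
    c = summary.group_comparison
    print(f"SS-IDR vs other disordered columns: U={c.statistic:.0f}, "
          f"p={c.p_value:.3g}")
else:
    print("group comparison:", "; ".join(summary.notes))

root_clade = min(summary.clade_net_gain)
print(f"net disorder gain at {root_clade}: "
      f"{summary.clade_net_gain[root_clade]:+d} "
      f"(0->1 minus 1->0 edge changes, summed over columns)")
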