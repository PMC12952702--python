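# idrscope

Analysis of intrinsically disordered regions (IDRs) in spliceosome
proteins: segment calling from per-residue disorder scores, typing of
disordered regions by compositional bias and secondary-structure content,
enrichment statistics for post-translational modifications (PTMs) and
cancer-associated mutations, and disorder-to-order transition (DOT)
analysis over ortholog phylogenies. A seeded synthetic-data generator
produces complete ground-truth-labeled datasets, so every stage is
testable without any database downloads.

Spliceosomal proteins — SR proteins, hnRNPs, snRNP components, and the
accessory factors of the E/A/B/Bact/C assembly states — are unusually
rich in disorder, and that disorder is where much of their regulation
happens: RS domains get phosphorylated, RGG boxes drive RNA binding and
condensation, and cancer mutations cluster in the same neighborhoods as
the modification sites. `idrscope` rebuilds the standard analysis chain
for this biology as a reusable, tested library.

## What it computes

**Region calling.** Residues with disorder score ≥ *t* (default 0.5) are
disorder-positive; maximal positive runs separated by ≤ `max_gap`
negatives merge, merged runs shorter than `min_len` are dropped, and the
complement is emitted as ordered, so regions tile the protein exactly.
Group summaries report the unweighted per-protein mean disorder
percentage, the residue-pooled mean, and the five-number summary
(quartiles by linear interpolation) with 1.5·IQR outliers.

**IDR typing.** Disordered regions of ≥ 25 residues are scanned with
25-residue windows for compositional bias: RS-like (R+S fraction ≥ 0.40
with ≥ 3 RS/SR dipeptides in a window), G-rich (Gly fraction ≥ 0.30 or
≥ 2 matches among RGG, [RSY]GG, R[AGT][AGTFIVR], poly-G), poly-P/Q
(homorepeat ≥ 5), charged (D/E/K/R fraction ≥ 0.35), and a noncharged
residual class (any residue ≥ 3× its vertebrate background frequency).
Precedence on multi-match is RS > G > PQ > CHARGED > NONCHARGED. Regions
whose residues sit ≥ 50% inside helix/strand runs of ≥ 4 residues are
SS-IDRs; the CB call is retained alongside.

**PTM statistics.** Residue-level partition into a 2×2 table
(PTM-bearing / PTM-free × disordered / ordered) tested with Fisher's
exact test (statistic = sample odds ratio *ad/bc*); paired Wilcoxon
signed-rank on per-protein PTM densities; annotation-level per-type
in-IDR ratios and type distributions.

**Mutation analysis.** Region mapping with per-family counts of distinct
mutated IDR residues and per-tumor-type counts; "flanking" pairs are
(PTM, mutation) pairs at distance ≤ 5 residues on the same protein,
tested against a within-protein uniform re-placement permutation null.

**Disorder evolution.** Each alignment column of an ortholog family
becomes a binary character (1 = disordered, 0 = ordered, gaps missing);
minimum state changes per column come from Fitch parsimony (Hartigan's
counting rule on polytomies, missing-as-ambiguous). The DOT rate is
normalized as changes per node = Σ changes / (edges × scored columns);
SS-IDR columns are compared to other disordered columns by Mann–Whitney
(exact enumeration for small groups), and per-clade net gain of disorder
counts 0→1 minus 1→0 edges under a deterministic leafward ancestral
assignment.

## Worked example

```python
from idrscope import ContingencyTable2x2, fisher_enrichment

table = ContingencyTable2x2(1012, 32068, 831, 78059)
res = fisher_enrichment(table, alternative="two_sided")
print(f"odds ratio {res.statistic:.3f}, p = 10^{__import__('math').log10(res.p_value):.1f}")
```

prints

```
odds ratio 2.964, two-sided p = 10^-114.8
```

i.e. with 1012 PTM-bearing among 33 080 disordered residues against 831
among 78 890 ordered residues, a residue inside disorder is about three
times as likely to carry a PTM, far beyond chance.

The `examples/` directory holds one short script per capability
(region calling, typing, PTM enrichment, mutation/flanking analysis,
disorder evolution, full pipeline). `examples/03_ptm_enrichment.py`
additionally simulates a 500-protein study with a planted odds ratio of
3 and prints

```
recovered odds ratio 3.05 (planted 3.0), p = 10^-226
paired per-protein density test: wilcoxon_signed_rank_two_sided, p = 10^-71
```

— the analysis chain recovers the parameter it was supposed to measure.

A thin CLI wraps the same functions:

```bash
idrscope simulate --seed 1 --n-proteins 60 --out data/
idrscope run --config pipeline.yaml     # all stages, TSV report + manifest
idrscope report-validate report/        # reconcile marginal totals
```

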