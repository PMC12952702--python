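# Methods

This note documents the models and conventions behind `idrscope`: what
each stage computes, which knobs matter, what the synthetic generator
does and does not emulate, and where genuinely open design choices were
resolved.

## Coordinates and input contracts

All residue coordinates are 1-based inclusive (UniProt convention), and
alignment columns are 1-based. Sequences are uppercased on input;
characters outside the 20 canonical amino acids become `X` and are
excluded from every composition denominator, which keeps frequency
statistics well-defined. Disorder evidence is a per-residue score in
[0, 1]; binary predictor output (0/1 labels) flows through the same
thresholding path unchanged. The package consumes predictor output — it
does not predict disorder or secondary structure itself. A
charge/hydropathy sliding-window score (`heuristic_disorder_score`) is
included strictly as demo plumbing and is labeled as such.

## Region calling

Segmentation is a run-length scan: residues with score ≥ `threshold`
(default 0.5) are positive; maximal positive runs separated by at most
`max_gap` negatives (default 0 — no smoothing unless asked) are merged;
merged runs shorter than `min_len` (default 1) are dropped; the
complement becomes ordered regions. The output always tiles 1..L, which
downstream stages rely on and tests enforce. The ≥ 25-residue length
rule belongs to compositional-bias typing, not to raw calling, so the
caller's default `min_len` is 1.

Group summaries distinguish the unweighted mean of per-protein disorder
percentages from the residue-pooled mean (long proteins dominate the
latter; the gap between the two is itself informative). Quartiles use
linear interpolation (numpy's default, "type 7"), fixed here because box
plot conventions differ between tools; outliers are points beyond
1.5·IQR fences. A protein belonging to several splicing complexes
contributes to each of them.

## IDR typing

Only the ≥ 25-residue bound is externally fixed; every other threshold
is a documented, config-exposed convention chosen so that clearly biased
segments classify and unbiased disorder does not:

| parameter | default | role |
|---|---|---|
| `cb_min_len` | 25 | minimum region length for CB typing |
| `window` | 25 | sliding-window size inside the region |
| `rs_frac` / `rs_min_dipeptides` | 0.40 / 3 | RS-like rule |
| `g_frac` / `g_min_motifs` | 0.30 / 2 | G-rich rule (fraction OR motif route) |
| `homorepeat_len` | 5 | poly-P/Q (and poly-G motif) run length |
| `charged_frac` | 0.35 | D/E/K/R window fraction |
| `bias_fold` | 3.0 | noncharged residual bias vs background |
| `ss_min_elem` / `ss_overlap_frac` | 4 / 0.50 | SS-IDR rule |

Whether G-richness should be defined by Gly fraction or by Gly-centred
motifs is ambiguous in practice; both routes are implemented with an OR.
Precedence on multi-match is RS > G > PQ > CHARGED > NONCHARGED; RS
outranks CHARGED deliberately, because Arg/Ser-rich domains of SR
proteins are conventionally reported as RS-like even though Arg is
charged. An SS-IDR call overrides the CB label for the primary subtype
but the CB call is retained in a secondary field, so reports can show SS
and CB content side by side without discarding either. The vertebrate
background composition ships as a constant table of average frequencies
(SwissProt-style) and can be replaced via TSV.

## PTM statistics

Enrichment is residue-level: a residue either hosts ≥ 1 PTM or it does
not, giving a pooled 2×2 table of PTM-bearing/PTM-free × disordered/
ordered residues, tested with Fisher's exact test. The reported
statistic is the sample odds ratio (a·d)/(b·c), ∞ when b·c = 0 with
a·d > 0. Tests are two-sided by default. Annotation-level counting
(every PTM record) is used only for per-type ratios and distributions,
where modifications rather than residues are the natural unit.

The per-protein density comparison is a **paired** Wilcoxon signed-rank
test: both densities (PTMs per disordered residue, PTMs per ordered
residue) come from the same protein, so pairing is the natural choice;
an unpaired Mann–Whitney variant is available via `paired=False`.
Proteins lacking one of the two compartments have an undefined density
and are excluded (counts logged in the result); zero differences are
dropped; the exact signed-rank null is used up to n = 25 non-zero pairs
and the continuity-corrected normal approximation beyond.

## Mutation analysis

"Flanking" means |Δposition| ≤ 5 inclusive, on the same protein.
Per-family counts use distinct mutated residues within IDRs (a residue
hit by several records counts once); per-tumor-type counts use mutation
records. No established closed-form test exists for "how many proteins
have a mutation near a PTM", so the package supplies a permutation test
as its own documented choice: mutations are re-placed uniformly within
their protein (optionally within the same region kind), PTMs stay fixed,
and p = (1 + #{null ≥ observed}) / (1 + n_perm) with the add-one rule.
Permutation results are bit-reproducible given (seed, n_perm).
Phenotype-ontology grouping is a pure group-by on supplied identifiers —
no ontology reasoning.

## Disorder evolution

Characters are binary per alignment column: 1 disordered, 0 ordered,
gaps missing. Columns with > 50% missing leaves (configurable) or fewer
than two informative leaves are unscored. Ancestral reconstruction uses
parsimony rather than likelihood — the quantity of interest is an
integer change count, parsimony is deterministic, and it admits
exhaustive validation. On bifurcating trees this is Fitch's set
recursion; on polytomies the plain set recursion undercounts (four
children with states 0,0,1,1 need two changes, not one), so Hartigan's
counting generalization is used: keep the states carried by the most
children, add (children − max count) changes. Missing leaves carry the
full state set, which provably matches pruning them for binary
characters; the test suite verifies equality with brute-force
minimization over all ancestral assignments for every rooted tree shape
(multifurcations included) up to 6 leaves and all labelings.

The normalized DOT rate is defined here as
changes per node = Σ per-column changes / (edge count × scored columns),
stated in output headers. Under per-edge flip probabilities of a few
percent this lands in the 0.01–0.08 range typical of conserved
disordered proteins.

SS-IDR site selection: a reference SS-IDR position enters group A if it
lies within `adjacency_cols` (default 1) alignment columns of an ordered
reference region, or if ≥ `ortholog_ordered_frac` (default 0.5) of the
non-missing ortholog states at its column are ordered — both parameters
are conventions, since "adjacent" has no canonical width. Group B is the
remaining disordered reference columns. The comparison is a two-sided
Mann–Whitney U with exact enumeration over index subsets when both
groups have ≤ 8 observations (tie-safe by construction) and the
tie-corrected, continuity-corrected normal approximation otherwise.

Per-clade net gain requires a single ancestral assignment: ambiguity is
resolved DELTRAN-style (a child keeps its parent's state whenever its
state set allows, pushing changes toward the leaves) with root ties
resolved to 0 (ordered). The assignment provably realizes the parsimony
minimum; clades are named by their lexicographically smallest leaf.
Unrooted input trees are midpoint-rooted with a logged notice (branch
lengths defaulting to 1 when absent), since the reconstruction needs a
root and midpoint is the least arbitrary choice.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with every stage driven by independent substreams spawned from one seed
(byte-identical datasets per config, stages regenerable in isolation).

*Proteins.* 60 proteins by default, lengths uniform in 200–600, per-
protein disorder fraction uniform in 0.25–0.65, laid out as 1–2
disordered segments (≥ 30 residues) between ordered segments. Ordered
residues draw from a hydrophobic-rich globular composition, generic
disordered residues from a disorder-promoting composition (P, Q, S, N, T
enriched). Scores are Normal(0.9, 0.05) inside true disorder and
Normal(0.1, 0.05) outside, clipped to [0, 1] and quantized to 6 decimals
so TSV round-trips are exact. A configurable fraction (0.30) of generic
disordered segments receives a helix run covering 60% of the segment
(SS-IDR truth); ordered segments get realistic mixed H/E/C states.

*Planted compositional bias.* The default motif plan assigns 8 proteins
each to RS, poly-P/Q, G-rich, and charged classes; the planted segment
(40 residues, or the protein's whole disorder budget when it has a
single disordered segment) *is* an entire disordered segment, drawn from
a class-specific composition: RS ≈ 42% R + 42% S; PQ ≈ 33% P + 33% Q
with one guaranteed 8-residue homorepeat; G ≈ 48% G with two guaranteed
RGG motifs and no Ser (so the RS dipeptide rule cannot fire); charged
≈ 74% D/E/K with no Arg (so Arg-centred G-motifs cannot fire). The
generic disordered background is deliberately kept clear of all CB
thresholds — charged mass ≈ 0.05, G ≈ 0.03, R ≈ 0.001, homorepeat runs
capped at 4 by construction — because the typing-recovery benchmark is
only meaningful when background disorder cannot trigger a planted class.
With these defaults, residue-level precision and recall of every planted
class stay ≥ 0.9 across seeds.

*PTMs and mutations.* PTMs are residue-wise Bernoulli with rate
`ptm_base_rate` = 0.01 in ordered truth and the rate solving
odds(p_idr)/odds(p_ord) = `ptm_odds_ratio` (default 3.0) in disordered
truth; types draw from a fixed categorical distribution dominated by
phosphoserine. Mutation counts are Poisson(0.004 × length); a
`flank_rate` = 0.8 fraction is placed uniformly within ±5 of a randomly
chosen PTM (a flank-scheduled mutation on a PTM-free protein is skipped,
so `flank_rate = 1` guarantees universal flanking), the rest uniformly;
tumor types and phenotype identifiers are random draws from small label
sets. The realized 2×2 table is recorded and equals what
`partition_ptms` recomputes from the emitted files.

*Families.* For 3 reference proteins (chosen among those without planted
CB segments), a random Yule topology with 16 leaves and exponential
branch lengths is generated; each reference residue's true state is the
root state, evolved down every edge with flip probabilities `gain_rate`
(0→1) and `loss_rate` (1→0), both 0.05 by default. Ortholog sequences
are re-emitted residue-wise from the state-specific compositions;
alignments are gap-free by default so coordinate mapping is exact, and
per-edge flip events are logged per column, giving the parsimony
lower-bound check (Fitch minimum ≤ simulated events) its ground truth.

*What the generator does not emulate* — and hence what passing tests do
not show about real data: real disorder predictors' correlated,
boundary-blurred score profiles; amino-acid substitution processes
(ortholog sequences are composition draws, not evolved sequences);
indels and alignment error; realistic tumor-type or phenotype
distributions; PTM-type-specific sequence context (phosphosites on S/T
residues, etc.); and inter-protein homology. Results on real datasets
additionally depend on the chosen disorder predictor and database
snapshots, which is why dataset-dependent headline numbers are not
reproduction targets at this scale.

## Numerical and engineering choices

Problem sizes are chosen for exactness and speed: 60-protein default
datasets (500 for enrichment recovery, where odds-ratio sampling error
must be small), 16-taxon trees, 200-column rate contrasts, 999
permutations. Exhaustive oracles (hypergeometric enumeration, all-tree
parsimony minimization, subset-enumeration Mann–Whitney) back every
bespoke statistic in the test suite. Ties in disorder ranking break by
accession; all pipeline outputs are pure functions of (inputs, config),
with a JSON manifest echoing the full configuration, a config hash, and
per-stage timings. p-values reported in log10 by the acceptance script
are floored at 1e-300 to avoid log-of-zero.

## Known limitations

Disorder calling has no hysteresis or predictor-consensus logic — one
score track in, one segmentation out. The SS-IDR rule counts helix and
strand runs identically and ignores run interruptions shorter than the
element minimum. The permutation flanking test conditions on the
observed number of mutations per protein. Fitch parsimony ignores branch
lengths; families with heavy gap content lose columns to the missing-
data threshold rather than being realigned. The per-clade net gain
depends on the stated ambiguity-resolution convention; alternative
resolutions (ACCTRAN) can shift individual clade totals while preserving
the overall change count.
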