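"""Ground-truth-labeled synthetic datasets for every pipeline stage.

The generator emulates a disordered-proteome study: proteins laid out as
alternating ordered/disordered segments, disorder scores concentrated
near 0.9 inside true disorder and 0.1 outside, compositionally biased
segments (RS-like, poly-P/Q, G-rich, charged) planted as whole disordered
segments, helix runs planted in a fraction of generic disordered segments
(SS-IDR truth), PTMs placed residue-wise with a controlled
disordered-vs-ordered odds ratio, mutations co-located with PTMs at a
controlled rate, and binary disorder characters evolved over Yule trees
with per-edge gain/loss probabilities.

Everything is driven by one seed through independent per-stage
substreams, so identical configs give byte-identical datasets and stages
can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import io as fio
from .model import (AnnotatedSite, ContingencyTable2x2, DisorderProfile,
                    OrthologFamily, ProteinRecord, Region, RegionKind,
                    SecondaryStructureProfile, SiteClass, Subtype)

AA = "ACDEFGHIKLMNPQRSTVWY"

#: Composition of generic (unbiased) disordered segments.  Enriched in
#: disorder-promoting residues (P, Q, S, G, E, K) yet kept clear of the
#: CB-typing thresholds so that only planted segments should classify.
DISORDER_COMP = {
    "A": 0.100, "C": 0.015, "D": 0.005, "E": 0.020, "F": 0.030,
    "G": 0.025, "H": 0.040, "I": 0.040, "K": 0.015, "L": 0.050,
    "M": 0.030, "N": 0.095, "P": 0.090, "Q": 0.070, "R": 0.001,
    "S": 0.130, "T": 0.090, "V": 0.055, "W": 0.010, "Y": 0.020,
}
_d_total = sum(DISORDER_COMP.values())
DISORDER_COMP = {k: v / _d_total for k, v in DISORDER_COMP.items()}

#: Composition of ordered (globular) segments: hydrophobic-rich.
GLOBULAR_COMP = {
    "A": 0.085, "C": 0.025, "D": 0.050, "E": 0.060, "F": 0.045,
    "G": 0.060, "H": 0.025, "I": 0.060, "K": 0.055, "L": 0.110,
    "M": 0.025, "N": 0.035, "P": 0.035, "Q": 0.035, "R": 0.050,
    "S": 0.055, "T": 0.050, "V": 0.075, "W": 0.015, "Y": 0.035,
}
_g_total = sum(GLOBULAR_COMP.values())
GLOBULAR_COMP = {k: v / _g_total for k, v in GLOBULAR_COMP.items()}

#: Compositions of planted CB segments, one per subtype.
PLANTED_COMPS = {
    Subtype.CB_RS: {"R": 0.42, "S": 0.42, "G": 0.03, "P": 0.03, "E": 0.03,
                    "D": 0.02, "T": 0.03, "A": 0.02},
    Subtype.CB_PQ: {"P": 0.33, "Q": 0.33, "S": 0.10, "G": 0.05, "A": 0.07,
                    "T": 0.07, "E": 0.05},
    # Ser-free so the RS-dipeptide rule can never fire inside G segments
    Subtype.CB_G: {"G": 0.48, "R": 0.06, "A": 0.11, "Y": 0.05,
                   "N": 0.13, "P": 0.06, "Q": 0.05, "T": 0.06},
    # acidic/basic without Arg, so the Arg-centred G-motifs cannot fire
    Subtype.CB_CHARGED: {"E": 0.27, "K": 0.27, "D": 0.20, "S": 0.05,
                         "T": 0.06, "A": 0.06, "P": 0.04, "G": 0.03,
                         "Q": 0.02},
}

PTM_TYPE_PROBS = {
    "phosphoserine": 0.45, "phosphothreonine": 0.15, "phosphotyrosine": 0.05,
    "N-acetylalanine": 0.10, "N-acetylserine": 0.05, "N6-acetyllysine": 0.08,
    "omega-N-methylarginine": 0.07, "citrulline": 0.05,
}

TUMOR_TYPES = ["carcinoma", "lymphoma", "melanoma", "leukemia", "sarcoma"]
PHENOTYPES = ["HP:0000951", "HP:0002664", "HP:0001871"]
GROUP_LABELS = ["SR protein", "hnRNP", "U1 snRNP", "U2 snRNP", "EJC",
                "NineTeen complex"]
COMPLEX_LABELS = ["E", "A", "pre-B", "B", "Bact", "C", "P"]


@dataclass
class SimConfig:
    """Study conditions of the synthetic dataset (see module docstring)."""

    n_proteins: int = 60
    length_range: tuple[int, int] = (200, 600)
    disorder_fraction_range: tuple[float, float] = (0.25, 0.65)
    #: per planted CB subtype: (number of proteins, planted segment length)
    motif_plan: dict[Subtype, tuple[int, int]] = field(default_factory=lambda: {
        Subtype.CB_RS: (8, 40), Subtype.CB_PQ: (8, 40),
        Subtype.CB_G: (8, 40), Subtype.CB_CHARGED: (8, 40)})
    ss_idr_frac: float = 0.30     # fraction of generic IDR segments given helix runs
    score_noise_sd: float = 0.05
    ptm_odds_ratio: float = 3.0
    ptm_base_rate: float = 0.01   # PTM probability per ordered residue
    mutation_rate: float = 0.004  # expected mutations per residue
    flank_rate: float = 0.8       # fraction of mutations forced within +/-5 of a PTM
    n_families: int = 3
    n_taxa: int = 16
    birth_rate: float = 1.0
    gain_rate: float = 0.05       # per-edge P(order -> disorder)
    loss_rate: float = 0.05       # per-edge P(disorder -> order)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.n_taxa < 1:
            raise ValueError("n_proteins and n_taxa must be >= 1")
        if not (0 < self.ptm_base_rate < 1):
            raise ValueError("ptm_base_rate must be in (0,1)")
        if self.ptm_odds_ratio <= 0:
            raise ValueError("ptm_odds_ratio must be > 0")
        if not (0 <= self.flank_rate <= 1):
            raise ValueError("flank_rate must be in [0,1]")
        for r in (self.gain_rate, self.loss_rate):
            if not (0 <= r < 1):
                raise ValueError("gain/loss rates must be in [0,1)")


@dataclass
class GroundTruth:
    """Bookkeeping of everything the generator planted."""

    regions: list[Region] = field(default_factory=list)
    disorder_fraction: dict[str, float] = field(default_factory=dict)
    ptm_table: ContingencyTable2x2 | None = None
    ptm_positions: dict[str, set[int]] = field(default_factory=dict)
    n_flanking_mutations: int = 0
    family_events: dict[str, np.ndarray] = field(default_factory=dict)
    family_leaf_states: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def realized_odds_ratio(self) -> float:
        return self.ptm_table.odds_ratio if self.ptm_table else float("nan")


def _streams(seed: int, n: int):
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n)]


def _draw_seq(rng, comp: dict[str, float], n: int,
              max_run: int | None = None) -> str:
    """Draw ``n`` residues i.i.d. from ``comp``.

    ``max_run`` caps homorepeat runs (a residue extending a run beyond the
    cap is redrawn); the generic disordered background uses this so that
    homorepeats exist only where the motif plan puts them.
    """
    letters = sorted(comp)
    p = np.array([comp[c] for c in letters])
    p = p / p.sum()
    drawn = list(rng.choice(list(letters), size=n, p=p))
    if max_run is not None:
        run = 1
        for i in range(1, n):
            run = run + 1 if drawn[i] == drawn[i - 1] else 1
            while run > max_run:
                drawn[i] = str(rng.choice(list(letters), p=p))
                run = run + 1 if drawn[i] == drawn[i - 1] else 1
    return "".join(drawn)


def _noisy_scores(rng, mean: float, sd: float, n: int) -> np.ndarray:
    # 6-decimal quantization keeps TSV round-trips exact
    return np.round(np.clip(rng.normal(mean, sd, n), 0.0, 1.0), 6)


def _split_budget(rng, total: int, parts: int, min_part: int) -> list[int]:
    """Split ``total`` into ``parts`` chunks, each >= min_part (greedy random)."""
    if parts == 0:
        return []
    if total < parts * min_part:
        min_part = max(0, total // parts)
    sizes = [min_part] * parts
    remainder = total - min_part * parts
    for _ in range(remainder):
        sizes[int(rng.integers(parts))] += 1
    return sizes


def simulate_proteins(config: SimConfig):
    """Generate sequences, disorder scores, SS states and the truth table.

    Returns ``(records, disorder_profiles, ss_profiles, truth)``.
    """
    rng = _streams(config.seed, 4)[0]
    plan: list[Subtype | None] = []
    for sub, (count, _) in sorted(config.motif_plan.items(),
                                  key=lambda kv: kv[0].value):
        plan.extend([sub] * count)
    if len(plan) > config.n_proteins:
        raise ValueError("motif_plan assigns more proteins than n_proteins")
    plan.extend([None] * (config.n_proteins - len(plan)))

    records, dprofiles, sprofiles = [], {}, {}
    truth = GroundTruth()
    lo_f, hi_f = config.disorder_fraction_range
    for i, planted in enumerate(plan):
        pid = f"P{i + 1:05d}"
        L = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        frac = float(rng.uniform(lo_f, hi_f))
        dis_total = max(30, int(round(frac * L)))
        dis_total = min(dis_total, L - 20)

        seg_len = config.motif_plan[planted][1] if planted else None
        if planted and seg_len > dis_total:
            raise ValueError(
                f"motif_plan segment length {seg_len} exceeds disordered "
                f"budget {dis_total} for {pid}")
        n_dis = int(rng.integers(1, 3))  # 1 or 2 disordered segments
        if planted:
            if n_dis > 1 and dis_total - seg_len >= 30:
                others = _split_budget(rng, dis_total - seg_len, n_dis - 1, 30)
            else:
                # keep the full disorder budget in the planted segment
                seg_len = max(seg_len, dis_total)
                others = []
            dis_sizes = [seg_len] + others
            dis_types: list[Subtype | None] = [planted] + [None] * len(others)
        else:
            dis_sizes = _split_budget(rng, dis_total, n_dis, 30)
            dis_sizes = [s for s in dis_sizes if s >= 30] or [dis_total]
            dis_types = [None] * len(dis_sizes)
        order_perm = rng.permutation(len(dis_sizes))
        dis_sizes = [dis_sizes[j] for j in order_perm]
        dis_types = [dis_types[j] for j in order_perm]
        ord_sizes = _split_budget(rng, L - sum(dis_sizes),
                                  len(dis_sizes) + 1, 10)

        seq_parts, score_parts, ss_parts = [], [], []
        cursor = 1
        for k, d_size in enumerate(dis_sizes):
            o_size = ord_sizes[k]
            if o_size:
                seq_parts.append(_draw_seq(rng, GLOBULAR_COMP, o_size))
                score_parts.append(
                    _noisy_scores(rng, 0.1, config.score_noise_sd, o_size))
                ss_parts.append("".join(
                    rng.choice(["H", "E", "C"], size=o_size, p=[0.35, 0.2, 0.45])))
                truth.regions.append(Region(pid, cursor, cursor + o_size - 1,
                                            RegionKind.ORDERED))
                cursor += o_size
            sub = dis_types[k]
            if sub is not None:
                seg = _draw_seq(rng, PLANTED_COMPS[sub], d_size)
                if sub is Subtype.CB_PQ:   # guarantee one homorepeat run
                    aa = "Q" if rng.random() < 0.5 else "P"
                    start = int(rng.integers(0, d_size - 8 + 1))
                    seg = seg[:start] + aa * 8 + seg[start + 8:]
                if sub is Subtype.CB_G:    # guarantee two Gly motifs
                    for start in (2, d_size - 6):
                        seg = seg[:start] + "RGG" + seg[start + 3:]
                ss_seg = "C" * d_size
                region_sub = sub
            else:
                seg = _draw_seq(rng, DISORDER_COMP, d_size, max_run=4)
                if rng.random() < config.ss_idr_frac:
                    run = max(4, int(0.6 * d_size))
                    start = int(rng.integers(0, d_size - run + 1))
                    ss_seg = "C" * start + "H" * run + "C" * (d_size - start - run)
                    region_sub = Subtype.SS_IDR
                else:
                    ss_seg = "C" * d_size
                    region_sub = Subtype.NONE
            seq_parts.append(seg)
            score_parts.append(
                _noisy_scores(rng, 0.9, config.score_noise_sd, d_size))
            ss_parts.append(ss_seg)
            truth.regions.append(Region(pid, cursor, cursor + d_size - 1,
                                        RegionKind.DISORDERED,
                                        subtype=region_sub))
            cursor += d_size
        o_size = ord_sizes[-1]
        if o_size:
            seq_parts.append(_draw_seq(rng, GLOBULAR_COMP, o_size))
            score_parts.append(
                _noisy_scores(rng, 0.1, config.score_noise_sd, o_size))
            ss_parts.append("".join(
                rng.choice(["H", "E", "C"], size=o_size, p=[0.35, 0.2, 0.45])))
            truth.regions.append(Region(pid, cursor, cursor + o_size - 1,
                                        RegionKind.ORDERED))
            cursor += o_size

        sequence = "".join(seq_parts)
        group = GROUP_LABELS[i % len(GROUP_LABELS)]
        n_cplx = int(rng.integers(1, 4))
        complexes = frozenset(rng.choice(COMPLEX_LABELS, size=n_cplx,
                                         replace=False))
        records.append(ProteinRecord(pid, sequence, group=group,
                                     complexes=complexes,
                                     abundant=bool(rng.random() < 0.3)))
        dprofiles[pid] = DisorderProfile(
            pid, tuple(float(s) for s in np.concatenate(score_parts)))
        sprofiles[pid] = SecondaryStructureProfile(pid, "".join(ss_parts))
        truth.disorder_fraction[pid] = sum(dis_sizes) / len(sequence)
    return records, dprofiles, sprofiles, truth


def _truth_mask(truth: GroundTruth, pid: str, length: int) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for r in truth.regions:
        if r.protein_id == pid and r.kind is RegionKind.DISORDERED:
            mask[r.start - 1:r.end] = True
    return mask


def simulate_ptms_and_mutations(config: SimConfig,
                                records: list[ProteinRecord],
                                truth: GroundTruth):
    """Place PTMs (controlled IDR/ordered odds ratio) and mutations
    (a ``flank_rate`` fraction forced within +/-5 residues of a PTM).

    Returns ``(ptm_sites, mutation_sites, truth)`` with the realized 2x2
    table recorded in the truth object.  Mutations scheduled to flank a
    PTM on a PTM-free protein are skipped, so ``flank_rate = 1`` implies
    every emitted mutation has a flanking PTM.
    """
    rng_ptm, rng_mut = _streams(config.seed, 4)[1:3]
    p_ord = config.ptm_base_rate
    odds_ord = p_ord / (1 - p_ord)
    odds_idr = config.ptm_odds_ratio * odds_ord
    p_idr = odds_idr / (1 + odds_idr)
    if p_idr >= 1.0:
        raise ValueError("ptm_odds_ratio x base rate gives p >= 1; "
                         "use a smaller ptm_base_rate")
    types = sorted(PTM_TYPE_PROBS)
    type_p = np.array([PTM_TYPE_PROBS[t] for t in types])
    type_p = type_p / type_p.sum()

    ptms: list[AnnotatedSite] = []
    a = b = c = d = 0
    for rec in records:
        L = len(rec)
        mask = _truth_mask(truth, rec.id, L)
        probs = np.where(mask, p_idr, p_ord)
        hits = rng_ptm.random(L) < probs
        a += int((hits & mask).sum())
        b += int((~hits & mask).sum())
        c += int((hits & ~mask).sum())
        d += int((~hits & ~mask).sum())
        positions = np.nonzero(hits)[0] + 1
        truth.ptm_positions[rec.id] = set(int(p) for p in positions)
        for pos in positions:
            label = str(rng_ptm.choice(types, p=type_p))
            ptms.append(AnnotatedSite(rec.id, int(pos), SiteClass.PTM, label))
    truth.ptm_table = ContingencyTable2x2(a, b, c, d)

    muts: list[AnnotatedSite] = []
    n_flank = 0
    for rec in records:
        L = len(rec)
        ptm_pos = sorted(truth.ptm_positions.get(rec.id, ()))
        n_mut = int(rng_mut.poisson(config.mutation_rate * L))
        for _ in range(n_mut):
            if rng_mut.random() < config.flank_rate:
                if not ptm_pos:
                    continue  # cannot flank on a PTM-free protein
                anchor = int(rng_mut.choice(ptm_pos))
                pos = int(np.clip(anchor + int(rng_mut.integers(-5, 6)), 1, L))
                n_flank += 1
            else:
                pos = int(rng_mut.integers(1, L + 1))
            ref = rec.sequence[pos - 1]
            alt = str(rng_mut.choice([x for x in AA if x != ref]))
            tumors = frozenset(rng_mut.choice(
                TUMOR_TYPES, size=int(rng_mut.integers(1, 3)), replace=False))
            phen = frozenset(rng_mut.choice(
                PHENOTYPES, size=int(rng_mut.integers(1, 3)), replace=False))
            muts.append(AnnotatedSite(rec.id, pos, SiteClass.MUTATION,
                                      f"{ref}{pos}{alt}", tumor_types=tumors,
                                      phenotype_ids=phen))
    truth.n_flanking_mutations = n_flank
    return ptms, muts, truth


def _yule_newick(rng, n_taxa: int, birth_rate: float,
                 leaf_names: list[str]) -> str:
    """Newick for a random Yule tree with exponential branch lengths."""
    nodes = {0: None, 1: None}  # leaf id -> newick fragment (filled at end)
    children: dict[int, list[int]] = {}
    counter = 2
    leaves = [0, 1]
    while len(leaves) < n_taxa:
        parent = leaves.pop(int(rng.integers(len(leaves))))
        kids = [counter, counter + 1]
        counter += 2
        children[parent] = kids
        leaves.extend(kids)

    lengths = {}

    def render(node: int) -> str:
        bl = lengths.setdefault(node, float(rng.exponential(1.0 / birth_rate)))
        if node in children:
            inner = ",".join(render(k) for k in children[node])
            return f"({inner}):{bl:.6f}"
        name = leaf_names[render.leaf_counter]
        render.leaf_counter += 1
        return f"{name}:{bl:.6f}"
    render.leaf_counter = 0
    left, right = render(0), render(1)
    return f"({left},{right});"


def simulate_families(config: SimConfig, records: list[ProteinRecord],
                      truth: GroundTruth):
    """Evolve binary disorder characters over Yule trees for
    ``n_families`` reference proteins (the last records, which carry no
    planted CB segment under the default motif plan and so can host
    SS-IDR truth segments).

    Returns ``(families, regions_by_sequence, truth)``; alignments are
    gap-free, ortholog sequences re-emitted from the state-specific
    composition tables, and per-edge flip events logged per column.
    """
    rng = _streams(config.seed, 4)[3]
    families: list[OrthologFamily] = []
    regions_by_sequence: dict[str, dict[str, list[Region]]] = {}
    for rec in records[-config.n_families:]:
        fam_id = f"FAM_{rec.id}"
        L = len(rec)
        leaf_names = [rec.id] + [f"{rec.id}_o{i}" for i in range(1, config.n_taxa)]
        newick = _yule_newick(rng, config.n_taxa, config.birth_rate, leaf_names)
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)

        root_states = _truth_mask(truth, rec.id, L).astype(np.int8)
        nodes = list(tree.preorder_node_iter())
        node_states: dict[int, np.ndarray] = {id(tree.seed_node): root_states}
        events = np.zeros(L, dtype=int)
        for node in nodes:
            if node is tree.seed_node:
                continue
            parent_states = node_states[id(node.parent_node)]
            flip_p = np.where(parent_states == 0, config.gain_rate,
                              config.loss_rate)
            flips = rng.random(L) < flip_p
            node_states[id(node)] = np.where(flips, 1 - parent_states,
                                             parent_states).astype(np.int8)
            events += flips.astype(int)

        alignment: dict[str, str] = {}
        fam_regions: dict[str, list[Region]] = {}
        for leaf in tree.leaf_node_iter():
            name = leaf.taxon.label
            states = node_states[id(leaf)]
            dis_draw = _draw_seq(rng, DISORDER_COMP, L)
            glob_draw = _draw_seq(rng, GLOBULAR_COMP, L)
            seq = "".join(dis_draw[i] if states[i] else glob_draw[i]
                          for i in range(L))
            alignment[name] = seq
            regions: list[Region] = []
            start = 1
            for pos in range(2, L + 2):
                if pos == L + 1 or states[pos - 1] != states[start - 1]:
                    kind = (RegionKind.DISORDERED if states[start - 1]
                            else RegionKind.ORDERED)
                    regions.append(Region(name, start, pos - 1, kind))
                    start = pos
            fam_regions[name] = regions
        family = OrthologFamily(family_id=fam_id, alignment=alignment,
                                tree=tree, reference_id=rec.id)
        families.append(family)
        regions_by_sequence[fam_id] = fam_regions
        truth.family_events[fam_id] = events
        truth.family_leaf_states[fam_id] = np.vstack(
            [node_states[id(leaf)] for leaf in tree.leaf_node_iter()])
    return families, regions_by_sequence, truth


@dataclass
class Dataset:
    """One complete simulated study."""

    config: SimConfig
    records: list[ProteinRecord]
    disorder_profiles: dict[str, DisorderProfile]
    ss_profiles: dict[str, SecondaryStructureProfile]
    ptms: list[AnnotatedSite]
    mutations: list[AnnotatedSite]
    families: list[OrthologFamily]
    family_regions: dict[str, dict[str, list[Region]]]
    truth: GroundTruth


def simulate_dataset(config: SimConfig | None = None) -> Dataset:
    """Run all three simulation stages under one config."""
    config = config or SimConfig()
    records, dprof, sprof, truth = simulate_proteins(config)
    ptms, muts, truth = simulate_ptms_and_mutations(config, records, truth)
    families, fam_regions, truth = simulate_families(config, records, truth)
    return Dataset(config, records, dprof, sprof, ptms, muts, families,
                   fam_regions, truth)


def write_dataset(dataset: Dataset, outdir: str | Path) -> None:
    """Emit the dataset as the pipeline's flat-file formats."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fio.write_fasta(dataset.records, out / "proteins.fasta")
    fio.write_profile_table(dataset.disorder_profiles, out / "disorder.tsv")
    fio.write_profile_table(dataset.ss_profiles, out / "ss.tsv")
    fio.write_site_table(dataset.ptms, out / "ptms.tsv")
    fio.write_site_table(dataset.mutations, out / "mutations.tsv")
    fio.write_metadata(dataset.records, out / "meta.tsv")
    fam_dir = out / "families"
    fam_dir.mkdir(exist_ok=True)
    fam_index = []
    for family in dataset.families:
        fio.write_family(family, fam_dir / f"{family.family_id}.afa",
                         fam_dir / f"{family.family_id}.nwk")
        regions = [r for regs in dataset.family_regions[family.family_id].values()
                   for r in regs]
        fio.write_regions(regions, fam_dir / f"{family.family_id}_regions.tsv")
        fam_index.append((family.family_id, family.reference_id))
    pd.DataFrame(fam_index, columns=["family_id", "reference_id"]).to_csv(
        out / "families.tsv", sep="\t", index=False)
    gt_dir = out / "ground_truth"
    gt_dir.mkdir(exist_ok=True)
    fio.write_regions(dataset.truth.regions, gt_dir / "regions.tsv")
    t = dataset.truth.ptm_table
    pd.DataFrame([{"a": t.a, "b": t.b, "c": t.c, "d": t.d,
                   "odds_ratio": t.odds_ratio}]).to_csv(
        gt_dir / "ptm_table.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(pid, f) for pid, f in sorted(dataset.truth.disorder_fraction.items())],
        columns=["protein_id", "true_disorder_fraction"]).to_csv(
        gt_dir / "disorder_fraction.tsv", sep="\t", index=False)
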