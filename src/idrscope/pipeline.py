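"""End-to-end orchestration: region calling -> typing -> PTM analysis ->
mutation analysis -> disorder-evolution analysis, with a machine-readable
run manifest.

Outputs are a pure function of (inputs, config); every table is TSV.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as fio
from .classify import TypingParams, read_background_tsv, type_regions, typing_report
from .evolution import build_character_matrix, dot_summary, ss_idr_site_set
from .model import ProteinRecord, Region, RegionKind
from .mutations import flanking_enrichment, flanking_pairs, map_mutations
from .ptm import (density_comparison, fisher_enrichment, partition_ptms,
                  ptm_idr_ratio, ptm_type_distribution)
from .regions import call_regions, disorder_fraction, summarize_group

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All inputs, thresholds and test options of one pipeline run."""

    fasta: str
    disorder_scores: str
    out_dir: str
    metadata: str | None = None
    ss_states: str | None = None
    ptm_sites: str | None = None
    mutation_sites: str | None = None
    families: str | None = None           # TSV: family_id, reference_id
    family_dir: str | None = None         # holds <fam>.afa/.nwk/_regions.tsv
    background: str | None = None
    threshold: float = 0.5
    min_len: int = 1
    max_gap: int = 0
    typing: TypingParams = field(default_factory=TypingParams)
    rank_cutoff: float = 70.0
    flank_window: int = 5
    n_perm: int = 999
    seed: int = 0
    alternative: str = "two_sided"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        typing = TypingParams(**raw.pop("typing", {}))
        return cls(typing=typing, **raw)


def rank_by_disorder(proteins: list[tuple[ProteinRecord, list[Region]]],
                     cutoff: float = 70.0) -> pd.DataFrame:
    """Proteins above a disorder-fraction cutoff, most disordered first.

    Ties are broken by accession so the output is deterministic; the
    ``abundant`` column allows splitting the table by abundance.
    """
    rows = []
    for rec, regions in proteins:
        pct = disorder_fraction(regions, len(rec))
        rows.append({"protein_id": rec.id, "disorder_percent": pct,
                     "group": rec.group, "abundant": rec.abundant})
    df = pd.DataFrame(rows)
    df = df[df["disorder_percent"] >= cutoff]
    return df.sort_values(["disorder_percent", "protein_id"],
                          ascending=[False, True]).reset_index(drop=True)


def _summary_frame(summaries) -> pd.DataFrame:
    rows = []
    for s in summaries:
        mn, q1, med, q3, mx = s.five_number
        rows.append({
            "group": s.group_label, "n_proteins": s.n_proteins,
            "per_protein_mean": s.per_protein_mean,
            "per_residue_mean": s.per_residue_mean,
            "min": mn, "q1": q1, "median": med, "q3": q3, "max": mx,
            "outliers": ";".join(f"{pid}:{p:.1f}" for pid, p in s.outliers)})
    return pd.DataFrame(rows)


def run_all(config: PipelineConfig) -> Path:
    """Execute every stage the supplied inputs allow; returns the report dir.

    Stage failures abort with the stage name prefixed to the error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "seeds": {"seed": config.seed}}
    t_start = time.time()

    def stage(name):
        def wrap(fn):
            t0 = time.time()
            try:
                result = fn()
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = {"seconds": round(time.time() - t0, 3)}
            log.info("stage %s done in %.2fs", name, time.time() - t0)
            return result
        return wrap

    records = stage("read_inputs")(lambda: fio.read_fasta(config.fasta))
    lengths = {r.id: len(r) for r in records}
    if config.metadata:
        fio.apply_metadata(records, fio.read_metadata(config.metadata))
    profiles = fio.read_profile_table(config.disorder_scores, "disorder")
    ss_profiles = (fio.read_profile_table(config.ss_states, "ss")
                   if config.ss_states else {})
    background = (read_background_tsv(config.background)
                  if config.background else None)

    def _call():
        regions = {}
        for rec in records:
            prof = profiles.get(rec.id)
            if prof is None:
                raise ValueError(f"no disorder profile for {rec.id}")
            regions[rec.id] = call_regions(
                prof, threshold=config.threshold, min_len=config.min_len,
                max_gap=config.max_gap, sequence_length=len(rec))
        return regions
    regions_by_protein = stage("call_regions")(_call)

    def _type():
        typed = {}
        for rec in records:
            typed[rec.id] = type_regions(
                rec, regions_by_protein[rec.id],
                ss=ss_profiles.get(rec.id), params=config.typing,
                background=background)
        return typed
    typed_regions = stage("typing")(_type)
    all_regions = [r for regs in typed_regions.values() for r in regs]
    fio.write_regions(all_regions, out / "typed_regions.tsv")

    pairs = [(rec, typed_regions[rec.id]) for rec in records]
    stage("summaries")(lambda: (
        _summary_frame(summarize_group(pairs, "by_class")).to_csv(
            out / "disorder_by_class.tsv", sep="\t", index=False),
        _summary_frame(summarize_group(pairs, "by_complex")).to_csv(
            out / "disorder_by_complex.tsv", sep="\t", index=False),
        typing_report(pairs).to_csv(out / "typing_by_class.tsv", sep="\t",
                                    index=False),
        rank_by_disorder(pairs, config.rank_cutoff).to_csv(
            out / "disorder_ranking.tsv", sep="\t", index=False)))

    groups = {rec.id: rec.group for rec in records}
    ptms = []
    if config.ptm_sites:
        def _ptm():
            sites, rejected = fio.read_site_table(config.ptm_sites, "PTM",
                                                  lengths=lengths)
            partition = partition_ptms(sites, all_regions)
            pooled = partition.pooled
            pd.DataFrame([{"a_ptm_idr": pooled.a, "b_free_idr": pooled.b,
                           "c_ptm_ordered": pooled.c,
                           "d_free_ordered": pooled.d}]).to_csv(
                out / "ptm_pooled_table.tsv", sep="\t", index=False)
            fisher = fisher_enrichment(pooled, config.alternative)
            density = density_comparison(partition, config.alternative)
            pd.DataFrame([
                {"test": fisher.method, "statistic": fisher.statistic,
                 "p_value": fisher.p_value},
                {"test": density.method, "statistic": density.statistic,
                 "p_value": density.p_value}]).to_csv(
                out / "ptm_tests.tsv", sep="\t", index=False)
            ptm_idr_ratio(sites, all_regions).to_csv(
                out / "ptm_type_ratios.tsv", sep="\t", header=True)
            ptm_type_distribution(sites, all_regions, "idr_only",
                                  groups=groups).to_csv(
                out / "ptm_type_distribution.tsv", sep="\t", index=False)
            manifest["stages"].setdefault("ptm", {})["rejected_sites"] = \
                len(rejected)
            return sites
        ptms = stage("ptm")(_ptm)
    else:
        manifest["stages"]["ptm"] = "skipped"

    if config.mutation_sites:
        def _mut():
            sites, _ = fio.read_site_table(config.mutation_sites, "MUTATION",
                                           lengths=lengths)
            mapping = map_mutations(sites, all_regions, groups=groups)
            mapping.table.to_csv(out / "mutations_mapped.tsv", sep="\t",
                                 index=False)
            mapping.family_idr_counts.to_csv(
                out / "mutations_by_family.tsv", sep="\t", header=True)
            mapping.tumor_type_idr_counts.to_csv(
                out / "mutations_by_tumor_type.tsv", sep="\t", header=True)
            if ptms:
                pairs_ = flanking_pairs(sites, ptms, config.flank_window)
                pd.DataFrame([{
                    "protein_id": p.protein_id, "ptm_position": p.ptm_position,
                    "mutation_position": p.mutation_position,
                    "distance": p.distance, "ptm_type": p.ptm_type}
                    for p in pairs_]).to_csv(
                    out / "flanking_pairs.tsv", sep="\t", index=False)
                enr = flanking_enrichment(
                    sites, ptms, all_regions, window=config.flank_window,
                    n_perm=config.n_perm, seed=config.seed)
                pd.DataFrame([{"test": enr.method,
                               "proteins_with_flank": enr.statistic,
                               "p_value": enr.p_value,
                               "n_perm": config.n_perm}]).to_csv(
                    out / "flanking_enrichment.tsv", sep="\t", index=False)
            return sites
        stage("mutations")(_mut)
    else:
        manifest["stages"]["mutations"] = "skipped"

    if config.families and config.family_dir:
        def _dot():
            fam_df = pd.read_csv(config.families, sep="\t")
            fam_dir = Path(config.family_dir)
            rows, clade_rows = [], []
            for row in fam_df.itertuples(index=False):
                family = fio.read_family(
                    fam_dir / f"{row.family_id}.afa",
                    fam_dir / f"{row.family_id}.nwk",
                    reference_id=row.reference_id, family_id=row.family_id)
                regs = fio.read_regions(
                    fam_dir / f"{row.family_id}_regions.tsv")
                by_seq: dict[str, list[Region]] = {}
                for r in regs:
                    by_seq.setdefault(r.protein_id, []).append(r)
                matrix = build_character_matrix(family, by_seq)
                ref_regions = typed_regions.get(row.reference_id,
                                                by_seq.get(row.reference_id, []))
                sites = ss_idr_site_set(ref_regions, matrix) \
                    if ref_regions else set()
                summary = dot_summary(matrix, family.tree, sites)
                comp = summary.group_comparison
                rows.append({
                    "family_id": row.family_id,
                    "changes_per_node": summary.changes_per_node,
                    "mw_U": comp.statistic if comp else float("nan"),
                    "mw_p": comp.p_value if comp else float("nan"),
                    "notes": ";".join(summary.notes)})
                for clade, gain in sorted(summary.clade_net_gain.items()):
                    clade_rows.append({"family_id": row.family_id,
                                       "clade": clade, "net_gain": gain})
            pd.DataFrame(rows).to_csv(out / "dot_summary.tsv", sep="\t",
                                      index=False)
            pd.DataFrame(clade_rows).to_csv(out / "dot_clade_gain.tsv",
                                            sep="\t", index=False)
        stage("evolution")(_dot)
    else:
        manifest["stages"]["evolution"] = "skipped"

    cfg_dict = asdict(config)
    manifest["config"] = cfg_dict
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True, default=str).encode()).hexdigest()
    manifest["total_seconds"] = round(time.time() - t_start, 3)
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out


def validate_report(out_dir: str | Path) -> list[str]:
    """Cross-check marginal totals of the report tables; returns problems."""
    out = Path(out_dir)
    problems: list[str] = []
    regions = fio.read_regions(out / "typed_regions.tsv")
    by_protein: dict[str, list[Region]] = {}
    for r in regions:
        by_protein.setdefault(r.protein_id, []).append(r)
    # tiling check
    for pid, regs in by_protein.items():
        regs = sorted(regs, key=lambda r: r.start)
        cursor = 1
        for r in regs:
            if r.start != cursor:
                problems.append(f"{pid}: region gap/overlap at {r.start}")
                break
            cursor = r.end + 1
    pooled_path = out / "ptm_pooled_table.tsv"
    if pooled_path.exists():
        pooled = pd.read_csv(pooled_path, sep="\t").iloc[0]
        total_residues = sum(max(r.end for r in regs)
                             for regs in by_protein.values())
        if int(pooled.sum()) != total_residues:
            problems.append(
                f"pooled 2x2 sums to {int(pooled.sum())}, expected "
                f"{total_residues} residues")
    dist_path = out / "ptm_type_distribution.tsv"
    if dist_path.exists():
        dist = pd.read_csv(dist_path, sep="\t")
        if len(dist):
            sums = dist.groupby("group")["percent"].sum()
            for group, s in sums.items():
                if abs(s - 100.0) > 1e-6:
                    problems.append(f"PTM distribution for {group} sums to {s}")
    return problems
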