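"""Cancer-associated mutation analysis: mapping variants onto regions,
family and tumor-type summaries, and the PTM-flanking co-location test.

"Flanking" means an absolute residue-index distance of at most ``window``
(default 5, inclusive) between a mutation and a PTM on the same protein.
The enrichment question — do mutations cluster near PTM sites more
often than chance? — is answered with a within-protein permutation
null: each protein's mutations are re-placed uniformly at
random and the number of proteins with at least one flanking pair is
recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import AnnotatedSite, Region, RegionKind, SiteClass, StatTestResult
from .regions import disorder_mask


@dataclass
class FlankingPair:
    """A (PTM, mutation) pair on one protein within the flanking window."""

    protein_id: str
    ptm_position: int
    mutation_position: int
    distance: int
    ptm_type: str
    phenotype_ids: frozenset[str]


@dataclass
class MutationMapping:
    """Region-annotated mutation table plus the two headline summaries."""

    table: pd.DataFrame                 # one row per mutation record
    family_idr_counts: pd.Series        # family -> distinct mutated IDR residues
    tumor_type_idr_counts: pd.Series    # tumor type -> mutations in IDRs


def _region_lookup(regions: list[Region]):
    by_protein: dict[str, list[Region]] = {}
    for r in regions:
        by_protein.setdefault(r.protein_id, []).append(r)
    for regs in by_protein.values():
        regs.sort(key=lambda r: r.start)

    def locate(pid: str, pos: int) -> Region | None:
        for r in by_protein.get(pid, ()):
            if r.contains(pos):
                return r
        return None

    return locate, by_protein


def map_mutations(sites: list[AnnotatedSite], regions: list[Region],
                  groups: dict[str, str] | None = None) -> MutationMapping:
    """Annotate each mutation with its region kind/subtype and summarize.

    ``family_idr_counts`` counts distinct mutated residues inside IDRs per
    protein family (a residue hit by several records counts once);
    ``tumor_type_idr_counts`` counts mutation records in IDRs per tumor
    type (a record with several tumor types contributes to each).
    """
    locate, _ = _region_lookup(regions)
    groups = groups or {}
    rows = []
    idr_residues: dict[str, set[tuple[str, int]]] = {}
    tumor_counts: dict[str, int] = {}
    for s in sites:
        if s.site_class is not SiteClass.MUTATION:
            continue
        region = locate(s.protein_id, s.position)
        kind = region.kind.value if region else "UNMAPPED"
        subtype = region.subtype.value if region else "NONE"
        in_idr = region is not None and region.kind is RegionKind.DISORDERED
        rows.append({
            "protein_id": s.protein_id, "position": s.position,
            "label": s.label, "region_kind": kind, "subtype": subtype,
            "in_idr": in_idr,
            "tumor_types": ";".join(sorted(s.tumor_types)),
            "phenotype_ids": ";".join(sorted(s.phenotype_ids)),
        })
        if in_idr:
            fam = groups.get(s.protein_id, "(unassigned)")
            idr_residues.setdefault(fam, set()).add((s.protein_id, s.position))
            for t in s.tumor_types:
                tumor_counts[t] = tumor_counts.get(t, 0) + 1
    table = pd.DataFrame(rows, columns=[
        "protein_id", "position", "label", "region_kind", "subtype",
        "in_idr", "tumor_types", "phenotype_ids"])
    fam_counts = pd.Series({f: len(v) for f, v in idr_residues.items()},
                           dtype=int, name="mutated_idr_residues").sort_index()
    tum_counts = pd.Series(tumor_counts, dtype=int,
                           name="idr_mutations").sort_index()
    return MutationMapping(table, fam_counts, tum_counts)


def flanking_pairs(mutations: list[AnnotatedSite], ptms: list[AnnotatedSite],
                   window: int = 5) -> list[FlankingPair]:
    """All (PTM, mutation) pairs on the same protein within ``window`` residues.

    A mutation may pair with several PTMs and vice versa.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    ptm_by_protein: dict[str, list[AnnotatedSite]] = {}
    for p in ptms:
        if p.site_class is SiteClass.PTM:
            ptm_by_protein.setdefault(p.protein_id, []).append(p)
    pairs = []
    for m in mutations:
        if m.site_class is not SiteClass.MUTATION:
            continue
        for p in ptm_by_protein.get(m.protein_id, ()):
            dist = abs(m.position - p.position)
            if dist <= window:
                pairs.append(FlankingPair(
                    protein_id=m.protein_id, ptm_position=p.position,
                    mutation_position=m.position, distance=dist,
                    ptm_type=p.label, phenotype_ids=m.phenotype_ids))
    pairs.sort(key=lambda fp: (fp.protein_id, fp.ptm_position,
                               fp.mutation_position))
    return pairs


def proteins_with_flanking(pairs: list[FlankingPair]) -> set[str]:
    return {p.protein_id for p in pairs}


def flanking_enrichment(mutations: list[AnnotatedSite],
                        ptms: list[AnnotatedSite],
                        regions: list[Region], window: int = 5,
                        n_perm: int = 999, seed: int = 0,
                        preserve_region_kind: bool = False) -> StatTestResult:
    """Permutation test for mutation/PTM co-location.

    Observed statistic: number of proteins with at least one flanking
    pair.  Null: each protein's mutations are re-positioned uniformly at
    random over its residues (restricted to positions of the same region
    kind when ``preserve_region_kind``), PTMs held fixed; p = (1 + #{null
    >= observed}) / (1 + n_perm).  Reproducible given (seed, n_perm).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    muts = [m for m in mutations if m.site_class is SiteClass.MUTATION]
    if not muts:
        raise ValueError("no mutations supplied")
    _, by_protein = _region_lookup(regions)
    lengths = {pid: max(r.end for r in regs) for pid, regs in by_protein.items()}

    ptm_pos: dict[str, np.ndarray] = {}
    for p in ptms:
        if p.site_class is SiteClass.PTM:
            ptm_pos.setdefault(p.protein_id, [])
    for p in ptms:
        if p.site_class is SiteClass.PTM:
            ptm_pos[p.protein_id].append(p.position)
    ptm_pos = {pid: np.asarray(sorted(v)) for pid, v in ptm_pos.items()}

    def has_flank(pid: str, positions: np.ndarray) -> bool:
        pp = ptm_pos.get(pid)
        if pp is None or len(pp) == 0 or len(positions) == 0:
            return False
        idx = np.searchsorted(pp, positions)
        left = np.clip(idx - 1, 0, len(pp) - 1)
        right = np.clip(idx, 0, len(pp) - 1)
        dmin = np.minimum(np.abs(positions - pp[left]),
                          np.abs(positions - pp[right]))
        return bool((dmin <= window).any())

    mut_by_protein: dict[str, list[AnnotatedSite]] = {}
    for m in muts:
        mut_by_protein.setdefault(m.protein_id, []).append(m)

    observed = sum(
        has_flank(pid, np.array([m.position for m in ms]))
        for pid, ms in mut_by_protein.items())

    # candidate positions per protein for the null
    candidates: dict[str, dict[str, np.ndarray]] = {}
    for pid, ms in mut_by_protein.items():
        L = lengths.get(pid)
        if L is None:
            raise ValueError(f"mutations on protein {pid} without regions")
        if preserve_region_kind:
            mask = disorder_mask(by_protein[pid], L)
            candidates[pid] = {
                "DISORDERED": np.nonzero(mask)[0] + 1,
                "ORDERED": np.nonzero(~mask)[0] + 1,
            }
        else:
            candidates[pid] = {"ANY": np.arange(1, L + 1)}

    locate, _ = _region_lookup(regions)
    mut_kinds: dict[str, list[str]] = {}
    for pid, ms in mut_by_protein.items():
        kinds = []
        for m in ms:
            if preserve_region_kind:
                r = locate(pid, m.position)
                kinds.append(r.kind.value if r else "ANY")
            else:
                kinds.append("ANY")
        mut_kinds[pid] = kinds

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        count = 0
        for pid, ms in mut_by_protein.items():
            pools = candidates[pid]
            new_pos = np.array([
                int(rng.choice(pools[k])) if len(pools.get(k, ())) else m.position
                for k, m in zip(mut_kinds[pid], ms)])
            if has_flank(pid, new_pos):
                count += 1
        if count >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return StatTestResult(
        statistic=float(observed), p_value=p,
        method="flanking_permutation",
        n={"n_perm": n_perm, "proteins_with_mutations": len(mut_by_protein),
           "window": window})
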