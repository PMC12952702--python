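"""PTM statistics: residue-level enrichment of modification sites in
disordered versus ordered regions, per-protein density comparison, and
PTM-type ratios / distributions.

Enrichment counts are residue-level (a residue either hosts at least one
PTM or it does not), matching a pooled 2x2 contingency layout of
PTM-bearing and PTM-free residues in the two compartments.  Type ratios
and distributions are annotation-level, counting every PTM record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import (AnnotatedSite, ContingencyTable2x2, Region, RegionKind,
                    SiteClass, StatTestResult)
from .regions import disorder_mask


def _group_regions(regions: list[Region]) -> dict[str, list[Region]]:
    by_protein: dict[str, list[Region]] = {}
    for r in regions:
        by_protein.setdefault(r.protein_id, []).append(r)
    return by_protein


def _lengths(by_protein: dict[str, list[Region]]) -> dict[str, int]:
    return {pid: max(r.end for r in rs) for pid, rs in by_protein.items()}


@dataclass
class PTMPartition:
    """Residue-level PTM counts per protein plus the pooled 2x2 table.

    ``per_protein`` maps protein id to (ptm_in_idr, non_ptm_in_idr,
    ptm_in_ordered, non_ptm_in_ordered); the four entries always sum to
    the protein length.
    """

    per_protein: dict[str, tuple[int, int, int, int]]

    @property
    def pooled(self) -> ContingencyTable2x2:
        sums = [0, 0, 0, 0]
        for counts in self.per_protein.values():
            for i, v in enumerate(counts):
                sums[i] += v
        return ContingencyTable2x2(*sums)


def partition_ptms(sites: list[AnnotatedSite],
                   regions: list[Region]) -> PTMPartition:
    """Count PTM-bearing vs PTM-free residues inside and outside IDRs.

    Each residue is counted exactly once; a residue carrying several PTM
    annotations is a single PTM-bearing site.  Every protein with regions
    contributes, PTMs or not.  A site on a protein without regions is an
    error.
    """
    by_protein = _group_regions(regions)
    lengths = _lengths(by_protein)
    orphans = sorted({s.protein_id for s in sites
                      if s.site_class is SiteClass.PTM
                      and s.protein_id not in by_protein})
    if orphans:
        raise ValueError(f"PTM sites on proteins without regions: {orphans}")

    ptm_positions: dict[str, set[int]] = {}
    for s in sites:
        if s.site_class is SiteClass.PTM:
            ptm_positions.setdefault(s.protein_id, set()).add(s.position)

    per_protein = {}
    for pid, regs in by_protein.items():
        L = lengths[pid]
        mask = disorder_mask(regs, L)
        ptm = np.zeros(L, dtype=bool)
        for pos in ptm_positions.get(pid, ()):
            ptm[pos - 1] = True
        a = int((ptm & mask).sum())
        b = int((~ptm & mask).sum())
        c = int((ptm & ~mask).sum())
        d = int((~ptm & ~mask).sum())
        per_protein[pid] = (a, b, c, d)
    return PTMPartition(per_protein)


def fisher_enrichment(table: ContingencyTable2x2,
                      alternative: str = "two_sided") -> StatTestResult:
    """Fisher's exact test on a pooled 2x2 table.

    The statistic is the sample odds ratio (a*d)/(b*c) (inf when b*c = 0
    and a*d > 0); the p-value is the exact hypergeometric tail.
    """
    alt = {"two_sided": "two-sided", "greater": "greater",
           "less": "less"}.get(alternative)
    if alt is None:
        raise ValueError(f"unknown alternative {alternative!r}")
    _, p = stats.fisher_exact(table.as_array(), alternative=alt)
    return StatTestResult(
        statistic=table.odds_ratio, p_value=float(min(p, 1.0)),
        method=f"fisher_exact_{alternative}",
        n={"a": table.a, "b": table.b, "c": table.c, "d": table.d})


def density_comparison(partition: PTMPartition,
                       alternative: str = "two_sided",
                       paired: bool = True) -> StatTestResult:
    """Compare per-protein PTM densities between IDRs and ordered regions.

    For each protein with residues in both compartments the densities
    ptm_in_idr/idr_len and ptm_in_ordered/ord_len are formed.  The default
    is a paired Wilcoxon signed-rank test on the differences (both
    densities come from the same protein); zero differences are dropped,
    the exact null distribution is used up to n = 25 and the
    continuity-corrected normal approximation beyond.  ``paired=False``
    falls back to a two-sample Mann-Whitney test.
    """
    alt = {"two_sided": "two-sided", "greater": "greater",
           "less": "less"}[alternative]
    d_idr, d_ord = [], []
    skipped = 0
    for a, b, c, d in partition.per_protein.values():
        idr_len, ord_len = a + b, c + d
        if idr_len == 0 or ord_len == 0:
            skipped += 1
            continue
        d_idr.append(a / idr_len)
        d_ord.append(c / ord_len)
    if len(d_idr) < 2:
        raise ValueError("fewer than 2 proteins with both compartments")
    if not paired:
        u, p = stats.mannwhitneyu(d_idr, d_ord, alternative=alt)
        return StatTestResult(float(u), float(p), f"mannwhitney_{alternative}",
                              n={"pairs": len(d_idr), "skipped": skipped})
    diffs = np.asarray(d_idr) - np.asarray(d_ord)
    nonzero = diffs[diffs != 0]
    if len(nonzero) < 2:
        raise ValueError("no nonzero density pairs to rank")
    method = "exact" if len(nonzero) <= 25 else "approx"
    res = stats.wilcoxon(nonzero, alternative=alt, correction=True,
                         method=method)
    return StatTestResult(float(res.statistic), float(res.pvalue),
                          f"wilcoxon_signed_rank_{alternative}",
                          n={"pairs": len(d_idr), "nonzero": len(nonzero),
                             "skipped": skipped})


def _in_idr_lookup(regions: list[Region]):
    by_protein = _group_regions(regions)
    masks = {pid: disorder_mask(regs, max(r.end for r in regs))
             for pid, regs in by_protein.items()}

    def in_idr(site: AnnotatedSite) -> bool:
        mask = masks.get(site.protein_id)
        if mask is None or site.position > len(mask):
            raise ValueError(
                f"site {site.protein_id}:{site.position} has no region cover")
        return bool(mask[site.position - 1])

    return in_idr


def ptm_idr_ratio(sites: list[AnnotatedSite],
                  regions: list[Region]) -> pd.Series:
    """Per PTM type: fraction of annotations located in IDRs.

    Annotation-level counting (every PTM record counts); types with zero
    total are omitted.
    """
    in_idr = _in_idr_lookup(regions)
    total: dict[str, int] = {}
    inside: dict[str, int] = {}
    for s in sites:
        if s.site_class is not SiteClass.PTM:
            continue
        total[s.label] = total.get(s.label, 0) + 1
        if in_idr(s):
            inside[s.label] = inside.get(s.label, 0) + 1
    ratio = {t: inside.get(t, 0) / n for t, n in total.items()}
    return pd.Series(ratio, name="idr_ratio").sort_index()


def ptm_type_distribution(sites: list[AnnotatedSite], regions: list[Region],
                          scope: str = "idr_only",
                          groups: dict[str, str] | None = None) -> pd.DataFrame:
    """Percentage of each PTM type among all PTMs in the chosen scope.

    ``scope`` is ``"idr_only"`` (PTMs falling in disordered regions) or
    ``"all"``.  When ``groups`` maps protein id to a class label the
    distribution is reported per class plus an "ALL" row; percentages sum
    to 100 within each stratum.  Empty scope yields an empty table.
    """
    if scope not in ("idr_only", "all"):
        raise ValueError(f"unknown scope {scope!r}")
    in_idr = _in_idr_lookup(regions)
    counts: dict[str, dict[str, int]] = {}
    for s in sites:
        if s.site_class is not SiteClass.PTM:
            continue
        if scope == "idr_only" and not in_idr(s):
            continue
        strata = ["ALL"]
        if groups is not None:
            strata.append(groups.get(s.protein_id, "(unassigned)"))
        for st in strata:
            counts.setdefault(st, {})
            counts[st][s.label] = counts[st].get(s.label, 0) + 1
    rows = []
    for stratum in sorted(counts):
        total = sum(counts[stratum].values())
        for label in sorted(counts[stratum]):
            rows.append({"group": stratum, "ptm_type": label,
                         "percent": 100.0 * counts[stratum][label] / total})
    return pd.DataFrame(rows, columns=["group", "ptm_type", "percent"])


def permuted_odds_ratios(partition: PTMPartition, n_perm: int,
                         seed: int) -> np.ndarray:
    """Null sample odds ratios from uniform within-protein PTM re-placement.

    Used to check calibration: under the permutation null the expected
    pooled odds ratio is 1.
    """
    rng = np.random.default_rng(seed)
    layouts = []
    for a, b, c, d in partition.per_protein.values():
        idr_len, ord_len = a + b, c + d
        layouts.append((idr_len, ord_len, a + c))
    ors = np.empty(n_perm)
    for k in range(n_perm):
        A = B = C = D = 0
        for idr_len, ord_len, n_ptm in layouts:
            L = idr_len + ord_len
            if L == 0:
                continue
            n_in = int(rng.hypergeometric(idr_len, ord_len, n_ptm)) if n_ptm else 0
            A += n_in
            B += idr_len - n_in
            C += n_ptm - n_in
            D += ord_len - (n_ptm - n_in)
        den = B * C
        ors[k] = math.inf if den == 0 else (A * D) / den
    return ors
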