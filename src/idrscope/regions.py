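"""Segmentation of per-residue disorder scores into ordered/disordered
regions, and group-level disorder summaries.

A residue is disorder-positive when its score is >= ``threshold``.
Maximal positive runs separated by at most ``max_gap`` negative residues
are merged into one segment; merged segments shorter than ``min_len`` are
dropped; whatever is not disordered is emitted as ORDERED, so the
returned regions always tile positions 1..L exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import DisorderProfile, ProteinRecord, Region, RegionKind

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2, "X": 0.0,
}


def call_regions(profile: DisorderProfile, threshold: float = 0.5,
                 min_len: int = 1, max_gap: int = 0,
                 sequence_length: int | None = None) -> list[Region]:
    """Segment a disorder profile into ORDERED/DISORDERED regions.

    Parameters mirror the segmentation rule in the module docstring.
    ``sequence_length``, when given, is checked against the profile length.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    L = len(profile)
    if sequence_length is not None and sequence_length != L:
        raise ValueError(
            f"{profile.protein_id}: profile length {L} != sequence length "
            f"{sequence_length}")

    positive = np.asarray(profile.scores) >= threshold
    # maximal positive runs as (start, end) 1-based
    runs: list[list[int]] = []
    i = 0
    while i < L:
        if positive[i]:
            j = i
            while j + 1 < L and positive[j + 1]:
                j += 1
            runs.append([i + 1, j + 1])
            i = j + 1
        else:
            i += 1
    # merge runs separated by <= max_gap negatives
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 <= max_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    kept = [(s, e) for s, e in merged if e - s + 1 >= min_len]

    regions: list[Region] = []
    cursor = 1
    for s, e in kept:
        if s > cursor:
            regions.append(Region(profile.protein_id, cursor, s - 1,
                                  RegionKind.ORDERED))
        regions.append(Region(profile.protein_id, s, e, RegionKind.DISORDERED))
        cursor = e + 1
    if cursor <= L:
        regions.append(Region(profile.protein_id, cursor, L, RegionKind.ORDERED))
    return regions


def validate_tiling(regions: list[Region], length: int) -> None:
    """Raise unless the regions tile 1..length without gaps or overlap."""
    if not regions:
        raise ValueError("no regions supplied")
    ordered = sorted(regions, key=lambda r: r.start)
    cursor = 1
    for r in ordered:
        if r.start != cursor:
            raise ValueError(
                f"{r.protein_id}: regions do not tile; expected start {cursor}, "
                f"got {r.start}")
        cursor = r.end + 1
    if cursor != length + 1:
        raise ValueError(
            f"{ordered[0].protein_id}: regions end at {cursor - 1}, "
            f"length is {length}")


def disorder_mask(regions: list[Region], length: int) -> np.ndarray:
    """Boolean per-residue mask (index 0 = residue 1) of disorder."""
    validate_tiling(regions, length)
    mask = np.zeros(length, dtype=bool)
    for r in regions:
        if r.kind is RegionKind.DISORDERED:
            mask[r.start - 1:r.end] = True
    return mask


def disorder_fraction(regions: list[Region], length: int) -> float:
    """Percent of residues in disordered regions (regions must tile 1..length)."""
    return 100.0 * float(disorder_mask(regions, length).sum()) / length


@dataclass
class GroupDisorderSummary:
    """Disorder statistics for one protein group (complex or class).

    ``per_protein_mean`` is the unweighted mean of per-protein disorder
    percentages; ``per_residue_mean`` pools residues across the group, so
    long proteins weigh more.  ``five_number`` holds (min, Q1, median, Q3,
    max) of the per-protein percentages with quartiles by linear
    interpolation; ``outliers`` are proteins outside the 1.5*IQR fences.
    """

    group_label: str
    n_proteins: int
    per_protein_mean: float = float("nan")
    per_residue_mean: float = float("nan")
    five_number: tuple[float, float, float, float, float] = (
        float("nan"),) * 5
    outliers: list[tuple[str, float]] = field(default_factory=list)

    @property
    def defined(self) -> bool:
        return self.n_proteins > 0


def _summarize_one(label: str,
                   members: list[tuple[ProteinRecord, float]],
                   residue_num: float, residue_den: int) -> GroupDisorderSummary:
    if not members:
        return GroupDisorderSummary(group_label=label, n_proteins=0)
    percents = np.array([p for _, p in members])
    q1, med, q3 = np.percentile(percents, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = [(rec.id, p) for rec, p in members if p < lo or p > hi]
    return GroupDisorderSummary(
        group_label=label, n_proteins=len(members),
        per_protein_mean=float(percents.mean()),
        per_residue_mean=100.0 * residue_num / residue_den,
        five_number=(float(percents.min()), float(q1), float(med), float(q3),
                     float(percents.max())),
        outliers=outliers)


def summarize_group(proteins: list[tuple[ProteinRecord, list[Region]]],
                    grouping: str = "by_class") -> list[GroupDisorderSummary]:
    """Per-group disorder summaries.

    ``grouping`` is ``"by_class"`` (each protein counted under its group
    label) or ``"by_complex"`` (a protein contributes to every splicing
    complex it belongs to).
    """
    if grouping not in ("by_class", "by_complex"):
        raise ValueError(f"unknown grouping {grouping!r}")
    buckets: dict[str, list[tuple[ProteinRecord, float]]] = {}
    res_num: dict[str, float] = {}
    res_den: dict[str, int] = {}
    for rec, regions in proteins:
        pct = disorder_fraction(regions, len(rec))
        n_dis = pct * len(rec) / 100.0
        labels = [rec.group] if grouping == "by_class" else sorted(rec.complexes)
        for label in labels:
            buckets.setdefault(label, []).append((rec, pct))
            res_num[label] = res_num.get(label, 0.0) + n_dis
            res_den[label] = res_den.get(label, 0) + len(rec)
    return [_summarize_one(label, buckets[label], res_num[label], res_den[label])
            for label in sorted(buckets)]


def heuristic_disorder_score(sequence: str, window: int = 21) -> DisorderProfile:
    """Crude charge/hydropathy sliding-window disorder score.

    Demo plumbing only: a 21-residue window is scored by how far its mean
    Kyte-Doolittle hydropathy falls below the charge-dependent folding
    boundary (low hydropathy + high net charge -> disorder-like).  This is
    NOT a disorder predictor; real analyses should supply per-residue
    scores from a dedicated predictor.
    """
    seq = sequence.upper()
    L = len(seq)
    half = window // 2
    hyd = np.array([KYTE_DOOLITTLE.get(c, 0.0) for c in seq])
    charge = np.array([1.0 if c in "KR" else (-1.0 if c in "DE" else 0.0)
                       for c in seq])
    scores = []
    for i in range(L):
        lo, hi = max(0, i - half), min(L, i + half + 1)
        h = (hyd[lo:hi].mean() + 4.5) / 9.0          # normalized to [0,1]
        r = abs(charge[lo:hi].mean())
        boundary = (r + 1.151) / 2.785               # Uversky-style boundary
        scores.append(float(np.clip(0.5 + 2.0 * (boundary - h), 0.0, 1.0)))
    return DisorderProfile("heuristic", tuple(scores))
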