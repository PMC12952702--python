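"""Readers and writers for the flat-file formats the pipeline touches.

FASTA for sequences and alignments, Newick for trees, TSV for every
site/score/region/metadata table.  All tables are plain tab-separated
files with a header row so fixtures stay diffable.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import dendropy
import pandas as pd
from Bio import SeqIO

from .model import (AnnotatedSite, CANONICAL_AA, DisorderProfile, OrthologFamily,
                    ProteinRecord, Region, RegionKind, SecondaryStructureProfile,
                    SiteClass, Subtype)

log = logging.getLogger(__name__)

_UNIPROT_HEADER = re.compile(r"^(?:sp|tr)\|([^|]+)\|")
_NONCANONICAL = re.compile(f"[^{CANONICAL_AA}X]")


def _header_to_id(header: str) -> str:
    """UniProt-style ``sp|ACC|NAME`` headers yield ACC; otherwise the first token."""
    m = _UNIPROT_HEADER.match(header)
    if m:
        return m.group(1)
    return header.split()[0]


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein sequences from FASTA into :class:`ProteinRecord` objects.

    Sequences are uppercased; characters outside the 20 canonical letters
    are mapped to X with a logged warning.  Empty files and duplicate ids
    raise ``ValueError``.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        pid = _header_to_id(entry.description or entry.id)
        if pid in seen:
            raise ValueError(f"duplicate protein id {pid!r} in {path}")
        seen.add(pid)
        seq = str(entry.seq).upper()
        if _NONCANONICAL.search(seq):
            n_bad = len(_NONCANONICAL.findall(seq))
            log.warning("%s: %d non-canonical residue(s) mapped to X", pid, n_bad)
            seq = _NONCANONICAL.sub("X", seq)
        records.append(ProteinRecord(id=pid, sequence=seq))
    if not records:
        raise ValueError(f"no FASTA entries found in {path}")
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i:i + 60] + "\n")


def _check_contiguous(pid: str, positions: list[int]) -> None:
    expect = list(range(1, len(positions) + 1))
    if positions != expect:
        missing = sorted(set(expect) - set(positions))
        dupes = sorted({p for p in positions if positions.count(p) > 1}) \
            if len(set(positions)) != len(positions) else []
        parts = []
        if missing:
            parts.append(f"missing position(s) {missing[:10]}")
        if dupes:
            parts.append(f"duplicated position(s) {dupes[:10]}")
        if not parts:  # e.g. does not start at 1
            parts.append(f"positions not contiguous from 1 (got {positions[:5]}...)")
        raise ValueError(f"{pid}: " + "; ".join(parts))


def read_profile_table(path: str | Path, kind: str):
    """Read a per-residue TSV (protein_id, position, value) into profiles.

    ``kind`` is ``"disorder"`` (float scores in [0,1]) or ``"ss"``
    (H/E/C states).  Positions must be contiguous 1..L per protein.
    Returns a dict keyed by protein id.
    """
    if kind not in ("disorder", "ss"):
        raise ValueError(f"unknown profile kind {kind!r}")
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    for col in ("protein_id", "position", "value"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    profiles = {}
    for pid, sub in df.groupby("protein_id", sort=False):
        sub = sub.sort_values("position")
        _check_contiguous(pid, [int(p) for p in sub["position"]])
        if kind == "disorder":
            vals = [float(v) for v in sub["value"]]
            for pos, v in zip(sub["position"], vals):
                if not (0.0 <= v <= 1.0):
                    raise ValueError(
                        f"{pid}: disorder value {v} at position {pos} outside [0, 1]")
            profiles[pid] = DisorderProfile(pid, tuple(vals))
        else:
            profiles[pid] = SecondaryStructureProfile(
                pid, "".join(str(v) for v in sub["value"]))
    return profiles


def write_profile_table(profiles: dict, path: str | Path) -> None:
    rows = []
    for pid, prof in profiles.items():
        values = prof.scores if isinstance(prof, DisorderProfile) else prof.states
        for i, v in enumerate(values, start=1):
            rows.append((pid, i, v))
    pd.DataFrame(rows, columns=["protein_id", "position", "value"]).to_csv(
        path, sep="\t", index=False)


def _split_set(value) -> frozenset[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return frozenset()
    return frozenset(part for part in str(value).split(";") if part)


def read_site_table(path: str | Path, site_class: SiteClass | str,
                    lengths: dict[str, int] | None = None):
    """Read a PTM or mutation TSV into :class:`AnnotatedSite` objects.

    Columns: protein_id, position, label, and (mutations) optional
    semicolon-delimited tumor_types / phenotype_ids.  When ``lengths`` is
    supplied, out-of-range sites are rejected and returned in a report.

    Returns ``(sites, rejected)`` where ``rejected`` lists
    ``(protein_id, position, reason)`` tuples.
    """
    site_class = SiteClass(site_class)
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "label": str})
    for col in ("protein_id", "position", "label"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    sites: list[AnnotatedSite] = []
    rejected: list[tuple[str, object, str]] = []
    for row in df.itertuples(index=False):
        try:
            pos = int(row.position)
            if pos != float(row.position):
                raise ValueError
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}: non-integer position {row.position!r} for {row.protein_id}")
        site = AnnotatedSite(
            protein_id=row.protein_id, position=pos, site_class=site_class,
            label=str(row.label),
            tumor_types=_split_set(getattr(row, "tumor_types", None)),
            phenotype_ids=_split_set(getattr(row, "phenotype_ids", None)))
        if lengths is not None:
            L = lengths.get(site.protein_id)
            if L is None:
                rejected.append((site.protein_id, pos, "unknown protein"))
                continue
            if pos > L:
                rejected.append((site.protein_id, pos, f"position > length {L}"))
                continue
        sites.append(site)
    if rejected:
        log.warning("%s: rejected %d out-of-range site(s)", path, len(rejected))
    return sites, rejected


def write_site_table(sites: list[AnnotatedSite], path: str | Path) -> None:
    rows = [(s.protein_id, s.position, s.label,
             ";".join(sorted(s.tumor_types)), ";".join(sorted(s.phenotype_ids)))
            for s in sites]
    pd.DataFrame(rows, columns=["protein_id", "position", "label",
                                "tumor_types", "phenotype_ids"]).to_csv(
        path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Protein metadata TSV: protein_id, group, complexes (semicolon list), abundant."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "group": str})
    df["complexes"] = df.get("complexes", "").map(_split_set)
    df["abundant"] = df.get("abundant", False).astype(bool)
    return df


def apply_metadata(records: list[ProteinRecord], meta: pd.DataFrame) -> None:
    """Attach group/complex/abundance labels to records in place."""
    by_id = meta.set_index("protein_id")
    for rec in records:
        if rec.id in by_id.index:
            row = by_id.loc[rec.id]
            rec.group = str(row.get("group", "") or "")
            rec.complexes = frozenset(row.get("complexes", frozenset()))
            rec.abundant = bool(row.get("abundant", False))


def write_metadata(records: list[ProteinRecord], path: str | Path) -> None:
    rows = [(r.id, r.group, ";".join(sorted(r.complexes)), r.abundant)
            for r in records]
    pd.DataFrame(rows, columns=["protein_id", "group", "complexes",
                                "abundant"]).to_csv(path, sep="\t", index=False)


REGION_COLUMNS = ["protein_id", "start", "end", "kind", "subtype",
                  "cb_subtype", "alpha_frac", "beta_frac"]


def write_regions(regions: list[Region], path: str | Path) -> None:
    rows = [(r.protein_id, r.start, r.end, r.kind.value, r.subtype.value,
             r.cb_subtype.value, r.alpha_frac, r.beta_frac) for r in regions]
    pd.DataFrame(rows, columns=REGION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_regions(path: str | Path) -> list[Region]:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    return [Region(protein_id=row.protein_id, start=int(row.start),
                   end=int(row.end), kind=RegionKind(row.kind),
                   subtype=Subtype(row.subtype),
                   cb_subtype=Subtype(getattr(row, "cb_subtype", "NONE")),
                   alpha_frac=float(getattr(row, "alpha_frac", 0.0)),
                   beta_frac=float(getattr(row, "beta_frac", 0.0)))
            for row in df.itertuples(index=False)]


def read_family(alignment_path: str | Path, tree_path: str | Path,
                reference_id: str, family_id: str | None = None) -> OrthologFamily:
    """Load an ortholog family from aligned FASTA + Newick.

    The tree must be rooted; an unrooted tree (basal polytomy) is
    midpoint-rooted with a logged notice, since ancestral-state analysis
    needs a root and branch lengths make midpoint the least arbitrary
    choice.  Polytomies elsewhere are preserved.
    """
    alignment: dict[str, str] = {}
    for entry in SeqIO.parse(str(alignment_path), "fasta"):
        pid = _header_to_id(entry.description or entry.id)
        if pid in alignment:
            raise ValueError(f"duplicate aligned sequence id {pid!r}")
        alignment[pid] = str(entry.seq).upper()
    if not alignment:
        raise ValueError(f"no aligned sequences in {alignment_path}")

    tree = dendropy.Tree.get(path=str(tree_path), schema="newick",
                             preserve_underscores=True)
    if len(tree.seed_node.child_nodes()) > 2 and len(tree.leaf_nodes()) > 2:
        log.info("%s: unrooted tree (basal polytomy); midpoint-rooting", tree_path)
        for edge in tree.preorder_edge_iter():
            if edge.length is None:
                edge.length = 1.0
        tree.reroot_at_midpoint(update_bipartitions=False)
    return OrthologFamily(
        family_id=family_id or Path(str(alignment_path)).stem,
        alignment=alignment, tree=tree, reference_id=reference_id)


def write_family(family: OrthologFamily, alignment_path: str | Path,
                 tree_path: str | Path) -> None:
    with open(alignment_path, "w") as fh:
        for pid, seq in family.alignment.items():
            fh.write(f">{pid}\n{seq}\n")
    family.tree.write(path=str(tree_path), schema="newick",
                      suppress_rooting=True, unquoted_underscores=True)
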