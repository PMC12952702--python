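"""Typing of disordered regions: compositional-bias (CB) subtypes and
secondary-structure-containing IDRs (SS-IDRs).

CB subtypes follow the field's usual low-complexity classes for splicing
factors: RS-like (Arg/Ser-rich with RS/SR dipeptides, the hallmark of SR
proteins), poly-P/Q homorepeats, G-rich (Gly fraction or Gly-centred
motifs RGG / [RSY]GG / R[AGT][AGTFIVR]), charged (D/E/K/R-rich), and a
noncharged residual class for any other strong single-residue bias
relative to a vertebrate background composition.  Only regions of at
least ``cb_min_len`` (default 25) residues are considered compositionally
biased.  When one region satisfies several classes the precedence is
RS > G > PQ > CHARGED > NONCHARGED.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import (CB_SUBTYPES, ProteinRecord, Region, RegionKind,
                    SecondaryStructureProfile, Subtype)

#: Average vertebrate amino-acid frequencies (SwissProt-style averages,
#: rounded and renormalized).  Replaceable via a two-column TSV.
VERTEBRATE_BACKGROUND: dict[str, float] = {
    "A": 0.0702, "R": 0.0558, "N": 0.0359, "D": 0.0473, "C": 0.0222,
    "Q": 0.0475, "E": 0.0710, "G": 0.0657, "H": 0.0262, "I": 0.0434,
    "L": 0.0996, "K": 0.0573, "M": 0.0221, "F": 0.0365, "P": 0.0630,
    "S": 0.0833, "T": 0.0536, "W": 0.0122, "Y": 0.0266, "V": 0.0606,
}


@dataclass
class BackgroundComposition:
    """Expected amino-acid frequencies used by the noncharged-bias test."""

    freq: dict[str, float] = field(
        default_factory=lambda: dict(VERTEBRATE_BACKGROUND))

    def __post_init__(self) -> None:
        if set(self.freq) != set("ACDEFGHIKLMNPQRSTVWY"):
            raise ValueError("background must cover exactly the 20 canonical letters")
        total = sum(self.freq.values())
        if abs(total - 1.0) > 1e-6:
            self.freq = {k: v / total for k, v in self.freq.items()}


@dataclass
class TypingParams:
    """Thresholds of the region-typing rules.

    Only ``cb_min_len`` (25 residues) is fixed by the analysis design; the
    remaining values are tunable conventions, all evaluated over sliding
    windows of ``window`` residues within the region.
    """

    cb_min_len: int = 25
    window: int = 25
    rs_frac: float = 0.40          # min (R+S) fraction in some window
    rs_min_dipeptides: int = 3     # min RS/SR dipeptides in that window
    homorepeat_len: int = 5        # min P/Q (or G) homorepeat run
    g_frac: float = 0.30           # min Gly fraction in some window
    g_min_motifs: int = 2          # or: min G-motif matches in some window
    charged_frac: float = 0.35     # min D/E/K/R fraction in some window
    bias_fold: float = 3.0         # region freq >= fold x background
    ss_min_elem: int = 4           # min helix/strand run length
    ss_overlap_frac: float = 0.50  # min fraction of region in SS runs

    def __post_init__(self) -> None:
        for name in ("rs_frac", "g_frac", "charged_frac", "ss_overlap_frac"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0,1], got {v}")
        for name in ("cb_min_len", "window", "rs_min_dipeptides",
                     "homorepeat_len", "g_min_motifs", "ss_min_elem"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


MOTIF_PATTERNS = {
    "RGG": re.compile(r"(?=(RGG))"),
    "XGG": re.compile(r"(?=([RSY]GG))"),
    "RXT": re.compile(r"(?=(R[AGT][AGTFIVR]))"),
    "RS_DIPEPTIDE": re.compile(r"(?=(RS|SR))"),
}
_HOMOREPEATS = {"POLY_P": "P", "POLY_Q": "Q", "POLY_G": "G"}


def find_motifs(sequence: str, motif_set, homorepeat_len: int = 5):
    """Locate motif occurrences (1-based inclusive coordinates).

    ``motif_set`` draws from {RGG, XGG, RXT, POLY_P, POLY_Q, POLY_G,
    RS_DIPEPTIDE}.  Overlapping matches are all reported; POLY_* motifs
    report maximal homorepeat runs of length >= ``homorepeat_len``.
    """
    hits: list[tuple[str, int, int]] = []
    for motif in motif_set:
        if motif in MOTIF_PATTERNS:
            for m in MOTIF_PATTERNS[motif].finditer(sequence):
                hits.append((motif, m.start() + 1, m.start() + len(m.group(1))))
        elif motif in _HOMOREPEATS:
            aa = _HOMOREPEATS[motif]
            for m in re.finditer(f"{aa}{{{homorepeat_len},}}", sequence):
                hits.append((motif, m.start() + 1, m.end()))
        else:
            raise ValueError(f"unknown motif label {motif!r}")
    return sorted(hits, key=lambda h: (h[1], h[2], h[0]))


def _window_fracs(seq: str, letters: str, window: int) -> np.ndarray:
    """Per-window fraction of ``letters``, denominator excluding X."""
    L = len(seq)
    w = min(window, L)
    hit = np.array([c in letters for c in seq], dtype=float)
    valid = np.array([c != "X" for c in seq], dtype=float)
    ch = np.concatenate([[0.0], np.cumsum(hit)])
    cv = np.concatenate([[0.0], np.cumsum(valid)])
    num = ch[w:] - ch[:-w]
    den = cv[w:] - cv[:-w]
    with np.errstate(invalid="ignore", divide="ignore"):
        fr = np.where(den > 0, num / den, 0.0)
    return fr


def _window_motif_counts(seq: str, motifs, window: int,
                         homorepeat_len: int) -> np.ndarray:
    """Number of motif matches fully inside each sliding window."""
    L = len(seq)
    w = min(window, L)
    hits = find_motifs(seq, motifs, homorepeat_len=homorepeat_len)
    counts = np.zeros(L - w + 1, dtype=int)
    for _, s, e in hits:
        lo = max(0, e - w)          # window starts (0-based) covering [s,e]
        hi = min(L - w, s - 1)
        if lo <= hi:
            counts[lo:hi + 1] += 1
    return counts


def classify_cb(record: ProteinRecord, region: Region,
                params: TypingParams | None = None,
                background: BackgroundComposition | None = None) -> Region:
    """Assign a compositional-bias subtype to one disordered region.

    Returns a copy of the region with ``subtype`` set (NONE when the
    region is shorter than ``cb_min_len`` or shows no qualifying bias).
    The call depends only on the residues inside the region.
    """
    params = params or TypingParams()
    background = background or BackgroundComposition()
    if region.kind is not RegionKind.DISORDERED:
        raise ValueError("classify_cb expects a disordered region")
    if region.end > len(record):
        raise ValueError(
            f"{record.id}: region {region.start}..{region.end} outside sequence")
    seq = record.sequence[region.start - 1:region.end]
    if len(seq) < params.cb_min_len:
        return replace(region, subtype=Subtype.NONE)

    w = params.window
    rs_frac = _window_fracs(seq, "RS", w)
    rs_dipep = _window_motif_counts(seq, {"RS_DIPEPTIDE"}, w,
                                    params.homorepeat_len)
    is_rs = bool(np.any((rs_frac >= params.rs_frac)
                        & (rs_dipep >= params.rs_min_dipeptides)))

    g_frac = _window_fracs(seq, "G", w)
    g_motifs = _window_motif_counts(seq, {"RGG", "XGG", "RXT", "POLY_G"}, w,
                                    params.homorepeat_len)
    is_g = bool(np.any(g_frac >= params.g_frac)
                or np.any(g_motifs >= params.g_min_motifs))

    pq_hits = find_motifs(seq, {"POLY_P", "POLY_Q"},
                          homorepeat_len=params.homorepeat_len)
    is_pq = bool(pq_hits)

    is_charged = bool(np.any(_window_fracs(seq, "DEKR", w)
                             >= params.charged_frac))

    if is_rs:
        sub = Subtype.CB_RS
    elif is_g:
        sub = Subtype.CB_G
    elif is_pq:
        sub = Subtype.CB_PQ
    elif is_charged:
        sub = Subtype.CB_CHARGED
    else:
        sub = Subtype.NONE
        denom = sum(1 for c in seq if c != "X")
        if denom:
            for aa, bg in background.freq.items():
                if seq.count(aa) / denom >= params.bias_fold * bg:
                    sub = Subtype.CB_NONCHARGED
                    break
    return replace(region, subtype=sub)


def _qualifying_run_mask(states: str, letter: str, min_len: int) -> np.ndarray:
    mask = np.zeros(len(states), dtype=bool)
    for m in re.finditer(f"{letter}+", states):
        if m.end() - m.start() >= min_len:
            mask[m.start():m.end()] = True
    return mask


def annotate_ss_idr(region: Region, ss: SecondaryStructureProfile,
                    params: TypingParams | None = None) -> Region:
    """Flag a disordered region as SS-IDR when enough of it sits in
    helix/strand runs.

    Runs of H or E with length >= ``ss_min_elem`` are computed on the whole
    profile; if the in-region residues covered by such runs reach
    ``ss_overlap_frac`` of the region, the primary subtype becomes SS_IDR
    and any prior CB call is kept in ``cb_subtype``.  ``alpha_frac`` /
    ``beta_frac`` are always set.
    """
    params = params or TypingParams()
    if region.kind is not RegionKind.DISORDERED:
        raise ValueError("annotate_ss_idr expects a disordered region")
    if region.end > len(ss):
        raise ValueError(
            f"{region.protein_id}: region end {region.end} beyond profile "
            f"length {len(ss)}")
    h_mask = _qualifying_run_mask(ss.states, "H", params.ss_min_elem)
    e_mask = _qualifying_run_mask(ss.states, "E", params.ss_min_elem)
    lo, hi = region.start - 1, region.end
    n = hi - lo
    alpha = float(h_mask[lo:hi].sum()) / n
    beta = float(e_mask[lo:hi].sum()) / n
    out = replace(region, alpha_frac=alpha, beta_frac=beta)
    if alpha + beta >= params.ss_overlap_frac:
        cb = region.subtype if region.subtype in CB_SUBTYPES else region.cb_subtype
        out = replace(out, subtype=Subtype.SS_IDR, cb_subtype=cb)
    return out


def type_regions(record: ProteinRecord, regions: list[Region],
                 ss: SecondaryStructureProfile | None = None,
                 params: TypingParams | None = None,
                 background: BackgroundComposition | None = None) -> list[Region]:
    """Run CB typing then SS-IDR annotation over one protein's regions."""
    params = params or TypingParams()
    out = []
    for r in regions:
        if r.kind is RegionKind.DISORDERED:
            r = classify_cb(record, r, params, background)
            if ss is not None:
                r = annotate_ss_idr(r, ss, params)
        out.append(r)
    return out


def typing_report(proteins: list[tuple[ProteinRecord, list[Region]]]) -> pd.DataFrame:
    """Per-class table of secondary-structure vs compositional-bias content.

    For each protein class: percent of its residues inside SS-IDRs (split
    into helix/strand components) and inside each CB subtype.  The SS and
    CB columns are computed independently (an SS-IDR region with a
    retained CB call contributes to both), with the class's total residue
    count as denominator throughout.
    """
    rows: dict[str, dict[str, float]] = {}
    totals: dict[str, int] = {}
    cb_cols = [s.value for s in CB_SUBTYPES]
    for rec, regions in proteins:
        group = rec.group or "(unassigned)"
        acc = rows.setdefault(group, {c: 0.0 for c in
                                      ["SS_IDR", "SS_alpha", "SS_beta"] + cb_cols})
        totals[group] = totals.get(group, 0) + len(rec)
        for r in regions:
            if r.kind is not RegionKind.DISORDERED:
                continue
            n = len(r)
            if r.subtype is Subtype.SS_IDR:
                acc["SS_IDR"] += n
                acc["SS_alpha"] += r.alpha_frac * n
                acc["SS_beta"] += r.beta_frac * n
            cb = r.subtype if r.subtype in CB_SUBTYPES else r.cb_subtype
            if cb in CB_SUBTYPES:
                acc[cb.value] += n
    records = []
    for group in sorted(rows):
        total = totals[group]
        rec = {"group": group, "n_residues": total}
        rec.update({col: 100.0 * v / total for col, v in rows[group].items()})
        records.append(rec)
    return pd.DataFrame.from_records(records)


def read_background_tsv(path) -> BackgroundComposition:
    """Load a replacement background from a two-column TSV (aa, freq)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["aa", "freq"],
                     comment="#")
    return BackgroundComposition(dict(zip(df["aa"], df["freq"].astype(float))))
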