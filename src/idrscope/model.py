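"""Core domain types shared by every analysis stage.

Coordinates are 1-based inclusive throughout (UniProt convention).
Alignment columns are likewise 1-based.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
"""The 20 canonical amino-acid letters; anything else is stored as X."""


class RegionKind(str, enum.Enum):
    ORDERED = "ORDERED"
    DISORDERED = "DISORDERED"


class Subtype(str, enum.Enum):
    """Primary label of a disordered region.

    ``SS_IDR`` marks disorder with embedded secondary-structure elements;
    the ``CB_*`` labels are compositional-bias classes (Arg/Ser-rich,
    Pro/Gln homorepeat, Gly-rich, charged, other residue bias).
    """

    NONE = "NONE"
    SS_IDR = "SS_IDR"
    CB_RS = "CB_RS"
    CB_PQ = "CB_PQ"
    CB_G = "CB_G"
    CB_CHARGED = "CB_CHARGED"
    CB_NONCHARGED = "CB_NONCHARGED"


CB_SUBTYPES = (Subtype.CB_RS, Subtype.CB_G, Subtype.CB_PQ,
               Subtype.CB_CHARGED, Subtype.CB_NONCHARGED)


class SiteClass(str, enum.Enum):
    PTM = "PTM"
    MUTATION = "MUTATION"


@dataclass
class ProteinRecord:
    """A protein sequence with its study metadata.

    ``group`` is a free-text class/family label (e.g. ``"SR protein"``,
    ``"U1 snRNP"``); ``complexes`` lists the splicing-cycle assembly states
    (E, A, pre-B, B, Bact, B*, C, C*, P, ILS, ...) the protein belongs to;
    ``abundant`` flags high-abundance proteins.
    """

    id: str
    sequence: str
    group: str = ""
    complexes: frozenset[str] = field(default_factory=frozenset)
    abundant: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be nonempty")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.id}: sequence must have length >= 1")
        self.complexes = frozenset(self.complexes)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class DisorderProfile:
    """Per-residue disorder evidence in [0, 1] (binary labels admitted as 0/1)."""

    protein_id: str
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        self.scores = tuple(float(s) for s in self.scores)
        for i, s in enumerate(self.scores, start=1):
            if not (0.0 <= s <= 1.0) or math.isnan(s):
                raise ValueError(
                    f"{self.protein_id}: disorder score at position {i} "
                    f"is {s}, outside [0, 1]")

    def __len__(self) -> int:
        return len(self.scores)


SS_STATES = frozenset("HEC")


@dataclass
class SecondaryStructureProfile:
    """Per-residue secondary-structure states over {H, E, C}."""

    protein_id: str
    states: str

    def __post_init__(self) -> None:
        bad = set(self.states) - SS_STATES
        if bad:
            raise ValueError(
                f"{self.protein_id}: invalid secondary-structure states {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.states)


@dataclass
class Region:
    """A typed interval on a protein (1-based, inclusive ends).

    ``subtype`` is the primary label; when an SS-IDR call overrides a
    compositional-bias call the CB label is retained in ``cb_subtype`` so
    that neither annotation is discarded.  ``alpha_frac``/``beta_frac`` are
    the fractions of region residues inside qualifying helix/strand runs.
    """

    protein_id: str
    start: int
    end: int
    kind: RegionKind
    subtype: Subtype = Subtype.NONE
    cb_subtype: Subtype = Subtype.NONE
    alpha_frac: float = 0.0
    beta_frac: float = 0.0

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.protein_id}: bad region bounds {self.start}..{self.end}")
        if self.kind is RegionKind.ORDERED and self.subtype is not Subtype.NONE:
            raise ValueError("ordered regions cannot carry a disorder subtype")
        if self.alpha_frac + self.beta_frac > 1.0 + 1e-9:
            raise ValueError("alpha_frac + beta_frac must not exceed 1")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class AnnotatedSite:
    """A PTM or mutation anchored to a residue position."""

    protein_id: str
    position: int
    site_class: SiteClass
    label: str
    tumor_types: frozenset[str] = field(default_factory=frozenset)
    phenotype_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"{self.protein_id}: position must be >= 1")
        if not self.label:
            raise ValueError(f"{self.protein_id}: site label must be nonempty")
        self.tumor_types = frozenset(self.tumor_types)
        self.phenotype_ids = frozenset(self.phenotype_ids)


@dataclass
class OrthologFamily:
    """An ortholog family: alignment + rooted tree + reference sequence id.

    ``alignment`` maps sequence id to an aligned string (gap ``-``); the
    tree's leaf taxa must be exactly the alignment keys.
    """

    family_id: str
    alignment: dict[str, str]
    tree: "object"  # dendropy.Tree; typed loosely to keep imports light
    reference_id: str

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.alignment.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.family_id}: aligned sequences differ in length")
        if self.reference_id not in self.alignment:
            raise ValueError(
                f"{self.family_id}: reference {self.reference_id!r} not in alignment")
        leaves = {lf.taxon.label for lf in self.tree.leaf_node_iter()}
        if leaves != set(self.alignment):
            diff = leaves.symmetric_difference(self.alignment)
            raise ValueError(
                f"{self.family_id}: tree/alignment mismatch: {sorted(diff)}")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.alignment.values())))


@dataclass
class ContingencyTable2x2:
    """Pooled site counts: a/b = PTM-bearing / PTM-free residues in disorder,
    c/d = the same in ordered regions."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValueError(f"contingency entry {name} is negative")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("contingency table is empty")

    @property
    def odds_ratio(self) -> float:
        """Sample odds ratio (a*d)/(b*c); inf when b*c == 0 and a*d > 0."""
        num, den = self.a * self.d, self.b * self.c
        if den == 0:
            return math.inf if num > 0 else math.nan
        return num / den

    def as_array(self):
        return [[self.a, self.b], [self.c, self.d]]

    def __add__(self, other: "ContingencyTable2x2") -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.a + other.a, self.b + other.b,
                                   self.c + other.c, self.d + other.d)


@dataclass
class StatTestResult:
    """Outcome of one statistical test (odds ratio / U / signed-rank W, p, n)."""

    statistic: float
    p_value: float
    method: str
    n: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.method:
            raise ValueError("method label must be nonempty")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
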