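"""Core domain types: replicons, gene records, R-M systems and thresholds.

Coordinate convention: all intervals are 0-based, half-open ``[start, end)``
on the forward strand of the replicon.  A gene on a circular replicon that
spans the origin is stored as two arcs under a single ``gene_id`` (each arc
a valid ``[start, end)`` interval); ``start > end`` records are rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence, Tuple

__all__ = [
    "Role",
    "RMType",
    "Topology",
    "Replicon",
    "GeneRecord",
    "RMSystem",
    "Thresholds",
    "ValidationError",
    "interval_gap",
    "intervals_overlap",
]


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


class Role(str, Enum):
    RE = "RE"
    MTASE = "MTase"
    S_SUBUNIT = "S_subunit"
    FUSED_RM = "fused_RM"
    OTHER = "other"

    @classmethod
    def parse(cls, text: str) -> "Role":
        t = text.strip()
        for member in cls:
            if member.value.lower() == t.lower():
                return member
        return cls.OTHER


class RMType(str, Enum):
    I = "I"
    II = "II"
    III = "III"
    IIG = "IIG"
    IIM = "IIM"
    IV = "IV"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, text: str) -> "RMType":
        t = text.strip()
        for member in cls:
            if member.value.lower() == t.lower():
                return member
        return cls.UNKNOWN


class Topology(str, Enum):
    CIRCULAR = "circular"
    LINEAR = "linear"


_AA_ALPHABET = frozenset("ARNDCQEGHILKMFPSTWYVBZXUO")


def validate_protein(seq: str) -> str:
    """Return ``seq`` upper-cased, or raise ValidationError on non-amino-acid characters."""
    s = seq.upper()
    bad = set(s) - _AA_ALPHABET
    if bad:
        raise ValidationError(f"non-amino-acid characters in protein sequence: {sorted(bad)}")
    return s


@dataclass(frozen=True)
class Replicon:
    """A chromosome or plasmid of one genome."""

    id: str
    genome_id: str
    length: int
    topology: Topology = Topology.LINEAR
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValidationError(f"replicon {self.id}: length must be >= 1, got {self.length}")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValidationError(
                f"replicon {self.id}: sequence length {len(self.sequence)} != declared length {self.length}"
            )

    @property
    def circular(self) -> bool:
        return self.topology is Topology.CIRCULAR


@dataclass(frozen=True)
class GeneRecord:
    """One annotated R-M-related gene.

    ``arcs`` is normally ``None`` (the gene occupies ``[start, end)``).  For a
    gene spanning the origin of a circular replicon it holds the two arcs, in
    transcription order on the forward coordinate system; ``start``/``end``
    then mirror the first arc's start and the last arc's end.
    """

    gene_id: str
    genome_id: str
    replicon_id: str
    start: int
    end: int
    strand: str = "+"
    role: Role = Role.OTHER
    rm_type: RMType = RMType.UNKNOWN
    corrupted: bool = False
    protein_seq: Optional[str] = None
    system_id: Optional[str] = None
    product: Optional[str] = None
    arcs: Optional[Tuple[Tuple[int, int], ...]] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be '+' or '-'")
        for s, e in self.intervals:
            if not (0 <= s < e):
                raise ValidationError(
                    f"gene {self.gene_id}: invalid interval [{s}, {e}) (need 0 <= start < end)"
                )
        # a non-corrupted R-M gene must eventually carry a protein sequence, but
        # annotation and FASTA load separately; require_protein() enforces it
        if self.protein_seq is not None:
            object.__setattr__(self, "protein_seq", validate_protein(self.protein_seq))

    @property
    def intervals(self) -> Tuple[Tuple[int, int], ...]:
        if self.arcs is not None:
            return self.arcs
        return ((self.start, self.end),)

    @property
    def span_nt(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def require_protein(self) -> str:
        """The protein sequence; raises for a non-corrupted R-M gene lacking one."""
        if not self.protein_seq:
            raise ValidationError(
                f"gene {self.gene_id}: non-corrupted {self.role.value} gene must carry a protein sequence"
            )
        return self.protein_seq

    @property
    def length_aa(self) -> int:
        if self.protein_seq is None:
            raise ValidationError(f"gene {self.gene_id} has no protein sequence")
        return len(self.protein_seq)

    def validate_against(self, replicon: Replicon) -> None:
        if self.replicon_id != replicon.id:
            raise ValidationError(f"gene {self.gene_id} is not on replicon {replicon.id}")
        for s, e in self.intervals:
            if e > replicon.length:
                raise ValidationError(
                    f"gene {self.gene_id}: interval [{s}, {e}) exceeds replicon length {replicon.length}"
                )

    def with_protein(self, seq: str) -> "GeneRecord":
        return replace(self, protein_seq=seq)


@dataclass
class RMSystem:
    """A grouping of co-annotated RE / MTase / S-subunit genes."""

    system_id: str
    genome_id: str
    re_genes: list = field(default_factory=list)
    mtase_genes: list = field(default_factory=list)
    s_genes: list = field(default_factory=list)
    other_genes: list = field(default_factory=list)

    @property
    def genes(self) -> list:
        return list(self.re_genes) + list(self.mtase_genes) + list(self.s_genes) + list(self.other_genes)

    def add(self, gene: GeneRecord) -> None:
        if gene.role is Role.RE:
            self.re_genes.append(gene)
        elif gene.role is Role.MTASE:
            self.mtase_genes.append(gene)
        elif gene.role is Role.S_SUBUNIT:
            self.s_genes.append(gene)
        else:
            self.other_genes.append(gene)

    @property
    def completeness(self) -> str:
        """``complete`` iff the system holds >=1 non-corrupted RE and >=1 non-corrupted MTase.

        A fused RE-MTase gene counts for both roles.
        """
        has_re = any(not g.corrupted for g in self.re_genes)
        has_mt = any(not g.corrupted for g in self.mtase_genes)
        fused = any(g.role is Role.FUSED_RM and not g.corrupted for g in self.other_genes)
        return "complete" if (has_re or fused) and (has_mt or fused) else "incomplete"

    @property
    def rm_type(self) -> RMType:
        for g in self.genes:
            if g.rm_type is not RMType.UNKNOWN:
                return g.rm_type
        return RMType.UNKNOWN


def build_systems(genes: Iterable[GeneRecord]) -> dict:
    """Group genes by their annotated ``system_id`` into RMSystem objects.

    Genes with no system_id are left out (they are not part of any annotated
    system; MGE / ``other`` genes typically fall here).
    """
    systems: dict = {}
    for gene in genes:
        if gene.system_id is None:
            continue
        sys_obj = systems.get(gene.system_id)
        if sys_obj is None:
            sys_obj = RMSystem(system_id=gene.system_id, genome_id=gene.genome_id)
            systems[gene.system_id] = sys_obj
        elif sys_obj.genome_id != gene.genome_id:
            raise ValidationError(
                f"system {gene.system_id} spans genomes {sys_obj.genome_id} and {gene.genome_id}"
            )
        sys_obj.add(gene)
    return systems


@dataclass(frozen=True)
class Thresholds:
    """All numeric parameters of the pipeline, with the published defaults."""

    vicinity_bp: int = 4000
    separated_bp: int = 4000
    neighborhood_bp: int = 20000
    orf_evalue: float = 0.01
    typeiv_evalue: float = 0.001
    re_ortho_identity: float = 0.40
    re_ortho_coverage: float = 0.80
    mtase_ortho_identity: float = 0.50
    mtase_ortho_coverage: float = 0.80
    trunc_homolog_identity: float = 0.20
    trunc_homolog_evalue: float = 10.0  # default reporting cutoff of a BLASTp-style search
    trunc_length_fraction: float = 0.80
    cluster_identity: float = 0.40
    cluster_coverage: float = 0.60
    bootstrap_reps: int = 100
    min_orf_nt: int = 150

    def __post_init__(self) -> None:
        for name in (
            "re_ortho_identity",
            "re_ortho_coverage",
            "mtase_ortho_identity",
            "mtase_ortho_coverage",
            "trunc_homolog_identity",
            "trunc_length_fraction",
            "cluster_identity",
            "cluster_coverage",
        ):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValidationError(f"threshold {name} must lie in (0, 1], got {v}")
        for name in ("vicinity_bp", "separated_bp", "neighborhood_bp", "min_orf_nt"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v > 0):
                raise ValidationError(f"threshold {name} must be a positive integer, got {v}")
        for name in ("orf_evalue", "typeiv_evalue", "trunc_homolog_evalue"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"threshold {name} must be > 0")
        if self.bootstrap_reps < 1:
            raise ValidationError("bootstrap_reps must be >= 1")


# ---------------------------------------------------------------------------
# interval arithmetic shared by vicinity / distance / neighborhood logic
# ---------------------------------------------------------------------------

def intervals_overlap(a: Tuple[int, int], b: Tuple[int, int]) -> bool:
    """Overlap by >=1 bp between two half-open intervals on the same linear axis."""
    return a[0] < b[1] and b[0] < a[1]


def interval_gap(
    a: Tuple[int, int],
    b: Tuple[int, int],
    length: Optional[int] = None,
    circular: bool = False,
) -> int:
    """Edge-to-edge gap in bp between two half-open intervals (0 if they overlap).

    On a circular replicon of size ``length`` the shorter of the two arcs is
    returned.
    """
    if intervals_overlap(a, b):
        return 0
    if not circular:
        if a[1] <= b[0]:
            return b[0] - a[1]
        return a[0] - b[1]
    if length is None:
        raise ValidationError("circular gap needs the replicon length")
    fwd = (b[0] - a[1]) % length  # arc running a.end -> b.start
    rev = (a[0] - b[1]) % length  # arc running b.end -> a.start
    return min(fwd, rev)


def gene_gap(
    gene_a: GeneRecord,
    gene_b: GeneRecord,
    replicon: Replicon,
) -> int:
    """Edge-to-edge gap between two (possibly multi-arc) genes on one replicon."""
    best = math.inf
    for ia in gene_a.intervals:
        for ib in gene_b.intervals:
            g = interval_gap(ia, ib, length=replicon.length, circular=replicon.circular)
            best = min(best, g)
    return int(best)
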