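"""Separated R-M system prediction and the final solitary-RE classification.

The partner-transfer algorithm: for a solitary RE, take each of its RE
orthologs that sits in a *complete* system, and map that system's MTase back
into the solitary RE's genome by best-bidirectional hit.  A recovered
non-corrupted MTase forms a putative R-M system with the solitary RE; it is
*separated* when the edge-to-edge gene distance exceeds the threshold (or
the genes sit on different replicons of the genome, treated as infinitely
distant).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from . import align, orthology
from .model import (
    GeneRecord,
    Replicon,
    RMSystem,
    Role,
    RMType,
    Thresholds,
    ValidationError,
    gene_gap,
)
from .orthology import OrthologGroup, OrthologPair
from .solitary import VicinityScanResult

__all__ = [
    "Provenance",
    "PutativeRMSystem",
    "SolitaryClassification",
    "CLASSES",
    "gene_distance",
    "find_partner_mtase",
    "classify_solitary",
    "summarize_groups",
]

CLASSES = (
    "probably_truncated",
    "separated_system_member",
    "corrupted_mtase_nearby",
    "no_paired_mtase",
    "no_orthologs",
)


@dataclass(frozen=True)
class Provenance:
    """One supporting orthologous complete system."""

    genome_id: str
    re_gene_id: str
    mtase_gene_id: str
    system_id: Optional[str]


@dataclass
class PutativeRMSystem:
    re_gene: GeneRecord
    mtase_gene: GeneRecord
    genome_id: str
    separation_bp: float  # bp, or math.inf for different replicons
    status: str  # ordinary | separated
    provenance: List[Provenance] = field(default_factory=list)
    s_genes: List[GeneRecord] = field(default_factory=list)


@dataclass
class SolitaryClassification:
    re_gene: GeneRecord
    verdict: str
    evidence: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.verdict not in CLASSES:
            raise ValidationError(f"unknown classification {self.verdict!r}")


def gene_distance(
    gene_x: GeneRecord,
    gene_y: GeneRecord,
    replicons: Mapping[str, Replicon],
) -> float:
    """Edge-to-edge distance in bp; 0 when overlapping; inf across replicons.

    On circular replicons the shorter arc counts.  Genes must come from the
    same genome.
    """
    if gene_x.genome_id != gene_y.genome_id:
        raise ValidationError(
            f"distance between genes of different genomes "
            f"({gene_x.genome_id} vs {gene_y.genome_id}) is undefined"
        )
    if gene_x.replicon_id != gene_y.replicon_id:
        return math.inf
    replicon = replicons[gene_x.replicon_id]
    return float(gene_gap(gene_x, gene_y, replicon))


def _separation_status(separation: float, thresholds: Thresholds) -> str:
    return "separated" if separation > thresholds.separated_bp else "ordinary"


def find_partner_mtase(
    solitary_re: GeneRecord,
    genes: Sequence[GeneRecord],
    systems: Mapping[str, RMSystem],
    re_pairs: Sequence[OrthologPair],
    replicons: Mapping[str, Replicon],
    thresholds: Thresholds = Thresholds(),
    cache: Optional[align.SimilarityCache] = None,
) -> List[PutativeRMSystem]:
    """Recover partner MTase(s) for a solitary RE via orthologous complete systems.

    Several supporting systems pointing at the same MTase merge into one
    putative system with combined provenance.  For Type I partners,
    S-subunit genes co-located with the recovered MTase (within the vicinity
    window) are attached as cassette members.
    """
    if cache is None:
        cache = align.SimilarityCache(
            {g.gene_id: g.protein_seq for g in genes if g.protein_seq}
        )
    by_genome_mtases: Dict[str, List[GeneRecord]] = {}
    for g in genes:
        if g.role is Role.MTASE and not g.corrupted and g.protein_seq:
            by_genome_mtases.setdefault(g.genome_id, []).append(g)
    for lst in by_genome_mtases.values():
        lst.sort(key=lambda g: g.gene_id)

    home_mtases = by_genome_mtases.get(solitary_re.genome_id, [])

    # RE orthologs of the solitary RE, from the precomputed BBH pair set
    ortho_res: List[GeneRecord] = []
    for p in re_pairs:
        if p.gene_a.gene_id == solitary_re.gene_id:
            ortho_res.append(p.gene_b)
        elif p.gene_b.gene_id == solitary_re.gene_id:
            ortho_res.append(p.gene_a)
    ortho_res.sort(key=lambda g: g.gene_id)

    results: Dict[str, PutativeRMSystem] = {}
    for re_prime in ortho_res:
        if re_prime.system_id is None:
            continue
        system = systems.get(re_prime.system_id)
        if system is None or system.completeness != "complete":
            continue
        for m_prime in sorted(system.mtase_genes, key=lambda g: g.gene_id):
            if m_prime.corrupted or not m_prime.protein_seq:
                continue
            if m_prime.rm_type is not solitary_re.rm_type:
                continue
            m = orthology.best_hit(m_prime, home_mtases, thresholds, cache=cache)
            if m is None:
                continue
            back = orthology.best_hit(
                m, by_genome_mtases.get(m_prime.genome_id, []), thresholds, cache=cache
            )
            if back is None or back.gene_id != m_prime.gene_id:
                continue
            prov = Provenance(
                genome_id=re_prime.genome_id,
                re_gene_id=re_prime.gene_id,
                mtase_gene_id=m_prime.gene_id,
                system_id=re_prime.system_id,
            )
            entry = results.get(m.gene_id)
            if entry is None:
                separation = gene_distance(solitary_re, m, replicons)
                entry = PutativeRMSystem(
                    re_gene=solitary_re,
                    mtase_gene=m,
                    genome_id=solitary_re.genome_id,
                    separation_bp=separation,
                    status=_separation_status(separation, thresholds),
                    provenance=[prov],
                    s_genes=_cassette_s_genes(m, genes, replicons, thresholds),
                )
                results[m.gene_id] = entry
            elif prov not in entry.provenance:
                entry.provenance.append(prov)
    return [results[k] for k in sorted(results)]


def _cassette_s_genes(
    mtase: GeneRecord,
    genes: Sequence[GeneRecord],
    replicons: Mapping[str, Replicon],
    thresholds: Thresholds,
) -> List[GeneRecord]:
    if mtase.rm_type is not RMType.I:
        return []
    out = []
    for g in genes:
        if (
            g.role is Role.S_SUBUNIT
            and g.genome_id == mtase.genome_id
            and g.replicon_id == mtase.replicon_id
            and gene_distance(mtase, g, replicons) <= thresholds.vicinity_bp
        ):
            out.append(g)
    out.sort(key=lambda g: g.gene_id)
    return out


def classify_solitary(
    re_gene: GeneRecord,
    truncated: bool,
    has_orthologs: bool,
    partners: Sequence[PutativeRMSystem],
    scan: Optional[VicinityScanResult],
) -> SolitaryClassification:
    """Assign exactly one class per solitary RE, in fixed precedence order.

    Precedence: probably_truncated, then no_orthologs, then
    separated_system_member, then corrupted_mtase_nearby, then
    no_paired_mtase.  Truncation is checked first because fragments are
    excluded before the ortholog/partner search.
    """
    separated = [p for p in partners if p.status == "separated"]
    evidence: Dict[str, object] = {
        "truncated": truncated,
        "has_orthologs": has_orthologs,
        "n_separated_partners": len(separated),
        "corrupted_mtase_nearby": bool(scan and scan.has_corrupted_mtase),
    }
    if truncated:
        verdict = "probably_truncated"
    elif not has_orthologs:
        verdict = "no_orthologs"
    elif separated:
        verdict = "separated_system_member"
        evidence["partners"] = [p.mtase_gene.gene_id for p in separated]
    elif scan is not None and scan.has_corrupted_mtase:
        verdict = "corrupted_mtase_nearby"
    else:
        verdict = "no_paired_mtase"
    return SolitaryClassification(re_gene=re_gene, verdict=verdict, evidence=evidence)


@dataclass(frozen=True)
class GroupSummary:
    group_id: str
    rm_type: str
    n_systems: int
    n_annotated: int
    n_separated: int
    n_solitary: int


def summarize_groups(
    putative_systems: Sequence[PutativeRMSystem],
    groups: Sequence[OrthologGroup],
    systems: Mapping[str, RMSystem],
) -> List[GroupSummary]:
    """Per-ortholog-group summary over groups containing separated systems.

    A group may count more separated systems than solitary REs when one RE
    pairs with several MTase cassettes; groups with no separated member are
    omitted.
    """
    member_to_group: Dict[str, str] = {}
    group_by_id = {g.group_id: g for g in groups}
    for g in groups:
        for m in g.members:
            member_to_group[m.gene_id] = g.group_id

    separated = [p for p in putative_systems if p.status == "separated"]
    by_group: Dict[str, List[PutativeRMSystem]] = {}
    for p in separated:
        gid = member_to_group.get(p.re_gene.gene_id)
        if gid is not None:
            by_group.setdefault(gid, []).append(p)

    out: List[GroupSummary] = []
    for gid in sorted(by_group):
        group = group_by_id[gid]
        member_ids = set(group.member_ids)
        annotated = {
            s.system_id
            for s in systems.values()
            if s.completeness == "complete"
            and any(g.gene_id in member_ids for g in s.re_genes)
        }
        seps = by_group[gid]
        n_solitary = len({p.re_gene.gene_id for p in seps})
        out.append(
            GroupSummary(
                group_id=gid,
                rm_type=group.rm_type.value,
                n_systems=len(annotated) + len(seps),
                n_annotated=len(annotated),
                n_separated=len(seps),
                n_solitary=n_solitary,
            )
        )
    return out
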