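"""Best-bidirectional-hit orthology with role-specific thresholds.

Two genes from different genomes are orthologs when each is the other's
best qualifying hit in its genome.  Qualifying means identity and
longer-sequence coverage above the role's thresholds (strict inequalities);
comparisons never cross R-M types.  Ortholog groups are single-linkage
connected components of the pair graph; singletons are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx

from . import align
from .model import GeneRecord, Role, RMType, Thresholds, ValidationError

__all__ = [
    "OrthologPair",
    "OrthologGroup",
    "role_thresholds",
    "best_hit",
    "bbh_orthologs",
    "build_groups",
]


@dataclass(frozen=True)
class OrthologPair:
    gene_a: GeneRecord
    gene_b: GeneRecord
    role: Role
    hit_ab: align.AlignmentHit
    hit_ba: align.AlignmentHit

    def __post_init__(self) -> None:
        if self.gene_a.genome_id == self.gene_b.genome_id:
            raise ValidationError("ortholog pair within one genome")

    @property
    def key(self) -> Tuple[str, str]:
        return tuple(sorted((self.gene_a.gene_id, self.gene_b.gene_id)))


@dataclass
class OrthologGroup:
    group_id: str
    role: Role
    rm_type: RMType
    members: List[GeneRecord] = field(default_factory=list)

    @property
    def member_ids(self) -> List[str]:
        return sorted(g.gene_id for g in self.members)


def role_thresholds(role: Role, thresholds: Thresholds) -> Tuple[float, float]:
    """(identity_min, coverage_min) for a role; MTases use the stricter identity."""
    if role is Role.RE:
        return thresholds.re_ortho_identity, thresholds.re_ortho_coverage
    if role is Role.MTASE:
        return thresholds.mtase_ortho_identity, thresholds.mtase_ortho_coverage
    raise ValidationError(f"no ortholog thresholds defined for role {role.value}")


def _qualifying_hit(
    query: GeneRecord,
    target: GeneRecord,
    identity_min: float,
    coverage_min: float,
    cache: align.SimilarityCache,
) -> Optional[align.AlignmentHit]:
    hit = cache.hit(query.gene_id, target.gene_id)
    if hit is None:
        return None
    if not align.meets(hit, identity_min, coverage_min, coverage_basis="longer"):
        return None
    return hit


def best_hit(
    query: GeneRecord,
    target_genome_proteins: Sequence[GeneRecord],
    thresholds: Thresholds,
    cache: Optional[align.SimilarityCache] = None,
) -> Optional[GeneRecord]:
    """Highest-scoring target of the same role and R-M type passing the thresholds.

    Ties break by score, then identity, then lexicographically smallest
    gene id, so runs are deterministic.
    """
    if cache is None:
        cache = _cache_for([query, *target_genome_proteins])
    identity_min, coverage_min = role_thresholds(query.role, thresholds)
    best: Optional[Tuple[Tuple, GeneRecord]] = None
    for target in target_genome_proteins:
        if target.role is not query.role or target.rm_type is not query.rm_type:
            continue
        if target.corrupted or not target.protein_seq:
            continue
        hit = _qualifying_hit(query, target, identity_min, coverage_min, cache)
        if hit is None:
            continue
        key = (-hit.score, -hit.identity, target.gene_id)
        if best is None or key < best[0]:
            best = (key, target)
    return None if best is None else best[1]


def _cache_for(genes: Iterable[GeneRecord]) -> align.SimilarityCache:
    return align.SimilarityCache(
        {g.gene_id: g.protein_seq for g in genes if g.protein_seq}
    )


def bbh_orthologs(
    genome_a: Sequence[GeneRecord],
    genome_b: Sequence[GeneRecord],
    role: Role,
    thresholds: Thresholds = Thresholds(),
    cache: Optional[align.SimilarityCache] = None,
) -> List[OrthologPair]:
    """Best-bidirectional-hit pairs between two genomes for one role.

    Symmetric in its genome arguments; each gene appears in at most one pair
    per partner genome by construction.
    """
    a_genes = sorted(
        (g for g in genome_a if g.role is role and not g.corrupted and g.protein_seq),
        key=lambda g: g.gene_id,
    )
    b_genes = sorted(
        (g for g in genome_b if g.role is role and not g.corrupted and g.protein_seq),
        key=lambda g: g.gene_id,
    )
    if not a_genes or not b_genes:
        return []
    if a_genes[0].genome_id == b_genes[0].genome_id:
        raise ValidationError("bbh_orthologs requires genes from two different genomes")
    if cache is None:
        cache = _cache_for([*a_genes, *b_genes])
    pairs: List[OrthologPair] = []
    for x in a_genes:
        y = best_hit(x, b_genes, thresholds, cache=cache)
        if y is None:
            continue
        x_back = best_hit(y, a_genes, thresholds, cache=cache)
        if x_back is not None and x_back.gene_id == x.gene_id:
            pairs.append(
                OrthologPair(
                    gene_a=x,
                    gene_b=y,
                    role=role,
                    hit_ab=cache.hit(x.gene_id, y.gene_id),
                    hit_ba=cache.hit(y.gene_id, x.gene_id),
                )
            )
    pairs.sort(key=lambda p: p.key)
    return pairs


def all_bbh_pairs(
    genes: Sequence[GeneRecord],
    role: Role,
    thresholds: Thresholds = Thresholds(),
    cache: Optional[align.SimilarityCache] = None,
) -> List[OrthologPair]:
    """BBH pairs over every ordered genome pair of a cohort (deduplicated)."""
    by_genome: Dict[str, List[GeneRecord]] = {}
    for g in genes:
        if g.role is role:
            by_genome.setdefault(g.genome_id, []).append(g)
    if cache is None:
        cache = _cache_for(genes)
    genome_ids = sorted(by_genome)
    pairs: List[OrthologPair] = []
    for i, ga in enumerate(genome_ids):
        for gb in genome_ids[i + 1 :]:
            pairs.extend(
                bbh_orthologs(by_genome[ga], by_genome[gb], role, thresholds, cache=cache)
            )
    pairs.sort(key=lambda p: p.key)
    return pairs


def build_groups(pairs: Sequence[OrthologPair], prefix: str = "OG") -> List[OrthologGroup]:
    """Single-linkage connected components of the ortholog-pair graph.

    Proteins that occur in no pair form no group (groups have >=2 members).
    Group ids are assigned in order of the lexicographically smallest member.
    """
    graph = nx.Graph()
    genes: Dict[str, GeneRecord] = {}
    for p in pairs:
        graph.add_edge(p.gene_a.gene_id, p.gene_b.gene_id)
        genes[p.gene_a.gene_id] = p.gene_a
        genes[p.gene_b.gene_id] = p.gene_b
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)), key=lambda c: c[0]
    )
    groups: List[OrthologGroup] = []
    for idx, comp in enumerate(components, 1):
        members = [genes[gid] for gid in comp]
        roles = {g.role for g in members}
        types = {g.rm_type for g in members}
        if len(roles) != 1 or len(types) != 1:
            raise ValidationError(f"ortholog group {idx} mixes roles or R-M types")
        groups.append(
            OrthologGroup(
                group_id=f"{prefix}{idx:04d}",
                role=members[0].role,
                rm_type=members[0].rm_type,
                members=members,
            )
        )
    return groups
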