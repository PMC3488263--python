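"""Mobile-genetic-element scan around the genes of separated R-M systems.

Annotated ``other`` genes within the neighborhood window whose product text
matches one of the (editable) keyword classes are reported, sorted by
distance.  Window inclusion follows the same edge-to-edge, overlap-by->=1-bp
semantics as the vicinity rule.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

from .model import GeneRecord, Replicon, Role, Thresholds
from .separated import PutativeRMSystem, gene_distance

__all__ = ["MGEHit", "DEFAULT_KEYWORD_MAP", "scan_mge", "mge_enrichment_summary"]

DEFAULT_KEYWORD_MAP: Dict[str, str] = {
    "insertion_sequence": r"insertion sequence|\bIS\d+",
    "transposase": r"transposase|transposon",
    "integrase": r"integrase",
    "phage_related": r"phage|prophage",
}


@dataclass(frozen=True)
class MGEHit:
    anchor_gene_id: str
    mge_gene_id: str
    category: str
    distance_bp: int
    product: str


def _categorize(product: str, keyword_map: Mapping[str, str]) -> Optional[str]:
    for category in sorted(keyword_map):
        if re.search(keyword_map[category], product, flags=re.IGNORECASE):
            return category
    return None


def scan_mge(
    anchor_gene: GeneRecord,
    annotation: Sequence[GeneRecord],
    replicons: Mapping[str, Replicon],
    window_bp: Optional[int] = None,
    keyword_map: Mapping[str, str] = DEFAULT_KEYWORD_MAP,
    thresholds: Thresholds = Thresholds(),
) -> List[MGEHit]:
    """MGE-annotated genes within ``window_bp`` of the anchor, nearest first.

    Results are invariant under annotation row order (sorted by distance,
    then gene id).
    """
    if window_bp is None:
        window_bp = thresholds.neighborhood_bp
    hits: List[MGEHit] = []
    for g in annotation:
        if g.gene_id == anchor_gene.gene_id or g.role is not Role.OTHER or not g.product:
            continue
        if g.genome_id != anchor_gene.genome_id or g.replicon_id != anchor_gene.replicon_id:
            continue
        category = _categorize(g.product, keyword_map)
        if category is None:
            continue
        distance = gene_distance(anchor_gene, g, replicons)
        if distance >= window_bp:  # a gene starting exactly window_bp away is outside
            continue
        hits.append(
            MGEHit(
                anchor_gene_id=anchor_gene.gene_id,
                mge_gene_id=g.gene_id,
                category=category,
                distance_bp=int(distance),
                product=g.product,
            )
        )
    hits.sort(key=lambda h: (h.distance_bp, h.mge_gene_id))
    return hits


def mge_enrichment_summary(
    separated_systems: Sequence[PutativeRMSystem],
    scans: Mapping[str, Sequence[MGEHit]],
) -> Optional[float]:
    """Fraction of separated systems with >=1 MGE near the RE or the MTase.

    ``scans`` maps anchor gene ids to their scan results.  Returns ``None``
    (not applicable) for an empty system list.
    """
    if not separated_systems:
        return None
    with_mge = 0
    for system in separated_systems:
        near_re = scans.get(system.re_gene.gene_id, ())
        near_mt = scans.get(system.mtase_gene.gene_id, ())
        if near_re or near_mt:
            with_mge += 1
    return with_mge / len(separated_systems)
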