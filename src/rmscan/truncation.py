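"""Flagging of solitary REs that are probably fragments of full-length RE genes.

A solitary RE is compared with every RE from a complete system; homologs are
those with alignment identity above ``trunc_homolog_identity`` among hits a
BLASTp-style search would report at all (E-value below
``trunc_homolog_evalue``; no coverage floor is applied).  The RE is flagged
*probably truncated* if it is shorter
by at least ``1 - trunc_length_fraction`` than any single homolog, i.e.
``len(solitary) <= trunc_length_fraction * len(homolog)`` — the boundary is
inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from . import align
from .model import GeneRecord, Thresholds, ValidationError

__all__ = ["TruncationEvidence", "is_probably_truncated"]


@dataclass(frozen=True)
class TruncationEvidence:
    solitary_id: str
    homolog_id: Optional[str]
    identity: Optional[float]
    length_ratio: Optional[float]  # len(solitary) / len(homolog)
    verdict: bool
    note: str = ""


def is_probably_truncated(
    solitary_re: GeneRecord,
    complete_system_res: Sequence[GeneRecord],
    thresholds: Thresholds = Thresholds(),
    cache: Optional[align.SimilarityCache] = None,
) -> Tuple[bool, List[TruncationEvidence]]:
    """Probable-fragment verdict plus the evidence rows that triggered it.

    With an empty homolog pool the verdict is False ("no homologs"): a gene
    that cannot be compared cannot be judged truncated.
    """
    if not solitary_re.protein_seq:
        raise ValidationError(f"gene {solitary_re.gene_id} has no protein sequence")
    evidence: List[TruncationEvidence] = []
    sol_len = solitary_re.length_aa
    verdict = False
    for hom in sorted(complete_system_res, key=lambda g: g.gene_id):
        if hom.gene_id == solitary_re.gene_id or not hom.protein_seq:
            continue
        if cache is not None:
            hit = cache.hit(solitary_re.gene_id, hom.gene_id)
        else:
            hit = align.align_pair(
                solitary_re.protein_seq,
                hom.protein_seq,
                query_id=solitary_re.gene_id,
                subject_id=hom.gene_id,
            )
        if hit is None or hit.evalue >= thresholds.trunc_homolog_evalue:
            continue
        if not hit.identity > thresholds.trunc_homolog_identity:
            continue
        ratio = sol_len / hom.length_aa
        if sol_len <= thresholds.trunc_length_fraction * hom.length_aa:
            verdict = True
            evidence.append(
                TruncationEvidence(
                    solitary_id=solitary_re.gene_id,
                    homolog_id=hom.gene_id,
                    identity=hit.identity,
                    length_ratio=ratio,
                    verdict=True,
                )
            )
    if not evidence:
        note = "no homologs" if not any(
            e.homolog_id is not None for e in evidence
        ) else ""
        evidence.append(
            TruncationEvidence(
                solitary_id=solitary_re.gene_id,
                homolog_id=None,
                identity=None,
                length_ratio=None,
                verdict=False,
                note="no triggering homolog",
            )
        )
    return verdict, evidence


def write_evidence_tsv(rows: Sequence[TruncationEvidence], path) -> None:
    with open(path, "w") as fh:
        fh.write("solitary_id\thomolog_id\tidentity\tlength_ratio\tverdict\tnote\n")
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        r.solitary_id,
                        r.homolog_id or "",
                        f"{r.identity:.4f}" if r.identity is not None else "",
                        f"{r.length_ratio:.4f}" if r.length_ratio is not None else "",
                        "true" if r.verdict else "false",
                        r.note,
                    ]
                )
                + "\n"
            )
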