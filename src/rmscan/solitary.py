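"""Solitary-RE detection: completeness, 4 kb vicinity windows and the MTase ORF scan.

An RE gene is called *solitary* when no non-corrupted MTase gene — annotated
or recovered as an MTase-like ORF — lies within the vicinity window around
it.  The window covers the gene itself plus ``vicinity_bp`` upstream and
downstream; a gene or ORF counts as "in the vicinity" if it overlaps the
window by at least 1 bp, so a gene starting exactly ``vicinity_bp`` beyond
the RE's end is outside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from Bio.Seq import Seq

from . import align
from .model import (
    GeneRecord,
    Replicon,
    RMSystem,
    Role,
    Thresholds,
    ValidationError,
    intervals_overlap,
)

__all__ = [
    "OrfCandidate",
    "VicinityScanResult",
    "classify_completeness",
    "vicinity_interval",
    "six_frame_orfs",
    "scan_vicinity_for_mtases",
    "call_solitary",
    "solitary_candidates",
]

_STOPS = ("TAA", "TAG", "TGA")

_MTASE_ROLES = (Role.MTASE, Role.FUSED_RM)  # a fused RE-MTase gene provides MTase activity
_RM_ROLES = (Role.RE, Role.MTASE, Role.S_SUBUNIT, Role.FUSED_RM)


@dataclass(frozen=True)
class OrfCandidate:
    """A six-frame ORF in the vicinity with its best hit against the MTase references."""

    intervals: Tuple[Tuple[int, int], ...]  # replicon coordinates, 0-based half-open
    strand: str
    frame: int
    protein: str
    best_hit: align.AlignmentHit
    overlaps_annotated_rm: bool = False


@dataclass
class VicinityScanResult:
    re_gene_id: str
    intervals: Tuple[Tuple[int, int], ...]
    candidate_orfs: List[OrfCandidate] = field(default_factory=list)
    has_noncorrupted_mtase: bool = False
    has_corrupted_mtase: bool = False
    annotation_only: bool = False

    @property
    def has_novel_mtase_orf(self) -> bool:
        """True if an MTase-like ORF not attributable to any annotated R-M gene was found."""
        return any(not orf.overlaps_annotated_rm for orf in self.candidate_orfs)


def classify_completeness(system: RMSystem) -> str:
    """``complete`` iff >=1 non-corrupted RE and >=1 non-corrupted MTase gene."""
    if not system.genes:
        raise ValidationError(f"system {system.system_id} has no genes")
    return system.completeness


# ---------------------------------------------------------------------------
# vicinity windows
# ---------------------------------------------------------------------------

def _circular_window(s0: int, e0: int, length: int) -> Tuple[Tuple[int, int], ...]:
    span = e0 - s0
    if span >= length:
        return ((0, length),)
    s = s0 % length
    if s + span <= length:
        return ((s, s + span),)
    return ((s, length), (0, s + span - length))


def vicinity_interval(
    gene: GeneRecord, window_bp: int, replicon: Replicon
) -> Tuple[Tuple[int, int], ...]:
    """Interval(s) covering the gene plus ``window_bp`` on both sides.

    Linear replicons clip at the ends; circular replicons wrap, yielding up
    to two arcs listed in genomic-contiguous order.
    """
    if window_bp <= 0:
        raise ValidationError("window_bp must be > 0")
    gene.validate_against(replicon)
    arcs = gene.intervals
    if replicon.circular:
        # unwrap an origin-spanning gene to a contiguous pseudo-interval
        if len(arcs) > 1:
            s0, e0 = arcs[0][0], replicon.length + arcs[-1][1]
        else:
            s0, e0 = arcs[0]
        return _circular_window(s0 - window_bp, e0 + window_bp, replicon.length)
    out = []
    for s, e in arcs:
        out.append((max(0, s - window_bp), min(replicon.length, e + window_bp)))
    out.sort()
    merged: List[Tuple[int, int]] = []
    for s, e in out:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return tuple(merged)


def _overlaps_any(
    gene_arcs: Sequence[Tuple[int, int]], windows: Sequence[Tuple[int, int]]
) -> bool:
    return any(intervals_overlap(a, w) for a in gene_arcs for w in windows)


# ---------------------------------------------------------------------------
# six-frame ORF extraction (stop-to-stop, getorf-style)
# ---------------------------------------------------------------------------

def six_frame_orfs(seq: str, min_len_nt: int = 150) -> List[Tuple[int, int, str, int, str]]:
    """Stop-to-stop open reading frames in all six frames.

    Returns ``(start, end, strand, frame, protein)`` tuples with 0-based
    half-open coordinates on the forward strand of ``seq``.  Segments at the
    sequence edges count (start-codon-agnostic, as getorf's default), so
    frameshift remnants are not missed.
    """
    seq = seq.upper()
    n = len(seq)
    results: List[Tuple[int, int, str, int, str]] = []

    def scan(s: str, strand: str) -> None:
        for frame in range(3):
            seg_start = frame
            pos = frame
            while pos + 3 <= len(s):
                codon = s[pos : pos + 3]
                if codon in _STOPS:
                    _emit(s, seg_start, pos, strand, frame)
                    seg_start = pos + 3
                pos += 3
            _emit(s, seg_start, pos, strand, frame)

    def _emit(s: str, seg_start: int, seg_end: int, strand: str, frame: int) -> None:
        if seg_end - seg_start < min_len_nt:
            return
        segment = s[seg_start:seg_end]
        protein = str(Seq(segment).translate())
        if strand == "+":
            results.append((seg_start, seg_end, "+", frame, protein))
        else:
            results.append((len(s) - seg_end, len(s) - seg_start, "-", frame, protein))

    scan(seq, "+")
    scan(str(Seq(seq).reverse_complement()), "-")
    results.sort(key=lambda t: (t[0], t[1], t[2], t[3]))
    return results


def _extract_vicinity_seq(
    replicon: Replicon, windows: Sequence[Tuple[int, int]]
) -> Tuple[str, List[Tuple[int, int]]]:
    """Concatenated window sequence plus local-offset -> replicon-arc map."""
    chunks = []
    offsets = []  # (local_start, replicon_start) per window, windows are contiguous on the circle
    pos = 0
    for s, e in windows:
        chunks.append(replicon.sequence[s:e])
        offsets.append((pos, s))
        pos += e - s
    return "".join(chunks), offsets


def _local_to_replicon(
    local_start: int,
    local_end: int,
    windows: Sequence[Tuple[int, int]],
    offsets: Sequence[Tuple[int, int]],
) -> Tuple[Tuple[int, int], ...]:
    arcs = []
    for (lo, rs), (ws, we) in zip(offsets, windows):
        wlen = we - ws
        a = max(local_start, lo)
        b = min(local_end, lo + wlen)
        if a < b:
            arcs.append((rs + (a - lo), rs + (b - lo)))
    return tuple(arcs)


# ---------------------------------------------------------------------------
# the vicinity scan and the solitary call
# ---------------------------------------------------------------------------

def scan_vicinity_for_mtases(
    re_gene: GeneRecord,
    replicon: Replicon,
    annotated_genes: Sequence[GeneRecord],
    mtase_reference_proteins: Mapping[str, str],
    thresholds: Thresholds = Thresholds(),
) -> VicinityScanResult:
    """Scan the vicinity of an RE gene for MTase genes and MTase-like ORFs.

    Annotated MTase (and fused RE-MTase) genes overlapping the window set the
    ``has_noncorrupted_mtase`` / ``has_corrupted_mtase`` flags.  If the
    replicon sequence is available, all six-frame ORFs in the window are
    translated and searched against the MTase reference set at
    ``orf_evalue``; an ORF overlapping an annotated R-M gene is attributed to
    that gene (so a frameshifted pseudo-MTase's intact fragment does not
    masquerade as a novel MTase).  Without a sequence the scan degrades to
    annotation-only and is flagged as such.
    """
    windows = vicinity_interval(re_gene, thresholds.vicinity_bp, replicon)
    result = VicinityScanResult(re_gene_id=re_gene.gene_id, intervals=windows)

    rm_gene_arcs: List[Tuple[int, int]] = []
    for g in annotated_genes:
        if g.replicon_id != replicon.id:
            continue
        if g.role in _RM_ROLES and _overlaps_any(g.intervals, windows):
            rm_gene_arcs.extend(g.intervals)
            if g.role in _MTASE_ROLES:
                if g.corrupted:
                    result.has_corrupted_mtase = True
                else:
                    result.has_noncorrupted_mtase = True

    if replicon.sequence is None:
        result.annotation_only = True
        return result

    vic_seq, offsets = _extract_vicinity_seq(replicon, windows)
    refs = dict(mtase_reference_proteins)
    for start, end, strand, frame, protein in six_frame_orfs(vic_seq, thresholds.min_orf_nt):
        protein = protein.rstrip("*")
        if len(protein) * 3 < thresholds.min_orf_nt:
            continue
        hits = align.search({"orf": protein}, refs, thresholds.orf_evalue)
        if not hits:
            continue
        arcs = _local_to_replicon(start, end, windows, offsets)
        overlaps = any(intervals_overlap(a, b) for a in arcs for b in rm_gene_arcs)
        result.candidate_orfs.append(
            OrfCandidate(
                intervals=arcs,
                strand=strand,
                frame=frame,
                protein=protein,
                best_hit=hits[0],
                overlaps_annotated_rm=overlaps,
            )
        )
    return result


def call_solitary(re_gene: GeneRecord, scan: VicinityScanResult) -> bool:
    """True iff no non-corrupted MTase evidence was found in the vicinity."""
    if re_gene.corrupted:
        raise ValidationError(
            f"gene {re_gene.gene_id}: solitary calls are made for non-corrupted RE genes only"
        )
    if scan.re_gene_id != re_gene.gene_id:
        raise ValidationError("scan result does not belong to this gene")
    return not (scan.has_noncorrupted_mtase or scan.has_novel_mtase_orf)


def solitary_candidates(systems: Mapping[str, RMSystem]) -> List[GeneRecord]:
    """Non-corrupted RE genes of incomplete systems, in deterministic order."""
    out = []
    for sid in sorted(systems):
        system = systems[sid]
        if system.completeness == "incomplete":
            out.extend(g for g in system.re_genes if not g.corrupted)
    out.sort(key=lambda g: g.gene_id)
    return out
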