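"""Pairwise protein similarity engine.

Local (Smith-Waterman-style) alignment with BLOSUM62 scores and affine gaps
(a gap of length *k* costs ``gap_open + k * gap_extend``), plus a
Karlin-Altschul-style E-value.  This approximates the default behaviour of a
BLASTp search; it is not bit-exact with NCBI BLAST.  An adapter for standard
tabular search output is provided so an external tool can be swapped in.

Determinism: for fixed inputs and scoring parameters the reported alignment
is unique.  DP tie-breaking prefers diagonal over gap-in-query over
gap-in-subject; gap states prefer opening over extending; the traceback
starts from the highest-scoring cell with the smallest (row, column).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from Bio.Align import substitution_matrices

from .model import ValidationError, validate_protein

__all__ = [
    "AlignmentHit",
    "Scoring",
    "align_pair",
    "search",
    "meets",
    "hit_sort_key",
    "read_tabular_hits",
]

_NEG = -(10 ** 9)


@dataclass(frozen=True)
class AlignmentHit:
    """One pairwise local-alignment result.

    ``identity`` is the fraction of identical residue pairs among aligned
    residue-pair columns (gap columns excluded from the denominator).
    Coverages are aligned-span fractions of the query, the subject, and the
    longer of the two, so that either coverage convention is auditable.
    """

    query_id: str
    subject_id: str
    identity: float
    coverage_query: float
    coverage_subject: float
    coverage_longer: float
    aln_length: int
    score: float
    evalue: float
    n_identical: int = 0
    query_start: int = 0
    query_end: int = 0
    subject_start: int = 0
    subject_end: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0):
            raise ValidationError(f"identity out of range: {self.identity}")
        for name in ("coverage_query", "coverage_subject", "coverage_longer"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValidationError(f"{name} out of range: {v}")
        if self.aln_length < 1:
            raise ValidationError("aln_length must be >= 1")
        if self.evalue < 0:
            raise ValidationError("evalue must be >= 0")

    def swapped(self) -> "AlignmentHit":
        return AlignmentHit(
            query_id=self.subject_id,
            subject_id=self.query_id,
            identity=self.identity,
            coverage_query=self.coverage_subject,
            coverage_subject=self.coverage_query,
            coverage_longer=self.coverage_longer,
            aln_length=self.aln_length,
            score=self.score,
            evalue=self.evalue,
            n_identical=self.n_identical,
            query_start=self.subject_start,
            query_end=self.subject_end,
            subject_start=self.query_start,
            subject_end=self.query_end,
        )


@dataclass(frozen=True)
class Scoring:
    """Scoring parameters; defaults approximate BLASTp (BLOSUM62, 11/1).

    ``ka_lambda`` / ``ka_k`` are the published Karlin-Altschul parameters for
    gapped BLOSUM62 11/1 searches; E = K * m * n * exp(-lambda * S).
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    ka_lambda: float = 0.267
    ka_k: float = 0.041


_DEFAULT_SCORING = Scoring()
_MATRIX_CACHE: Dict[str, Tuple[str, np.ndarray]] = {}


def _load_matrix(name: str) -> Tuple[str, np.ndarray]:
    cached = _MATRIX_CACHE.get(name)
    if cached is not None:
        return cached
    mat = substitution_matrices.load(name)
    alphabet = str(mat.alphabet)
    arr = np.asarray(mat, dtype=np.int32)
    _MATRIX_CACHE[name] = (alphabet, arr)
    return alphabet, arr


def _encode(seq: str, alphabet: str) -> np.ndarray:
    lut = {c: i for i, c in enumerate(alphabet)}
    x_idx = lut.get("X", 0)
    out = np.empty(len(seq), dtype=np.int64)
    for i, c in enumerate(seq):
        out[i] = lut.get(c, x_idx)  # U/O and other rarities score as X
    return out


def _fill_py(ai, bi, sub, gap_open, gap_extend):  # pragma: no cover - numba path used when available
    m = ai.shape[0]
    n = bi.shape[0]
    H = np.zeros((m + 1, n + 1), np.int32)
    E = np.full((m + 1, n + 1), _NEG, np.int32)
    F = np.full((m + 1, n + 1), _NEG, np.int32)
    ptrH = np.zeros((m + 1, n + 1), np.int8)
    ptrE = np.zeros((m + 1, n + 1), np.int8)
    ptrF = np.zeros((m + 1, n + 1), np.int8)
    best = 0
    best_i = 0
    best_j = 0
    first_gap = gap_open + gap_extend
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            eo = H[i, j - 1] - first_gap
            ee = E[i, j - 1] - gap_extend
            if eo >= ee:
                E[i, j] = eo
                ptrE[i, j] = 1
            else:
                E[i, j] = ee
                ptrE[i, j] = 0
            fo = H[i - 1, j] - first_gap
            fe = F[i - 1, j] - gap_extend
            if fo >= fe:
                F[i, j] = fo
                ptrF[i, j] = 1
            else:
                F[i, j] = fe
                ptrF[i, j] = 0
            h = H[i - 1, j - 1] + sub[ai[i - 1], bi[j - 1]]
            p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            if h <= 0:
                h = 0
                p = 0
            H[i, j] = h
            ptrH[i, j] = p
            if h > best:
                best = h
                best_i = i
                best_j = j
    return best, best_i, best_j, ptrH, ptrE, ptrF


try:  # optional JIT; the pure-Python path is the reference behaviour
    from numba import njit

    _fill = njit(cache=True)(_fill_py)
except Exception:  # pragma: no cover
    _fill = _fill_py


def _traceback(ai, bi, bi_, bj_, ptrH, ptrE, ptrF):
    """Walk the pointer matrices; returns (n_cols, n_pair_cols, n_identical, qstart, qend, sstart, send)."""
    i, j = bi_, bj_
    state = 0  # 0=H, 1=E (gap in query, consumes subject), 2=F (gap in subject, consumes query)
    n_cols = 0
    n_pair = 0
    n_id = 0
    qend, send = i, j
    while True:
        if state == 0:
            p = ptrH[i, j]
            if p == 0:
                break
            if p == 1:
                n_cols += 1
                n_pair += 1
                if ai[i - 1] == bi[j - 1]:
                    n_id += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            opened = ptrE[i, j]
            n_cols += 1
            j -= 1
            state = 0 if opened else 1
        else:
            opened = ptrF[i, j]
            n_cols += 1
            i -= 1
            state = 0 if opened else 2
    return n_cols, n_pair, n_id, i, qend, j, send


def evalue_for_score(score: float, m: int, n: int, scoring: Scoring = _DEFAULT_SCORING) -> float:
    return scoring.ka_k * m * n * math.exp(-scoring.ka_lambda * score)


def align_pair(
    seq_a: str,
    seq_b: str,
    query_id: str = "query",
    subject_id: str = "subject",
    scoring: Scoring = _DEFAULT_SCORING,
) -> Optional[AlignmentHit]:
    """Optimal local alignment of two protein sequences.

    Returns ``None`` when no alignment with positive score exists (no local
    similarity at all); otherwise a fully populated :class:`AlignmentHit`.

    The result is exactly symmetric under argument swap: the pair is aligned
    in a canonical orientation (lexicographically smaller sequence first) so
    that tie-breaking among co-optimal alignments cannot depend on argument
    order.
    """
    a = validate_protein(seq_a)
    b = validate_protein(seq_b)
    if not a or not b:
        raise ValidationError("align_pair requires non-empty sequences")
    if a > b:  # canonical orientation; swap the hit back afterwards
        hit = align_pair(b, a, query_id=subject_id, subject_id=query_id, scoring=scoring)
        return hit.swapped() if hit is not None else None
    alphabet, sub = _load_matrix(scoring.matrix_name)
    ai = _encode(a, alphabet)
    bi = _encode(b, alphabet)
    best, bi_, bj_, ptrH, ptrE, ptrF = _fill(ai, bi, sub, scoring.gap_open, scoring.gap_extend)
    if best <= 0:
        return None
    n_cols, n_pair, n_id, qstart, qend, sstart, send = _traceback(ai, bi, bi_, bj_, ptrH, ptrE, ptrF)
    longer = max(len(a), len(b))
    span_longer = (qend - qstart) if len(a) >= len(b) else (send - sstart)
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        identity=n_id / n_pair if n_pair else 0.0,
        coverage_query=(qend - qstart) / len(a),
        coverage_subject=(send - sstart) / len(b),
        coverage_longer=span_longer / longer,
        aln_length=n_cols,
        score=float(best),
        evalue=evalue_for_score(best, len(a), len(b), scoring),
        n_identical=n_id,
        query_start=qstart,
        query_end=qend,
        subject_start=sstart,
        subject_end=send,
    )


def hit_sort_key(hit: AlignmentHit):
    """Deterministic 'better first' ordering: score desc, identity desc, subject id asc."""
    return (-hit.score, -hit.identity, hit.subject_id)


def search(
    queries: Mapping[str, str] | Iterable[Tuple[str, str]],
    subjects: Mapping[str, str] | Iterable[Tuple[str, str]],
    evalue_max: float,
    scoring: Scoring = _DEFAULT_SCORING,
    skip_self: bool = False,
) -> List[AlignmentHit]:
    """All-vs-all similarity search keeping hits with E-value below ``evalue_max``.

    One best hit per ordered (query, subject) pair.  Results are sorted by
    query id, then by the deterministic 'better first' hit order.
    """
    if evalue_max <= 0:
        raise ValidationError("evalue_max must be > 0")
    qitems = sorted(dict(queries).items())
    sitems = sorted(dict(subjects).items())
    hits: List[AlignmentHit] = []
    for qid, qseq in qitems:
        for sid, sseq in sitems:
            if skip_self and qid == sid:
                continue
            hit = align_pair(qseq, sseq, query_id=qid, subject_id=sid, scoring=scoring)
            if hit is not None and hit.evalue < evalue_max:
                hits.append(hit)
    hits.sort(key=lambda h: (h.query_id,) + tuple(hit_sort_key(h)))
    return hits


def meets(
    hit: AlignmentHit,
    identity_min: float,
    coverage_min: float,
    coverage_basis: str = "longer",
) -> bool:
    """Strict-inequality threshold predicate (published thresholds use '>').

    ``coverage_basis``: ``longer`` tests the longer sequence's coverage,
    ``each`` requires both query and subject coverage, ``query`` only the
    query's.
    """
    if coverage_basis not in ("longer", "each", "query"):
        raise ValidationError(f"unknown coverage basis {coverage_basis!r}")
    if not hit.identity > identity_min:
        return False
    if coverage_basis == "longer":
        return hit.coverage_longer > coverage_min
    if coverage_basis == "each":
        return hit.coverage_query > coverage_min and hit.coverage_subject > coverage_min
    return hit.coverage_query > coverage_min


def read_tabular_hits(
    path,
    query_lengths: Optional[Mapping[str, int]] = None,
    subject_lengths: Optional[Mapping[str, int]] = None,
) -> List[AlignmentHit]:
    """Adapter for standard 12-column tabular search output (optionally +qlen,slen).

    Columns: query, subject, %identity, aln length, mismatches, gap opens,
    qstart, qend, sstart, send, evalue, bitscore[, qlen, slen] with 1-based
    inclusive coordinates.  Lengths must come from the extra columns or the
    mappings, otherwise coverages cannot be derived.
    """
    hits: List[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValidationError(f"{path}:{lineno}: expected >=12 tab-separated columns")
            qid, sid = parts[0], parts[1]
            pident = float(parts[2]) / 100.0
            aln_len = int(parts[3])
            qstart, qend = int(parts[6]) - 1, int(parts[7])
            sstart, send = int(parts[8]) - 1, int(parts[9])
            ev = float(parts[10])
            score = float(parts[11])
            if len(parts) >= 14:
                qlen, slen = int(parts[12]), int(parts[13])
            else:
                if query_lengths is None or subject_lengths is None:
                    raise ValidationError(
                        f"{path}:{lineno}: need qlen/slen columns or explicit length mappings"
                    )
                qlen, slen = query_lengths[qid], subject_lengths[sid]
            cov_q = (qend - qstart) / qlen
            cov_s = (send - sstart) / slen
            cov_longer = cov_q if qlen >= slen else cov_s
            hits.append(
                AlignmentHit(
                    query_id=qid,
                    subject_id=sid,
                    identity=pident,
                    coverage_query=cov_q,
                    coverage_subject=cov_s,
                    coverage_longer=cov_longer,
                    aln_length=aln_len,
                    score=score,
                    evalue=ev,
                    n_identical=round(pident * aln_len),
                    query_start=qstart,
                    query_end=qend,
                    subject_start=sstart,
                    subject_end=send,
                )
            )
    return hits


class SimilarityCache:
    """Memoized symmetric ``align_pair`` over a fixed id -> sequence table."""

    def __init__(self, sequences: Mapping[str, str], scoring: Scoring = _DEFAULT_SCORING):
        self.sequences = dict(sequences)
        self.scoring = scoring
        self._cache: Dict[Tuple[str, str], Optional[AlignmentHit]] = {}

    def hit(self, id_a: str, id_b: str) -> Optional[AlignmentHit]:
        key = (id_a, id_b)
        if key in self._cache:
            return self._cache[key]
        rkey = (id_b, id_a)
        if rkey in self._cache:
            rhit = self._cache[rkey]
            hit = rhit.swapped() if rhit is not None else None
        else:
            hit = align_pair(
                self.sequences[id_a],
                self.sequences[id_b],
                query_id=id_a,
                subject_id=id_b,
                scoring=self.scoring,
            )
        self._cache[key] = hit
        return hit
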