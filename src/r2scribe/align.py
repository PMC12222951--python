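"""Deterministic pairwise alignment with explicit CIGAR operations.

Two modes are provided:

``align_local``
    Smith-Waterman local alignment with affine gap costs (Gotoh), used to
    annotate short features (locus flanks, transgene, 3' UTR) on long reads.

``align_spliced``
    Glocal alignment (the query is aligned end-to-end, reference ends are
    free) with a two-piece gap cost.  The second, cheap-extension gap class
    makes kilobase-scale gaps affordable, so a read carrying a transgene
    insert aligns across the insert-less wild-type reference in one piece,
    and a 5'-truncated insert shows up as a single long deletion/skip run
    against the integrated reference.

Operations use single-letter codes: M (match), X (mismatch), I (insertion,
query-consuming), D (deletion, reference-consuming), N (skip; a deletion of
at least ``skip_min_len`` bases, reference-consuming), S (softclip).  All
coordinates are 0-based half-open.  Tie-breaking is deterministic: among
equal-scoring alignments the one with the smallest reference start, then
smallest query start, wins; on equal scores the forward strand wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .sequence import encode, revcomp

NEG = -(10**9)

# pointer encoding: low 3 bits = H source, high bits = gap-open flags
_H_STOP, _H_DIAG, _H_E, _H_F, _H_E2, _H_F2 = 0, 1, 2, 3, 4, 5
_E_OPEN, _F_OPEN, _E2_OPEN, _F2_OPEN = 8, 16, 32, 64

QUERY_OPS = frozenset("MXIS")
REF_OPS = frozenset("MXDN")


@dataclass(frozen=True)
class Scoring:
    """Alignment scoring scheme (all values are signed integers).

    A gap of length L in the short class costs ``gap_open + L*gap_extend``;
    the long class costs ``long_gap_open + L*long_gap_extend`` and is only
    used by the spliced mode.  With the defaults the long class takes over
    for gaps of ~19 bases and makes insert-sized gaps cheap.
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    long_gap_open: int = -24
    long_gap_extend: int = -1
    skip_min_len: int = 50


@dataclass(frozen=True)
class CigarOp:
    op: str
    length: int

    def __post_init__(self):
        if self.op not in "MXIDNS":
            raise ValueError(f"unknown CIGAR op {self.op!r}")
        if self.length < 1:
            raise ValueError("CIGAR op length must be >= 1")


def _merge_ops(ops: list[CigarOp]) -> tuple[CigarOp, ...]:
    merged: list[CigarOp] = []
    for op in ops:
        if merged and merged[-1].op == op.op:
            merged[-1] = CigarOp(op.op, merged[-1].length + op.length)
        else:
            merged.append(op)
    return tuple(merged)


@dataclass(frozen=True)
class Alignment:
    """A pairwise alignment of a query interval to a reference interval.

    For strand '-', the reverse complement of the query was aligned to the
    forward reference; ``query_start/end`` are reported in original query
    coordinates while ``ops`` follow the reference left to right.
    """

    query_start: int
    query_end: int
    ref_start: int
    ref_end: int
    strand: str
    ops: tuple[CigarOp, ...]
    score: int

    @property
    def cigar(self) -> str:
        return "".join(f"{o.length}{o.op}" for o in self.ops)

    @property
    def n_matches(self) -> int:
        return sum(o.length for o in self.ops if o.op == "M")

    @property
    def aligned_query_bases(self) -> int:
        return sum(o.length for o in self.ops if o.op in "MXI")

    @property
    def identity(self) -> float:
        aligned = self.aligned_query_bases
        return self.n_matches / aligned if aligned else 0.0

    def validate(self) -> None:
        q = sum(o.length for o in self.ops if o.op in QUERY_OPS and o.op != "S")
        r = sum(o.length for o in self.ops if o.op in REF_OPS)
        if q != self.query_end - self.query_start:
            raise AssertionError("query-consuming op lengths != query interval")
        if r != self.ref_end - self.ref_start:
            raise AssertionError("ref-consuming op lengths != ref interval")
        for a, b in zip(self.ops, self.ops[1:]):
            if a.op == b.op:
                raise AssertionError("adjacent ops of the same kind not merged")


@njit(cache=True)
def _local_kernel(q, r, ma, mi, go, ge):
    n, m = q.size, r.size
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)
    E = np.full(m + 1, NEG, dtype=np.int32)
    for i in range(1, n + 1):
        f = NEG
        qi = q[i - 1]
        for j in range(1, m + 1):
            p = 0
            # E: gap in reference (query-consuming, I), vertical move
            e_open = H[i - 1, j] + go + ge
            e_ext = E[j] + ge
            if e_open >= e_ext:
                E[j] = e_open
                p |= _E_OPEN
            else:
                E[j] = e_ext
            # F: gap in query (reference-consuming, D), horizontal move
            f_open = H[i, j - 1] + go + ge
            f_ext = f + ge
            if f_open >= f_ext:
                f = f_open
                p |= _F_OPEN
            else:
                f = f_ext
            s = ma if (qi == r[j - 1] and qi < 4) else mi
            diag = H[i - 1, j - 1] + s
            best = 0
            src = _H_STOP
            if diag > best:
                best = diag
                src = _H_DIAG
            if E[j] > best:
                best = E[j]
                src = _H_E
            if f > best:
                best = f
                src = _H_F
            H[i, j] = best
            ptr[i, j] = p | src
    return H, ptr


@njit(cache=True)
def _spliced_kernel(q, r, ma, mi, go, ge, go2, ge2):
    n, m = q.size, r.size
    H = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)
    E = np.full(m + 1, NEG, dtype=np.int32)
    E2 = np.full(m + 1, NEG, dtype=np.int32)
    H[0, :] = 0  # free reference start: query-global, reference-local
    for i in range(1, n + 1):
        f = NEG
        f2 = NEG
        qi = q[i - 1]
        for j in range(0, m + 1):
            p = 0
            e_open = H[i - 1, j] + go + ge
            e_ext = E[j] + ge
            if e_open >= e_ext:
                E[j] = e_open
                p |= _E_OPEN
            else:
                E[j] = e_ext
            e2_open = H[i - 1, j] + go2 + ge2
            e2_ext = E2[j] + ge2
            if e2_open >= e2_ext:
                E2[j] = e2_open
                p |= _E2_OPEN
            else:
                E2[j] = e2_ext
            if j > 0:
                f_open = H[i, j - 1] + go + ge
                f_ext = f + ge
                if f_open >= f_ext:
                    f = f_open
                    p |= _F_OPEN
                else:
                    f = f_ext
                f2_open = H[i, j - 1] + go2 + ge2
                f2_ext = f2 + ge2
                if f2_open >= f2_ext:
                    f2 = f2_open
                    p |= _F2_OPEN
                else:
                    f2 = f2_ext
            best = NEG
            src = _H_STOP
            if j > 0:
                s = ma if (qi == r[j - 1] and qi < 4) else mi
                diag = H[i - 1, j - 1] + s
                if diag > best:
                    best = diag
                    src = _H_DIAG
            if E[j] > best:
                best = E[j]
                src = _H_E
            if E2[j] > best:
                best = E2[j]
                src = _H_E2
            if j > 0 and f > best:
                best = f
                src = _H_F
            if j > 0 and f2 > best:
                best = f2
                src = _H_F2
            H[i, j] = best
            ptr[i, j] = p | src
    return H, ptr


def _traceback(q, r, ptr, i, j, glocal: bool):
    """Walk pointers from (i, j) back to an alignment start.

    Returns (query_start, ref_start, ops list in left-to-right order).
    """
    ops: list[CigarOp] = []
    while True:
        src = ptr[i, j] & 7
        if src == _H_STOP:
            if glocal and i > 0:
                raise AssertionError("glocal traceback ended mid-query")
            break
        if glocal and i == 0:
            break
        if src == _H_DIAG:
            op = "M" if (q[i - 1] == r[j - 1] and q[i - 1] < 4) else "X"
            ops.append(CigarOp(op, 1))
            i -= 1
            j -= 1
        elif src in (_H_E, _H_E2):
            flag = _E_OPEN if src == _H_E else _E2_OPEN
            while True:
                ops.append(CigarOp("I", 1))
                opened = ptr[i, j] & flag
                i -= 1
                if opened:
                    break
        else:  # _H_F, _H_F2
            flag = _F_OPEN if src == _H_F else _F2_OPEN
            while True:
                ops.append(CigarOp("D", 1))
                opened = ptr[i, j] & flag
                j -= 1
                if opened:
                    break
    ops.reverse()
    return i, j, ops


def _relabel_skips(ops: tuple[CigarOp, ...], skip_min_len: int) -> tuple[CigarOp, ...]:
    return tuple(
        CigarOp("N", o.length) if o.op == "D" and o.length >= skip_min_len else o
        for o in ops
    )


def _finish(q, r, ptr, end_i, end_j, score, strand, qlen, glocal, scoring):
    qs, rs, ops = _traceback(q, r, ptr, end_i, end_j, glocal)
    ops = _merge_ops(ops)
    if glocal:
        ops = _relabel_skips(ops, scoring.skip_min_len)
    q_start, q_end = qs, end_i
    if strand == "-":
        q_start, q_end = qlen - end_i, qlen - qs
    aln = Alignment(q_start, q_end, rs, end_j, strand, ops, int(score))
    aln.validate()
    return aln


def _best_local(qcodes, rcodes, scoring, strand, qlen):
    H, ptr = _local_kernel(
        qcodes, rcodes, scoring.match, scoring.mismatch,
        scoring.gap_open, scoring.gap_extend,
    )
    best = int(H.max())
    if best <= 0:
        return None, 0
    cells = np.argwhere(H == best)
    candidates = []
    for i, j in cells:
        qs, rs, ops = _traceback(qcodes, rcodes, ptr, int(i), int(j), False)
        candidates.append((rs, qs, int(j), int(i), ops))
    rs, qs, j, i, ops = min(candidates, key=lambda c: c[:4])
    ops = _merge_ops(ops)
    q_start, q_end = qs, i
    if strand == "-":
        q_start, q_end = qlen - i, qlen - qs
    aln = Alignment(q_start, q_end, rs, j, strand, ops, best)
    aln.validate()
    return aln, best


def align_local(
    query: str,
    ref: str,
    scoring: Scoring | None = None,
    both_strands: bool = False,
    min_score: int = 1,
) -> Optional[Alignment]:
    """Best local alignment of ``query`` against ``ref``, or None.

    Returns None if the optimal score is below ``min_score``.  With
    ``both_strands`` the reverse complement of the query is also tried and
    the higher-scoring strand wins (forward wins ties).
    """
    if not query or not ref:
        raise ValueError("align_local requires non-empty sequences")
    scoring = scoring or Scoring()
    rcodes = encode(ref)
    fwd, fwd_score = _best_local(encode(query), rcodes, scoring, "+", len(query))
    best = fwd
    if both_strands:
        rev, rev_score = _best_local(
            encode(revcomp(query)), rcodes, scoring, "-", len(query)
        )
        if rev is not None and (best is None or rev_score > fwd_score):
            best = rev
    if best is None or best.score < min_score:
        return None
    return best


def _best_spliced(qcodes, rcodes, scoring, strand, qlen):
    H, ptr = _spliced_kernel(
        qcodes, rcodes, scoring.match, scoring.mismatch,
        scoring.gap_open, scoring.gap_extend,
        scoring.long_gap_open, scoring.long_gap_extend,
    )
    last = H[qcodes.size, :]
    best = int(last.max())
    end_j = int(np.argmax(last))  # smallest ref end among ties
    aln = _finish(qcodes, rcodes, ptr, qcodes.size, end_j, best, strand, qlen,
                  True, scoring)
    return aln


def align_spliced(
    query: str,
    ref: str,
    scoring: Scoring | None = None,
    both_strands: bool = False,
) -> Alignment:
    """Glocal alignment with two-piece gap costs.

    The query is aligned end to end; reference ends are free.  Long
    reference-consuming gaps (>= ``scoring.skip_min_len``) are reported as
    skip (N) ops; a kilobase insert present in the query but absent from
    the reference appears as one long insertion (I) op.
    """
    if not query or not ref:
        raise ValueError("align_spliced requires non-empty sequences")
    scoring = scoring or Scoring()
    rcodes = encode(ref)
    best = _best_spliced(encode(query), rcodes, scoring, "+", len(query))
    if both_strands:
        rev = _best_spliced(encode(revcomp(query)), rcodes, scoring, "-", len(query))
        if rev.score > best.score:
            best = rev
    return best


def consecutive_gap_runs(aln: Alignment, min_len: int = 4) -> list[tuple[int, int]]:
    """Maximal runs of deletion/skip (D/N) ops with total length >= min_len.

    Returns ``(ref_position, run_length)`` tuples in reference order.
    Insertions terminate a run; only reference-consuming gap ops count.
    """
    runs: list[tuple[int, int]] = []
    ref_pos = aln.ref_start
    run_start, run_len = None, 0
    for op in aln.ops:
        if op.op in ("D", "N"):
            if run_start is None:
                run_start = ref_pos
            run_len += op.length
            ref_pos += op.length
        else:
            if run_start is not None and run_len >= min_len:
                runs.append((run_start, run_len))
            run_start, run_len = None, 0
            if op.op in ("M", "X"):
                ref_pos += op.length
    if run_start is not None and run_len >= min_len:
        runs.append((run_start, run_len))
    return runs


def alignment_row(name: str, ref_name: str, aln: Alignment) -> dict:
    """One SAM-like record (for TSV serialization / debugging)."""
    return {
        "query": name,
        "ref": ref_name,
        "strand": aln.strand,
        "ref_start": aln.ref_start,
        "query_start": aln.query_start,
        "cigar": aln.cigar,
        "score": aln.score,
        "identity": round(aln.identity, 4),
    }
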