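"""Long-read integration-outcome classification.

Pipeline per read: annotate the six library features on both strands,
require >= 100 annotated nt of both the 5'-end and 3'-end locus flanks in
one orientation, trim to the furthest-apart same-orientation flank pair,
then classify:

* ``uninserted`` — no transgene and no 3' UTR annotation;
* ``full_length`` — exactly one transgene and one 3' UTR hit and no run of
  >= 4 consecutive deleted/skipped bases (D/N) against the integrated
  reference within the insert span;
* ``jump`` — more than one transgene or 3' UTR hit with non-overlapping
  reference projections, or a single transgene hit anchored within the
  first 10 nt of the transgene 5' end (and not full-length);
* ``five_prime_truncation`` — one transgene + one 3' UTR hit, a >= 4-base
  D/N run, and a transgene alignment that does not reach the 5' end;
* ``other`` — everything else (e.g. snap-backs with inverted segments).

Reads that carry the ddPCR probe site flanked by convergent primer sites
(each within 2 substitutions) are additionally counted as
"ddPCR-detectable"; that count anchors the full-length copy-number
estimate in :mod:`r2scribe.quant`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .align import Alignment, Scoring, align_local, align_spliced, consecutive_gap_runs
from .refsim import DonorSpec, ReferenceSet, SimulatedRead
from .sequence import encode, revcomp

FLANKS_5P = ("5end_400nt", "5end_200nt")
FLANKS_3P = ("3end_200nt", "3end_400nt")
INSERT_FEATURES = ("transgene", "3utr")

CATEGORIES = ("full_length", "jump", "five_prime_truncation", "other")


@dataclass(frozen=True)
class FeatureHit:
    """One feature annotation on a read.

    ``feature_start/end`` is the projection onto the feature's forward
    coordinates regardless of orientation.
    """

    feature: str
    read_start: int
    read_end: int
    orientation: str
    identity: float
    feature_start: int
    feature_end: int
    alignment: Alignment

    @property
    def read_span(self) -> int:
        return self.read_end - self.read_start


@dataclass(frozen=True)
class TrimResult:
    trimmed: str
    flanked_segment: str
    trimmed_interval: tuple[int, int]
    orientation: str


@dataclass(frozen=True)
class ReadClassification:
    read_id: str
    status: str  # rejected | uninserted | inserted
    category: Optional[str] = None
    reason: Optional[str] = None
    n_transgene_features: int = 0
    n_utr_features: int = 0
    max_gap_run: int = 0
    aligns_to_transgene_5p: bool = False
    trimmed_interval: Optional[tuple[int, int]] = None

    def __post_init__(self):
        if (self.status == "inserted") != (self.category is not None):
            raise ValueError("category present iff status == inserted")


@dataclass
class ClassifierConfig:
    min_identity: float = 0.8
    min_hit_length: int = 30
    min_flank_nt: int = 100
    max_gap_run_full_length: int = 3  # a run of >= 4 disqualifies full-length
    transgene_5p_bound: int = 10
    split_gap: int = 20  # internal gap >= this splits an annotation hit in two
    scoring: Scoring = field(default_factory=Scoring)

    @property
    def min_hit_score(self) -> int:
        s = self.scoring
        return int(self.min_hit_length *
                   (self.min_identity * s.match + (1 - self.min_identity) * s.mismatch))


def _split_alignment(aln: Alignment, split_gap: int):
    """Split an alignment at internal gaps >= ``split_gap`` bases.

    A feature hit spanning a large insertion or deletion (e.g. a transgene
    with an internal segment missing from the read) is reported as separate
    hits, the way a repeat annotator would; each piece is
    ``(q0, q1, r0, r1, ops)`` in the aligned orientation.
    """
    pieces = []
    q = aln.query_start
    r = aln.ref_start
    q0, r0 = q, r
    ops: list = []
    for op in aln.ops:
        if op.op in ("I", "D", "N") and op.length >= split_gap:
            if ops:
                pieces.append((q0, q, r0, r, tuple(ops)))
            if op.op == "I":
                q += op.length
            else:
                r += op.length
            q0, r0, ops = q, r, []
        else:
            ops.append(op)
            if op.op in ("M", "X"):
                q += op.length
                r += op.length
            elif op.op == "I":
                q += op.length
            else:
                r += op.length
    if ops:
        pieces.append((q0, q, r0, r, tuple(ops)))
    return pieces


def _score_ops(ops, scoring: Scoring) -> int:
    total = 0
    for op in ops:
        if op.op == "M":
            total += scoring.match * op.length
        elif op.op == "X":
            total += scoring.mismatch * op.length
        else:
            total += scoring.gap_open + scoring.gap_extend * op.length
    return total


def annotate_features(
    read: str,
    feature_library: dict[str, str],
    config: ClassifierConfig | None = None,
) -> list[FeatureHit]:
    """All hits of each library feature on both strands of the read.

    Iterated best-local-alignment with masking: after each accepted hit the
    matched read interval is masked so duplicated features (jumps) yield
    separate non-overlapping hits.  Hits below the identity or length
    thresholds are discarded; overlapping same-feature, same-orientation
    hits are merged.
    """
    if not feature_library:
        raise ValueError("feature library must be non-empty")
    config = config or ClassifierConfig()
    hits: list[FeatureHit] = []
    for name, feature in feature_library.items():
        for orientation in "+-":
            query = feature if orientation == "+" else revcomp(feature)
            masked = read
            for _ in range(8):  # cap pathological repeats
                aln = align_local(query, masked, config.scoring,
                                  min_score=config.min_hit_score)
                if aln is None:
                    break
                for q0, q1, r0, r1, ops in _split_alignment(aln, config.split_gap):
                    piece = Alignment(q0, q1, r0, r1, "+", ops,
                                      _score_ops(ops, config.scoring))
                    if (piece.aligned_query_bases < config.min_hit_length
                            or piece.identity < config.min_identity):
                        continue
                    if orientation == "+":
                        fs, fe = q0, q1
                    else:
                        fs, fe = len(feature) - q1, len(feature) - q0
                    hits.append(FeatureHit(
                        feature=name,
                        read_start=r0,
                        read_end=r1,
                        orientation=orientation,
                        identity=piece.identity,
                        feature_start=fs,
                        feature_end=fe,
                        alignment=piece,
                    ))
                masked = (masked[:aln.ref_start]
                          + "N" * (aln.ref_end - aln.ref_start)
                          + masked[aln.ref_end:])
    return _merge_hits(hits)


def _merge_hits(hits: list[FeatureHit]) -> list[FeatureHit]:
    """Merge overlapping same-feature, same-orientation hits (interval union)."""
    out: list[FeatureHit] = []
    for key in sorted({(h.feature, h.orientation) for h in hits}):
        group = sorted((h for h in hits if (h.feature, h.orientation) == key),
                       key=lambda h: h.read_start)
        cur = group[0]
        for h in group[1:]:
            if h.read_start < cur.read_end:  # overlap on the read
                keep = cur if cur.read_span >= h.read_span else h
                cur = FeatureHit(
                    feature=cur.feature,
                    read_start=min(cur.read_start, h.read_start),
                    read_end=max(cur.read_end, h.read_end),
                    orientation=cur.orientation,
                    identity=keep.identity,
                    feature_start=min(cur.feature_start, h.feature_start),
                    feature_end=max(cur.feature_end, h.feature_end),
                    alignment=keep.alignment,
                )
            else:
                out.append(cur)
                cur = h
        out.append(cur)
    return sorted(out, key=lambda h: (h.read_start, h.feature, h.orientation))


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total, end = 0, -1
    for s, e in sorted(intervals):
        s = max(s, end)
        if e > s:
            total += e - s
            end = e
        end = max(end, e)
    return total


def _flank_coverage(hits: Sequence[FeatureHit], names, orientation) -> int:
    iv = [(h.read_start, h.read_end) for h in hits
          if h.feature in names and h.orientation == orientation]
    return _union_length(iv)


def filter_informative(
    hits: Sequence[FeatureHit],
    min_flank_nt: int = 100,
) -> tuple[bool, Optional[str]]:
    """Require >= ``min_flank_nt`` annotated nt of both 5'-end and 3'-end
    flanks in one common orientation (pooled across the two segments per
    side)."""
    for orientation in "+-":
        c5 = _flank_coverage(hits, FLANKS_5P, orientation)
        c3 = _flank_coverage(hits, FLANKS_3P, orientation)
        if c5 >= min_flank_nt and c3 >= min_flank_nt:
            return True, None
    c5 = max(_flank_coverage(hits, FLANKS_5P, o) for o in "+-")
    c3 = max(_flank_coverage(hits, FLANKS_3P, o) for o in "+-")
    if c5 < min_flank_nt and c3 < min_flank_nt:
        return False, f"both flanks < {min_flank_nt} nt"
    if c5 < min_flank_nt:
        return False, f"5end flank < {min_flank_nt} nt"
    if c3 < min_flank_nt:
        return False, f"3end flank < {min_flank_nt} nt"
    return False, "flanks not in a common orientation"


def trim_to_flanked(
    read: str,
    hits: Sequence[FeatureHit],
    min_flank_nt: int = 100,
) -> Optional[TrimResult]:
    """Trim to the region between the furthest-apart same-orientation flank
    pair; the trimmed sequence is returned in insert-forward orientation.

    ``flanked_segment`` additionally includes the chosen flank hits
    themselves — the anchored segment the gap-run alignment uses.
    Returns None when no valid pair exists.
    """
    best = None
    for orientation in "+-":
        if (_flank_coverage(hits, FLANKS_5P, orientation) < min_flank_nt
                or _flank_coverage(hits, FLANKS_3P, orientation) < min_flank_nt):
            continue
        # the two adjacent flank features on each side form one block; only
        # duplicated blocks (rare rearrangements) yield multiple candidates
        b5 = _flank_blocks(hits, FLANKS_5P, orientation)
        b3 = _flank_blocks(hits, FLANKS_3P, orientation)
        for a in b5:
            for b in b3:
                if orientation == "+":
                    inner = (a[1], b[0])
                    outer = (a[0], b[1])
                else:
                    inner = (b[1], a[0])
                    outer = (b[0], a[1])
                if inner[1] < inner[0]:
                    continue
                span = inner[1] - inner[0]
                cand = (span, orientation, inner, outer)
                if best is None or cand[0] > best[0]:
                    best = cand
    if best is None:
        return None
    span, orientation, inner, outer = best
    trimmed = read[inner[0]:inner[1]]
    segment = read[outer[0]:outer[1]]
    if orientation == "-":
        trimmed = revcomp(trimmed)
        segment = revcomp(segment)
    return TrimResult(trimmed, segment, inner, orientation)


def _flank_blocks(hits, names, orientation, merge_gap: int = 30):
    """Group one side's flank hits into blocks, merging intervals separated
    by at most ``merge_gap`` bases (adjacent 400/200-nt features with
    boundary jitter)."""
    iv = sorted((h.read_start, h.read_end) for h in hits
                if h.feature in names and h.orientation == orientation)
    blocks: list[list[int]] = []
    for s, e in iv:
        if blocks and s <= blocks[-1][1] + merge_gap:
            blocks[-1][1] = max(blocks[-1][1], e)
        else:
            blocks.append([s, e])
    return [tuple(b) for b in blocks]


def classify_read(
    read: SimulatedRead | str,
    refset: ReferenceSet,
    config: ClassifierConfig | None = None,
    hits: Optional[list[FeatureHit]] = None,
) -> ReadClassification:
    """Classify one read into rejected / uninserted / inserted + category."""
    config = config or ClassifierConfig()
    if isinstance(read, SimulatedRead):
        read_id, seq = read.read_id, read.sequence
    else:
        read_id, seq = "read", read
    if refset.integrated_locus is None:
        raise ValueError("reference set lacks the integrated reference")
    if hits is None:
        hits = annotate_features(seq, refset.feature_library, config)

    ok, reason = filter_informative(hits, config.min_flank_nt)
    if not ok:
        return ReadClassification(read_id, "rejected", reason=reason)

    tg_hits = [h for h in hits if h.feature == "transgene"]
    utr_hits = [h for h in hits if h.feature == "3utr"]
    if not tg_hits and not utr_hits:
        return ReadClassification(read_id, "uninserted")

    trim = trim_to_flanked(seq, hits, config.min_flank_nt)
    if trim is None:
        return ReadClassification(read_id, "rejected", reason="no valid flank pair")

    # gap runs against the integrated reference, restricted to the insert
    # span: the flank hits anchor the glocal alignment so missing insert
    # bases surface as D/N runs, while flank-only sequencing dropouts
    # outside the insert do not count against insert integrity
    aln = align_spliced(trim.flanked_segment, refset.integrated_locus,
                        config.scoring)
    nick = refset.nick_site
    insert_iv = (nick, nick + refset.insert_len)
    runs = [r for r in consecutive_gap_runs(aln, config.max_gap_run_full_length + 1)
            if r[0] < insert_iv[1] and r[0] + r[1] > insert_iv[0]]
    max_run = max((r[1] for r in runs), default=0)

    n_tg, n_utr = len(tg_hits), len(utr_hits)
    sole_tg = tg_hits[0] if n_tg == 1 else None
    reaches_5p = any(h.feature_start < config.transgene_5p_bound for h in tg_hits)

    def result(cat):
        return ReadClassification(
            read_id, "inserted", category=cat,
            n_transgene_features=n_tg, n_utr_features=n_utr,
            max_gap_run=max_run, aligns_to_transgene_5p=reaches_5p,
            trimmed_interval=trim.trimmed_interval,
        )

    # precedence: full_length -> jump -> five_prime_truncation -> other
    if n_tg == 1 and n_utr == 1 and max_run <= config.max_gap_run_full_length:
        return result("full_length")
    if _disjoint_projections(tg_hits) or _disjoint_projections(utr_hits):
        return result("jump")
    if sole_tg is not None and sole_tg.feature_start < config.transgene_5p_bound:
        return result("jump")
    if (n_tg == 1 and n_utr == 1 and max_run > config.max_gap_run_full_length
            and not reaches_5p):
        return result("five_prime_truncation")
    return result("other")


def _disjoint_projections(hits: list[FeatureHit], overlap_tol: int = 10) -> bool:
    """True if some pair of hits has non-overlapping feature projections.

    Local-alignment boundaries jitter by a few bases (chance matches extend
    a hit past its true edge), so overlaps up to ``overlap_tol`` bases still
    count as disjoint; true duplications/snap-backs overlap by far more.
    """
    for i, a in enumerate(hits):
        for b in hits[i + 1:]:
            overlap = (min(a.feature_end, b.feature_end)
                       - max(a.feature_start, b.feature_start))
            if overlap <= overlap_tol:
                return True
    return False


def _find_site_matches(read_codes: np.ndarray, pattern: str, max_mismatch: int) -> np.ndarray:
    """Start positions where ``pattern`` occurs with <= max_mismatch
    substitutions (no gaps)."""
    p = encode(pattern)
    if read_codes.size < p.size:
        return np.empty(0, dtype=int)
    windows = np.lib.stride_tricks.sliding_window_view(read_codes, p.size)
    mism = (windows != p).sum(axis=1)
    return np.flatnonzero(mism <= max_mismatch)


def ddpcr_detectable(read: str, donor: DonorSpec, max_mismatch: int = 2) -> bool:
    """True if the read contains the ddPCR probe site flanked by convergent
    primer sites on one strand, each within ``max_mismatch`` substitutions."""
    for seq in (read, revcomp(read)):
        codes = encode(seq)
        fwd = _find_site_matches(codes, donor.ddpcr_fwd_primer, max_mismatch)
        if fwd.size == 0:
            continue
        probe = _find_site_matches(codes, donor.ddpcr_probe, max_mismatch)
        if probe.size == 0:
            continue
        rev = _find_site_matches(codes, revcomp(donor.ddpcr_rev_primer), max_mismatch)
        if rev.size == 0:
            continue
        flen, plen = len(donor.ddpcr_fwd_primer), len(donor.ddpcr_probe)
        for p in probe:
            if (fwd + flen <= p).any() and (rev >= p + plen).any():
                return True
    return False


def count_ddpcr_detectable(
    reads: Sequence[SimulatedRead | str],
    donor: DonorSpec,
    max_mismatch: int = 2,
) -> int:
    seqs = (r.sequence if isinstance(r, SimulatedRead) else r for r in reads)
    return sum(ddpcr_detectable(s, donor, max_mismatch) for s in seqs)


@dataclass(frozen=True)
class ClassReport:
    counts: dict[str, int]  # keys: rejected, uninserted, and each category
    fractions: Optional[dict[str, float]]  # over inserted reads; None if none
    n_ddpcr_detectable: int

    @property
    def n_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def n_inserted(self) -> int:
        return sum(self.counts.get(c, 0) for c in CATEGORIES)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key, n in self.counts.items():
            frac = self.fractions.get(key) if self.fractions else None
            rows.append({"class": key, "count": n, "fraction_of_inserted": frac})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "fractions_of_inserted": self.fractions,
            "n_ddpcr_detectable": self.n_ddpcr_detectable,
        }


def aggregate(
    classifications: Sequence[ReadClassification],
    n_ddpcr: int = 0,
) -> ClassReport:
    """Aggregate per-read classifications into a class report.

    Fractions of completed integrations are computed over inserted reads
    only and are None (undefined) when there are no inserted reads.
    """
    counts = {"rejected": 0, "uninserted": 0}
    counts.update({c: 0 for c in CATEGORIES})
    for c in classifications:
        key = c.category if c.status == "inserted" else c.status
        counts[key] += 1
    n_ins = sum(counts[c] for c in CATEGORIES)
    fractions = None
    if n_ins > 0:
        fractions = {c: counts[c] / n_ins for c in CATEGORIES}
    return ClassReport(counts, fractions, n_ddpcr)


def classify_reads(
    reads: Sequence[SimulatedRead],
    refset: ReferenceSet,
    config: ClassifierConfig | None = None,
    count_ddpcr: bool = True,
) -> tuple[list[ReadClassification], ClassReport]:
    """Run the full per-read pipeline and aggregate."""
    config = config or ClassifierConfig()
    results = [classify_read(r, refset, config) for r in reads]
    n_ddpcr = count_ddpcr_detectable(reads, refset.donor) if count_ddpcr else 0
    return results, aggregate(results, n_ddpcr)


def classifications_frame(results: Sequence[ReadClassification]) -> pd.DataFrame:
    """Per-read table (one row per read, evidence columns included)."""
    return pd.DataFrame([{
        "read_id": r.read_id,
        "status": r.status,
        "category": r.category,
        "reason": r.reason,
        "n_transgene_features": r.n_transgene_features,
        "n_utr_features": r.n_utr_features,
        "max_gap_run": r.max_gap_run,
        "aligns_to_transgene_5p": r.aligns_to_transgene_5p,
        "trimmed_start": r.trimmed_interval[0] if r.trimmed_interval else None,
        "trimmed_end": r.trimmed_interval[1] if r.trimmed_interval else None,
    } for r in results])
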