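"""Insertion-site specificity analysis from UTR-anchored read pairs.

The assay reads from the donor 3' UTR into flanking genomic DNA, so read 1
of every informative pair starts with the UTR tail.  The pipeline:

1. anchor extraction — keep pairs whose read 1 begins with the UTR tail
   (bounded error rate, indels allowed) and trim it off;
2. two-tier mapping — fragments are first mapped to the 28S reference
   (on-target); the remainder is mapped to the genome with a convergent
   mate check, and each distinct junction coordinate becomes a site;
3. window classification — a site whose 120-bp window matches the
   wild-type 28S at >= 108 positions (maximum over all ungapped offsets,
   both strands) is pseudo-28S on-target, otherwise off-target;
4. read-weighted logo — off-target flanks, oriented by insertion strand,
   accumulate into a position-frequency matrix weighted by read count;
5. junction base frequencies — amplicon-anchored quantification with
   homology and phred-quality filters.

Fragment mapping uses edlib (bounded edit distance, infix mode); the
window-identity maximization is an exhaustive ungapped scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import numpy as np
import pandas as pd

from .align import Scoring, align_local
from .refsim import SimulatedRead
from .sequence import BASES, encode, revcomp

#: printed 59-nt junction amplicon (donor 3' UTR tail | 28S downstream flank)
#: and the guide-style sequence whose 3' end marks the junction, as used for
#: the human-cell junction quantification
JUNCTION_AMPLICON = "GGAACATATATAATTTATGTGTGTTCGATAAATAGCCAAATGCCTCGTCATCTAATTAG"
JUNCTION_GUIDE = "TTATGTGTGTTCGATAAA"

SITE_CLASSES = ("on_28S", "pseudo_28S_on", "off_target")


@dataclass
class InsertionSite:
    coord: int  # insertion junction on the genome, 0-based
    strand: str
    read_count: int
    site_class: Optional[str] = None
    window_matches: Optional[int] = None
    partial_window: bool = False


@dataclass(frozen=True)
class MapTally:
    """Read-pair bookkeeping; all rejected pairs are counted, not dropped."""

    n_pairs: int
    n_anchor_rejected: int
    n_on_28s: int
    n_genome_mapped: int
    n_unmapped: int
    n_improper_pair: int
    n_ambiguous: int

    def conserved(self) -> bool:
        return (self.n_anchor_rejected + self.n_on_28s + self.n_genome_mapped
                + self.n_unmapped + self.n_improper_pair + self.n_ambiguous
                ) == self.n_pairs


def extract_utr_anchored(
    read1: str,
    utr_tail: str,
    max_error_rate: float = 0.1,
) -> Optional[str]:
    """Trim the UTR tail off read 1; None if the read does not start with it.

    The tail must align to a prefix of read 1 within
    ``ceil(max_error_rate * len(utr_tail))`` edits (mismatches or indels).
    """
    if not utr_tail:
        raise ValueError("utr_tail must be non-empty")
    k = math.ceil(max_error_rate * len(utr_tail))
    res = edlib.align(utr_tail, read1, mode="SHW", task="locations", k=k)
    if res["editDistance"] < 0:
        return None
    end = res["locations"][0][1] + 1
    return read1[end:]


def _edlib_best(query: str, target: str, k: int):
    """Best infix alignment location(s) of query in target within k edits."""
    res = edlib.align(query, target, mode="HW", task="locations", k=k)
    if res["editDistance"] < 0:
        return None, []
    return res["editDistance"], res["locations"]


def map_sites(
    fragments: Sequence[tuple[str, str]],
    wt_28s: str,
    genome: str,
    genome_28s_offset: Optional[int] = None,
    max_divergence_28s: float = 0.05,
    max_divergence_genome: float = 0.12,
    max_fragment_span: int = 600,
) -> tuple[list[InsertionSite], MapTally]:
    """Two-tier mapping of UTR-trimmed fragments (with mates) to sites.

    ``fragments`` holds ``(fragment, mate)`` pairs that already passed
    anchor extraction.  Tier 1 maps the fragment to the 28S reference; hits
    are tallied as on-target sites (placed on the genome when
    ``genome_28s_offset`` is known).  Tier 2 maps the remainder to the
    genome, requires the mate to map convergently within
    ``max_fragment_span``, and keys sites by (junction coordinate, strand).
    Ambiguous (tied) placements and improper pairs are counted, never
    silently dropped.
    """
    counts: dict[tuple[int, str, str], int] = {}
    n_on = n_gen = n_unmapped = n_improper = n_ambig = 0
    for frag, mate in fragments:
        if not frag:
            n_unmapped += 1
            continue
        k1 = int(max_divergence_28s * len(frag))
        hit = None
        for strand, seq in (("+", frag), ("-", revcomp(frag))):
            d, locs = _edlib_best(seq, wt_28s, k1)
            if d is None:
                continue
            if hit is None or d < hit[0]:
                hit = (d, strand, locs)
            elif d == hit[0]:
                hit = (d, hit[1], hit[2] + locs) if strand != hit[1] else hit
        if hit is not None:
            d, strand, locs = hit
            starts = sorted({loc[0] for loc in locs})
            ends = sorted({loc[1] + 1 for loc in locs})
            if len(starts) > 1 or len(ends) > 1:
                n_ambig += 1
                continue
            pos = starts[0] if strand == "+" else ends[0]
            coord = pos + (genome_28s_offset or 0)
            counts[(coord, strand, "on_28S")] = counts.get((coord, strand, "on_28S"), 0) + 1
            n_on += 1
            continue
        # tier 2: genome, both strands, unique best placement required
        k2 = int(max_divergence_genome * len(frag))
        best = None
        ambiguous = False
        for strand, seq in (("+", frag), ("-", revcomp(frag))):
            d, locs = _edlib_best(seq, genome, k2)
            if d is None:
                continue
            spans = sorted({(loc[0], loc[1] + 1) for loc in locs})
            if best is None or d < best[0]:
                best = (d, strand, spans)
                ambiguous = len(spans) > 1
            elif d == best[0]:
                ambiguous = True
        if best is None:
            n_unmapped += 1
            continue
        if ambiguous:
            n_ambig += 1
            continue
        d, strand, [(start, end)] = best
        if not _mate_proper(mate, genome, strand, start, end, max_fragment_span,
                            max_divergence_genome):
            n_improper += 1
            continue
        coord = start if strand == "+" else end
        counts[(coord, strand, None)] = counts.get((coord, strand, None), 0) + 1
        n_gen += 1
    sites = [
        InsertionSite(coord, strand, n, site_class=cls)
        for (coord, strand, cls), n in sorted(counts.items(),
                                              key=lambda kv: (kv[0][0], kv[0][1]))
    ]
    tally = MapTally(
        n_pairs=len(fragments), n_anchor_rejected=0,
        n_on_28s=n_on, n_genome_mapped=n_gen, n_unmapped=n_unmapped,
        n_improper_pair=n_improper, n_ambiguous=n_ambig,
    )
    return sites, tally


def _mate_proper(mate, genome, strand, start, end, max_span, max_div) -> bool:
    """Mate must map on the opposite strand, facing the fragment, nearby."""
    if not mate:
        return False
    k = max(2, int(max_div * len(mate)))
    probe = revcomp(mate) if strand == "+" else mate
    if strand == "+":
        lo, hi = start, min(len(genome), start + max_span)
    else:
        lo, hi = max(0, end - max_span), end
    d, locs = _edlib_best(probe, genome[lo:hi], k)
    return d is not None


def window_matches_scan(window: str, wt_28s: str) -> int:
    """Maximum ungapped matches of ``window`` against any offset of the
    wild-type 28S sequence, on either strand."""
    best = 0
    warr = encode(wt_28s)
    for seq in (window, revcomp(window)):
        q = encode(seq)
        if q.size > warr.size:
            continue
        sw = np.lib.stride_tricks.sliding_window_view(warr, q.size)
        best = max(best, int((sw == q).sum(axis=1).max()))
    return best


def classify_site(
    site: InsertionSite,
    genome: str,
    wt_28s: str,
    window: int = 120,
    min_matches: int = 108,
    locus_interval: Optional[tuple[int, int]] = None,
) -> InsertionSite:
    """Assign pseudo-28S / off-target by window identity (in place).

    The window is centred on the insertion coordinate; at genome ends the
    available bases are used and the site flagged partial.  Sites falling
    inside ``locus_interval`` (the annotated 28S locus) and sites already
    tier-1 mapped keep the on-target class.
    """
    if window % 2:
        raise ValueError("window must be even")
    if site.site_class == "on_28S":
        site.window_matches = window
        return site
    if locus_interval and locus_interval[0] <= site.coord < locus_interval[1]:
        site.site_class = "on_28S"
        site.window_matches = window
        return site
    half = window // 2
    lo, hi = site.coord - half, site.coord + half
    partial = lo < 0 or hi > len(genome)
    win = genome[max(0, lo):min(len(genome), hi)]
    matches = window_matches_scan(win, wt_28s)
    site.window_matches = matches
    site.partial_window = partial
    site.site_class = "pseudo_28S_on" if matches >= min_matches else "off_target"
    return site


def classify_sites(sites, genome, wt_28s, window=120, min_matches=108,
                   locus_interval=None) -> list[InsertionSite]:
    return [classify_site(s, genome, wt_28s, window, min_matches, locus_interval)
            for s in sites]


@dataclass(frozen=True)
class WeightedLogo:
    positions: tuple[int, ...]  # relative to the insertion site, upstream < 0
    matrix: pd.DataFrame  # index positions, columns A/C/G/T, rows sum to 1
    total_weight: int
    counts: pd.DataFrame

    def weight(self, position: int, base: str) -> float:
        return float(self.matrix.loc[position, base])


def build_weighted_logo(
    sites: Sequence[InsertionSite],
    genome: str,
    logo_range: tuple[int, int] = (-30, 7),
) -> WeightedLogo:
    """Read-count-weighted position-frequency matrix of off-target flanks.

    Position 0 is the first base downstream of the junction in insertion
    orientation; upstream positions are negative.  The default range
    [-30, +7) covers the upstream recognition region (including -20) and
    the downstream 3'-homology match.
    """
    if not sites:
        raise ValueError("cannot build a logo from an empty site list")
    lo, hi = logo_range
    positions = tuple(range(lo, hi))
    counts = np.zeros((len(positions), 4), dtype=float)
    total = 0
    for site in sites:
        oriented = _oriented_flank(site, genome, lo, hi)
        if oriented is None:
            continue
        codes = encode(oriented)
        total += site.read_count
        counts[np.arange(len(positions)), codes] += site.read_count
    if total == 0:
        raise ValueError("no site had a complete window inside the genome")
    freq = counts / counts.sum(axis=1, keepdims=True)
    matrix = pd.DataFrame(freq, index=list(positions), columns=list(BASES))
    cdf = pd.DataFrame(counts, index=list(positions), columns=list(BASES))
    return WeightedLogo(positions, matrix, total, cdf)


def _oriented_flank(site: InsertionSite, genome: str, lo: int, hi: int) -> Optional[str]:
    """Genomic bases at positions [lo, hi) relative to the junction, read in
    insertion orientation."""
    if site.strand == "+":
        a, b = site.coord + lo, site.coord + hi
        if a < 0 or b > len(genome):
            return None
        return genome[a:b]
    a, b = site.coord - hi, site.coord - lo
    if a < 0 or b > len(genome):
        return None
    return revcomp(genome[a:b])


@dataclass(frozen=True)
class JunctionProfile:
    amplicon: str
    window_positions: tuple[int, ...]
    frequencies: Optional[pd.DataFrame]  # index positions, columns A/C/G/T/-
    n_reads_passing: int


def junction_frequencies(
    reads: Sequence[SimulatedRead | tuple[str, str]],
    amplicon: str,
    junction_pos: Optional[int] = None,
    guide: Optional[str] = None,
    window: int = 5,
    min_homology: float = 0.6,
    min_q: int = 20,
    scoring: Scoring | None = None,
) -> JunctionProfile:
    """Per-position base frequencies in a window centred on the junction.

    Reads are excluded when their mean phred quality or any single base
    quality is below ``min_q``, or when their alignment homology to the
    amplicon (matches / amplicon length) is below ``min_homology``.
    ``junction_pos`` is the amplicon coordinate of the first base after the
    junction; when omitted it is derived from the 3' end of ``guide``.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if junction_pos is None:
        if guide is None:
            raise ValueError("provide junction_pos or guide")
        idx = amplicon.find(guide)
        if idx < 0:
            raise ValueError("guide not found in amplicon")
        junction_pos = idx + len(guide)
    if not 0 <= junction_pos < len(amplicon):
        raise ValueError("junction_pos outside amplicon")
    half = window // 2
    w_pos = tuple(junction_pos + d for d in range(-half, half + 1))
    if w_pos[0] < 0 or w_pos[-1] >= len(amplicon):
        raise ValueError("quantification window extends beyond amplicon")
    scoring = scoring or Scoring()
    alphabet = list(BASES) + ["-"]
    counts = np.zeros((window, len(alphabet)), dtype=float)
    n_pass = 0
    for read in reads:
        if isinstance(read, SimulatedRead):
            seq, qual = read.sequence, read.qualities
        else:
            seq, qual = read
        phred = [ord(c) - 33 for c in qual]
        if not phred or min(phred) < min_q or sum(phred) / len(phred) < min_q:
            continue
        aln = align_local(seq, amplicon, scoring)
        if aln is None or aln.n_matches / len(amplicon) < min_homology:
            continue
        bases = _bases_at(aln, seq, w_pos)
        if bases is None:
            continue
        n_pass += 1
        for i, b in enumerate(bases):
            counts[i, alphabet.index(b)] += 1
    if n_pass == 0:
        return JunctionProfile(amplicon, w_pos, None, 0)
    freq = counts / counts.sum(axis=1, keepdims=True)
    df = pd.DataFrame(freq, index=list(w_pos), columns=alphabet)
    return JunctionProfile(amplicon, w_pos, df, n_pass)


def _bases_at(aln, seq: str, ref_positions) -> Optional[list[str]]:
    """Read base aligned to each reference position; '-' for deletions,
    None if any position is outside the aligned reference interval."""
    wanted = set(ref_positions)
    found: dict[int, str] = {}
    q, r = aln.query_start, aln.ref_start
    for op in aln.ops:
        if op.op in ("M", "X"):
            for t in range(op.length):
                if r + t in wanted:
                    found[r + t] = seq[q + t]
            q += op.length
            r += op.length
        elif op.op == "I":
            q += op.length
        else:
            for t in range(op.length):
                if r + t in wanted:
                    found[r + t] = "-"
            r += op.length
    if any(p not in found for p in ref_positions):
        return None
    return [found[p] for p in ref_positions]


def specificity_summary(
    sites: Sequence[InsertionSite],
    tally: Optional[MapTally] = None,
) -> dict:
    """Read-weighted on/off-target summary over classified sites.

    ``on_fraction`` counts on_28S plus pseudo-28S reads over all site
    reads; when a tally is given, ``on_fraction_of_pairs`` uses all input
    pairs (including anchor-rejected/unmapped) as the denominator.
    """
    on = sum(s.read_count for s in sites
             if s.site_class in ("on_28S", "pseudo_28S_on"))
    off = sum(s.read_count for s in sites if s.site_class == "off_target")
    total = on + off
    off_loci = [s for s in sites if s.site_class == "off_target"]
    out = {
        "n_reads": total,
        "on_reads": on,
        "off_reads": off,
        "on_fraction": on / total if total else float("nan"),
        "off_fraction": off / total if total else float("nan"),
        "n_off_loci": len(off_loci),
        "n_off_loci_gt10": sum(1 for s in off_loci if s.read_count > 10),
    }
    if tally is not None:
        out["n_pairs"] = tally.n_pairs
        out["on_fraction_of_pairs"] = on / tally.n_pairs if tally.n_pairs else float("nan")
    return out


def sites_frame(sites: Sequence[InsertionSite]) -> pd.DataFrame:
    """BED-like site table (start = junction coordinate)."""
    return pd.DataFrame([{
        "start": s.coord,
        "end": s.coord + 1,
        "strand": s.strand,
        "read_count": s.read_count,
        "site_class": s.site_class,
        "window_matches": s.window_matches,
        "partial_window": s.partial_window,
    } for s in sites])


def run_ttiss(
    pairs: Sequence[tuple[SimulatedRead, SimulatedRead]],
    utr_tail: str,
    wt_28s: str,
    genome: str,
    genome_28s_offset: Optional[int] = None,
    locus_interval: Optional[tuple[int, int]] = None,
    max_error_rate: float = 0.1,
    window: int = 120,
    min_matches: int = 108,
) -> tuple[list[InsertionSite], MapTally, dict]:
    """Anchor, map, classify and summarize a TTISS experiment."""
    fragments = []
    n_rej = 0
    for r1, r2 in pairs:
        frag = extract_utr_anchored(r1.sequence, utr_tail, max_error_rate)
        if frag is None:
            n_rej += 1
            continue
        fragments.append((frag, r2.sequence))
    sites, tally = map_sites(fragments, wt_28s, genome, genome_28s_offset)
    tally = MapTally(
        n_pairs=len(pairs), n_anchor_rejected=n_rej,
        n_on_28s=tally.n_on_28s, n_genome_mapped=tally.n_genome_mapped,
        n_unmapped=tally.n_unmapped, n_improper_pair=tally.n_improper_pair,
        n_ambiguous=tally.n_ambiguous,
    )
    sites = classify_sites(sites, genome, wt_28s, window, min_matches,
                           locus_interval)
    return sites, tally, specificity_summary(sites, tally)
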