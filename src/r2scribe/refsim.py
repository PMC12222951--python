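"""Seeded synthetic data: references, integration alleles, long reads, and
tagmentation-based integration-site (TTISS-like) read pairs with known truth.

The generator emulates the read structure of an R2 retrotransposon
transgene-insertion experiment on a toy 28S locus:

* a wild-type locus with a first-strand nick site and the six named flank /
  insert features used for read annotation;
* integration alleles for every outcome class (full-length, 5'-truncated,
  jumped/rearranged, snap-back, uninserted);
* nanopore-like long reads spanning the insertion point under a
  substitution/indel error model that includes occasional multi-base
  deletions;
* TTISS read pairs whose read 1 starts with the donor 3' UTR tail followed
  by genomic flank, drawn from a site plan with planted on-target,
  pseudo-28S (>= 108/120 window matches) and off-target loci carrying the
  insertion motif (3'-homology match downstream, T at position -20).

Everything is a pure function of its inputs and seed.  Coordinates are
0-based half-open; strands are '+'/'-'.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .sequence import random_seq, revcomp

FEATURE_NAMES = ("5end_400nt", "5end_200nt", "transgene", "3utr",
                 "3end_200nt", "3end_400nt")

OUTCOME_CATEGORIES = ("uninserted", "full_length", "five_prime_truncation",
                      "jump_multi", "jump_5p", "other_snapback")

#: truth category -> category the read classifier is expected to assign
EXPECTED_CLASS = {
    "uninserted": "uninserted",
    "full_length": "full_length",
    "five_prime_truncation": "five_prime_truncation",
    "jump_multi": "jump",
    "jump_5p": "jump",
    "other_snapback": "other",
}


@dataclass(frozen=True)
class DonorSpec:
    """Donor RNA layout (DNA sense) plus the ddPCR assay oligos.

    ``homology_5p`` matches the locus immediately upstream of the nick and
    ``homology_3p`` the bases immediately downstream; on perfect integration
    both merge into the locus, so the integrated scar is transgene + 3' UTR.
    """

    homology_5p: str
    transgene: str
    utr3: str
    homology_3p: str
    ddpcr_probe: str
    ddpcr_fwd_primer: str
    ddpcr_rev_primer: str

    @property
    def insert(self) -> str:
        """Sequence added to the locus by a perfect full-length integration."""
        return self.transgene + self.utr3


@dataclass(frozen=True)
class ReferenceSet:
    wt_locus: str
    nick_site: int
    donor: DonorSpec
    integrated_locus: str
    feature_library: dict[str, str]

    @property
    def insert_len(self) -> int:
        return len(self.donor.insert)

    def validate(self) -> None:
        nick = self.nick_site
        wt = self.wt_locus
        lib = self.feature_library
        assert lib["5end_400nt"] == wt[nick - 400:nick - 200]
        assert lib["5end_200nt"] == wt[nick - 200:nick]
        assert lib["3end_200nt"] == wt[nick:nick + 200]
        assert lib["3end_400nt"] == wt[nick + 200:nick + 400]
        assert lib["transgene"] == self.donor.transgene
        assert lib["3utr"] == self.donor.utr3
        assert self.integrated_locus == wt[:nick] + self.donor.insert + wt[nick:]
        assert self.donor.homology_5p == wt[nick - len(self.donor.homology_5p):nick]
        assert self.donor.homology_3p == wt[nick:nick + len(self.donor.homology_3p)]


@dataclass(frozen=True)
class OutcomeSpec:
    """Ground-truth integration outcome used to build an allele.

    ``jump_segments`` lists (feature, (start, end), orientation) pieces that
    replace the perfect insert for jump / snap-back outcomes; the caller
    includes the 3' UTR segment explicitly.
    """

    category: str
    truncation_point: Optional[int] = None
    jump_segments: Optional[tuple[tuple[str, tuple[int, int], str], ...]] = None

    def __post_init__(self):
        if self.category not in OUTCOME_CATEGORIES:
            raise ValueError(f"unknown outcome category {self.category!r}")
        needs_trunc = self.category == "five_prime_truncation"
        if needs_trunc != (self.truncation_point is not None):
            raise ValueError("truncation_point present iff five_prime_truncation")
        needs_seg = self.category.startswith("jump") or self.category == "other_snapback"
        if needs_seg != (self.jump_segments is not None):
            raise ValueError("jump_segments present iff jump/snap-back category")


@dataclass(frozen=True)
class ErrorModel:
    """Per-base substitution/indel error model with occasional long deletions.

    ``long_del_rate`` is the per-read probability of one deletion whose
    length is drawn uniformly from ``long_del_range``; these are what the
    >=4-consecutive-D/N classification rule has to tolerate or flag.
    """

    sub_rate: float = 0.02
    ins_rate: float = 0.01
    del_rate: float = 0.01
    long_del_rate: float = 0.1
    long_del_range: tuple[int, int] = (10, 100)
    seed: int = 0

    def __post_init__(self):
        for name in ("sub_rate", "ins_rate", "del_rate", "long_del_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


ZERO_ERROR = ErrorModel(0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    qualities: str
    truth: Optional[OutcomeSpec] = None
    truth_site: Optional[int] = None

    def __post_init__(self):
        if len(self.qualities) != len(self.sequence):
            raise ValueError("qualities and sequence lengths differ")


@dataclass(frozen=True)
class SiteEntry:
    coord: int
    strand: str
    site_class: str  # on_28S | pseudo_28S | off_target
    planted_identity: int  # matches per 120-bp window against wild-type 28S
    read_count: int


@dataclass(frozen=True)
class SitePlan:
    entries: tuple[SiteEntry, ...]

    def __post_init__(self):
        for e in self.entries:
            if e.site_class == "pseudo_28S" and e.planted_identity < 108:
                raise ValueError("pseudo_28S entries require planted_identity >= 108")
            if e.site_class == "off_target" and e.planted_identity >= 108:
                raise ValueError("off_target entries require planted_identity < 108")

    @property
    def total_reads(self) -> int:
        return sum(e.read_count for e in self.entries)


def make_reference_set(
    locus_len: int = 4000,
    nick_site: int = 2000,
    transgene_len: int = 720,
    utr3_len: int = 100,
    homology_5p_len: int = 36,
    homology_3p_len: int = 5,
    seed: int = 0,
) -> ReferenceSet:
    """Build a toy wild-type locus, donor, and integrated reference.

    The nick site must sit at least 400 nt from both locus ends so that all
    four flank features exist.
    """
    if nick_site < 400:
        raise ValueError(f"nick_site must be >= 400 (got {nick_site})")
    if nick_site > locus_len - 400:
        raise ValueError(
            f"nick_site must be <= locus_len - 400 (got {nick_site} of {locus_len})"
        )
    rng = np.random.default_rng(seed)
    wt = random_seq(locus_len, rng)
    transgene = random_seq(transgene_len, rng)
    utr3 = random_seq(utr3_len, rng)
    nick = nick_site
    integrated = wt[:nick] + transgene + utr3 + wt[nick:]
    # ddPCR 5' junction assay: forward primer upstream of the nick, probe
    # spanning the junction, reverse primer inside the transgene 5' region.
    fwd = integrated[nick - 120:nick - 98]
    probe = integrated[nick - 12:nick + 12]
    rev = revcomp(integrated[nick + 60:nick + 82])
    donor = DonorSpec(
        homology_5p=wt[nick - homology_5p_len:nick],
        transgene=transgene,
        utr3=utr3,
        homology_3p=wt[nick:nick + homology_3p_len],
        ddpcr_probe=probe,
        ddpcr_fwd_primer=fwd,
        ddpcr_rev_primer=rev,
    )
    lib = {
        "5end_400nt": wt[nick - 400:nick - 200],
        "5end_200nt": wt[nick - 200:nick],
        "transgene": transgene,
        "3utr": utr3,
        "3end_200nt": wt[nick:nick + 200],
        "3end_400nt": wt[nick + 200:nick + 400],
    }
    refset = ReferenceSet(wt, nick, donor, integrated, lib)
    refset.validate()
    return refset


def build_allele(refset: ReferenceSet, outcome: OutcomeSpec) -> str:
    """Construct the genomic allele sequence for an integration outcome."""
    wt, nick = refset.wt_locus, refset.nick_site
    donor = refset.donor
    cat = outcome.category
    if cat == "uninserted":
        return wt
    if cat == "full_length":
        return refset.integrated_locus
    if cat == "five_prime_truncation":
        t = outcome.truncation_point
        if not 0 <= t <= len(donor.transgene):
            raise ValueError(
                f"truncation_point {t} outside transgene [0, {len(donor.transgene)}]"
            )
        return wt[:nick] + donor.transgene[t:] + donor.utr3 + wt[nick:]
    # jump_multi / jump_5p / other_snapback: insert assembled from segments
    pieces = []
    for feature, (start, end), orient in outcome.jump_segments:
        src = {"transgene": donor.transgene, "3utr": donor.utr3}[feature]
        if not 0 <= start < end <= len(src):
            raise ValueError(f"segment ({start}, {end}) outside {feature}")
        seg = src[start:end]
        pieces.append(seg if orient == "+" else revcomp(seg))
    return wt[:nick] + "".join(pieces) + wt[nick:]


def default_outcome_panel(refset: ReferenceSet,
                          truncation_points: Sequence[int] = (50, 200, 350, 500, 650),
                          ) -> list[OutcomeSpec]:
    """The standard outcome panel exercised by the long-read pipeline tests.

    Covers uninserted, full-length, five 5'-truncation depths, a rearranged
    multi-segment jump, a 5'-anchored jump (internal deletion that keeps the
    transgene 5' end), and an inverted-duplication snap-back.
    """
    L = len(refset.donor.transgene)
    ulen = len(refset.donor.utr3)
    utr_seg = ("3utr", (0, ulen), "+")
    panel = [
        OutcomeSpec("uninserted"),
        OutcomeSpec("full_length"),
    ]
    for t in truncation_points:
        panel.append(OutcomeSpec("five_prime_truncation", truncation_point=t))
    panel.append(OutcomeSpec("jump_multi", jump_segments=(
        ("transgene", (300, L), "+"), ("transgene", (0, 300), "+"), utr_seg)))
    panel.append(OutcomeSpec("jump_5p", jump_segments=(
        ("transgene", (0, 250), "+"), ("transgene", (450, L), "+"), utr_seg)))
    panel.append(OutcomeSpec("other_snapback", jump_segments=(
        ("transgene", (0, L), "+"), ("transgene", (L - 300, L), "-"), utr_seg)))
    return panel


def _insert_len(refset: ReferenceSet, outcome: OutcomeSpec) -> int:
    return len(build_allele(refset, outcome)) - len(refset.wt_locus)


def apply_errors(seq: str, error_model: ErrorModel, rng: np.random.Generator) -> str:
    """Apply the error model to one read; returns the corrupted sequence."""
    em = error_model
    out = list(seq)
    # one optional long deletion, placed away from the read ends
    if em.long_del_rate > 0 and rng.random() < em.long_del_rate:
        lo, hi = em.long_del_range
        dlen = int(rng.integers(lo, hi + 1))
        if len(out) > dlen + 100:
            start = int(rng.integers(50, len(out) - dlen - 50))
            del out[start:start + dlen]
    if em.sub_rate == em.ins_rate == em.del_rate == 0.0:
        return "".join(out)
    bases = "ACGT"
    res: list[str] = []
    n = len(out)
    draws = rng.random(n)
    for i, b in enumerate(out):
        p = draws[i]
        if p < em.del_rate:
            continue
        if p < em.del_rate + em.sub_rate:
            res.append(bases[(bases.index(b) + int(rng.integers(1, 4))) % 4])
        else:
            res.append(b)
        if rng.random() < em.ins_rate:
            res.append(bases[int(rng.integers(0, 4))])
    return "".join(res)


def simulate_long_reads(
    alleles: Sequence[tuple[str, OutcomeSpec]],
    n_per_allele: int,
    error_model: ErrorModel = ErrorModel(),
    nick_site: int = 2000,
    wt_len: int = 4000,
    flank_span: tuple[int, int] = (500, 800),
    rc_prob: float = 0.5,
    phred: int = 30,
) -> list[SimulatedRead]:
    """Simulate nanopore-like reads spanning the insertion point.

    Every allele is wt[:nick] + insert + wt[nick:], so the insert length is
    len(allele) - wt_len.  Each read covers the whole insert plus
    ``flank_span`` (uniform) locus flank on both sides, so all four flank
    features are recoverable.  A fraction ``rc_prob`` of reads is emitted
    reverse-complemented.  Deterministic for a given ``error_model.seed``.
    """
    if n_per_allele < 1:
        raise ValueError("n_per_allele must be >= 1")
    if not alleles:
        raise ValueError("alleles must be non-empty")
    lo, hi = flank_span
    if not 0 < lo <= hi:
        raise ValueError("flank_span must satisfy 0 < lo <= hi")
    if nick_site < hi:
        raise ValueError("flank_span exceeds upstream locus margin")
    rng = np.random.default_rng(error_model.seed)
    qchar = chr(phred + 33)
    reads = []
    k = 0
    for allele, outcome in alleles:
        ins_len = len(allele) - wt_len
        if ins_len < 0:
            raise ValueError("allele shorter than wild-type locus")
        if nick_site + ins_len + hi > len(allele):
            raise ValueError("flank_span exceeds downstream locus margin")
        for _ in range(n_per_allele):
            left = int(rng.integers(lo, hi + 1))
            right = int(rng.integers(lo, hi + 1))
            frag = allele[nick_site - left:nick_site + ins_len + right]
            frag = apply_errors(frag, error_model, rng)
            if rng.random() < rc_prob:
                frag = revcomp(frag)
            reads.append(SimulatedRead(
                read_id=f"read{k:05d}_{outcome.category}",
                sequence=frag,
                qualities=qchar * len(frag),
                truth=outcome,
            ))
            k += 1
    return reads


def simulate_panel_reads(
    refset: ReferenceSet,
    outcomes: Sequence[OutcomeSpec],
    n_per_allele: int,
    error_model: ErrorModel = ErrorModel(),
    flank_span: tuple[int, int] = (500, 800),
    rc_prob: float = 0.5,
    phred: int = 30,
) -> list[SimulatedRead]:
    """Build alleles for ``outcomes`` and simulate reads over the panel."""
    alleles = [(build_allele(refset, oc), oc) for oc in outcomes]
    return simulate_long_reads(
        alleles, n_per_allele, error_model,
        nick_site=refset.nick_site, wt_len=len(refset.wt_locus),
        flank_span=flank_span, rc_prob=rc_prob, phred=phred,
    )


def make_toy_genome(
    refset: ReferenceSet,
    n_pseudo: int = 3,
    identities: Sequence[int] = (114, 111, 108),
    n_off: int = 240,
    background_len: int = 40000,
    t_minus20_prob: float = 0.9,
    off_read_count_p: float = 0.35,
    on_read_count: int = 2400,
    pseudo_read_count_range: tuple[int, int] = (20, 60),
    minus_strand_frac: float = 0.1,
    seed: int = 0,
) -> tuple[str, SitePlan]:
    """Toy genome with one exact 28S locus, degenerate pseudo-28S copies and
    off-target insertion sites carrying the downstream-homology / T(-20)
    motif; the returned plan records the ground truth.

    ``identities`` gives the number of matching bases per 120-bp window for
    each planted degenerate copy (>= 108 makes it pseudo-28S, below that it
    is a 28S-like off-target).  Motif off-targets land in random background
    with the donor's 3' homology planted immediately downstream of the
    junction and a T at -20 with probability ``t_minus20_prob``.
    """
    if len(identities) != n_pseudo:
        raise ValueError("identities must have n_pseudo entries")
    for ident in identities:
        if not 0 <= ident <= 120:
            raise ValueError(f"window identity {ident} outside [0, 120]")
    rng = np.random.default_rng(seed)
    genome = list(random_seq(background_len, rng))
    wt, nick = refset.wt_locus, refset.nick_site

    def plant(pos: int, seq: str):
        genome[pos:pos + len(seq)] = list(seq)

    entries: list[SiteEntry] = []
    # exact 28S locus
    locus_start = 2000
    plant(locus_start, wt)
    on_coord = locus_start + nick
    entries.append(SiteEntry(on_coord, "+", "on_28S", 120, on_read_count))

    # degenerate 28S copies: 600 nt centred on the nick, with 120-identity
    # substitutions spaced evenly across the +/-60 window and ~5% divergence
    # outside it
    copy_src = wt[nick - 300:nick + 300]
    pseudo_start = locus_start + len(wt) + 1500
    for i, ident in enumerate(identities):
        seq = list(copy_src)
        n_sub = 120 - ident
        win_lo = 240  # window [-60, +60) around the copy-local junction (300)
        positions = [win_lo + round(j * 120 / n_sub) for j in range(n_sub)] if n_sub else []
        for p in positions:
            seq[p] = _other_base(seq[p], rng)
        for p in range(len(seq)):
            if (p < win_lo or p >= win_lo + 120) and rng.random() < 0.05:
                seq[p] = _other_base(seq[p], rng)
        pos = pseudo_start + i * 1000
        plant(pos, "".join(seq))
        coord = pos + 300
        cls = "pseudo_28S" if ident >= 108 else "off_target"
        count = int(rng.integers(*pseudo_read_count_range))
        entries.append(SiteEntry(coord, "+", cls, ident, count))

    # motif off-targets in remaining background
    off_region_start = pseudo_start + n_pseudo * 1000 + 500
    avail = background_len - 400 - off_region_start
    if n_off > 0:
        if avail < n_off * 80:
            raise ValueError("background too small for requested off-target count")
        step = avail // n_off
        hlen_choices = (4, 5)
        for i in range(n_off):
            coord = off_region_start + i * step + int(rng.integers(0, min(30, step - 70)))
            strand = "-" if rng.random() < minus_strand_frac else "+"
            hlen = hlen_choices[int(rng.integers(0, 2))]
            hom = refset.donor.homology_3p[:hlen]
            t20 = rng.random() < t_minus20_prob
            if strand == "+":
                plant(coord, hom)
                if t20:
                    genome[coord - 20] = "T"
            else:
                plant(coord - hlen, revcomp(hom))
                if t20:
                    genome[coord + 19] = "A"  # T at -20 on the minus strand
            count = int(rng.geometric(off_read_count_p))
            entries.append(SiteEntry(coord, strand, "off_target", 30, count))
    return "".join(genome), SitePlan(tuple(entries))


def _other_base(base: str, rng: np.random.Generator) -> str:
    bases = "ACGT"
    return bases[(bases.index(base) + int(rng.integers(1, 4))) % 4]


def simulate_ttiss_pairs(
    refset: ReferenceSet,
    genome: str,
    plan: SitePlan,
    utr_tail_len: int = 32,
    r1_genomic_len: int = 88,
    fragment_len: int = 300,
    r2_len: int = 120,
    error_model: ErrorModel = ZERO_ERROR,
    phred: int = 30,
) -> list[tuple[SimulatedRead, SimulatedRead]]:
    """Simulate TTISS read pairs for every planned site.

    Read 1 is the 3'-most ``utr_tail_len`` bases of the donor 3' UTR
    followed by downstream genomic flank at the site (in insertion
    orientation); read 2 is the opposite-strand mate at the far end of the
    fragment.  Read multiplicities follow ``plan.read_count``.
    """
    if utr_tail_len > len(refset.donor.utr3):
        raise ValueError("utr_tail_len exceeds 3' UTR length")
    tail = refset.donor.utr3[-utr_tail_len:]
    rng = np.random.default_rng(error_model.seed)
    qc = chr(phred + 33)
    pairs = []
    k = 0
    for entry in plan.entries:
        c = entry.coord
        if entry.strand == "+":
            if c + fragment_len > len(genome):
                raise ValueError(f"site {c} too close to genome end")
            flank = genome[c:c + r1_genomic_len]
            mate = revcomp(genome[c + fragment_len - r2_len:c + fragment_len])
        else:
            if c - fragment_len < 0:
                raise ValueError(f"site {c} too close to genome start")
            flank = revcomp(genome[c - r1_genomic_len:c])
            mate = genome[c - fragment_len:c - fragment_len + r2_len]
        for _ in range(entry.read_count):
            r1 = apply_errors(tail + flank, error_model, rng)
            r2 = apply_errors(mate, error_model, rng)
            pairs.append((
                SimulatedRead(f"pair{k:05d}/1", r1, qc * len(r1), truth_site=c),
                SimulatedRead(f"pair{k:05d}/2", r2, qc * len(r2), truth_site=c),
            ))
            k += 1
    return pairs
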