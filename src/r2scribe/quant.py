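"""Closed-form quantification: ddPCR copies per genome, the long-read
anchored full-length copy estimate, and gel %-processed metrics.

ddPCR reports absolute target and reference-gene concentrations; with two
RPP30 copies per diploid genome, junction copies per genome are
``2 * target / rpp30``.  The ddPCR assay only sees the 5' junction, so the
full-length copy number is the junction copy number scaled by the fraction
of ddPCR-detectable long reads that are full-length integrations:

    full_length_copies = junction_copies * n_full / n_detectable

With 3.8 junctions per genome, 452 full-length of 519 detectable reads,
this gives ~3.3 full-length copies per genome.

Gel lanes from in-vitro target-primed reverse transcription (TPRT) assays
are summarized as %-processed: the top (unlabeled) strand is processed once
cleaved; the bottom strand is processed when cleaved or extended into the
TPRT product.  Template-jumping ("other") bands count toward total lane
intensity only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional


@dataclass(frozen=True)
class DdPCRMeasurement:
    target_conc: float  # copies/uL
    rpp30_conc: float  # copies/uL

    def __post_init__(self):
        if self.target_conc < 0 or self.rpp30_conc < 0:
            raise ValueError("concentrations must be non-negative")


@dataclass(frozen=True)
class CopyEstimate:
    junction_copies_per_genome: float
    n_ddpcr_detectable_reads: int
    n_full_length_reads: int
    full_length_copies_per_genome: float

    @property
    def rounded(self) -> float:
        """Display value at one decimal (round-half-even)."""
        return round(self.full_length_copies_per_genome, 1)


@dataclass(frozen=True)
class LaneProfile:
    uncleaved: float = 0.0
    cleaved: float = 0.0
    tprt: float = 0.0
    other: float = 0.0

    def __post_init__(self):
        for name in ("uncleaved", "cleaved", "tprt", "other"):
            if getattr(self, name) < 0:
                raise ValueError(f"band intensity {name} must be non-negative")

    @property
    def total(self) -> float:
        return self.uncleaved + self.cleaved + self.tprt + self.other


def ddpcr_copies_per_genome(m: DdPCRMeasurement) -> float:
    """Copies per genome, assuming two RPP30 copies per genome."""
    if m.rpp30_conc == 0:
        raise ZeroDivisionError("RPP30 concentration is zero; ratio undefined")
    return 2.0 * m.target_conc / m.rpp30_conc


def estimate_full_length_copies(
    junction_copies: float,
    n_detectable: int,
    n_full: int,
) -> CopyEstimate:
    """Scale ddPCR junction copies by the full-length read fraction."""
    if n_detectable <= 0:
        raise ValueError("n_detectable must be > 0")
    if junction_copies < 0 or n_full < 0:
        raise ValueError("inputs must be non-negative")
    full = junction_copies * n_full / n_detectable
    return CopyEstimate(junction_copies, n_detectable, n_full, full)


def percent_processed_top(lane: LaneProfile) -> float:
    """Top strand: 100 * cleaved / total lane intensity."""
    total = lane.total
    if total <= 0:
        raise ValueError("total lane intensity must be > 0")
    return 100.0 * lane.cleaved / total


def percent_processed_bottom(lane: LaneProfile) -> float:
    """Bottom strand: 100 * (cleaved + TPRT) / total lane intensity."""
    total = lane.total
    if total <= 0:
        raise ValueError("total lane intensity must be > 0")
    return 100.0 * (lane.cleaved + lane.tprt) / total
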