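"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately naive pure-Python implementations,
independent of the package's alignment kernels, used to cross-check
scores and window identities on small instances.
"""

from __future__ import annotations

import numpy as np
import pytest

from r2scribe.refsim import (ZERO_ERROR, default_outcome_panel,
                             make_reference_set, make_toy_genome,
                             simulate_panel_reads, simulate_ttiss_pairs)
from r2scribe.sequence import revcomp


@pytest.fixture(scope="session")
def refset():
    return make_reference_set(seed=1)


@pytest.fixture(scope="session")
def panel(refset):
    return default_outcome_panel(refset)


@pytest.fixture(scope="session")
def clean_reads(refset, panel):
    """Two zero-error reads per outcome allele (20 reads)."""
    return simulate_panel_reads(refset, panel, 2, ZERO_ERROR)


@pytest.fixture(scope="session")
def small_ttiss(refset):
    """Compact TTISS experiment: toy genome, truth plan, zero-error pairs."""
    genome, plan = make_toy_genome(
        refset, n_pseudo=2, identities=(112, 106), n_off=30,
        background_len=16000, on_read_count=50, seed=3,
    )
    pairs = simulate_ttiss_pairs(refset, genome, plan)
    return genome, plan, pairs


def local_affine_score_bruteforce(q, r, match=2, mismatch=-3,
                                  gap_open=-5, gap_extend=-2):
    """Quadratic-time Gotoh local-alignment score (reference implementation)."""
    n, m = len(q), len(r)
    NEG = -(10**9)
    Hprev = [0] * (m + 1)
    Eprev = [NEG] * (m + 1)
    best = 0
    for i in range(1, n + 1):
        H = [0] * (m + 1)
        E = [NEG] * (m + 1)
        f = NEG
        qi = q[i - 1]
        for j in range(1, m + 1):
            E[j] = max(Hprev[j] + gap_open + gap_extend, Eprev[j] + gap_extend)
            f = max(H[j - 1] + gap_open + gap_extend, f + gap_extend)
            s = match if qi == r[j - 1] else mismatch
            h = max(0, Hprev[j - 1] + s, E[j], f)
            H[j] = h
            if h > best:
                best = h
        Hprev, Eprev = H, E
    return best


def window_matches_bruteforce(window, wt):
    """Exhaustive ungapped offset/strand scan for the window-identity rule."""
    best = 0
    for seq in (window, revcomp(window)):
        L = len(seq)
        for off in range(len(wt) - L + 1):
            best = max(best, sum(a == b for a, b in zip(seq, wt[off:off + L])))
    return best
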