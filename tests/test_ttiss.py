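"""TTISS pipeline: anchoring, mapping, window classification, logo, and
junction quantification."""

import numpy as np
import pytest

from r2scribe.refsim import SiteEntry, SitePlan, make_toy_genome, simulate_ttiss_pairs
from r2scribe.sequence import random_seq, revcomp
from r2scribe.ttiss import (JUNCTION_AMPLICON, JUNCTION_GUIDE, InsertionSite,
                            build_weighted_logo, classify_site,
                            extract_utr_anchored, junction_frequencies,
                            map_sites, run_ttiss, specificity_summary,
                            window_matches_scan)

from .conftest import window_matches_bruteforce


class TestAnchor:
    TAIL = "ACGTACGTACGTACGTACGTACGTACGTAC"  # 30 nt

    def test_exact_prefix_trimmed(self):
        flank = "GGGTTTCCCAAA"
        assert extract_utr_anchored(self.TAIL + flank, self.TAIL) == flank

    def test_read_without_utr_prefix_rejected(self):
        rng = np.random.default_rng(0)
        read = random_seq(80, rng)
        # a random 80-mer essentially never carries the 30-nt tail prefix
        assert extract_utr_anchored(read, self.TAIL) is None

    def test_one_mismatch_within_error_budget_accepted(self):
        tail = list(self.TAIL)
        tail[10] = "T" if tail[10] != "T" else "A"
        read = "".join(tail) + "GGGTTTCCC"
        assert extract_utr_anchored(read, self.TAIL, 0.1) == "GGGTTTCCC"

    def test_empty_tail_rejected(self):
        with pytest.raises(ValueError):
            extract_utr_anchored("ACGT", "")


class TestMapSites:
    def test_end_to_end_sites_match_plan(self, refset, small_ttiss):
        genome, plan, pairs = small_ttiss
        tail = refset.donor.utr3[-32:]
        locus = (2000, 2000 + len(refset.wt_locus))
        sites, tally, _ = run_ttiss(pairs, tail, refset.wt_locus, genome,
                                    genome_28s_offset=2000, locus_interval=locus)
        truth = {(e.coord, e.strand): e for e in plan.entries}
        assert len(sites) == len(plan.entries)
        for s in sites:
            e = truth[(s.coord, s.strand)]
            assert s.read_count == e.read_count
            expected = {"on_28S": "on_28S", "pseudo_28S": "pseudo_28S_on",
                        "off_target": "off_target"}[e.site_class]
            assert s.site_class == expected

    def test_read_conservation(self, refset, small_ttiss):
        genome, plan, pairs = small_ttiss
        tail = refset.donor.utr3[-32:]
        _, tally, _ = run_ttiss(pairs, tail, refset.wt_locus, genome,
                                genome_28s_offset=2000)
        assert tally.conserved()
        assert tally.n_pairs == len(pairs)

    def test_improperly_paired_mate_counted_not_dropped(self, refset, small_ttiss):
        genome, _, _ = small_ttiss
        frag = genome[12000:12080]  # random background, not 28S-like
        same_strand_mate = genome[12150:12270]  # not reverse-complemented
        sites, tally = map_sites([(frag, same_strand_mate)], refset.wt_locus,
                                 genome)
        assert tally.n_improper_pair == 1
        assert sites == []

    def test_unmappable_fragment_counted(self, refset, small_ttiss):
        genome, _, _ = small_ttiss
        rng = np.random.default_rng(99)
        sites, tally = map_sites([(random_seq(80, rng), random_seq(80, rng))],
                                 refset.wt_locus, genome)
        assert tally.n_unmapped == 1


class TestClassifySite:
    def test_perfect_window_is_on_target_class(self, refset, small_ttiss):
        genome, plan, _ = small_ttiss
        on = [e for e in plan.entries if e.site_class == "on_28S"][0]
        site = classify_site(InsertionSite(on.coord, "+", 1), genome,
                             refset.wt_locus)
        assert site.window_matches == 120
        assert site.site_class == "pseudo_28S_on"  # without locus annotation

    def test_locus_interval_overrides_to_on_28s(self, refset, small_ttiss):
        genome, plan, _ = small_ttiss
        on = [e for e in plan.entries if e.site_class == "on_28S"][0]
        site = classify_site(InsertionSite(on.coord, "+", 1), genome,
                             refset.wt_locus, locus_interval=(2000, 6000))
        assert site.site_class == "on_28S"

    def test_13_substitutions_fall_below_threshold(self, refset):
        rng = np.random.default_rng(21)
        wt = refset.wt_locus
        window = list(wt[1000:1120])
        for i in range(13):
            p = i * 9
            window[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[window[p]]
        genome = random_seq(500, rng) + "".join(window) + random_seq(500, rng)
        site = classify_site(InsertionSite(560, "+", 1), genome, wt)
        assert site.window_matches == 107
        assert site.site_class == "off_target"

    def test_scan_equals_bruteforce_on_random_windows(self):
        rng = np.random.default_rng(5)
        wt = random_seq(600, rng)
        for _ in range(25):
            if rng.random() < 0.5:
                start = int(rng.integers(0, 480))
                window = list(wt[start:start + 120])
                for _ in range(int(rng.integers(0, 30))):
                    p = int(rng.integers(0, 120))
                    window[p] = "ACGT"[int(rng.integers(0, 4))]
                window = "".join(window)
            else:
                window = random_seq(120, rng)
            if rng.random() < 0.5:
                window = revcomp(window)
            assert window_matches_scan(window, wt) == \
                window_matches_bruteforce(window, wt)

    def test_truncated_window_at_genome_edge_flagged(self, refset):
        genome = refset.wt_locus[:200]
        site = classify_site(InsertionSite(10, "+", 1), genome, refset.wt_locus)
        assert site.partial_window

    def test_odd_window_rejected(self, refset, small_ttiss):
        genome, _, _ = small_ttiss
        with pytest.raises(ValueError):
            classify_site(InsertionSite(8000, "+", 1), genome,
                          refset.wt_locus, window=121)


class TestLogo:
    def test_single_site_gives_one_hot_logo(self, small_ttiss):
        genome, _, _ = small_ttiss
        site = InsertionSite(8000, "+", 10, site_class="off_target")
        logo = build_weighted_logo([site], genome)
        assert logo.total_weight == 10
        flank = genome[8000 - 30:8000 + 7]
        for pos, base in zip(logo.positions, flank):
            assert logo.weight(pos, base) == 1.0

    def test_read_count_weighting(self, small_ttiss):
        genome, _, _ = small_ttiss
        a = InsertionSite(8000, "+", 3)
        b = InsertionSite(9000, "+", 1)
        logo = build_weighted_logo([a, b], genome)
        pos = next(p for p in logo.positions
                   if genome[8000 + p] != genome[9000 + p])
        assert logo.weight(pos, genome[8000 + pos]) == pytest.approx(0.75)
        assert logo.weight(pos, genome[9000 + pos]) == pytest.approx(0.25)

    def test_rows_normalized_and_weight_conserved(self, refset, small_ttiss):
        genome, plan, pairs = small_ttiss
        tail = refset.donor.utr3[-32:]
        sites, _, _ = run_ttiss(pairs, tail, refset.wt_locus, genome,
                                genome_28s_offset=2000)
        off = [s for s in sites if s.site_class == "off_target"]
        logo = build_weighted_logo(off, genome)
        assert np.allclose(logo.matrix.sum(axis=1), 1.0, atol=1e-9)
        assert logo.total_weight == sum(s.read_count for s in off)

    def test_minus_strand_site_read_in_insertion_orientation(self, small_ttiss):
        genome, _, _ = small_ttiss
        plus = InsertionSite(8000, "+", 1)
        # the minus-strand junction whose oriented flank equals the plus one
        minus = InsertionSite(8000, "-", 1)
        lp = build_weighted_logo([plus], genome)
        lm = build_weighted_logo([minus], genome)
        # position p reads complement(genome[coord - 1 - p])
        flank = revcomp(genome[8000 - 7:8000 + 30])
        for pos, base in zip(lm.positions, flank):
            assert lm.weight(pos, base) == 1.0
        assert not lp.matrix.equals(lm.matrix)

    def test_empty_site_list_is_an_error(self, small_ttiss):
        genome, _, _ = small_ttiss
        with pytest.raises(ValueError, match="empty site list"):
            build_weighted_logo([], genome)


def _reads(seqs, phred=30):
    return [(s, chr(phred + 33) * len(s)) for s in seqs]


class TestJunctionFrequencies:
    def test_perfect_reads_give_one_hot_window(self):
        prof = junction_frequencies(_reads([JUNCTION_AMPLICON] * 10),
                                    JUNCTION_AMPLICON, guide=JUNCTION_GUIDE)
        assert prof.n_reads_passing == 10
        jp = JUNCTION_AMPLICON.find(JUNCTION_GUIDE) + len(JUNCTION_GUIDE)
        assert prof.window_positions == tuple(range(jp - 2, jp + 3))
        for pos in prof.window_positions:
            assert prof.frequencies.loc[pos, JUNCTION_AMPLICON[pos]] == 1.0

    @pytest.mark.parametrize("q,passing", [(19, 0), (20, 1)])
    def test_single_base_quality_threshold(self, q, passing):
        qual = "?" * len(JUNCTION_AMPLICON)  # phred 30
        qual = qual[:5] + chr(q + 33) + qual[6:]
        prof = junction_frequencies([(JUNCTION_AMPLICON, qual)],
                                    JUNCTION_AMPLICON, guide=JUNCTION_GUIDE)
        assert prof.n_reads_passing == passing

    def test_mean_quality_threshold(self):
        n = len(JUNCTION_AMPLICON)
        qual = chr(19 + 33) * n  # every base phred 19 -> mean 19
        prof = junction_frequencies([(JUNCTION_AMPLICON, qual)],
                                    JUNCTION_AMPLICON, guide=JUNCTION_GUIDE)
        assert prof.n_reads_passing == 0

    def test_low_homology_read_excluded(self):
        rng = np.random.default_rng(3)
        half = JUNCTION_AMPLICON[:25] + random_seq(34, rng)
        prof = junction_frequencies(_reads([half]), JUNCTION_AMPLICON,
                                    guide=JUNCTION_GUIDE)
        assert prof.n_reads_passing == 0

    def test_all_filtered_yields_undefined_frequencies(self):
        prof = junction_frequencies([], JUNCTION_AMPLICON, guide=JUNCTION_GUIDE)
        assert prof.n_reads_passing == 0 and prof.frequencies is None

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            junction_frequencies([], JUNCTION_AMPLICON, guide=JUNCTION_GUIDE,
                                 window=4)


class TestSummary:
    @staticmethod
    def _site(cls, count, coord=0):
        return InsertionSite(coord, "+", count, site_class=cls)

    def test_all_on_target(self):
        sites = [self._site("on_28S", 100)]
        assert specificity_summary(sites)["on_fraction"] == 1.0

    def test_mixed_fraction(self):
        sites = [self._site("on_28S", 900), self._site("pseudo_28S_on", 90),
                 self._site("off_target", 10, 1)]
        s = specificity_summary(sites)
        assert s["on_fraction"] == pytest.approx(0.99)
        assert s["n_off_loci"] == 1

    def test_loci_over_ten_reads_counted(self):
        sites = [self._site("off_target", c, i) for i, c in
                 enumerate([1, 5, 10, 11, 40])]
        s = specificity_summary(sites)
        assert s["n_off_loci"] == 5
        assert s["n_off_loci_gt10"] == 2
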