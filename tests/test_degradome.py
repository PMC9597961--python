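import numpy as np
import pytest

from mirmod.degradome import (
    AlignmentError,
    call_cleavage,
    categorize,
    duplex_score,
    pair_catalog,
    scan_targets,
)
from mirmod.io import DegradomeProfile, SequenceRecord
from mirmod.seqs import GU_PAIRS, WC_PAIRS, random_seq, revcomp


def oracle_min_score(mirna: str, site: str) -> float:
    """Independent oracle: recursive enumeration of every monotone alignment
    with at most one gap (terminal miRNA overhangs allowed, site insertions
    internal only), scored per the documented penalty scheme."""
    L, S = len(mirna), len(site)
    mrev = mirna[::-1]  # column j pairs miRNA position L - j

    def w(i):
        return 2.0 if 2 <= i <= 13 else 1.0

    def pair_cost(i, base):
        pair = (mirna[i - 1], base)
        if pair in WC_PAIRS:
            return 0.0
        if pair in GU_PAIRS:
            return 0.5 * w(i)
        return 1.0 * w(i)

    best = [np.inf]

    def walk(j, q, gaps, acc):
        if acc >= best[0]:
            return
        if j == L and q == S:
            best[0] = acc
            return
        if j < L and q < S:  # pair column
            walk(j + 1, q + 1, gaps, acc + pair_cost(L - j, site[q]))
        if j < L and gaps == 0 and (S - q) < (L - j):  # skip a miRNA base
            walk(j + 1, q, 1, acc + 2.0 * w(L - j))
        if q < S and gaps == 0 and 1 <= j <= L - 1 and (L - j) < (S - q):
            # consume an unpaired site base between miRNA positions L-j and L-j+1
            i = L - j
            walk(j, q + 1, 1, acc + 2.0 * (2.0 if 2 <= i <= 12 else 1.0))
        return

    walk(0, 0, 0, 0.0)
    return best[0]


class TestDuplexScore:
    def test_perfect_site_scores_zero(self):
        m = SequenceRecord("m", "ACGUACGUACGUACGUACGUA")
        aln = duplex_score(m, revcomp(m.seq))
        assert aln.score == 0.0
        assert set(aln.states) == {"match"}

    def test_seed_region_mismatch_costs_double(self):
        m = SequenceRecord("m", "A" * 21)
        site = list(revcomp(m.seq))  # all U
        site_distal = site.copy()
        site_distal[21 - 15] = "C"  # mismatch at miRNA position 15
        assert duplex_score(m, "".join(site_distal)).score == 1.0
        site_seed = site.copy()
        site_seed[21 - 5] = "C"  # same mismatch at miRNA position 5
        assert duplex_score(m, "".join(site_seed)).score == 2.0

    def test_wobble_plus_distal_mismatch(self):
        # G:U wobble at miRNA position 3 (0.5 doubled = 1.0) plus a
        # mismatch at position 20 (1.0) = 2.0 total
        m = "AAGAAAAAAAAAAAAAAAAUA"
        site = list(revcomp(m))
        site[21 - 3] = "U"   # opposite the G at position 3 -> G:U
        site[21 - 20] = "G"  # opposite the U at position 20: U-G is a wobble, use C
        site[21 - 20] = "C"  # U:C cannot pair -> mismatch
        aln = duplex_score(SequenceRecord("m", m), "".join(site))
        assert aln.score == 2.0
        assert aln.states[2] == "GU_wobble"
        assert aln.states[19] == "mismatch"

    def test_gap_variants_match_enumeration_oracle(self, rng):
        for _ in range(150):
            L = int(rng.integers(8, 13))
            m = random_seq(rng, L)
            span = L + int(rng.integers(-1, 2))
            site = random_seq(rng, span)
            aln = duplex_score(SequenceRecord("m", m), site)
            assert aln.score == pytest.approx(oracle_min_score(m, site), abs=1e-9)

    def test_near_complement_with_bulge_matches_oracle(self, rng):
        # adversarial case: perfect complement with one inserted site base
        for _ in range(60):
            L = int(rng.integers(9, 13))
            m = random_seq(rng, L)
            site = list(revcomp(m))
            site.insert(int(rng.integers(1, L)), random_seq(rng, 1))
            site = "".join(site)
            aln = duplex_score(SequenceRecord("m", m), site)
            assert aln.score == pytest.approx(oracle_min_score(m, site), abs=1e-9)
            assert aln.n_gaps == 1

    def test_incompatible_lengths_rejected(self):
        with pytest.raises(AlignmentError):
            duplex_score(SequenceRecord("m", "ACGUACGUACGU"), "ACGU")


class TestScanTargets:
    def test_embedded_perfect_site_found_with_coordinates(self, rng):
        m = SequenceRecord("m", random_seq(rng, 21))
        site = revcomp(m.seq)
        tx = SequenceRecord("tx", random_seq(rng, 200) + site + random_seq(rng, 200))
        hits = scan_targets(m, tx, max_score=0.0)
        assert len(hits) == 1
        assert hits[0].site_start == 201 and hits[0].site_end == 221
        assert hits[0].score == 0.0
        # miRNA position 10 pairs the 10th base from the site 3' end
        assert hits[0].coord_map[10] == 221 - 9

    def test_matches_brute_force_window_scoring(self, rng):
        # oracle: score every candidate window directly with duplex_score
        m = SequenceRecord("m", random_seq(rng, 10))
        tx = SequenceRecord("tx", random_seq(rng, 120))
        cutoff = 9.0
        hits = {h.site_start: h.score for h in scan_targets(m, tx, max_score=cutoff)}
        L, T = 10, 120
        expected = {}
        for s in range(1, T + 1):  # 1-based site starts
            best = np.inf
            for span in (L - 1, L, L + 1):
                if span == L - 1 and not 2 <= s <= T - L + 1:
                    continue  # shortened sites are anchored at full-window starts
                                # and need one base of left context
                if span == L + 1 and s + span - 1 > T:
                    continue
                window = tx.seq[s - 1: s - 1 + span]
                if len(window) == span:
                    best = min(best, duplex_score(m, window).score)
            if best <= cutoff:
                expected[s] = best
        assert set(hits) == set(expected)
        for s, score in expected.items():
            assert hits[s] == pytest.approx(score), f"start {s}"

    def test_cutoff_monotonicity(self, rng):
        m = SequenceRecord("m", random_seq(rng, 21))
        tx = SequenceRecord("tx", random_seq(rng, 500))
        loose = {h.site_start for h in scan_targets(m, tx, max_score=12.0)}
        tight = {h.site_start for h in scan_targets(m, tx, max_score=6.0)}
        assert tight <= loose

    def test_random_pair_has_no_perfect_hit(self, rng):
        m = SequenceRecord("m", random_seq(rng, 21))
        tx = SequenceRecord("tx", random_seq(rng, 1000))
        assert scan_targets(m, tx, max_score=0.0) == []


class TestCleavage:
    def _aln(self, rng, peak_shift=0):
        m = SequenceRecord("m", random_seq(rng, 21))
        tx = SequenceRecord("tx", random_seq(rng, 100) + revcomp(m.seq) + random_seq(rng, 100))
        aln = scan_targets(m, tx, max_score=0.0)[0]
        return aln, aln.coord_map[10]

    def test_peak_opposite_position_ten(self, rng):
        aln, pos10 = self._aln(rng)
        profile = DegradomeProfile("tx", {pos10: 50, pos10 + 30: 3})
        ev = call_cleavage(aln, profile)
        assert ev.cleavage_pos == pos10 and ev.degradome_count == 50

    def test_no_coverage_in_window_gives_no_event(self, rng):
        aln, pos10 = self._aln(rng)
        profile = DegradomeProfile("tx", {pos10 + 30: 9})
        assert call_cleavage(aln, profile) is None

    def test_tie_prefers_canonical_position(self, rng):
        aln, pos10 = self._aln(rng)
        profile = DegradomeProfile("tx", {pos10 - 1: 4, pos10: 4})
        assert call_cleavage(aln, profile).cleavage_pos == pos10

    def test_off_canonical_peak_within_window_is_used(self, rng):
        aln, pos10 = self._aln(rng)
        profile = DegradomeProfile("tx", {pos10 + 1: 10, pos10: 2})
        ev = call_cleavage(aln, profile)
        assert ev.cleavage_pos == pos10 + 1


class TestCategorize:
    def _event(self, rng, profile, pos):
        m = SequenceRecord("m", random_seq(rng, 21))
        aln = duplex_score(m, revcomp(m.seq), transcript_id=profile.transcript_id,
                           site_start=pos - 11)
        from mirmod.degradome import CleavageEvent
        return CleavageEvent(aln, pos, profile.count_at(pos), "ST")

    def test_unique_maximum_is_category_zero(self, rng):
        profile = DegradomeProfile("tx", {100: 9, 200: 2, 300: 1})
        assert categorize(self._event(rng, profile, 100), profile).category == 0

    def test_tied_maximum_is_category_one(self, rng):
        profile = DegradomeProfile("tx", {100: 5, 150: 5, 300: 1})
        assert categorize(self._event(rng, profile, 100), profile).category == 1

    def test_single_read_is_category_four(self, rng):
        profile = DegradomeProfile("tx", {100: 1})
        assert categorize(self._event(rng, profile, 100), profile).category == 4

    def test_above_median_is_category_two_else_three(self, rng):
        profile = DegradomeProfile("tx", {100: 3, 150: 9, 200: 2, 250: 2})
        assert categorize(self._event(rng, profile, 100), profile).category == 2
        assert categorize(self._event(rng, profile, 200), profile).category == 3

    def test_categories_partition_simulated_events(self, default_result):
        for events in default_result.events_by_genotype.values():
            assert all(ev.category in (0, 1, 2, 3, 4) for ev in events)


class TestPairCatalog:
    def _event_at(self, rng, mirna_id, tx_id, pos, genotype):
        m = SequenceRecord(mirna_id, random_seq(rng, 21))
        aln = duplex_score(m, revcomp(m.seq), transcript_id=tx_id, site_start=pos - 11)
        from mirmod.degradome import CleavageEvent
        return CleavageEvent(aln, pos, 5, genotype)

    def test_same_position_in_both_genotypes_is_shared(self, rng):
        ev_st = self._event_at(rng, "m", "t", 101, "ST")
        ev_ss = self._event_at(rng, "m", "t", 101, "SS")
        cat = pair_catalog({"ST": [ev_st], "SS": [ev_ss]})
        assert list(cat["occurrence"]) == ["shared"]

    def test_different_cleavage_positions_are_distinct_pairs(self, rng):
        ev1 = self._event_at(rng, "m", "t", 101, "ST")
        ev2 = self._event_at(rng, "m", "t", 105, "ST")
        cat = pair_catalog({"ST": [ev1, ev2], "SS": []})
        assert len(cat) == 2

    def test_occurrence_classes_partition_catalog(self, default_result):
        cat = default_result.pair_catalog
        occ = cat["occurrence"].value_counts()
        assert occ.sum() == len(cat)
        assert set(occ.index) <= {"ST_specific", "SS_specific", "shared"}
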