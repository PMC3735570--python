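"""Electronic PCR, marker categorization and QTL summaries."""

import numpy as np
import pytest

from rgene_atlas.qtl_colocalization import (
    EpcrParams,
    PrimerPair,
    QtlParams,
    categorize_marker,
    epcr,
    revcomp,
    summarize_qtl,
    MarkerCall,
)
from rgene_atlas.records import GeneLocus
from rgene_atlas.util import pct


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _plant(seq, pos, fwd, rev, size):
    s = list(seq)
    s[pos : pos + len(fwd)] = fwd
    rc = revcomp(rev)
    s[pos + size - len(rc) : pos + size] = rc
    return "".join(s)


# --- independent oracle: all-position-pairs brute force --------------------


def oracle_epcr(genome, pair, params):
    """Check every (left site, right site) position pair on both
    orientations with naive string comparison."""
    def sites(seq, primer, anchor_at_end):
        out = []
        m = len(primer)
        for i in range(len(seq) - m + 1):
            window = seq[i : i + m]
            mm = sum(x != y for x, y in zip(window, primer))
            if mm > params.max_mismatch:
                continue
            anchor = (
                window[m - params.anchor3 :] == primer[m - params.anchor3 :]
                if anchor_at_end
                else window[: params.anchor3] == primer[: params.anchor3]
            )
            if anchor:
                out.append(i)
        return out

    products = set()
    for seq_id in genome:
        seq = genome[seq_id].upper()
        for left, right in ((pair.fwd, pair.rev), (pair.rev, pair.fwd)):
            for i in sites(seq, left.upper(), True):
                for k in sites(seq, revcomp(right).upper(), False):
                    if k < i:
                        continue
                    size = k + len(right) - i
                    if params.size_min <= size <= params.size_max:
                        products.add((seq_id, i + 1, k + len(right)))
    return products


class TestEpcr:
    def test_planted_perfect_site_yields_one_product(self, rng):
        fwd, rev = _random_seq(rng, 20), _random_seq(rng, 20)
        seq = _plant(_random_seq(rng, 5000), 1000, fwd, rev, 300)
        hits = epcr({"chr1": seq}, PrimerPair("m", fwd, rev))
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end, hits[0].size) == (1001, 1300, 300)

    def test_product_outside_size_window_is_dropped(self, rng):
        fwd, rev = _random_seq(rng, 20), _random_seq(rng, 20)
        seq = _plant(_random_seq(rng, 5000), 1000, fwd, rev, 750)
        assert epcr({"chr1": seq}, PrimerPair("m", fwd, rev)) == []

    def test_mismatch_and_anchor_rules(self, rng):
        fwd, rev = _random_seq(rng, 20), _random_seq(rng, 20)

        def flip(base):
            return "ACGT"[("ACGT".index(base) + 1) % 4]

        degraded = flip(fwd[0]) + fwd[1:5] + flip(fwd[5]) + fwd[6:]
        seq = _plant(_random_seq(rng, 4000), 500, degraded, rev, 200)
        # two internal/5' mismatches are tolerated
        hits = epcr({"c": seq}, PrimerPair("m", fwd, rev))
        assert len(hits) == 1 and hits[0].fwd_mismatches == 2
        # a 3'-anchor mismatch kills the site
        broken = fwd[:-1] + ("A" if fwd[-1] != "A" else "C")
        seq2 = _plant(_random_seq(rng, 4000), 500, broken, rev, 200)
        assert epcr({"c": seq2}, PrimerPair("m", fwd, rev)) == []

    def test_matches_brute_force_oracle_with_degenerate_sites(self, rng):
        params = EpcrParams()
        for i in range(12):
            fwd, rev = _random_seq(rng, 18), _random_seq(rng, 18)
            seq = _random_seq(rng, 2500)
            for _ in range(int(rng.integers(1, 4))):  # plant degraded copies
                pos = int(rng.integers(0, 1800))
                size = int(rng.integers(60, 800))
                site = list(_plant(seq, pos, fwd, rev, min(size, 2500 - pos)))
                for _ in range(int(rng.integers(0, 4))):  # sprinkle mismatches
                    p = int(rng.integers(pos, pos + 18))
                    site[p] = "ACGT"[int(rng.integers(0, 4))]
                seq = "".join(site)
            genome = {"chr": seq}
            pair = PrimerPair("m", fwd, rev)
            got = {(h.seq_id, h.start, h.end) for h in epcr(genome, pair, params)}
            assert got == oracle_epcr(genome, pair, params), f"instance {i}"

    def test_reverse_complement_invariance(self, rng):
        fwd, rev = _random_seq(rng, 20), _random_seq(rng, 20)
        seq = _plant(_random_seq(rng, 3000), 700, fwd, rev, 250)
        fwd_hits = epcr({"c": seq}, PrimerPair("m", fwd, rev))
        rc_hits = epcr({"c": revcomp(seq)}, PrimerPair("m", fwd, rev))
        assert len(fwd_hits) == len(rc_hits) == 1
        n = len(seq)
        assert rc_hits[0].start == n - fwd_hits[0].end + 1
        assert rc_hits[0].end == n - fwd_hits[0].start + 1

    def test_primer_shorter_than_anchor_rejected(self):
        with pytest.raises(ValueError, match="15"):
            PrimerPair("m", "ACGTACGTAC", "ACGTACGTACGTACGT")
        pair = PrimerPair("m", "ACGTACGTACGTACG", "ACGTACGTACGTACG")
        with pytest.raises(ValueError, match="anchor"):
            epcr({"c": "ACGT" * 100}, pair, EpcrParams(anchor3=16))


class TestCategorization:
    loci = [GeneLocus("g1", "chr1", 5_000_000, 5_003_000)]
    lengths = {"chr1": 20_000_000, "scaffoldA": 1_500_000, "scaffoldB": 1_500_000,
               "scaffoldC": 3_000_000}

    def _placement(self, seq, start):
        from rgene_atlas.qtl_colocalization import MarkerPlacement

        return MarkerPlacement("m", seq, start, start + 299, start, start, 0, 0, "+")

    def test_within_and_outside_flank(self):
        near = categorize_marker(
            [self._placement("chr1", 2_500_000)], self.loci, self.lengths
        )
        assert near.category == "within_flank"
        far = categorize_marker(
            [self._placement("chr1", 10_000_000)], self.loci, self.lengths
        )
        assert far.category == "outside_flank"

    def test_scaffold_cases(self):
        no_genes = categorize_marker(
            [self._placement("scaffoldA", 700_000)], self.loci, self.lengths
        )
        assert no_genes.category == "small_scaffold_no_nbs"
        with_genes = categorize_marker(
            [self._placement("scaffoldB", 10_000)],
            self.loci + [GeneLocus("g2", "scaffoldB", 900_000, 903_000)],
            self.lengths,
        )
        assert with_genes.category == "scaffold_with_nbs"
        big_empty = categorize_marker(
            [self._placement("scaffoldC", 10_000)], self.loci, self.lengths
        )
        assert big_empty.category == "outside_flank"

    def test_unplaced_and_unknown_sequence(self):
        assert categorize_marker([], self.loci, self.lengths,
                                 marker_id="m").category == "unplaced"
        with pytest.raises(ValueError, match="unknown"):
            categorize_marker(
                [self._placement("chrZ", 100)], self.loci, self.lengths
            )

    def test_multi_hit_marker_takes_nearest_placement(self):
        calls = categorize_marker(
            [self._placement("chr1", 15_000_000),
             self._placement("chr1", 4_000_000)],
            self.loci, self.lengths,
        )
        assert calls.category == "within_flank"
        assert calls.placement.start == 4_000_000


class TestSummary:
    def test_published_ratio_conventions(self):
        # 34 of 74 placed markers co-localized -> 45.9%; 74/98 placed -> 75.5%
        calls = (
            [_call(f"w{i}", "within_flank") for i in range(32)]
            + [_call(f"s{i}", "scaffold_with_nbs") for i in range(2)]
            + [_call(f"o{i}", "outside_flank") for i in range(23)]
            + [_call(f"n{i}", "small_scaffold_no_nbs") for i in range(17)]
            + [_call(f"u{i}", "unplaced", placed=False) for i in range(24)]
        )
        summary = summarize_qtl(calls, [])
        assert summary.n_placed == 74
        assert summary.n_within_total == 34
        assert summary.within_pct == 45.9
        assert summary.placed_pct == 75.5
        assert (
            summary.n_within_chromosome + summary.n_outside
            + summary.n_scaffold_with_nbs + summary.n_scaffold_no_nbs
            + summary.n_unplaced
        ) == summary.n_markers

    def test_zero_markers(self):
        summary = summarize_qtl([], [])
        assert summary.n_markers == 0 and summary.within_pct == 0.0


def _call(mid, category, placed=True):
    from rgene_atlas.qtl_colocalization import MarkerPlacement

    placement = (
        MarkerPlacement(mid, "chr1", 100, 399, 100, 100, 0, 0, "+")
        if placed
        else None
    )
    return MarkerCall(mid, category, placement, 0.0)
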