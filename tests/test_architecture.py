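"""Clusters (200-kb chaining), 70/70 duplications, families, summaries."""

import numpy as np
import pytest

from rgene_atlas.genome_architecture import (
    ClusterParams,
    DuplicationEvent,
    DuplicationParams,
    align_pair,
    build_families,
    detect_clusters,
    detect_duplications,
    singleton_location_genes,
    summarize_architecture,
)
from rgene_atlas.records import GeneLocus, ProteinRecord
from rgene_atlas.synthetic_data import mutate_to_identity
from rgene_atlas.util import pct

AA = "ACDEFGHIKLMNPQRSTVWY"


def _loc(gid, seq, start, length=3000):
    return GeneLocus(gid, seq, start, start + length - 1)


class TestClusters:
    def test_pair_within_gap_forms_cluster(self):
        loci = [_loc("a", "chr1", 100_000), _loc("b", "chr1", 198_000)]
        clusters = detect_clusters(loci)
        assert len(clusters) == 1 and clusters[0].members == ("a", "b")

    def test_pair_beyond_gap_does_not(self):
        loci = [_loc("a", "chr1", 100_000), _loc("b", "chr1", 353_001)]
        assert detect_clusters(loci) == []

    def test_transitive_chaining_spans_beyond_the_gap(self):
        # successive 150-kb gaps chain into one 3-gene cluster even though
        # the extreme members are 300+ kb apart
        loci = [
            _loc("a", "chr1", 100_000),
            _loc("b", "chr1", 253_000),
            _loc("c", "chr1", 406_000),
        ]
        clusters = detect_clusters(loci)
        assert len(clusters) == 1 and clusters[0].members == ("a", "b", "c")

    def test_permutation_invariance_and_seq_separation(self, rng):
        loci = [
            _loc(f"g{i}", f"chr{1 + i % 2}", 50_000 + (i // 2) * 120_000)
            for i in range(10)
        ]
        base = detect_clusters(loci)
        perm = list(loci)
        rng.shuffle(perm)
        assert detect_clusters(perm) == base
        for cluster in base:
            assert all(
                l.seq_id == cluster.seq_id
                for l in loci if l.gene_id in cluster.members
            )
        seen = [g for c in base for g in c.members]
        assert len(seen) == len(set(seen))

    def test_duplicate_gene_id_rejected(self):
        loci = [_loc("a", "chr1", 1000), _loc("a", "chr2", 1000)]
        with pytest.raises(ValueError, match="duplicate"):
            detect_clusters(loci)


# --- independent oracle: hand-rolled Needleman-Wunsch ----------------------


def oracle_align(a, b, match=1.0, mismatch=-1.0, gap=-2.0):
    """Linear-gap global DP with deterministic traceback (diag>up>left);
    returns (coverage, identity) under the same column conventions."""
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1))
    score[:, 0] = np.arange(n + 1) * gap
    score[0, :] = np.arange(m + 1) * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = score[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            score[i, j] = max(diag, score[i - 1, j] + gap, score[i, j - 1] + gap)
    i, j = n, m
    alignable = identical = 0
    while i > 0 and j > 0:
        sub = match if a[i - 1] == b[j - 1] else mismatch
        if score[i, j] == score[i - 1, j - 1] + sub:
            alignable += 1
            identical += a[i - 1] == b[j - 1]
            i, j = i - 1, j - 1
        elif score[i, j] == score[i - 1, j] + gap:
            i -= 1
        else:
            j -= 1
    longer = max(n, m)
    return alignable / longer, (identical / alignable) if alignable else 0.0


class TestDuplications:
    def test_identical_proteins_are_an_event(self):
        p = {g: ProteinRecord(g, "M" + "ACDEFGHIKL" * 30) for g in ("a", "b")}
        loci = [_loc("a", "chr1", 1000), _loc("b", "chr1", 900_000)]
        events = detect_duplications(p, loci, [])
        assert len(events) == 1
        assert events[0].coverage == pytest.approx(1.0)
        assert events[0].identity == pytest.approx(1.0)

    def test_sixty_percent_identity_is_no_event(self, rng):
        base = "".join(AA[i] for i in rng.integers(0, 20, 300))
        other = mutate_to_identity(base, 0.60, rng)
        p = {"a": ProteinRecord("a", base), "b": ProteinRecord("b", other)}
        loci = [_loc("a", "chr1", 1000), _loc("b", "chr1", 900_000)]
        assert detect_duplications(p, loci, []) == []

    def test_decisions_match_dp_oracle_on_random_pairs(self, rng):
        params = DuplicationParams()
        for i in range(25):
            n = int(rng.integers(80, 400))
            a = "".join(AA[k] for k in rng.integers(0, 20, n))
            if i % 2 == 0:  # related pair at a controlled identity
                ident = float(rng.uniform(0.55, 0.95))
                b = mutate_to_identity(a, ident, rng)
            else:  # unrelated pair
                b = "".join(AA[k] for k in rng.integers(0, 20, int(rng.integers(80, 400))))
            cov, ident_got = align_pair(
                ProteinRecord("a", a), ProteinRecord("b", b), params
            )
            o_cov, o_id = oracle_align(a, b)
            mine = cov > 0.70 and ident_got > 0.70
            oracle = o_cov > 0.70 and o_id > 0.70
            assert mine == oracle, f"instance {i}"

    def test_missing_protein_errors(self):
        loci = [_loc("a", "chr1", 1000)]
        with pytest.raises(ValueError, match="missing protein"):
            detect_duplications({}, loci, [])

    def test_event_symmetry_and_bounds(self, rng):
        base = "".join(AA[i] for i in rng.integers(0, 20, 250))
        p = {
            "a": ProteinRecord("a", base),
            "b": ProteinRecord("b", mutate_to_identity(base, 0.9, rng)),
        }
        for order in (["a", "b"], ["b", "a"]):
            loci = [_loc(order[0], "chr1", 1000), _loc(order[1], "chr2", 1000)]
            events = detect_duplications(p, loci, [])
            assert len(events) == 1
            ev = events[0]
            assert ev.pair == frozenset(("a", "b"))
            assert 0 < ev.identity <= 1 and 0 < ev.coverage <= 1
            assert ev.chromosome_level


class TestFamilies:
    def test_transitive_linkage_merges(self):
        events = [_event("A", "B"), _event("B", "C")]
        fams = build_families(events)
        assert len(fams) == 1 and fams[0].members == frozenset("ABC")

    def test_disjoint_pairs_stay_separate(self):
        fams = build_families([_event("A", "B"), _event("C", "D")])
        assert sorted(sorted(f.members) for f in fams) == [["A", "B"], ["C", "D"]]

    def test_published_family_census_arithmetic(self):
        # 16 disjoint pairs plus 7 chains of >= 3 members -> 23 families
        events = [_event(f"p{i}a", f"p{i}b") for i in range(16)]
        for i in range(7):
            events += [_event(f"t{i}a", f"t{i}b"), _event(f"t{i}b", f"t{i}c")]
        fams = build_families(events)
        assert len(fams) == 23
        assert sum(1 for f in fams if len(f) == 2) == 16
        assert sum(1 for f in fams if len(f) >= 3) == 7
        assert len(fams) <= len(events)


class TestSummary:
    def test_clustered_share_uses_reduced_denominator(self):
        # 12 genes, 2 sole-location genes excluded, 8 clustered -> 80.00%
        loci = [_loc(f"g{i}", "chr1", 50_000 + i * 100_000) for i in range(8)]
        loci += [_loc("s1", "chr2", 1000), _loc("s2", "chr3", 1000)]
        loci += [
            _loc("u1", "chr4", 1000), _loc("u2", "chr4", 900_000),
        ]
        clusters = detect_clusters(loci)
        summary = summarize_architecture(loci, clusters, [])
        assert summary.n_excluded == 2
        assert summary.total_clustered == 8
        assert summary.clustered_pct == pct(8, 10)
        assert summary.table["n_genes"].sum() == summary.total_genes

    def test_duplicated_in_cluster_share_one_decimal(self):
        loci = [_loc(f"g{i}", "chr1", 50_000 + i * 100_000) for i in range(4)]
        clusters = detect_clusters(loci)
        events = [_event("g0", "g1"), _event("g2", "g3")]
        summary = summarize_architecture(loci, clusters, events)
        assert summary.dup_in_cluster_pct == 100.0

    def test_empty_genome(self):
        summary = summarize_architecture([], [], [])
        assert summary.total_genes == 0 and summary.clustered_pct == 0.0

    def test_singleton_exclusion_helper(self):
        loci = [_loc("a", "chr1", 1), _loc("b", "chr1", 500_000),
                _loc("c", "chr2", 1)]
        assert singleton_location_genes(loci) == {"c"}


def _event(a, b):
    a, b = sorted((a, b))
    return DuplicationEvent(a, b, 0.9, 0.9)
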