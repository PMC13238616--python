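import numpy as np
import pytest

from abalonepg import roh
from abalonepg.core import MISSING

import oracles
from conftest import make_gm


def _segment(sample, start, end, scaffold="s1", n=200):
    return roh.ROHSegment(sample, scaffold, start, end, n)


class TestDetectROH:
    def test_fully_homozygous_scaffold_one_segment(self):
        # 300 SNPs over 200 kb, individual 0 all hom, individual 1 het-rich
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(np.arange(1, 200_001), 300, replace=False))
        G = np.zeros((300, 2), dtype=np.int8)
        G[:, 1] = rng.integers(0, 3, 300)
        gm = make_gm(G, positions=pos, scaffold_length=200_000)
        segs = roh.detect_roh(gm)
        mine = [s for s in segs if s.sample == "ind0"]
        assert len(mine) == 1
        assert mine[0].start == pos[0] and mine[0].end == pos[-1]
        assert mine[0].n_snps == 300

    def test_forty_spread_hets_break_runs(self):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(np.arange(1, 200_001), 300, replace=False))
        G = np.zeros((300, 1), dtype=np.int8)
        G[::8, 0] = 1  # ~38 evenly spread hets
        gm = make_gm(G, positions=pos, scaffold_length=200_000)
        assert roh.detect_roh(gm) == []

    def test_segments_disjoint_and_gated(self, roh_planted):
        res, _ = roh_planted
        segs = roh.detect_roh(res.gm)
        params = roh.ROHParams()
        by_key = {}
        for s in segs:
            assert s.length_bp >= params.min_length_bp
            assert s.n_snps >= params.min_snps
            assert s.length_bp / s.n_snps <= params.min_density_bp_per_snp
            by_key.setdefault((s.sample, s.scaffold), []).append(s)
        for group in by_key.values():
            group.sort(key=lambda s: s.start)
            for a, b in zip(group, group[1:]):
                assert a.end < b.start

    def test_planted_tracts_recovered_with_window_accuracy(self, roh_planted):
        res, tracts = roh_planted
        segs = roh.detect_roh(res.gm)
        pos = res.gm.sites["pos"].to_numpy()
        scaff = res.gm.sites["scaffold"].to_numpy()
        recovered = 0
        for sample, scaffold, start, end in tracts:
            # one scanning window of slack, in bp, at the local SNP density
            local = np.sort(pos[scaff == scaffold])
            spacing = np.median(np.diff(local))
            slack = 50 * spacing
            for s in segs:
                if s.sample == sample and s.scaffold == scaffold:
                    if abs(s.start - start) <= slack and abs(s.end - end) <= slack:
                        recovered += 1
                        break
        assert recovered >= 9

    def test_short_scaffold_skipped_with_warning(self):
        gm = make_gm(np.zeros((10, 1), dtype=np.int8))
        with pytest.warns(UserWarning, match="skipped"):
            assert roh.detect_roh(gm) == []


class TestSummarize:
    def test_no_segments(self):
        out = roh.summarize_roh([], ["a"], genome_length=1_000_000)
        assert out[0].nroh == 0 and out[0].sroh_bp == 0 and out[0].froh == 0

    def test_arithmetic(self):
        segs = [_segment("a", 1, 200_000), _segment("a", 300_001, 600_000, "s2")]
        out = roh.summarize_roh(segs, ["a"], genome_length=100_000_000)
        assert out[0].sroh_bp == 500_000
        assert out[0].sroh_fraction == pytest.approx(0.005)
        assert out[0].froh == 0.0  # nothing >= 1.5 Mb

    def test_froh_counts_only_long_segments(self):
        segs = [_segment("a", 1, 2_000_000), _segment("a", 3_000_001, 3_200_000, "s2")]
        out = roh.summarize_roh(segs, ["a"], genome_length=10_000_000)
        assert out[0].froh == pytest.approx(0.2)

    def test_random_sets_match_hand_sums(self):
        rng = np.random.default_rng(5)
        samples = [f"i{k}" for k in range(4)]
        segs = []
        for _ in range(30):
            start = int(rng.integers(1, 10_000_000))
            segs.append(
                _segment(samples[rng.integers(0, 4)], start,
                         start + int(rng.integers(100_000, 500_000)))
            )
        out = {s.sample: s for s in roh.summarize_roh(segs, samples, 50_000_000)}
        for name in samples:
            mine = [s for s in segs if s.sample == name]
            assert out[name].nroh == len(mine)
            assert out[name].sroh_bp == sum(s.end - s.start + 1 for s in mine)


class TestCollapse:
    def test_identical_segments_merge(self):
        segs = [_segment("a", 100, 1000), _segment("b", 100, 1000)]
        out = roh.collapse_roh(segs)
        assert len(out) == 1
        assert out[0].carriers == ["a", "b"]
        assert (out[0].start, out[0].end) == (100, 1000)

    def test_disjoint_segments_stay_apart(self):
        out = roh.collapse_roh([_segment("a", 100, 1000), _segment("b", 5000, 9000)])
        assert len(out) == 2

    def test_chain_links_by_single_linkage(self):
        # A-B overlap 60%, B-C 60%, A-C only 20% -> one cluster
        a = _segment("a", 1, 1000)
        b = _segment("b", 401, 1400)
        c = _segment("c", 801, 1800)
        out = roh.collapse_roh([a, b, c], min_overlap=0.5)
        assert len(out) == 1
        assert oracles.collapse_partition(
            [(1, 1000), (401, 1400), (801, 1800)], 0.5
        ) == [frozenset({0, 1, 2})]

    def test_output_partitions_input(self):
        rng = np.random.default_rng(2)
        segs = []
        for k in range(40):
            start = int(rng.integers(1, 1_000_000))
            segs.append(
                _segment(f"i{k % 6}", start, start + int(rng.integers(100_000, 300_000)))
            )
        out = roh.collapse_roh(segs)
        members = [m for u in out for m in u.members]
        assert len(members) == len(segs)
        # cross-check the partition against the brute-force linkage oracle
        ordered = sorted(segs, key=lambda s: (s.scaffold, s.start, s.end, s.sample))
        expected = oracles.collapse_partition([(s.start, s.end) for s in ordered], 0.5)
        got = []
        index_of = {id(s): i for i, s in enumerate(ordered)}
        for u in out:
            got.append(frozenset(index_of[id(m)] for m in u.members))
        assert sorted(got, key=min) == sorted(expected, key=min)

    def test_order_independence(self):
        rng = np.random.default_rng(3)
        segs = []
        for k in range(20):
            start = int(rng.integers(1, 500_000))
            segs.append(_segment(f"i{k}", start, start + 150_000))
        a = roh.collapse_roh(segs)
        b = roh.collapse_roh(list(reversed(segs)))
        assert [(u.start, u.end, tuple(u.carriers)) for u in a] == [
            (u.start, u.end, tuple(u.carriers)) for u in b
        ]


class TestSharingMatrix:
    def test_one_roh_two_locations(self):
        u = roh.UniqueROH(0, "s1", 1, 1000, [], carriers=["a", "b"])
        M = roh.sharing_matrix([u], {"a": "loc1", "b": "loc2"})
        assert M.loc["loc1", "loc2"] == 1
        assert M.loc["loc1", "loc1"] == 1

    def test_no_shared_rohs_zero_offdiagonal(self):
        us = [
            roh.UniqueROH(0, "s1", 1, 1000, [], carriers=["a"]),
            roh.UniqueROH(1, "s1", 5000, 9000, [], carriers=["b"]),
        ]
        M = roh.sharing_matrix(us, {"a": "loc1", "b": "loc2"})
        assert M.loc["loc1", "loc2"] == 0

    def test_random_incidence_matches_double_loop_oracle(self):
        rng = np.random.default_rng(4)
        locations = ["loc1", "loc2", "loc3"]
        sample_loc = {f"i{k}": locations[rng.integers(0, 3)] for k in range(12)}
        uniques, carrier_lists = [], []
        for k in range(15):
            carriers = list(
                rng.choice(list(sample_loc), size=rng.integers(1, 6), replace=False)
            )
            uniques.append(roh.UniqueROH(k, "s1", 1, 1000, [], carriers=carriers))
            carrier_lists.append([sample_loc[c] for c in carriers])
        M = roh.sharing_matrix(uniques, sample_loc)
        expected = oracles.sharing_counts(carrier_lists, locations)
        np.testing.assert_allclose(M.to_numpy(), expected)
        # Gram matrix: symmetric positive semi-definite
        np.testing.assert_allclose(M.to_numpy(), M.to_numpy().T)
        assert np.linalg.eigvalsh(M.to_numpy()).min() >= -1e-9


class TestDateROH:
    @pytest.mark.parametrize(
        "length_mb,rate,expected",
        [(0.1, 1.0, 500.0), (50.0, 1.0, 1.0), (1.05, 1.0, 47.619)],
    )
    def test_formula_values(self, length_mb, rate, expected):
        assert roh.date_roh(length_mb, rate) == pytest.approx(expected, abs=0.001)

    def test_longest_observed_segment_rounds_to_48(self):
        assert round(roh.date_roh(1.05, 1.0)) == 48

    def test_strictly_decreasing_and_inverse_in_rate(self):
        lengths = np.linspace(0.1, 5.0, 20)
        ages = [roh.date_roh(l, 1.0) for l in lengths]
        assert all(a > b for a, b in zip(ages, ages[1:]))
        assert roh.date_roh(0.5, 0.5) == pytest.approx(2 * roh.date_roh(0.5, 1.0))

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            roh.date_roh(0.0, 1.0)
        with pytest.raises(ValueError):
            roh.date_roh(1.0, -1.0)
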