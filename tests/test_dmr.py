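import numpy as np
import pandas as pd
import pytest

from conftest import make_cytosine_frame, make_track
from helpers_oracles import (
    fisher_two_sided_oracle,
    interval_overlap_oracle,
    merge_oracle,
)
from epidiff.dmr import (
    DifferentialMethylation,
    DmcParams,
    DmrFilterParams,
    MergeParams,
    call_dmcs,
    filter_dmrs,
    map_dmrs_to_features,
    merge_dmcs,
    overlap_summary,
    smooth_genotype,
)
from epidiff.dmr import test_region as region_test
from epidiff.smoothing import SmoothingParams, savitzky_golay_smooth


def _dmc_frame(positions, types, context="CG", chrom="chr1"):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "context": context,
            "type": types,
            "p_value": 0.01,
            "rate_wt": 0.8,
            "rate_mut": 0.2,
            "diff": [-0.6 if t == "hypo" else 0.6 for t in types],
        }
    )


class TestSmoothGenotype:
    def test_all_zero_library(self):
        lib = make_cytosine_frame(
            [("chr1", p, "+", "CG", 0, 0) for p in range(10, 110, 10)]
        )
        (track,) = smooth_genotype([lib]).values()
        assert np.all(track.meth == 0) and np.all(track.unmeth == 0)
        assert np.all(np.isnan(track.rate))

    def test_two_identical_libraries_double_one(self):
        rng = np.random.default_rng(1)
        lib = make_cytosine_frame(
            [
                ("chr1", 10 * (i + 1), "+", "CG",
                 int(rng.integers(0, 20)), int(rng.integers(0, 20)))
                for i in range(60)
            ]
        )
        single = smooth_genotype([lib])[("chr1", "CG")]
        double = smooth_genotype([lib, lib.copy()])[("chr1", "CG")]
        np.testing.assert_allclose(double.meth, 2 * single.meth, atol=1e-9)
        np.testing.assert_allclose(double.unmeth, 2 * single.unmeth, atol=1e-9)

    def test_missing_positions_are_zero_counts(self):
        lib_a = make_cytosine_frame(
            [("chr1", p, "+", "CG", 4, 4) for p in range(10, 210, 10)]
        )
        lib_b = lib_a[lib_a.pos != 100].reset_index(drop=True)
        track = smooth_genotype([lib_a, lib_b])[("chr1", "CG")]
        # union scaffold: position 100 present, with lib_b contributing a 0
        assert 100 in track.pos
        raw_b = np.array([4.0] * 20)
        raw_b[9] = 0.0
        expected = savitzky_golay_smooth(np.full(20, 4.0)) + savitzky_golay_smooth(raw_b)
        i = list(track.pos).index(100)
        assert track.meth[i] == pytest.approx(expected[9], abs=1e-9)

    def test_spike_matches_oracle(self):
        from helpers_oracles import local_quadratic_fit_oracle

        rows = [("chr1", 10 * (i + 1), "+", "CG", 0, 0) for i in range(41)]
        rows[20] = ("chr1", 210, "+", "CG", 11, 0)
        lib = make_cytosine_frame(rows)
        track = smooth_genotype([lib])[("chr1", "CG")]
        spike = np.zeros(41)
        spike[20] = 11.0
        np.testing.assert_allclose(
            track.meth, local_quadratic_fit_oracle(spike), atol=1e-9
        )

    def test_differing_chrom_sets_warn(self):
        lib_a = make_cytosine_frame([("chr1", 10, "+", "CG", 1, 1)])
        lib_b = make_cytosine_frame([("chr2", 10, "+", "CG", 1, 1)])
        with pytest.warns(UserWarning, match="union"):
            tracks = smooth_genotype([lib_a, lib_b])
        assert set(tracks) == {("chr1", "CG"), ("chr2", "CG")}


class TestCallDmcs:
    def test_strong_hypo(self):
        wt = make_track("wt", "CG", [100], [10.0], [0.0])
        mut = make_track("mut", "CG", [100], [0.0], [10.0])
        dmcs = call_dmcs(wt, mut)
        assert len(dmcs) == 1
        d = dmcs.iloc[0]
        assert d.type == "hypo"
        assert d["diff"] == pytest.approx(-1.0)
        assert d.p_value == pytest.approx(2 / 184756, abs=1e-12)

    def test_identical_tracks_silent(self):
        t = make_track("wt", "CG", [100, 200], [5.0, 5.0], [5.0, 5.0])
        assert call_dmcs(t, t).empty

    def test_small_rate_shift_excluded_despite_tiny_p(self):
        # 0.50 vs 0.58: |diff| = 0.08 <= 0.1, excluded by the strict rule
        wt = make_track("wt", "CG", [100], [500.0], [500.0])
        mut = make_track("mut", "CG", [100], [580.0], [420.0])
        assert fisher_two_sided_oracle(580, 420, 500, 500) < 0.01
        assert call_dmcs(wt, mut).empty

    def test_zero_coverage_skipped(self):
        wt = make_track("wt", "CG", [100, 200], [0.0, 8.0], [0.0, 0.0])
        mut = make_track("mut", "CG", [100, 200], [0.0, 0.0], [9.0, 8.0])
        dmcs = call_dmcs(wt, mut)
        assert list(dmcs.pos) == [200]

    def test_rounding_feeds_exact_test(self):
        # smoothed (10.4, 0.3) vs (0.4, 10.3) rounds to (10,0) vs (0,10)
        wt = make_track("wt", "CG", [50], [10.4], [0.3])
        mut = make_track("mut", "CG", [50], [0.4], [10.3])
        d = call_dmcs(wt, mut).iloc[0]
        assert d.p_value == pytest.approx(2 / 184756, abs=1e-12)


class TestMergeDmcs:
    def test_chain_within_gap(self):
        dmcs = _dmc_frame([100, 200, 280], ["hypo"] * 3)
        regions = merge_dmcs(dmcs, "CG")
        assert len(regions) == 1
        r = regions.iloc[0]
        assert (r.start, r.end, r.n_dmcs) == (100, 280, 3)

    def test_opposite_type_blocks(self):
        dmcs = _dmc_frame([100, 150, 220], ["hypo", "hyper", "hypo"])
        regions = merge_dmcs(dmcs, "CG")
        assert len(regions) == 3
        assert all(regions.n_dmcs == 1)

    def test_strict_gap_ceiling(self):
        dmcs = _dmc_frame([100, 171], ["hypo", "hypo"], context="CHH")
        regions = merge_dmcs(dmcs, "CHH")  # gap 71 > 70
        assert len(regions) == 2
        at_gap = merge_dmcs(_dmc_frame([100, 170], ["hypo"] * 2, context="CHH"), "CHH")
        assert len(at_gap) == 1

    def test_unsorted_rejected(self):
        dmcs = _dmc_frame([200, 100], ["hypo", "hypo"])
        with pytest.raises(ValueError, match="sorted"):
            merge_dmcs(dmcs, "CG")

    @pytest.mark.parametrize("context,gap", [("CG", 160), ("CHG", 240), ("CHH", 70)])
    def test_random_configs_match_union_find_oracle(self, context, gap):
        rng = np.random.default_rng(17)
        for _ in range(300):
            k = int(rng.integers(1, 7))
            positions = sorted(rng.choice(np.arange(1, 501), size=k, replace=False))
            types = list(rng.choice(["hyper", "hypo"], size=k))
            got = merge_dmcs(_dmc_frame(positions, types, context=context), context)
            want = merge_oracle([int(p) for p in positions], types, gap)
            got_set = sorted(
                (int(r.start), int(r.end), r.type, int(r.n_dmcs))
                for r in got.itertuples()
            )
            assert got_set == want


class TestTestRegion:
    def test_extreme_difference(self):
        wt = make_track("wt", "CG", [100, 150, 200], [10.0] * 3, [0.0] * 3)
        mut = make_track("mut", "CG", [100, 150, 200], [0.0] * 3, [10.0] * 3)
        res = region_test(100, 200, wt, mut)
        assert res["p_value"] == pytest.approx(2 / 184756, abs=1e-12)
        assert res["diff"] == pytest.approx(-1.0)

    def test_identical_tracks(self):
        t = make_track("wt", "CG", [100, 150], [5.0, 7.0], [5.0, 3.0])
        res = region_test(100, 150, t, t)
        assert res["p_value"] == 1.0
        assert res["diff"] == pytest.approx(0.0)

    def test_half_to_even_rounding_of_averages(self):
        # WT averages (4.5, 5.5) must enter the test as (4, 6)
        wt = make_track("wt", "CG", [10, 20], [4.0, 5.0], [5.0, 6.0])
        mut = make_track("mut", "CG", [10, 20], [9.0, 9.0], [1.0, 1.0])
        res = region_test(10, 20, wt, mut)
        assert res["p_value"] == pytest.approx(
            fisher_two_sided_oracle(9, 1, 4, 6), abs=1e-12
        )

    def test_zero_coverage_region(self):
        z = make_track("wt", "CG", [10], [0.2], [0.2])
        res = region_test(10, 10, z, z)
        assert res["p_value"] == 1.0


class TestFilterDmrs:
    def _candidate(self, **kw):
        base = dict(
            chrom="chr1", start=100, end=400, context="CG", type="hypo",
            n_dmcs=6, rate_wt=0.8, rate_mut=0.2, p_value=1e-6, fdr=1e-4,
        )
        base["diff"] = base["rate_mut"] - base["rate_wt"]
        base.update(kw)
        return base

    def test_passing_region_kept(self):
        df = pd.DataFrame([self._candidate()])
        assert len(filter_dmrs(df)) == 1

    @pytest.mark.parametrize(
        "override",
        [
            {"n_dmcs": 4},
            {"end": 148},                      # length 49 bp
            {"fdr": 0.06},
            {"diff": -0.35, "context": "CG"},  # below the 0.40 CG threshold
        ],
    )
    def test_each_filter_rejects(self, override):
        df = pd.DataFrame([self._candidate(**override)])
        assert len(filter_dmrs(df)) == 0

    def test_chg_threshold_is_looser(self):
        df = pd.DataFrame([self._candidate(context="CHG", diff=-0.35)])
        assert len(filter_dmrs(df)) == 1


class TestOverlap:
    def _dmrs(self, intervals, context="CG", typ="hypo"):
        return pd.DataFrame(
            [
                {"chrom": "chr1", "start": s, "end": e, "context": context,
                 "type": typ, "n_dmcs": 5, "rate_wt": 0.8, "rate_mut": 0.2,
                 "diff": -0.6, "p_value": 1e-6, "fdr": 1e-4}
                for s, e in intervals
            ]
        )

    def _features(self, intervals):
        return pd.DataFrame(
            [
                {"id": f"F{i}", "chrom": "chr1", "start": s, "end": e,
                 "strand": "+", "kind": "TE", "compartment": "euchromatin"}
                for i, (s, e) in enumerate(intervals)
            ]
        )

    def test_single_nucleotide_overlap_counts(self):
        hits = map_dmrs_to_features(self._dmrs([(100, 200)]), self._features([(200, 300)]))
        assert len(hits) == 1

    def test_adjacency_is_not_overlap(self):
        hits = map_dmrs_to_features(self._dmrs([(100, 199)]), self._features([(200, 300)]))
        assert len(hits) == 0

    def test_random_pairs_match_per_base_oracle(self):
        rng = np.random.default_rng(23)
        starts = rng.integers(1, 500, size=(100, 2))
        lens = rng.integers(1, 80, size=(100, 2))
        for (s1, s2), (l1, l2) in zip(starts, lens):
            got = len(
                map_dmrs_to_features(
                    self._dmrs([(s1, s1 + l1)]), self._features([(s2, s2 + l2)])
                )
            )
            want = interval_overlap_oracle(s1, s1 + l1, s2, s2 + l2)
            assert bool(got) == want

    def test_overlap_summary_counts_features_once(self):
        dmrs = self._dmrs([(100, 200), (150, 260)])
        feats = self._features([(180, 400), (1000, 1200)])
        out = overlap_summary({"CG": dmrs}, feats)
        row = out.iloc[0]
        assert (row.n_dmrs, row.n_upregulated, row.n_overlap) == (2, 2, 1)

    def test_no_dmrs_zero_overlap(self):
        out = overlap_summary({"CG": self._dmrs([])}, self._features([(1, 10)]))
        assert out.iloc[0].n_overlap == 0


class TestModelEndToEnd:
    def test_injected_hypo_region_is_called(self):
        """A strongly hypomethylated block in an otherwise flat methylome
        is recovered as one CG hypo-DMR with sensible coordinates."""
        rng = np.random.default_rng(4)
        positions = np.sort(rng.choice(np.arange(1, 20_000), size=900, replace=False))
        inside = (positions >= 8000) & (positions <= 9000)

        def library(genotype_seed, mutated):
            r = np.random.default_rng(genotype_seed)
            cov = r.poisson(20, len(positions))
            rate = np.full(len(positions), 0.8)
            if mutated:
                rate[inside] = 0.05
            meth = r.binomial(cov, rate)
            return make_cytosine_frame(
                [
                    ("chr1", int(p), "+", "CG", int(m), int(c - m))
                    for p, m, c in zip(positions, meth, cov)
                ]
            )

        model = DifferentialMethylation(
            [library(1, False), library(2, False)],
            [library(3, True), library(4, True)],
            contexts=("CG",),
        )
        res = model.fit()
        assert len(res.dmrs) == 1
        dmr = res.dmrs.iloc[0]
        assert dmr.type == "hypo"
        assert abs(dmr.start - 8000) < 300 and abs(dmr.end - 9000) < 300
        assert dmr["diff"] < -0.4
        assert "hypo" in res.summary()

    def test_no_opposite_type_dmc_inside_dmr(self):
        """Emitted DMRs never span an opposite-type DMC."""
        rng = np.random.default_rng(8)
        positions = np.sort(rng.choice(np.arange(1, 30_000), size=1200, replace=False))

        def library(seed, shift):
            r = np.random.default_rng(seed)
            cov = r.poisson(15, len(positions))
            rate = np.clip(0.5 + shift * np.sin(positions / 500.0), 0.01, 0.99)
            meth = r.binomial(cov, rate)
            return make_cytosine_frame(
                [
                    ("chr1", int(p), "+", "CHH", int(m), int(c - m))
                    for p, m, c in zip(positions, meth, cov)
                ]
            )

        res = DifferentialMethylation(
            [library(1, 0.0), library(2, 0.0)],
            [library(3, 0.4), library(4, 0.4)],
            contexts=("CHH",),
        ).fit()
        for dmr in res.dmrs.itertuples():
            inside = res.dmcs[
                (res.dmcs.pos >= dmr.start) & (res.dmcs.pos <= dmr.end)
                & (res.dmcs.context == dmr.context)
            ]
            assert set(inside.type) <= {dmr.type}
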