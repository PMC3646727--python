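"""Postprocessing, rate matrices, decay fits, substructure, genome scan."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

import ibdhist as ih
from ibdhist.summaries import (IBDBlock, SegmentCall, _balls_in_boxes_test,
                               blocks_frame, distance_decay_fit, genome_scan,
                               great_circle_km, mann_whitney_sharing,
                               postprocess_calls, rate_matrix,
                               sharing_correlation, substructure_test)

SEG_COLS = ["sample_a", "sample_b", "chromosome", "start_cM", "end_cM",
            "score", "run_id"]


def seg(a, b, chrom, s, e, score, run):
    return (a, b, chrom, s, e, score, run)


class TestPostprocessCalls:
    def test_ten_segment_worked_example(self):
        """Hand-computed outcome of the three rules on a 10-segment fixture."""
        runs = pd.DataFrame([
            # pair s1-s2: two overlapping clusters, one merged across a gap
            seg("s1", "s2", "chr1", 0.0, 3.0, 1e-10, 1),
            seg("s1", "s2", "chr1", 0.5, 2.5, 1e-5, 2),
            seg("s1", "s2", "chr1", 3.5, 4.0, 1e-4, 1),
            seg("s1", "s2", "chr1", 3.5, 4.0, 1e-5, 2),
            # high-score cluster: survives overlap rule, fails score rule
            seg("s1", "s2", "chr1", 20.0, 21.0, 1e-3, 1),
            seg("s1", "s2", "chr1", 20.0, 21.2, 1e-4, 2),
            # single-run segments: removed by the overlap rule
            seg("s1", "s2", "chr1", 10.0, 11.0, 1e-12, 1),
            seg("s1", "s2", "chr1", 30.0, 30.5, 1e-11, 2),
            seg("s1", "s2", "chr2", 40.0, 46.0, 1e-10, 1),
            # second pair: overlapping low-score cluster kept
            seg("s3", "s4", "chr1", 5.0, 6.0, 1e-12, 1),
        ], columns=SEG_COLS)
        assert len(runs) == 10
        out = postprocess_calls(pd.concat(
            [runs, pd.DataFrame([seg("s3", "s4", "chr1", 5.5, 6.5, 1e-3, 2)],
                                columns=SEG_COLS)], ignore_index=True))
        expected = {("s1", "s2", "chr1", 0.0, 4.0),
                    ("s3", "s4", "chr1", 5.0, 6.5)}
        got = {(r.sample_a, r.sample_b, r.chromosome, r.start_cM, r.end_cM)
               for r in out.itertuples()}
        assert got == expected

    def test_gap_merge_rule(self):
        # gap 0.5 < len([0,3]) and <= 5 -> merged; low score kept
        runs = pd.DataFrame([
            seg("a", "b", "c1", 0.0, 3.0, 1e-10, 1),
            seg("a", "b", "c1", 0.0, 3.0, 1e-4, 2),
            seg("a", "b", "c1", 3.5, 4.0, 1e-4, 1),
            seg("a", "b", "c1", 3.5, 4.0, 1e-4, 2),
        ], columns=SEG_COLS)
        out = postprocess_calls(runs)
        assert len(out) == 1
        assert (out.start_cM[0], out.end_cM[0]) == (0.0, 4.0)

    def test_long_gap_not_merged(self):
        # gap 6 > 5 cM: never merged regardless of lengths
        runs = pd.DataFrame([
            seg("a", "b", "c1", 0.0, 10.0, 1e-10, 1),
            seg("a", "b", "c1", 0.0, 10.0, 1e-10, 2),
            seg("a", "b", "c1", 16.0, 26.0, 1e-10, 1),
            seg("a", "b", "c1", 16.0, 26.0, 1e-10, 2),
        ], columns=SEG_COLS)
        assert len(postprocess_calls(runs)) == 2

    def test_identical_segment_two_runs_unchanged(self):
        runs = pd.DataFrame([
            seg("a", "b", "c1", 1.0, 4.0, 1e-12, 1),
            seg("a", "b", "c1", 1.0, 4.0, 1e-12, 2),
        ], columns=SEG_COLS)
        out = postprocess_calls(runs)
        assert len(out) == 1
        assert (out.start_cM[0], out.end_cM[0]) == (1.0, 4.0)

    def test_single_run_errors(self):
        runs = pd.DataFrame([seg("a", "b", "c1", 0.0, 2.0, 1e-10, 1)],
                            columns=SEG_COLS)
        with pytest.raises(ValueError, match=">= 2 runs"):
            postprocess_calls(runs)

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(2)
        rows = []
        for r in (1, 2, 3):
            for i in range(30):
                s = rng.uniform(0, 200)
                rows.append(seg("a", "b", "c1", s, s + rng.uniform(0.5, 8),
                                10.0 ** -rng.uniform(3, 13), r))
        out1 = postprocess_calls(pd.DataFrame(rows, columns=SEG_COLS))
        # feed the output back as two identical runs
        again = pd.concat([out1.assign(run_id=1), out1.assign(run_id=2)],
                          ignore_index=True)
        out2 = postprocess_calls(again)
        pd.testing.assert_frame_equal(
            out1.sort_values(["start_cM"]).reset_index(drop=True)[
                ["sample_a", "sample_b", "chromosome", "start_cM", "end_cM"]],
            out2.sort_values(["start_cM"]).reset_index(drop=True)[
                ["sample_a", "sample_b", "chromosome", "start_cM", "end_cM"]])


class TestRateMatrix:
    def test_no_blocks_all_zero(self):
        pops = pd.DataFrame({"sample": list("abcd"),
                             "population": ["X", "X", "Y", "Y"]})
        rm = rate_matrix(pd.DataFrame(columns=blocks_frame.__defaults__ or
                                      ["sample_a", "sample_b", "chromosome",
                                       "start_cM", "end_cM"]), pops)
        assert np.nansum(rm.rates) == 0.0

    def test_cross_pair_denominator(self):
        pops = pd.DataFrame({"sample": ["a1", "a2", "b1", "b2", "b3"],
                             "population": ["A", "A", "B", "B", "B"]})
        blocks = pd.DataFrame(
            [(f"a{i % 2 + 1}", f"b{i % 3 + 1}", "c1", 0.0, 2.0)
             for i in range(6)],
            columns=["sample_a", "sample_b", "chromosome", "start_cM", "end_cM"])
        rm = rate_matrix(blocks, pops)
        assert rm.rate("A", "B") == 1.0
        assert rm.rate("B", "A") == 1.0  # symmetric

    def test_singleton_population_within_rate_missing(self):
        pops = pd.DataFrame({"sample": ["a1", "b1", "b2"],
                             "population": ["A", "B", "B"]})
        rm = rate_matrix(pd.DataFrame(columns=["sample_a", "sample_b",
                                               "chromosome", "start_cM",
                                               "end_cM"]), pops)
        assert np.isnan(rm.rate("A", "A"))
        assert rm.rate("B", "B") == 0.0

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(11)
        samples = [f"s{i}" for i in range(12)]
        popof = {s: rng.choice(["P", "Q", "R"]) for s in samples}
        pops = pd.DataFrame({"sample": samples,
                             "population": [popof[s] for s in samples]})
        rows = []
        for _ in range(200):
            a, b = rng.choice(samples, 2, replace=False)
            start = rng.uniform(0, 100)
            rows.append((a, b, "c1", start, start + rng.uniform(0.5, 12)))
        blocks = pd.DataFrame(rows, columns=["sample_a", "sample_b",
                                             "chromosome", "start_cM", "end_cM"])
        classes = [(1.0, 4.0), (4.0, np.inf)]
        rm = rate_matrix(blocks, pops, length_classes=classes)
        # O(n^2) oracle
        for k, (lo, hi) in enumerate(classes):
            for x in "PQR":
                for y in "PQR":
                    total = 0
                    for r in blocks.itertuples():
                        ln = r.end_cM - r.start_cM
                        if not (lo <= ln < hi):
                            continue
                        pa, pb = popof[r.sample_a], popof[r.sample_b]
                        if {pa, pb} == {x, y} or (x == y and pa == pb == x):
                            total += 1
                    nx = sum(1 for s in samples if popof[s] == x)
                    ny = sum(1 for s in samples if popof[s] == y)
                    denom = nx * (nx - 1) / 2 if x == y else nx * ny
                    assert rm.rate(x, y, k) == pytest.approx(total / denom)
        # totals conserved across classes
        assert int(sum((rm.rates[k] * rm.pair_counts)[np.triu_indices(3)].sum()
                       for k in range(2))) == \
            int(((blocks.end_cM - blocks.start_cM) >= 1.0).sum())


class TestSharingCorrelation:
    @staticmethod
    def _rm_from_matrix(I):
        P = I.shape[0]
        return ih.RateMatrix(tuple(f"p{i}" for i in range(P)),
                             ((1.0, np.inf),), I[None], np.ones((P, P)))

    def test_identical_profiles_correlate_fully(self):
        I = np.array([[1.0, 0.5, 0.3, 0.2, 0.7],
                      [0.5, 1.0, 0.3, 0.2, 0.7],
                      [0.3, 0.3, 2.0, 0.9, 0.1],
                      [0.2, 0.2, 0.9, 1.5, 0.4],
                      [0.7, 0.7, 0.1, 0.4, 1.0]])
        C = sharing_correlation(self._rm_from_matrix(I))
        # populations 0 and 1 share identical profiles over the others
        assert C.iloc[0, 1] == pytest.approx(1.0)

    def test_matches_direct_pearson(self):
        rng = np.random.default_rng(3)
        I = rng.random((6, 6))
        I = (I + I.T) / 2
        C = sharing_correlation(self._rm_from_matrix(I))
        for i in range(6):
            for j in range(i + 1, 6):
                mask = np.ones(6, bool)
                mask[[i, j]] = False
                expect = np.corrcoef(I[i, mask], I[j, mask])[0, 1]
                assert C.iloc[i, j] == pytest.approx(expect)

    def test_too_few_populations(self):
        with pytest.raises(ValueError):
            sharing_correlation(self._rm_from_matrix(np.eye(3)))


class TestDistanceDecay:
    def test_recovers_generating_decay(self):
        """Rates generated exactly as a*exp(-b d) with huge weights recover
        (a, b) within 1%."""
        rng = np.random.default_rng(8)
        P = 10
        names = tuple(f"p{i}" for i in range(P))
        coords = pd.DataFrame({"population": names,
                               "lon": rng.uniform(0, 25, P),
                               "lat": rng.uniform(40, 55, P)})
        loc = {r.population: (r.lon, r.lat) for r in coords.itertuples()}
        a_true, b_true = 1.4, 1.1e-3
        I = np.zeros((P, P))
        for i in range(P):
            for j in range(P):
                d = great_circle_km(*loc[names[i]], *loc[names[j]])
                I[i, j] = a_true * np.exp(-b_true * d)
        rm = ih.RateMatrix(names, ((1.0, np.inf),), I[None],
                           np.full((P, P), 1e7))
        res = distance_decay_fit(rm, coords, lambda x, y: "all")
        assert np.exp(res.loc["all", "intercept"]) == pytest.approx(a_true,
                                                                    rel=0.01)
        assert res.loc["all", "decay_per_km"] == pytest.approx(b_true, rel=0.01)

    def test_constant_rates_no_decay(self):
        rng = np.random.default_rng(9)
        P = 6
        names = tuple(f"p{i}" for i in range(P))
        coords = pd.DataFrame({"population": names,
                               "lon": rng.uniform(0, 25, P),
                               "lat": rng.uniform(40, 55, P)})
        rm = ih.RateMatrix(names, ((1.0, np.inf),),
                           np.full((1, P, P), 0.8), np.full((P, P), 1e6))
        res = distance_decay_fit(rm, coords, lambda x, y: "all")
        assert abs(res.loc["all", "decay_per_km"]) < 1e-5

    def test_great_circle_basics(self):
        assert great_circle_km(10.0, 50.0, 10.0, 50.0) == 0.0
        # one degree of latitude is ~111 km
        assert great_circle_km(0.0, 0.0, 0.0, 1.0) == pytest.approx(111.2,
                                                                    abs=0.5)


class TestSubstructure:
    @staticmethod
    def _fixture(counts_per_member, pop_y_size=3):
        members = [f"x{i}" for i in range(len(counts_per_member))]
        others = [f"y{i}" for i in range(pop_y_size)]
        pops = pd.DataFrame({
            "sample": members + others,
            "population": ["X"] * len(members) + ["Y"] * len(others)})
        rows = []
        for m, c in zip(members, counts_per_member):
            for _ in range(c):
                rows.append((m, "y0", "c1", 0.0, 2.0))
        blocks = pd.DataFrame(rows, columns=["sample_a", "sample_b",
                                             "chromosome", "start_cM",
                                             "end_cM"])
        return blocks, pops

    def test_extreme_concentration_hits_minimum_p(self):
        blocks, pops = self._fixture([60, 0, 0, 0, 0, 0])
        r = substructure_test(blocks, pops, "X", "Y", n_perm=1000, seed=0)
        assert r.p_value == pytest.approx(1 / 1001)
        assert r.z_score > 5

    def test_no_blocks(self):
        blocks, pops = self._fixture([0, 0, 0])
        r = substructure_test(blocks, pops, "X", "Y", seed=0)
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_seed_reproducible(self):
        blocks, pops = self._fixture([5, 3, 2, 8])
        a = substructure_test(blocks, pops, "X", "Y", seed=42)
        b = substructure_test(blocks, pops, "X", "Y", seed=42)
        assert a == b

    def test_null_p_values_uniform(self):
        """Permutation p-values are calibrated under multinomial-uniform
        sharing."""
        rng = np.random.default_rng(123)
        m = 20
        ps = []
        for _ in range(300):
            k = int(rng.integers(80, 300))
            counts = rng.multinomial(k, np.full(m, 1.0 / m))
            _, p, _ = _balls_in_boxes_test(counts, 1000, rng)
            ps.append(p)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_small_population_errors(self):
        blocks, pops = self._fixture([3])
        with pytest.raises(ValueError, match=">= 2 members"):
            substructure_test(blocks, pops, "X", "Y", seed=0)


class TestGenomeScan:
    def test_uniform_coverage_near_zero_scores(self):
        rng = np.random.default_rng(5)
        pos = {"c1": np.sort(rng.uniform(0, 200, 5000))}
        rows = []
        for _ in range(3000):  # uniform blocks everywhere
            s = rng.uniform(-10, 200)
            rows.append(("a", "b", "c1", s, s + rng.uniform(1.1, 2.2)))
        blocks = pd.DataFrame(rows, columns=["sample_a", "sample_b",
                                             "chromosome", "start_cM",
                                             "end_cM"])
        df = genome_scan(blocks, pos, length_cuts=(1.0, 2.5))
        z = df["z_1.0_2.5"].to_numpy()
        assert abs(z.mean()) < 1e-9
        assert z.std(ddof=1) == pytest.approx(1.0)
        assert np.abs(z).max() < 6  # no spurious extreme site

    def test_planted_anomaly_localizes(self):
        rng = np.random.default_rng(6)
        pos = {"c1": np.linspace(0, 100, 2000)}
        rows = []
        for _ in range(800):
            s = rng.uniform(0, 99)
            rows.append(("a", "b", "c1", s, s + 1.5))
        for _ in range(800):  # doubled coverage in [40, 50]
            s = rng.uniform(40, 48.5)
            rows.append(("a", "b", "c1", s, s + 1.5))
        blocks = pd.DataFrame(rows, columns=["sample_a", "sample_b",
                                             "chromosome", "start_cM",
                                             "end_cM"])
        df = genome_scan(blocks, pos, length_cuts=(1.0, 2.5))
        top = df.nlargest(50, "z_1.0_2.5")["pos_cM"]
        assert ((top >= 39) & (top <= 51)).all()

    def test_sparse_chromosome_skipped(self):
        with pytest.warns(UserWarning, match="skipped"):
            df = genome_scan(pd.DataFrame(columns=["sample_a", "sample_b",
                                                   "chromosome", "start_cM",
                                                   "end_cM"]),
                             {"c1": np.linspace(0, 10, 100), "c2": [1.0]})
        assert set(df["chromosome"]) == {"c1"}


def test_block_record_validation():
    with pytest.raises(ValueError):
        IBDBlock("a", "a", "c1", 0.0, 1.0)
    with pytest.raises(ValueError):
        IBDBlock("a", "b", "c1", 2.0, 1.0)
    with pytest.raises(ValueError):
        SegmentCall("a", "b", "c1", 0.0, 1.0, score=0.0, run_id=1)
    assert SegmentCall("a", "b", "c1", 0.0, 1.0, score=1e-5, run_id=1).length == 1.0


def test_mann_whitney_thin_wrapper():
    rng = np.random.default_rng(0)
    res = mann_whitney_sharing(rng.poisson(3.0, 200), rng.poisson(4.5, 200))
    assert res.pvalue < 0.01
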