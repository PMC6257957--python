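"""Contact calling: background model, Poisson/binomial calls, annotation,
bootstrap enrichment, and proportion tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hicsqueeze import GenomeBinning, make_truth, simulate_map
from hicsqueeze import contacts as ct
from hicsqueeze.compartments import CompartmentProfile
from hicsqueeze.matrix import downsample_to_common_total
from hicsqueeze.synth import BASELINE, CONSTRICTED, TruthConfig


def toy_windowed(counts: np.ndarray, chrom="chr1", step=ct.STEP) -> ct.WindowedMap:
    nw = counts.shape[0]
    binning = GenomeBinning({chrom: step * (nw - 1) + ct.WINDOW}, 20_000)
    starts = np.arange(nw) * step
    return ct.WindowedMap(binning, {chrom: starts}, {chrom: counts.astype(float)},
                          int(np.triu(counts).sum()))


def truth_profile(truth, cond=BASELINE):
    binning = truth.binning
    return CompartmentProfile(
        binning,
        {c: np.where(truth.labels[cond][c] == "A", 1.0, -1.0) for c in binning.chroms},
        {c: truth.labels[cond][c].copy() for c in binning.chroms},
        {c: 1.0 for c in binning.chroms}, {c: False for c in binning.chroms},
        {c: False for c in binning.chroms})


class TestExpectedBackground:
    def test_matches_direct_formula_on_toy(self, rng):
        k = rng.integers(1, 50, (10, 10)).astype(float)
        k = (k + k.T) / 2
        wmap = toy_windowed(k)
        e = ct.expected_background(wmap)["chr1"]
        # direct formula: p(d) over diagonals, c_i marginal shares, scaled to T
        nw = 10
        p = np.array([np.diagonal(k, offset=d).mean() for d in range(nw)])
        marg = k.sum(axis=1)
        c = marg / marg.sum()
        d = np.abs(np.subtract.outer(np.arange(nw), np.arange(nw)))
        e0 = p[d] * np.outer(c, c)
        t = np.triu(k).sum()
        expect = e0 * t / np.triu(e0).sum()
        assert np.allclose(e, expect, atol=1e-10)

    def test_sum_matches_total(self, rng):
        k = rng.integers(0, 30, (15, 15)).astype(float)
        k = (k + k.T) / 2
        wmap = toy_windowed(k)
        e = ct.expected_background(wmap)["chr1"]
        assert np.triu(e).sum() == pytest.approx(np.triu(k).sum(), rel=1e-6)

    def test_uniform_map_uniform_within_diagonal(self):
        wmap = toy_windowed(np.full((12, 12), 8.0))
        e = ct.expected_background(wmap)["chr1"]
        for d in range(1, 12):
            diag = np.diagonal(e, offset=d)
            assert np.allclose(diag, diag[0])


class TestCallSignificant:
    def test_obs_equal_expected_no_calls(self):
        k = np.full((20, 20), 10.0)
        wmap = toy_windowed(k)
        e = {"chr1": k.copy()}
        calls = ct.call_significant(wmap, expected=e)
        assert len(calls) == 0

    def test_closed_form_poisson_tail_survives_bh(self):
        # one pair at obs = 10*E with E = 5 among ~100 null pairs
        rng = np.random.default_rng(3)
        nw = 16
        e_val = 5.0
        k = rng.poisson(e_val, (nw, nw)).astype(float)
        k = np.triu(k) + np.triu(k, 1).T
        k[2, 10] = k[10, 2] = 50.0
        wmap = toy_windowed(k)
        calls = ct.call_significant(wmap, expected={"chr1": np.full((nw, nw), e_val)})
        hit = calls[(calls["start1"] == 2 * ct.STEP) & (calls["start2"] == 10 * ct.STEP)]
        assert len(hit) == 1
        assert hit["p"].iloc[0] == pytest.approx(sps.poisson.sf(49, 5.0), rel=1e-10)

    def test_null_calibration_fraction_below_fdr(self):
        cfg = TruthConfig(chrom_lengths=(("chr1", 15_000_000),), kappa=1.0, tau=1.0,
                          flip_fraction=0.0, boundary_deletion_fraction=0.0,
                          delta=1.0, n_genes=500, set_sizes=(10, 10, 10))
        fracs = []
        for seed in range(5):
            t = make_truth(cfg, seed=seed)
            m = simulate_map(t, BASELINE, 1_000_000, seed=seed, binsize=20_000)
            w = ct.window_counts(m)
            calls = ct.call_significant(w)
            fracs.append(len(calls) / calls.attrs["n_pairs"])
        assert max(fracs) <= 0.05

    def test_bh_monotone_before_suppression(self, rng):
        k = rng.poisson(6, (40, 40)).astype(float)
        k = np.triu(k) + np.triu(k, 1).T
        wmap = toy_windowed(k)
        loose = ct.call_significant(wmap, fdr_threshold=0.5, suppress=False)
        tight = ct.call_significant(wmap, fdr_threshold=0.1, suppress=False)
        keys_loose = set(zip(loose["start1"], loose["start2"]))
        keys_tight = set(zip(tight["start1"], tight["start2"]))
        assert keys_tight <= keys_loose

    def test_nms_removes_overlapping_windows(self):
        nw = 20
        k = np.full((nw, nw), 4.0)
        # two overlapping strong pairs 40 kb apart; the stronger survives
        k[2, 12] = k[12, 2] = 60.0
        k[3, 13] = k[13, 3] = 50.0
        wmap = toy_windowed(k)
        calls = ct.call_significant(wmap, expected={"chr1": np.full((nw, nw), 4.0)})
        starts = set(zip(calls["start1"], calls["start2"]))
        assert (2 * ct.STEP, 12 * ct.STEP) in starts
        assert (3 * ct.STEP, 13 * ct.STEP) not in starts


class TestDifferential:
    def test_identical_maps_no_calls(self, rng):
        k = rng.poisson(20, (25, 25)).astype(float)
        k = np.triu(k) + np.triu(k, 1).T
        wmap = toy_windowed(k)
        universe = ct.call_significant(wmap, expected={"chr1": np.full((25, 25), 15.0)})
        if len(universe) == 0:
            pytest.skip("no universe")
        diff = ct.differential_contacts(wmap, wmap, universe)
        assert (diff["direction"] == "ns").all()

    def test_binomial_closed_form_with_symmetric_profiles(self):
        nw = 20
        base = np.full((nw, nw), 10.0)
        ka, kb = base.copy(), base.copy()
        # swapped pairs at the same separation keep decay profiles equal
        ka[1, 8], kb[1, 8] = 20.0, 5.0
        ka[2, 9], kb[2, 9] = 5.0, 20.0
        ka, kb = (np.triu(m, 1) + np.triu(m, 1).T + np.diag(np.diag(base))
                  for m in (ka, kb))
        wa, wb = toy_windowed(ka), toy_windowed(kb)
        universe = pd.DataFrame({"chrom": "chr1", "start1": [1 * ct.STEP, 2 * ct.STEP],
                                 "start2": [8 * ct.STEP, 9 * ct.STEP],
                                 "sep": [7 * ct.STEP, 7 * ct.STEP],
                                 "observed": [20.0, 5.0], "expected": [10.0, 10.0],
                                 "p": 0.5, "fdr": 0.5})
        diff = ct.differential_contacts(wa, wb, universe)
        assert diff["q_null"].iloc[0] == pytest.approx(0.5)
        expect = 2 * sps.binom.sf(19, 25, 0.5)
        assert diff["p_diff"].iloc[0] == pytest.approx(expect, rel=1e-10)

    def test_swap_negates_logfc_and_directions(self, truth):
        m20 = {c: simulate_map(truth, c, 1_500_000, seed=k, binsize=20_000)
               for k, c in enumerate((BASELINE, CONSTRICTED))}
        ma, mb = downsample_to_common_total(list(m20.values()), seed=5)
        wa, wb = ct.window_counts(ma), ct.window_counts(mb)
        universe = ct.call_significant(ct.pooled_windowed(wa, wb))
        d1 = ct.differential_contacts(wa, wb, universe)
        d2 = ct.differential_contacts(wb, wa, universe)
        assert np.allclose(d1["logfc_norm"], -d2["logfc_norm"], atol=1e-12)
        assert np.array_equal(d1["direction"] == "decreased", d2["direction"] == "increased")


class TestRangeProportion:
    def test_balanced_calls_flat(self):
        calls = pd.DataFrame({"sep": [200_000] * 100,
                              "direction": ["decreased"] * 50 + ["increased"] * 50})
        res = ct.range_proportion_test(calls)
        assert res["short"].pvalue > 0.9

    def test_matches_hand_computed_chi2(self):
        calls = pd.DataFrame({"sep": [500_000] * 40,
                              "direction": ["decreased"] * 30 + ["increased"] * 10})
        res = ct.range_proportion_test(calls)["short"]
        # (|30-20| - .5)^2 / 10 = 9.025
        assert res.statistic == pytest.approx(9.025, abs=1e-10)


class TestAnnotate:
    def test_planted_labels_recovered(self, truth):
        calls = pd.DataFrame({"chrom": "chr1",
                              "start1": [0, 0], "start2": [200_000, 500_000],
                              "sep": [200_000, 500_000]})
        prof = truth_profile(truth)
        act = truth.active_bins()
        ann = ct.annotate_contacts(calls, prof, act)
        lab = truth.labels[BASELINE]["chr1"]
        assert ann["comp1"].iloc[0] == lab[0]
        assert ann["comp2"].iloc[1] == lab[5]

    def test_mixed_and_masked(self):
        binning = GenomeBinning({"chr1": 2_000_000}, 100_000)
        labels = np.array(["A", "B"] + [""] * 18, dtype="<U1")
        prof = CompartmentProfile(binning, {"chr1": np.where(labels == "A", 1.0, -1.0)},
                                  {"chr1": labels}, {"chr1": 1.0},
                                  {"chr1": False}, {"chr1": False})
        act = {"chr1": np.zeros(20, dtype=bool)}
        calls = pd.DataFrame({"chrom": "chr1", "start1": [0, 0],
                              "start2": [100_000, 300_000],
                              "sep": [100_000, 300_000]})
        ann = ct.annotate_contacts(calls, prof, act)
        assert ann["compartment"].tolist() == ["mixed", "masked"]


class TestBootstrap:
    def _annotated(self, rng, n=400, b_prop=0.5, sep_range=(150_000, 900_000)):
        seps = rng.integers(*sep_range, n)
        comp = np.where(rng.random(n) < b_prop, "B", "A")
        return pd.DataFrame({"sep": seps, "compartment": comp})

    def test_degenerate_single_label_pool(self, rng):
        total = pd.DataFrame({"sep": [200_000] * 50, "compartment": ["A"] * 50})
        disrupted = total.iloc[:10]
        out = ct.bootstrap_proportions(total, disrupted, n_boot=500, seed=1)
        row = out.iloc[0]
        assert row["ci_lo"] == row["ci_hi"] == 0.0
        assert not row["b_enriched"] and not row["b_depleted"]

    def test_random_subsample_mostly_inside_ci(self, rng):
        total = self._annotated(rng, n=600)
        inside = 0
        reps = 60
        for seed in range(reps):
            sub_rng = np.random.default_rng(1000 + seed)
            disrupted = total.iloc[sub_rng.choice(600, 150, replace=False)]
            out = ct.bootstrap_proportions(total, disrupted, n_boot=2_000, seed=seed)
            inside += bool((~out["b_enriched"] & ~out["b_depleted"]).all())
        assert inside / reps >= 0.9

    def test_reproducible_and_ci_shrinks_with_n(self, rng):
        total = self._annotated(rng, n=2_000)
        small = total.iloc[:40]
        big = total.iloc[:1_000]
        a = ct.bootstrap_proportions(total, small, seed=3)
        b = ct.bootstrap_proportions(total, small, seed=3)
        pd.testing.assert_frame_equal(a, b)
        wide = (a["ci_hi"] - a["ci_lo"]).mean()
        narrow_tbl = ct.bootstrap_proportions(total, big, seed=3)
        narrow = (narrow_tbl["ci_hi"] - narrow_tbl["ci_lo"]).mean()
        assert narrow < wide


class TestActivityDifference:
    def _table(self, n, active_frac, comp="B", sep=300_000):
        rng = np.random.default_rng(0)
        return pd.DataFrame({"sep": [sep] * n, "compartment": [comp] * n,
                             "active": rng.random(n) < active_frac})

    def test_disrupted_equal_total_flat(self):
        total = self._table(500, 0.4)
        res = ct.activity_difference(total, total, "B")["short"]
        assert res.aux["diff"] == 0.0
        assert res.pvalue > 0.9

    def test_invalid_compartment_rejected(self):
        t = self._table(10, 0.5)
        with pytest.raises(ValueError):
            ct.activity_difference(t, t, "C")

    def test_null_pvalues_not_anticonservative(self):
        # activity independent of disruption: at alpha=0.05 the rejection
        # rate stays at or below the nominal level (continuity correction
        # makes the test slightly conservative)
        rejections = 0
        reps = 200
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            n = 800
            total = pd.DataFrame({"sep": [300_000] * n, "compartment": ["B"] * n,
                                  "active": rng.random(n) < 0.4})
            disrupted = total.iloc[rng.choice(n, 200, replace=False)]
            res = ct.activity_difference(total, disrupted, "B")["short"]
            rejections += res.pvalue < 0.05
        assert rejections / reps <= 0.06
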