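"""TAD calling, conservation scoring, and TAD-level statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hicsqueeze import GenomeBinning, make_truth, simulate_map
from hicsqueeze import domains as dm
from hicsqueeze.compartments import CompartmentProfile
from hicsqueeze.matrix import ContactMap, ice_balance
from hicsqueeze.synth import BASELINE, CONSTRICTED, TruthConfig

from conftest import bal_from_dense


def _binning(n, bs=50_000):
    return GenomeBinning({"chr1": n * bs}, bs)


def diamond_oracle(m, i, w):
    """Brute-force diamond mean: entries (u,v), i-w+1 <= u <= i < v <= i+w."""
    vals = []
    n = m.shape[0]
    for u in range(max(0, i - w + 1), i + 1):
        for v in range(i + 1, min(i + w, n - 1) + 1):
            if np.isfinite(m[u, v]):
                vals.append(m[u, v])
    return np.mean(vals) if vals else np.nan


def two_block_matrix(n=40, split=20, tau=2.0, alpha=1.0):
    sep = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    block = np.equal.outer(np.arange(n) >= split, np.arange(n) >= split)
    return (sep + 1.0) ** (-alpha) * np.where(block, tau, 1.0) * 1000


class TestBinSignal:
    def test_uniform_matrix_constant_signal(self):
        bal = bal_from_dense(_binning(30), {"chr1": np.ones((30, 30))})
        sig = dm.bin_signal(bal)["chr1"]
        fin = np.isfinite(sig)
        assert np.allclose(sig[fin], 1.0)

    def test_two_blocks_minimum_at_junction(self):
        bal = bal_from_dense(_binning(40), {"chr1": two_block_matrix()})
        sig = dm.bin_signal(bal)["chr1"]
        interior = slice(5, 35)
        assert np.nanargmin(sig[interior]) + 5 == 19  # last bin of block 1

    def test_matches_brute_force_diamond_means(self, rng):
        m = rng.poisson(20, (30, 30)).astype(float)
        m = np.triu(m) + np.triu(m, 1).T
        bal = bal_from_dense(_binning(30), {"chr1": m})
        sig = dm.bin_signal(bal, w=5)["chr1"]
        dense = bal.balanced_dense("chr1")
        for i in range(30):
            expect = diamond_oracle(dense, i, 5)
            if np.isnan(expect):
                assert np.isnan(sig[i])
            else:
                assert sig[i] == pytest.approx(expect, abs=1e-12)

    def test_rejects_small_w_or_chrom(self):
        bal = bal_from_dense(_binning(30), {"chr1": np.ones((30, 30))})
        with pytest.raises(ValueError):
            dm.bin_signal(bal, w=1)
        tiny = bal_from_dense(_binning(8), {"chr1": np.ones((8, 8))})
        with pytest.raises(ValueError):
            dm.bin_signal(tiny)


class TestCallTads:
    def test_single_planted_boundary_gives_two_domains(self, rng):
        base = two_block_matrix(n=60, split=30)
        noisy = rng.poisson(base).astype(float)
        noisy = np.triu(noisy) + np.triu(noisy, 1).T
        cmap = ContactMap.from_dense(_binning(60), {"chr1": noisy})
        bal = ice_balance(cmap)
        tads = dm.call_tads(dm.bin_signal(bal), bal)
        assert len(tads.domains) == 2
        assert abs(int(tads.boundaries["pos"].iloc[0]) - 30 * 50_000) <= 50_000

    def test_uniform_matrix_rarely_fires(self):
        # flat-mean Poisson matrices at study-scale chromosome size:
        # no boundary retained in >= 95% of simulations
        fires = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            m = rng.poisson(30, (600, 600)).astype(float)
            m = np.triu(m) + np.triu(m, 1).T
            cmap = ContactMap.from_dense(_binning(600), {"chr1": m})
            bal = ice_balance(cmap)
            fires += len(dm.call_tads(dm.bin_signal(bal), bal).boundaries) > 0
        assert fires <= 1

    def test_planted_boundary_recovery(self):
        truth = make_truth(seed=3)
        m = simulate_map(truth, BASELINE, 3_000_000, seed=11, binsize=50_000)
        bal = ice_balance(m)
        tads = dm.call_tads(dm.bin_signal(bal), bal)
        tp = fp = hits = n_planted = 0
        for chrom in truth.binning.chroms:
            planted = truth.boundaries[BASELINE][chrom] // 50_000
            called = tads.boundaries.loc[tads.boundaries["chrom"] == chrom,
                                         "pos"].to_numpy() // 50_000
            n_planted += planted.size
            for c in called:
                (tp, fp) = (tp + 1, fp) if np.any(np.abs(planted - c) <= 1) \
                    else (tp, fp + 1)
            for p in planted:
                hits += bool(np.any(np.abs(called - p) <= 1))
        assert hits / n_planted >= 0.9
        assert tp / (tp + fp) >= 0.8

    def test_boundary_count_monotone_in_alpha(self, truth):
        m = simulate_map(truth, BASELINE, 2_000_000, seed=21, binsize=50_000)
        bal = ice_balance(m)
        sig = dm.bin_signal(bal)
        n_loose = len(dm.call_tads(sig, bal, alpha=0.05).boundaries)
        n_tight = len(dm.call_tads(sig, bal, alpha=0.001).boundaries)
        assert n_tight <= n_loose

    def test_domains_tile_chromosomes(self, truth):
        m = simulate_map(truth, BASELINE, 2_000_000, seed=22, binsize=50_000)
        bal = ice_balance(m)
        tads = dm.call_tads(dm.bin_signal(bal), bal)
        for chrom in truth.binning.chroms:
            sub = tads.domains[tads.domains["chrom"] == chrom].sort_values("start")
            assert sub["start"].iloc[0] == 0
            assert sub["end"].iloc[-1] == truth.binning.chrom_lengths[chrom]
            assert np.array_equal(sub["end"].to_numpy()[:-1], sub["start"].to_numpy()[1:])


def tadset_from_intervals(intervals, chrom_len=10_000_000, conserved=None):
    binning = GenomeBinning({"chr1": chrom_len}, 50_000)
    dom = pd.DataFrame([("chr1", a, b) for a, b in intervals],
                       columns=["chrom", "start", "end"])
    if conserved is not None:
        dom["conserved"] = conserved
    return dm.TadSet(binning, dom)


class TestConservation:
    def test_identical_sets_all_conserved(self):
        ts = tadset_from_intervals([(0, 1_000_000), (1_000_000, 2_500_000)])
        out = dm.conservation(ts, ts)
        assert out.domains["conserved"].all()

    def test_disjoint_sets_none_conserved(self):
        a = tadset_from_intervals([(0, 500_000)])
        b = tadset_from_intervals([(5_000_000, 6_000_000)])
        assert not dm.conservation(a, b).domains["conserved"].any()

    def test_boundary_inclusive_at_exactly_frac(self):
        # 0-1 Mb vs 0-0.8 Mb: overlap = 0.8 of the larger -> conserved at 0.8
        a = tadset_from_intervals([(0, 1_000_000)])
        b = tadset_from_intervals([(0, 800_000)])
        assert dm.conservation(a, b, frac=0.8).domains["conserved"].iloc[0]
        assert not dm.conservation(a, b, frac=0.81).domains["conserved"].iloc[0]

    @given(st.lists(st.integers(1, 40), min_size=1, max_size=8),
           st.floats(0.1, 1.0))
    @settings(max_examples=40, deadline=None)
    def test_self_conservation_for_any_frac(self, lengths, frac):
        edges = np.concatenate([[0], np.cumsum(lengths)]) * 50_000
        ts = tadset_from_intervals(list(zip(edges[:-1], edges[1:])),
                                   chrom_len=int(edges[-1]))
        assert dm.conservation(ts, ts, frac=frac).domains["conserved"].all()


class TestSizeModel:
    def test_size_balanced_classes_give_flat_slope(self):
        sizes = [500_000, 1_000_000, 2_000_000] * 2
        flags = [True, True, True, False, False, False]
        starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
        ts = tadset_from_intervals(list(zip(starts, starts + np.array(sizes))),
                                   chrom_len=int(sum(sizes)), conserved=flags)
        res = dm.size_conservation_model(ts)
        assert res.statistic == pytest.approx(0.0, abs=1e-6)

    def test_clean_separation_flagged_negative(self):
        sizes = [500_000] * 3 + [1_000_000] * 3
        flags = [True] * 3 + [False] * 3
        starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
        ts = tadset_from_intervals(list(zip(starts, starts + np.array(sizes))),
                                   chrom_len=int(sum(sizes)), conserved=flags)
        res = dm.size_conservation_model(ts)
        assert res.statistic < 0
        assert res.aux["separation"]

    def test_single_class_rejected(self):
        ts = tadset_from_intervals([(0, 500_000), (500_000, 900_000)],
                                   conserved=[True, True])
        with pytest.raises(ValueError):
            dm.size_conservation_model(ts)


class TestDomainSummary:
    def _tads_and_bals(self, tau, seed=0):
        cfg = TruthConfig(kappa=1.0, tau=tau, flip_fraction=0.0,
                          boundary_deletion_fraction=0.0, bias_sigma=0.0, delta=1.0)
        truth = make_truth(cfg, seed=seed)
        bals = {c: ice_balance(simulate_map(truth, c, 3_000_000, seed=5 + k,
                                            binsize=50_000))
                for k, c in enumerate((BASELINE, CONSTRICTED))}
        dom = []
        for chrom in truth.binning.chroms:
            cuts = np.concatenate([[0], truth.boundaries[BASELINE][chrom],
                                   [truth.binning.chrom_lengths[chrom]]])
            dom += [(chrom, a, b) for a, b in zip(cuts[:-1], cuts[1:])]
        tads = dm.TadSet(truth.binning.with_binsize(50_000),
                         pd.DataFrame(dom, columns=["chrom", "start", "end"]))
        return truth, bals, tads

    def test_tau_one_within_equals_between(self):
        _, bals, tads = self._tads_and_bals(tau=1.0)
        df = dm.domain_contact_summary(bals[BASELINE], bals[CONSTRICTED], tads)
        sub = df[(df["condition"] == "a") & (df["sep_bins"].between(2, 6))]
        w = sub[sub["kind"] == "within"].set_index("sep_bins")["mean_freq"]
        b = sub[sub["kind"] == "between"].set_index("sep_bins")["mean_freq"]
        shared = w.index.intersection(b.index)
        ratio = (w[shared] / b[shared]).mean()
        assert ratio == pytest.approx(1.0, abs=0.1)

    def test_tau_two_distance_matched_ratio(self):
        _, bals, tads = self._tads_and_bals(tau=2.0)
        df = dm.domain_contact_summary(bals[BASELINE], bals[CONSTRICTED], tads)
        sub = df[(df["condition"] == "a") & (df["sep_bins"].between(2, 6))]
        w = sub[sub["kind"] == "within"].set_index("sep_bins")["mean_freq"]
        b = sub[sub["kind"] == "between"].set_index("sep_bins")["mean_freq"]
        shared = w.index.intersection(b.index)
        ratio = (w[shared] / b[shared]).mean()
        assert ratio == pytest.approx(2.0, rel=0.15)

    def test_identical_maps_identical_summaries(self):
        _, bals, tads = self._tads_and_bals(tau=1.5)
        df = dm.domain_contact_summary(bals[BASELINE], bals[BASELINE], tads)
        a = df[df["condition"] == "a"].reset_index(drop=True)
        b = df[df["condition"] == "b"].reset_index(drop=True)
        assert np.allclose(a["mean_freq"], b["mean_freq"])


class TestCompartmentTest:
    def _profile(self, binning, labels):
        return CompartmentProfile(
            binning, {c: np.where(l == "A", 1.0, -1.0) for c, l in labels.items()},
            {c: l.copy() for c, l in labels.items()},
            {c: 1.0 for c in labels}, {c: False for c in labels},
            {c: False for c in labels})

    def test_identical_distributions_flat(self):
        # both classes carry the same multiset of fraction-A values -> F ~ 0
        binning = GenomeBinning({"chr1": 80 * 100_000}, 100_000)
        a_counts = [2, 4, 6, 8, 2, 4, 6, 8]  # A bins per 10-bin domain
        lab = np.concatenate([np.repeat(["A", "B"], [k, 10 - k]) for k in a_counts])
        prof = self._profile(binning, {"chr1": lab})
        starts = np.arange(8) * 1_000_000
        dom = pd.DataFrame({"chrom": "chr1", "start": starts,
                            "end": starts + 1_000_000,
                            "conserved": [True] * 4 + [False] * 4})
        ts = dm.TadSet(binning.with_binsize(50_000), dom)
        res = dm.conserved_tad_compartment_test(ts, prof)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue > 0.99

    def test_b_deletions_leave_conserved_domains_more_a(self):
        # boundary deletions planted only in B regions -> conserved TADs
        # skew toward compartment A
        hits = 0
        for seed in range(5):
            cfg = TruthConfig(flip_fraction=0.0, deletion_b_weight=1.0,
                              boundary_deletion_fraction=0.3)
            truth = make_truth(cfg, seed=seed)
            bals = {c: ice_balance(simulate_map(truth, c, 3_000_000,
                                                seed=100 * seed + k, binsize=50_000))
                    for k, c in enumerate((BASELINE, CONSTRICTED))}
            tads = {c: dm.call_tads(dm.bin_signal(bals[c]), bals[c])
                    for c in (BASELINE, CONSTRICTED)}
            cons = dm.conservation(tads[CONSTRICTED], tads[BASELINE])
            prof = self._profile(truth.binning, truth.labels[BASELINE])
            try:
                res = dm.conserved_tad_compartment_test(cons, prof)
            except ValueError:
                continue
            grp = res.aux["groups"]
            hits += (grp["conserved"] > grp["nonconserved"]) and res.pvalue < 0.05
        assert hits >= 4

    def test_single_class_rejected(self):
        binning = GenomeBinning({"chr1": 2_000_000}, 100_000)
        labels = {"chr1": np.repeat("A", 20).astype("<U1")}
        prof = self._profile(binning, labels)
        dom = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [2_000_000],
                            "conserved": [True]})
        ts = dm.TadSet(binning.with_binsize(50_000), dom)
        with pytest.raises(ValueError):
            dm.conserved_tad_compartment_test(ts, prof)
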