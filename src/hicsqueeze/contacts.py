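"""Significant and differential contact calling on a sliding-window lattice.

Contacts are counted in 100-kb windows tiled every 40 kb along each
chromosome (so boundaries between fixed bins are not penalized). A
distance- and coverage-factorized background gives the expected count per
window pair; significant contacts are Poisson upper-tail calls (BH, FDR <
0.05) more than 100 kb apart; differential contacts between depth-matched
conditions are conditional binomial calls (BH, FDR < 0.1). Compartment /
activity annotation, range-stratified proportion tests, and the
distance-binned bootstrap enrichment of B-compartment contacts reproduce
the downstream comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .binning import GenomeBinning
from .compartments import CompartmentProfile
from .matrix import ContactMap
from .stats import TestResult, bh_adjust, binom_test_2sided, prop_test_1sample, \
    prop_test_2sample

WINDOW = 100_000
STEP = 40_000
RANGE_CUT = 1_000_000
#: distance-bin edges in bp for enrichment tables ("uneven" by design)
DEFAULT_DIST_EDGES = (100_000, 250_000, 500_000, 1_000_000, 2_000_000,
                      5_000_000, 10_000_000)


@dataclass
class WindowedMap:
    """Per-chromosome window-pair count matrices on the 100 kb / 40 kb lattice.

    ``starts[chrom]`` are window start positions; ``counts[chrom]`` is the
    symmetric window-pair count matrix (entries share underlying bin counts,
    as windows overlap).
    """

    binning: GenomeBinning  # binning of the source map
    starts: dict[str, np.ndarray]
    counts: dict[str, np.ndarray]
    total_reads: int

    @property
    def chroms(self) -> list[str]:
        return list(self.starts)


def window_counts(cmap: ContactMap, window: int = WINDOW, step: int = STEP) -> WindowedMap:
    """Aggregate a fine-binned map into overlapping-window pair counts.

    The source binsize must divide both ``window`` and ``step``. A window
    pair's count is the sum of source-bin pairs whose bins lie fully within
    the respective windows.
    """
    bs = cmap.binning.binsize
    if window % bs or step % bs:
        raise ValueError("source binsize must divide window and step")
    wb, sb = window // bs, step // bs
    starts, counts = {}, {}
    for chrom in cmap.binning.chroms:
        n = cmap.binning.n_bins(chrom)
        length = cmap.binning.chrom_lengths[chrom]
        w_starts = np.arange(0, length - window + 1, step)
        nw = w_starts.size
        m = cmap.dense(chrom)
        first = (w_starts // bs).astype(np.int64)
        # sliding sum over rows then columns
        rows = np.zeros((nw, n))
        for a in range(wb):
            rows += m[first + a, :]
        k = np.zeros((nw, nw))
        for a in range(wb):
            k += rows[:, first + a]
        starts[chrom] = w_starts
        counts[chrom] = k
    return WindowedMap(cmap.binning, starts, counts, cmap.total)


def pooled_windowed(wmap_a: WindowedMap, wmap_b: WindowedMap) -> WindowedMap:
    """Sum two conditions' window counts (the pooled contact universe).

    Selecting significant contacts on the pooled counts keeps the
    downstream conditional binomial test exactly calibrated: the selection
    event depends only on a + b, and given a + b the split is Binomial(1/2)
    under the null, so no winner's-curse bias leaks into differential
    calls. Selecting on a single condition's counts does not have this
    property.
    """
    if any(not np.array_equal(wmap_a.starts[c], wmap_b.starts[c]) for c in wmap_a.chroms):
        raise ValueError("window lattices differ")
    counts = {c: wmap_a.counts[c] + wmap_b.counts[c] for c in wmap_a.chroms}
    return WindowedMap(wmap_a.binning, {c: s.copy() for c, s in wmap_a.starts.items()},
                       counts, wmap_a.total_reads + wmap_b.total_reads)


def window_decay_profile(wmap: WindowedMap) -> np.ndarray:
    """Genome-wide mean window-pair count at each lattice separation."""
    max_nw = max(s.size for s in wmap.starts.values())
    sums = np.zeros(max_nw)
    cnts = np.zeros(max_nw)
    for chrom in wmap.chroms:
        k = wmap.counts[chrom]
        nw = k.shape[0]
        for d in range(nw):
            diag = np.diagonal(k, offset=d)
            sums[d] += diag.sum()
            cnts[d] += diag.size
    with np.errstate(invalid="ignore"):
        return np.where(cnts > 0, sums / np.maximum(cnts, 1), 0.0)


def expected_background(wmap: WindowedMap) -> dict[str, np.ndarray]:
    """Distance x coverage factorized expected counts per window pair.

    E_ij = T * p(d_ij) * c_i * c_j / Z where p(d) is the genome-wide mean
    window-pair count at lattice separation d, c_i the window coverage
    share (marginal / total marginal), and Z normalizes so the sum of E
    over all upper-triangle window pairs equals the total T. Zero-coverage
    windows get E = 0 and are excluded from calling.
    """
    p = window_decay_profile(wmap)
    out = {}
    # coverage shares, global
    margs = {c: wmap.counts[c].sum(axis=1) for c in wmap.chroms}
    tot_marg = sum(m.sum() for m in margs.values())
    t = sum(np.triu(wmap.counts[c]).sum() for c in wmap.chroms)
    e0 = {}
    z = 0.0
    for chrom in wmap.chroms:
        nw = wmap.counts[chrom].shape[0]
        c = margs[chrom] / tot_marg if tot_marg > 0 else np.zeros(nw)
        d = np.abs(np.subtract.outer(np.arange(nw), np.arange(nw)))
        e = p[d] * np.outer(c, c)
        e0[chrom] = e
        z += np.triu(e).sum()
    for chrom in wmap.chroms:
        out[chrom] = e0[chrom] * (t / z) if z > 0 else e0[chrom]
    return out


def _pair_table(wmap: WindowedMap, expected: dict[str, np.ndarray],
                min_sep: int) -> pd.DataFrame:
    rows = []
    for chrom in wmap.chroms:
        st = wmap.starts[chrom]
        k = wmap.counts[chrom]
        e = expected[chrom]
        nw = st.size
        iu, ju = np.triu_indices(nw)
        sep = st[ju] - st[iu]
        keep = sep > min_sep
        cov_ok = (k.sum(axis=1)[iu] > 0) & (k.sum(axis=1)[ju] > 0)
        keep &= cov_ok
        rows.append(pd.DataFrame({
            "chrom": chrom, "start1": st[iu[keep]], "start2": st[ju[keep]],
            "sep": sep[keep], "observed": k[iu[keep], ju[keep]],
            "expected": e[iu[keep], ju[keep]]}))
    return pd.concat(rows, ignore_index=True)


def call_significant(wmap: WindowedMap, expected: dict[str, np.ndarray] | None = None,
                     fdr_threshold: float = 0.05, min_sep: int = WINDOW,
                     suppress: bool = True) -> pd.DataFrame:
    """Poisson upper-tail significant contacts with genome-wide BH control.

    Window pairs more than ``min_sep`` apart with observed > expected are
    tested with P(X >= obs | E); BH runs across all tested pairs. Calls
    passing FDR < ``fdr_threshold`` are de-duplicated by non-maximum
    suppression on the 40-kb lattice: of any two calls whose anchors both
    lie within 100 kb, only the more significant survives.

    Returns a contact table; ``attrs`` records parameters and the number of
    pairs tested (for calibration assessments).
    """
    if expected is None:
        expected = expected_background(wmap)
    pairs = _pair_table(wmap, expected, min_sep)
    tested = pairs[(pairs["observed"] > pairs["expected"]) & (pairs["expected"] > 0)].copy()
    tested["p"] = sps.poisson.sf(tested["observed"].to_numpy() - 1,
                                 tested["expected"].to_numpy())
    tested["fdr"] = bh_adjust(tested["p"].to_numpy())
    calls = tested[tested["fdr"] < fdr_threshold].copy()
    if suppress:
        calls = _nonmax_suppress(calls)
    calls = calls.reset_index(drop=True)
    calls.attrs.update({"n_pairs": len(pairs), "n_tested": len(tested),
                        "fdr_threshold": fdr_threshold, "min_sep": min_sep})
    return calls


def _nonmax_suppress(calls: pd.DataFrame) -> pd.DataFrame:
    """Collapse overlapping-window duplicate calls to the local p minimum."""
    if calls.empty:
        return calls
    order = calls.sort_values(["p", "chrom", "start1", "start2"],
                              kind="stable").index
    grid: dict[tuple, list[tuple[int, int]]] = {}
    keep = []
    for idx in order:
        row = calls.loc[idx]
        c1, c2 = int(row["start1"]) // WINDOW, int(row["start2"]) // WINDOW
        clash = False
        for g1 in (c1 - 1, c1, c1 + 1):
            for g2 in (c2 - 1, c2, c2 + 1):
                for (s1, s2) in grid.get((row["chrom"], g1, g2), ()):
                    if abs(s1 - int(row["start1"])) < WINDOW \
                            and abs(s2 - int(row["start2"])) < WINDOW:
                        clash = True
                        break
                if clash:
                    break
            if clash:
                break
        if not clash:
            keep.append(idx)
            grid.setdefault((row["chrom"], c1, c2), []).append(
                (int(row["start1"]), int(row["start2"])))
    return calls.loc[sorted(keep)]


def differential_contacts(wmap_a: WindowedMap, wmap_b: WindowedMap,
                          universe: pd.DataFrame,
                          fdr_threshold: float = 0.1) -> pd.DataFrame:
    """Differential calls over a universe of contacts, condition a vs b.

    Requires depth-matched maps. For each universe window pair, the count
    in condition a is tested against a + b with an exact two-sided binomial
    test; the null success probability is condition a's share of the two
    distance-decay profiles at that separation, q = p_a(d)/(p_a(d) + p_b(d)),
    which is 1/2 when the profiles agree. Normalizing by the per-condition
    decay profile keeps genome-wide compositional shifts (mass lost in one
    stratum reappearing elsewhere at fixed depth) from flooding the other
    strata with spurious calls, while per-bin coverage biases, being shared
    between conditions, cancel on their own. BH across the universe; the reported
    logFC = log2((a + 0.5)/(b + 0.5)) is the raw count ratio, while
    ``logfc_norm`` subtracts the background share and sets the direction
    (decreased / increased / ns from condition a's perspective) at
    FDR < ``fdr_threshold``. Pairs with zero counts in both conditions are
    excluded.
    """
    pa = window_decay_profile(wmap_a)
    pb = window_decay_profile(wmap_b)
    out = universe.copy()
    ca = np.empty(len(out))
    cb = np.empty(len(out))
    qa = np.empty(len(out))
    for k, row in enumerate(out.itertuples(index=False)):
        chrom = row.chrom
        ia = np.searchsorted(wmap_a.starts[chrom], row.start1)
        ja = np.searchsorted(wmap_a.starts[chrom], row.start2)
        ca[k] = wmap_a.counts[chrom][ia, ja]
        cb[k] = wmap_b.counts[chrom][ia, ja]
        d = ja - ia
        qa[k] = pa[d] / (pa[d] + pb[d]) if pa[d] + pb[d] > 0 else 0.5
    out["count_a"], out["count_b"], out["q_null"] = ca, cb, qa
    out = out[(ca + cb) > 0].copy()
    pvals = np.array([binom_test_2sided(int(a), int(a + b), q)
                      for a, b, q in zip(out["count_a"], out["count_b"], out["q_null"])])
    out["p_diff"] = pvals
    out["fdr_diff"] = bh_adjust(pvals)
    out["logfc"] = np.log2((out["count_a"] + 0.5) / (out["count_b"] + 0.5))
    out["logfc_norm"] = out["logfc"] - np.log2(out["q_null"] / (1 - out["q_null"]))
    out["direction"] = "ns"
    sig = out["fdr_diff"] < fdr_threshold
    out.loc[sig & (out["logfc_norm"] < 0), "direction"] = "decreased"
    out.loc[sig & (out["logfc_norm"] > 0), "direction"] = "increased"
    out["range_class"] = np.where(out["sep"] < RANGE_CUT, "short", "long")
    out.attrs.update(dict(universe.attrs))
    out.attrs["diff_fdr_threshold"] = fdr_threshold
    return out.reset_index(drop=True)


def range_proportion_test(calls: pd.DataFrame) -> dict[str, TestResult]:
    """Within each range class, are decreased and increased calls 50:50?

    Chi-squared with continuity correction of the decreased count against
    half of decreased + increased. Empty classes are omitted.
    """
    if "range_class" not in calls:
        calls = calls.assign(range_class=np.where(calls["sep"] < RANGE_CUT,
                                                  "short", "long"))
    out = {}
    for cls, sub in calls.groupby("range_class"):
        dec = int((sub["direction"] == "decreased").sum())
        inc = int((sub["direction"] == "increased").sum())
        if dec + inc == 0:
            continue
        res = prop_test_1sample(dec, dec + inc, 0.5)
        res.aux.update({"decreased": dec, "increased": inc})
        out[str(cls)] = res
    return out


def annotate_contacts(calls: pd.DataFrame, profile: CompartmentProfile,
                      activity: dict[str, np.ndarray]) -> pd.DataFrame:
    """Label each contact's anchors with compartment and activity.

    An anchor takes the label of the 100-kb compartment bin containing its
    window midpoint. Contact-level compartment is A or B when both anchors
    agree, "mixed" when they differ, "masked" when either is unlabeled;
    contact-level activity is true when either anchor's bin is active.
    """
    out = calls.copy()
    cbs = profile.binning.binsize
    comp1, comp2, act1, act2 = [], [], [], []
    for row in out.itertuples(index=False):
        lab = profile.labels[row.chrom]
        acts = activity[row.chrom]
        labels, actives = [], []
        for start in (row.start1, row.start2):
            b = (int(start) + WINDOW // 2) // cbs
            b = min(b, lab.size - 1)
            labels.append(lab[b])
            actives.append(bool(acts[b]))
        comp1.append(labels[0])
        comp2.append(labels[1])
        act1.append(actives[0])
        act2.append(actives[1])
    out["comp1"], out["comp2"] = comp1, comp2
    out["active1"], out["active2"] = act1, act2
    comp = np.where((out["comp1"] == "") | (out["comp2"] == ""), "masked",
                    np.where(out["comp1"] == out["comp2"], out["comp1"], "mixed"))
    out["compartment"] = comp
    out["active"] = out["active1"] | out["active2"]
    out.attrs.update(dict(calls.attrs))
    return out


def bootstrap_proportions(total: pd.DataFrame, disrupted: pd.DataFrame,
                          n_boot: int = 10_000, ci: float = 0.99,
                          dist_edges=DEFAULT_DIST_EDGES, seed: int = 0) -> pd.DataFrame:
    """Bootstrap test of B-compartment enrichment among disrupted contacts.

    Per distance bin, the observed B proportion of disrupted contacts
    (among A/B-labeled ones) is compared against the distribution of B
    proportions in ``n_boot`` resamples of the same size drawn with
    replacement from the total contacts in that bin. Resampling a binary
    label with replacement is an exact binomial draw, which is how the
    resamples are realized. A bin is flagged enriched (depleted) when the
    observed proportion lies above (below) the percentile CI at level
    ``ci``. Bins without total or disrupted contacts are skipped.
    """
    edges = np.asarray(dist_edges, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    tot = total[total["compartment"].isin(["A", "B"])]
    dis = disrupted[disrupted["compartment"].isin(["A", "B"])]
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        t = tot[(tot["sep"] >= lo) & (tot["sep"] < hi)]
        d = dis[(dis["sep"] >= lo) & (dis["sep"] < hi)]
        if len(t) == 0 or len(d) == 0:
            continue
        pool_b = float((t["compartment"] == "B").mean())
        obs_b = float((d["compartment"] == "B").mean())
        m = len(d)
        boots = rng.binomial(m, pool_b, size=n_boot) / m
        qlo, qhi = np.quantile(boots, [(1 - ci) / 2, 1 - (1 - ci) / 2])
        rows.append((lo, hi, len(t), m, pool_b, obs_b, float(qlo), float(qhi),
                     obs_b > qhi, obs_b < qlo))
    df = pd.DataFrame(rows, columns=["edge_lo", "edge_hi", "n_total", "n_disrupted",
                                     "pool_b_prop", "obs_b_prop", "ci_lo", "ci_hi",
                                     "b_enriched", "b_depleted"])
    df.attrs.update({"n_boot": n_boot, "ci": ci, "seed": seed})
    return df


def activity_difference(total: pd.DataFrame, disrupted: pd.DataFrame,
                        compartment: str) -> dict[str, TestResult]:
    """Are disrupted contacts less transcriptionally active than total ones?

    Two-sample proportion test (continuity corrected, 95% CI of the
    difference) of the active fraction — a contact is active when either
    anchor's bin contains an expressed gene — in disrupted vs total
    contacts, within one compartment, stratified by range class. Strata
    with no contacts on either side are omitted.
    """
    if compartment not in ("A", "B"):
        raise ValueError("compartment must be 'A' or 'B'")
    def stratum(df: pd.DataFrame, cls: str) -> pd.DataFrame:
        rc = df["range_class"] if "range_class" in df else \
            pd.Series(np.where(df["sep"] < RANGE_CUT, "short", "long"), index=df.index)
        return df[(df["compartment"] == compartment) & (rc == cls)]

    out = {}
    for cls in ("short", "long"):
        t = stratum(total, cls)
        d = stratum(disrupted, cls)
        if len(t) == 0 or len(d) == 0:
            continue
        res = prop_test_2sample(int(d["active"].sum()), len(d),
                                int(t["active"].sum()), len(t))
        res.aux.update({"compartment": compartment, "range_class": cls,
                        "active_disrupted": float(d["active"].mean()),
                        "active_total": float(t["active"].mean())})
        out[cls] = res
    return out
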