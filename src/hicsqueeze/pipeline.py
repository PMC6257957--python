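"""End-to-end orchestration: simulate -> balance -> compartments -> TADs ->
contacts -> expression integration, with serialized outputs and a summary.

Every stochastic stage draws its generator from the single global seed via
a fixed per-stage spawn key, so inserting a stage never reshuffles the
randomness of the ones after it, and a rerun with the same config and seed
reproduces every output byte for byte.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compartments as cp
from . import contacts as ct
from . import domains as dm
from . import expression as xp
from .matrix import (compare_decay, decay_curve, downsample_to_common_total,
                     ice_balance, observed_expected)
from .synth import (BASELINE, CONSTRICTED, SyntheticTruth, TruthConfig,
                    make_truth, simulate_de, simulate_map)

# fixed spawn keys; append-only so stage insertion keeps streams stable
_STAGE_KEYS = {
    "truth": 0, "de": 1,
    "map:baseline:analysis": 10, "map:constricted:analysis": 11,
    "map:baseline:tad": 12, "map:constricted:tad": 13,
    "map:baseline:contact": 14, "map:constricted:contact": 15,
    "downsample:analysis": 20, "downsample:tad": 21, "downsample:contact": 22,
    "switch_test": 30, "bootstrap": 31,
}

STAGES = ("simulate", "balance", "compartments", "tads", "contacts", "integrate")


@dataclass
class RunConfig:
    """All pipeline thresholds plus the simulation spec and global seed."""

    truth: TruthConfig = field(default_factory=TruthConfig)
    seed: int = 0
    reads_baseline: int = 3_000_000
    reads_constricted: int = 2_800_000
    analysis_binsize: int = 100_000   # compartments, decay, switching
    tad_binsize: int = 50_000
    contact_binsize: int = 20_000     # base resolution for 100 kb/40 kb windows
    r_threshold: float = 0.6
    overlap_frac: float = 0.8
    sig_fdr: float = 0.05
    diff_fdr: float = 0.1
    de_fdr: float = 0.05
    tad_window: int = 5
    n_boot: int = 10_000
    boot_ci: float = 0.99
    contact_pool: str = "pooled"      # or "baseline"

    def __post_init__(self) -> None:
        if not 0 < self.r_threshold < 1 or not 0 < self.overlap_frac <= 1:
            raise ValueError("thresholds out of range")
        for f_ in (self.sig_fdr, self.diff_fdr, self.de_fdr, self.boot_ci):
            if not 0 < f_ < 1:
                raise ValueError("FDR/CI levels must be in (0,1)")
        if self.contact_pool not in ("pooled", "baseline"):
            raise ValueError("contact_pool must be 'pooled' or 'baseline'")

    def stage_seed(self, name: str) -> np.random.SeedSequence:
        return np.random.SeedSequence(self.seed, spawn_key=(_STAGE_KEYS[name],))

    def stage_seed_int(self, name: str) -> int:
        return int(self.stage_seed(name).generate_state(1)[0] % (2**31))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        truth_raw = raw.pop("truth", {})
        if "chrom_lengths" in truth_raw:
            truth_raw["chrom_lengths"] = tuple(
                (str(c), int(l)) for c, l in truth_raw["chrom_lengths"])
        for key in ("set_sizes", "rho_sets"):
            if key in truth_raw:
                truth_raw[key] = tuple(truth_raw[key])
        return cls(truth=TruthConfig(**truth_raw), **raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["truth"]["chrom_lengths"] = [list(x) for x in raw["truth"]["chrom_lengths"]]
        raw["truth"]["set_sizes"] = list(raw["truth"]["set_sizes"])
        raw["truth"]["rho_sets"] = list(raw["truth"]["rho_sets"])
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=True))


def _log(msg: str, t0: float) -> None:
    print(f"[hicsqueeze +{time.time() - t0:7.1f}s] {msg}", file=sys.stderr)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: RunConfig, outdir=None, upto: str = "integrate") -> dict:
    """Run the pipeline through stage ``upto`` and return the results bundle.

    The bundle maps stage names to their in-memory products; when
    ``outdir`` is given, each stage also writes its plain-text outputs
    there, and the final stage writes ``summary.json``. A stage failure
    propagates with the stage name attached; earlier outputs remain on
    disk.
    """
    if upto not in STAGES:
        raise ValueError(f"unknown stage {upto!r}")
    upto_i = STAGES.index(upto)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    results: dict = {"config": config}
    stage = "simulate"
    try:
        # -- simulate -----------------------------------------------------
        truth = make_truth(config.truth, config.stage_seed_int("truth"))
        de = simulate_de(truth, seed=config.stage_seed_int("de"))
        reads = {BASELINE: config.reads_baseline, CONSTRICTED: config.reads_constricted}
        binsizes = {"analysis": config.analysis_binsize, "tad": config.tad_binsize,
                    "contact": config.contact_binsize}
        maps = {}
        for level, bs in binsizes.items():
            pair = [simulate_map(truth, cond, reads[cond],
                                 config.stage_seed_int(f"map:{cond}:{level}"), bs)
                    for cond in (BASELINE, CONSTRICTED)]
            pair = downsample_to_common_total(pair, config.stage_seed_int(f"downsample:{level}"))
            maps[level] = dict(zip((BASELINE, CONSTRICTED), pair))
        results.update({"truth": truth, "de": de, "maps": maps})
        _log("simulated 2 conditions x 3 resolutions", t0)
        if out is not None:
            truth.to_dir(out / "truth")
            de.to_csv(out / "de_table.tsv", sep="\t", index=False)
            for level, pair in maps.items():
                for cond, cmap in pair.items():
                    cmap.write_tsv(out / f"map_{cond}_{binsizes[level]//1000}kb.tsv")
        if upto_i < 1:
            return results

        # -- balance ------------------------------------------------------
        stage = "balance"
        balanced = {level: {cond: ice_balance(cmap) for cond, cmap in pair.items()}
                    for level, pair in maps.items()}
        curves = {cond: decay_curve(balanced["analysis"][cond])
                  for cond in (BASELINE, CONSTRICTED)}
        ks = compare_decay(balanced["analysis"][BASELINE], balanced["analysis"][CONSTRICTED])
        results.update({"balanced": balanced, "decay": curves, "decay_ks": ks})
        _log(f"balanced maps; decay KS D={ks.statistic:.4f} p={ks.pvalue:.3g}", t0)
        if out is not None:
            for cond, curve in curves.items():
                curve.to_frame().to_csv(out / f"decay_{cond}.tsv", sep="\t", index=False)
            for cond in (BASELINE, CONSTRICTED):
                bal = balanced["analysis"][cond]
                rows = []
                for chrom in bal.binning.chroms:
                    rows.append(pd.DataFrame({
                        "chrom": chrom,
                        "start": np.arange(bal.biases[chrom].size) * bal.binning.binsize,
                        "bias": bal.biases[chrom]}))
                pd.concat(rows, ignore_index=True).to_csv(
                    out / f"ice_bias_{cond}.tsv", sep="\t", index=False)
        if upto_i < 2:
            return results

        # -- compartments -------------------------------------------------
        stage = "compartments"
        binning = truth.binning
        activity = xp.active_bins(de, binning)
        act_track = {c: v.astype(float) for c, v in activity.items()}
        oes = {cond: observed_expected(balanced["analysis"][cond])
               for cond in (BASELINE, CONSTRICTED)}
        corrs = {cond: cp.correlation_matrix(oes[cond]) for cond in oes}
        profiles = {cond: cp.compartment_profile(corrs[cond], act_track, binning)
                    for cond in corrs}
        centromeres = {c: binning.chrom_lengths[c] // 2 for c in binning.chroms}
        for cond in profiles:
            cp.flag_arm_artifact(profiles[cond], centromeres)
        rdiff = cp.correlation_diff(corrs[BASELINE], corrs[CONSTRICTED])
        switches = cp.call_switches(profiles[BASELINE], profiles[CONSTRICTED], rdiff,
                                    config.r_threshold)
        switch_test = cp.switch_compartment_test(
            switches, n_boot=config.n_boot, ci=config.boot_ci,
            seed=config.stage_seed_int("switch_test"))
        results.update({"activity": activity, "profiles": profiles, "corr": corrs,
                        "rdiff": rdiff, "switches": switches, "switch_test": switch_test})
        _log(f"compartments: {switches['status'].value_counts().to_dict()}", t0)
        if out is not None:
            for cond, prof in profiles.items():
                prof.label_frame().to_csv(out / f"compartments_{cond}.tsv",
                                          sep="\t", index=False)
            switches.to_csv(out / "switch_table.tsv", sep="\t", index=False)
        if upto_i < 3:
            return results

        # -- tads ---------------------------------------------------------
        stage = "tads"
        tads = {}
        for cond in (BASELINE, CONSTRICTED):
            bal = balanced["tad"][cond]
            sig = dm.bin_signal(bal, config.tad_window)
            tads[cond] = dm.call_tads(sig, bal, config.tad_window)
        tads_cons = dm.conservation(tads[CONSTRICTED], tads[BASELINE], config.overlap_frac)
        tads_cons = dm.annotate_fraction_a(tads_cons, profiles[BASELINE])
        size_model = dm.size_conservation_model(tads_cons)
        try:
            tad_comp_test = dm.conserved_tad_compartment_test(tads_cons, profiles[BASELINE])
        except ValueError:
            tad_comp_test = None
        dom_summary = dm.domain_contact_summary(balanced["tad"][CONSTRICTED],
                                                balanced["tad"][BASELINE], tads_cons)
        results.update({"tads": tads, "tads_conserved": tads_cons,
                        "tad_size_model": size_model, "tad_comp_test": tad_comp_test,
                        "domain_summary": dom_summary})
        _log(f"TADs: {len(tads[BASELINE].domains)} baseline, "
             f"{len(tads[CONSTRICTED].domains)} constricted, "
             f"{tads_cons.domains['conserved'].mean():.1%} conserved", t0)
        if out is not None:
            for cond, ts in tads.items():
                ts.to_bed(out / f"tads_{cond}.bed")
            tads_cons.to_bed(out / "tads_constricted_conservation.bed")
            dom_summary.to_csv(out / "domain_contact_summary.tsv", sep="\t", index=False)
        if upto_i < 4:
            return results

        # -- contacts -----------------------------------------------------
        stage = "contacts"
        wins = {cond: ct.window_counts(maps["contact"][cond])
                for cond in (BASELINE, CONSTRICTED)}
        universe_map = wins[BASELINE] if config.contact_pool == "baseline" \
            else ct.pooled_windowed(wins[BASELINE], wins[CONSTRICTED])
        sig_calls = ct.call_significant(universe_map, fdr_threshold=config.sig_fdr)
        diff_calls = ct.differential_contacts(wins[CONSTRICTED], wins[BASELINE],
                                              sig_calls, fdr_threshold=config.diff_fdr)
        sig_ann = ct.annotate_contacts(sig_calls, profiles[BASELINE], activity)
        diff_ann = ct.annotate_contacts(diff_calls, profiles[BASELINE], activity)
        decreased = diff_ann[diff_ann["direction"] == "decreased"]
        range_test = ct.range_proportion_test(diff_ann)
        boot = ct.bootstrap_proportions(sig_ann, decreased, n_boot=config.n_boot,
                                        ci=config.boot_ci,
                                        seed=config.stage_seed_int("bootstrap"))
        act_tests = {comp: ct.activity_difference(sig_ann, decreased, comp)
                     for comp in ("A", "B")}
        results.update({"windows": wins, "significant": sig_ann, "differential": diff_ann,
                        "range_test": range_test, "bootstrap": boot,
                        "activity_tests": act_tests})
        _log(f"contacts: {len(sig_ann)} significant, "
             f"{(diff_ann['direction'] == 'decreased').sum()} decreased, "
             f"{(diff_ann['direction'] == 'increased').sum()} increased", t0)
        if out is not None:
            bedpe = diff_ann.copy()
            bedpe.insert(1, "end1", bedpe["start1"] + ct.WINDOW)
            bedpe.insert(3, "chrom2", bedpe["chrom"])
            bedpe.insert(5, "end2", bedpe["start2"] + ct.WINDOW)
            bedpe.to_csv(out / "contacts_differential.bedpe", sep="\t", index=False)
            boot.to_csv(out / "bootstrap_enrichment.tsv", sep="\t", index=False)
        if upto_i < 5:
            return results

        # -- integrate ----------------------------------------------------
        stage = "integrate"
        gene_sets = xp.classify_sets(de, config.de_fdr)
        try:
            lfc_test = xp.logfc_by_switch(de, switches, fdr=config.de_fdr)
        except ValueError:
            lfc_test = None
        results.update({"gene_sets": gene_sets, "lfc_switch_test": lfc_test})
        summary = build_summary(results)
        results["summary"] = summary
        _log(f"gene sets: {gene_sets.sizes}", t0)
        if out is not None:
            gene_table = de[["gene_id", "chrom", "start", "end"]].copy()
            gene_table["set_label"] = gene_sets.labels
            gene_table.to_csv(out / "gene_sets.tsv", sep="\t", index=False)
            (out / "summary.json").write_text(
                json.dumps(summary, indent=2, sort_keys=True, default=_json_default)
                + "\n")
        return results
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err


def _switch_summary(switches: pd.DataFrame) -> dict:
    counts = switches["status"].value_counts().to_dict()
    n_unmasked = int((switches["status"] != "masked").sum())
    n_all = len(switches)
    out = {"counts": {k: int(v) for k, v in counts.items()},
           "n_bins": n_all, "n_unmasked": n_unmasked,
           "partial_criterion_bins": int(switches.attrs.get("partial", 0))}
    for comp, stable_key, switch_key in (("A", "stable-A", "switch A>B"),
                                         ("B", "stable-B", "switch B>A")):
        stable = counts.get(stable_key, 0)
        switched = counts.get(switch_key, 0)
        tot = stable + switched
        # primary denominator: unmasked bins of that source compartment;
        # the share of all bins (masked included) is reported alongside
        out[f"stable_{comp}_pct_of_unmasked"] = 100.0 * stable / tot if tot else float("nan")
        out[f"stable_{comp}_pct_of_all"] = 100.0 * stable / n_all if n_all else float("nan")
    return out


def build_summary(results: dict) -> dict:
    """Condense a results bundle into the JSON-ready run summary."""
    config: RunConfig = results["config"]
    switches = results["switches"]
    st = results["switch_test"]
    gene_sets: xp.GeneSets = results["gene_sets"]
    boot = results["bootstrap"]
    diff = results["differential"]
    summary = {
        "seed": config.seed,
        "parameters": {
            "r_threshold": config.r_threshold, "overlap_frac": config.overlap_frac,
            "sig_fdr": config.sig_fdr, "diff_fdr": config.diff_fdr,
            "n_boot": config.n_boot, "boot_ci": config.boot_ci,
            "tad_window": config.tad_window, "contact_pool": config.contact_pool,
        },
        "decay_ks": {"D": results["decay_ks"].statistic, "p": results["decay_ks"].pvalue},
        "compartments": _switch_summary(switches),
        "switch_test": {"coef_B": st.statistic, "p": st.pvalue,
                        "separation": st.aux["separation"],
                        "bootstrap": st.aux["bootstrap"]},
        "tads": {
            "n_baseline": len(results["tads"][BASELINE].domains),
            "n_constricted": len(results["tads"][CONSTRICTED].domains),
            "conserved_pct": 100.0 * float(results["tads_conserved"]
                                           .domains["conserved"].mean()),
            "size_model": {"coef": results["tad_size_model"].statistic,
                           "p": results["tad_size_model"].pvalue,
                           "mcfadden_r2": results["tad_size_model"].aux["mcfadden_r2"]},
            "compartment_test": None if results["tad_comp_test"] is None else
            {"F": results["tad_comp_test"].statistic,
             "p": results["tad_comp_test"].pvalue},
        },
        "contacts": {
            "n_significant": len(results["significant"]),
            "by_direction": {k: int(v) for k, v in
                             diff["direction"].value_counts().items()},
            "range_tests": {cls: {"decreased": r.aux["decreased"],
                                  "increased": r.aux["increased"], "p": r.pvalue}
                            for cls, r in results["range_test"].items()},
            "bootstrap_enrichment": boot.to_dict(orient="records"),
            "activity_tests": {
                comp: {cls: {"p": r.pvalue, "diff": r.aux["diff"], "ci": r.aux["ci"]}
                       for cls, r in tests.items()}
                for comp, tests in results["activity_tests"].items()},
        },
        "gene_sets": {"sizes": gene_sets.sizes, "r2": gene_sets.r2,
                      "venn": gene_sets.venn, "overlap13": gene_sets.overlap13},
        "lfc_switch_test": None if results["lfc_switch_test"] is None else
        {"F": results["lfc_switch_test"].statistic,
         "p": results["lfc_switch_test"].pvalue,
         "tukey": results["lfc_switch_test"].aux["tukey"]},
    }
    return summary


def region_report(results: dict, region: str) -> pd.DataFrame:
    """Aligned per-bin tracks for one region ("chrom:start-end").

    Columns: PC1 per condition, inter-condition correlation R (with the
    switching threshold recorded in attrs), switch status, TAD boundary
    and conservation flags, significant-contact anchor counts, expressed
    gene counts, and DE-gene counts for the constriction contrast.
    """
    config: RunConfig = results["config"]
    truth: SyntheticTruth = results["truth"]
    binning = truth.binning
    chrom, _, span = region.partition(":")
    if chrom not in binning.chrom_lengths:
        raise ValueError(f"unknown chromosome {chrom!r}")
    if span:
        lo, hi = (int(x) for x in span.split("-"))
    else:
        lo, hi = 0, binning.chrom_lengths[chrom]
    if not 0 <= lo < hi <= binning.chrom_lengths[chrom]:
        raise ValueError(f"region {region!r} outside chromosome")
    b_lo, b_hi = lo // binning.binsize, -(-hi // binning.binsize)
    idx = np.arange(b_lo, b_hi)
    starts = idx * binning.binsize
    sw = results["switches"]
    sub = sw[(sw["chrom"] == chrom) & sw["start"].isin(starts)].set_index("start")
    rows = pd.DataFrame({
        "chrom": chrom, "start": starts,
        "end": np.minimum(starts + binning.binsize, binning.chrom_lengths[chrom]),
        "pc1_baseline": sub["pc1_a"].reindex(starts).to_numpy(),
        "pc1_constricted": sub["pc1_b"].reindex(starts).to_numpy(),
        "r": sub["r"].reindex(starts).to_numpy(),
        "status": sub["status"].reindex(starts).fillna("masked").to_numpy(),
    })
    for cond in (BASELINE, CONSTRICTED):
        bounds = results["tads"][cond].boundaries
        bpos = bounds.loc[bounds["chrom"] == chrom, "pos"].to_numpy()
        rows[f"tad_boundary_{cond}"] = [
            bool(np.any((bpos >= s) & (bpos < e)))
            for s, e in zip(rows["start"], rows["end"])]
    cons = results["tads_conserved"].domains
    cons = cons[(cons["chrom"] == chrom) & ~cons["conserved"]]
    rows["in_nonconserved_tad"] = [
        bool(np.any((cons["start"] < e) & (cons["end"] > s)))
        for s, e in zip(rows["start"], rows["end"])]
    sig = results["significant"]
    sig = sig[sig["chrom"] == chrom]
    anchors = np.concatenate([sig["start1"].to_numpy(), sig["start2"].to_numpy()]) \
        if len(sig) else np.empty(0)
    rows["n_contact_anchors"] = [
        int(np.sum((anchors + ct.WINDOW / 2 >= s) & (anchors + ct.WINDOW / 2 < e)))
        for s, e in zip(rows["start"], rows["end"])]
    de = results["de"]
    genes = de[de["chrom"] == chrom]
    mid = (genes["start"] + genes["end"]) // 2
    rows["n_expressed_genes"] = [
        int(((mid >= s) & (mid < e) & genes["expressed"]).sum())
        for s, e in zip(rows["start"], rows["end"])]
    rows["n_de_genes_5v14"] = [
        int(((mid >= s) & (mid < e) & (genes["fdr_5v14"] < config.de_fdr)).sum())
        for s, e in zip(rows["start"], rows["end"])]
    rows.attrs["r_threshold"] = config.r_threshold
    return rows
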