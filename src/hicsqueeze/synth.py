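"""Synthetic multi-condition Hi-C and expression data with planted truth.

The generator emulates the features a constricted-migration Hi-C study
depends on: power-law distance decay, checkerboard A/B compartment
structure, TAD enrichment, per-bin coverage bias, Poisson count noise, and
condition-specific perturbations — compartment flips and TAD-boundary
deletions concentrated in the B compartment, plus a multiplicative
depletion of short-range (< 1 Mb) B-B contacts in the "constricted"
condition. Expression tables plant three differentially-expressed gene
sets with configurable sizes and inter-contrast fold-change correlations.

All parameters are carried in :class:`TruthConfig`; all randomness flows
from a single seed, so identical (config, seed) pairs give bit-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .binning import GenomeBinning
from .matrix import ContactMap

BASELINE = "baseline"      # migration without constriction (14-um analog)
CONSTRICTED = "constricted"  # migration with constriction (5-um analog)
CONDITIONS = (BASELINE, CONSTRICTED)

#: contrast keys: 5-um vs control, 14-um vs control, 5-um vs 14-um
CONTRASTS = ("5v0", "14v0", "5v14")


@dataclass(frozen=True)
class TruthConfig:
    """Simulation parameters; defaults define the desk-scale study conditions.

    The genome is 2 chromosomes x 30 Mb. Compartment labels live on 100-kb
    bins, TAD boundaries on a 50-kb lattice. ``alpha`` is the distance-decay
    exponent, ``kappa`` the same-compartment enrichment, ``tau`` the
    within-TAD enrichment, ``delta`` the short-range B-B depletion factor
    applied only in the constricted condition, and ``bias_sigma`` the
    log-normal coverage-bias spread.
    """

    chrom_lengths: tuple[tuple[str, int], ...] = (("chr1", 30_000_000), ("chr2", 30_000_000))
    comp_binsize: int = 100_000
    tad_binsize: int = 50_000
    alpha: float = 1.0
    kappa: float = 1.5
    tau: float = 1.8
    delta: float = 0.6
    bias_sigma: float = 0.3
    block_min_bins: int = 5          # compartment block length range, 100-kb bins
    block_max_bins: int = 15
    tad_min_bins: int = 8            # TAD length range, 50-kb bins
    tad_max_bins: int = 24
    flip_fraction: float = 0.05      # fraction of 100-kb bins flipped in constricted
    flip_b_weight: float = 0.9       # share of flips drawn from B bins (rest from A)
    boundary_deletion_fraction: float = 0.2
    deletion_b_weight: float = 0.9   # share of deletions drawn from B-flanked boundaries
    n_genes: int = 15_000
    set_sizes: tuple[int, int, int] = (420, 1443, 199)
    rho_sets: tuple[float, float, float] = (0.92, 0.82, 0.32)
    lfc_sigma: float = 1.5
    p_active_a: float = 0.9          # P(100-kb bin transcriptionally active | A)
    p_active_b: float = 0.4
    p_expressed_in_active: float = 0.5

    def binning(self) -> GenomeBinning:
        return GenomeBinning(dict(self.chrom_lengths), self.comp_binsize)


@dataclass
class SyntheticTruth:
    """Planted ground truth for one simulated experiment."""

    config: TruthConfig
    seed: int
    labels: dict[str, dict[str, np.ndarray]]        # condition -> chrom -> 'A'/'B' per 100-kb bin
    boundaries: dict[str, dict[str, np.ndarray]]    # condition -> chrom -> boundary bp, increasing
    bias: dict[str, np.ndarray]                     # chrom -> positive bias per 100-kb bin
    genes: pd.DataFrame                             # gene_id, chrom, start, end, expressed, de_set

    @property
    def binning(self) -> GenomeBinning:
        return self.config.binning()

    def active_bins(self) -> dict[str, np.ndarray]:
        """Planted per-100-kb-bin activity: has >= 1 expressed gene."""
        binning = self.binning
        out = {c: np.zeros(binning.n_bins(c), dtype=bool) for c in binning.chroms}
        bs = binning.binsize
        expressed = self.genes[self.genes["expressed"]]
        for chrom, sub in expressed.groupby("chrom", sort=False):
            lo = sub["start"].to_numpy() // bs
            hi = (sub["end"].to_numpy() - 1) // bs
            for a, b in zip(lo, hi):
                out[str(chrom)][a:b + 1] = True
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, SyntheticTruth):
            return NotImplemented
        if self.config != other.config or self.seed != other.seed:
            return False
        for cond in self.labels:
            for chrom in self.labels[cond]:
                if not np.array_equal(self.labels[cond][chrom], other.labels[cond][chrom]):
                    return False
                if not np.array_equal(self.boundaries[cond][chrom],
                                      other.boundaries[cond][chrom]):
                    return False
        for chrom in self.bias:
            if not np.allclose(self.bias[chrom], other.bias[chrom], rtol=0, atol=1e-12):
                return False
        return self.genes.reset_index(drop=True).equals(other.genes.reset_index(drop=True))

    # -- serialization ----------------------------------------------------

    def to_dir(self, path) -> None:
        """Write truth as plain-text tables (BED/TSV + flat config)."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        lines = [f"seed: {self.seed}"]
        for key, val in asdict(self.config).items():
            if key == "chrom_lengths":
                val = ",".join(f"{c}:{l}" for c, l in val)
            elif isinstance(val, tuple):
                val = ",".join(str(v) for v in val)
            lines.append(f"{key}: {val}")
        (path / "config.txt").write_text("\n".join(lines) + "\n")
        binning = self.binning
        for cond in self.labels:
            rows = []
            for chrom in binning.chroms:
                lab = self.labels[cond][chrom]
                starts = np.arange(lab.size) * binning.binsize
                ends = np.minimum(starts + binning.binsize, binning.chrom_lengths[chrom])
                rows.append(pd.DataFrame({"chrom": chrom, "start": starts,
                                          "end": ends, "name": lab}))
            pd.concat(rows, ignore_index=True).to_csv(
                path / f"compartments_{cond}.bed", sep="\t", index=False, header=False)
            rows = []
            for chrom in binning.chroms:
                b = self.boundaries[cond][chrom]
                rows.append(pd.DataFrame({"chrom": chrom, "start": b, "end": b + 1}))
            pd.concat(rows, ignore_index=True).to_csv(
                path / f"boundaries_{cond}.bed", sep="\t", index=False, header=False)
        rows = []
        for chrom in binning.chroms:
            b = self.bias[chrom]
            rows.append(pd.DataFrame({"chrom": chrom,
                                      "start": np.arange(b.size) * binning.binsize,
                                      "bias": b}))
        pd.concat(rows, ignore_index=True).to_csv(path / "bias.tsv", sep="\t",
                                                  index=False, float_format="%.17g")
        self.genes.to_csv(path / "genes.bed", sep="\t", index=False)

    @classmethod
    def from_dir(cls, path) -> "SyntheticTruth":
        path = Path(path)
        kv = {}
        for line in (path / "config.txt").read_text().splitlines():
            key, _, val = line.partition(":")
            kv[key.strip()] = val.strip()
        seed = int(kv.pop("seed"))
        chrom_lengths = tuple(
            (part.split(":")[0], int(part.split(":")[1]))
            for part in kv.pop("chrom_lengths").split(","))
        defaults = TruthConfig()
        kwargs = {"chrom_lengths": chrom_lengths}
        for f_ in defaults.__dataclass_fields__.values():
            if f_.name in ("chrom_lengths",) or f_.name not in kv:
                continue
            raw = kv[f_.name]
            default = getattr(defaults, f_.name)
            if isinstance(default, tuple):
                parts = raw.split(",")
                kwargs[f_.name] = tuple(type(default[0])(p) for p in parts)
            elif isinstance(default, bool):
                kwargs[f_.name] = raw == "True"
            elif isinstance(default, int):
                kwargs[f_.name] = int(raw)
            elif isinstance(default, float):
                kwargs[f_.name] = float(raw)
            else:
                kwargs[f_.name] = raw
        config = TruthConfig(**kwargs)
        binning = config.binning()
        labels: dict = {}
        boundaries: dict = {}
        for cond in CONDITIONS:
            comp = pd.read_csv(path / f"compartments_{cond}.bed", sep="\t", header=None,
                               names=["chrom", "start", "end", "name"])
            labels[cond] = {
                chrom: sub.sort_values("start")["name"].to_numpy(dtype="<U1")
                for chrom, sub in comp.groupby("chrom", sort=False)}
            try:
                bnd = pd.read_csv(path / f"boundaries_{cond}.bed", sep="\t", header=None,
                                  names=["chrom", "start", "end"])
            except pd.errors.EmptyDataError:
                bnd = pd.DataFrame(columns=["chrom", "start", "end"])
            boundaries[cond] = {
                chrom: np.sort(bnd.loc[bnd["chrom"] == chrom, "start"].to_numpy(dtype=np.int64))
                for chrom in binning.chroms}
        bias_df = pd.read_csv(path / "bias.tsv", sep="\t")
        bias = {chrom: sub.sort_values("start")["bias"].to_numpy(dtype=float)
                for chrom, sub in bias_df.groupby("chrom", sort=False)}
        genes = pd.read_csv(path / "genes.bed", sep="\t")
        genes["expressed"] = genes["expressed"].astype(bool)
        genes["de_set"] = genes["de_set"].astype(str)
        return cls(config, seed, labels, boundaries, bias, genes)


def _alternating_blocks(n_bins: int, lo: int, hi: int, rng: np.random.Generator) -> np.ndarray:
    """Alternating A/B labels in blocks of uniform random length in [lo, hi]."""
    labels = np.empty(n_bins, dtype="<U1")
    pos = 0
    current = "A" if rng.integers(2) == 0 else "B"
    while pos < n_bins:
        length = int(rng.integers(lo, hi + 1))
        labels[pos:pos + length] = current
        pos += length
        current = "B" if current == "A" else "A"
    return labels


def _tad_boundaries(n_bins: int, lo: int, hi: int, binsize: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Interior TAD boundary positions (bp) from uniform random domain lengths."""
    edges = []
    pos = 0
    while True:
        pos += int(rng.integers(lo, hi + 1))
        if pos >= n_bins:
            break
        edges.append(pos * binsize)
    return np.asarray(edges, dtype=np.int64)


def _biased_choice(primary: np.ndarray, rest: np.ndarray, k: int, weight: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Choose k items without replacement, round(weight*k) from ``primary``.

    Shortfalls on either side spill over to the other, so exactly
    min(k, total) items come back.
    """
    k = min(k, primary.size + rest.size)
    take_primary = min(int(round(weight * k)), primary.size)
    take_rest = min(k - take_primary, rest.size)
    take_primary = k - take_rest  # spill back if rest was short
    chosen = []
    if take_primary:
        chosen.append(rng.choice(primary, size=take_primary, replace=False))
    if take_rest:
        chosen.append(rng.choice(rest, size=take_rest, replace=False))
    return (np.concatenate(chosen).astype(np.int64) if chosen
            else np.empty(0, dtype=np.int64))


def make_truth(config: TruthConfig | None = None, seed: int = 0) -> SyntheticTruth:
    """Generate planted truth: compartments, TADs, biases, genes, DE sets.

    The constricted condition is derived from the baseline by flipping
    ``flip_fraction`` of compartment bins (a ``flip_b_weight`` share drawn
    from B bins, the rest from A) and deleting
    ``boundary_deletion_fraction`` of TAD boundaries (``deletion_b_weight``
    share drawn from B-flanked boundaries).
    """
    config = config or TruthConfig()
    if not 0.0 < config.delta <= 1.0:
        raise ValueError("delta must be in (0, 1]")
    if config.kappa < 1 or config.tau < 1:
        raise ValueError("kappa and tau must be >= 1")
    if config.block_min_bins < 2:
        raise ValueError("compartment blocks must span >= 2 bins")
    binning = config.binning()
    for chrom in binning.chroms:
        if binning.n_bins(chrom) < 10:
            raise ValueError(f"{chrom} shorter than 10 bins at {config.comp_binsize} bp")
        if config.block_max_bins > binning.n_bins(chrom):
            raise ValueError("compartment block length exceeds chromosome length")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    # baseline compartments and TADs
    base_labels = {c: _alternating_blocks(binning.n_bins(c), config.block_min_bins,
                                          config.block_max_bins, rng)
                   for c in binning.chroms}
    # TAD boundaries: random-length domains, plus every compartment block
    # edge (compartment transitions are domain boundaries in real genomes;
    # the kappa checkerboard makes them contact discontinuities regardless)
    tad_bins = {c: -(-binning.chrom_lengths[c] // config.tad_binsize) for c in binning.chroms}
    base_bounds = {}
    for c in binning.chroms:
        rand_bounds = _tad_boundaries(tad_bins[c], config.tad_min_bins, config.tad_max_bins,
                                      config.tad_binsize, rng)
        edges = (np.flatnonzero(base_labels[c][1:] != base_labels[c][:-1]) + 1) \
            * config.comp_binsize
        base_bounds[c] = np.unique(np.concatenate([rand_bounds, edges])).astype(np.int64)

    # per-100-kb-bin coverage bias, log-normal
    bias = {c: rng.lognormal(0.0, config.bias_sigma, binning.n_bins(c))
            for c in binning.chroms}

    # compartment flips (constricted condition)
    flat_labels = np.concatenate([base_labels[c] for c in binning.chroms])
    total_bins = flat_labels.size
    n_flip = int(round(config.flip_fraction * total_bins))
    primary = np.flatnonzero(flat_labels == "B")
    rest = np.flatnonzero(flat_labels == "A")
    flipped = np.sort(_biased_choice(primary, rest, n_flip, config.flip_b_weight, rng))
    pert_flat = flat_labels.copy()
    pert_flat[flipped] = np.where(pert_flat[flipped] == "A", "B", "A")
    pert_labels = {}
    pos = 0
    for c in binning.chroms:
        n = binning.n_bins(c)
        pert_labels[c] = pert_flat[pos:pos + n]
        pos += n

    # boundary deletions (constricted condition)
    all_bounds = [(c, b) for c in binning.chroms for b in base_bounds[c]]
    n_del = int(round(config.boundary_deletion_fraction * len(all_bounds)))
    if all_bounds:
        is_b_flanked = np.array([
            base_labels[c][max((b - 1) // config.comp_binsize, 0)] == "B"
            and base_labels[c][min(b // config.comp_binsize,
                                   binning.n_bins(c) - 1)] == "B"
            for c, b in all_bounds])
        idx = np.arange(len(all_bounds))
        deleted = set(_biased_choice(idx[is_b_flanked], idx[~is_b_flanked], n_del,
                                     config.deletion_b_weight, rng).tolist())
    else:
        deleted = set()
    pert_bounds = {c: np.asarray([b for k, (cc, b) in enumerate(all_bounds)
                                  if cc == c and k not in deleted], dtype=np.int64)
                   for c in binning.chroms}

    genes = _make_gene_table(binning, base_labels, config, rng)
    _assign_de_sets(genes, config.set_sizes, rng)

    return SyntheticTruth(
        config=config, seed=seed,
        labels={BASELINE: base_labels, CONSTRICTED: pert_labels},
        boundaries={BASELINE: base_bounds, CONSTRICTED: pert_bounds},
        bias=bias, genes=genes)


def _make_gene_table(binning: GenomeBinning, labels: dict[str, np.ndarray],
                     config: TruthConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Place genes within single 100-kb bins; expression follows planted
    per-bin activity (A bins more often active than B bins)."""
    active = {}
    for chrom in binning.chroms:
        p = np.where(labels[chrom] == "A", config.p_active_a, config.p_active_b)
        active[chrom] = rng.random(labels[chrom].size) < p
    chrom_arr = np.concatenate([np.repeat(c, binning.n_bins(c)) for c in binning.chroms])
    bin_arr = np.concatenate([np.arange(binning.n_bins(c)) for c in binning.chroms])
    gidx = rng.integers(0, chrom_arr.size, size=config.n_genes)
    lengths = rng.integers(2_000, 40_001, size=config.n_genes)
    chroms = chrom_arr[gidx]
    bins = bin_arr[gidx]
    bin_starts = bins * binning.binsize
    bin_ends = np.minimum(bin_starts + binning.binsize,
                          np.array([binning.chrom_lengths[c] for c in chroms]))
    lengths = np.minimum(lengths, bin_ends - bin_starts)
    starts = bin_starts + (rng.random(config.n_genes)
                           * (bin_ends - bin_starts - lengths)).astype(np.int64)
    ends = starts + lengths
    bin_active = np.array([active[c][b] for c, b in zip(chroms, bins)])
    expressed = bin_active & (rng.random(config.n_genes) < config.p_expressed_in_active)
    genes = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends,
                          "expressed": expressed, "_bin": bins})
    # active bins with genes but no expressed gene get one forced, so the
    # planted per-bin activity equals "contains an expressed gene"
    for (chrom, b), sub in genes.groupby(["chrom", "_bin"], sort=True):
        if active[chrom][b] and not sub["expressed"].any():
            genes.loc[sub.index[0], "expressed"] = True
    genes = genes.drop(columns="_bin")
    genes = genes.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
    genes.insert(0, "gene_id", [f"g{k:06d}" for k in range(len(genes))])
    genes["de_set"] = "other"
    return genes


def _assign_de_sets(genes: pd.DataFrame, set_sizes: tuple[int, int, int],
                    rng: np.random.Generator) -> None:
    """Assign planted DE-set labels, preferring expressed genes."""
    total = int(sum(set_sizes))
    if total > len(genes):
        raise ValueError("sum of set sizes exceeds gene count")
    expressed_idx = genes.index[genes["expressed"]].to_numpy()
    other_idx = genes.index[~genes["expressed"]].to_numpy()
    chosen = _biased_choice(expressed_idx, other_idx, total, 1.0, rng)
    pos = 0
    for name, size in zip(("set1", "set2", "set3"), set_sizes):
        genes.loc[chosen[pos:pos + size], "de_set"] = name
        pos += size


def expected_contact_matrix(truth: SyntheticTruth, condition: str, chrom: str,
                            binsize: int | None = None) -> np.ndarray:
    """Closed-form unnormalized contact intensity mu for one chromosome.

    mu_ij = (|i-j| + 1)^-alpha * kappa^[same compartment] * tau^[same TAD]
            * b_i b_j * delta^[constricted and both B and separation < 1 Mb].
    Exposed so tests can use the generative law as an oracle.
    """
    config = truth.config
    if condition not in truth.labels:
        raise ValueError(f"unknown condition {condition!r}")
    binsize = binsize or config.comp_binsize
    binning = truth.binning.with_binsize(binsize)
    n = binning.n_bins(chrom)
    mids = np.asarray(binning.bin_mid(chrom, np.arange(n)))
    parent = (mids // config.comp_binsize).astype(np.int64)
    lab = truth.labels[condition][chrom][parent]
    tad_id = np.searchsorted(truth.boundaries[condition][chrom], mids, side="right")
    b = truth.bias[chrom][parent]
    sep = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    mu = (sep + 1.0) ** (-config.alpha)
    mu *= np.where(np.equal.outer(lab, lab), config.kappa, 1.0)
    mu *= np.where(np.equal.outer(tad_id, tad_id), config.tau, 1.0)
    mu *= np.outer(b, b)
    if condition == CONSTRICTED:
        both_b = np.logical_and.outer(lab == "B", lab == "B")
        short = sep * binsize < 1_000_000
        mu *= np.where(both_b & short, config.delta, 1.0)
    return mu


def simulate_map(truth: SyntheticTruth, condition: str, total_reads: int,
                 seed: int = 0, binsize: int | None = None,
                 exact_total: bool = False) -> ContactMap:
    """Draw a contact map for one condition at the given resolution.

    Entry means follow :func:`expected_contact_matrix`, scaled so the sum of
    the upper triangle (diagonal included) over all chromosomes equals
    ``total_reads``; counts are independent Poisson. With ``exact_total``
    the counts are instead a single multinomial draw of exactly
    ``total_reads`` contacts, so the total is conserved exactly.
    """
    if condition not in truth.labels:
        raise ValueError(f"unknown condition {condition!r}")
    if total_reads < 0:
        raise ValueError("total_reads must be >= 0")
    config = truth.config
    binsize = binsize or config.comp_binsize
    binning = truth.binning.with_binsize(binsize)
    if total_reads == 0:
        return ContactMap(binning, {c: (np.empty(0, np.int64),) * 3 for c in binning.chroms})
    mus, triu = {}, {}
    z = 0.0
    for chrom in binning.chroms:
        mu = expected_contact_matrix(truth, condition, chrom, binsize)
        iu, ju = np.triu_indices(mu.shape[0])
        vals = mu[iu, ju]
        mus[chrom] = (iu, ju, vals)
        z += vals.sum()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    pixels = {}
    if exact_total:
        flat = np.concatenate([mus[c][2] for c in binning.chroms])
        draws = rng.multinomial(total_reads, flat / flat.sum())
        pos = 0
        for chrom in binning.chroms:
            iu, ju, vals = mus[chrom]
            c = draws[pos:pos + vals.size]
            pos += vals.size
            keep = c > 0
            pixels[chrom] = (iu[keep], ju[keep], c[keep].astype(np.int64))
    else:
        scale = total_reads / z
        for chrom in binning.chroms:
            iu, ju, vals = mus[chrom]
            c = rng.poisson(vals * scale)
            keep = c > 0
            pixels[chrom] = (iu[keep], ju[keep], c[keep].astype(np.int64))
    return ContactMap(binning, pixels)


def simulate_de(truth: SyntheticTruth, n_genes: int | None = None,
                set_sizes: tuple[int, int, int] | None = None,
                rho_sets: tuple[float, float, float] | None = None,
                seed: int = 0) -> pd.DataFrame:
    """Differential-expression tables for the three contrasts.

    Per-set log2 fold changes for the 5-um-vs-control and 14-um-vs-control
    contrasts are correlated bivariate normals at the planted per-set
    correlation; the 5-um-vs-14-um fold change is their difference. FDR
    columns are planted exactly below 0.05 for the contrasts that define
    each set and at or above 0.05 otherwise, so a set classifier recovers
    membership by construction. Background genes are null in all contrasts.

    By default the table is built on the truth's gene table and planted set
    labels; passing ``n_genes``/``set_sizes`` regenerates an independent
    gene universe with the same recipe.
    """
    config = truth.config
    rho_sets = tuple(rho_sets) if rho_sets is not None else config.rho_sets
    for rho in rho_sets:
        if not -1.0 <= rho <= 1.0:
            raise ValueError(f"rho out of [-1,1]: {rho}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    regenerate = ((n_genes is not None and n_genes != len(truth.genes))
                  or (set_sizes is not None and tuple(set_sizes) != tuple(config.set_sizes)))
    if regenerate:
        n_genes = n_genes if n_genes is not None else len(truth.genes)
        set_sizes = tuple(set_sizes) if set_sizes is not None else config.set_sizes
        if sum(set_sizes) > n_genes:
            raise ValueError("sum of set sizes exceeds n_genes")
        cfg = replace(config, n_genes=n_genes, set_sizes=set_sizes)
        genes = _make_gene_table(truth.binning, truth.labels[BASELINE], cfg, rng)
        _assign_de_sets(genes, set_sizes, rng)
    else:
        genes = truth.genes.copy()
    de = genes.copy()
    n = len(de)
    for contrast in CONTRASTS:
        de[f"lfc_{contrast}"] = 0.0
        de[f"fdr_{contrast}"] = 0.0

    def plant_fdr(idx, contrast, significant):
        m = len(idx)
        if significant:
            de.loc[idx, f"fdr_{contrast}"] = rng.uniform(1e-8, 0.049999, m)
        else:
            de.loc[idx, f"fdr_{contrast}"] = rng.uniform(0.05, 1.0, m)

    # which contrasts are planted significant for each set
    sig_plan = {"set1": ("5v0", "14v0"), "set2": ("5v0",), "set3": ("5v0", "5v14")}
    for name, rho in zip(("set1", "set2", "set3"), rho_sets):
        idx = de.index[de["de_set"] == name]
        m = len(idx)
        x = rng.standard_normal(m)
        y = rho * x + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal(m)
        lfc5 = config.lfc_sigma * x
        lfc14 = config.lfc_sigma * y * (0.5 if name == "set2" else 1.0)
        de.loc[idx, "lfc_5v0"] = lfc5
        de.loc[idx, "lfc_14v0"] = lfc14
        de.loc[idx, "lfc_5v14"] = lfc5 - lfc14
        for contrast in CONTRASTS:
            plant_fdr(idx, contrast, contrast in sig_plan[name])
    bg = de.index[de["de_set"] == "other"]
    m = len(bg)
    lfc5 = rng.normal(0.0, 0.15, m)
    lfc14 = rng.normal(0.0, 0.15, m)
    de.loc[bg, "lfc_5v0"] = lfc5
    de.loc[bg, "lfc_14v0"] = lfc14
    de.loc[bg, "lfc_5v14"] = lfc5 - lfc14
    for contrast in CONTRASTS:
        plant_fdr(bg, contrast, False)
    return de
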