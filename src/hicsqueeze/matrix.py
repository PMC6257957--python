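"""Contact-map container, ICE balancing, depth matching, and distance decay.

A :class:`ContactMap` holds intrachromosomal binned counts for one condition
as per-chromosome sparse upper-triangular triples. Matrices at desk scale
(hundreds to a couple of thousand bins per chromosome) are densified freely
for the numerical steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .binning import GenomeBinning
from .stats import TestResult, weighted_quantile_expand


@dataclass
class ContactMap:
    """Sparse upper-triangular intrachromosomal contact counts.

    ``pixels`` maps chromosome -> (bin1, bin2, count) integer arrays with
    bin1 <= bin2 and count >= 0; per-chromosome bin indices.
    """

    binning: GenomeBinning
    pixels: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        for chrom, (i, j, c) in self.pixels.items():
            n = self.binning.n_bins(chrom)
            if np.any(c < 0):
                raise ValueError(f"negative counts on {chrom}")
            if np.any(i > j):
                raise ValueError(f"lower-triangle entries on {chrom}")
            if np.any(i < 0) or np.any(j >= n):
                raise ValueError(f"bin index out of range on {chrom}")

    @property
    def total(self) -> int:
        return int(sum(int(c.sum()) for _, _, c in self.pixels.values()))

    def dense(self, chrom: str) -> np.ndarray:
        """Dense symmetric counts matrix for one chromosome."""
        n = self.binning.n_bins(chrom)
        m = np.zeros((n, n), dtype=float)
        if chrom in self.pixels:
            i, j, c = self.pixels[chrom]
            m[i, j] = c
            m[j, i] = c  # diagonal written twice, same value
        return m

    @classmethod
    def from_dense(cls, binning: GenomeBinning, mats: dict[str, np.ndarray]) -> "ContactMap":
        pixels = {}
        for chrom, m in mats.items():
            iu, ju = np.triu_indices(m.shape[0])
            c = np.asarray(m[iu, ju])
            keep = c > 0
            vals = c[keep]
            if vals.size and np.allclose(vals, np.round(vals)):
                vals = np.round(vals).astype(np.int64)
            pixels[chrom] = (iu[keep].astype(np.int64), ju[keep].astype(np.int64), vals)
        return cls(binning, pixels)

    def to_frame(self) -> pd.DataFrame:
        """Sparse triples as a DataFrame (chrom, start1, start2, count)."""
        bs = self.binning.binsize
        parts = [
            pd.DataFrame({"chrom": chrom, "start1": i * bs, "start2": j * bs, "count": c})
            for chrom, (i, j, c) in self.pixels.items()
        ]
        if not parts:
            return pd.DataFrame(columns=["chrom", "start1", "start2", "count"])
        return pd.concat(parts, ignore_index=True)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, binning: GenomeBinning) -> "ContactMap":
        df = pd.read_csv(path, sep="\t")
        pixels = {}
        bs = binning.binsize
        for chrom, sub in df.groupby("chrom", sort=False):
            pixels[str(chrom)] = (
                (sub["start1"].to_numpy() // bs).astype(np.int64),
                (sub["start2"].to_numpy() // bs).astype(np.int64),
                sub["count"].to_numpy().astype(np.int64),
            )
        return cls(binning, pixels)


@dataclass
class BalancedMap:
    """ICE-balanced map: source counts, per-bin biases, and bin mask.

    ``biases`` are NaN at masked bins; ``balanced_ij = count_ij/(bias_i bias_j)``.
    """

    source: ContactMap
    biases: dict[str, np.ndarray]
    mask: dict[str, np.ndarray]  # True where the bin is excluded
    converged: dict[str, bool]
    n_iter: dict[str, int]

    @property
    def binning(self) -> GenomeBinning:
        return self.source.binning

    def balanced_dense(self, chrom: str) -> np.ndarray:
        """Dense balanced matrix, NaN at masked rows/columns."""
        m = self.source.dense(chrom)
        b = self.biases[chrom]
        with np.errstate(invalid="ignore", divide="ignore"):
            out = m / np.outer(b, b)
        out[self.mask[chrom], :] = np.nan
        out[:, self.mask[chrom]] = np.nan
        return out


def ice_balance(cmap: ContactMap, tol: float = 1e-5, max_iter: int = 200,
                min_marginal: float = 0.0) -> BalancedMap:
    """Iterative correction (ICE) of a contact map, per chromosome.

    Bins whose raw marginal sum is zero or below ``min_marginal`` are masked
    before iteration. Each iteration computes the balanced marginals
    m_i = sum_j count_ij/(b_i b_j) and updates b_i <- b_i * m_i / mean(m),
    stopping when the coefficient of variation of the unmasked marginals
    drops below ``tol``. A chromosome that fails to converge within
    ``max_iter`` is flagged, not raised.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if cmap.total == 0 and not cmap.pixels:
        raise ValueError("empty contact map")
    biases, mask, converged, n_iter = {}, {}, {}, {}
    for chrom in cmap.binning.chroms:
        W = cmap.dense(chrom)
        n = W.shape[0]
        marg = W.sum(axis=1)
        excl = (marg <= 0) | (marg < min_marginal)
        b = np.ones(n)
        ok = False
        it = 0
        if np.all(excl):
            b[:] = np.nan
            biases[chrom], mask[chrom] = b, excl
            converged[chrom], n_iter[chrom] = True, 0  # fully masked, trivially done
            continue
        Wm = W[np.ix_(~excl, ~excl)]
        bu = np.ones(Wm.shape[0])
        for it in range(1, max_iter + 1):
            m = (Wm @ (1.0 / bu)) / bu
            mean = m.mean()
            cv = m.std() / mean
            if cv < tol:
                ok = True
                break
            bu *= m / mean
        b[:] = np.nan
        b[~excl] = bu
        biases[chrom], mask[chrom] = b, excl
        converged[chrom], n_iter[chrom] = ok, it
    return BalancedMap(cmap, biases, mask, converged, n_iter)


def downsample_to_common_total(maps: list[ContactMap], seed: int) -> list[ContactMap]:
    """Thin maps to the minimum total count among them.

    Sampling is without replacement from the multiset of contacts (exact
    multivariate hypergeometric on the concatenated entry counts), so totals
    match exactly and zero entries stay zero.
    """
    if len(maps) < 2:
        raise ValueError("need at least two maps")
    target = min(m.total for m in maps)
    out = []
    for k, cmap in enumerate(maps):
        if cmap.total == target:
            out.append(cmap)
            continue
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(k,)))
        chroms = [c for c in cmap.pixels]
        counts = np.concatenate([cmap.pixels[c][2] for c in chroms])
        thinned = rng.multivariate_hypergeometric(counts, target, method="marginals")
        pixels = {}
        pos = 0
        for c in chroms:
            i, j, old = cmap.pixels[c]
            new = thinned[pos:pos + old.size]
            pos += old.size
            keep = new > 0
            pixels[c] = (i[keep], j[keep], new[keep].astype(np.int64))
        out.append(ContactMap(cmap.binning, pixels))
    return out


@dataclass
class DecayCurve:
    """Mean balanced contact frequency per genomic-separation stratum."""

    edges: np.ndarray  # bp, len k+1, increasing
    freq: np.ndarray   # len k, NaN where the stratum is empty

    def __post_init__(self) -> None:
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("edges must be increasing")
        if np.any(self.freq[np.isfinite(self.freq)] < 0):
            raise ValueError("negative frequencies")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"edge_lo": self.edges[:-1], "edge_hi": self.edges[1:],
                             "mean_freq": self.freq})


def default_decay_edges(binning: GenomeBinning) -> np.ndarray:
    """Log-spaced separation edges (factor sqrt(2)) from one bin to the longest chromosome."""
    lo = binning.binsize
    hi = max(binning.chrom_lengths.values())
    edges = [float(lo)]
    while edges[-1] < hi:
        edges.append(edges[-1] * np.sqrt(2.0))
    return np.asarray(edges)


def decay_curve(bal: BalancedMap, edges: np.ndarray | None = None) -> DecayCurve:
    """Distance-decay P(s): mean balanced frequency per separation stratum.

    Strata means are computed per chromosome over all unmasked pairs (zeros
    included), then averaged across chromosomes. Empty strata are NaN.
    """
    binning = bal.binning
    if edges is None:
        edges = default_decay_edges(binning)
    edges = np.asarray(edges, dtype=float)
    k = edges.size - 1
    if k < 1:
        raise ValueError("need at least one stratum")
    per_chrom = np.full((len(binning.chroms), k), np.nan)
    for ci, chrom in enumerate(binning.chroms):
        m = bal.balanced_dense(chrom)
        n = m.shape[0]
        sums = np.zeros(k)
        cnts = np.zeros(k)
        for s in range(1, n):
            sep_bp = s * binning.binsize
            stratum = np.searchsorted(edges, sep_bp, side="right") - 1
            if stratum < 0 or stratum >= k:
                continue
            d = np.diagonal(m, offset=s)
            fin = np.isfinite(d)
            sums[stratum] += d[fin].sum()
            cnts[stratum] += fin.sum()
        per_chrom[ci] = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    fin = np.isfinite(per_chrom)
    with np.errstate(invalid="ignore"):
        freq = np.where(fin.any(axis=0),
                        np.nansum(np.where(fin, per_chrom, 0.0), axis=0)
                        / np.maximum(fin.sum(axis=0), 1), np.nan)
    return DecayCurve(edges, freq)


def compare_decay(bal_a: BalancedMap, bal_b: BalancedMap,
                  n_points: int = 100_000) -> TestResult:
    """Two-sample KS test on contact-weighted genomic-separation distributions.

    Each map contributes the distribution of pairwise separations weighted by
    balanced contact frequency, realized as a deterministic ``n_points``-point
    weighted-quantile expansion; the expansions are compared with the
    standard two-sample KS test.
    """
    if bal_a.binning.chrom_lengths != bal_b.binning.chrom_lengths or \
            bal_a.binning.binsize != bal_b.binning.binsize:
        raise ValueError("maps must share a binning")

    def weighted_seps(bal: BalancedMap) -> np.ndarray:
        # weight per separation = total balanced frequency at that separation
        seps, weights = [], []
        for chrom in bal.binning.chroms:
            m = bal.balanced_dense(chrom)
            for s in range(1, m.shape[0]):
                w = np.nansum(np.diagonal(m, offset=s))
                if w > 0:
                    seps.append(s * bal.binning.binsize)
                    weights.append(w)
        if not seps:
            raise ValueError("empty balanced map")
        return weighted_quantile_expand(np.asarray(seps, float),
                                        np.asarray(weights, float), n_points)

    xa, xb = weighted_seps(bal_a), weighted_seps(bal_b)
    d, p = sps.ks_2samp(xa, xb)
    return TestResult(float(d), float(p),
                      f"weighted KS on separation distributions "
                      f"(quantile expansion, n={n_points})")


def observed_expected(bal: BalancedMap) -> dict[str, np.ndarray]:
    """Observed/expected matrices: each entry over the per-chromosome mean
    balanced frequency at its separation. Masked bins and zero-expected
    separations propagate as NaN.
    """
    out = {}
    for chrom in bal.binning.chroms:
        m = bal.balanced_dense(chrom)
        n = m.shape[0]
        oe = np.full_like(m, np.nan)
        for s in range(0, n):
            d = np.diagonal(m, offset=s)
            fin = np.isfinite(d)
            if not fin.any():
                continue
            exp = np.nanmean(d)
            if not np.isfinite(exp) or exp <= 0:
                continue
            idx = np.arange(n - s)
            oe[idx, idx + s] = d / exp
            oe[idx + s, idx] = d / exp
        out[chrom] = oe
    return out
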