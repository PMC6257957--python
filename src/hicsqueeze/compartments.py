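"""A/B compartment calling, inter-condition comparison, and switch detection.

Compartments are the sign structure of the first principal component of
the per-chromosome Pearson correlation matrix of the observed/expected
contact map, oriented so that positive PC1 correlates with transcriptional
activity (A = active, B = inactive). A bin switches compartment between two
conditions when its PC1 sign flips AND its interaction pattern decorrelates
(per-bin correlation of the two correlation-matrix rows below a threshold,
0.6 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binning import GenomeBinning
from .stats import TestResult, logistic_fit

STATUSES = ("stable-A", "stable-B", "switch A>B", "switch B>A", "masked")


def correlation_matrix(oe: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Per-chromosome Pearson correlation of O/E rows over unmasked columns.

    Bins whose O/E row is entirely missing, or constant, come back as NaN
    rows/columns. Requires >= 3 unmasked bins per chromosome.
    """
    out = {}
    for chrom, m in oe.items():
        n = m.shape[0]
        valid = ~np.all(np.isnan(m), axis=1)
        if valid.sum() < 3:
            raise ValueError(f"{chrom}: fewer than 3 unmasked bins")
        sub = m[np.ix_(valid, valid)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            corr = np.ma.corrcoef(np.ma.masked_invalid(sub)).filled(np.nan)
        # constant rows have zero variance -> undefined correlation -> masked
        const = np.nanstd(sub, axis=1) == 0
        corr[const, :] = np.nan
        corr[:, const] = np.nan
        full = np.full((n, n), np.nan)
        full[np.ix_(valid, valid)] = corr
        out[chrom] = full
    return out


@dataclass
class CompartmentProfile:
    """Per-bin PC1 scores and A/B labels for one condition.

    ``pc1`` is NaN at masked bins; ``labels`` holds 'A' (PC1 > 0),
    'B' (PC1 < 0) or '' (masked). ``orientation_r`` is the correlation
    between PC1 and the activity track used to fix the sign;
    ``ambiguous`` flags chromosomes where that correlation is too weak to
    orient confidently, and ``degenerate`` flags (near-)tied leading
    eigenvalues. ``arm_flag`` is filled by :func:`flag_arm_artifact`.
    """

    binning: GenomeBinning
    pc1: dict[str, np.ndarray]
    labels: dict[str, np.ndarray]
    orientation_r: dict[str, float]
    ambiguous: dict[str, bool]
    degenerate: dict[str, bool]
    arm_flag: dict[str, bool] = field(default_factory=dict)

    def label_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in self.binning.chroms:
            lab = self.labels[chrom]
            starts = np.arange(lab.size) * self.binning.binsize
            ends = np.minimum(starts + self.binning.binsize,
                              self.binning.chrom_lengths[chrom])
            rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends,
                                      "label": lab, "pc1": self.pc1[chrom]}))
        return pd.concat(rows, ignore_index=True)


def compartment_profile(corr: dict[str, np.ndarray], activity_track: dict[str, np.ndarray],
                        binning: GenomeBinning, ambiguity_r: float = 0.1) -> CompartmentProfile:
    """PC1 of the correlation matrix per chromosome, oriented by activity.

    The sign is flipped so that correlation(PC1, activity) >= 0; if that
    correlation's magnitude is below ``ambiguity_r`` the chromosome is
    flagged ambiguous (orientation kept but untrustworthy).
    """
    pc1, labels, orient, ambig, degen = {}, {}, {}, {}, {}
    for chrom, c in corr.items():
        n = c.shape[0]
        valid = ~np.all(np.isnan(c), axis=1)
        x = c[np.ix_(valid, valid)]
        x = np.where(np.isnan(x), 0.0, x)  # residual missing entries contribute nothing
        xc = x - x.mean(axis=0, keepdims=True)
        u, s, _ = np.linalg.svd(xc, full_matrices=False)
        scores = u[:, 0] * s[0]
        degen[chrom] = bool(s.size > 1 and (s[0] - s[1]) <= 1e-10 * max(s[0], 1e-300))
        act = np.asarray(activity_track[chrom], dtype=float)[valid]
        if np.std(scores) == 0 or np.std(act) == 0:
            r = 0.0
        else:
            r = float(np.corrcoef(scores, act)[0, 1])
        if r < 0:
            scores = -scores
        orient[chrom] = abs(r)
        ambig[chrom] = abs(r) < ambiguity_r
        v = np.full(n, np.nan)
        v[valid] = scores
        pc1[chrom] = v
        lab = np.full(n, "", dtype="<U1")
        lab[valid & (v > 0)] = "A"
        lab[valid & (v < 0)] = "B"
        labels[chrom] = lab
    return CompartmentProfile(binning, pc1, labels, orient, ambig, degen)


def flag_arm_artifact(profile: CompartmentProfile, centromeres: dict[str, int],
                      threshold: float = 0.7) -> dict[str, bool]:
    """Flag chromosomes whose PC1 tracks the chromosome arms, not compartments.

    The arm indicator is -1 before / +1 after the centromere; a chromosome is
    flagged when |corr(PC1, indicator)| exceeds ``threshold`` and should be
    excluded from switching analysis. Flags are stored on the profile and
    returned.
    """
    flags = {}
    for chrom in profile.binning.chroms:
        cen = centromeres[chrom]
        if not 0 < cen < profile.binning.chrom_lengths[chrom]:
            raise ValueError(f"centromere outside {chrom}")
        v = profile.pc1[chrom]
        fin = np.isfinite(v)
        mids = profile.binning.bin_mid(chrom, np.arange(v.size))
        arm = np.where(mids < cen, -1.0, 1.0)
        if fin.sum() < 3 or np.std(v[fin]) == 0 or np.std(arm[fin]) == 0:
            flags[chrom] = False
        else:
            r = np.corrcoef(v[fin], arm[fin])[0, 1]
            flags[chrom] = bool(abs(r) > threshold)
    profile.arm_flag = flags
    return flags


def correlation_diff(corr_a: dict[str, np.ndarray],
                     corr_b: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Per-bin correlation R between conditions' interaction patterns.

    R_i is the Pearson correlation between row i of the two correlation
    matrices over mutually unmasked columns, the diagonal excluded; NaN
    when fewer than 3 shared columns remain.
    """
    out = {}
    for chrom in corr_a:
        a, b = corr_a[chrom], corr_b[chrom]
        if a.shape != b.shape:
            raise ValueError(f"{chrom}: shape mismatch")
        n = a.shape[0]
        r = np.full(n, np.nan)
        for i in range(n):
            ra, rb = a[i].copy(), b[i].copy()
            ra[i] = rb[i] = np.nan
            shared = np.isfinite(ra) & np.isfinite(rb)
            if shared.sum() < 3:
                continue
            x, y = ra[shared], rb[shared]
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            r[i] = np.corrcoef(x, y)[0, 1]
        out[chrom] = r
    return out


def call_switches(profile_a: CompartmentProfile, profile_b: CompartmentProfile,
                  diff: dict[str, np.ndarray], r_threshold: float = 0.6,
                  skip_arm_flagged: bool = True) -> pd.DataFrame:
    """Classify each 100-kb bin as stable, switched, or masked.

    A switch requires BOTH an opposite PC1 sign between conditions AND an
    interaction-pattern correlation strictly below ``r_threshold``. Bins
    meeting exactly one criterion are conservatively labeled stable (by the
    condition-A sign); their count is reported in ``attrs['partial']``.
    Chromosomes arm-flagged in either profile are masked wholesale.
    """
    rows = []
    partial = 0
    binning = profile_a.binning
    for chrom in binning.chroms:
        pa, pb = profile_a.pc1[chrom], profile_b.pc1[chrom]
        r = diff[chrom]
        n = pa.size
        starts = np.arange(n) * binning.binsize
        arm_skip = skip_arm_flagged and (profile_a.arm_flag.get(chrom, False)
                                         or profile_b.arm_flag.get(chrom, False))
        status = np.full(n, "masked", dtype=object)
        for i in range(n):
            if arm_skip or not (np.isfinite(pa[i]) and np.isfinite(pb[i])
                                and np.isfinite(r[i])) or pa[i] == 0 or pb[i] == 0:
                continue
            opposite = (pa[i] > 0) != (pb[i] > 0)
            low_r = r[i] < r_threshold
            if opposite and low_r:
                status[i] = "switch A>B" if pa[i] > 0 else "switch B>A"
            else:
                if opposite != low_r:  # exactly one criterion met
                    partial += 1
                status[i] = "stable-A" if pa[i] > 0 else "stable-B"
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts,
                                  "pc1_a": pa, "pc1_b": pb, "r": r, "status": status}))
    table = pd.concat(rows, ignore_index=True)
    table.attrs["r_threshold"] = r_threshold
    table.attrs["partial"] = partial
    return table


def switch_compartment_test(table: pd.DataFrame, n_boot: int = 10_000,
                            ci: float = 0.99, seed: int = 0) -> TestResult:
    """Is switching biased toward one source compartment?

    Logistic regression of switched (0/1) on source compartment (B vs A,
    source = compartment in condition A), plus a bins bootstrap
    (``n_boot`` resamples, percentile CI at level ``ci``) of each
    compartment's switch rate. When the regression is separable the Wald
    output is flagged and the bootstrap is authoritative.
    """
    sub = table[table["status"] != "masked"]
    src_b = sub["status"].isin(["stable-B", "switch B>A"]).to_numpy()
    if src_b.all() or not src_b.any():
        raise ValueError("both compartments must be represented")
    switched = sub["status"].str.startswith("switch").to_numpy().astype(float)
    res = logistic_fit(switched, src_b.astype(float))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rates = {}
    for name, mask in (("A", ~src_b), ("B", src_b)):
        y = switched[mask]
        n = y.size
        idx = rng.integers(0, n, size=(n_boot, n))
        boots = y[idx].mean(axis=1)
        lo, hi = np.quantile(boots, [(1 - ci) / 2, 1 - (1 - ci) / 2])
        rates[name] = {"rate": float(y.mean()), "n": int(n),
                       "ci": (float(lo), float(hi))}
    res.aux["bootstrap"] = rates
    res.aux["n_boot"] = n_boot
    res.method = "logistic regression of switching on source compartment"
    return res
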