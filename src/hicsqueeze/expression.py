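"""Differential-expression integration: three-set gene classification,
per-bin transcriptional activity, and expression-vs-switching tests.

The three contrasts are migration-with-constriction vs control ("5v0",
after the 5-um pore condition), migration-without-constriction vs control
("14v0"), and the two migration conditions against each other ("5v14").
Genes significant after constricted migration split into: set1, shared
migration effects (also significant without constriction); set2,
amplified-by-constriction effects (significant only vs control); and
set3, constriction-specific effects (also significant between the two
migration conditions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binning import GenomeBinning
from .stats import TestResult, anova_tukey

SET_NAMES = ("set1", "set2", "set3")


@dataclass
class GeneSets:
    """Classification outcome: per-gene labels, sizes, and per-set R^2.

    ``venn`` holds all seven significance regions (keys like "5v0&14v0"),
    counted before set precedence is applied; ``overlap13`` is the number
    of genes meeting both the set1 and set3 definitions (assigned to set3).
    """

    labels: pd.Series
    sizes: dict[str, int]
    r2: dict[str, float]
    venn: dict[str, int]
    overlap13: int


def _ols_r2(x: np.ndarray, y: np.ndarray) -> float:
    """R^2 of a simple least-squares line (symmetric in x and y)."""
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def classify_sets(de: pd.DataFrame, fdr: float = 0.05) -> GeneSets:
    """Partition genes into the three migration-response sets.

    set1 = significant in 5v0 AND 14v0; set3 = significant in 5v0 AND
    5v14 (taking precedence over set1 when both definitions match);
    set2 = significant in 5v0 only. Everything else is "other". Per-set
    R^2 relates the 14v0 to the 5v0 log2 fold changes of the set's genes.
    """
    for c in ("5v0", "14v0", "5v14"):
        if f"fdr_{c}" not in de or f"lfc_{c}" not in de:
            raise ValueError(f"missing contrast columns for {c}")
    s5 = de["fdr_5v0"] < fdr
    s14 = de["fdr_14v0"] < fdr
    s514 = de["fdr_5v14"] < fdr
    labels = pd.Series("other", index=de.index, name="set_label")
    labels[s5 & s14] = "set1"
    labels[s5 & ~s14 & ~s514] = "set2"
    labels[s5 & s514] = "set3"  # precedence over set1
    overlap13 = int((s5 & s14 & s514).sum())
    venn = {}
    for key, m in (("5v0 only", s5 & ~s14 & ~s514),
                   ("14v0 only", ~s5 & s14 & ~s514),
                   ("5v14 only", ~s5 & ~s14 & s514),
                   ("5v0&14v0", s5 & s14 & ~s514),
                   ("5v0&5v14", s5 & ~s14 & s514),
                   ("14v0&5v14", ~s5 & s14 & s514),
                   ("all", s5 & s14 & s514)):
        venn[key] = int(m.sum())
    sizes = {name: int((labels == name).sum()) for name in SET_NAMES}
    r2 = {}
    for name in SET_NAMES:
        sub = de[labels == name]
        r2[name] = _ols_r2(sub["lfc_5v0"].to_numpy(), sub["lfc_14v0"].to_numpy()) \
            if len(sub) else float("nan")
    return GeneSets(labels, sizes, r2, venn, overlap13)


def active_bins(de: pd.DataFrame, binning: GenomeBinning) -> dict[str, np.ndarray]:
    """Flag each bin transcriptionally active iff >= 1 expressed gene overlaps it.

    Any overlap counts, so a gene spanning a bin edge activates both bins.
    Genes outside the binning's chromosomes or coordinates raise.
    """
    flags = {c: np.zeros(binning.n_bins(c), dtype=bool) for c in binning.chroms}
    for row in de.itertuples(index=False):
        if row.chrom not in flags:
            raise ValueError(f"gene {row.gene_id} on unknown chromosome {row.chrom}")
        if row.start < 0 or row.end > binning.chrom_lengths[row.chrom] or row.end <= row.start:
            raise ValueError(f"gene {row.gene_id} outside {row.chrom}")
        if not row.expressed:
            continue
        lo = row.start // binning.binsize
        hi = (row.end - 1) // binning.binsize
        flags[row.chrom][lo:hi + 1] = True
    return flags


def logfc_by_switch(de: pd.DataFrame, switches: pd.DataFrame,
                    contrast: str = "5v14", fdr: float = 0.05,
                    binsize: int = 100_000) -> TestResult:
    """Does expression change track compartment-switch status?

    One-way ANOVA (Tukey-adjusted pairwise p-values) of the ``contrast``
    log2 fold change of significant genes across the switch status of the
    bin containing each gene's midpoint (stable-A, stable-B, A>B, B>A).
    Categories with fewer than 2 genes are dropped with a warning; fewer
    than two surviving categories is an error.
    """
    sig = de[de[f"fdr_{contrast}"] < fdr].copy()
    status_map = {(row.chrom, int(row.start) // binsize): row.status
                  for row in switches.itertuples(index=False)}
    mids = ((sig["start"] + sig["end"]) // 2 // binsize).astype(int)
    sig["status"] = [status_map.get((c, b), "masked")
                     for c, b in zip(sig["chrom"], mids)]
    sig = sig[sig["status"] != "masked"]
    counts = sig["status"].value_counts()
    small = counts[counts < 2].index.tolist()
    if small:
        warnings.warn(f"dropping switch categories with < 2 genes: {small}")
        sig = sig[~sig["status"].isin(small)]
    if sig["status"].nunique() < 2:
        raise ValueError("need at least two switch categories with >= 2 genes")
    res = anova_tukey(sig[f"lfc_{contrast}"].to_numpy(), sig["status"].to_numpy())
    res.method = f"one-way ANOVA of {contrast} logFC by switch status (Tukey)"
    return res
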