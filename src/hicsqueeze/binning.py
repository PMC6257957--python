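"""Genome binning: fixed-width bins over a set of chromosomes.

Coordinates are 0-based half-open throughout. The last bin of each
chromosome may be partial. Bins carry both a per-chromosome index and a
contiguous global index (chromosomes concatenated in declaration order).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class GenomeBinning:
    """Fixed-size binning of a genome.

    Parameters
    ----------
    chrom_lengths:
        Mapping chromosome name -> length in bp, in genome order.
    binsize:
        Bin width in bp; must be positive.
    """

    chrom_lengths: dict[str, int]
    binsize: int
    _offsets: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.binsize <= 0:
            raise ValueError(f"binsize must be positive, got {self.binsize}")
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length")
        offsets, cum = {}, 0
        for chrom in self.chrom_lengths:
            offsets[chrom] = cum
            cum += self.n_bins(chrom)
        object.__setattr__(self, "_offsets", offsets)

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    def n_bins(self, chrom: str) -> int:
        return -(-self.chrom_lengths[chrom] // self.binsize)  # ceil div

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.chroms)

    def offset(self, chrom: str) -> int:
        """Global index of the first bin of ``chrom``."""
        return self._offsets[chrom]

    def bin_index(self, chrom: str, pos: int | np.ndarray) -> int | np.ndarray:
        """Per-chromosome bin index of position ``pos`` (0-based)."""
        length = self.chrom_lengths[chrom]
        if np.any(np.asarray(pos) < 0) or np.any(np.asarray(pos) >= length):
            raise ValueError(f"position out of range for {chrom}")
        return np.asarray(pos) // self.binsize if isinstance(pos, np.ndarray) else pos // self.binsize

    def bin_start(self, chrom: str, i: int | np.ndarray) -> int | np.ndarray:
        return i * self.binsize

    def bin_mid(self, chrom: str, i: int | np.ndarray) -> int | np.ndarray:
        """Midpoint of bin i, clipped to the chromosome for partial last bins."""
        start = i * self.binsize
        end = np.minimum(start + self.binsize, self.chrom_lengths[chrom])
        return (start + end) // 2

    def with_binsize(self, binsize: int) -> "GenomeBinning":
        return GenomeBinning(dict(self.chrom_lengths), binsize)

    def bins_table(self):
        """All bins as a (chrom, start, end) DataFrame in genome order."""
        import pandas as pd

        rows = []
        for chrom in self.chroms:
            n = self.n_bins(chrom)
            starts = np.arange(n) * self.binsize
            ends = np.minimum(starts + self.binsize, self.chrom_lengths[chrom])
            rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)
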