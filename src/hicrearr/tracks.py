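"""Per-bin scalar tracks (compartment scores, insulation, ChIP-like signal)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import BinIndex

__all__ = ["BinnedTrack"]


@dataclass
class BinnedTrack:
    """One real value (or NaN for missing) per global bin of a :class:`BinIndex`."""

    bins: BinIndex
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.bins.n_bins,):
            raise ValueError(
                f"track length {self.values.shape} != bin count {self.bins.n_bins}"
            )

    def chrom_values(self, chrom: str) -> np.ndarray:
        lo, hi = self.bins.chrom_span(chrom)
        return self.values[lo:hi]

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def mask_intervals(self, intervals) -> "BinnedTrack":
        """Return a copy with bins overlapping any (chrom, start, end) set to NaN."""
        out = self.values.copy()
        res = self.bins.resolution
        for chrom, start, end in intervals:
            lo, hi = self.bins.chrom_span(chrom)
            b0 = lo + int(start) // res
            b1 = lo + (int(end) - 1) // res + 1
            out[max(lo, b0):min(hi, b1)] = np.nan
        return BinnedTrack(self.bins, out, self.label)
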