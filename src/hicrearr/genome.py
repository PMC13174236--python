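"""Genome layout and fixed-resolution bin indexing.

All coordinates in this package are 0-based, half-open. Bins are addressed
by a single global integer id that runs over chromosomes in layout order;
the last bin of each chromosome may be shorter than the resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenomeLayout", "BinIndex", "make_bin_index", "toy_layout"]


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths (bp)."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "GenomeLayout":
        return cls(tuple(d.keys()), tuple(int(v) for v in d.values()))

    def length_of(self, name: str) -> int:
        return self.lengths[self.names.index(name)]

    def __contains__(self, name: str) -> bool:
        return name in self.names


def toy_layout(n_chroms: int = 4, chrom_length: int = 10_000_000) -> GenomeLayout:
    """Default desk-scale genome: ``n_chroms`` chromosomes of equal length."""
    return GenomeLayout(
        tuple(f"chr{i + 1}" for i in range(n_chroms)),
        tuple(chrom_length for _ in range(n_chroms)),
    )


@dataclass
class BinIndex:
    """Tiling of a :class:`GenomeLayout` into fixed-width bins.

    Global bin ids are contiguous, chromosome-major. ``n_bins_per_chrom[c]``
    = ceil(length/resolution); ``offsets[c]`` is the global id of the first
    bin of chromosome ``c``.
    """

    layout: GenomeLayout
    resolution: int
    offsets: np.ndarray = field(init=False, repr=False)
    n_bins_per_chrom: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be a positive integer")
        lengths = np.asarray(self.layout.lengths, dtype=np.int64)
        self.n_bins_per_chrom = -(-lengths // self.resolution)
        self.offsets = np.concatenate([[0], np.cumsum(self.n_bins_per_chrom)])
        self._chrom_idx = {n: i for i, n in enumerate(self.layout.names)}

    @property
    def n_bins(self) -> int:
        return int(self.offsets[-1])

    def chrom_index(self, chrom: str) -> int:
        try:
            return self._chrom_idx[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in layout") from None

    def bin_id(self, chrom: str, pos: int) -> int:
        """Global bin id of base ``pos`` on ``chrom``; raises if out of range."""
        c = self.chrom_index(chrom)
        if not 0 <= pos < self.layout.lengths[c]:
            raise ValueError(f"position {pos} outside {chrom}")
        return int(self.offsets[c] + pos // self.resolution)

    def bin_ids(self, chroms: np.ndarray, positions: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`bin_id`; ``chroms`` is an array of chromosome indices."""
        return self.offsets[chroms] + positions // self.resolution

    def chrom_span(self, chrom: str) -> tuple[int, int]:
        """Half-open global-bin-id span of a chromosome."""
        c = self.chrom_index(chrom)
        return int(self.offsets[c]), int(self.offsets[c + 1])

    def bin_interval(self, bin_id: int) -> tuple[str, int, int]:
        """(chrom, start, end) half-open interval of a global bin id."""
        if not 0 <= bin_id < self.n_bins:
            raise IndexError(f"bin id {bin_id} out of range")
        c = int(np.searchsorted(self.offsets, bin_id, side="right") - 1)
        local = bin_id - int(self.offsets[c])
        start = local * self.resolution
        end = min(start + self.resolution, self.layout.lengths[c])
        return self.layout.names[c], int(start), int(end)

    def bin_starts(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (chrom index, start bp) for every global bin."""
        chrom = np.repeat(
            np.arange(len(self.layout.names)), self.n_bins_per_chrom
        )
        local = np.concatenate(
            [np.arange(n, dtype=np.int64) for n in self.n_bins_per_chrom]
        )
        return chrom, local * self.resolution

    def same_resolution(self, other: "BinIndex") -> bool:
        return self.layout == other.layout and self.resolution == other.resolution


def make_bin_index(layout: GenomeLayout, resolution: int) -> BinIndex:
    """Tile every chromosome of ``layout`` with half-open ``resolution``-bp bins."""
    return BinIndex(layout, int(resolution))
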