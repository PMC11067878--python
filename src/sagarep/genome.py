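"""Fixed-resolution binning of a genome.

A :class:`BinnedGenome` partitions each chromosome into consecutive,
non-overlapping bins of width ``resolution`` bp (the last bin of a
chromosome may be shorter).  Every per-bin quantity in this package —
state labels, posterior rows, r-values — is indexed by the global bin id
``g`` in ``[0, G)``, assigned in chromosome order, then position order.
Coordinates are BED-style 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class GenomeError(ValueError):
    """Invalid chromosome sizes, resolution, or out-of-bounds coordinates."""


@dataclass(frozen=True)
class BinnedGenome:
    """Partition of chromosomes into ``G`` fixed-width bins.

    Parameters
    ----------
    chrom_names : tuple of str
        Chromosome identifiers, in the order bins are laid out.
    chrom_sizes : tuple of int
        Length of each chromosome in bp.
    resolution : int
        Bin width in bp.
    """

    chrom_names: tuple[str, ...]
    chrom_sizes: tuple[int, ...]
    resolution: int
    # derived, filled in __post_init__
    n_bins_per_chrom: tuple[int, ...] = field(init=False)
    chrom_offsets: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.resolution < 1:
            raise GenomeError(f"resolution must be >= 1, got {self.resolution}")
        if len(self.chrom_names) != len(self.chrom_sizes):
            raise GenomeError("chrom_names and chrom_sizes length mismatch")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise GenomeError("duplicate chromosome names")
        for name, size in zip(self.chrom_names, self.chrom_sizes):
            if size < 1:
                raise GenomeError(f"chromosome {name!r} has non-positive size {size}")
        n_bins = tuple(
            int(-(-size // self.resolution)) for size in self.chrom_sizes
        )
        offsets = tuple(int(x) for x in np.concatenate([[0], np.cumsum(n_bins)[:-1]]))
        object.__setattr__(self, "n_bins_per_chrom", n_bins)
        object.__setattr__(self, "chrom_offsets", offsets)

    @property
    def G(self) -> int:
        """Total number of bins."""
        return sum(self.n_bins_per_chrom)

    def chrom_index(self, chrom: str) -> int:
        try:
            return self.chrom_names.index(chrom)
        except ValueError:
            raise GenomeError(f"unknown chromosome {chrom!r}") from None

    def bin_index(self, chrom: str, start: int) -> int:
        """Global bin id of the bin whose start coordinate is ``start``."""
        ci = self.chrom_index(chrom)
        if start < 0 or start >= self.chrom_sizes[ci]:
            raise GenomeError(f"position {chrom}:{start} outside chromosome")
        if start % self.resolution != 0:
            raise GenomeError(f"{start} is not a bin start at resolution {self.resolution}")
        return self.chrom_offsets[ci] + start // self.resolution

    def bin_of_position(self, chrom: str, pos: int) -> int:
        """Global bin id of the bin containing bp position ``pos``."""
        ci = self.chrom_index(chrom)
        if pos < 0 or pos >= self.chrom_sizes[ci]:
            raise GenomeError(f"position {chrom}:{pos} outside chromosome")
        return self.chrom_offsets[ci] + pos // self.resolution

    def bin_location(self, g: int) -> tuple[str, int, int]:
        """(chrom, start, end) of global bin ``g``; end is clipped to the chromosome."""
        if g < 0 or g >= self.G:
            raise GenomeError(f"bin id {g} outside [0, {self.G})")
        ci = int(np.searchsorted(np.array(self.chrom_offsets), g, side="right")) - 1
        local = g - self.chrom_offsets[ci]
        start = local * self.resolution
        end = min(start + self.resolution, self.chrom_sizes[ci])
        return self.chrom_names[ci], start, end

    def chrom_slices(self) -> dict[str, slice]:
        """Map chrom name -> slice of global bin ids covering it."""
        return {
            name: slice(off, off + n)
            for name, off, n in zip(self.chrom_names, self.chrom_offsets, self.n_bins_per_chrom)
        }

    def bins_per_window(self, w_bp: int) -> int:
        """Convert a bp tolerance window to whole bins, rounding up."""
        if w_bp < 0:
            raise GenomeError(f"window must be >= 0, got {w_bp}")
        return int(-(-w_bp // self.resolution))


def bin_genome(chrom_sizes: dict[str, int], resolution: int) -> BinnedGenome:
    """Build a :class:`BinnedGenome` from a chrom -> size mapping.

    Bin ids are assigned in the mapping's iteration order, then by
    position within each chromosome.
    """
    return BinnedGenome(
        chrom_names=tuple(chrom_sizes.keys()),
        chrom_sizes=tuple(int(s) for s in chrom_sizes.values()),
        resolution=int(resolution),
    )
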