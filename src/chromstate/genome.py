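"""Genome bin grid: fixed-width tiling of chromosomes into half-open bins.

All coordinates are 0-based, half-open, as in BED. A chromosome of length L
with bin size w has ceil(L / w) bins; the last bin may be truncated.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class BinnedGenome:
    """A fixed-width tiling of a genome.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    bin_size
        Bin width in bp (default 200, the resolution used throughout).
    """

    chromosomes: tuple[tuple[str, int], ...]
    bin_size: int = 200
    _offsets: dict = field(init=False, repr=False, compare=False)

    def __init__(self, chromosomes, bin_size: int = 200):
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        chroms = tuple((str(n), int(l)) for n, l in chromosomes)
        if not chroms:
            raise ValueError("genome must have at least one chromosome")
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for n, l in chroms:
            if l <= 0:
                raise ValueError(f"chromosome {n!r} has non-positive length")
        object.__setattr__(self, "chromosomes", chroms)
        object.__setattr__(self, "bin_size", int(bin_size))
        offsets, cum = {}, 0
        for n, l in chroms:
            offsets[n] = cum
            cum += -(-l // bin_size)
        object.__setattr__(self, "_offsets", offsets)
        object.__setattr__(self, "_total", cum)

    @property
    def chrom_names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    def chrom_length(self, chrom: str) -> int:
        for n, l in self.chromosomes:
            if n == chrom:
                return l
        raise KeyError(f"unknown chromosome {chrom!r}")

    def n_bins(self, chrom: str) -> int:
        """Number of bins on one chromosome."""
        return -(-self.chrom_length(chrom) // self.bin_size)

    @property
    def total_bins(self) -> int:
        return self._total  # type: ignore[attr-defined]

    def chrom_offset(self, chrom: str) -> int:
        """Global bin index of the first bin of ``chrom``."""
        try:
            return self._offsets[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global bin index containing bp position ``pos`` (0-based)."""
        if pos < 0 or pos >= self.chrom_length(chrom):
            raise ValueError(f"position {pos} outside {chrom!r}")
        return self.chrom_offset(chrom) + pos // self.bin_size

    def bin_location(self, index: int) -> tuple[str, int]:
        """Map a global bin index back to ``(chrom, start_bp)``."""
        if index < 0 or index >= self.total_bins:
            raise IndexError(f"bin index {index} out of range")
        for n, _ in self.chromosomes:
            off = self._offsets[n]
            if index < off + self.n_bins(n):
                return n, (index - off) * self.bin_size
        raise AssertionError("unreachable")
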