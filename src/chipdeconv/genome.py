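"""Genomic binning containers.

The whole pipeline operates on average read coverage over contiguous,
non-overlapping, fixed-width genomic bins (default 200 bp).  ``GenomeBins``
describes the binning of a genome; ``BinnedTracks`` holds the G x N coverage
matrix for a set of samples on that binning, possibly restricted to a subset
of bins after blacklist filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .samples import SampleInfo

__all__ = ["GenomeBins", "BinnedTracks"]


@dataclass(frozen=True)
class GenomeBins:
    """Contiguous fixed-width binning of a genome.

    Bins are half-open ``[start, end)`` intervals, 0-based, tiling each
    chromosome in order.  The final bin of a chromosome may be shorter than
    ``bin_width``; its coverage is averaged over its true width.
    """

    chrom_sizes: dict[str, int]
    bin_width: int = 200

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        for name, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {size}")

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)

    def n_bins(self, chrom: str) -> int:
        return -(-self.chrom_sizes[chrom] // self.bin_width)  # ceil division

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.chrom_sizes)

    def chrom_offset(self, chrom: str) -> int:
        """Index of the chromosome's first bin in the genome-wide ordering."""
        off = 0
        for c in self.chrom_sizes:
            if c == chrom:
                return off
            off += self.n_bins(c)
        raise KeyError(chrom)

    def bin_table(self) -> pd.DataFrame:
        """All bins as a (chrom, start, end) frame in genome-wide order."""
        frames = []
        for chrom, size in self.chrom_sizes.items():
            starts = np.arange(0, size, self.bin_width, dtype=np.int64)
            ends = np.minimum(starts + self.bin_width, size)
            frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        return pd.concat(frames, ignore_index=True)

    def bin_widths(self) -> np.ndarray:
        """True width of every bin (last bin per chromosome may be short)."""
        tab = self.bin_table()
        return (tab["end"] - tab["start"]).to_numpy()

    def overlapping_bins(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Genome-wide indices of bins overlapping [start, end) by >= 1 bp."""
        if chrom not in self.chrom_sizes or end <= start:
            return np.empty(0, dtype=np.int64)
        size = self.chrom_sizes[chrom]
        start = max(0, start)
        end = min(end, size)
        if end <= start:
            return np.empty(0, dtype=np.int64)
        first = start // self.bin_width
        last = (end - 1) // self.bin_width
        return self.chrom_offset(chrom) + np.arange(first, last + 1, dtype=np.int64)


@dataclass
class BinnedTracks:
    """Per-bin average coverage for N samples over a shared set of bins.

    ``values`` is G x N with all entries >= 0.  Columns follow the canonical
    sample order (controls first, then treatments grouped by condition).
    ``bin_index`` maps rows to genome-wide bin indices of ``bins`` so that
    blacklist-filtered matrices keep a coordinate round-trip.
    """

    bins: GenomeBins
    values: np.ndarray
    samples: list[SampleInfo]
    bin_index: np.ndarray | None = None
    fragment_lengths: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape[1] != len(self.samples):
            raise ValueError("column count does not match sample metadata")
        if np.any(self.values < 0):
            raise ValueError("coverage values must be non-negative")
        if self.bin_index is None:
            self.bin_index = np.arange(self.bins.total_bins, dtype=np.int64)
        else:
            self.bin_index = np.asarray(self.bin_index, dtype=np.int64)
        if len(self.bin_index) != self.values.shape[0]:
            raise ValueError("bin_index length does not match matrix rows")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def conditions(self) -> list[str]:
        """Distinct conditions in column order (control condition(s) first)."""
        seen: list[str] = []
        for s in self.samples:
            if s.condition not in seen:
                seen.append(s.condition)
        return seen

    @property
    def treatment_conditions(self) -> list[str]:
        return [c for c in self.conditions if not self._is_control_condition(c)]

    def _is_control_condition(self, condition: str) -> bool:
        return any(s.is_control for s in self.samples if s.condition == condition)

    def columns_for(self, condition: str) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.samples) if s.condition == condition],
            dtype=np.intp,
        )

    @property
    def control_columns(self) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.samples) if s.is_control], dtype=np.intp
        )

    @property
    def treatment_columns(self) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.samples) if not s.is_control], dtype=np.intp
        )

    def bin_coordinates(self) -> pd.DataFrame:
        """(chrom, start, end) for every retained row, in row order."""
        return self.bins.bin_table().iloc[self.bin_index].reset_index(drop=True)

    def subset_bins(self, keep: np.ndarray) -> "BinnedTracks":
        """New BinnedTracks restricted to the given row positions."""
        keep = np.asarray(keep)
        return BinnedTracks(
            bins=self.bins,
            values=self.values[keep],
            samples=list(self.samples),
            bin_index=self.bin_index[keep],
            fragment_lengths=dict(self.fragment_lengths),
        )
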