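"""Enriched-region calling on fold-change tracks.

Regions are maximal runs of bins whose fold-change meets a fixed threshold;
nearby regions are merged and very small ones dropped.  No significance
testing is performed, so no multiple-testing correction is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeBins

__all__ = ["RegionSet", "call_regions", "evaluate_regions", "regions_to_bin_mask"]

# defaults; the narrow/broad distinction only affects the minimum width
DEFAULT_THRESHOLD = 2.0
DEFAULT_MERGE_GAP_BINS = 2
MIN_WIDTH_BINS_NARROW = 2
MIN_WIDTH_BINS_BROAD = 5


@dataclass
class RegionSet:
    """Called enriched regions plus the parameters that produced them.

    ``regions`` columns: chrom, start, end (bp, half-open), mean_fc, max_fc.
    """

    regions: pd.DataFrame
    threshold: float
    merge_gap: int  # bp
    min_width: int  # bp

    def __len__(self) -> int:
        return len(self.regions)

    @property
    def total_bases(self) -> int:
        if len(self.regions) == 0:
            return 0
        return int((self.regions["end"] - self.regions["start"]).sum())

    def to_bed6(self, name: str) -> pd.DataFrame:
        """BED6 frame: score = mean fold-change x 100, capped at 1000."""
        r = self.regions
        return pd.DataFrame(
            {
                "chrom": r["chrom"],
                "start": r["start"],
                "end": r["end"],
                "name": name,
                "score": np.minimum(np.round(r["mean_fc"] * 100).astype(int), 1000),
                "strand": ".",
            }
        )


def call_regions(
    fold_change: np.ndarray,
    bins: GenomeBins,
    threshold: float = DEFAULT_THRESHOLD,
    merge_gap: int | None = None,
    min_width: int | None = None,
    bin_index: np.ndarray | None = None,
) -> RegionSet:
    """Threshold a per-bin fold-change track into enriched regions.

    Maximal runs of bins with fold-change >= ``threshold`` become candidate
    intervals; intervals separated by <= ``merge_gap`` bp (same chromosome)
    are merged; intervals narrower than ``min_width`` bp are dropped.
    Defaults: merge gap of 2 bins, minimum width of 2 bins.
    ``bin_index`` maps track rows to genome-wide bins when the matrix was
    blacklist-filtered.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    W = bins.bin_width
    merge_gap = DEFAULT_MERGE_GAP_BINS * W if merge_gap is None else merge_gap
    min_width = MIN_WIDTH_BINS_NARROW * W if min_width is None else min_width

    fold_change = np.asarray(fold_change, dtype=float)
    tab = bins.bin_table()
    if bin_index is not None:
        tab = tab.iloc[np.asarray(bin_index)].reset_index(drop=True)
    if len(tab) != len(fold_change):
        raise ValueError("fold-change vector does not match bin count")

    rows: list[tuple[str, int, int, float, float]] = []
    hot = fold_change >= threshold
    chroms = tab["chrom"].to_numpy()
    starts = tab["start"].to_numpy()
    ends = tab["end"].to_numpy()

    # candidate runs of consecutive hot bins (contiguous in coordinates)
    run_start = None
    run_vals: list[float] = []
    prev_end = None
    prev_chrom = None

    def flush(chrom, s, e, vals):
        rows.append((chrom, int(s), int(e), float(np.mean(vals)), float(np.max(vals))))

    for i in range(len(tab)):
        if hot[i]:
            contiguous = (
                run_start is not None
                and chroms[i] == prev_chrom
                and starts[i] == prev_end
            )
            if not contiguous:
                if run_start is not None:
                    flush(prev_chrom, run_start, prev_end, run_vals)
                run_start = starts[i]
                run_vals = []
            run_vals.append(fold_change[i])
            prev_end = ends[i]
            prev_chrom = chroms[i]
        elif run_start is not None:
            flush(prev_chrom, run_start, prev_end, run_vals)
            run_start = None
    if run_start is not None:
        flush(prev_chrom, run_start, prev_end, run_vals)

    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_fc", "max_fc"])

    # merge regions closer than merge_gap (weighting means by width)
    merged: list[list] = []
    for row in frame.itertuples(index=False):
        if (
            merged
            and row.chrom == merged[-1][0]
            and row.start - merged[-1][2] <= merge_gap
        ):
            prev = merged[-1]
            w_prev = prev[2] - prev[1]
            w_new = row.end - row.start
            prev[3] = (prev[3] * w_prev + row.mean_fc * w_new) / (w_prev + w_new)
            prev[4] = max(prev[4], row.max_fc)
            prev[2] = row.end
        else:
            merged.append(list(row))
    frame = pd.DataFrame(merged, columns=["chrom", "start", "end", "mean_fc", "max_fc"])
    if len(frame):
        frame = frame[frame["end"] - frame["start"] >= min_width].reset_index(drop=True)
    return RegionSet(
        regions=frame, threshold=threshold, merge_gap=merge_gap, min_width=min_width
    )


def regions_to_bin_mask(
    regions: pd.DataFrame, bins: GenomeBins
) -> np.ndarray:
    """Boolean per-bin mask of bins overlapping any region by >= 1 bp."""
    mask = np.zeros(bins.total_bins, dtype=bool)
    for row in regions.itertuples(index=False):
        mask[bins.overlapping_bins(row.chrom, int(row.start), int(row.end))] = True
    return mask


def evaluate_regions(
    called: RegionSet | pd.DataFrame,
    truth: RegionSet | pd.DataFrame,
    bins: GenomeBins,
) -> dict[str, float]:
    """Bin-level precision/recall/F1 of called regions against truth."""
    called_df = called.regions if isinstance(called, RegionSet) else called
    truth_df = truth.regions if isinstance(truth, RegionSet) else truth
    pred = regions_to_bin_mask(called_df, bins)
    true = regions_to_bin_mask(truth_df, bins)
    tp = int((pred & true).sum())
    fp = int((pred & ~true).sum())
    fn = int((~pred & true).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "precision": precision,
        "recall": recall,
        "f1": f1,
    }
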