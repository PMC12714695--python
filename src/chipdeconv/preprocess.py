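"""From aligned reads to a blacklist-filtered, normalized, binned matrix.

The preprocessing contract, per sample:

1. estimate one fragment length per treatment condition (strand
   cross-correlation); the control condition uses the median of treatment
   fragment lengths;
2. extend reads to the fragment length — treatment reads 5'→3' from their 5'
   end, control reads symmetrically about their midpoint;
3. weight every read by ``25e6 / library_size`` so each sample's weighted
   total is exactly 25 million reads;
4. compute average coverage over contiguous fixed-width bins;
5. drop every bin overlapping a blacklist region, consistently across all
   samples.

Reads come from an indexed BAM (via pysam) or from a pre-binned bedGraph.
Alignments failing vendor QC, duplicates, secondary/supplementary records
and unmapped reads are excluded up front; library size counts the retained
alignments before extension.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bedio import read_bed, read_bedgraph
from .genome import BinnedTracks, GenomeBins
from .samples import SampleSheet

__all__ = [
    "ReadSet",
    "load_alignments",
    "estimate_fragment_length",
    "estimate_fragment_lengths",
    "extend_reads",
    "library_weight",
    "bin_coverage",
    "blacklisted_bins",
    "apply_blacklist",
    "preprocess_samples",
    "TARGET_LIBRARY_SIZE",
]

logger = logging.getLogger(__name__)

TARGET_LIBRARY_SIZE = 25_000_000  # reads; every sample is scaled to this total

MIN_SHIFT = 50   # bp, fragment-length search range for cross-correlation
MAX_SHIFT = 500


@dataclass
class ReadSet:
    """Filtered alignments for one sample, grouped by chromosome.

    Per chromosome: ``start``/``end`` are 0-based half-open alignment spans,
    ``reverse`` flags minus-strand reads.  The 5' end of a read is ``start``
    on the plus strand and ``end`` on the minus strand.
    """

    by_chrom: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    @property
    def n_reads(self) -> int:
        return sum(len(d["start"]) for d in self.by_chrom.values())

    def add(self, chrom: str, start: np.ndarray, end: np.ndarray, reverse: np.ndarray) -> None:
        self.by_chrom[chrom] = {
            "start": np.asarray(start, dtype=np.int64),
            "end": np.asarray(end, dtype=np.int64),
            "reverse": np.asarray(reverse, dtype=bool),
        }


def write_sam(path: str | Path, chrom_sizes: dict[str, int], reads: ReadSet) -> None:
    """Write a ReadSet as a coordinate-sorted SAM file (ungapped alignments)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": int(n)} for c, n in chrom_sizes.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for chrom, d in reads.by_chrom.items():
            tid = out.get_tid(chrom)
            for i in np.argsort(d["start"], kind="stable"):
                aln = pysam.AlignedSegment()
                aln.query_name = f"r_{chrom}_{i}"
                aln.reference_id = tid
                aln.reference_start = int(d["start"][i])
                aln.cigarstring = f"{int(d['end'][i] - d['start'][i])}M"
                aln.flag = 16 if d["reverse"][i] else 0
                aln.mapping_quality = 60
                out.write(aln)


def load_alignments(path: str | Path, chroms: list[str] | None = None) -> ReadSet:
    """Read QC-passing primary alignments from a BAM/SAM file."""
    import pysam

    mode = "r" if str(path).endswith(".sam") else "rb"
    reads = ReadSet()
    per_chrom: dict[str, list[tuple[int, int, bool]]] = {}
    with pysam.AlignmentFile(str(path), mode) as bam:
        for aln in bam.fetch(until_eof=True):
            if (
                aln.is_unmapped
                or aln.is_secondary
                or aln.is_supplementary
                or aln.is_qcfail
                or aln.is_duplicate
            ):
                continue
            chrom = aln.reference_name
            if chroms is not None and chrom not in chroms:
                continue
            per_chrom.setdefault(chrom, []).append(
                (aln.reference_start, aln.reference_end, aln.is_reverse)
            )
    for chrom, rows in per_chrom.items():
        arr = np.array(rows, dtype=np.int64)
        reads.add(chrom, arr[:, 0], arr[:, 1], arr[:, 2].astype(bool))
    return reads


def estimate_fragment_length(
    reads: ReadSet,
    chrom_sizes: dict[str, int],
    min_shift: int = MIN_SHIFT,
    max_shift: int = MAX_SHIFT,
) -> int:
    """Fragment length by strand cross-correlation.

    Builds per-base 5'-end count profiles for each strand and returns the
    shift in ``[min_shift, max_shift]`` maximizing the Pearson correlation
    between the plus-strand profile and the minus-strand profile shifted
    towards 5'.  Requires reads on both strands.
    """
    n_plus = sum(int((~d["reverse"]).sum()) for d in reads.by_chrom.values())
    n_minus = sum(int(d["reverse"].sum()) for d in reads.by_chrom.values())
    if n_plus == 0 or n_minus == 0:
        raise ValueError(
            "fragment-length estimation needs reads on both strands "
            f"(plus={n_plus}, minus={n_minus})"
        )
    shifts = np.arange(min_shift, max_shift + 1)
    # accumulate cross-products over chromosomes; correlation computed from
    # pooled sums so short chromosomes do not dominate
    sxy = np.zeros(len(shifts))
    sx = sy = sxx = syy = n_tot = 0.0
    for chrom, d in reads.by_chrom.items():
        size = chrom_sizes.get(chrom)
        if size is None or size <= max_shift:
            continue
        pos5_plus = d["start"][~d["reverse"]]
        pos5_minus = d["end"][d["reverse"]] - 1  # 5' base of a minus read
        fwd = np.bincount(np.clip(pos5_plus, 0, size - 1), minlength=size).astype(float)
        rev = np.bincount(np.clip(pos5_minus, 0, size - 1), minlength=size).astype(float)
        for i, s in enumerate(shifts):
            sxy[i] += fwd[: size - s] @ rev[s:]
        sx += fwd.sum()
        sy += rev.sum()
        sxx += (fwd**2).sum()
        syy += (rev**2).sum()
        n_tot += size
    if n_tot == 0:
        raise ValueError("no chromosome long enough for fragment-length estimation")
    # Pearson r per shift from pooled moments (means taken over the genome)
    mean_x, mean_y = sx / n_tot, sy / n_tot
    denom = np.sqrt((sxx - n_tot * mean_x**2) * (syy - n_tot * mean_y**2))
    if denom == 0:
        raise ValueError("degenerate strand profiles; cannot estimate fragment length")
    corr = (sxy - n_tot * mean_x * mean_y) / denom
    return int(shifts[int(np.argmax(corr))])


def estimate_fragment_lengths(
    reads_by_condition: dict[str, ReadSet],
    chrom_sizes: dict[str, int],
    control_conditions: list[str] | None = None,
    min_shift: int = MIN_SHIFT,
    max_shift: int = MAX_SHIFT,
) -> dict[str, float]:
    """One fragment length per condition.

    Treatment conditions are estimated from their own reads; control
    conditions get the median of the treatment estimates.
    """
    control_conditions = control_conditions or []
    out: dict[str, float] = {}
    treatment_lengths = []
    for cond, reads in reads_by_condition.items():
        if cond in control_conditions:
            continue
        L = estimate_fragment_length(reads, chrom_sizes, min_shift, max_shift)
        out[cond] = float(L)
        treatment_lengths.append(float(L))
    if not treatment_lengths and control_conditions:
        raise ValueError("no treatment condition to derive the control fragment length")
    for cond in control_conditions:
        out[cond] = float(np.median(treatment_lengths))
    return out


def extend_reads(
    reads: ReadSet, fragment_length: int, is_control: bool, chrom_sizes: dict[str, int]
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Extend each read to ``fragment_length`` bp.

    Treatment reads extend 5'→3' from their 5' end; control reads grow
    symmetrically about their alignment midpoint.  Intervals are clipped to
    chromosome bounds.  Returns per-chromosome (starts, ends).
    """
    if fragment_length <= 0:
        raise ValueError("fragment_length must be positive")
    L = int(round(fragment_length))
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, d in reads.by_chrom.items():
        size = chrom_sizes.get(chrom)
        if size is None:
            continue
        if is_control:
            mid = (d["start"] + d["end"]) // 2
            starts = mid - L // 2
            ends = starts + L
        else:
            starts = np.where(d["reverse"], d["end"] - L, d["start"])
            ends = starts + L
        out[chrom] = (np.clip(starts, 0, size), np.clip(ends, 0, size))
    return out


def library_weight(n_reads: int, target: int = TARGET_LIBRARY_SIZE) -> float:
    """Per-read weight scaling the library to exactly ``target`` reads."""
    if n_reads <= 0:
        raise ValueError("library is empty; cannot normalize")
    return target / n_reads


def bin_coverage(
    intervals: dict[str, tuple[np.ndarray, np.ndarray]],
    bins: GenomeBins,
    weight: float = 1.0,
) -> np.ndarray:
    """Average weighted coverage per bin.

    value(bin) = sum over intervals of (overlap bp x weight) / bin width,
    with the true (possibly short) width used for chromosome-end bins.
    Intervals on chromosomes absent from ``bins`` are skipped and counted.
    """
    sums = np.zeros(bins.total_bins)
    W = bins.bin_width
    skipped = 0
    for chrom, (starts, ends) in intervals.items():
        if chrom not in bins.chrom_sizes:
            skipped += len(starts)
            continue
        size = bins.chrom_sizes[chrom]
        offset = bins.chrom_offset(chrom)
        nb = bins.n_bins(chrom)
        s = np.clip(np.asarray(starts, dtype=np.int64), 0, size)
        e = np.clip(np.asarray(ends, dtype=np.int64), 0, size)
        keep = e > s
        s, e = s[keep], e[keep]
        if len(s) == 0:
            continue
        first = s // W
        last = (e - 1) // W
        chrom_sums = np.zeros(nb)
        # single-bin intervals: full overlap within one bin
        one = first == last
        np.add.at(chrom_sums, first[one], (e[one] - s[one]).astype(float))
        multi = ~one
        if multi.any():
            fs, ls = first[multi], last[multi]
            np.add.at(chrom_sums, fs, ((fs + 1) * W - s[multi]).astype(float))
            np.add.at(chrom_sums, ls, (e[multi] - ls * W).astype(float))
            # interior bins get the full bin width each, via a difference array
            diff = np.zeros(nb + 1)
            interior = ls - fs > 1
            np.add.at(diff, fs[interior] + 1, float(W))
            np.add.at(diff, ls[interior], -float(W))
            chrom_sums += np.cumsum(diff[:-1])
        sums[offset : offset + nb] += chrom_sums * weight
    if skipped:
        logger.warning("skipped %d intervals on chromosomes absent from binning", skipped)
    return sums / bins.bin_widths()


def blacklisted_bins(bins: GenomeBins, blacklist: pd.DataFrame) -> np.ndarray:
    """Genome-wide indices of bins overlapping any blacklist interval (>=1 bp)."""
    hit: set[int] = set()
    for row in blacklist.itertuples():
        hit.update(bins.overlapping_bins(row.chrom, int(row.start), int(row.end)).tolist())
    return np.array(sorted(hit), dtype=np.int64)


def apply_blacklist(tracks: BinnedTracks, blacklist: pd.DataFrame | None) -> BinnedTracks:
    """Drop every bin overlapping a blacklist region from all columns."""
    if blacklist is None or len(blacklist) == 0:
        return tracks
    bad = set(blacklisted_bins(tracks.bins, blacklist).tolist())
    keep = np.array([i for i, b in enumerate(tracks.bin_index) if int(b) not in bad])
    return tracks.subset_bins(keep)


def preprocess_samples(
    sheet: SampleSheet,
    chrom_sizes: dict[str, int],
    bin_width: int = 200,
    blacklist_path: str | Path | None = None,
    fragment_lengths: dict[str, float] | None = None,
) -> BinnedTracks:
    """Run the full preprocessing chain for every sample in the sheet.

    Samples whose ``filepath`` ends in ``.bedgraph``/``.bdg`` are taken as
    pre-binned coverage and bypass read extension and normalization.
    """
    bins = GenomeBins(chrom_sizes=chrom_sizes, bin_width=bin_width)
    control_conditions = sorted({e.condition for e in sheet.controls})

    bam_reads: dict[str, ReadSet] = {}
    columns: dict[str, np.ndarray] = {}
    for entry in sheet.entries:
        path = str(entry.filepath)
        if path.endswith((".bedgraph", ".bdg")):
            columns[path] = read_bedgraph(path, bins)
        else:
            bam_reads[path] = load_alignments(path, chroms=list(chrom_sizes))

    if fragment_lengths is None:
        fragment_lengths = {}
    missing = [
        c
        for c in sheet.conditions
        if c not in fragment_lengths
        and any(e.filepath in bam_reads for e in sheet.entries if e.condition == c)
    ]
    if missing:
        pooled: dict[str, ReadSet] = {}
        for entry in sheet.entries:
            if entry.filepath not in bam_reads or entry.condition not in missing:
                continue
            pool = pooled.setdefault(entry.condition, ReadSet())
            for chrom, d in bam_reads[entry.filepath].by_chrom.items():
                if chrom in pool.by_chrom:
                    cur = pool.by_chrom[chrom]
                    pool.add(
                        chrom,
                        np.concatenate([cur["start"], d["start"]]),
                        np.concatenate([cur["end"], d["end"]]),
                        np.concatenate([cur["reverse"], d["reverse"]]),
                    )
                else:
                    pool.add(chrom, d["start"], d["end"], d["reverse"])
        fragment_lengths = dict(fragment_lengths)
        fragment_lengths.update(
            estimate_fragment_lengths(pooled, chrom_sizes, control_conditions)
        )

    values = np.empty((bins.total_bins, len(sheet.entries)))
    for j, entry in enumerate(sheet.entries):
        path = str(entry.filepath)
        if path in columns:
            values[:, j] = columns[path]
            continue
        reads = bam_reads[path]
        L = int(round(fragment_lengths[entry.condition]))
        intervals = extend_reads(reads, L, entry.is_control, chrom_sizes)
        values[:, j] = bin_coverage(intervals, bins, weight=library_weight(reads.n_reads))

    tracks = BinnedTracks(
        bins=bins,
        values=values,
        samples=list(sheet.entries),
        fragment_lengths=dict(fragment_lengths),
    )
    if blacklist_path is not None:
        tracks = apply_blacklist(tracks, read_bed(blacklist_path))
    return tracks
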