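"""Plain-text genomic I/O: bedGraph, BED, and the binned-matrix container.

All coordinates are 0-based half-open.  bedGraph rows are written only for
non-zero runs to keep files compact; reading restores a dense per-bin vector
on the supplied binning.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import BinnedTracks, GenomeBins
from .samples import SampleInfo

__all__ = [
    "write_bedgraph",
    "read_bedgraph",
    "write_bed",
    "read_bed",
    "save_tracks",
    "load_tracks",
]


def write_bedgraph(
    path: str | Path,
    bins: GenomeBins,
    values: np.ndarray,
    bin_index: np.ndarray | None = None,
) -> None:
    """Write a per-bin signal vector as 4-column bedGraph.

    Zero-valued bins are omitted; consecutive equal-valued bins are not
    merged so that round-tripping through :func:`read_bedgraph` is exact at
    bin resolution.
    """
    values = np.asarray(values, dtype=float)
    tab = bins.bin_table()
    if bin_index is not None:
        tab = tab.iloc[np.asarray(bin_index)].reset_index(drop=True)
    if len(tab) != len(values):
        raise ValueError("value vector does not match bin count")
    mask = values != 0
    out = tab.loc[mask].copy()
    out["value"] = np.round(values[mask], 6)
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def read_bedgraph(path: str | Path, bins: GenomeBins) -> np.ndarray:
    """Read a bedGraph into a dense per-bin vector on ``bins``.

    Intervals need not align to bin boundaries; each bin receives the
    width-weighted average of overlapping interval values.
    """
    frame = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "value"],
        comment="#",
        dtype={"chrom": str},
    )
    out = np.zeros(bins.total_bins)
    width = bins.bin_widths().astype(float)
    for chrom, sub in frame.groupby("chrom", sort=False):
        if chrom not in bins.chrom_sizes:
            continue
        offset = bins.chrom_offset(chrom)
        size = bins.chrom_sizes[chrom]
        starts = np.clip(sub["start"].to_numpy(np.int64), 0, size)
        ends = np.clip(sub["end"].to_numpy(np.int64), 0, size)
        vals = sub["value"].to_numpy(float)
        for s, e, v in zip(starts, ends, vals):
            if e <= s or v == 0:
                continue
            first, last = s // bins.bin_width, (e - 1) // bins.bin_width
            for b in range(first, last + 1):
                lo = max(s, b * bins.bin_width)
                hi = min(e, (b + 1) * bins.bin_width, size)
                out[offset + b] += v * (hi - lo)
    return out / width


def write_bed(path: str | Path, frame: pd.DataFrame) -> None:
    """Write a BED frame (chrom/start/end plus optional extra columns)."""
    frame.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path, n_fields: int = 3) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name", "score", "strand"][:n_fields]
    frame = pd.read_csv(
        path, sep="\t", header=None, comment="#", usecols=range(n_fields),
        names=names, dtype={"chrom": str},
    )
    frame["start"] = frame["start"].astype(np.int64)
    frame["end"] = frame["end"].astype(np.int64)
    return frame


def save_tracks(directory: str | Path, tracks: BinnedTracks) -> None:
    """Persist a binned matrix as .npy + JSON sidecar (bin map, metadata)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / "matrix.npy", tracks.values)
    sidecar = {
        "chrom_sizes": tracks.bins.chrom_sizes,
        "bin_width": tracks.bins.bin_width,
        "bin_index": np.asarray(tracks.bin_index).tolist(),
        "fragment_lengths": tracks.fragment_lengths,
        "samples": [
            {
                "filepath": s.filepath,
                "condition": s.condition,
                "is_control": s.is_control,
                "replicate": s.replicate,
            }
            for s in tracks.samples
        ],
    }
    (directory / "matrix.json").write_text(json.dumps(sidecar, indent=1))


def load_tracks(directory: str | Path) -> BinnedTracks:
    directory = Path(directory)
    sidecar = json.loads((directory / "matrix.json").read_text())
    bins = GenomeBins(
        chrom_sizes={k: int(v) for k, v in sidecar["chrom_sizes"].items()},
        bin_width=int(sidecar["bin_width"]),
    )
    samples = [SampleInfo(**s) for s in sidecar["samples"]]
    return BinnedTracks(
        bins=bins,
        values=np.load(directory / "matrix.npy"),
        samples=samples,
        bin_index=np.asarray(sidecar["bin_index"], dtype=np.int64),
        fragment_lengths={k: float(v) for k, v in sidecar["fragment_lengths"].items()},
    )
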