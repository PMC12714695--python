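"""Sample sheet parsing and validation.

Experiments are declared in a CSV with header
``filepath,condition,is_control,replicate`` — one row per sequenced sample.
Conditions are enumerated in a stable order with control condition(s) first,
so the same set of rows always yields the same sample ordering regardless of
row order in the file.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["SampleInfo", "SampleSheet", "parse_sample_sheet"]

REQUIRED_COLUMNS = ("filepath", "condition", "is_control", "replicate")

_TRUTHY = {"1", "true", "yes", "y", "t"}
_FALSY = {"0", "false", "no", "n", "f", ""}


@dataclass(frozen=True)
class SampleInfo:
    """One sequenced sample: file, experimental condition, role, replicate."""

    filepath: str
    condition: str
    is_control: bool
    replicate: int


@dataclass(frozen=True)
class SampleSheet:
    """Validated, canonically ordered collection of samples.

    Column order is: all control samples first (sorted by condition then
    replicate), then treatment samples grouped by condition (conditions in
    sorted order, replicates ascending within each).
    """

    entries: tuple[SampleInfo, ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("sample sheet contains no samples")

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for e in self.entries:
            if e.condition not in seen:
                seen.append(e.condition)
        return seen

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def controls(self) -> list[SampleInfo]:
        return [e for e in self.entries if e.is_control]

    @property
    def treatments(self) -> list[SampleInfo]:
        return [e for e in self.entries if not e.is_control]

    @property
    def treatment_conditions(self) -> list[str]:
        seen: list[str] = []
        for e in self.treatments:
            if e.condition not in seen:
                seen.append(e.condition)
        return seen


def _parse_flag(value: object) -> bool:
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise ValueError(f"cannot interpret is_control value {value!r}")


def _canonical_order(entries: list[SampleInfo]) -> tuple[SampleInfo, ...]:
    key = lambda e: (not e.is_control, e.condition, e.replicate)
    return tuple(sorted(entries, key=key))


def build_sample_sheet(
    entries: list[SampleInfo], allow_no_control: bool = False
) -> SampleSheet:
    """Validate entries and return them in canonical order."""
    if not entries:
        raise ValueError("sample sheet contains no samples")
    pairs = [(e.condition, e.replicate) for e in entries]
    if len(set(pairs)) != len(pairs):
        dupes = sorted({p for p in pairs if pairs.count(p) > 1})
        raise ValueError(f"duplicate (condition, replicate) pairs: {dupes}")
    paths = [e.filepath for e in entries]
    if len(set(paths)) != len(paths):
        raise ValueError("sample file paths must be distinct")
    if not any(e.is_control for e in entries) and not allow_no_control:
        raise ValueError(
            "sample sheet declares no control sample; pass allow_no_control=True "
            "to analyse treatment-only data"
        )
    for e in entries:
        if e.replicate < 1:
            raise ValueError(f"replicate index must be >= 1, got {e.replicate}")
    return SampleSheet(entries=_canonical_order(entries))


def parse_sample_sheet(path: str | Path, allow_no_control: bool = False) -> SampleSheet:
    """Read and validate a sample sheet CSV.

    Parameters
    ----------
    path
        CSV file with header ``filepath,condition,is_control,replicate``.
    allow_no_control
        Accept a sheet without any control (input/WCE) sample.  Off by
        default: the deconvolution model is built around a shared control.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype=str, comment="#", skip_blank_lines=True)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(
            f"sample sheet {path} is missing required column(s): {missing}; "
            f"expected header {','.join(REQUIRED_COLUMNS)}"
        )
    if len(frame) == 0:
        raise ValueError(f"sample sheet {path} contains no samples")
    entries = [
        SampleInfo(
            filepath=str(row.filepath).strip(),
            condition=str(row.condition).strip(),
            is_control=_parse_flag(row.is_control),
            replicate=int(row.replicate),
        )
        for row in frame.itertuples()
    ]
    return build_sample_sheet(entries, allow_no_control=allow_no_control)
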