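"""End-to-end orchestration: simulate/preprocess -> deconvolve -> debias -> peaks.

A :class:`RunConfig` captures every stage's parameters and round-trips
through YAML losslessly; :func:`run_pipeline` executes the stages in order,
writing each stage's outputs plus a JSON run manifest with content hashes,
so a re-run with the same seed reproduces the hashes exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bedio import write_bed, write_bedgraph, save_tracks
from .genome import BinnedTracks
from .hsr import DIVISOR_FLOOR, debias_signal
from .nmf import FactorizationConfig, FactorizationResult, deconvolve
from .peaks import (
    DEFAULT_MERGE_GAP_BINS,
    DEFAULT_THRESHOLD,
    MIN_WIDTH_BINS_NARROW,
    call_regions,
)
from .preprocess import preprocess_samples
from .samples import parse_sample_sheet
from .simulate import MarkConfig, SimulationConfig, simulate_experiment, write_simulation

__all__ = ["RunConfig", "PeakConfig", "run_pipeline", "diagnose_mixing", "read_chrom_sizes"]

logger = logging.getLogger(__name__)


@dataclass
class PeakConfig:
    """Region-calling parameters (bp units for gap/width)."""

    threshold: float = DEFAULT_THRESHOLD
    merge_gap_bins: int = DEFAULT_MERGE_GAP_BINS
    min_width_bins: int = MIN_WIDTH_BINS_NARROW


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    outdir: str = "chipdeconv_out"
    seed: int = 0
    bin_width: int = 200
    # real-data inputs (ignored when simulate=True)
    sample_sheet: str | None = None
    chrom_sizes: str | None = None
    blacklist: str | None = None
    allow_no_control: bool = False
    simulate: bool = False
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    factorization: FactorizationConfig = field(default_factory=FactorizationConfig)
    hsr_floor: float = DIVISOR_FLOOR
    peaks: PeakConfig = field(default_factory=PeakConfig)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        raw["simulation"]["marks"] = [
            dataclasses.asdict(m) for m in self.simulation.marks
        ]
        raw["simulation"]["mappability_beta"] = list(self.simulation.mappability_beta)
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim_raw = raw.pop("simulation", {})
        marks = tuple(MarkConfig(**m) for m in sim_raw.pop("marks", []))
        if "mappability_beta" in sim_raw:
            sim_raw["mappability_beta"] = tuple(sim_raw["mappability_beta"])
        simulation = SimulationConfig(
            **sim_raw, **({"marks": marks} if marks else {})
        )
        factorization = FactorizationConfig(**raw.pop("factorization", {}))
        peaks = PeakConfig(**raw.pop("peaks", {}))
        return cls(
            simulation=simulation, factorization=factorization, peaks=peaks, **raw
        )


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV (chromosome name, length in bp)."""
    frame = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "size"], dtype={"chrom": str}
    )
    return dict(zip(frame["chrom"], frame["size"].astype(int)))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def diagnose_mixing(
    result: FactorizationResult, flag_above: float = 0.8
) -> pd.DataFrame:
    """Per-sample antibody-quality readout from the mixing matrix.

    The background (chromatin-bias) row's share of each sample's total
    mixing weight estimates how much of the sample is unspecific signal:
    near 1 for input controls, lower for specific, well-enriched ChIP
    samples.  Samples whose fraction exceeds ``flag_above`` are flagged.
    """
    frac = result.background_fraction()
    frame = pd.DataFrame(
        {
            "sample": result.sample_names,
            "background_fraction": frac,
            "flagged": frac > flag_above,
        }
    )
    return frame


def run_pipeline(
    config: RunConfig, tracks: BinnedTracks | None = None
) -> dict:
    """Execute all stages and write outputs plus a JSON run manifest.

    ``tracks`` may be supplied directly (e.g. from a previous preprocess
    run) to skip the input stage.  Returns the manifest dict; it is also
    written to ``<outdir>/manifest.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "outputs": {}}
    t_start = time.time()
    truth = None

    def record(stage: str, t0: float, paths: list[Path]) -> None:
        entry = {
            "stage": stage,
            "wall_seconds": round(time.time() - t0, 3),
            "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in paths},
        }
        manifest["stages"].append(entry)
        manifest["outputs"].update(entry["outputs"])
        logger.info("stage %-12s %6.2fs  %d output file(s)", stage, entry["wall_seconds"], len(paths))

    # ---- input stage -----------------------------------------------------
    t0 = time.time()
    if tracks is None:
        if config.simulate:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            truth, tracks = simulate_experiment(sim)
            simdir = outdir / "simulation"
            write_simulation(simdir, truth, tracks)
            record("simulate", t0, sorted(simdir.glob("*")))
        else:
            if config.sample_sheet is None or config.chrom_sizes is None:
                raise ValueError(
                    "run needs either simulate=True or both sample_sheet and "
                    "chrom_sizes"
                )
            sheet = parse_sample_sheet(
                config.sample_sheet, allow_no_control=config.allow_no_control
            )
            tracks = preprocess_samples(
                sheet,
                read_chrom_sizes(config.chrom_sizes),
                bin_width=config.bin_width,
                blacklist_path=config.blacklist,
            )
            matdir = outdir / "preprocessed"
            save_tracks(matdir, tracks)
            record("preprocess", t0, sorted(matdir.glob("*")))

    # ---- deconvolution ---------------------------------------------------
    t0 = time.time()
    result = deconvolve(tracks, config.factorization, seed=config.seed)
    decdir = outdir / "deconvolution"
    decdir.mkdir(exist_ok=True)
    for j, name in enumerate(result.signal_names):
        write_bedgraph(
            decdir / f"signal_{name}.bedgraph",
            tracks.bins,
            result.W[:, j],
            bin_index=tracks.bin_index,
        )
    pd.DataFrame(
        result.K, index=result.signal_names, columns=result.sample_names
    ).to_csv(decdir / "mixing_matrix.csv")
    (decdir / "run_log.json").write_text(
        json.dumps(
            {
                "loss_trace": result.loss_trace,
                "n_train_bins": int(len(result.train_idx)),
                "config": dataclasses.asdict(config.factorization),
                "seed": config.seed,
            },
            indent=1,
        )
    )
    diagnose_mixing(result).to_csv(decdir / "mixing_diagnostics.csv", index=False)
    record("deconvolve", t0, sorted(decdir.glob("*")))

    # ---- half-sibling regression ----------------------------------------
    t0 = time.time()
    hsrdir = outdir / "hsr"
    hsrdir.mkdir(exist_ok=True)
    train_mask = np.zeros(tracks.n_bins, dtype=bool)
    train_mask[result.train_idx] = True
    x = result.bias
    debiased: dict[str, np.ndarray] = {}
    hsr_params = {}
    for cond in result.signal_names[:-1]:
        s_hat, _, fit = debias_signal(
            result.signal(cond), x, fit_mask=train_mask, floor=config.hsr_floor
        )
        debiased[cond] = s_hat
        hsr_params[cond] = {
            "slope": fit.slope,
            "intercept": fit.intercept,
            "n_fit_bins": fit.n_fit_bins,
            "floor": config.hsr_floor,
        }
        write_bedgraph(
            hsrdir / f"foldchange_{cond}.bedgraph",
            tracks.bins,
            s_hat,
            bin_index=tracks.bin_index,
        )
    (hsrdir / "hsr_params.json").write_text(json.dumps(hsr_params, indent=1))
    record("hsr", t0, sorted(hsrdir.glob("*")))

    # ---- peak calling ----------------------------------------------------
    t0 = time.time()
    peakdir = outdir / "peaks"
    peakdir.mkdir(exist_ok=True)
    W = tracks.bins.bin_width
    for cond, s_hat in debiased.items():
        regions = call_regions(
            s_hat,
            tracks.bins,
            threshold=config.peaks.threshold,
            merge_gap=config.peaks.merge_gap_bins * W,
            min_width=config.peaks.min_width_bins * W,
            bin_index=tracks.bin_index,
        )
        write_bed(peakdir / f"peaks_{cond}.bed", regions.to_bed6(cond))
        regions.regions.to_csv(
            peakdir / f"peaks_{cond}.tsv", sep="\t", index=False
        )
    record("call_peaks", t0, sorted(peakdir.glob("*")))

    manifest["wall_seconds"] = round(time.time() - t_start, 3)
    config.to_yaml(outdir / "config.yaml")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
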