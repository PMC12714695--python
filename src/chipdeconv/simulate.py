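"""Generative simulator for multi-assay ChIP-seq experiments.

The simulator produces binned coverage tracks with complete ground truth
under the multiplicative observation model

    control:    c_b   = D * a_b * m_b * n_b
    treatment:  t_b   = D * a_b * m_b * (k * s_b + n_b)

where per bin ``a`` is chromatin accessibility, ``m`` mappability, ``n``
non-specific signal, ``s`` the latent mark-specific enrichment, and per
sample ``D`` is a sequencing-depth factor and ``k`` the antibody
specificity.  Observed counts are Poisson (optionally negative-binomial or
noiseless) draws around these expectations.

Genome layout comes from a run-length Markov chain over a background state
and three peak states (narrow, broad, randomly placed), each occupying a
fixed length per occurrence: background 1000 bp, narrow 450 bp, broad
1200 bp, random 750 bp.

Everything is driven by a single seed; identical seeds give identical
output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import BinnedTracks, GenomeBins
from .samples import SampleInfo, build_sample_sheet

__all__ = [
    "MarkConfig",
    "SimulationConfig",
    "SimulationTruth",
    "layout_genome",
    "draw_latents",
    "emit_counts",
    "simulate_experiment",
    "simulate_reads",
    "write_simulation",
]

BACKGROUND = "background"

#: fixed bp length of each occurrence of a state
DEFAULT_STATE_LENGTHS = {
    BACKGROUND: 1000,
    "narrow": 450,
    "broad": 1200,
    "random": 750,
}


@dataclass(frozen=True)
class MarkConfig:
    """One simulated histone modification.

    ``peak_type`` selects which Markov state carries this mark's signal.
    ``peak_strength`` is the mean latent enrichment amplitude ``s`` inside a
    peak (fold units relative to the non-specific level, which has mean 1).
    ``specificity`` is the mean antibody-specificity factor ``k``.
    """

    name: str
    peak_type: str  # narrow | broad | random
    n_replicates: int = 3
    peak_strength: float = 6.0
    specificity: float = 1.0


def _default_marks() -> tuple[MarkConfig, ...]:
    return (
        MarkConfig("narrow_mark", "narrow", peak_strength=8.0),
        MarkConfig("broad_mark", "broad", peak_strength=4.0),
        MarkConfig("random_mark", "random", peak_strength=5.0),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study design and nuisance-process parameters for one simulation.

    Defaults emulate the reference design: three mark types (narrow, broad,
    random peaks) with three replicates each plus two input controls on a
    1 Mb genome binned at 200 bp, with Poisson count noise.
    """

    genome_length: int = 1_000_000
    bin_width: int = 200
    chrom_name: str = "chrSim"
    state_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_STATE_LENGTHS)
    )
    #: probability that a background run is followed by another background run;
    #: the remainder is split evenly among the peak states in use
    background_stay: float = 0.5
    marks: tuple[MarkConfig, ...] = field(default_factory=_default_marks)
    n_control_replicates: int = 2
    #: mean expected control reads per bin; per-sample depth D jitters around it
    base_depth: float = 20.0
    depth_jitter_sd: float = 0.15
    specificity_jitter_sd: float = 0.15
    #: stationary sd / lag-1 autocorrelation of log accessibility a
    accessibility_sd: float = 0.3
    accessibility_rho: float = 0.95
    #: stationary sd / lag-1 autocorrelation of log non-specific signal n
    nonspecific_sd: float = 0.3
    nonspecific_rho: float = 0.8
    #: m = 1 - mappability_range * Beta(a, b); range 0.5 keeps m in (0.5, 1]
    mappability_range: float = 0.5
    mappability_beta: tuple[float, float] = (1.0, 5.0)
    #: per-peak amplitude ~ peak_strength * LogNormal(0, amplitude_sd)
    amplitude_sd: float = 0.25
    noise: str = "poisson"  # poisson | nb | none
    nb_dispersion: float = 0.1
    seed: int = 0

    def peak_types(self) -> list[str]:
        seen: list[str] = []
        for m in self.marks:
            if m.peak_type not in seen:
                seen.append(m.peak_type)
        return seen

    @property
    def n_bins(self) -> int:
        return -(-self.genome_length // self.bin_width)

    def make_bins(self) -> GenomeBins:
        return GenomeBins(
            chrom_sizes={self.chrom_name: self.genome_length},
            bin_width=self.bin_width,
        )


@dataclass
class SimulationTruth:
    """Complete latent state of one simulated experiment."""

    config: SimulationConfig
    bins: GenomeBins
    state_runs: list[tuple[str, int, int]]  # (state, start bp, end bp)
    accessibility: np.ndarray  # a, per bin, > 0
    mappability: np.ndarray  # m, per bin, in (0, 1]
    nonspecific: np.ndarray  # n, per bin, > 0
    signal: dict[str, np.ndarray]  # s_h per mark, per bin, >= 0
    depths: dict[str, float]  # D per sample
    specificity: dict[str, float]  # k per treatment sample

    @property
    def bias(self) -> np.ndarray:
        """The shared chromatin-bias track x = a * m * n."""
        return self.accessibility * self.mappability * self.nonspecific

    def mark_track(self, mark: str) -> np.ndarray:
        """The bias-confounded mark signal y_h = a * m * s_h."""
        return self.accessibility * self.mappability * self.signal[mark]

    def sample_names(self) -> list[str]:
        names = [f"control_rep{r}" for r in range(1, self.config.n_control_replicates + 1)]
        for mark in self.config.marks:
            names += [f"{mark.name}_rep{r}" for r in range(1, mark.n_replicates + 1)]
        return names

    def expected_counts(self, sample: str) -> np.ndarray:
        """Noise-free expected coverage for one sample under the model."""
        D = self.depths[sample]
        if sample.startswith("control_rep"):
            return D * self.bias
        mark = sample.rsplit("_rep", 1)[0]
        k = self.specificity[sample]
        return (
            D
            * self.accessibility
            * self.mappability
            * (k * self.signal[mark] + self.nonspecific)
        )

    def peak_regions(self, mark: str) -> pd.DataFrame:
        """Ground-truth enriched intervals (bp) for one mark, as BED3."""
        peak_type = {m.name: m.peak_type for m in self.config.marks}[mark]
        rows = [
            (self.config.chrom_name, s, e)
            for state, s, e in self.state_runs
            if state == peak_type
        ]
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def peak_bin_mask(self, mark: str) -> np.ndarray:
        """Boolean per-bin mask of bins overlapping the mark's true peaks."""
        return self.signal[mark] > 0


def layout_genome(config: SimulationConfig, rng: np.random.Generator) -> list[tuple[str, int, int]]:
    """Assign peak and background regions with a run-length Markov chain.

    Each emitted state run occupies exactly its configured length.  After a
    peak the chain always returns to background; after a background run it
    stays in background with probability ``background_stay`` and otherwise
    picks a peak state uniformly.  A peak that would not fit in the
    remaining genome is replaced by background fill, so every emitted peak
    run has its full length.  Adjacent background runs are merged.
    """
    peak_types = config.peak_types()
    bg_len = config.state_lengths[BACKGROUND]
    if peak_types:
        max_peak = max(config.state_lengths[p] for p in peak_types)
        if config.genome_length < bg_len + max_peak:
            raise ValueError(
                "genome too short for one background+peak cycle: need at least "
                f"{bg_len + max_peak} bp, got {config.genome_length}"
            )
    runs: list[tuple[str, int, int]] = []
    pos = 0
    state = BACKGROUND
    while pos < config.genome_length:
        length = config.state_lengths[state]
        if state != BACKGROUND and pos + length > config.genome_length:
            state = BACKGROUND  # peak would be truncated; fill with background
            continue
        end = min(pos + length, config.genome_length)
        if runs and runs[-1][0] == state == BACKGROUND:
            runs[-1] = (BACKGROUND, runs[-1][1], end)
        else:
            runs.append((state, pos, end))
        pos = end
        if state == BACKGROUND and peak_types and config.background_stay < 1.0:
            p_each = (1.0 - config.background_stay) / len(peak_types)
            probs = [config.background_stay] + [p_each] * len(peak_types)
            state = str(rng.choice([BACKGROUND] + peak_types, p=probs))
        else:
            state = BACKGROUND
    return runs


def _log_ar1(n: int, sd: float, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Positive track exp(z) with z a stationary AR(1), Var(z) = sd^2."""
    if sd == 0:
        return np.ones(n)
    z = np.empty(n)
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    z[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for i in range(1, n):
        z[i] = rho * z[i - 1] + eps[i - 1]
    return np.exp(z)


def _bin_state_overlap(
    runs: list[tuple[str, int, int]], state: str, config: SimulationConfig
) -> np.ndarray:
    """Fraction of each bin covered by runs of ``state`` (0..1 per bin)."""
    frac = np.zeros(config.n_bins)
    W = config.bin_width
    for s_name, start, end in runs:
        if s_name != state:
            continue
        first, last = start // W, (end - 1) // W
        for b in range(first, last + 1):
            lo, hi = max(start, b * W), min(end, (b + 1) * W, config.genome_length)
            width = min(W, config.genome_length - b * W)
            frac[b] += (hi - lo) / width
    return np.clip(frac, 0.0, 1.0)


def draw_latents(
    runs: list[tuple[str, int, int]],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> SimulationTruth:
    """Draw all latent tracks and per-sample factors for a laid-out genome.

    Accessibility and non-specific signal are smooth positive log-AR(1)
    processes with mean ~1; mappability is i.i.d. ``1 - range*Beta`` in
    (1-range, 1].  Mark signals are per-peak amplitudes times the bin/peak
    overlap fraction, giving flat-topped peaks with one-bin linear
    shoulders.  Setting the corresponding sd/range parameters to 0 yields
    the pure-signal limit a = m = n = 1.
    """
    G = config.n_bins
    a = _log_ar1(G, config.accessibility_sd, config.accessibility_rho, rng)
    n = _log_ar1(G, config.nonspecific_sd, config.nonspecific_rho, rng)
    if config.mappability_range == 0:
        m = np.ones(G)
    else:
        beta_a, beta_b = config.mappability_beta
        m = 1.0 - config.mappability_range * rng.beta(beta_a, beta_b, size=G)

    signal: dict[str, np.ndarray] = {}
    for mark in config.marks:
        s = np.zeros(G)
        W = config.bin_width
        for s_name, start, end in runs:
            if s_name != mark.peak_type:
                continue
            amp = mark.peak_strength * float(
                np.exp(rng.normal(0.0, config.amplitude_sd))
                if config.amplitude_sd > 0
                else 1.0
            )
            first, last = start // W, (end - 1) // W
            for b in range(first, last + 1):
                lo, hi = max(start, b * W), min(end, (b + 1) * W, config.genome_length)
                width = min(W, config.genome_length - b * W)
                s[b] += amp * (hi - lo) / width
        signal[mark.name] = s

    depths: dict[str, float] = {}
    specificity: dict[str, float] = {}
    for r in range(1, config.n_control_replicates + 1):
        jit = rng.normal(0.0, config.depth_jitter_sd) if config.depth_jitter_sd else 0.0
        depths[f"control_rep{r}"] = config.base_depth * float(np.exp(jit))
    for mark in config.marks:
        for r in range(1, mark.n_replicates + 1):
            name = f"{mark.name}_rep{r}"
            jit = rng.normal(0.0, config.depth_jitter_sd) if config.depth_jitter_sd else 0.0
            depths[name] = config.base_depth * float(np.exp(jit))
            kj = (
                rng.normal(0.0, config.specificity_jitter_sd)
                if config.specificity_jitter_sd
                else 0.0
            )
            specificity[name] = mark.specificity * float(np.exp(kj))

    return SimulationTruth(
        config=config,
        bins=config.make_bins(),
        state_runs=runs,
        accessibility=a,
        mappability=m,
        nonspecific=n,
        signal=signal,
        depths=depths,
        specificity=specificity,
    )


def emit_counts(
    truth: SimulationTruth, rng: np.random.Generator, noise: str | None = None
) -> BinnedTracks:
    """Draw observed binned tracks around the model expectations.

    ``noise``: ``"poisson"`` (default), ``"nb"`` (gamma-Poisson with the
    configured dispersion), or ``"none"`` (tracks equal their expectations).
    """
    config = truth.config
    noise = noise if noise is not None else config.noise
    names = truth.sample_names()
    values = np.empty((config.n_bins, len(names)))
    for j, name in enumerate(names):
        mu = truth.expected_counts(name)
        if noise == "none":
            values[:, j] = mu
        elif noise == "poisson":
            values[:, j] = rng.poisson(mu).astype(float)
        elif noise == "nb":
            shape = 1.0 / config.nb_dispersion
            lam = rng.gamma(shape, mu / shape)
            values[:, j] = rng.poisson(lam).astype(float)
        else:
            raise ValueError(f"unknown noise model {noise!r}")

    entries = []
    for name in names:
        is_control = name.startswith("control_rep")
        condition = "control" if is_control else name.rsplit("_rep", 1)[0]
        rep = int(name.rsplit("_rep", 1)[1])
        entries.append(
            SampleInfo(
                filepath=f"sim://{name}",
                condition=condition,
                is_control=is_control,
                replicate=rep,
            )
        )
    sheet = build_sample_sheet(entries)
    order = [names.index(_entry_name(e)) for e in sheet.entries]
    return BinnedTracks(
        bins=truth.bins,
        values=values[:, order],
        samples=list(sheet.entries),
        fragment_lengths={},
    )


def _entry_name(entry: SampleInfo) -> str:
    return entry.filepath.removeprefix("sim://")


def simulate_experiment(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[SimulationTruth, BinnedTracks]:
    """Lay out a genome, draw latents, and emit observed tracks in one call."""
    config = config or SimulationConfig()
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    rng_layout, rng_latent, rng_counts = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    runs = layout_genome(config, rng_layout)
    truth = draw_latents(runs, config, rng_latent)
    tracks = emit_counts(truth, rng_counts)
    return truth, tracks


def simulate_reads(
    truth: SimulationTruth,
    sample: str,
    rng: np.random.Generator,
    fragment_length: int = 200,
    read_length: int = 50,
    n_reads: int | None = None,
):
    """Draw individual stranded reads for one sample.

    Per bin, a Poisson count around the sample's expected coverage; each
    read is one end of a fragment whose midpoint is uniform in the bin, with
    strand chosen fairly.  If ``n_reads`` is given, expected counts are
    rescaled so the expected total equals it.  Returns a
    :class:`~chipdeconv.preprocess.ReadSet`.
    """
    from .preprocess import ReadSet

    config = truth.config
    mu = truth.expected_counts(sample).copy()
    if n_reads is not None:
        mu *= n_reads / mu.sum()
    counts = rng.poisson(mu)
    total = int(counts.sum())
    W = config.bin_width
    bin_ids = np.repeat(np.arange(config.n_bins), counts)
    mid = bin_ids * W + rng.integers(0, W, size=total)
    f_start = mid - fragment_length // 2
    f_end = f_start + fragment_length
    reverse = rng.random(total) < 0.5
    starts = np.where(reverse, f_end - read_length, f_start)
    ends = starts + read_length
    size = config.genome_length
    keep = (starts >= 0) & (ends <= size)
    reads = ReadSet()
    reads.add(config.chrom_name, starts[keep], ends[keep], reverse[keep])
    return reads


def write_simulation(
    outdir: str | Path, truth: SimulationTruth, tracks: BinnedTracks
) -> dict:
    """Write bedGraphs, truth peak BEDs, truth tracks, and a JSON manifest."""
    from .bedio import write_bed, write_bedgraph

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bins = truth.bins
    for j, s in enumerate(tracks.samples):
        write_bedgraph(outdir / f"{_entry_name(s)}.bedgraph", bins, tracks.values[:, j])
    for mark in truth.config.marks:
        write_bed(outdir / f"truth_peaks_{mark.name}.bed", truth.peak_regions(mark.name))
        write_bedgraph(
            outdir / f"truth_signal_{mark.name}.bedgraph", bins, truth.signal[mark.name]
        )
    for name, track in [
        ("accessibility", truth.accessibility),
        ("mappability", truth.mappability),
        ("nonspecific", truth.nonspecific),
        ("bias", truth.bias),
    ]:
        write_bedgraph(outdir / f"truth_{name}.bedgraph", bins, track)
    manifest = {
        "seed": truth.config.seed,
        "depths": truth.depths,
        "specificity": truth.specificity,
        "config": {
            **{
                k: v
                for k, v in asdict(truth.config).items()
                if k not in ("marks", "state_lengths", "mappability_beta")
            },
            "marks": [asdict(m) for m in truth.config.marks],
            "state_lengths": truth.config.state_lengths,
            "mappability_beta": list(truth.config.mappability_beta),
        },
        "samples": [_entry_name(s) for s in tracks.samples],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
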