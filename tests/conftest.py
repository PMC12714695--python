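"""Shared fixtures: small simulated experiments and toy factorization inputs."""

from __future__ import annotations

import numpy as np
import pytest

from chipdeconv.genome import BinnedTracks, GenomeBins
from chipdeconv.samples import SampleInfo
from chipdeconv.simulate import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def default_sim():
    """Default-design simulation (3 marks x 3 reps + 2 controls, 1 Mb)."""
    return simulate_experiment(seed=1)


@pytest.fixture(scope="session")
def small_sim():
    """Fast 200 kb simulation for tests that re-run the pipeline."""
    config = SimulationConfig(genome_length=200_000, seed=7)
    return simulate_experiment(config)


def make_toy_tracks(G, n_controls, treat_conds, seed, bin_width=200):
    """Toy matrix drawn from the generative model: shared background x plus
    per-condition sparse signals, Poisson counts."""
    rng = np.random.default_rng(seed)
    samples, cols = [], []
    x = rng.gamma(3.0, 2.0, G)
    signals = {c: rng.gamma(1.5, 3.0, G) * (rng.random(G) < 0.3) for c, _ in treat_conds}
    for r in range(n_controls):
        samples.append(SampleInfo(f"ctrl{r}", "control", True, r + 1))
        cols.append(rng.poisson(x * rng.uniform(0.7, 1.3)).astype(float))
    for cond, reps in treat_conds:
        for r in range(reps):
            samples.append(SampleInfo(f"{cond}{r}", cond, False, r + 1))
            cols.append(
                rng.poisson(
                    x * rng.uniform(0.5, 1.0) + signals[cond] * rng.uniform(0.8, 1.2)
                ).astype(float)
            )
    bins = GenomeBins({"chrT": G * bin_width}, bin_width)
    return BinnedTracks(bins, np.column_stack(cols), samples)


def plain_kl_nmf_reference(V, rank, lambda_W, lambda_K, n_restarts, seed,
                           max_iter=3000, tol=1e-12):
    """Independent oracle: plain multiplicative-update KL-NMF with L2
    penalties, random restarts, best final regularized loss.

    Deliberately written as a free-standing loop (dense random init, joint
    W/K updates, no staging) so it shares no code path with the staged
    factorization it checks.
    """
    rng = np.random.default_rng(seed)
    eps = 1e-12
    best = np.inf
    scale = np.sqrt(max(V.mean(), eps) / rank)
    for _ in range(n_restarts):
        W = rng.uniform(0.1, 1.0, (V.shape[0], rank)) * scale
        K = rng.uniform(0.1, 1.0, (rank, V.shape[1])) * scale
        prev = np.inf
        for _ in range(max_iter):
            WK = np.maximum(W @ K, eps)
            W = W * ((V / WK) @ K.T) / np.maximum(
                K.sum(axis=1)[None, :] + 2 * lambda_W * W, eps
            )
            WK = np.maximum(W @ K, eps)
            K = K * (W.T @ (V / WK)) / np.maximum(
                W.sum(axis=0)[:, None] + 2 * lambda_K * K, eps
            )
            WK = np.maximum(W @ K, eps)
            pos = V > 0
            loss = (
                float(np.sum(V[pos] * np.log(V[pos] / WK[pos])) - V.sum() + WK.sum())
                + lambda_W * float(np.sum(W**2))
                + lambda_K * float(np.sum(K**2))
            )
            if prev - loss < tol * max(abs(prev), 1.0):
                break
            prev = loss
        best = min(best, loss)
    return best


from chipdeconv.preprocess import write_sam  # noqa: E402,F401  (re-export for tests)
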