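"""Constrained KL-NMF deconvolution of multi-assay coverage matrices.

The binned coverage matrix V (bins x samples, controls first) is factorized
as V ~ W K with W >= 0 (bins x l) and K >= 0 (l x samples), where l is the
number of experimental conditions.  The last W column is the shared
chromatin-bias signal x = a*m*n; the other columns are the per-condition
specific signals y_h = a*m*s_h.  K mixes them back into the observed
samples and jointly absorbs sequencing-depth and antibody-specificity
factors.

The factorization is staged so the decomposition keeps its intended
interpretation:

1. rank-1 KL-NMF of the control block alone learns x and the control
   mixing coefficients;
2. with x fixed, a single background coefficient per treatment sample is
   fitted, explaining as much of each treatment as possible with the
   control signal alone;
3. the background component is subtracted and each condition's residual
   replicates are factorized rank-1 into y_h plus per-replicate
   coefficients;
4. the block structure of K is relaxed and W, K are refined by alternating
   multiplicative updates on the full training matrix.

All stages minimize generalized KL divergence with L2 penalties
(lambda_W = 0.01 on W, lambda_K = 0.001 on K).  The mixing matrix is
learned on a subsample of training bins, then fixed to extract W
genome-wide (a row-separable convex solve).  Finally each W column is
rescaled so its 98th percentile equals 1, with the inverse scale pushed
into K so W K is unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genome import BinnedTracks

__all__ = [
    "FactorizationConfig",
    "FactorizationResult",
    "kl_divergence",
    "regularized_loss",
    "multiplicative_update_W",
    "multiplicative_update_K",
    "assemble_matrix",
    "select_training_bins",
    "fit_control_stage",
    "fit_background_coefficients",
    "fit_specific_stage",
    "relax_and_alternate",
    "rescale_result",
    "extend_genomewide",
    "deconvolve",
]

logger = logging.getLogger(__name__)

EPS = 1e-12
BIAS_NAME = "chromatin_bias"

#: training-set size presets: generic default, deeply sequenced real data,
#: and small simulated genomes
TRAIN_BINS_DEFAULT = 100_000
TRAIN_BINS_DEEP = 400_000
TRAIN_BINS_SIMULATED = 5_000


@dataclass
class FactorizationConfig:
    """Hyperparameters of the staged factorization.

    ``min_mean_coverage`` restricts training bins to those whose
    cross-sample mean coverage exceeds it (use > 1 for real data, 0 for
    simulations).  ``lambda_W``/``lambda_K`` weight the L2 penalties on the
    signal and mixing matrices.
    """

    n_train_bins: int = TRAIN_BINS_DEFAULT
    min_mean_coverage: float = 0.0
    lambda_W: float = 0.01
    lambda_K: float = 0.001
    max_iter: int = 500
    tol: float = 1e-6
    rescale_percentile: float = 98.0
    extend_chunk: int = 200_000
    #: zero K entries are re-seeded at this fraction of the matrix mean
    #: before the relaxed stage (multiplicative updates cannot leave 0)
    relax_floor: float = 1e-2
    seed: int = 0


@dataclass
class FactorizationResult:
    """Genome-wide signal matrix, mixing matrix, and fit diagnostics."""

    W: np.ndarray  # bins x l, bias column last
    K: np.ndarray  # l x samples
    signal_names: list[str]  # per W column; last is the chromatin bias
    sample_names: list[str]  # per K column, matching the input track order
    loss_trace: dict[str, list[float]]
    train_idx: np.ndarray

    @property
    def bias(self) -> np.ndarray:
        """The shared chromatin-bias signal x (last W column)."""
        return self.W[:, -1]

    def signal(self, condition: str) -> np.ndarray:
        """The specific signal y_h for one treatment condition."""
        return self.W[:, self.signal_names.index(condition)]

    def background_fraction(self) -> np.ndarray:
        """Per sample, the bias row's share of its total mixing weight."""
        totals = self.K.sum(axis=0)
        return np.divide(self.K[-1], totals, out=np.zeros_like(totals), where=totals > 0)


def kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    """Generalized KL divergence D(V || WH) = sum V log(V/WH) - V + WH."""
    V = np.asarray(V, dtype=float)
    WH = np.maximum(np.asarray(WH, dtype=float), EPS)
    pos = V > 0
    return float(
        np.sum(V[pos] * np.log(V[pos] / WH[pos])) - V.sum() + WH.sum()
    )


def regularized_loss(
    V: np.ndarray, W: np.ndarray, K: np.ndarray, lambda_W: float, lambda_K: float
) -> float:
    """KL reconstruction loss plus L2 penalties on W and K."""
    return (
        kl_divergence(V, W @ K)
        + lambda_W * float(np.sum(W**2))
        + lambda_K * float(np.sum(K**2))
    )


def multiplicative_update_W(
    V: np.ndarray, W: np.ndarray, K: np.ndarray, lambda_W: float
) -> np.ndarray:
    """One multiplicative KL update of W (monotone for the penalized loss)."""
    WK = np.maximum(W @ K, EPS)
    numer = (V / WK) @ K.T
    denom = K.sum(axis=1)[None, :] + 2.0 * lambda_W * W
    return W * numer / np.maximum(denom, EPS)


def multiplicative_update_K(
    V: np.ndarray, W: np.ndarray, K: np.ndarray, lambda_K: float
) -> np.ndarray:
    """One multiplicative KL update of K."""
    WK = np.maximum(W @ K, EPS)
    numer = W.T @ (V / WK)
    denom = W.sum(axis=0)[:, None] + 2.0 * lambda_K * K
    return K * numer / np.maximum(denom, EPS)


def _run_mu(
    V: np.ndarray,
    W: np.ndarray,
    K: np.ndarray,
    lambda_W: float,
    lambda_K: float,
    max_iter: int,
    tol: float,
    update_W: bool = True,
    update_K: bool = True,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Alternate multiplicative updates until relative improvement < tol."""
    trace = [regularized_loss(V, W, K, lambda_W, lambda_K)]
    for _ in range(max_iter):
        if update_W:
            W = multiplicative_update_W(V, W, K, lambda_W)
        if update_K:
            K = multiplicative_update_K(V, W, K, lambda_K)
        loss = regularized_loss(V, W, K, lambda_W, lambda_K)
        prev = trace[-1]
        trace.append(loss)
        if loss > prev * (1 + 1e-8) + 1e-10:
            raise RuntimeError(
                f"KL loss increased during multiplicative updates "
                f"({prev:.6g} -> {loss:.6g}); aborting"
            )
        if prev - loss < tol * max(abs(prev), 1.0):
            break
    return W, K, trace


def assemble_matrix(tracks: BinnedTracks) -> tuple[np.ndarray, list[str], int]:
    """The G x N data matrix, condition order, and latent dimension l.

    Columns are already in canonical order (controls first, then treatments
    grouped by condition); l is the number of experimental conditions
    (treatment conditions + control).
    """
    if len(tracks.control_columns) == 0:
        raise ValueError(
            "deconvolution requires at least one control (input) sample"
        )
    conditions = tracks.conditions
    return tracks.values, conditions, len(conditions)


def select_training_bins(
    V: np.ndarray, config: FactorizationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Uniform sample (without replacement) of coverage-eligible bins."""
    mean_cov = V.mean(axis=1)
    eligible = np.flatnonzero(mean_cov > config.min_mean_coverage)
    if len(eligible) == 0:
        raise ValueError(
            f"no bins exceed the training coverage threshold "
            f"{config.min_mean_coverage}"
        )
    n = config.n_train_bins
    if len(eligible) <= n:
        if len(eligible) < n:
            logger.warning(
                "only %d eligible training bins (requested %d); using all",
                len(eligible),
                n,
            )
        return np.sort(eligible)
    return np.sort(rng.choice(eligible, size=n, replace=False))


def fit_control_stage(
    V_controls: np.ndarray, config: FactorizationConfig
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Rank-1 KL-NMF of the control block: V_c ~ x k_c^T.

    Deterministic initialization: x starts at the mean control column, the
    coefficients at each column's mass ratio against it.
    """
    V_controls = np.atleast_2d(np.asarray(V_controls, dtype=float))
    if V_controls.ndim == 1:
        V_controls = V_controls[:, None]
    if not np.any(V_controls > 0):
        raise ValueError("control block is all zero; cannot learn a bias signal")
    x0 = V_controls.mean(axis=1) + EPS
    k0 = V_controls.sum(axis=0) / x0.sum()
    x, kc, trace = _run_mu(
        V_controls,
        x0[:, None],
        k0[None, :],
        config.lambda_W,
        config.lambda_K,
        config.max_iter,
        config.tol,
    )
    return x[:, 0], kc[0], trace


def fit_background_coefficients(
    V_treatments: np.ndarray, x: np.ndarray, lambda_K: float = 0.001
) -> np.ndarray:
    """Per treatment column j, the beta_j >= 0 minimizing KL(V_j || beta x).

    The penalized objective's stationarity condition is the quadratic
    ``2 lambda beta^2 + sum(x) beta - sum(V_j) = 0``, solved in closed form
    (beta = sum(V_j)/sum(x) when lambda = 0).
    """
    x = np.asarray(x, dtype=float)
    if not np.any(x > 0):
        raise ValueError("bias signal x is all zero")
    V_treatments = np.atleast_2d(np.asarray(V_treatments, dtype=float))
    sx = x.sum()
    sv = V_treatments.sum(axis=0)
    if lambda_K == 0:
        return sv / sx
    return (-sx + np.sqrt(sx**2 + 8.0 * lambda_K * sv)) / (4.0 * lambda_K)


def fit_specific_stage(
    V_treatments: np.ndarray,
    x: np.ndarray,
    beta: np.ndarray,
    condition_cols: list[np.ndarray],
    config: FactorizationConfig,
) -> tuple[np.ndarray, list[np.ndarray], list[list[float]]]:
    """Factorize the background-subtracted residual per condition.

    ``condition_cols`` gives, per treatment condition, the column positions
    within ``V_treatments``.  Each condition's residual
    ``max(V_j - beta_j x, 0)`` block gets a rank-1 KL-NMF, yielding the
    specific signal y_h and per-replicate coefficients.
    """
    G = V_treatments.shape[0]
    residual = np.maximum(V_treatments - np.outer(x, beta), 0.0)
    Y = np.zeros((G, len(condition_cols)))
    coeffs: list[np.ndarray] = []
    traces: list[list[float]] = []
    for h, cols in enumerate(condition_cols):
        block = residual[:, cols]
        if not np.any(block > 0):
            logger.warning("condition %d residual is identically zero", h)
            coeffs.append(np.zeros(len(cols)))
            traces.append([0.0])
            continue
        y0 = block.mean(axis=1) + EPS
        c0 = block.sum(axis=0) / y0.sum()
        y, c, trace = _run_mu(
            block,
            y0[:, None],
            c0[None, :],
            config.lambda_W,
            config.lambda_K,
            config.max_iter,
            config.tol,
        )
        Y[:, h] = y[:, 0]
        coeffs.append(c[0])
        traces.append(trace)
    return Y, coeffs, traces


def relax_and_alternate(
    V: np.ndarray,
    W0: np.ndarray,
    K0: np.ndarray,
    config: FactorizationConfig,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Free all K entries and refine W, K by alternating updates.

    Multiplicative updates cannot move an exactly-zero entry, so the
    blocked-out K entries (and any zero W entries) are re-seeded at a small
    fraction of the corresponding matrix mean before optimization.
    """
    W = W0.copy()
    K = K0.copy()
    k_floor = config.relax_floor * max(K[K > 0].mean() if np.any(K > 0) else 1.0, EPS)
    K[K <= 0] = k_floor
    w_floor = config.relax_floor * max(W[W > 0].mean() if np.any(W > 0) else 1.0, EPS) * 1e-3
    W[W <= 0] = w_floor
    return _run_mu(
        V, W, K, config.lambda_W, config.lambda_K, config.max_iter, config.tol
    )


def rescale_result(
    W: np.ndarray, K: np.ndarray, percentile: float = 98.0
) -> tuple[np.ndarray, np.ndarray]:
    """Normalize each W column's given percentile to 1, compensating in K.

    The corresponding K row is multiplied by the same factor, so the
    reconstruction W K is algebraically unchanged.  All-zero (or
    zero-percentile) columns are left unscaled with a warning.
    """
    W = W.copy()
    K = K.copy()
    for j in range(W.shape[1]):
        q = float(np.percentile(W[:, j], percentile))
        if q <= 0:
            logger.warning("W column %d has %gth percentile 0; not rescaled", j, percentile)
            continue
        W[:, j] /= q
        K[j, :] *= q
    return W, K


def extend_genomewide(
    V: np.ndarray, K: np.ndarray, config: FactorizationConfig
) -> np.ndarray:
    """Solve the signal matrix genome-wide under a fixed mixing matrix.

    With K fixed the penalized KL objective is convex and separable across
    bins, so rows are solved independently with a per-row stopping rule:
    each row's trajectory depends only on its own data, making the result
    exactly independent of how the genome is chunked.  All-zero bins map to
    all-zero W rows.
    """
    G, N = V.shape
    l = K.shape[0]
    W = np.empty((G, l))
    ksum = K.sum()

    def row_loss(chunk: np.ndarray, Wc: np.ndarray) -> np.ndarray:
        WK = np.maximum(Wc @ K, EPS)
        kl = np.where(chunk > 0, chunk * np.log(np.maximum(chunk, EPS) / WK), 0.0)
        return (
            kl.sum(axis=1)
            - chunk.sum(axis=1)
            + WK.sum(axis=1)
            + config.lambda_W * (Wc**2).sum(axis=1)
        )

    for lo in range(0, G, config.extend_chunk):
        hi = min(lo + config.extend_chunk, G)
        chunk = V[lo:hi]
        Wc = np.repeat((chunk.sum(axis=1) / max(ksum, EPS))[:, None], l, axis=1)
        active = np.flatnonzero(np.ones(hi - lo, dtype=bool))
        prev = row_loss(chunk, Wc)
        for _ in range(config.max_iter):
            sub = chunk[active]
            Wc[active] = multiplicative_update_W(sub, Wc[active], K, config.lambda_W)
            loss = row_loss(sub, Wc[active])
            done = prev[active] - loss < config.tol * np.maximum(np.abs(prev[active]), 1.0)
            prev[active] = loss
            active = active[~done]
            if active.size == 0:
                break
        W[lo:hi] = Wc
    return W


def deconvolve(
    tracks: BinnedTracks,
    config: FactorizationConfig | None = None,
    seed: int | None = None,
) -> FactorizationResult:
    """Run the full staged factorization on a binned coverage matrix."""
    config = config or FactorizationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    V, conditions, l = assemble_matrix(tracks)
    train_idx = select_training_bins(V, config, rng)
    Vt = V[train_idx]

    ctrl_cols = tracks.control_columns
    treat_cols = tracks.treatment_columns
    treat_conditions = tracks.treatment_conditions
    cond_cols_local = [
        np.array([k for k, j in enumerate(treat_cols) if tracks.samples[j].condition == c])
        for c in treat_conditions
    ]

    x, k_ctrl, trace1 = fit_control_stage(Vt[:, ctrl_cols], config)
    beta = fit_background_coefficients(Vt[:, treat_cols], x, config.lambda_K)
    Y, spec_coeffs, traces3 = fit_specific_stage(
        Vt[:, treat_cols], x, beta, cond_cols_local, config
    )

    # assemble the staged initialization: W = [y_1 .. y_{l-1}, x], K blocked
    W0 = np.column_stack([Y, x])
    K0 = np.zeros((l, V.shape[1]))
    K0[-1, ctrl_cols] = k_ctrl
    K0[-1, treat_cols] = beta
    for h, cols in enumerate(cond_cols_local):
        K0[h, treat_cols[cols]] = spec_coeffs[h]

    Wt, K, trace4 = relax_and_alternate(Vt, W0, K0, config)
    W_full = extend_genomewide(V, K, config)
    W_full, K = rescale_result(W_full, K, config.rescale_percentile)

    return FactorizationResult(
        W=W_full,
        K=K,
        signal_names=treat_conditions + [BIAS_NAME],
        sample_names=[s.filepath for s in tracks.samples],
        loss_trace={
            "control": trace1,
            "specific": [t[-1] for t in traces3],
            "relaxed": trace4,
        },
        train_idx=train_idx,
    )
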