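"""Half-sibling regression: remove the shared chromatin confounder.

The deconvolved mark signal y_h = a*m*s_h is still confounded by
accessibility and mappability (a*m), which also drive the chromatin-bias
signal x = a*m*n.  Assuming the true enrichment s_h is independent of x,
the confounder's effect is removed by subtracting, in log scale, the part
of log y_h predictable from log x:

    log s_hat_h = log y_h - E[log y_h | log x]

with the conditional expectation fitted by ordinary least squares.  In
linear scale this divides y_h by a fitted divisor, giving a fold-change
style track.  The divisor is floored at 0.1, so the signal is amplified by
at most a factor of 10 where the predicted background is essentially zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "HsrFit",
    "fit_hsr",
    "debias",
    "debias_signal",
    "correlation_report",
    "DIVISOR_FLOOR",
]

logger = logging.getLogger(__name__)

DIVISOR_FLOOR = 0.1  # minimum divisor; caps amplification at 10x


@dataclass(frozen=True)
class HsrFit:
    """OLS fit of log y on log x, with the bins it was fitted on."""

    slope: float
    intercept: float
    n_fit_bins: int


def fit_hsr(
    y: np.ndarray, x: np.ndarray, fit_mask: np.ndarray | None = None
) -> HsrFit:
    """Least-squares regression of log y on log x.

    Only bins with both y > 0 and x > 0 participate (no pseudocount); an
    optional ``fit_mask`` further restricts the fit (e.g. to the NMF
    training bins).  A constant x degenerates to slope 0 with the mean log
    y as intercept.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    ok = (y > 0) & (x > 0)
    if fit_mask is not None:
        ok &= np.asarray(fit_mask, dtype=bool)
    if ok.sum() < 2:
        raise ValueError("need at least two bins with positive y and x to fit")
    ly, lx = np.log(y[ok]), np.log(x[ok])
    if np.ptp(lx) == 0:
        logger.warning("bias signal is constant on fit bins; slope fixed at 0")
        return HsrFit(slope=0.0, intercept=float(ly.mean()), n_fit_bins=int(ok.sum()))
    slope, intercept = np.polyfit(lx, ly, 1)
    return HsrFit(slope=float(slope), intercept=float(intercept), n_fit_bins=int(ok.sum()))


def debias(
    y: np.ndarray,
    x: np.ndarray,
    fit: HsrFit,
    floor: float = DIVISOR_FLOOR,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply a fitted regression: s_hat = y / max(exp(fit(log x)), floor).

    Bins with x = 0 use the floored divisor.  Returns (s_hat, divisor).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    divisor = np.full_like(y, floor)
    pos = x > 0
    divisor[pos] = np.maximum(
        np.exp(fit.intercept + fit.slope * np.log(x[pos])), floor
    )
    return y / divisor, divisor


def debias_signal(
    y: np.ndarray,
    x: np.ndarray,
    fit_mask: np.ndarray | None = None,
    floor: float = DIVISOR_FLOOR,
) -> tuple[np.ndarray, np.ndarray, HsrFit]:
    """Fit and apply in one call; returns (s_hat, divisor, fit)."""
    fit = fit_hsr(y, x, fit_mask)
    s_hat, divisor = debias(y, x, fit, floor)
    return s_hat, divisor, fit


def correlation_report(
    tracks: dict[str, np.ndarray],
    mask: np.ndarray | None = None,
    hist_bins: int = 50,
) -> tuple["pd.DataFrame", dict[tuple[str, str], np.ndarray]]:
    """Pairwise Pearson correlations and 2-D log-density histograms.

    All tracks must share the same binning; ``mask`` restricts the
    comparison (e.g. to non-blacklisted bins).  Histograms are computed on
    log1p coverage; returns (correlation frame, {(name_i, name_j): H}).
    """
    import pandas as pd

    names = list(tracks)
    arrays = [np.asarray(tracks[n], dtype=float) for n in names]
    G = len(arrays[0])
    if any(len(a) != G for a in arrays):
        raise ValueError("all tracks must share the same bin count")
    if mask is not None:
        arrays = [a[np.asarray(mask, dtype=bool)] for a in arrays]
    if len(arrays[0]) < 2:
        raise ValueError("need at least two bins to correlate")
    corr = np.corrcoef(np.vstack(arrays))
    frame = pd.DataFrame(corr, index=names, columns=names)
    hists: dict[tuple[str, str], np.ndarray] = {}
    for i, ni in enumerate(names):
        for j, nj in enumerate(names):
            if j <= i:
                continue
            H, _, _ = np.histogram2d(
                np.log1p(arrays[i]), np.log1p(arrays[j]), bins=hist_bins
            )
            hists[(ni, nj)] = np.log1p(H)
    return frame, hists
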