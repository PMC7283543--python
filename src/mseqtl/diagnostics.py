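"""Cross-normalization and batch-effect diagnostics (RLE, SVD scores).

Subtracting the estimated unwanted component ``W alpha`` computed from a fit
that used every sample over-adjusts: each sample's own noise leaks into its
adjustment. Cross-normalization instead holds each sample out in turn,
estimates the control-gene factor loadings from the remaining samples, maps
the held-out sample onto those factors through its control-gene values
only, and subtracts the resulting unwanted component. The held-out sample's
non-control values never influence its own adjustment.

Relative log expression (RLE, per-gene-median-centered values) and SVD
sample scores before/after adjustment are the standard visual checks for
the presence and removal of batch effects; this module computes the
numbers behind those plots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ruv_core import RuvConfig, RuvDesign, fit, partial_out

logger = logging.getLogger(__name__)

__all__ = ["AdjustedExpression", "RleSvdReport", "cross_normalize", "rle_stats", "svd_scores"]


@dataclass
class AdjustedExpression:
    """Cross-normalized expression: samples x genes, plus held-out W rows."""

    Y_adjusted: np.ndarray  # (n, m), same orientation as the design's Y
    W_holdout: np.ndarray  # (n, k)
    n_factors: int


@dataclass
class RleSvdReport:
    """Per-sample RLE summary and/or SVD sample scores."""

    rle: pd.DataFrame | None = None  # columns: rle_median, rle_iqr
    scores: np.ndarray | None = None  # (n_samples, d)
    variance_fractions: np.ndarray | None = None


def _auto_k(design: RuvDesign, config: RuvConfig) -> int:
    """Number of unwanted factors by parallel analysis of the control residuals.

    The configured RUV fit runs once on all samples; the control columns of
    its residuals are decomposed, and eigenvalues are kept while they exceed
    the largest eigenvalue of the same matrix with each column independently
    permuted across samples (Horn's parallel analysis, fixed permutation
    seed). Pure-noise residuals therefore yield k ~ 0 and the adjustment
    leaves the data essentially untouched.
    """
    res = fit(design, config)
    Y0 = partial_out(design.Y, design.Z)
    X0 = partial_out(design.X, design.Z)
    R = (Y0 - X0 @ res.beta)[:, design.ctl]
    lam = np.linalg.svd(R, compute_uv=False) ** 2
    rng = np.random.default_rng(0)
    perm = np.column_stack([rng.permutation(R[:, j]) for j in range(R.shape[1])])
    lam_null = np.linalg.svd(perm, compute_uv=False) ** 2
    return int(np.sum(lam > lam_null.max()))


def cross_normalize(
    design: RuvDesign, config: RuvConfig | None = None, n_factors: int | str = "auto"
) -> AdjustedExpression:
    """Leave-one-out removal of unwanted variation.

    For each sample i: the configured RUV fit runs on the other samples;
    their residuals' control columns are factor-analyzed by SVD (``n_factors``
    components, ``"auto"`` = parallel analysis on the full-data residuals,
    which yields 0 when there is no unwanted structure); the held-out
    sample's factor coordinates come from regressing its centered
    control-gene values on the control loadings; the adjusted row is the
    observed row minus that estimated unwanted component. Factor-of-interest
    effects (the X beta term) are left in the data — the point of the
    procedure is to remove batch structure without touching the signal.
    """
    config = config or RuvConfig()
    n, m = design.Y.shape
    if n < 10:
        raise ValueError(f"cross-normalization needs >= 10 samples, got {n}")
    k_fixed = _auto_k(design, config) if n_factors == "auto" else int(n_factors)
    ctl = design.ctl
    adjusted = design.Y.copy()
    if k_fixed == 0:
        return AdjustedExpression(Y_adjusted=adjusted, W_holdout=np.zeros((n, 0)), n_factors=0)
    k_used = 0
    W_rows = []
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        sub = RuvDesign(
            Y=design.Y[keep],
            X=design.X[keep],
            ctl=ctl,
            Z=design.Z[keep],
            factor_names=design.factor_names,
        )
        res = fit(sub, config)
        Y0 = partial_out(sub.Y, sub.Z)
        X0 = partial_out(sub.X, sub.Z)
        R = Y0 - X0 @ res.beta
        U, s, Vt = np.linalg.svd(R[:, ctl], full_matrices=False)
        k = min(k_fixed, s.size)
        k_used = k
        L_ctl = s[:k, None] * Vt[:k]  # (k, m_c) control loadings
        L_all = U[:, :k].T @ R  # (k, m) loadings for every gene
        # held-out row, centered with the training Z fit (intercept: train mean)
        zcoef, *_ = np.linalg.lstsq(sub.Z, sub.Y, rcond=None)
        y0_i = design.Y[i] - design.Z[i] @ zcoef
        w_i, *_ = np.linalg.lstsq(L_ctl.T, y0_i[ctl], rcond=None)
        adjusted[i] = design.Y[i] - w_i @ L_all
        W_rows.append(w_i)
    k_max = max(len(w) for w in W_rows)
    W = np.zeros((n, k_max))
    for i, w in enumerate(W_rows):  # auto-k may differ across held-out fits
        W[i, : len(w)] = w
    return AdjustedExpression(Y_adjusted=adjusted, W_holdout=W, n_factors=k_used)


def rle_stats(Y) -> RleSvdReport:
    """Relative log expression: per-sample median and IQR.

    ``Y`` is genes x samples (DataFrame or array). RLE[g, s] =
    Y[g, s] - median over samples of gene g; per construction the per-gene
    medians of the RLE matrix are zero.
    """
    vals = Y.to_numpy(dtype=float) if hasattr(Y, "to_numpy") else np.asarray(Y, dtype=float)
    if vals.shape[1] < 2:
        raise ValueError("RLE needs at least 2 samples")
    rle = vals - np.median(vals, axis=1, keepdims=True)
    q1, med, q3 = np.percentile(rle, [25, 50, 75], axis=0)
    idx = list(Y.columns) if hasattr(Y, "columns") else list(range(vals.shape[1]))
    df = pd.DataFrame({"rle_median": med, "rle_iqr": q3 - q1}, index=idx)
    return RleSvdReport(rle=df)


def svd_scores(Y, d: int = 5) -> RleSvdReport:
    """First ``d`` SVD sample scores of the gene-centered expression matrix.

    ``Y`` is genes x samples; each gene (row) is mean-centered before the
    decomposition. Scores are the right singular vectors scaled by their
    singular values, with a deterministic sign convention (the
    largest-magnitude gene loading of each component is positive).
    Variance fractions are the normalized squared singular values.
    """
    vals = Y.to_numpy(dtype=float) if hasattr(Y, "to_numpy") else np.asarray(Y, dtype=float)
    centered = vals - vals.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    rank = int(np.sum(s > s.max() * max(centered.shape) * np.finfo(float).eps)) if s.size else 0
    if d > rank:
        logger.info("requested %d components but rank is %d; truncating", d, rank)
        d = rank
    for comp in range(d):
        lead = np.argmax(np.abs(U[:, comp]))
        if U[lead, comp] < 0:
            U[:, comp] *= -1
            Vt[comp] *= -1
    scores = (s[:d, None] * Vt[:d]).T  # (n_samples, d)
    var_frac = (s[:d] ** 2) / (s ** 2).sum() if s.size else np.array([])
    return RleSvdReport(scores=scores, variance_fractions=var_frac)
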