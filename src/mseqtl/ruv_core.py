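"""Removal of unwanted variation (RUV) with negative-control genes.

The model is ``Y = X beta + W alpha + epsilon`` where Y is a samples x genes
log2 expression matrix, X holds the factors of interest (risk-allele dosage
G, disease phenotype P, and optionally their interaction G x P), and W holds
latent unwanted factors (batch, sample quality) with gene loadings alpha.
W is never observed; it is estimated from negative-control genes — genes
assumed unassociated with X (housekeeping genes) — by factor analysis
(RUV-2, RUV-4) or absorbed implicitly by generalized least squares with the
control-gene second-moment matrix as a noise proxy (RUV-inv and its ridged
variant RUV-rinv).

Empirical variance calibration rescales each factor's t statistics so the
control genes' statistics have unit mean square, making the control genes an
internal null reference for inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RuvDesign",
    "RuvConfig",
    "FitResult",
    "partial_out",
    "ruv2_fit",
    "ruv4_fit",
    "ruv_inv_fit",
    "ruv_rinv_fit",
    "empirical_calibrate",
    "bh_fdr",
    "fit",
]

_RANK_TOL = 1e-10


@dataclass
class RuvDesign:
    """Aligned design for one RUV fit.

    Attributes
    ----------
    Y : (n, m) samples x genes log2 expression.
    X : (n, p) factors of interest.
    ctl : (m,) boolean mask of negative-control genes.
    Z : (n, q) nuisance covariates; default a lone intercept column.
    factor_names : names for X's columns (e.g. ["G", "P", "GxP"]).
    """

    Y: np.ndarray
    X: np.ndarray
    ctl: np.ndarray
    Z: np.ndarray | None = None
    factor_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        self.ctl = np.asarray(self.ctl, dtype=bool)
        n = self.Y.shape[0]
        if self.Z is None:
            self.Z = np.ones((n, 1))
        else:
            self.Z = np.asarray(self.Z, dtype=float)
            if self.Z.ndim == 1:
                self.Z = self.Z[:, None]
        if self.X.shape[0] != n or self.Z.shape[0] != n:
            raise ValueError("Y, X, Z row counts differ")
        if self.ctl.shape[0] != self.Y.shape[1]:
            raise ValueError("control mask length != number of genes")
        if self.ctl.sum() < 2:
            raise ValueError("need at least 2 negative-control genes")
        for name, M in (("Y", self.Y), ("X", self.X), ("Z", self.Z)):
            if not np.all(np.isfinite(M)):
                raise ValueError(f"{name} contains missing/non-finite values")
        X0 = partial_out(self.X, self.Z)
        if np.any(np.ptp(X0, axis=0) < _RANK_TOL * max(1.0, np.abs(self.X).max())):
            raise ValueError("an X column is constant after Z-projection")
        if self.factor_names is None:
            self.factor_names = [f"x{j}" for j in range(self.X.shape[1])]

    @property
    def n_samples(self) -> int:
        return self.Y.shape[0]

    @property
    def n_genes(self) -> int:
        return self.Y.shape[1]


@dataclass
class RuvConfig:
    """Method selection for a RUV fit.

    method: one of "ruv2", "ruv4", "ruvinv", "ruvrinv", "ols".
    k: number of unwanted factors (ruv2/ruv4 only).
    ridge: ridge rho >= 0 or "auto" (= mean eigenvalue of the control
        second-moment matrix, trace(A)/n) — ruvrinv only.
    calibrate: apply empirical variance calibration to the t statistics.
    """

    method: str = "ruvrinv"
    k: int = 0
    ridge: float | str = "auto"
    calibrate: bool = True

    def __post_init__(self) -> None:
        if self.method not in {"ruv2", "ruv4", "ruvinv", "ruvrinv", "ols"}:
            raise ValueError(f"unknown RUV method {self.method!r}")


@dataclass
class FitResult:
    """Per-gene x per-factor estimates from one RUV fit.

    ``beta``, ``se``, ``t_raw`` are (p, m) arrays over factors x genes.
    After :func:`empirical_calibrate`, ``t_cal``/``p_cal`` hold the
    calibrated statistics (standard-normal reference) and ``c_hat`` the
    per-factor calibration multipliers; ``p_raw`` uses a t reference with
    ``df`` degrees of freedom.
    """

    beta: np.ndarray
    se: np.ndarray
    t_raw: np.ndarray
    p_raw: np.ndarray
    df: float
    factor_names: list[str]
    c_hat: np.ndarray | None = None
    t_cal: np.ndarray | None = None
    p_cal: np.ndarray | None = None

    @property
    def p(self) -> np.ndarray:
        """Calibrated p-values when available, raw otherwise."""
        return self.p_cal if self.p_cal is not None else self.p_raw

    @property
    def t(self) -> np.ndarray:
        return self.t_cal if self.t_cal is not None else self.t_raw


def partial_out(M: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residual of M after least-squares projection on Z.

    Returns ``(I - Z (Z'Z)^-1 Z') M``; idempotent. Z must have full column
    rank; the offending (collinear) columns are named otherwise.
    """
    M = np.asarray(M, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if M.ndim == 1:
        M = M[:, None]
    q, r = np.linalg.qr(Z)
    diag = np.abs(np.diag(r))
    bad = np.where(diag < _RANK_TOL * (diag.max() if diag.size else 1.0))[0]
    if bad.size:
        raise ValueError(f"Z is rank-deficient; collinear column indices: {bad.tolist()}")
    return M - q @ (q.T @ M)


def _ols_stats(Xfull: np.ndarray, Y: np.ndarray, p_interest: int, df: float,
               factor_names: list[str]) -> FitResult:
    """OLS of Y on Xfull; report the first ``p_interest`` coefficients."""
    XtX = Xfull.T @ Xfull
    beta_full, *_ = np.linalg.lstsq(Xfull, Y, rcond=None)
    resid = Y - Xfull @ beta_full
    sigma2 = (resid ** 2).sum(axis=0) / df
    xtx_inv = np.linalg.pinv(XtX)
    var_scale = np.diag(xtx_inv)[:p_interest]
    beta = beta_full[:p_interest]
    se = np.sqrt(np.outer(var_scale, sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df=df)
    return FitResult(beta=beta, se=se, t_raw=t, p_raw=p, df=df, factor_names=list(factor_names))


def ruv2_fit(design: RuvDesign, k: int) -> FitResult:
    """RUV-2: factor-analyze the control genes, then adjust by regression.

    After projecting out Z, the control columns are decomposed by SVD;
    W-hat is the first k left singular vectors scaled by their singular
    values, and beta-hat comes from OLS of Y on [X, W-hat]. k = 0 reduces
    exactly to OLS of Y on X.
    """
    Y0 = partial_out(design.Y, design.Z)
    X0 = partial_out(design.X, design.Z)
    n, m = Y0.shape
    p = X0.shape[1]
    q = design.Z.shape[1]
    m_c = int(design.ctl.sum())
    if k < 0 or (k > 0 and k >= min(n - p - q, m_c)):
        raise ValueError(f"k={k} must satisfy 0 <= k < min(n-p-q, n_controls)={min(n - p - q, m_c)}")
    if k == 0:
        Xfull = X0
    else:
        U, s, _ = np.linalg.svd(Y0[:, design.ctl], full_matrices=False)
        W = U[:, :k] * s[:k]
        Xfull = np.hstack([X0, W])
    df = n - p - q - k
    return _ols_stats(Xfull, Y0, p, df, design.factor_names)


def ruv4_fit(design: RuvDesign, k: int) -> FitResult:
    """RUV-4: estimate W from controls residualized on the factors of interest.

    The controls are projected free of [Z, X] and factor-analyzed by SVD to
    obtain k control loadings alpha_C; W-hat is then recovered by regressing
    the (Z-projected, X-unresidualized) control values on alpha_C, and
    beta-hat comes from OLS of Y on [X, W-hat]. Keeping X out of the factor
    analysis protects the factors of interest from absorption into W.
    """
    Y0 = partial_out(design.Y, design.Z)
    X0 = partial_out(design.X, design.Z)
    n, m = Y0.shape
    p = X0.shape[1]
    q = design.Z.shape[1]
    m_c = int(design.ctl.sum())
    k_max = min(n - p - q, m_c)
    if k < 0 or k > k_max:
        raise ValueError(f"k={k} must satisfy 0 <= k <= min(n-p-q, n_controls)={k_max}")
    if k == 0:
        return _ols_stats(X0, Y0, p, n - p - q, design.factor_names)
    Yc0 = Y0[:, design.ctl]
    Yc1 = partial_out(Yc0, X0)  # Z already removed
    _, _, Vt = np.linalg.svd(Yc1, full_matrices=False)
    alpha_c = Vt[:k]  # (k, m_c)
    # W-hat from unresidualized controls: Y_C alpha' (alpha alpha')^-1
    W = Yc0 @ alpha_c.T @ np.linalg.pinv(alpha_c @ alpha_c.T)
    Xfull = np.hstack([X0, W])
    df = n - p - q - k
    if df > 0:
        return _ols_stats(Xfull, Y0, p, df, design.factor_names)
    # maximal-factor limit (k = n - p - q): [X, W] saturates the sample space,
    # the OLS residual is identically zero, and per-gene variances come from
    # the control-gene GLS quadratic form instead — the limit in which this
    # estimator coincides with the spectral RUV-inv route.
    beta_full, *_ = np.linalg.lstsq(Xfull, Y0, rcond=None)
    beta = beta_full[:p]
    B = np.linalg.pinv(Yc0 @ Yc0.T)
    M_inv = np.linalg.pinv(X0.T @ B @ X0)
    df = n - p - q
    resid = Y0 - X0 @ ((M_inv @ (X0.T @ B)) @ Y0)
    sigma2 = np.einsum("ng,nh,hg->g", resid, B, resid) / df
    se = np.sqrt(np.outer(np.diag(M_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p_raw = 2 * stats.t.sf(np.abs(t), df=df)
    return FitResult(beta=beta, se=se, t_raw=t, p_raw=p_raw, df=df,
                     factor_names=list(design.factor_names))


def _rinv_core(design: RuvDesign, ridge: float | str, pseudo: bool) -> FitResult:
    Y0 = partial_out(design.Y, design.Z)
    X0 = partial_out(design.X, design.Z)
    n = Y0.shape[0]
    p = X0.shape[1]
    q = design.Z.shape[1]
    Yc = Y0[:, design.ctl]
    A = Yc @ Yc.T
    w, V = np.linalg.eigh(A)
    w = np.clip(w, 0.0, None)
    if pseudo:
        tol = w.max() * n * np.finfo(float).eps if w.size else 0.0
        if np.sum(w > tol) < n:
            # rank-deficient A without ridge: drop null directions (pseudo-inverse)
            pass
        inv_sqrt = np.where(w > tol, 1.0 / np.sqrt(np.where(w > tol, w, 1.0)), 0.0)
    else:
        rho = float(np.trace(A) / n) if ridge == "auto" else float(ridge)
        if rho < 0:
            raise ValueError("ridge must be >= 0")
        if rho == 0 and w.min() <= w.max() * n * np.finfo(float).eps:
            raise ValueError(
                "control second-moment matrix is singular at ridge 0; "
                "use ridge > 0 (RUV-rinv) or the pseudo-inverse mode (RUV-inv)"
            )
        inv_sqrt = 1.0 / np.sqrt(w + rho)
    # whitening transform T = D^{-1/2} V' turns GLS into OLS
    Xt = (inv_sqrt[:, None] * (V.T @ X0))
    Yt = (inv_sqrt[:, None] * (V.T @ Y0))
    df = n - p - q
    res = _ols_stats(Xt, Yt, p, df, design.factor_names)
    _loo_control_stats(res, design.ctl, V, inv_sqrt, X0, Yc, df)
    return res


def _loo_control_stats(res: FitResult, ctl: np.ndarray, V: np.ndarray,
                       inv_sqrt: np.ndarray, X0: np.ndarray, Yc: np.ndarray,
                       df: float) -> None:
    """Replace control-gene statistics with leave-one-out versions.

    A control gene's own expression vector enters A = Y_C Y_C', so the full
    GLS systematically shrinks its statistics relative to a non-control
    gene's — which would make the controls a biased null reference. Each
    control's fit is therefore recomputed with its own column removed from
    A, via a Sherman-Morrison rank-one downdate of A_rho^-1; controls and
    test genes then play by the same rules.
    """
    p = X0.shape[1]
    Binv_half = inv_sqrt[:, None] * V.T  # B = (A_rho)^-1 = Binv_half' Binv_half
    Xw = Binv_half @ X0  # (n, p)
    Yw = Binv_half @ Yc  # (n, m_c)
    M = Xw.T @ Xw  # X' B X
    qv = Xw.T @ Yw  # (p, m_c): X' B y_g
    s = np.sum(Yw * Yw, axis=0)  # y_g' B y_g
    d = np.clip(1.0 - s, 1e-12, None)
    m_c = Yc.shape[1]
    Mg = M[None, :, :] + np.einsum("ig,jg,g->gij", qv, qv, 1.0 / d)
    rhs = (qv / d).T[:, :, None]  # (m_c, p, 1)
    beta = np.linalg.solve(Mg, rhs)[:, :, 0]  # (m_c, p)
    rss = (s - np.einsum("gp,pg->g", beta, qv)) / d
    sigma2 = np.clip(rss, 0.0, None) / df
    inv_diag = np.diagonal(np.linalg.inv(Mg), axis1=1, axis2=2)  # (m_c, p)
    se = np.sqrt(inv_diag * sigma2[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    idx = np.flatnonzero(ctl)
    res.beta[:, idx] = beta.T
    res.se[:, idx] = se.T
    res.t_raw[:, idx] = t.T
    res.p_raw[:, idx] = 2 * stats.t.sf(np.abs(t.T), df=df)


def ruv_rinv_fit(design: RuvDesign, ridge: float | str = "auto") -> FitResult:
    """Ridged-inverse RUV: GLS with the control second-moment matrix.

    With A = Y_C Y_C' (samples x samples, Z-projected controls) and
    A_rho = A + rho I,

        beta-hat = (X' A_rho^-1 X)^-1 X' A_rho^-1 Y,

    i.e. generalized least squares weighting down the sample directions in
    which the control genes covary (the unwanted variation). ``ridge="auto"``
    sets rho to the mean eigenvalue trace(A)/n, a one-unit shrink toward
    OLS; rho -> infinity recovers OLS exactly. Per-gene variances come from
    the whitened residuals with df = n - p - q.

    Unlike RUV-2/RUV-4 this requires no choice of the number of unwanted
    factors.
    """
    return _rinv_core(design, ridge, pseudo=False)


def ruv_inv_fit(design: RuvDesign) -> FitResult:
    """RUV-inv: the ridge-free limit, via the Moore-Penrose pseudo-inverse."""
    return _rinv_core(design, 0.0, pseudo=True)


def empirical_calibrate(fit: FitResult, ctl: np.ndarray) -> FitResult:
    """Rescale t statistics so control-gene statistics have unit mean square.

    For each factor, c-hat = mean over control genes of the squared raw t;
    calibrated t = raw t / sqrt(c-hat), with two-sided p-values from the
    standard normal reference. The control genes' calibrated statistics then
    have mean square exactly 1 — the controls act as an internal null.
    """
    ctl = np.asarray(ctl, dtype=bool)
    if ctl.sum() < 30:
        warnings.warn(
            f"only {int(ctl.sum())} control genes; empirical calibration may be unstable",
            stacklevel=2,
        )
    t_ctl = fit.t_raw[:, ctl]
    c_hat = np.mean(t_ctl ** 2, axis=1)
    if np.any(c_hat <= 0) or not np.all(np.isfinite(c_hat)):
        raise ValueError("degenerate calibration: control mean-square t is zero or non-finite")
    t_cal = fit.t_raw / np.sqrt(c_hat)[:, None]
    p_cal = 2 * stats.norm.sf(np.abs(t_cal))
    return replace(fit, c_hat=c_hat, t_cal=t_cal, p_cal=p_cal)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values for one multiple-testing family."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fit(design: RuvDesign, config: RuvConfig) -> FitResult:
    """Dispatch a RUV fit per ``config`` and optionally calibrate it."""
    if config.method == "ruv2":
        res = ruv2_fit(design, config.k)
    elif config.method == "ruv4":
        res = ruv4_fit(design, config.k)
    elif config.method == "ruvinv":
        res = ruv_inv_fit(design)
    elif config.method == "ruvrinv":
        res = ruv_rinv_fit(design, config.ridge)
    else:  # ols
        res = ruv2_fit(design, 0)
    if config.calibrate:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = empirical_calibrate(res, design.ctl)
    return res
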