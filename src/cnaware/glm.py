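"""Negative-binomial GLM engine with copy-number dosage offsets.

The model for gene g in sample n is

    y_{g,n} ~ NB(mu_{g,n}, alpha_g),    Var = mu + alpha * mu^2
    mu_{g,n} = s_n * (CN_{g,n} / 2) * exp(sum_f x_{n,f} beta_{g,f})

where s_n is a median-of-ratios size factor and CN/2 is the per-gene,
per-sample copy-number dosage relative to the diploid reference.  With CN == 2
everywhere the dosage term is 1 and the model reduces to the standard
("CN-naive") NB GLM.  Fitting follows the empirical-Bayes recipe of
DESeq2-style tools: gene-wise dispersion MLE, a parametric a0 + a1/mu trend,
MAP shrinkage of log-dispersion toward the trend, IRLS coefficient fits, a
heavy-tailed (Cauchy) prior MAP estimate of the condition log fold change, and
a Wald test of a user contrast.

Everything is vectorised across genes; dispersions are profiled by bisection
on the score function in log-dispersion space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, polygamma
from scipy.stats import norm

from .io import DesignSpec

LN2 = float(np.log(2.0))


@dataclass
class GLMConfig:
    """Numerical knobs of the NB GLM engine (safe defaults)."""

    cn_floor: float = 0.1          # CN values below this are floored before CN/2
    min_disp: float = 1e-8
    max_disp: float = 30.0         # raised to n_samples when larger
    irls_maxiter: int = 100
    irls_tol: float = 1e-8
    ridge: float = 1e-6            # stabiliser on the IRLS normal equations
    disp_rounds: int = 2           # (dispersion | coefficient) alternations
    disp_bisections: int = 40
    prior_var_floor: float = 0.25  # floor on log-dispersion prior variance
    shrink: bool = True
    prior_scale_floor: float = 0.05   # Cauchy scale floor (natural-log units)
    wald_on: str = "mle"           # "mle" (default) or "map" coefficients
    size_factor_pseudocount: bool = False  # pseudo-reference fallback


# ---------------------------------------------------------------------------
# likelihood

def nb_logpmf(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Elementwise NB log-pmf in the (mean, dispersion) parameterisation.

    With r = 1/alpha:  log Gamma(y+r) - log Gamma(r) - log Gamma(y+1)
    + r log(r/(r+mu)) + y log(mu/(r+mu)).
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    r = 1.0 / alpha
    return (
        gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )


def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Per-gene NB log-likelihood, summed over samples (last axis)."""
    a = np.asarray(alpha, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    return nb_logpmf(y, mu, a).sum(axis=-1)


# ---------------------------------------------------------------------------
# size factors and offsets

def estimate_size_factors(
    counts: pd.DataFrame | np.ndarray, pseudo_reference: bool = False
) -> np.ndarray:
    """Median-of-ratios size factors.

    s_n = median over reference genes of y_{g,n} / geomean_m(y_{g,m}), using
    genes with all-positive counts as the reference set.  When no gene is
    positive in every sample, ``pseudo_reference=True`` adds 0.5 to all counts
    for the reference computation only.
    """
    y = np.asarray(counts, dtype=float)
    if pseudo_reference:
        y = y + 0.5
    positive = (y > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; "
            "re-run with pseudo_reference=True"
        )
    logy = np.log(y[positive])
    log_ratios = logy - logy.mean(axis=1, keepdims=True)
    return np.exp(np.median(log_ratios, axis=0))


def build_offsets(
    size_factors: np.ndarray,
    cn: pd.DataFrame | np.ndarray | None,
    mode: str = "aware",
    n_genes: int | None = None,
    cn_floor: float = 0.1,
) -> np.ndarray:
    """Natural-log offset matrix log(s_n * CN/2) (genes x samples).

    ``mode='naive'`` ignores CN (equivalent to CN == 2 everywhere).  CN values
    below ``cn_floor`` are floored so homozygous deletions do not produce
    -inf offsets.
    """
    s = np.asarray(size_factors, dtype=float)
    if (s <= 0).any():
        raise ValueError("size factors must be positive")
    if mode == "naive":
        if n_genes is None:
            if cn is None:
                raise ValueError("naive mode needs n_genes or a CN matrix for shape")
            n_genes = np.asarray(cn).shape[0]
        return np.broadcast_to(np.log(s), (n_genes, s.size)).copy()
    if mode != "aware":
        raise ValueError("mode must be 'aware' or 'naive'")
    if cn is None:
        raise ValueError("aware mode requires a CN matrix")
    cnv = np.maximum(np.asarray(cn, dtype=float), cn_floor)
    return np.log(s)[None, :] + np.log(cnv / 2.0)


# ---------------------------------------------------------------------------
# IRLS coefficient fitting

def _irls(
    y: np.ndarray,
    X: np.ndarray,
    log_offset: np.ndarray,
    alpha: np.ndarray,
    cfg: GLMConfig,
    beta_init: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised IRLS for the NB GLM with log link and fixed log offsets.

    Returns (beta (G,F), mu (G,N), converged (G,) bool).  Genes must have at
    least one positive count.
    """
    G, N = y.shape
    F = X.shape[1]
    a = np.asarray(alpha, dtype=float)
    if a.ndim == 0:
        a = np.full(G, float(a))
    a = a[:, None]

    if beta_init is None:
        beta = np.zeros((G, F))
        base = y * np.exp(-log_offset)
        beta[:, 0] = np.log(np.maximum(base.mean(axis=1), 1e-8))
    else:
        beta = beta_init.copy()

    eye = np.eye(F)
    converged = np.zeros(G, dtype=bool)
    for _ in range(cfg.irls_maxiter):
        lin = np.clip(beta @ X.T, -60.0, 60.0)
        mu = np.exp(lin + log_offset)
        mu = np.clip(mu, 1e-10, 1e15)
        W = mu / (1.0 + a * mu)
        z = lin + (y - mu) / mu
        A = np.einsum("gn,nf,nk->gfk", W, X, X, optimize=True)
        b = np.einsum("gn,nf->gf", W * z, X, optimize=True)
        A += cfg.ridge * eye
        beta_new = np.linalg.solve(A, b[..., None])[..., 0]
        step = beta_new - beta
        # damp huge steps to keep early iterations stable
        norm_step = np.max(np.abs(step), axis=1, keepdims=True)
        scale = np.where(norm_step > 10.0, 10.0 / np.maximum(norm_step, 1e-300), 1.0)
        beta = beta + step * scale
        converged = np.max(np.abs(step), axis=1) < cfg.irls_tol
        if converged.all():
            break
    lin = np.clip(beta @ X.T, -60.0, 60.0)
    mu = np.clip(np.exp(lin + log_offset), 1e-10, 1e15)
    return beta, mu, converged


def _fisher_cov(
    X: np.ndarray, mu: np.ndarray, alpha: np.ndarray, ridge: float = 0.0
) -> np.ndarray:
    """Inverse observed Fisher information (G,F,F) at the fitted means."""
    a = np.asarray(alpha, dtype=float)[:, None]
    W = mu / (1.0 + a * mu)
    A = np.einsum("gn,nf,nk->gfk", W, X, X, optimize=True)
    if ridge:
        A = A + ridge * np.eye(X.shape[1])
    return np.linalg.inv(A)


# ---------------------------------------------------------------------------
# dispersion estimation

def _disp_score(
    u: np.ndarray, y: np.ndarray, mu: np.ndarray, X: np.ndarray | None = None
) -> np.ndarray:
    """d (adjusted) loglik / d log(alpha) per gene, at log-dispersion ``u``.

    With r = 1/alpha, d ll/d u = -r * d ll/d r.  When a design matrix is
    given the Cox-Reid adjustment -0.5 log det(X' W X) is included, removing
    the downward bias of the plain MLE from estimating the coefficients
    (d/d alpha of the adjustment is +0.5 tr(A^-1 X' W^2 X) since
    dW/d alpha = -W^2).
    """
    alpha = np.exp(u)[:, None]
    r = 1.0 / alpha
    dll_dr = (
        digamma(y + r) - digamma(r)
        + np.log(r) + 1.0
        - np.log(r + mu) - (y + r) / (r + mu)
    ).sum(axis=1)
    score = -np.exp(-u) * dll_dr
    if X is not None:
        W = mu / (1.0 + alpha * mu)
        A = np.einsum("gn,nf,nk->gfk", W, X, X, optimize=True)
        C = np.einsum("gn,nf,nk->gfk", W * W, X, X, optimize=True)
        A += 1e-10 * np.eye(X.shape[1])
        tr = np.einsum("gfk,gkf->g", np.linalg.inv(A), C, optimize=True)
        score = score + 0.5 * np.exp(u) * tr
    return score


def _maximize_dispersion(
    y: np.ndarray,
    mu: np.ndarray,
    cfg: GLMConfig,
    X: np.ndarray | None = None,
    prior_mean_log: np.ndarray | None = None,
    prior_var: float | None = None,
) -> np.ndarray:
    """Per-gene maximiser of the (Cox-Reid adjusted, when X is given) NB
    log-dispersion likelihood, optionally with a normal prior on
    log-dispersion, by bisection on the score."""
    G = y.shape[0]
    lo = np.full(G, np.log(cfg.min_disp))
    hi = np.full(G, np.log(max(cfg.max_disp, y.shape[1])))

    def score(u, y_, mu_, pm):
        s = _disp_score(u, y_, mu_, X)
        if pm is not None:
            s = s - (u - pm) / prior_var
        return s

    s_lo = score(lo, y, mu, prior_mean_log)
    s_hi = score(hi, y, mu, prior_mean_log)
    at_lo = s_lo <= 0          # likelihood decreasing from the floor
    at_hi = s_hi >= 0          # still increasing at the ceiling
    interior = ~(at_lo | at_hi)

    u = np.where(at_lo, lo, np.where(at_hi, hi, 0.5 * (lo + hi)))
    if interior.any():
        a = lo[interior].copy()
        b = hi[interior].copy()
        ys, ms = y[interior], mu[interior]
        pm = prior_mean_log[interior] if prior_mean_log is not None else None
        for _ in range(cfg.disp_bisections):
            mid = 0.5 * (a + b)
            s = score(mid, ys, ms, pm)
            go_right = s > 0
            a = np.where(go_right, mid, a)
            b = np.where(go_right, b, mid)
        u[interior] = 0.5 * (a + b)
    # exp(log(min_disp)) can round a hair below the floor
    return np.clip(np.exp(u), cfg.min_disp, None)


def _fit_dispersion_trend(
    alpha_gw: np.ndarray, base_mean: np.ndarray, cfg: GLMConfig
) -> tuple[np.ndarray, tuple[float, float] | None]:
    """Parametric trend alpha(mu) = a0 + a1/mu via iterative gamma-weighted LS.

    Returns (fitted per-gene trend, (a0, a1) or None when the median fallback
    was used).  Genes whose gene-wise estimate sits at the optimisation bounds
    are excluded from the regression.
    """
    usable = (
        (alpha_gw > cfg.min_disp * 10)
        & (alpha_gw < cfg.max_disp * 0.99)
        & (base_mean > 0)
    )
    if usable.sum() < 20:
        med = float(np.median(alpha_gw[usable])) if usable.any() else float(
            np.median(alpha_gw)
        )
        return np.full_like(alpha_gw, max(med, cfg.min_disp * 10)), None

    x = 1.0 / base_mean[usable]
    a = alpha_gw[usable]
    keep = np.ones(a.size, dtype=bool)
    coef = np.array([np.median(a), 0.0])
    for _ in range(10):
        pred = coef[0] + coef[1] * x
        ratio = a / np.maximum(pred, 1e-12)
        keep = (ratio > 1e-4) & (ratio < 15.0)
        if keep.sum() < 20:
            break
        w = 1.0 / np.maximum(pred[keep], 1e-12) ** 2
        M = np.column_stack([np.ones(keep.sum()), x[keep]])
        WM = M * w[:, None]
        try:
            new = np.linalg.solve(M.T @ WM, WM.T @ a[keep])
        except np.linalg.LinAlgError:
            new = coef
        if new[0] <= 0 or new[1] < 0:
            break
        if np.allclose(new, coef, rtol=1e-6):
            coef = new
            break
        coef = new
    if coef[0] <= 0:
        med = float(np.median(a))
        return np.full_like(alpha_gw, max(med, cfg.min_disp * 10)), None
    trend = coef[0] + coef[1] / np.maximum(base_mean, 1e-8)
    return np.maximum(trend, cfg.min_disp), (float(coef[0]), float(coef[1]))


@dataclass
class DispersionFit:
    """Empirical-Bayes dispersion estimates and intermediates."""

    alpha_map: np.ndarray
    alpha_genewise: np.ndarray
    alpha_trend: np.ndarray
    trend_coefficients: tuple[float, float] | None
    prior_variance: float


def estimate_dispersions(
    y: np.ndarray,
    X: np.ndarray,
    log_offset: np.ndarray,
    cfg: GLMConfig | None = None,
    trend_mean: np.ndarray | None = None,
) -> DispersionFit:
    """Three-stage dispersion estimation (gene-wise MLE, trend, MAP shrinkage).

    Genes are assumed pre-filtered to have at least one positive count.  The
    initial coefficient fit uses a fixed dispersion of 0.1 and is then
    alternated with gene-wise dispersion maximisation; the parametric trend is
    fit to the gene-wise values and the final estimate maximises the
    likelihood plus a normal prior on log-dispersion centred at the trend.
    """
    cfg = cfg or GLMConfig()
    G, N = y.shape
    F = X.shape[1]

    alpha = np.full(G, 0.1)
    beta = None
    for _ in range(cfg.disp_rounds):
        beta, mu, _ = _irls(y, X, log_offset, alpha, cfg, beta_init=beta)
        alpha = _maximize_dispersion(y, mu, cfg, X=X)
    alpha_gw = alpha

    # trend covariate: mean expression normalised for depth only (size
    # factors), so the trend is a property of expression level, not of the
    # CN offsets
    base_mean = (
        trend_mean if trend_mean is not None
        else (y * np.exp(-log_offset)).mean(axis=1)
    )
    alpha_trend, trend_coef = _fit_dispersion_trend(alpha_gw, base_mean, cfg)

    log_resid = np.log(alpha_gw) - np.log(alpha_trend)
    usable = (alpha_gw > cfg.min_disp * 10) & (alpha_gw < cfg.max_disp * 0.99)
    if usable.sum() >= 10:
        mad = np.median(np.abs(log_resid[usable] - np.median(log_resid[usable])))
        s_lr = 1.4826 * mad
        spread = s_lr**2
    else:
        s_lr = np.sqrt(cfg.prior_var_floor)
        spread = cfg.prior_var_floor
    sampling_var = float(polygamma(1, max((N - F), 1) / 2.0))
    prior_var = max(spread - sampling_var, cfg.prior_var_floor)

    alpha_map = _maximize_dispersion(
        y, mu, cfg, X=X, prior_mean_log=np.log(alpha_trend), prior_var=prior_var
    )
    # dispersion outliers far above the trend are not shrunk (shrinking them
    # would understate their variance and make the Wald test liberal)
    outlier = log_resid > 2.0 * max(s_lr, np.sqrt(sampling_var))
    alpha_map = np.where(outlier, alpha_gw, alpha_map)
    return DispersionFit(
        alpha_map=alpha_map,
        alpha_genewise=alpha_gw,
        alpha_trend=alpha_trend,
        trend_coefficients=trend_coef,
        prior_variance=prior_var,
    )


# ---------------------------------------------------------------------------
# coefficient fit, shrinkage, Wald test

@dataclass
class GeneModelFit:
    """Per-gene NB GLM fit (coefficients on the natural-log scale)."""

    beta: np.ndarray               # (G, F) MLE coefficients
    se: np.ndarray                 # (G, F) Fisher-information standard errors
    cov: np.ndarray                # (G, F, F)
    mu: np.ndarray                 # (G, N) fitted means
    alpha: np.ndarray              # (G,) dispersions used
    converged: np.ndarray          # (G,) bool
    beta_map: np.ndarray | None = None   # shrunken coefficients
    shrink_ok: np.ndarray | None = None  # genes where the MAP optimiser succeeded
    prior_scale: float | None = None
    coef_names: list[str] = field(default_factory=list)

    @property
    def lfc_mle(self) -> np.ndarray:
        """MLE condition log2 fold change."""
        return self.beta[:, 1] / LN2

    @property
    def lfc(self) -> np.ndarray:
        """Reported log2 fold change (shrunken when available)."""
        b = self.beta_map if self.beta_map is not None else self.beta
        return b[:, 1] / LN2


def fit_glm(
    y: np.ndarray,
    X: np.ndarray,
    log_offset: np.ndarray,
    alpha: np.ndarray,
    cfg: GLMConfig | None = None,
) -> GeneModelFit:
    """MLE coefficient fit by IRLS with fixed dispersions."""
    cfg = cfg or GLMConfig()
    beta, mu, converged = _irls(y, X, log_offset, alpha, cfg)
    cov = _fisher_cov(X, mu, alpha, ridge=cfg.ridge)
    se = np.sqrt(np.einsum("gff->gf", cov))
    return GeneModelFit(
        beta=beta, se=se, cov=cov, mu=mu, alpha=np.asarray(alpha, float),
        converged=converged,
    )


def _cauchy_prior_scale(beta_c: np.ndarray, se_c: np.ndarray, cfg: GLMConfig) -> float:
    """Adaptive Cauchy prior scale: method-of-moments signal spread of the
    condition MLEs in excess of their sampling noise, floored and outlier-
    clipped (the heavy-tailed prior only needs the right order of magnitude)."""
    ok = np.isfinite(beta_c) & np.isfinite(se_c)
    if ok.sum() < 3:
        return 1.0
    b2 = beta_c[ok] ** 2
    cap = np.quantile(b2, 0.99)
    excess = np.mean(np.minimum(b2, cap) - se_c[ok] ** 2)
    return float(np.sqrt(max(excess, cfg.prior_scale_floor**2)))


def shrink_lfc(
    fit: GeneModelFit,
    y: np.ndarray,
    X: np.ndarray,
    log_offset: np.ndarray,
    cfg: GLMConfig | None = None,
) -> GeneModelFit:
    """MAP estimate of the condition coefficient under a Cauchy prior.

    Joint damped-Newton maximisation of loglik - log(1 + (b_c/S)^2) over all
    coefficients (Laplace / apeglm-style), started at the MLE.  On failure the
    MLE is kept and the gene flagged.
    """
    cfg = cfg or GLMConfig()
    G, F = fit.beta.shape
    S = _cauchy_prior_scale(fit.beta[:, 1], fit.se[:, 1], cfg)
    S2 = S * S
    r_full = 1.0 / fit.alpha[:, None]
    eye = np.eye(F)

    # only the beta-dependent part of the penalised log-posterior is needed
    # for the line search: y*log(mu) - (y+r)*log(r+mu) - log(1 + b_c^2/S^2)
    def objective(beta, y_, r_, off_):
        lin = np.clip(beta @ X.T, -60.0, 60.0)
        mu = np.clip(np.exp(lin + off_), 1e-10, 1e15)
        ll = (y_ * np.log(mu) - (y_ + r_) * np.log(r_ + mu)).sum(axis=1)
        return ll - np.log1p(beta[:, 1] ** 2 / S2)

    beta = fit.beta.copy()
    failed = np.zeros(G, dtype=bool)
    active = np.ones(G, dtype=bool)
    for _ in range(50):
        idx = np.nonzero(active)[0]
        if idx.size == 0:
            break
        b = beta[idx]
        y_, r_, off_ = y[idx], r_full[idx], log_offset[idx]
        a_ = 1.0 / r_
        obj = objective(b, y_, r_, off_)
        lin = np.clip(b @ X.T, -60.0, 60.0)
        mu = np.clip(np.exp(lin + off_), 1e-10, 1e15)
        W = mu / (1.0 + a_ * mu)
        grad = np.einsum("gn,nf->gf", (y_ - mu) / (1.0 + a_ * mu), X, optimize=True)
        bc = b[:, 1]
        grad[:, 1] -= 2.0 * bc / (S2 + bc**2)
        pen_h = np.maximum(2.0 * (S2 - bc**2) / (S2 + bc**2) ** 2, 0.0)
        H = np.einsum("gn,nf,nk->gfk", W, X, X, optimize=True)
        H += cfg.ridge * eye
        H[:, 1, 1] += pen_h
        step = np.linalg.solve(H, grad[..., None])[..., 0]
        # backtracking line search on the penalised objective
        t = np.ones(idx.size)
        improved = np.zeros(idx.size, dtype=bool)
        for _half in range(12):
            todo = ~improved
            cand = b[todo] + t[todo, None] * step[todo]
            obj_new = objective(cand, y_[todo], r_[todo], off_[todo])
            better = obj_new >= obj[todo] - 1e-12
            sel = np.nonzero(todo)[0][better]
            b[sel] = cand[better]
            improved[sel] = True
            if improved.all():
                break
            t[~improved] /= 2.0
        beta[idx] = b
        failed[idx[~improved]] = True
        done = improved & (np.max(np.abs(step), axis=1) < 1e-9)
        active[idx] = ~done & ~failed[idx]

    # ascent is monotone (steps only accepted when the objective improves),
    # so the running beta is valid except where the line search failed outright
    ok = ~failed & np.isfinite(beta).all(axis=1)
    beta_map = np.where(ok[:, None], beta, fit.beta)
    fit.beta_map = beta_map
    fit.shrink_ok = ok
    fit.prior_scale = S
    return fit


def wald_test(
    fit: GeneModelFit, contrast: np.ndarray, on: str = "mle"
) -> tuple[np.ndarray, np.ndarray]:
    """Wald z and two-sided p for H0: c'beta = 0.

    ``on='mle'`` (default) tests the unpenalised coefficients with
    Fisher-information standard errors; ``on='map'`` plugs in the shrunken
    coefficients instead (same SEs).
    """
    c = np.asarray(contrast, dtype=float)
    beta = fit.beta if on == "mle" or fit.beta_map is None else fit.beta_map
    est = beta @ c
    var = np.einsum("f,gfk,k->g", c, fit.cov, c, optimize=True)
    se = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, est / se, np.nan)
    p = 2.0 * norm.sf(np.abs(z))
    p = np.clip(p, 1e-300, 1.0)
    p[~np.isfinite(z)] = np.nan
    return z, p


# ---------------------------------------------------------------------------
# full single-mode pipeline

def run_dge(
    counts: pd.DataFrame,
    cn: pd.DataFrame | None,
    design: DesignSpec,
    mode: str = "aware",
    cfg: GLMConfig | None = None,
) -> pd.DataFrame:
    """Full per-gene NB GLM pipeline in CN-aware or CN-naive mode.

    Returns a DataFrame indexed by gene id with columns base_mean, lfc
    (reported, shrunken when enabled), lfc_mle, lfc_se, stat, pvalue,
    dispersion, converged and flag.  Genes with all-zero counts are reported
    with NaN statistics and flag ``allzero``.
    """
    cfg = cfg or GLMConfig()
    if mode not in ("aware", "naive"):
        raise ValueError("mode must be 'aware' or 'naive'")
    y_all = counts.to_numpy(dtype=float)
    X = design.matrix()
    s = estimate_size_factors(y_all, pseudo_reference=cfg.size_factor_pseudocount)
    log_off_all = build_offsets(
        s, cn, mode=mode, n_genes=y_all.shape[0], cn_floor=cfg.cn_floor
    )

    nonzero = y_all.sum(axis=1) > 0
    y = y_all[nonzero]
    log_off = log_off_all[nonzero]

    disp = estimate_dispersions(
        y, X, log_off, cfg, trend_mean=(y / s[None, :]).mean(axis=1)
    )
    fit = fit_glm(y, X, log_off, disp.alpha_map, cfg)
    if cfg.shrink:
        fit = shrink_lfc(fit, y, X, log_off, cfg)
    z, p = wald_test(fit, design.contrast, on=cfg.wald_on)

    G = y_all.shape[0]
    out = pd.DataFrame(index=counts.index)
    out["base_mean"] = (y_all / s[None, :]).mean(axis=1)

    def expand(v: np.ndarray, fill=np.nan) -> np.ndarray:
        full = np.full(G, fill, dtype=float)
        full[nonzero] = v
        return full

    out["lfc"] = expand(fit.lfc)
    out["lfc_mle"] = expand(fit.lfc_mle)
    out["lfc_se"] = expand(
        np.sqrt(
            np.einsum(
                "f,gfk,k->g", design.contrast, fit.cov, design.contrast,
                optimize=True,
            )
        )
        / LN2
    )
    out["stat"] = expand(z)
    out["pvalue"] = expand(p)
    out["dispersion"] = expand(fit.alpha)
    conv = np.zeros(G, dtype=bool)
    conv[nonzero] = fit.converged
    out["converged"] = conv
    flag = np.where(nonzero, "", "allzero").astype(object)
    bad = nonzero.copy()
    bad[nonzero] = ~fit.converged
    flag[bad] = "nonconverged"
    out.loc[bad, "pvalue"] = np.nan
    out["flag"] = flag
    return out
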