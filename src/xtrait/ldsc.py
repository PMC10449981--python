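"""LD-score regression: heritability, cross-trait genetic correlation, and
the effective number of independent traits.

Model
-----
For trait t with sample size N and M SNPs,

    E[chi2_j] = N * h2 * l_j / M + intercept,

where ``l_j`` is SNP j's LD score (sum of squared correlations with SNPs in
its region).  For a pair of traits,

    E[z1_j z2_j] = sqrt(n1*n2) * rho_g * l_j / M + gcov_int,

with ``gcov_int`` absorbing sample overlap (``n_s * rho_pheno /
sqrt(n1*n2)``); the genetic correlation is ``rg = rho_g / sqrt(h2_1*h2_2)``.
Both regressions are two-step inverse-variance weighted (heteroskedasticity
weights evaluated at a first-pass estimate), and standard errors come from a
delete-a-block jackknife over position-contiguous SNP blocks.

The cross-trait intercept can be constrained to zero, constrained
automatically when not significantly different from zero (|gcov_int| <
1.96 * SE, the conventional screening rule), or left free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, DomainError, EstimationError
from .simulate import LDPanel
from .sumstats import TraitGWAS

DEFAULT_JK_BLOCKS = 200


@dataclass
class H2Estimate:
    h2: float
    h2_se: float
    intercept: float
    intercept_se: float
    mean_chi2: float
    n_snps: int

    @property
    def z_h2(self) -> float:
        return self.h2 / self.h2_se


@dataclass
class RgEstimate:
    rg: float
    rg_se: float
    p: float
    gcov_int: float
    gcov_int_se: float
    gcov_int_p: float
    constrained: bool
    rho_g: float
    h2_1: float
    h2_2: float


def compute_ld_scores(panel: LDPanel, adjust_bias: bool = False,
                      n_ref: int | None = None) -> pd.Series:
    """Per-SNP LD scores ``l_j = sum_k r2_jk`` over the SNP's region.

    With ``adjust_bias`` the unbiased estimator ``r2 - (1-r2)/(n_ref-2)`` is
    used, with r2 taken from the reference genotypes when the panel carries
    them (otherwise from the stored correlation matrices).  Returns a Series
    indexed by snp_id, in panel order.
    """
    n_eff = n_ref if n_ref is not None else panel.n_ref
    if adjust_bias and (n_eff is None or n_eff < 3):
        raise ConfigurationError("adjust_bias requires n_ref >= 3")
    scores = np.empty(panel.n_snps)
    for r in range(panel.n_regions):
        sl = panel.region_slice(r)
        if adjust_bias and panel.genotypes is not None:
            R = np.corrcoef(panel.genotypes[r], rowvar=False)
        else:
            R = panel.ld[r]
        r2 = R ** 2
        if adjust_bias:
            r2 = r2 - (1.0 - r2) / (n_eff - 2)
        scores[sl] = r2.sum(axis=1)
    return pd.Series(scores, index=panel.snps["snp_id"].to_numpy(),
                     name="ld_score")


def _jackknife_blocks(m: int, n_blocks: int):
    """Contiguous block boundaries; shrinks the count on small inputs."""
    n_blocks = int(min(n_blocks, max(2, m // 50)))
    edges = np.linspace(0, m, n_blocks + 1).astype(int)
    return [(edges[i], edges[i + 1]) for i in range(n_blocks)]


def _wls_blockwise(X, y, w, blocks):
    """Weighted LS fit plus leave-one-block-out fits via sufficient stats."""
    Xw = X * w[:, None]
    A = X.T @ Xw           # p x p
    b = Xw.T @ y           # p
    A_blocks = np.stack([X[s:e].T @ (X[s:e] * w[s:e, None])
                         for s, e in blocks])
    b_blocks = np.stack([(X[s:e] * w[s:e, None]).T @ y[s:e]
                         for s, e in blocks])
    try:
        full = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as e:
        raise EstimationError("degenerate regression design "
                              "(constant LD scores?)") from e
    loo = np.stack([np.linalg.solve(A - Ab, b - bb)
                    for Ab, bb in zip(A_blocks, b_blocks)])
    return full, loo


def _jackknife_se(loo):
    B = loo.shape[0]
    return np.sqrt((B - 1) / B * ((loo - loo.mean(0)) ** 2).sum(0))


def _align(g: TraitGWAS, ld: pd.Series):
    idx = g.df["snp_id"].to_numpy()
    l = ld.reindex(idx)
    if l.isna().any():
        raise EstimationError("LD scores missing for some SNPs")
    return l.to_numpy()


def estimate_h2(g: TraitGWAS, ld: pd.Series,
                n_blocks_jk: int = DEFAULT_JK_BLOCKS) -> H2Estimate:
    """SNP heritability (observed scale) by two-step weighted LD-score
    regression of chi2 on N*l/M, with block-jackknife standard errors."""
    l = _align(g, ld)
    M = len(l)
    if M < 200:
        raise EstimationError("need at least 200 SNPs for LDSC")
    if n_blocks_jk < 2:
        raise ConfigurationError("n_blocks_jk must be >= 2")
    z = g.df["z"].to_numpy()
    n = g.df["n"].to_numpy(dtype=float)
    chi2 = z ** 2
    x = n * l / M
    X = np.column_stack([x, np.ones(M)])
    blocks = _jackknife_blocks(M, n_blocks_jk)

    h2_prev, icpt_prev = 0.0, 1.0
    for _ in range(2):
        w = 1.0 / (2.0 * (icpt_prev + h2_prev * x) ** 2 * np.maximum(l, 1.0))
        coef, loo = _wls_blockwise(X, chi2, w, blocks)
        h2_prev = float(np.clip(coef[0], 0.0, 1.0))
        icpt_prev = float(np.clip(coef[1], 0.5, None))
    se = _jackknife_se(loo)
    return H2Estimate(h2=float(coef[0]), h2_se=float(se[0]),
                      intercept=float(coef[1]), intercept_se=float(se[1]),
                      mean_chi2=float(chi2.mean()), n_snps=M)


def estimate_rg(g1: TraitGWAS, g2: TraitGWAS, ld: pd.Series,
                n_blocks_jk: int = DEFAULT_JK_BLOCKS,
                constrain_gcov_int: bool | str = "auto") -> RgEstimate:
    """Cross-trait genetic correlation with intercept handling.

    ``constrain_gcov_int`` may be True, False, or ``"auto"`` (constrain when
    the unconstrained intercept is not significantly different from zero at
    1.96 SE).  Raises EstimationError when either trait's heritability is
    non-positive, in which case rg is undefined.
    """
    if not g1.df["snp_id"].equals(g2.df["snp_id"]):
        raise EstimationError("traits must be harmonized to the same SNPs")
    h1 = estimate_h2(g1, ld, n_blocks_jk)
    h2 = estimate_h2(g2, ld, n_blocks_jk)
    if h1.h2 <= 0 or h2.h2 <= 0:
        raise EstimationError(
            "rg undefined: non-positive heritability estimate "
            f"(h2_1={h1.h2:.4g}, h2_2={h2.h2:.4g})")

    l = _align(g1, ld)
    M = len(l)
    z1 = g1.df["z"].to_numpy()
    z2 = g2.df["z"].to_numpy()
    n1 = g1.df["n"].to_numpy(dtype=float)
    n2 = g2.df["n"].to_numpy(dtype=float)
    y = z1 * z2
    x = np.sqrt(n1 * n2) * l / M
    blocks = _jackknife_blocks(M, n_blocks_jk)

    # heteroskedasticity weights at first-pass estimates (two-step)
    v1 = 1.0 + n1 * h1.h2 * l / M
    v2 = 1.0 + n2 * h2.h2 * l / M
    rho_prev, icpt_prev = 0.0, 0.0
    X2 = np.column_stack([x, np.ones(M)])
    for _ in range(2):
        w = 1.0 / ((v1 * v2 + (rho_prev * x + icpt_prev) ** 2)
                   * np.maximum(l, 1.0))
        coef_u, loo_u = _wls_blockwise(X2, y, w, blocks)
        rho_prev, icpt_prev = float(coef_u[0]), float(coef_u[1])
    se_u = _jackknife_se(loo_u)
    gcov_int, gcov_int_se = float(coef_u[1]), float(se_u[1])
    gcov_int_p = float(2 * stats.norm.sf(abs(gcov_int) / max(gcov_int_se, 1e-300)))

    if constrain_gcov_int == "auto":
        constrained = abs(gcov_int) < 1.96 * gcov_int_se
    else:
        constrained = bool(constrain_gcov_int)

    if constrained:
        X1 = x[:, None]
        coef, loo = _wls_blockwise(X1, y, w, blocks)
        rho_g = float(coef[0])
        rho_loo = loo[:, 0]
        icpt_report = 0.0
    else:
        rho_g = rho_prev
        rho_loo = loo_u[:, 0]
        icpt_report = gcov_int

    # h2 re-fit with the cross-regression weights: keeps the rg ratio exact
    # for identical inputs and shares one weighting scheme across numerator
    # and denominator; jackknifed jointly over the same blocks
    def _h2_same_weights(g):
        zz = g.df["z"].to_numpy() ** 2
        nn = g.df["n"].to_numpy(dtype=float)
        XX = np.column_stack([nn * l / M, np.ones(M)])
        full, lo = _wls_blockwise(XX, zz, w, blocks)
        return float(full[0]), lo[:, 0]

    h1_w, h1_loo = _h2_same_weights(g1)
    h2_w, h2_loo = _h2_same_weights(g2)
    if h1_w <= 0 or h2_w <= 0:
        raise EstimationError("rg undefined: non-positive weighted "
                              "heritability estimate")
    denom = np.sqrt(np.clip(h1_loo * h2_loo, 1e-12, None))
    rg_loo = rho_loo / denom
    rg = rho_g / np.sqrt(h1_w * h2_w)
    rg_se = float(_jackknife_se(rg_loo[:, None])[0])
    p = float(np.clip(2 * stats.norm.sf(abs(rg) / max(rg_se, 1e-300)),
                      np.finfo(float).tiny, 1.0))
    # soft clip: report within [-1, 1] but keep raw value in rho_g/h2 fields
    rg_reported = float(np.clip(rg, -1.0, 1.0))
    return RgEstimate(rg=rg_reported, rg_se=rg_se, p=p,
                      gcov_int=icpt_report, gcov_int_se=gcov_int_se,
                      gcov_int_p=gcov_int_p, constrained=bool(constrained),
                      rho_g=rho_g, h2_1=h1.h2, h2_2=h2.h2)


def effective_traits_matspd(rg_matrix, method: str = "nyholt") -> float:
    """Effective number of independent traits from a trait correlation matrix.

    ``nyholt``: ``Meff = 1 + (T-1) * (1 - Var(lambda)/T)`` with the sample
    variance of the eigenvalues; ``li_ji``: ``sum_i I(lambda_i >= 1) +
    (lambda_i - floor(lambda_i))``.
    """
    A = np.asarray(rg_matrix, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise DomainError("rg_matrix must be square")
    if not np.allclose(A, A.T, atol=1e-8):
        raise DomainError("rg_matrix must be symmetric")
    lam = np.linalg.eigvalsh(A)
    T = A.shape[0]
    if method == "nyholt":
        if T == 1:
            return 1.0
        var = lam.var(ddof=1)
        return float(1 + (T - 1) * (1 - var / T))
    if method == "li_ji":
        return float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))
    raise ConfigurationError(f"unknown method {method!r}")


def adjusted_threshold(alpha: float, meff: float, n_sides: int = 1) -> float:
    """Multiple-testing-adjusted threshold ``alpha / (meff * n_sides)``.

    ``meff`` is the effective number of independent traits; ``n_sides``
    counts symmetric experiment arms (e.g. 2 for forward+reverse MR).
    """
    if meff < 1 or n_sides < 1:
        raise DomainError("meff and n_sides must be >= 1")
    return alpha / (meff * n_sides)


def rg_matrix_from_pairs(pairs: dict, traits: list) -> pd.DataFrame:
    """Assemble a symmetric unit-diagonal rg matrix from pairwise estimates.

    ``pairs`` maps frozenset({a, b}) -> rg.  Missing pairs default to 0.
    """
    T = len(traits)
    A = np.eye(T)
    for i in range(T):
        for j in range(i + 1, T):
            r = pairs.get(frozenset((traits[i], traits[j])), 0.0)
            A[i, j] = A[j, i] = np.clip(r, -1, 1)
    return pd.DataFrame(A, index=traits, columns=traits)
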