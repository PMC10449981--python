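"""Pairwise GWAS analysis: regional Bayes factors and pleiotropy posteriors.

For each LD-independent region and each of two traits, per-SNP approximate
Bayes factors (Wakefield ABFs, averaged over a small grid of prior effect
variances) are combined into four regional Bayes factors:

* model 1 — one causal variant, trait 1 only:  BF1 = mean_i abf1_i
* model 2 — one causal variant, trait 2 only:  BF2 = mean_i abf2_i
* model 3 — one shared causal variant:         BF3 = mean_i abf1_i*abf2_i
* model 4 — two distinct causal variants:
  BF4 = (sum_i abf1_i * sum_j abf2_j - sum_i abf1_i*abf2_i) / (K*(K-1))

against the null model (BF0 = 1).  Mixture weights pi_0..pi_4 over regions
are estimated by EM (or fixed), giving posteriors PPA0..PPA4 per region.
A region is called a significant pleiotropic region when PPA3 > 0.9 and
suggestive when PPA3 > 0.5 (strict inequalities).

All Bayes-factor arithmetic is in log space: ABFs overflow double precision
for |z| beyond ~40.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .exceptions import ConfigurationError, DomainError
from .sumstats import TraitGWAS

DEFAULT_W_GRID = (0.01, 0.1, 0.5)


@dataclass
class RegionPPA:
    region_id: str
    chrom: int
    start: int
    end: int
    bf1: float  # log region Bayes factors
    bf2: float
    bf3: float
    bf4: float
    ppa0: float
    ppa1: float
    ppa2: float
    ppa3: float
    ppa4: float
    label: str


def log_wakefield_abf(z, v, w_grid=DEFAULT_W_GRID):
    """Log approximate Bayes factor for one SNP (vectorized over SNPs).

    ``ABF(W) = sqrt(v/(v+W)) * exp(z^2 W / (2 (v+W)))`` for effect-size prior
    variance W, averaged with equal weight over ``w_grid``.  ``v`` is the
    squared SE of beta.  Monotone nondecreasing in |z|.
    """
    z = np.asarray(z, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise DomainError("v must be positive")
    w = np.asarray(w_grid, dtype=float)
    if w.size == 0 or np.any(w < 0):
        raise ConfigurationError("w_grid must be nonempty and nonnegative")
    lab = (0.5 * np.log(v[..., None] / (v[..., None] + w))
           + z[..., None] ** 2 * w / (2.0 * (v[..., None] + w)))
    return logsumexp(lab, axis=-1) - np.log(w.size)


def wakefield_abf(z, v, w_grid=DEFAULT_W_GRID):
    """ABF on the natural scale (may overflow to inf for extreme |z|)."""
    return np.exp(log_wakefield_abf(z, v, w_grid))


def _log_mean(la):
    return logsumexp(la) - np.log(la.size)


def region_bfs(labf1, labf2):
    """Log regional Bayes factors (BF1..BF4) from per-SNP log ABFs.

    K=1 leaves model 4 impossible: its BF is 0 (log BF -> -inf).
    """
    labf1 = np.asarray(labf1, dtype=float)
    labf2 = np.asarray(labf2, dtype=float)
    if labf1.shape != labf2.shape or labf1.ndim != 1:
        raise DomainError("per-SNP ABF vectors must be 1-D and equal length")
    K = labf1.size
    if K == 0:
        raise DomainError("empty region")
    lbf1 = _log_mean(labf1)
    lbf2 = _log_mean(labf2)
    lbf3 = _log_mean(labf1 + labf2)
    if K == 1:
        return lbf1, lbf2, lbf3, -np.inf
    ls1 = logsumexp(labf1)
    ls2 = logsumexp(labf2)
    lcross = ls1 + ls2                       # log sum_i sum_j
    ldiag = logsumexp(labf1 + labf2)          # log sum_i (i == j)
    # log(exp(lcross) - exp(ldiag)), guarded: the diagonal can dominate
    # numerically when one SNP carries essentially all evidence
    diff = ldiag - lcross
    if diff >= 0:
        lnum = -np.inf
    else:
        lnum = lcross + np.log1p(-np.exp(diff))
    lbf4 = lnum - np.log(K) - np.log(K - 1)
    return lbf1, lbf2, lbf3, lbf4


def estimate_priors(log_bfs, method: str = "em", fixed=None,
                    max_iter: int = 1000, tol: float = 1e-10):
    """Mixture weights pi_0..pi_4 over regions.

    ``em`` maximizes  sum_regions log(pi0 + sum_m pi_m BF_m)  on the simplex
    by expectation-maximization (monotone in the objective, uniform start);
    ``fixed`` returns the supplied vector unchanged.
    """
    lb = np.asarray(log_bfs, dtype=float)
    if lb.ndim != 2 or lb.shape[1] != 4 or lb.shape[0] < 1:
        raise DomainError("log_bfs must be (n_regions, 4)")
    if method == "fixed":
        pi = np.asarray(fixed, dtype=float)
        if pi.shape != (5,) or np.any(pi < 0) or abs(pi.sum() - 1) > 1e-8:
            raise ConfigurationError("fixed priors must be a length-5 simplex")
        return pi
    if method != "em":
        raise ConfigurationError(f"unknown method {method!r}")

    la = np.column_stack([np.zeros(lb.shape[0]), lb])  # BF0 = 1
    pi = np.full(5, 0.2)
    obj = -np.inf
    for _ in range(max_iter):
        with np.errstate(divide="ignore"):
            lp = np.log(pi)
        t = la + lp
        norm = logsumexp(t, axis=1)
        new_obj = float(norm.sum())
        resp = np.exp(t - norm[:, None])
        pi_new = resp.mean(axis=0)
        if new_obj < obj - 1e-9:
            warnings.warn("EM objective decreased; returning best iterate")
            break
        if new_obj - obj < tol:
            pi = pi_new
            obj = new_obj
            break
        pi = pi_new
        obj = new_obj
    else:
        warnings.warn("EM did not converge within max_iter; "
                      "returning best iterate")
    return pi


def compute_ppa(log_bfs, pi):
    """Posterior model probabilities (ppa0..ppa4) from log BFs and priors.

    Accepts one region (length-4) or many (n x 4); the returned posteriors
    sum to 1 within 1e-9.
    """
    lb = np.atleast_2d(np.asarray(log_bfs, dtype=float))
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (5,) or np.any(pi < 0):
        raise DomainError("pi must be a length-5 simplex")
    la = np.column_stack([np.zeros(lb.shape[0]), lb])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = la + np.log(pi)
    t = np.where(np.isnan(t), -np.inf, t)  # 0 * inf from pi=0 on bf4=-inf
    ppa = np.exp(t - logsumexp(t, axis=1)[:, None])
    return ppa[0] if np.asarray(log_bfs).ndim == 1 else ppa


def classify_region(ppa3: float) -> str:
    """'significant' above 0.9, 'suggestive' above 0.5, else 'none'."""
    if not (0 <= ppa3 <= 1):
        raise DomainError("ppa3 must be in [0, 1]")
    if ppa3 > 0.9:
        return "significant"
    if ppa3 > 0.5:
        return "suggestive"
    return "none"


def analyze_regions(g1: TraitGWAS, g2: TraitGWAS, regions: pd.DataFrame,
                    priors: str = "em", fixed_priors=None,
                    w_grid=DEFAULT_W_GRID) -> pd.DataFrame:
    """Full pairwise analysis over a region table.

    ``regions`` is a DataFrame(region_id, chrom, start, end).  Traits must be
    harmonized (same SNP set).  Returns one row per region with log BFs,
    PPA0-4 and the pleiotropy label, mirroring the regional-posterior table
    layout.
    """
    if not g1.df["snp_id"].equals(g2.df["snp_id"]):
        raise DomainError("traits must be harmonized to the same SNPs")
    la1 = log_wakefield_abf(g1.df["z"].to_numpy(),
                            g1.df["se"].to_numpy() ** 2, w_grid)
    la2 = log_wakefield_abf(g2.df["z"].to_numpy(),
                            g2.df["se"].to_numpy() ** 2, w_grid)
    chrom = g1.df["chrom"].to_numpy()
    pos = g1.df["pos"].to_numpy()

    rows = []
    lbfs = []
    for _, reg in regions.iterrows():
        in_reg = (chrom == reg["chrom"]) & (pos >= reg["start"]) & (pos <= reg["end"])
        if not in_reg.any():
            continue
        lbfs.append(region_bfs(la1[in_reg], la2[in_reg]))
        rows.append(reg)
    lbfs = np.array(lbfs)
    if priors == "em":
        pi = estimate_priors(lbfs, method="em")
    else:
        pi = estimate_priors(lbfs, method="fixed", fixed=fixed_priors)
    ppa = compute_ppa(lbfs, pi)

    out = []
    for reg, lb, pp in zip(rows, lbfs, ppa):
        out.append(RegionPPA(reg["region_id"], int(reg["chrom"]),
                             int(reg["start"]), int(reg["end"]),
                             *map(float, lb), *map(float, pp),
                             classify_region(float(pp[3]))))
    df = pd.DataFrame([vars(r) for r in out])
    df.attrs["priors"] = pi
    return df
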