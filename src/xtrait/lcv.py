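"""Latent-causal-variable estimation of the genetic causality proportion.

Model: a latent trait L mediates the entire genetic correlation between two
traits, which load on it with strengths q1 and q2 (normalized genetic scale);
rho = q1*q2 is the genetic correlation.  The genetic causality proportion
(GCP) parameterizes the asymmetry of the loadings,

    q1^2 = |rho|^(1-gcp),    q2^2 = |rho|^(1+gcp),

so gcp = 1 means trait 1 *is* the latent trait (fully causal on trait 2),
gcp = 0 means symmetric horizontal pleiotropy, and the sign flips under a
trait swap.

Estimation uses mixed fourth moments of the marginal association statistics.
With x, y the variance-normalized z-scores, the excess mixed cumulants

    k31 = E[x^3 y] - 3 E[xy],     k13 = E[x y^3] - 3 E[xy]

are proportional to q1^3 q2 and q1 q2^3 times the excess kurtosis of the
latent effect distribution; Gaussian sampling noise and independent
trait-specific effects cancel from both.  After rescaling each side to the
genetic (heritability) scale — variance fractions t = (E[z^2]-1)/E[z^2],
the LD-score-regression decomposition of chi-square into signal plus
sampling noise — the moment-ratio estimating equation

    gcp = -log( (|k31|/|k13|) * t2/t1 ) / (2 log |rho_g|)

is solved directly, with rho_g the attenuation-corrected genetic
correlation.  Standard errors come from a delete-a-block jackknife over
position-contiguous SNP blocks.  The estimator needs a leptokurtic effect
distribution (polygenic-but-sparse architectures); under an exactly Gaussian
architecture the moments are uninformative and the estimate is noise around
zero.

Inputs should be munged as is conventional for moment-based estimators:
MAF > 0.05 and the MHC excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import EstimationError, InputError
from .sumstats import TraitGWAS

MIN_SNPS = 5_000
RHO_WEAK = 0.05
H2_Z_WARN = 7.0


@dataclass
class LCVResult:
    gcp: float
    gcp_se: float
    p_gcp: float
    rho_est: float
    q1: float
    q2: float
    n_jk_blocks: int
    n_snps: int
    warnings: list = field(default_factory=list)


def _gcp_from_sums(s):
    """Point estimate from accumulated weighted moment sums.

    ``s`` is a vector of weighted sums: [w, w*x^2, w*y^2, w*xy, w*x^3y,
    w*xy^3] over SNPs, with x, y raw z-scores.  Returns (gcp, rho_g).
    """
    sw, sx2, sy2, sxy, sx3y, sxy3 = s
    v1 = sx2 / sw
    v2 = sy2 / sw
    # normalize to unit variance
    rho = (sxy / sw) / np.sqrt(v1 * v2)
    k31 = (sx3y / sw) / (v1 ** 1.5 * v2 ** 0.5) - 3.0 * rho
    k13 = (sxy3 / sw) / (v1 ** 0.5 * v2 ** 1.5) - 3.0 * rho
    # genetic variance fractions: sampling noise contributes unit variance
    t1 = np.clip((v1 - 1.0) / v1, 1e-3, 1.0)
    t2 = np.clip((v2 - 1.0) / v2, 1e-3, 1.0)
    rho_g = rho / np.sqrt(t1 * t2)
    rho_g = np.clip(rho_g, -0.999, 0.999)
    ratio = (max(abs(k31), 1e-300) / max(abs(k13), 1e-300)) * (t2 / t1)
    denom = 2.0 * np.log(max(abs(rho_g), 1e-6))
    gcp = -np.log(ratio) / denom
    return float(gcp), float(rho_g)


def estimate_gcp(g1: TraitGWAS, g2: TraitGWAS, ld: pd.Series | None = None,
                 n_jk_blocks: int = 100,
                 h2_z: tuple | None = None) -> LCVResult:
    """Estimate the genetic causality proportion between two munged traits.

    ``ld`` (optional) supplies LD scores used as downweights
    ``1/max(1, l_j)`` for high-LD SNPs; omit it for LD-pruned or
    LD-independent inputs.  ``h2_z`` optionally passes the two traits'
    heritability z-scores so the result can carry the conventional low-power
    warning (z < 7).  The point estimate is clipped into [-1, 1]; the
    jackknife runs on the unclipped estimating equation.

    Positive gcp: trait 1 genetically causal for trait 2.
    """
    if not g1.df["snp_id"].equals(g2.df["snp_id"]):
        raise EstimationError("traits must be harmonized to the same SNPs")
    m = len(g1)
    if m < MIN_SNPS:
        raise InputError(f"LCV needs >= {MIN_SNPS} SNPs, got {m}")
    z1 = g1.df["z"].to_numpy()
    z2 = g2.df["z"].to_numpy()
    if ld is not None:
        l = ld.reindex(g1.df["snp_id"].to_numpy()).to_numpy()
        if np.isnan(l).any():
            raise EstimationError("LD scores missing for some SNPs")
        w = 1.0 / np.maximum(1.0, l)
    else:
        w = np.ones(m)

    contrib = np.column_stack([
        w, w * z1 ** 2, w * z2 ** 2, w * z1 * z2,
        w * z1 ** 3 * z2, w * z1 * z2 ** 3,
    ])
    total = contrib.sum(axis=0)
    gcp_full, rho_g = _gcp_from_sums(total)

    edges = np.linspace(0, m, n_jk_blocks + 1).astype(int)
    block_sums = np.add.reduceat(contrib, edges[:-1], axis=0)
    loo = np.array([_gcp_from_sums(total - bs)[0] for bs in block_sums])
    B = loo.shape[0]
    se = float(np.sqrt((B - 1) / B * np.sum((loo - loo.mean()) ** 2)))
    se = max(se, 1e-12)
    p = float(np.clip(2 * stats.norm.sf(abs(gcp_full) / se),
                      np.finfo(float).tiny, 1.0))

    warns = []
    if abs(rho_g) < RHO_WEAK:
        warns.append(f"weak genetic correlation (|rho|={abs(rho_g):.3f} < "
                     f"{RHO_WEAK}); gcp is weakly identified")
    if h2_z is not None:
        for name, zval in zip((g1.trait_name, g2.trait_name), h2_z):
            if zval < H2_Z_WARN:
                warns.append(f"low heritability z-score for {name} "
                             f"(z={zval:.2f} < {H2_Z_WARN:g}); estimate may "
                             "be unreliable")

    gcp_clip = float(np.clip(gcp_full, -1.0, 1.0))
    aq = abs(rho_g)
    q1 = aq ** ((1.0 - gcp_clip) / 2.0)
    q2 = np.sign(rho_g) * aq ** ((1.0 + gcp_clip) / 2.0)
    return LCVResult(gcp=gcp_clip, gcp_se=se, p_gcp=p, rho_est=float(rho_g),
                     q1=float(q1), q2=float(q2), n_jk_blocks=B, n_snps=m,
                     warnings=warns)


def classify_partial_causality(result: LCVResult, gcp_min: float = 0.6,
                               alpha: float = 0.05) -> bool:
    """Partial genetic causality: |gcp| above threshold and significant."""
    return bool(abs(result.gcp) > gcp_min and result.p_gcp < alpha)


def lcv_table(results: dict) -> pd.DataFrame:
    """Tabulate trait-pair LCV results (gcp, se, p, rho)."""
    rows = []
    for (t1, t2), r in results.items():
        rows.append({"trait1": t1, "trait2": t2, "gcp": r.gcp,
                     "gcp_se": r.gcp_se, "p_gcp": r.p_gcp,
                     "rho": r.rho_est,
                     "partial_causality": classify_partial_causality(r)})
    return pd.DataFrame(rows)
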