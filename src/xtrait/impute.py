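"""Conditional-normal imputation of missing z-scores from regional LD.

Given observed z-scores ``z_obs`` in a region with correlation matrix R, the
z-score of an untyped SNP t is imputed by the conditional expectation under
the joint-normal model of marginal statistics,

    z_t = R_to (R_oo + lam I)^-1 z_obs,

with imputation quality ``r2 = diag(R_to (R_oo + lam I)^-1 R_ot)`` — the
proportion of variance of z_t explained by the observed panel.  A small ridge
``lam`` regularizes the observed-block inverse (reference-panel sampling
noise); imputed SNPs with quality below a cutoff (default R² < 0.6) are
discarded, observed SNPs are always kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .exceptions import NumericalError
from .simulate import LDPanel
from .sumstats import TraitGWAS, from_frame, zscore_to_beta_se


@dataclass
class ImputedSnp:
    snp_id: str
    z_imp: float
    r2_quality: float
    beta: float | None = None
    se: float | None = None


def default_ridge(n_ref: int | None) -> float:
    """Default ridge 0.1/sqrt(n_ref): shrinks with reference-panel size."""
    return 0.1 / np.sqrt(n_ref) if n_ref else 0.01


def impute_region(z_obs, R, observed, targets, lam: float = 0.01):
    """Impute target SNPs of one region from its observed SNPs.

    Parameters
    ----------
    z_obs : observed z-scores, aligned with ``observed``
    R : full regional correlation matrix
    observed, targets : disjoint index arrays into R
    lam : ridge added to the observed-observed block

    Returns ``(z_imp, r2_quality)`` arrays aligned with ``targets``;
    quality is clipped into [0, 1] (tolerance 1e-8).  Deterministic.
    """
    observed = np.asarray(observed, dtype=int)
    targets = np.asarray(targets, dtype=int)
    if np.intersect1d(observed, targets).size:
        raise ValueError("targets must be disjoint from observed")
    z_obs = np.asarray(z_obs, dtype=float)
    if targets.size == 0:
        return np.empty(0), np.empty(0)
    if observed.size == 0:
        return np.zeros(targets.size), np.zeros(targets.size)

    R = np.asarray(R, dtype=float)
    Roo = R[np.ix_(observed, observed)] + lam * np.eye(observed.size)
    Rto = R[np.ix_(targets, observed)]
    try:
        cf = linalg.cho_factor(Roo, lower=True)
    except np.linalg.LinAlgError as e:
        raise NumericalError(
            "observed LD block is singular; use lam > 0") from e
    z_imp = Rto @ linalg.cho_solve(cf, z_obs)
    r2 = np.einsum("ij,ji->i", Rto, linalg.cho_solve(cf, Rto.T))
    r2 = np.clip(r2, 0.0, 1.0)
    return z_imp, r2


def filter_imputed(imps, r2_min: float = 0.6):
    """Keep imputed records with quality >= r2_min (boundary inclusive).

    Accepts a list of :class:`ImputedSnp` or a DataFrame with an
    ``r2_quality`` column; observed records (``imputed == 0``) are always
    retained when a DataFrame carries that flag.
    """
    if isinstance(imps, pd.DataFrame):
        keep = imps["r2_quality"] >= r2_min
        if "imputed" in imps:
            keep |= imps["imputed"] == 0
        return imps[keep].reset_index(drop=True)
    return [s for s in imps if s.r2_quality >= r2_min]


def impute_trait(g: TraitGWAS, panel: LDPanel, lam: float | None = None,
                 r2_min: float = 0.6) -> TraitGWAS:
    """Impute every panel SNP missing from ``g``, region by region.

    The returned TraitGWAS gains ``imputed`` (0/1) and ``r2_quality`` columns;
    imputed rows with quality below ``r2_min`` are dropped.  beta/se for
    imputed SNPs are derived from the imputed z at the panel allele frequency
    and the trait's median sample size.
    """
    if lam is None:
        lam = default_ridge(panel.n_ref)
    have = set(g.df["snp_id"])
    n_med = float(np.nanmedian(g.df["n"]))
    z_lookup = dict(zip(g.df["snp_id"], g.df["z"]))

    new_rows = []
    for r in range(panel.n_regions):
        sl = panel.region_slice(r)
        sub = panel.snps.iloc[sl]
        ids = sub["snp_id"].to_numpy()
        obs_mask = np.array([s in have for s in ids])
        targets = np.flatnonzero(~obs_mask)
        observed = np.flatnonzero(obs_mask)
        if targets.size == 0 or observed.size == 0:
            continue
        z_obs = np.array([z_lookup[ids[i]] for i in observed])
        z_imp, r2 = impute_region(z_obs, panel.ld[r], observed, targets, lam)
        keep = r2 >= r2_min
        for t, zi, q in zip(targets[keep], z_imp[keep], r2[keep]):
            row = sub.iloc[t]
            beta, se = zscore_to_beta_se(zi, row["eaf"], n_med)
            p = float(np.clip(2 * stats.norm.sf(abs(zi)),
                              np.finfo(float).tiny, 1.0))
            new_rows.append((row["snp_id"], int(row["chrom"]), int(row["pos"]),
                             "A", "G", row["eaf"], beta, se, zi, p, n_med, q))

    out = g.df.copy()
    out["imputed"] = 0
    out["r2_quality"] = 1.0
    if new_rows:
        add = pd.DataFrame(new_rows, columns=[
            "snp_id", "chrom", "pos", "a1", "a2", "eaf", "beta", "se", "z",
            "p", "n", "r2_quality"])
        add["imputed"] = 1
        out = pd.concat([out, add], ignore_index=True)
    out = out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    res = TraitGWAS(g.trait_name, out, g.binary, g.n_cases, g.n_controls,
                    dict(g.meta, n_imputed=int(out["imputed"].sum())))
    return res
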