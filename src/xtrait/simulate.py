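"""Synthetic LD panels and two-trait GWAS summary statistics with known truth.

The generator works at the level of marginal z-scores: within each of a set of
LD-independent regions the panel stores a SNP-by-SNP correlation matrix R
(AR(1) within blocks, zero across blocks), and marginal statistics for trait t
are drawn as

    z_t = sqrt(n_t) * R @ gamma_t + eps_t,      eps_t ~ N(0, R)

with joint causal effects gamma drawn bivariate-normal over a sparse causal
set (per-trait variance h2/M_causal, correlation rg), and the environmental
noise of the two traits correlated across traits with
cov(eps_1, eps_2) = (rho_pheno * n_s / sqrt(n1*n2)) * R, the term that sample
overlap contributes to the cross-trait LD-score-regression intercept.

The default toy scale is 100 regions x 200 SNPs (M = 20,000), mirroring the
genome's ~1700-region LD-independent partition at roughly 1/17 scale.  LD is
simulated at the correlation-matrix level, not via individual genotypes; all
downstream methods here consume only (z, R).  An optional Gaussian reference
"genotype" panel (standardized dosages) can be attached for estimated-LD
experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DomainError
from .sumstats import TraitGWAS, from_frame, zscore_to_beta_se

#: spacing that keeps blocks >1 Mb apart (hence clump-independent) while SNPs
#: within a block stay inside a 1 Mb window
BLOCK_SPACING_BP = 5_000_000
SNP_SPACING_BP = 2_000


@dataclass
class LDPanel:
    """Region-partitioned LD reference.

    regions : DataFrame(region_id, chrom, start, end)
    snps    : DataFrame(snp_id, chrom, pos, eaf, region) — `region` indexes
              into `regions`/`ld`, order matches genome order
    ld      : one correlation matrix per region (symmetric PSD, unit diagonal)
    genotypes : optional standardized reference dosage matrices per region
                (n_ref x m), used for sampling-noise-adjusted LD scores
    """

    regions: pd.DataFrame
    snps: pd.DataFrame
    ld: list
    genotypes: list | None = None
    n_ref: int | None = None
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._index:
            self._index = {s: i for i, s in enumerate(self.snps["snp_id"])}

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def region_slice(self, r: int) -> slice:
        if not hasattr(self, "_region_starts"):
            starts: dict[int, int] = {}
            for i, reg in enumerate(self.snps["region"].to_numpy()):
                starts.setdefault(int(reg), i)
            self._region_starts = starts
        start = self._region_starts[int(r)]
        return slice(start, start + len(self.ld[r]))

    def snp_index(self, snp_id):
        return self._index.get(snp_id)

    def r2(self, id1, id2) -> float:
        """LD r² between two panel SNPs; 0 across regions, NaN if unknown."""
        i, j = self.snp_index(id1), self.snp_index(id2)
        if i is None or j is None:
            return float("nan")
        ri = int(self.snps["region"].iat[i])
        rj = int(self.snps["region"].iat[j])
        if ri != rj:
            return 0.0
        s = self.region_slice(ri).start
        return float(self.ld[ri][i - s, j - s] ** 2)


@dataclass
class SimTruth:
    """Generating parameters of a simulated trait pair."""

    h2_1: float
    h2_2: float
    rg_true: float
    prop_causal: float
    n1: int
    n2: int
    n_s: int = 0
    rho_pheno: float = 0.0
    causal_idx: np.ndarray | None = None
    gamma1: np.ndarray | None = None
    gamma2: np.ndarray | None = None
    region_scenarios: list | None = None

    def __post_init__(self):
        if abs(self.rg_true) > 1:
            raise DomainError("rg_true must lie in [-1, 1]")
        if self.n_s > min(self.n1, self.n2):
            raise DomainError("overlap n_s cannot exceed min(n1, n2)")


def make_panel(n_blocks: int = 100, block_size: int = 200,
               ar1_rho=(0.2, 0.95), n_ref: int | None = None,
               eaf_range=(0.05, 0.5), seed: int = 0,
               genotypes: bool = False) -> LDPanel:
    """Build a block-diagonal AR(1) LD panel.

    Within block b, ``R[i, j] = rho_b ** |i-j|``; correlation across blocks
    is zero.  ``ar1_rho`` is either one decay for every block or a
    ``(lo, hi)`` pair giving an even gradient of decays across blocks —
    the default, because real LD strength varies regionally and a panel
    whose LD scores are nearly constant cannot identify an LD-score
    regression slope.  Blocks are laid out round-robin over chromosomes
    1-22 with >1 Mb gaps so that clumping windows never span blocks.
    Effect-allele frequencies are drawn uniformly in ``eaf_range``.
    Deterministic per seed.
    """
    if block_size < 1 or n_blocks < 1:
        raise ConfigurationError("block_size and n_blocks must be >= 1")
    lo, hi = eaf_range
    if not (0 < lo <= hi < 1):
        raise ConfigurationError("eaf_range must satisfy 0 < lo <= hi < 1")
    if np.isscalar(ar1_rho):
        rhos = np.full(n_blocks, float(ar1_rho))
    else:
        r_lo, r_hi = ar1_rho
        rhos = np.linspace(r_lo, r_hi, n_blocks)
    if np.any(rhos < 0) or np.any(rhos >= 1):
        raise ConfigurationError("ar1_rho must be in [0, 1)")

    rng = np.random.default_rng(seed)
    d = np.abs(np.subtract.outer(np.arange(block_size), np.arange(block_size)))

    rows, regions, lds = [], [], []
    per_chrom = {}
    for b in range(n_blocks):
        R = rhos[b] ** d if rhos[b] > 0 else np.eye(block_size)
        lds.append(R)
        chrom = (b % 22) + 1
        k = per_chrom.get(chrom, 0)
        per_chrom[chrom] = k + 1
        start = 1 + k * BLOCK_SPACING_BP
        pos = start + SNP_SPACING_BP * np.arange(block_size)
        eaf = rng.uniform(lo, hi, size=block_size)
        for j in range(block_size):
            rows.append((f"rs{b}_{j}", chrom, int(pos[j]), eaf[j], b))
        regions.append((f"region{b}", chrom, start,
                        int(pos[-1]) + SNP_SPACING_BP - 1))

    snps = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "eaf", "region"])
    region_df = pd.DataFrame(regions, columns=["region_id", "chrom", "start", "end"])

    geno = None
    if genotypes:
        if n_ref is None:
            n_ref = 500
        geno = []
        for b in range(n_blocks):
            L = np.linalg.cholesky(lds[b] + 1e-10 * np.eye(block_size))
            geno.append(rng.standard_normal((n_ref, block_size)) @ L.T)

    return LDPanel(region_df, snps, lds, genotypes=geno, n_ref=n_ref)


def _draw_effects(rng, M, h2_1, h2_2, rg, prop_causal):
    """Sparse bivariate-normal per-SNP effects matching (h2, rg) in expectation."""
    mc = max(1, int(round(prop_causal * M)))
    causal = np.sort(rng.choice(M, size=mc, replace=False))
    g1 = np.zeros(M)
    g2 = np.zeros(M)
    s1 = np.sqrt(h2_1 / mc)
    s2 = np.sqrt(h2_2 / mc)
    e1 = rng.standard_normal(mc)
    if abs(rg) == 1.0:
        e2 = np.sign(rg) * e1
    else:
        e2 = rg * e1 + np.sqrt(1 - rg ** 2) * rng.standard_normal(mc)
    g1[causal] = s1 * e1
    g2[causal] = s2 * e2
    return causal, g1, g2


def simulate_pair(panel: LDPanel, h2_1: float, h2_2: float, rg_true: float,
                  prop_causal: float = 0.2, n1: int = 50_000, n2: int = 50_000,
                  n_s: int = 0, rho_pheno: float = 0.0,
                  seed: int = 0) -> tuple[TraitGWAS, TraitGWAS, SimTruth]:
    """Simulate marginal summary statistics for two traits over the panel.

    Returns two TraitGWAS (beta/se derived from z via the standard z-to-beta
    conversion at the panel allele frequencies) plus the SimTruth holding the
    generating parameters and per-SNP true effects.
    """
    truth = SimTruth(h2_1, h2_2, rg_true, prop_causal, n1, n2, n_s, rho_pheno)
    rng = np.random.default_rng(seed)
    M = panel.n_snps
    causal, g1, g2 = _draw_effects(rng, M, h2_1, h2_2, rg_true, prop_causal)
    truth.causal_idx, truth.gamma1, truth.gamma2 = causal, g1, g2

    c = rho_pheno * n_s / np.sqrt(n1 * n2) if n_s else 0.0
    noise_chol = np.linalg.cholesky(np.array([[1.0, c], [c, 1.0]]))

    z1 = np.empty(M)
    z2 = np.empty(M)
    chol_cache = {}
    for r in range(panel.n_regions):
        sl = panel.region_slice(r)
        R = panel.ld[r]
        key = id(R)
        if key not in chol_cache:
            chol_cache[key] = np.linalg.cholesky(R + 1e-10 * np.eye(len(R)))
        L = chol_cache[key]
        U = rng.standard_normal((len(R), 2)) @ noise_chol.T
        eps = L @ U
        z1[sl] = np.sqrt(n1) * (R @ g1[sl]) + eps[:, 0]
        z2[sl] = np.sqrt(n2) * (R @ g2[sl]) + eps[:, 1]

    eaf = panel.snps["eaf"].to_numpy()
    out = []
    for name, z, n in (("trait1", z1, n1), ("trait2", z2, n2)):
        beta, se = zscore_to_beta_se(z, eaf, float(n))
        from scipy import stats as _st
        p = np.clip(2.0 * _st.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
        df = pd.DataFrame({
            "snp_id": panel.snps["snp_id"],
            "chrom": panel.snps["chrom"],
            "pos": panel.snps["pos"],
            "a1": "A", "a2": "G",
            "eaf": eaf, "beta": beta, "se": se, "z": z, "p": p,
            "n": float(n),
        })
        out.append(from_frame(name, df))
    return out[0], out[1], truth


SCENARIOS = ("null", "trait1_only", "trait2_only", "shared", "distinct")


def simulate_region_scenario(panel: LDPanel, region: int, scenario: str,
                             effect_size: float = 8.0, seed: int = 0):
    """Simulate one region's z-scores under a regional causal scenario.

    Scenarios mirror the four pairwise-GWAS models: a variant for trait 1
    only, trait 2 only, one shared variant, or two distinct variants (plus a
    null).  ``effect_size`` is the expected z-score at the causal SNP.
    Returns ``(z1, z2, info)`` where info records the planted indices.
    """
    if scenario not in SCENARIOS:
        raise ConfigurationError(f"unknown scenario {scenario!r}")
    R = panel.ld[region]
    m = len(R)
    if scenario == "distinct" and m < 2:
        raise ConfigurationError("'distinct' needs a region with >= 2 SNPs")
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(R + 1e-10 * np.eye(m))

    mean1 = np.zeros(m)
    mean2 = np.zeros(m)
    info = {"scenario": scenario, "causal1": None, "causal2": None}
    if scenario == "trait1_only":
        j = m // 2
        mean1 = effect_size * R[:, j]
        info["causal1"] = j
    elif scenario == "trait2_only":
        j = m // 2
        mean2 = effect_size * R[:, j]
        info["causal2"] = j
    elif scenario == "shared":
        j = m // 2
        mean1 = effect_size * R[:, j]
        mean2 = effect_size * R[:, j]
        info["causal1"] = info["causal2"] = j
    elif scenario == "distinct":
        j1, j2 = m // 4, (3 * m) // 4
        if j1 == j2:
            j1, j2 = 0, m - 1
        mean1 = effect_size * R[:, j1]
        mean2 = effect_size * R[:, j2]
        info["causal1"], info["causal2"] = j1, j2

    z1 = mean1 + L @ rng.standard_normal(m)
    z2 = mean2 + L @ rng.standard_normal(m)
    return z1, z2, info


def make_gene_map(panel: LDPanel, genes_per_block: int = 2,
                  gene_length: int = 50_000) -> pd.DataFrame:
    """Tile non-overlapping gene intervals across the panel's regions.

    Returns a DataFrame(gene_id, chrom, start, end); total genes equal
    ``n_blocks * genes_per_block``.  Deterministic.
    """
    out = []
    for r, row in panel.regions.iterrows():
        span = row["end"] - row["start"] + 1
        slot = span // genes_per_block
        if gene_length >= slot:
            raise ConfigurationError(
                f"gene_length {gene_length} does not fit {genes_per_block} "
                f"genes in a {span}-bp region")
        for k in range(genes_per_block):
            start = int(row["start"] + k * slot)
            out.append((f"gene{r}_{k}", row["chrom"], start,
                        start + gene_length - 1))
    return pd.DataFrame(out, columns=["gene_id", "chrom", "start", "end"])


def simulate_mr_instruments(k: int, beta_xy: float,
                            pleiotropy_frac: float = 0.0,
                            pleiotropy_mean: float = 0.0,
                            pleiotropy_sd: float = 0.01,
                            se_x: float = 0.003, se_y: float = 0.01,
                            bx_range=(0.05, 0.15),
                            seed: int = 0) -> pd.DataFrame:
    """Simulate per-instrument effect estimates for a two-sample MR study.

    True instrument-exposure effects bx are uniform on ``bx_range``; outcome
    effects are ``by = beta_xy * bx + alpha`` with a nonzero pleiotropic
    ``alpha ~ N(pleiotropy_mean, pleiotropy_sd)`` on ``ceil(pleiotropy_frac*k)``
    instruments (directional when the mean is nonzero, balanced at mean 0).
    Observed estimates add independent N(0, se) noise on both sides.

    Returns DataFrame(snp_id, bx, sex, by, sey, pleiotropic).
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if not (0 <= pleiotropy_frac <= 1):
        raise DomainError("pleiotropy_frac must be in [0, 1]")
    rng = np.random.default_rng(seed)
    bx_true = rng.uniform(*bx_range, size=k)
    alpha = np.zeros(k)
    n_pleio = int(np.ceil(pleiotropy_frac * k))
    if n_pleio:
        idx = rng.choice(k, size=n_pleio, replace=False)
        alpha[idx] = rng.normal(pleiotropy_mean, pleiotropy_sd, size=n_pleio)
    by_true = beta_xy * bx_true + alpha
    bx = bx_true + rng.normal(0.0, se_x, size=k)
    by = by_true + rng.normal(0.0, se_y, size=k)
    return pd.DataFrame({
        "snp_id": [f"iv{i}" for i in range(k)],
        "bx": bx, "sex": se_x, "by": by, "sey": se_y,
        "pleiotropic": alpha != 0.0,
    })


def simulate_lcv_pair(M: int = 20_000, mode: str = "causal",
                      h2_1: float = 0.3, h2_2: float = 0.3,
                      rho_latent: float = 0.5, prop_causal: float = 0.02,
                      n1: int = 100_000, n2: int = 100_000,
                      seed: int = 0) -> tuple[TraitGWAS, TraitGWAS]:
    """Simulate LD-free z-scores under a latent-variable architecture.

    ``mode='causal'``: trait 1 is itself the latent trait — every trait-1
    effect acts proportionally on trait 2, which additionally has its own
    independent sparse effects; the genetic causality proportion is 1 and the
    latent-mediated genetic correlation is ``rho_latent``.

    ``mode='shared'``: a shared latent factor loads equally on both traits
    (horizontal pleiotropy); the causality proportion is 0.

    Sparse (spike-and-slab) causal effects give the latent factor the excess
    kurtosis the mixed-fourth-moment estimator requires.  SNPs are
    LD-independent, so a unit LD-score vector is the matching reference.
    """
    if mode not in ("causal", "shared"):
        raise ConfigurationError("mode must be 'causal' or 'shared'")
    rng = np.random.default_rng(seed)

    def spike_slab(var_total, prop):
        mc = max(1, int(round(prop * M)))
        idx = rng.choice(M, size=mc, replace=False)
        g = np.zeros(M)
        g[idx] = rng.standard_normal(mc) * np.sqrt(var_total / mc)
        return g

    if mode == "causal":
        g1 = spike_slab(h2_1, prop_causal)
        # mediated share rho^2 of trait-2 heritability, rest independent
        b = rho_latent * np.sqrt(h2_2 / h2_1)
        g2 = b * g1 + spike_slab((1 - rho_latent ** 2) * h2_2, prop_causal)
    else:
        lat = spike_slab(1.0, prop_causal)
        q1 = np.sqrt(abs(rho_latent) * h2_1)
        q2 = np.sign(rho_latent) * np.sqrt(abs(rho_latent) * h2_2)
        g1 = q1 * lat + spike_slab((1 - abs(rho_latent)) * h2_1, prop_causal)
        g2 = q2 * lat + spike_slab((1 - abs(rho_latent)) * h2_2, prop_causal)

    eaf = rng.uniform(0.05, 0.5, size=M)
    out = []
    for name, g, n in (("trait1", g1, n1), ("trait2", g2, n2)):
        z = np.sqrt(n) * g + rng.standard_normal(M)
        beta, se = zscore_to_beta_se(z, eaf, float(n))
        from scipy import stats as _st
        p = np.clip(2.0 * _st.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
        chrom = 1 + (np.arange(M) * 22) // M
        pos = 1 + (np.arange(M) % int(np.ceil(M / 22))) * 10_000
        df = pd.DataFrame({
            "snp_id": [f"s{i}" for i in range(M)],
            "chrom": chrom, "pos": pos,
            "a1": "A", "a2": "G", "eaf": eaf,
            "beta": beta, "se": se, "z": z, "p": p, "n": float(n),
        })
        out.append(from_frame(name, df))
    return out[0], out[1]
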