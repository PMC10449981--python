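"""Reading, validation, munging and harmonization of GWAS summary statistics.

The canonical in-memory container is :class:`TraitGWAS`, a thin dataclass
around a pandas DataFrame with one row per SNP and the canonical columns
``snp_id, chrom, pos, a1, a2, eaf, beta, se, z, p, n``.  ``a1`` is the effect
allele; ``beta`` is the per-allele effect (log-odds ratio for binary traits);
``z = beta/se``.  Rows are kept sorted by ``(chrom, pos)`` and ``snp_id`` is
unique.

Conventions
-----------
* positions are 1-based inclusive (hg19-style tables);
* the MHC window defaults to chr6:25,000,000-35,000,000;
* palindromic (A/T, C/G) SNPs are only dropped when a caller asks for it —
  strand-ambiguity cannot be resolved from frequency alone, so we never guess.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, DomainError, InputError

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = [
    "snp_id", "chrom", "pos", "a1", "a2", "eaf", "beta", "se", "z", "p", "n",
]

#: recognized header synonyms, all compared lower-case
HEADER_SYNONYMS = {
    "snp_id": ["snp_id", "snp", "rsid", "snpid", "markername", "id"],
    "chrom": ["chrom", "chr", "chromosome"],
    "pos": ["pos", "bp", "position", "base_pair_location"],
    "a1": ["a1", "ea", "effect_allele", "allele1"],
    "a2": ["a2", "oa", "nea", "other_allele", "non_effect_allele", "allele2"],
    "eaf": ["eaf", "frq", "freq", "af", "effect_allele_frequency"],
    "beta": ["beta", "b", "effect"],
    "se": ["se", "stderr", "standard_error"],
    "z": ["z", "zscore", "z_score"],
    "p": ["p", "pval", "p_value", "pvalue"],
    "n": ["n", "nobs", "samplesize", "sample_size"],
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
MHC_REGION = (6, 25_000_000, 35_000_000)


@dataclass
class TraitGWAS:
    """Harmonized per-SNP summary statistics for one trait.

    Attributes
    ----------
    trait_name : str
    df : pandas.DataFrame with the canonical columns, sorted by (chrom, pos)
    binary : whether effects are log-odds ratios
    n_cases, n_controls : optional case/control counts for binary traits
    meta : free-form provenance log (drop counts, recomputed-p counts, ...)
    """

    trait_name: str
    df: pd.DataFrame
    binary: bool = False
    n_cases: int | None = None
    n_controls: int | None = None
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)

    def copy(self) -> "TraitGWAS":
        return TraitGWAS(self.trait_name, self.df.copy(), self.binary,
                         self.n_cases, self.n_controls, dict(self.meta))

    @property
    def snp_ids(self) -> pd.Series:
        return self.df["snp_id"]

    def to_tsv(self, path) -> None:
        """Write the canonical tab-separated representation."""
        self.df.to_csv(path, sep="\t", index=False)


def zscore_to_beta_se(z, eaf, n):
    """Convert a z-score to (beta, se) given allele frequency and sample size.

    Uses ``se = 1/sqrt(2*eaf*(1-eaf)*(n + z^2))`` and ``beta = z*se``, the
    standard conversion for standardized genotypes and phenotypes, so that
    ``beta/se == z`` exactly.

    Parameters are scalars or arrays (broadcast together).
    """
    z = np.asarray(z, dtype=float)
    eaf = np.asarray(eaf, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(eaf <= 0) or np.any(eaf >= 1):
        raise DomainError("eaf must lie strictly in (0, 1)")
    if np.any(n <= 0):
        raise DomainError("n must be positive")
    se = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * (n + z ** 2))
    beta = z * se
    return beta, se


def _resolve_columns(header, dialect):
    """Map canonical names to actual column names; None if absent."""
    lower = {h.lower(): h for h in header}
    resolved = {}
    for canon, synonyms in HEADER_SYNONYMS.items():
        if dialect and canon in dialect:
            actual = dialect[canon]
            if actual not in header:
                raise ConfigurationError(
                    f"dialect maps {canon!r} to {actual!r}, not in header")
            resolved[canon] = actual
            continue
        for syn in synonyms:
            if syn in lower:
                resolved[canon] = lower[syn]
                break
    return resolved


def read_sumstats(path, dialect=None, trait_name=None, binary=False) -> TraitGWAS:
    """Read a delimited summary-statistics file into a validated TraitGWAS.

    ``dialect`` optionally maps canonical column names to the file's header
    names; otherwise common synonyms are recognized (SNP/rsid, CHR, BP/POS,
    A1/EA, A2/OA/NEA, EAF/FRQ, BETA/B, SE, P/PVAL, N, Z).

    Requires snp, chrom, pos, a1, a2, p, and either (beta, se) or
    (z, eaf, n) — in the latter case beta/se are derived via
    :func:`zscore_to_beta_se`.  Rows failing validation are dropped and
    counted in ``result.meta['n_dropped']``.
    """
    raw = pd.read_csv(path, sep=r"\s+", dtype=str)
    cols = _resolve_columns(list(raw.columns), dialect)

    required = ["snp_id", "chrom", "pos", "a1", "a2", "p"]
    missing = [c for c in required if c not in cols]
    if missing:
        raise ConfigurationError(f"missing required column(s): {missing}")
    has_beta_se = "beta" in cols and "se" in cols
    has_z = "z" in cols and "eaf" in cols and "n" in cols
    if not has_beta_se and not has_z:
        raise ConfigurationError(
            "need either (beta, se) or (z, eaf, n) columns")

    df = pd.DataFrame()
    for canon, actual in cols.items():
        df[canon] = raw[actual]

    n0 = len(df)
    numeric = ["chrom", "pos", "eaf", "beta", "se", "z", "p", "n"]
    for c in numeric:
        if c in df:
            df[c] = pd.to_numeric(df[c], errors="coerce")
    for c in ("a1", "a2"):
        df[c] = df[c].str.upper()

    ok = (
        df["chrom"].between(1, 22)
        & (df["pos"] > 0)
        & df["a1"].isin(list("ACGT"))
        & df["a2"].isin(list("ACGT"))
        & (df["a1"] != df["a2"])
        & (df["p"] > 0) & (df["p"] <= 1)
    )
    if "eaf" in df:
        ok &= df["eaf"].isna() | ((df["eaf"] > 0) & (df["eaf"] < 1))
    if "se" in df:
        ok &= df["se"].isna() | (df["se"] > 0)
    if "n" in df:
        ok &= df["n"].isna() | (df["n"] > 0)
    df = df[ok.fillna(False)].copy()
    df = df.drop_duplicates(subset="snp_id", keep="first")
    n_dropped = n0 - len(df)
    if len(df) == 0:
        raise InputError(f"no parseable rows in {path}")

    # derive the missing member of the (beta, se) <-> z pair
    if has_beta_se:
        df["beta"] = df["beta"].astype(float)
        df["se"] = df["se"].astype(float)
        df = df[df["se"] > 0]
        if "z" not in df or df["z"].isna().all():
            df["z"] = df["beta"] / df["se"]
    else:
        beta, se = zscore_to_beta_se(df["z"].to_numpy(),
                                     df["eaf"].to_numpy(),
                                     df["n"].to_numpy())
        df["beta"], df["se"] = beta, se

    # p-values inconsistent with z by more than 10x are recomputed from z;
    # this protects the order statistics downstream Simes-type tests rely on
    implied = 2.0 * stats.norm.sf(np.abs(df["z"].to_numpy()))
    implied = np.clip(implied, np.finfo(float).tiny, 1.0)
    with np.errstate(divide="ignore"):
        bad = np.abs(np.log10(df["p"].to_numpy()) - np.log10(implied)) > 1.0
    n_recomputed = int(bad.sum())
    if n_recomputed:
        df.loc[bad, "p"] = implied[bad]
        logger.info("recomputed %d inconsistent p-values from z", n_recomputed)

    for c in CANONICAL_COLUMNS:
        if c not in df:
            df[c] = np.nan
    df = df[CANONICAL_COLUMNS].astype({"chrom": int, "pos": int})
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    if n_dropped:
        logger.info("dropped %d invalid rows reading %s", n_dropped, path)
    name = trait_name or str(path)
    return TraitGWAS(name, df, binary=binary,
                     meta={"n_dropped": n_dropped,
                           "n_p_recomputed": n_recomputed})


def from_frame(trait_name, df, binary=False, **kw) -> TraitGWAS:
    """Build a TraitGWAS from an already-canonical DataFrame (sorts + checks)."""
    df = df.copy()
    for c in CANONICAL_COLUMNS:
        if c not in df:
            df[c] = np.nan
    df = df[CANONICAL_COLUMNS].sort_values(
        ["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    if df["snp_id"].duplicated().any():
        raise InputError("duplicate snp_id")
    return TraitGWAS(trait_name, df, binary=binary, **kw)


def munge(g: TraitGWAS, keep_snps=None, maf_min: float = 0.0,
          exclude_mhc: bool = False, mhc=MHC_REGION) -> TraitGWAS:
    """Filter a TraitGWAS to well-behaved SNPs.

    Keeps SNPs with minor-allele frequency strictly above ``maf_min``,
    restricted to ``keep_snps`` when given, and outside the MHC window when
    ``exclude_mhc`` — the standard preprocessing for moment-based estimators
    (LDSC, LCV), which the MHC's extreme LD would otherwise distort.
    """
    if not (0 <= maf_min < 0.5):
        raise DomainError("maf_min must be in [0, 0.5)")
    df = g.df
    mask = pd.Series(True, index=df.index)
    if maf_min > 0:
        maf = np.minimum(df["eaf"], 1.0 - df["eaf"])
        mask &= maf > maf_min
    if keep_snps is not None:
        mask &= df["snp_id"].isin(set(keep_snps))
    if exclude_mhc:
        c, lo, hi = mhc
        mask &= ~((df["chrom"] == c) & (df["pos"] >= lo) & (df["pos"] <= hi))
    out = df[mask].reset_index(drop=True)
    if len(out) == 0:
        raise InputError("munge removed every SNP")
    meta = dict(g.meta)
    meta["munge_dropped"] = int(len(df) - len(out))
    return TraitGWAS(g.trait_name, out, g.binary, g.n_cases, g.n_controls, meta)


def _is_palindromic(a1, a2):
    return a2 == _COMPLEMENT[a1]


def harmonize_pair(g1: TraitGWAS, g2: TraitGWAS,
                   drop_ambiguous: bool = False) -> tuple[TraitGWAS, TraitGWAS]:
    """Align two traits on the shared SNP set with consistent effect alleles.

    Where g2 codes the opposite allele (directly or on the opposite strand),
    its beta/z signs are flipped and eaf reflected.  Irreconcilable allele
    pairs are dropped (counted in ``meta['harmonize_dropped']``); palindromic
    A/T and C/G SNPs are dropped when ``drop_ambiguous``.  Idempotent.
    """
    m = g1.df.merge(g2.df, on="snp_id", suffixes=("_1", "_2"))
    if len(m) == 0:
        raise InputError("no shared SNPs between traits")

    a1_1, a2_1 = m["a1_1"], m["a2_1"]
    a1_2, a2_2 = m["a1_2"], m["a2_2"]
    comp = lambda s: s.map(_COMPLEMENT)  # noqa: E731

    same = (a1_2 == a1_1) & (a2_2 == a2_1)
    swapped = (a1_2 == a2_1) & (a2_2 == a1_1)
    strand = (comp(a1_2) == a1_1) & (comp(a2_2) == a2_1)
    strand_swapped = (comp(a1_2) == a2_1) & (comp(a2_2) == a1_1)
    # palindromic SNPs match every pattern; treat them as 'same' orientation
    palindromic = a2_1 == a1_1.map(_COMPLEMENT)
    swapped &= ~same
    strand &= ~(same | swapped)
    strand_swapped &= ~(same | swapped | strand)

    reconcilable = same | swapped | strand | strand_swapped
    n_bad = int((~reconcilable).sum())
    keep = reconcilable.copy()
    if drop_ambiguous:
        keep &= ~palindromic
    m = m[keep].copy()
    flip = (swapped | strand_swapped)[keep]

    for col, sign_col in (("beta_2", True), ("z_2", True)):
        m.loc[flip, col] = -m.loc[flip, col]
    m.loc[flip, "eaf_2"] = 1.0 - m.loc[flip, "eaf_2"]
    # after alignment g2 carries g1's allele labels
    m["a1_2"] = m["a1_1"]
    m["a2_2"] = m["a2_1"]

    def _side(suffix, template):
        cols = {f"{c}_{suffix}": c for c in CANONICAL_COLUMNS if c != "snp_id"}
        df = m[["snp_id", *cols.keys()]].rename(columns=cols)
        df = df[CANONICAL_COLUMNS]
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        meta = dict(template.meta)
        meta["harmonize_dropped"] = n_bad
        return TraitGWAS(template.trait_name, df, template.binary,
                         template.n_cases, template.n_controls, meta)

    if n_bad:
        logger.info("harmonize_pair dropped %d irreconcilable SNPs", n_bad)
    return _side("1", g1), _side("2", g2)
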