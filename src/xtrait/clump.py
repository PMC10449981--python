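"""LD clumping of meta-analysis results and known-vs-novel classification.

Two greedy best-p-first passes, the convention of PLINK/FUMA clumping:

1. *independent significant SNPs* — among SNPs with p < 5e-8, keep a SNP
   unless it is in LD (r2 >= 0.6) with an already-kept SNP within 1 Mb;
2. *lead SNPs* — a second pass over the independent SNPs at r2 >= 0.1;
   independent SNPs absorbed in this pass become members of their lead.

Lead SNPs in LD (r2 > 0.1) with any known single-trait hit within the window
are classified ``known``; the rest are ``putative_novel``.  Output is
deterministic and independent of input row order (ties on p broken by
position, then id).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import LDPanel

logger = logging.getLogger(__name__)

GWS = 5e-8


@dataclass
class LeadSnp:
    snp_id: str
    chrom: int
    pos: int
    p_meta: float
    members: list = field(default_factory=list)
    status: str = "unclassified"
    nearest_gene: str | None = None


def _sorted_candidates(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["p_meta", "pos", "snp_id"],
                          kind="mergesort").reset_index(drop=True)


def _greedy_clump(df: pd.DataFrame, ld: LDPanel, r2_max: float,
                  window_bp: int):
    """Greedy best-p-first pass; returns (kept rows, member map)."""
    kept = []
    members: dict[str, list] = {}
    for _, row in df.iterrows():
        absorbed_by = None
        for krow in kept:
            if krow["chrom"] != row["chrom"]:
                continue
            if abs(krow["pos"] - row["pos"]) > window_bp:
                continue
            r2 = ld.r2(krow["snp_id"], row["snp_id"])
            if np.isnan(r2):
                continue
            if r2 >= r2_max:
                absorbed_by = krow["snp_id"]
                break
        if absorbed_by is None:
            kept.append(row)
            members[row["snp_id"]] = []
        else:
            members[absorbed_by].append(row["snp_id"])
    return kept, members


def independent_significant(snps: pd.DataFrame, ld: LDPanel,
                            p_max: float = GWS, r2_max: float = 0.6,
                            window_bp: int = 1_000_000) -> pd.DataFrame:
    """First-pass clumping into independent significant SNPs.

    ``snps`` needs columns snp_id, chrom, pos, p_meta.  Keeps SNPs with
    p_meta < p_max that are not in LD (r2 >= r2_max) with a better-p kept
    SNP within ``window_bp``.
    """
    sig = snps[snps["p_meta"] < p_max]
    if len(sig) == 0:
        return sig.reset_index(drop=True)
    sig = _sorted_candidates(sig)
    kept, _ = _greedy_clump(sig, ld, r2_max, window_bp)
    return pd.DataFrame(kept).reset_index(drop=True)


def lead_snps(ind_snps: pd.DataFrame, ld: LDPanel, r2_lead: float = 0.1,
              window_bp: int = 1_000_000) -> list[LeadSnp]:
    """Second-pass clumping of independent SNPs into lead SNPs.

    Independent SNPs absorbed at ``r2 >= r2_lead`` are recorded as members
    of the lead that absorbed them; every input SNP ends up either a lead or
    a member of exactly one lead.
    """
    if len(ind_snps) == 0:
        return []
    df = _sorted_candidates(ind_snps)
    kept, members = _greedy_clump(df, ld, r2_lead, window_bp)
    return [LeadSnp(r["snp_id"], int(r["chrom"]), int(r["pos"]),
                    float(r["p_meta"]), members[r["snp_id"]])
            for r in kept]


def _nearest_gene(chrom: int, pos: int, gene_map: pd.DataFrame) -> str | None:
    genes = gene_map[gene_map["chrom"] == chrom]
    if len(genes) == 0:
        return None
    start = genes["start"].to_numpy()
    end = genes["end"].to_numpy()
    dist = np.where(pos < start, start - pos,
                    np.where(pos > end, pos - end, 0))
    best = dist.min()
    names = genes["gene_id"].to_numpy()[dist == best]
    return ";".join(sorted(names))


def classify_novel(leads: list[LeadSnp], known_snps: dict, ld: LDPanel,
                   r2_known: float = 0.1, gene_map: pd.DataFrame | None = None,
                   window_bp: int = 1_000_000) -> list[LeadSnp]:
    """Classify lead SNPs as known or putative novel.

    ``known_snps`` maps a source label to a DataFrame(snp_id, chrom, pos) of
    that trait's genome-wide-significant hits.  A lead in LD (r2 > r2_known,
    strict) with any known hit within the window is ``known``; a lead absent
    from the LD panel is ``unassessed``.  ``nearest_gene`` is annotated from
    ``gene_map`` by minimal distance; equidistant genes are all reported.
    """
    for lead in leads:
        if ld.snp_index(lead.snp_id) is None:
            lead.status = "unassessed"
            logger.warning("lead %s absent from LD panel", lead.snp_id)
        else:
            lead.status = "putative_novel"
            for _, kdf in known_snps.items():
                sub = kdf[(kdf["chrom"] == lead.chrom)
                          & (np.abs(kdf["pos"] - lead.pos) <= window_bp)]
                if any(ld.r2(lead.snp_id, ks) > r2_known
                       for ks in sub["snp_id"]):
                    lead.status = "known"
                    break
        if gene_map is not None:
            lead.nearest_gene = _nearest_gene(lead.chrom, lead.pos, gene_map)
    return leads


def leads_to_frame(leads: list[LeadSnp]) -> pd.DataFrame:
    """Tabular view of lead SNPs (members joined with commas)."""
    return pd.DataFrame([{
        "snp_id": s.snp_id, "chrom": s.chrom, "pos": s.pos,
        "p_meta": s.p_meta, "n_members": len(s.members),
        "members": ",".join(s.members), "status": s.status,
        "nearest_gene": s.nearest_gene,
    } for s in leads])
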