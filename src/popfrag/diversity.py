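"""Sequence diversity: nucleotide diversity, haplotypes, Tajima's D.

Gap-containing columns are excluded from pi and from S (pairwise counts
use only comparable, non-missing positions), while indel sites still
contribute to haplotypes as binary presence/absence characters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from popfrag.alignment import HaplotypeAlignment, site_genotypes


def _comparable_columns(aln: HaplotypeAlignment,
                        region_mask: np.ndarray | None) -> np.ndarray:
    """Columns eligible for pi: inside the mask and free of gaps."""
    gap_free = ~(aln.seqs == "-").any(axis=0)
    if region_mask is None:
        return gap_free
    region_mask = np.asarray(region_mask, dtype=bool)
    if region_mask.shape != (aln.n_cols,):
        raise ValueError("region_mask length must equal alignment width")
    if not region_mask.any():
        raise ValueError("region_mask selects no columns")
    return gap_free & region_mask


def nucleotide_diversity(aln: HaplotypeAlignment,
                         region_mask: np.ndarray | None = None) -> float:
    """Per-site nucleotide diversity (pi).

    Mean over all unordered row pairs of (nucleotide differences) /
    (columns where both rows carry a base), restricted to gap-free
    columns within the optional region mask.
    """
    if aln.n_rows < 2:
        raise ValueError("need at least 2 rows")
    cols = _comparable_columns(aln, region_mask)
    seqs = aln.seqs[:, cols]
    ratio_sum, weight = _pairwise_stat(seqs, per_site=True)
    if weight == 0:
        return float("nan")
    return ratio_sum / weight


def mean_pairwise_differences(aln: HaplotypeAlignment) -> float:
    """Mean TOTAL pairwise differences over SNP-comparable columns.

    Enters Tajima's D; gap-containing columns are excluded entirely.
    """
    cols = _comparable_columns(aln, None)
    seqs = aln.seqs[:, cols]
    diff_sum, npairs = _pairwise_stat(seqs, per_site=False)
    return diff_sum / npairs if npairs else float("nan")


def _pairwise_stat(seqs: np.ndarray, per_site: bool) -> tuple[float, float]:
    """Sum over unordered row pairs of diffs (or diffs/length) and the
    pair count, collapsing duplicate rows for speed."""
    uniq, counts = np.unique(seqs, axis=0, return_counts=True)
    known = uniq != "N"
    u = uniq.shape[0]
    total = 0.0
    weight = 0.0
    for i in range(u):
        w_self = counts[i] * (counts[i] - 1) / 2.0
        if w_self > 0:
            length = int(known[i].sum())
            if length > 0 or not per_site:
                total += 0.0
                weight += w_self
        for j in range(i + 1, u):
            w = float(counts[i] * counts[j])
            both = known[i] & known[j]
            length = int(both.sum())
            if per_site:
                if length == 0:
                    continue
                diffs = int((uniq[i, both] != uniq[j, both]).sum())
                total += w * diffs / length
                weight += w
            else:
                diffs = int((uniq[i, both] != uniq[j, both]).sum())
                total += w * diffs
                weight += w
    return total, weight


# ---------------------------------------------------------------------------
# haplotypes
# ---------------------------------------------------------------------------

def haplotype_table(aln: HaplotypeAlignment, sites: pd.DataFrame) -> pd.DataFrame:
    """Haplotypes over all polymorphic sites (SNPs + indel presence/absence).

    Rows missing at any polymorphic site are excluded.  Returns a
    DataFrame (haplotype, count, frequency) sorted by descending count;
    a monomorphic gene yields a single empty-string haplotype.
    """
    if len(sites) == 0:
        return pd.DataFrame(
            {"haplotype": [""], "count": [aln.n_rows], "frequency": [1.0]})
    geno = site_genotypes(aln, sites)
    complete = geno.dropna()
    haps = complete.apply(lambda row: "|".join(map(str, row)), axis=1)
    counts = haps.value_counts()
    return pd.DataFrame({
        "haplotype": counts.index,
        "count": counts.to_numpy(),
        "frequency": counts.to_numpy() / counts.sum(),
    }).reset_index(drop=True)


def haplotype_diversity(frequencies, n: int) -> tuple[float, float]:
    """Sample-corrected haplotype diversity and its standard deviation.

    Hd = n/(n-1) * (1 - sum p_i^2); the SD follows Nei's (1987)
    variance of heterozygosity.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    p = np.asarray(frequencies, dtype=float)
    if not math.isclose(p.sum(), 1.0, abs_tol=1e-8):
        raise ValueError("frequencies must sum to 1")
    sum2 = float(np.sum(p**2))
    sum3 = float(np.sum(p**3))
    hd = n / (n - 1) * (1.0 - sum2)
    var = (2.0 / (n * (n - 1))) * (
        2.0 * (n - 2) * (sum3 - sum2**2) + sum2 - sum2**2
    )
    return hd, math.sqrt(max(var, 0.0))


def pool_rare_haplotypes(table: pd.DataFrame, min_freq: float = 0.05) -> pd.DataFrame:
    """Report-level pooling: haplotypes below min_freq collapse into 'rare'."""
    common = table[table["frequency"] >= min_freq]
    rare = table[table["frequency"] < min_freq]
    if len(rare) == 0:
        return table.reset_index(drop=True)
    pooled = pd.DataFrame({
        "haplotype": ["rare"],
        "count": [int(rare["count"].sum())],
        "frequency": [float(rare["frequency"].sum())],
    })
    return pd.concat([common, pooled], ignore_index=True)


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TajimaResult:
    D: float
    p: float
    S: int
    n: int
    pi_total: float
    defined: bool
    note: str = ""


def tajima_constants(n: int) -> dict[str, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajima_p_value(D: float, n: int) -> float:
    """Two-sided p from the bounded-beta approximation to D's null law."""
    k = tajima_constants(n)
    sq_e2 = math.sqrt(k["e2"])
    d_min = (2.0 / n - 1.0 / k["a1"]) / sq_e2
    if n % 2 == 0:
        pi_max = n / (2.0 * (n - 1))
    else:
        pi_max = (n + 1) / (2.0 * n)
    d_max = (pi_max - 1.0 / k["a1"]) / sq_e2
    if not d_min < d_max:
        return float("nan")
    # beta on [d_min, d_max] with mean 0 and variance 1
    alpha = -(1.0 + d_min * d_max) * d_max / (d_max - d_min)
    beta = (1.0 + d_min * d_max) * d_min / (d_max - d_min)
    if alpha <= 0 or beta <= 0:
        return float("nan")
    x = (D - d_min) / (d_max - d_min)
    x = min(max(x, 0.0), 1.0)
    cdf = stats.beta.cdf(x, beta, alpha)
    return float(2.0 * min(cdf, 1.0 - cdf))


def tajimas_d(aln: HaplotypeAlignment, sites: pd.DataFrame) -> TajimaResult:
    """Tajima's (1989) D with its beta-approximation p-value.

    S counts SNP sites only; pi enters as total mean pairwise
    differences.  Genes with S = 0 return a flagged, undefined result.
    """
    n = aln.n_rows
    S = int((sites["kind"] == "SNP").sum()) if len(sites) else 0
    if S == 0:
        return TajimaResult(float("nan"), float("nan"), 0, n, 0.0,
                            defined=False, note="no segregating sites")
    if n < 4:
        return TajimaResult(float("nan"), float("nan"), S, n, float("nan"),
                            defined=False, note="n < 4")
    k = tajima_constants(n)
    pi_total = mean_pairwise_differences(aln)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    D = (pi_total - S / k["a1"]) / math.sqrt(var)
    return TajimaResult(D, tajima_p_value(D, n), S, n, pi_total, defined=True)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def snp_density(total_bp: float, total_snps: float) -> int:
    """Average SNP spacing: one SNP per round(total_bp / total_snps) bp."""
    if total_snps <= 0:
        raise ValueError("need at least one SNP")
    return round(total_bp / total_snps)


def summarize_gene(aln: HaplotypeAlignment, sites: pd.DataFrame) -> dict:
    """Per-gene diversity record (one row of the gene summary table)."""
    n_snps = int((sites["kind"] == "SNP").sum()) if len(sites) else 0
    n_indels = int((sites["kind"] == "indel").sum()) if len(sites) else 0
    haps = haplotype_table(aln, sites)
    n_used = int(haps["count"].sum())
    hd, hd_sd = (haplotype_diversity(haps["frequency"], n_used)
                 if n_used >= 2 else (0.0, 0.0))
    pi = nucleotide_diversity(aln)
    pi_exon = float("nan")
    if aln.annotation is not None:
        exon_mask = aln.annotation.region_mask("exon", aln.n_cols)
        if exon_mask.any():
            pi_exon = nucleotide_diversity(aln, exon_mask)
    taj = tajimas_d(aln, sites)
    return {
        "gene_id": aln.gene_id,
        "length_bp": aln.n_cols,
        "n_lines": aln.n_rows,
        "n_snps": n_snps,
        "n_indels": n_indels,
        "n_haplotypes": int(len(haps)),
        "Hd": hd,
        "Hd_sd": hd_sd,
        "pi": pi,
        "pi_exon": pi_exon,
        "tajima_D": taj.D,
        "tajima_p": taj.p,
        "tajima_defined": taj.defined,
        "S": taj.S,
    }
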