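"""Pairwise linkage disequilibrium on phase-known haploid genotypes.

r-squared comes straight from haplotype counts (no EM — phase is known).
Biallelic pairs use D^2 / (pA pa pB pb); multiallelic pairs use the
frequency-weighted composite sum_ij D_ij^2 / [(1 - sum p_i^2)(1 - sum q_j^2)],
which reduces to the biallelic form when both loci have two alleles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

logger = logging.getLogger(__name__)


@dataclass
class LDMatrix:
    labels: list[str]
    genes: list[str]
    positions: np.ndarray    # bp, NaN when unknown (e.g. SSR loci)
    r2: np.ndarray           # symmetric, diagonal 1
    p_fisher: np.ndarray     # symmetric, NaN for multiallelic pairs
    distance_bp: np.ndarray  # defined (non-NaN) only for same-gene pairs

    def pair_table(self) -> pd.DataFrame:
        """Long-format upper-triangle pair table."""
        rows = []
        k = len(self.labels)
        for i in range(k - 1):
            for j in range(i + 1, k):
                rows.append({
                    "site_i": self.labels[i],
                    "site_j": self.labels[j],
                    "gene_i": self.genes[i],
                    "gene_j": self.genes[j],
                    "distance_bp": self.distance_bp[i, j],
                    "r2": self.r2[i, j],
                    "p_fisher": self.p_fisher[i, j],
                })
        return pd.DataFrame(rows)


def r2_pair(x, y) -> float:
    """Composite r^2 between two loci from paired haploid calls.

    ``x`` and ``y`` are equal-length allele-code sequences; entries where
    either is missing (NaN/None) are dropped (pairwise-complete).
    Returns NaN when either locus is monomorphic in the complete subset.
    """
    x = pd.Series(list(x), dtype=object)
    y = pd.Series(list(y), dtype=object)
    keep = x.notna() & y.notna()
    x, y = x[keep], y[keep]
    n = len(x)
    if n == 0:
        return float("nan")
    xa, xlabels = pd.factorize(x)
    ya, ylabels = pd.factorize(y)
    ka, kb = len(xlabels), len(ylabels)
    if ka < 2 or kb < 2:
        return float("nan")
    joint = np.zeros((ka, kb))
    np.add.at(joint, (xa, ya), 1.0)
    joint /= n
    p = joint.sum(axis=1)
    q = joint.sum(axis=0)
    D = joint - np.outer(p, q)
    denom = (1.0 - np.sum(p**2)) * (1.0 - np.sum(q**2))
    if denom <= 0:
        return float("nan")
    return float(np.sum(D**2) / denom)


def fisher_ld_test(x, y) -> float:
    """Two-sided Fisher's exact p for a biallelic pair (NaN if multiallelic)."""
    x = pd.Series(list(x), dtype=object)
    y = pd.Series(list(y), dtype=object)
    keep = x.notna() & y.notna()
    x, y = x[keep], y[keep]
    xa, xlabels = pd.factorize(x)
    ya, ylabels = pd.factorize(y)
    if len(xlabels) != 2 or len(ylabels) != 2:
        return float("nan")
    table = np.zeros((2, 2), dtype=int)
    np.add.at(table, (xa, ya), 1)
    return float(fisher_exact(table, alternative="two-sided")[1])


def _composite_r2_from_joint(joint: np.ndarray) -> float:
    n = joint.sum()
    if n == 0:
        return float("nan")
    joint = joint / n
    p = joint.sum(axis=1)
    q = joint.sum(axis=0)
    denom = (1.0 - np.sum(p**2)) * (1.0 - np.sum(q**2))
    if denom <= 0:
        return float("nan")
    D = joint - np.outer(p, q)
    return float(np.sum(D**2) / denom)


def pairwise_r2(geno: pd.DataFrame, genes: dict[str, str] | None = None,
                positions: dict[str, float] | None = None) -> LDMatrix:
    """All-pairs LD over a lines x sites genotype frame.

    Every column must be polymorphic among its non-missing calls (sites
    are expected to be MAF-filtered upstream).
    """
    labels = list(geno.columns)
    codes = {}
    n_alleles = {}
    for c in labels:
        code, uniques = pd.factorize(geno[c])  # missing -> -1
        if len(uniques) < 2:
            raise ValueError(f"monomorphic site reached pairwise_r2: {c}")
        codes[c] = code
        n_alleles[c] = len(uniques)
    k = len(labels)
    r2 = np.eye(k)
    pf = np.full((k, k), np.nan)
    dist = np.full((k, k), np.nan)
    gene_of = [genes.get(c, "") if genes else "" for c in labels]
    pos_of = np.array([positions.get(c, np.nan) if positions else np.nan
                       for c in labels])
    for i in range(k - 1):
        ci, ka = codes[labels[i]], n_alleles[labels[i]]
        for j in range(i + 1, k):
            cj, kb = codes[labels[j]], n_alleles[labels[j]]
            valid = (ci >= 0) & (cj >= 0)
            joint = np.bincount(ci[valid] * kb + cj[valid],
                                minlength=ka * kb).reshape(ka, kb)
            r2[i, j] = r2[j, i] = _composite_r2_from_joint(joint.astype(float))
            if ka == 2 and kb == 2:
                # only alleles seen in the complete subset count
                if (joint.sum(axis=1) > 0).sum() == 2 and \
                        (joint.sum(axis=0) > 0).sum() == 2:
                    pf[i, j] = pf[j, i] = float(
                        fisher_exact(joint, alternative="two-sided")[1])
            if gene_of[i] == gene_of[j] and gene_of[i] != "":
                d = abs(pos_of[i] - pos_of[j])
                dist[i, j] = dist[j, i] = d
    np.fill_diagonal(pf, np.nan)
    return LDMatrix(labels, gene_of, pos_of, r2, pf, dist)


def gene_mean_r2(ldm: LDMatrix, gene: str) -> float:
    """Unweighted mean r^2 over within-gene site pairs (NaN if <2 sites)."""
    idx = [i for i, g in enumerate(ldm.genes) if g == gene]
    if len(idx) < 2:
        return float("nan")
    vals = [ldm.r2[i, j] for a, i in enumerate(idx) for j in idx[a + 1:]]
    return float(np.nanmean(vals))


def intergenic_r2(geno_a: pd.DataFrame, geno_b: pd.DataFrame) -> float:
    """Mean r^2 between all cross-gene site pairs on shared lines."""
    shared = geno_a.index.intersection(geno_b.index)
    if len(shared) == 0:
        warnings.warn("no shared lines between genes; inter-genic r2 is NaN")
        return float("nan")
    if len(shared) < 10:
        warnings.warn(f"only {len(shared)} shared lines; inter-genic r2 unstable")
    a = geno_a.loc[shared]
    b = geno_b.loc[shared]
    vals = [r2_pair(a[ca], b[cb]) for ca in a.columns for cb in b.columns]
    if not vals or np.all(np.isnan(vals)):
        return float("nan")
    return float(np.nanmean(vals))
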