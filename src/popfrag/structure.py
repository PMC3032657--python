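"""Population structure: DICE similarity, classical PCoA, haploid AMOVA."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PCoAResult:
    coordinates: np.ndarray   # lines x axes (positive eigenvalues only)
    pct_variance: np.ndarray  # per axis, sums to 100
    eigenvalues: np.ndarray   # all eigenvalues, descending


@dataclass
class AMOVAResult:
    sigma2_among: float
    sigma2_within: float
    pct_among: float
    pct_within: float
    phi_st: float
    p_perm: float
    n_perm: int
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "source": ["among_populations", "within_populations", "total"],
            "df": [self.df_among, self.df_within, self.df_among + self.df_within],
            "SS": [self.ss_among, self.ss_within, self.ss_among + self.ss_within],
            "variance": [self.sigma2_among, self.sigma2_within,
                         self.sigma2_among + self.sigma2_within],
            "pct": [self.pct_among, self.pct_within, 100.0],
        })


# ---------------------------------------------------------------------------
# DICE similarity
# ---------------------------------------------------------------------------

def dice_matrix(profiles) -> np.ndarray:
    """Pairwise DICE similarity s = 2a / (2a + b + c) on binary profiles.

    Rows are lines, columns are presence/absence features (one per SSR
    allele or gene haplotype).  All-zero rows yield NaN similarities
    with a warning.
    """
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2:
        raise ValueError("profiles must be 2-D")
    if not np.isin(X, (0.0, 1.0)).all():
        raise ValueError("profiles must be binary 0/1")
    totals = X.sum(axis=1)
    a = X @ X.T
    denom = totals[:, None] + totals[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(denom > 0, 2.0 * a / denom, np.nan)
    if (totals == 0).any():
        warnings.warn("all-zero profiles produce NaN similarities")
        s[totals == 0, :] = np.nan
        s[:, totals == 0] = np.nan
    np.fill_diagonal(s, np.where(totals > 0, 1.0, np.nan))
    return s


def haplotype_profiles(assignments: pd.DataFrame) -> pd.DataFrame:
    """One-hot encode per-gene haplotype assignments into binary features.

    ``assignments``: lines x genes frame of haplotype labels (NaN = line
    missing for that gene).
    """
    blocks = []
    for gene in assignments.columns:
        onehot = pd.get_dummies(assignments[gene], prefix=str(gene))
        blocks.append(onehot.astype(int))
    return pd.concat(blocks, axis=1).fillna(0).astype(int)


def ssr_profiles(calls: pd.DataFrame) -> pd.DataFrame:
    """One-hot encode SSR allele calls (one feature per locus:allele)."""
    blocks = []
    for locus in calls.columns:
        onehot = pd.get_dummies(calls[locus], prefix=str(locus))
        blocks.append(onehot.astype(int))
    return pd.concat(blocks, axis=1).fillna(0).astype(int)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

def pcoa(distance) -> PCoAResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Gower double-centering of -1/2 D^2 followed by eigendecomposition;
    coordinates are eigenvectors scaled by sqrt(eigenvalue) and percent
    variance uses positive eigenvalues only.
    """
    D = np.asarray(distance, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise ValueError("distance must have a zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-10
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    pct = 100.0 * eigvals[pos] / eigvals[pos].sum()
    return PCoAResult(coordinates=coords, pct_variance=pct, eigenvalues=eigvals)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

def mismatch_distances(calls: pd.DataFrame) -> np.ndarray:
    """Squared molecular distances: allele mismatch counts across loci.

    Haploid calls; per pair only loci non-missing in both count.
    """
    arr = calls.to_numpy(dtype=object)
    n = arr.shape[0]
    d2 = np.zeros((n, n))
    known = pd.notna(calls).to_numpy()
    for i in range(n - 1):
        for j in range(i + 1, n):
            both = known[i] & known[j]
            d = sum(1 for k in np.flatnonzero(both) if arr[i, k] != arr[j, k])
            d2[i, j] = d2[j, i] = d
    return d2


def _ss_within(d2: np.ndarray, labels: np.ndarray, pops: np.ndarray) -> float:
    ss = 0.0
    for p in pops:
        idx = np.flatnonzero(labels == p)
        ss += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ss


def amova(d2, populations, n_perm: int = 15_000,
          seed: int | None = None) -> AMOVAResult:
    """Two-level haploid AMOVA from squared pairwise distances.

    Variance components follow the standard unequal-sample-size
    expectation (coefficient n0); significance from permuting whole
    individuals among populations, with the +1 correction so p > 0.
    """
    d2 = np.asarray(d2, dtype=float)
    labels = np.asarray(populations)
    n = labels.size
    if d2.shape != (n, n):
        raise ValueError("distance matrix / label length mismatch")
    pops, counts = np.unique(labels, return_counts=True)
    if pops.size < 2:
        raise ValueError("need at least 2 populations")
    if (counts < 2).any():
        bad = pops[counts < 2]
        raise ValueError(f"populations of size 1: {list(bad)}")

    ss_total = d2.sum() / (2.0 * n)
    ss_within = _ss_within(d2, labels, pops)
    ss_among = ss_total - ss_within
    df_among = pops.size - 1
    df_within = n - pops.size
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    n0 = (n - np.sum(counts**2) / n) / df_among
    sigma_within = ms_within
    sigma_among = (ms_among - ms_within) / n0
    total_var = sigma_among + sigma_within
    phi = sigma_among / total_var if total_var > 0 else float("nan")

    rng = np.random.default_rng(seed)
    exceed = 0
    perm_labels = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(perm_labels)
        ssw = _ss_within(d2, perm_labels, pops)
        ssa = ss_total - ssw
        msa = ssa / df_among
        msw = ssw / df_within
        s_a = (msa - msw) / n0
        tot = s_a + msw
        phi_p = s_a / tot if tot > 0 else float("-inf")
        if phi_p >= phi:
            exceed += 1
    p = (1.0 + exceed) / (n_perm + 1.0)

    return AMOVAResult(
        sigma2_among=float(sigma_among),
        sigma2_within=float(sigma_within),
        pct_among=float(100.0 * sigma_among / total_var),
        pct_within=float(100.0 * sigma_within / total_var),
        phi_st=float(phi),
        p_perm=float(p),
        n_perm=n_perm,
        df_among=df_among,
        df_within=df_within,
        ss_among=float(ss_among),
        ss_within=float(ss_within),
    )
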