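"""SSR marker diversity: PIC, rarefied allelic richness, private alleles.

Calls are haploid (one allele per line per locus); missing calls are
excluded locus-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln


@dataclass
class SSRMatrix:
    """Lines x loci single-allele calls with population labels.

    ``calls`` is a DataFrame indexed by line_id with one column per
    locus; values are allele labels (integer sizes), NaN = missing.
    """

    calls: pd.DataFrame
    populations: pd.Series  # indexed like calls

    def __post_init__(self) -> None:
        self.populations = self.populations.reindex(self.calls.index)
        if self.populations.isna().any():
            missing = list(self.calls.index[self.populations.isna()])
            raise ValueError(f"lines without population label: {missing}")
        empty = [c for c in self.calls.columns if self.calls[c].notna().sum() == 0]
        if empty:
            raise ValueError(f"loci with no calls: {empty}")

    @property
    def loci(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def pop_names(self) -> list[str]:
        return sorted(self.populations.unique())

    def subset(self, population: str) -> "SSRMatrix":
        mask = self.populations == population
        return SSRMatrix(self.calls.loc[mask], self.populations.loc[mask])

    def allele_counts(self, locus: str, population: str | None = None) -> pd.Series:
        col = self.calls[locus]
        if population is not None:
            col = col[self.populations == population]
        return col.dropna().value_counts()

    def to_csv(self, path) -> None:
        out = self.calls.copy()
        out.insert(0, "population", self.populations)
        out.index.name = "line_id"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "SSRMatrix":
        df = pd.read_csv(path, index_col="line_id")
        pops = df.pop("population")
        return cls(df, pops)


# ---------------------------------------------------------------------------
# per-locus statistics
# ---------------------------------------------------------------------------

def pic(allele_counts) -> float:
    """Polymorphic information content (Botstein et al. 1980).

    PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2.
    """
    counts = np.asarray(allele_counts, dtype=float)
    counts = counts[counts > 0]
    if counts.size == 0:
        raise ValueError("need at least one allele")
    p = counts / counts.sum()
    sum2 = np.sum(p**2)
    sum4 = np.sum(p**4)
    return float(1.0 - sum2 - (sum2**2 - sum4))


def pic_bootstrap(matrix: SSRMatrix, locus: str, B: int = 10_000,
                  level: float = 0.95, seed: int | None = None,
                  population: str | None = None) -> tuple[float, float, float]:
    """Percentile bootstrap CI and SD of PIC by resampling lines."""
    col = matrix.calls[locus]
    if population is not None:
        col = col[matrix.populations == population]
    calls = col.dropna().to_numpy()
    if calls.size < 2:
        raise ValueError("need at least 2 non-missing calls")
    rng = np.random.default_rng(seed)
    n = calls.size
    stats = np.empty(B)
    for b in range(B):
        sample = calls[rng.integers(0, n, n)]
        _, counts = np.unique(sample, return_counts=True)
        stats[b] = pic(counts)
    lo, hi = np.percentile(stats, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    return float(lo), float(hi), float(stats.std(ddof=1))


def allelic_richness(allele_counts, n: int) -> float:
    """Expected allele count in a rarefied subsample of n genotypes.

    Rs = sum_i [1 - C(N - N_i, n) / C(N, n)] with N = sum N_i; binomials
    are evaluated on the log-gamma scale, and C(N - N_i, n) = 0 when
    N - N_i < n.
    """
    counts = np.asarray(allele_counts, dtype=float)
    counts = counts[counts > 0]
    N = counts.sum()
    if not 1 <= n <= N:
        raise ValueError(f"rarefaction size n={n} outside [1, {int(N)}]")

    def log_comb(a: float, b: float) -> float:
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    rs = 0.0
    for ni in counts:
        if N - ni < n:
            rs += 1.0
        else:
            rs += 1.0 - np.exp(log_comb(N - ni, n) - log_comb(N, n))
    return float(rs)


def private_alleles(matrix: SSRMatrix) -> pd.DataFrame:
    """Per-population private-allele counts and percentages.

    An allele is private when observed in exactly one population; the
    percentage denominator is the population's total distinct alleles
    observed, summed over loci.
    """
    pops = matrix.pop_names
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    n_private = {p: 0 for p in pops}
    n_observed = {p: 0 for p in pops}
    for locus in matrix.loci:
        observed_in: dict = {}
        for pop in pops:
            alleles = set(matrix.allele_counts(locus, pop).index)
            n_observed[pop] += len(alleles)
            for a in alleles:
                observed_in.setdefault(a, set()).add(pop)
        for allele, where in observed_in.items():
            if len(where) == 1:
                n_private[next(iter(where))] += 1
    return pd.DataFrame({
        "population": pops,
        "n_private": [n_private[p] for p in pops],
        "n_observed": [n_observed[p] for p in pops],
        "pct_private": [100.0 * n_private[p] / n_observed[p] if n_observed[p]
                        else float("nan") for p in pops],
    }).set_index("population")


def percent_private(n_private: float, mean_alleles_per_locus: float,
                    n_loci: int) -> float:
    """Private-allele percentage from a population's summary numbers."""
    return 100.0 * n_private / (mean_alleles_per_locus * n_loci)


def _bootstrap_mean_pic(calls: pd.DataFrame, B: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Bootstrap replicates of the mean PIC over loci, resampling lines.

    Vectorised: allele calls are integer-coded per locus with a shared
    offset so one bincount per replicate tallies every locus at once.
    """
    n_lines, n_loci = calls.shape
    codes = np.empty((n_lines, n_loci), dtype=np.int64)
    k_per_locus = np.empty(n_loci, dtype=np.int64)
    offset = 0
    offsets = []
    for c, locus in enumerate(calls.columns):
        code, uniques = pd.factorize(calls[locus])
        k = len(uniques)
        # missing (-1) goes to a throwaway bin after the real alleles
        codes[:, c] = np.where(code >= 0, code, k) + offset
        k_per_locus[c] = k
        offsets.append(offset)
        offset += k + 1
    boot = np.empty(B)
    seg_starts = np.array(offsets)
    for b in range(B):
        idx = rng.integers(0, n_lines, n_lines)
        counts = np.bincount(codes[idx].ravel(), minlength=offset)
        vals = []
        for c in range(n_loci):
            k = k_per_locus[c]
            cnt = counts[seg_starts[c]:seg_starts[c] + k]
            if cnt.sum() > 0:
                vals.append(pic(cnt))
        boot[b] = np.mean(vals)
    return boot


# ---------------------------------------------------------------------------
# population summary (Table-2 shape)
# ---------------------------------------------------------------------------

def summarize_populations(matrix: SSRMatrix, rarefaction_n: int | None = None,
                          B: int = 1000, seed: int | None = None) -> pd.DataFrame:
    """Per-population SSR diversity table.

    The rarefaction size defaults to the smallest per-population sample
    size over loci (the usual multi-sample convention).
    """
    pops = matrix.pop_names
    priv = private_alleles(matrix)
    if rarefaction_n is None:
        sizes = [
            int(matrix.allele_counts(locus, pop).sum())
            for pop in pops for locus in matrix.loci
        ]
        rarefaction_n = max(1, min(s for s in sizes if s > 0))
    rng = np.random.default_rng(seed)
    rows = []
    for pop in pops:
        sub = matrix.subset(pop)
        n_alleles, pics, rs_vals = [], [], []
        for locus in matrix.loci:
            counts = sub.allele_counts(locus)
            if counts.sum() == 0:
                continue
            n_alleles.append(len(counts))
            pics.append(pic(counts.to_numpy()))
            n_eff = min(rarefaction_n, int(counts.sum()))
            rs_vals.append(allelic_richness(counts.to_numpy(), n_eff))
        boot = _bootstrap_mean_pic(sub.calls, B, rng)
        rows.append({
            "population": pop,
            "n_lines": int((matrix.populations == pop).sum()),
            "n_private": int(priv.loc[pop, "n_private"]),
            "pct_private": float(priv.loc[pop, "pct_private"]),
            "mean_alleles": float(np.mean(n_alleles)),
            "min_alleles": int(np.min(n_alleles)),
            "max_alleles": int(np.max(n_alleles)),
            "PIC": float(np.mean(pics)),
            "PIC_sd": float(boot.std(ddof=1)),
            "allelic_richness": float(np.mean(rs_vals)),
            "rarefaction_n": rarefaction_n,
        })
    return pd.DataFrame(rows).set_index("population")
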