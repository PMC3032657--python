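"""Counting-based dN/dS (Nei–Gojobori 1986 pathway counting, JC-corrected).

All unordered sequence pairs contribute; gene-level dN and dS are means
over pairs and omega is the ratio of those means.  Significance against
omega = 1 comes from a codon bootstrap of (dN - dS).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from popfrag._codon import STOP_CODONS, translate_codon
from popfrag.alignment import HaplotypeAlignment

_BASES = ("A", "C", "G", "T")


@dataclass
class SelectionSummary:
    gene_id: str
    n_codons: int
    n_polymorphic_codons: int
    N_sites: float
    S_sites: float
    dN: float
    dS: float
    omega: float  # nan when undefined (dS = 0 or no exonic polymorphism)
    p_neutral: float = float("nan")
    p_reliable: bool = True
    note: str = ""


def _syn_fraction(codon: str) -> float:
    """Fraction of the 9 single-base changes of a codon that are synonymous.

    Returned on the NG86 site scale (sum of per-position fractions,
    0..3).  Changes producing stop codons count as non-synonymous.
    """
    aa = translate_codon(codon)
    if aa == "*":
        raise ValueError(f"stop codon in coding sequence: {codon}")
    syn = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if translate_codon(alt) == aa:
                syn += 1.0 / 3.0
    return syn


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) substitutions between two codons.

    Multi-hit codons average over all mutational pathways with equal
    weight; pathways passing through stop codons are discarded (all
    pathways blocked falls back to including them).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    if len(diff_pos) == 1:
        i = diff_pos[0]
        syn = 1.0 if translate_codon(c1) == translate_codon(c2) else 0.0
        return syn, 1.0 - syn

    def walk(order):
        cur = c1
        steps = []
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1:]
            steps.append((cur, nxt))
            cur = nxt
        return steps

    pathways = []
    for order in itertools.permutations(diff_pos):
        steps = walk(order)
        if any(b in STOP_CODONS for _, b in steps[:-1]):
            continue
        sd = nd = 0.0
        for a, b in steps:
            if translate_codon(a) == translate_codon(b):
                sd += 1.0
            else:
                nd += 1.0
        pathways.append((sd, nd))
    if not pathways:
        for order in itertools.permutations(diff_pos):
            sd = nd = 0.0
            for a, b in walk(order):
                if translate_codon(a) == translate_codon(b):
                    sd += 1.0
                else:
                    nd += 1.0
            pathways.append((sd, nd))
    sd = sum(p[0] for p in pathways) / len(pathways)
    nd = sum(p[1] for p in pathways) / len(pathways)
    return sd, nd


def _jc_correct(p: float) -> float:
    """Jukes-Cantor multiple-hit correction of a substitution proportion.

    Saturated proportions (p >= 3/4, only reachable on very short toy
    inputs) fall back to the uncorrected value.
    """
    if p <= 0:
        return 0.0
    if p >= 0.75:
        return p
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def extract_codons(aln: HaplotypeAlignment) -> list[list[str | None]]:
    """Per-row codon lists over complete in-frame exonic codons.

    Codons containing gaps or N in a row are None for that row.
    """
    ann = aln.annotation
    if ann is None:
        raise ValueError("dN/dS requires an annotation with exon intervals")
    exon_cols = ann.exon_columns()
    offset = (3 - ann.frame_offset) % 3
    usable = exon_cols[offset:]
    n_codons = len(usable) // 3
    per_row: list[list[str | None]] = []
    for i in range(aln.n_rows):
        row = []
        for k in range(n_codons):
            cols = usable[3 * k:3 * k + 3]
            chars = aln.seqs[i, cols]
            if "-" in chars or "N" in chars:
                row.append(None)
            else:
                row.append("".join(chars))
        per_row.append(row)
    return per_row


@dataclass
class _PairTables:
    """Per-unique-pair, per-codon site and substitution tallies."""
    weights: np.ndarray       # (P,) pair multiplicities
    syn_sites: np.ndarray     # (P, K) mean synonymous sites per codon
    nonsyn_sites: np.ndarray  # (P, K)
    syn_subs: np.ndarray      # (P, K)
    nonsyn_subs: np.ndarray   # (P, K)


def _pair_tables(aln: HaplotypeAlignment) -> tuple[_PairTables, int]:
    codons = extract_codons(aln)
    n_codons = len(codons[0]) if codons else 0
    keys = [tuple(row) for row in codons]
    uniq: dict[tuple, int] = {}
    counts: list[int] = []
    for key in keys:
        if key in uniq:
            counts[uniq[key]] += 1
        else:
            uniq[key] = len(counts)
            counts.append(1)
    uniq_rows = list(uniq)
    U = len(uniq_rows)
    syn_site_cache: dict[str, float] = {}

    def ssites(codon: str) -> float:
        if codon not in syn_site_cache:
            syn_site_cache[codon] = _syn_fraction(codon)
        return syn_site_cache[codon]

    pairs = []
    for a in range(U):
        for b in range(a, U):
            w = (counts[a] * (counts[a] - 1) // 2) if a == b \
                else counts[a] * counts[b]
            if w > 0:
                pairs.append((a, b, w))
    P = len(pairs)
    tables = _PairTables(
        weights=np.array([w for _, _, w in pairs], dtype=float),
        syn_sites=np.zeros((P, n_codons)),
        nonsyn_sites=np.zeros((P, n_codons)),
        syn_subs=np.zeros((P, n_codons)),
        nonsyn_subs=np.zeros((P, n_codons)),
    )
    path_cache: dict[tuple[str, str], tuple[float, float]] = {}
    for p_idx, (a, b, _w) in enumerate(pairs):
        ra, rb = uniq_rows[a], uniq_rows[b]
        for k in range(n_codons):
            ca, cb = ra[k], rb[k]
            if ca is None or cb is None:
                continue
            s_a, s_b = ssites(ca), ssites(cb)
            s_mean = 0.5 * (s_a + s_b)
            tables.syn_sites[p_idx, k] = s_mean
            tables.nonsyn_sites[p_idx, k] = 3.0 - s_mean
            if ca != cb:
                key = (ca, cb) if ca <= cb else (cb, ca)
                if key not in path_cache:
                    path_cache[key] = _pathway_counts(*key)
                sd, nd = path_cache[key]
                tables.syn_subs[p_idx, k] = sd
                tables.nonsyn_subs[p_idx, k] = nd
    return tables, n_codons


def _dn_ds_from_sums(syn_sites, nonsyn_sites, syn_subs, nonsyn_subs, weights):
    """Weighted-mean pairwise dN and dS from per-pair codon sums."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ps = np.where(syn_sites > 0, syn_subs / syn_sites, 0.0)
        pn = np.where(nonsyn_sites > 0, nonsyn_subs / nonsyn_sites, 0.0)
    ds = np.array([_jc_correct(p) for p in np.atleast_1d(ps)])
    dn = np.array([_jc_correct(p) for p in np.atleast_1d(pn)])
    ok = ~(np.isnan(ds) | np.isnan(dn))
    if not ok.any():
        return float("nan"), float("nan")
    w = weights[ok] / weights[ok].sum()
    return float(np.sum(dn[ok] * w)), float(np.sum(ds[ok] * w))


def dnds(aln: HaplotypeAlignment) -> SelectionSummary:
    """Gene-level dN/dS over all unordered sequence pairs."""
    if aln.n_rows < 2:
        raise ValueError("need at least 2 sequences")
    tables, n_codons = _pair_tables(aln)
    if n_codons == 0 or tables.weights.size == 0:
        return SelectionSummary(aln.gene_id, 0, 0, 0.0, 0.0,
                                float("nan"), float("nan"), float("nan"),
                                note="no codons")
    sub_any = (tables.syn_subs + tables.nonsyn_subs) > 0
    n_poly = int(sub_any.any(axis=0).sum())
    S_sites = tables.syn_sites.sum(axis=1)
    N_sites = tables.nonsyn_sites.sum(axis=1)
    dn, ds = _dn_ds_from_sums(
        S_sites, N_sites,
        tables.syn_subs.sum(axis=1), tables.nonsyn_subs.sum(axis=1),
        tables.weights)
    if n_poly == 0:
        omega = float("nan")
        note = "no exonic polymorphism"
    elif ds == 0 or math.isnan(ds):
        omega = float("nan")
        note = "dS = 0"
    else:
        omega = dn / ds
        note = ""
    w = tables.weights / tables.weights.sum()
    return SelectionSummary(
        gene_id=aln.gene_id,
        n_codons=n_codons,
        n_polymorphic_codons=n_poly,
        N_sites=float(np.sum(N_sites * w)),
        S_sites=float(np.sum(S_sites * w)),
        dN=dn, dS=ds, omega=omega, note=note)


def test_neutrality(aln: HaplotypeAlignment, B: int = 1000,
                    seed: int | None = None) -> SelectionSummary:
    """Codon-bootstrap z-test of dN = dS.

    Codons are resampled with replacement B times; p is the two-sided
    normal tail of (dN - dS) / SD_boot.  Fewer than 10 polymorphic
    codons flags the p-value as unreliable.
    """
    summary = dnds(aln)
    if math.isnan(summary.omega) and summary.n_polymorphic_codons == 0:
        return summary
    tables, n_codons = _pair_tables(aln)
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_codons, np.full(n_codons, 1.0 / n_codons),
                             size=B).T.astype(float)  # (K, B)
    ss = tables.syn_sites @ counts      # (P, B)
    ns = tables.nonsyn_sites @ counts
    sd = tables.syn_subs @ counts
    nd = tables.nonsyn_subs @ counts
    with np.errstate(divide="ignore", invalid="ignore"):
        ps = np.where(ss > 0, sd / ss, 0.0)
        pn = np.where(ns > 0, nd / ns, 0.0)
        ds_b = np.where(ps < 0.75, -0.75 * np.log1p(-4.0 * np.minimum(ps, 0.749) / 3.0), ps)
        dn_b = np.where(pn < 0.75, -0.75 * np.log1p(-4.0 * np.minimum(pn, 0.749) / 3.0), pn)
    w = tables.weights[:, None]
    diff = np.nansum((dn_b - ds_b) * w, axis=0) / tables.weights.sum()
    sd_boot = float(np.nanstd(diff, ddof=1))
    if sd_boot == 0:
        p = 1.0 if summary.dN == summary.dS else 0.0
    else:
        from scipy.stats import norm
        z = (summary.dN - summary.dS) / sd_boot
        p = float(2.0 * norm.sf(abs(z)))
    summary.p_neutral = p
    summary.p_reliable = summary.n_polymorphic_codons >= 10
    return summary
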