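"""Forward-time generator of study-shaped inputs with known ground truth.

Each population evolves as a haploid Wright-Fisher population: every
child gamete is a (possibly recombinant) mosaic of two parents, with
infinite-sites-style point mutations.  Symmetric migration mixes
populations.  SSR loci drift independently per locus from a shared
ancestral allele-frequency vector, so they are unlinked by construction.
Indels enter as single atomic events (a derived SNP allele converted
into a gap run), mirroring their treatment as one polymorphic site.

For a population of S sequences the scaled recombination intensity
between sites d bp apart is Gamma = 2 * S * rec_per_bp * d (two times
the sequence count times the per-meiosis fraction).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from popfrag.alignment import (
    GeneAnnotation,
    HaplotypeAlignment,
    write_alignment,
    write_annotation,
)
from popfrag.decay import hill_weir_expectation
from popfrag.ssr import SSRMatrix
from popfrag._codon import STOP_CODONS

_BASES = np.array(["A", "C", "G", "T"])

#: study-shaped defaults: five populations, eleven gene fragments
DEFAULT_POP_SIZES = (33, 44, 15, 41, 68)
DEFAULT_GENE_LENGTHS = (619, 495, 1371, 623, 754, 560, 502, 435, 514, 1224, 542)
INDEL_LENGTHS = (1, 2, 3, 200)


@dataclass(frozen=True)
class SimConfig:
    n_pops: int = 5
    pop_sizes: tuple[int, ...] = DEFAULT_POP_SIZES
    n_genes: int = 11
    gene_lengths: tuple[int, ...] = DEFAULT_GENE_LENGTHS
    mu: float = 1e-5
    rec_per_bp: float = 7e-5
    n_generations: int = 800
    migration_rate: float = 0.04
    n_ssr_loci: int = 37
    ssr_allele_range: tuple[int, int] = (2, 18)
    ssr_mu: float = 2e-3     # K-allele mutation rate keeping loci polymorphic
    seed: int = 0
    sim_pop_size: int = 80    # simulated gametes per population
    max_indels_per_gene: int = 2

    def __post_init__(self) -> None:
        for name in ("mu", "rec_per_bp", "migration_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if len(self.pop_sizes) != self.n_pops:
            raise ValueError("pop_sizes length must equal n_pops")
        if len(self.gene_lengths) != self.n_genes:
            raise ValueError("gene_lengths length must equal n_genes")
        lo, hi = self.ssr_allele_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid ssr_allele_range")

    @property
    def gamma_per_bp(self) -> float:
        """Scaled recombination intensity per bp of the pooled sample.

        With migration the demes behave as one population of
        n_pops * sim_pop_size sequences; without it each deme stands
        alone.  Gamma between sites d bp apart is gamma_per_bp * d.
        """
        n_seq = self.sim_pop_size
        if self.migration_rate > 0 and self.n_pops > 1:
            n_seq *= self.n_pops
        return 2.0 * n_seq * self.rec_per_bp


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated study."""

    gene_haplotypes: dict[str, list[str]]       # emitted rows, per gene
    gene_annotations: dict[str, GeneAnnotation]
    gene_snp_positions: dict[str, list[int]]
    gene_indels: dict[str, list[dict]]          # anchor, length, carriers
    ssr_frequencies: dict[str, dict[str, list[float]]]
    ssr_alleles: dict[str, list[int]]
    gamma_per_bp: float


# ---------------------------------------------------------------------------
# gene-fragment machinery
# ---------------------------------------------------------------------------

def _make_annotation(length: int, rng: np.random.Generator) -> GeneAnnotation:
    """Random 5UTR/exon/intron/exon/3UTR layout covering the fragment."""
    if length < 60:
        return GeneAnnotation(((0, length, "exon"),), 0)
    b1 = int(length * rng.uniform(0.10, 0.20))        # end 5UTR
    b2 = b1 + int(length * rng.uniform(0.20, 0.35))   # end exon 1
    b3 = b2 + int(length * rng.uniform(0.10, 0.20))   # end intron
    b4 = b3 + int(length * rng.uniform(0.15, 0.30))   # end exon 2
    intervals = (
        (0, b1, "5UTR"),
        (b1, b2, "exon"),
        (b2, b3, "intron"),
        (b3, b4, "exon"),
        (b4, length, "3UTR"),
    )
    return GeneAnnotation(intervals, 0)


def _ancestral_sequence(length: int, annotation: GeneAnnotation,
                        rng: np.random.Generator) -> np.ndarray:
    """Random base codes (0..3) with stop-free in-frame exonic codons."""
    seq = rng.integers(0, 4, length, dtype=np.uint8)
    exon_cols = annotation.exon_columns()
    for k in range(len(exon_cols) // 3):
        cols = exon_cols[3 * k:3 * k + 3]
        while "".join(_BASES[seq[cols]]) in STOP_CODONS:
            seq[cols[2]] = rng.integers(0, 4)
    return seq


def _evolve_gene(length: int, annotation: GeneAnnotation, config: SimConfig,
                 rng: np.random.Generator) -> list[np.ndarray]:
    """Wright-Fisher forward simulation of one gene in all populations."""
    N = config.sim_pop_size
    P = config.n_pops
    ancestral = _ancestral_sequence(length, annotation, rng)
    pops = [np.tile(ancestral, (N, 1)) for _ in range(P)]
    m = config.migration_rate
    for _gen in range(config.n_generations):
        new_pops = []
        for p in range(P):
            src = np.full(N, p)
            if m > 0 and P > 1:
                migrants = rng.random(N) < m
                others = [q for q in range(P) if q != p]
                src[migrants] = rng.choice(others, migrants.sum())
            pa = rng.integers(0, N, N)
            pb = rng.integers(0, N, N)
            children = np.empty((N, length), dtype=ancestral.dtype)
            for q in np.unique(src):
                mask = src == q
                children[mask] = pops[q][pa[mask]]
            # recombination: mosaic of the two parents
            n_co = rng.binomial(length - 1, config.rec_per_bp, N)
            for c in np.flatnonzero(n_co):
                q = src[c]
                breaks = np.sort(rng.choice(
                    np.arange(1, length), n_co[c], replace=False))
                take_b = np.zeros(length, dtype=bool)
                state = bool(rng.integers(0, 2))
                prev = 0
                for b in list(breaks) + [length]:
                    if state:
                        take_b[prev:b] = True
                    state = not state
                    prev = b
                children[c, take_b] = pops[q][pb[c], take_b]
            # mutation: random new base at random positions
            n_mut = rng.poisson(config.mu * length * N)
            if n_mut:
                rows = rng.integers(0, N, n_mut)
                cols = rng.integers(0, length, n_mut)
                shift = rng.integers(1, 4, n_mut, dtype=np.uint8)
                children[rows, cols] = (children[rows, cols] + shift) % 4
            new_pops.append(children)
        pops = new_pops
    return pops


def _sample_rows(pops: list[np.ndarray], config: SimConfig,
                 rng: np.random.Generator) -> np.ndarray:
    rows = []
    for p, size in enumerate(config.pop_sizes):
        N = pops[p].shape[0]
        if size > N:
            raise ValueError(
                f"population pop{p + 1}: requested sample {size} exceeds "
                f"simulated population size {N}")
        idx = rng.choice(N, size=size, replace=False)
        rows.append(pops[p][np.sort(idx)])
    return np.vstack(rows)


def _repair_stops(sample: np.ndarray, ancestral_like: np.ndarray,
                  annotation: GeneAnnotation) -> None:
    """Revert any sampled codon translating to a stop to the majority codon."""
    exon_cols = annotation.exon_columns()
    for k in range(len(exon_cols) // 3):
        cols = exon_cols[3 * k:3 * k + 3]
        codons = ["".join(_BASES[sample[i, cols]]) for i in range(sample.shape[0])]
        stops = [i for i, c in enumerate(codons) if c in STOP_CODONS]
        if not stops:
            continue
        ok = [i for i in range(sample.shape[0]) if i not in stops]
        # a fixed stop (no clean row) falls back to a neutral AAA codon
        donor = sample[ok[0], cols] if ok else np.zeros(3, dtype=sample.dtype)
        for i in stops:
            sample[i, cols] = donor


def _plant_indels(chars: np.ndarray, base_sample: np.ndarray,
                  ancestral: np.ndarray, annotation: GeneAnnotation,
                  config: SimConfig, rng: np.random.Generator) -> list[dict]:
    """Convert up to max_indels_per_gene derived SNP alleles into gap runs."""
    length = chars.shape[1]
    n_indels = int(rng.integers(0, config.max_indels_per_gene + 1))
    if n_indels == 0:
        return []
    seg_cols = [
        j for j in range(length)
        if len(np.unique(base_sample[:, j])) > 1
    ]
    rng.shuffle(seg_cols)
    placed: list[dict] = []
    occupied: set[int] = set()
    for anchor in seg_cols:
        if len(placed) >= n_indels:
            break
        region = annotation.region_at(anchor)
        interval = next((iv for iv in annotation.intervals
                         if iv[0] <= anchor < iv[1]), None)
        if interval is None:
            continue
        if region == "exon":
            indel_len = 3
        else:
            choices = [l for l in INDEL_LENGTHS if l != 200] \
                if interval[1] - anchor < 200 else list(INDEL_LENGTHS)
            weights = np.ones(len(choices))
            if 200 in choices:
                weights[choices.index(200)] = 0.3
            indel_len = int(rng.choice(choices, p=weights / weights.sum()))
        end = anchor + indel_len
        if end > interval[1]:
            continue
        if any(c in occupied for c in range(anchor, end)):
            continue
        derived = base_sample[:, anchor] != ancestral[anchor]
        if derived.all() or not derived.any():
            continue
        carriers = np.flatnonzero(derived)
        # the founding mutation becomes the deletion: erase the SNP itself
        chars[:, anchor] = _BASES[ancestral[anchor]]
        for i in carriers:
            chars[i, anchor:end] = "-"
        # pad by one column so two gap runs can never touch and merge
        occupied.update(range(anchor - 1, end + 1))
        placed.append({"anchor": int(anchor), "length": indel_len,
                       "carriers": [int(i) for i in carriers]})
    return placed


def _truth_snp_positions(base_sample: np.ndarray, indels: list[dict]) -> list[int]:
    """Segregating columns of the emitted alignment, from the base matrix."""
    length = base_sample.shape[1]
    hidden: dict[int, set[int]] = {}
    erased: set[int] = set()
    for indel in indels:
        erased.add(indel["anchor"])
        for c in range(indel["anchor"], indel["anchor"] + indel["length"]):
            hidden.setdefault(c, set()).update(indel["carriers"])
    positions = []
    for j in range(length):
        if j in erased:
            continue
        visible = [i for i in range(base_sample.shape[0])
                   if i not in hidden.get(j, ())]
        if len(visible) >= 2 and len(np.unique(base_sample[visible, j])) > 1:
            positions.append(j)
    return positions


# ---------------------------------------------------------------------------
# SSR machinery
# ---------------------------------------------------------------------------

def _simulate_ssrs(config: SimConfig, rng: np.random.Generator,
                   line_pops: list[str], pop_names: list[str]):
    """Independent per-locus drift with migration; one haploid call per line."""
    N = config.sim_pop_size
    m = config.migration_rate
    lo, hi = config.ssr_allele_range
    calls: dict[str, list] = {}
    freqs: dict[str, dict[str, list[float]]] = {}
    alleles_out: dict[str, list[int]] = {}
    for locus_i in range(config.n_ssr_loci):
        locus = f"ssr{locus_i + 1:02d}"
        k = int(rng.integers(lo, hi + 1))
        base = rng.dirichlet(np.full(k, 2.0))
        x = np.tile(base, (config.n_pops, 1))
        for _gen in range(config.n_generations):
            xbar = x.mean(axis=0)
            new = np.empty_like(x)
            u = config.ssr_mu
            for p in range(config.n_pops):
                target = (1.0 - m) * x[p] + m * xbar
                target = (1.0 - u) * target + u / k
                target = np.clip(target, 0, None)
                target /= target.sum()
                new[p] = rng.multinomial(N, target) / N
            x = new
        allele_sizes = [150 + 2 * a for a in range(k)]
        locus_calls = []
        for pop in line_pops:
            p = pop_names.index(pop)
            locus_calls.append(int(allele_sizes[rng.choice(k, p=x[p])]))
        calls[locus] = locus_calls
        freqs[locus] = {pop_names[p]: [float(v) for v in x[p]]
                        for p in range(config.n_pops)}
        alleles_out[locus] = allele_sizes
    return calls, freqs, alleles_out


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def simulate_study(config: SimConfig
                   ) -> tuple[list[HaplotypeAlignment], SSRMatrix, SyntheticTruth]:
    """Simulate gene alignments + SSR genotypes for one synthetic study."""
    rng = np.random.default_rng(config.seed)
    pop_names = [f"pop{p + 1}" for p in range(config.n_pops)]
    line_ids, line_pops = [], []
    for p, size in enumerate(config.pop_sizes):
        for i in range(size):
            line_ids.append(f"{pop_names[p]}_{i + 1:03d}")
            line_pops.append(pop_names[p])

    alignments = []
    truth = SyntheticTruth(
        gene_haplotypes={}, gene_annotations={}, gene_snp_positions={},
        gene_indels={}, ssr_frequencies={}, ssr_alleles={},
        gamma_per_bp=config.gamma_per_bp)

    for g in range(config.n_genes):
        gene_id = f"gene{g + 1:02d}"
        length = config.gene_lengths[g]
        annotation = _make_annotation(length, rng)
        pops = _evolve_gene(length, annotation, config, rng)
        sample = _sample_rows(pops, config, rng)
        _repair_stops(sample, sample[0], annotation)
        chars = _BASES[sample].astype("U1")
        indels = _plant_indels(chars, sample, sample[0].copy(), annotation,
                               config, rng)
        # anchor the "ancestral" reference for indels to the majority base:
        aln = HaplotypeAlignment(gene_id, chars, list(line_ids),
                                 list(line_pops), annotation)
        alignments.append(aln)
        truth.gene_annotations[gene_id] = annotation
        truth.gene_haplotypes[gene_id] = [aln.row(i) for i in range(aln.n_rows)]
        truth.gene_indels[gene_id] = indels
        truth.gene_snp_positions[gene_id] = _truth_snp_positions(sample, indels)

    ssr_calls, ssr_freqs, ssr_alleles = _simulate_ssrs(
        config, rng, line_pops, pop_names)
    calls_df = pd.DataFrame(ssr_calls, index=line_ids, dtype="float")
    ssr = SSRMatrix(calls_df, pd.Series(line_pops, index=line_ids,
                                        name="population"))
    truth.ssr_frequencies = ssr_freqs
    truth.ssr_alleles = ssr_alleles
    return alignments, ssr, truth


def simulate_decay_scatter(gamma_per_bp: float, n: int, distances,
                           noise_sd: float, seed: int | None = None
                           ) -> list[tuple[float, float]]:
    """r^2-vs-distance points on the decay expectation plus Gaussian noise."""
    if gamma_per_bp <= 0:
        raise ValueError("gamma_per_bp must be positive")
    d = np.asarray(list(distances), dtype=float)
    if d.size == 0:
        raise ValueError("distances must be non-empty")
    rng = np.random.default_rng(seed)
    expected = hill_weir_expectation(gamma_per_bp * d, n)
    r2 = np.clip(expected + rng.normal(0.0, noise_sd, d.size), 0.0, 1.0)
    return list(zip(d.tolist(), r2.tolist()))


# ---------------------------------------------------------------------------
# fixture I/O
# ---------------------------------------------------------------------------

def write_fixtures(alignments: list[HaplotypeAlignment], ssr: SSRMatrix,
                   truth: SyntheticTruth, directory) -> dict[str, str]:
    """Write a full study to plain-text fixtures; returns the file map."""
    directory = str(directory)
    genes_dir = os.path.join(directory, "genes")
    os.makedirs(genes_dir, exist_ok=True)
    files: dict[str, str] = {}
    for aln in alignments:
        fasta = os.path.join(genes_dir, f"{aln.gene_id}.fasta")
        bed = os.path.join(genes_dir, f"{aln.gene_id}.bed")
        try:
            write_alignment(aln, fasta)
            write_annotation(aln.annotation, bed)
        except OSError as exc:
            raise OSError(f"failed writing fixtures for {aln.gene_id} "
                          f"under {genes_dir}: {exc}") from exc
        files[f"{aln.gene_id}.fasta"] = fasta
        files[f"{aln.gene_id}.bed"] = bed

    ssr_path = os.path.join(directory, "ssr.csv")
    ssr.to_csv(ssr_path)
    files["ssr.csv"] = ssr_path

    pops_path = os.path.join(directory, "populations.csv")
    aln0 = alignments[0]
    with open(pops_path, "w") as fh:
        fh.write("line_id,population\n")
        for line_id, pop in zip(aln0.line_ids, aln0.populations):
            fh.write(f"{line_id},{pop}\n")
    files["populations.csv"] = pops_path

    truth_path = os.path.join(directory, "truth.json")
    payload = {
        "gamma_per_bp": truth.gamma_per_bp,
        "gene_haplotypes": truth.gene_haplotypes,
        "gene_snp_positions": truth.gene_snp_positions,
        "gene_indels": truth.gene_indels,
        "gene_annotations": {
            g: {"intervals": [list(iv) for iv in ann.intervals],
                "frame_offset": ann.frame_offset}
            for g, ann in truth.gene_annotations.items()},
        "ssr_frequencies": truth.ssr_frequencies,
        "ssr_alleles": truth.ssr_alleles,
    }
    with open(truth_path, "w") as fh:
        json.dump(payload, fh)
    files["truth.json"] = truth_path
    return files


def read_truth(path) -> SyntheticTruth:
    with open(path) as fh:
        payload = json.load(fh)
    return SyntheticTruth(
        gene_haplotypes=payload["gene_haplotypes"],
        gene_annotations={
            g: GeneAnnotation(tuple(tuple(iv) for iv in spec["intervals"]),
                              spec["frame_offset"])
            for g, spec in payload["gene_annotations"].items()},
        gene_snp_positions={g: list(v) for g, v in
                            payload["gene_snp_positions"].items()},
        gene_indels=payload["gene_indels"],
        ssr_frequencies=payload["ssr_frequencies"],
        ssr_alleles=payload["ssr_alleles"],
        gamma_per_bp=payload["gamma_per_bp"],
    )
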