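# popfrag

Population-genetics toolkit for candidate-gene fragments and SSR markers
in structured plant populations. It analyses phase-known **haploid**
gene-fragment alignments (one gamete per line) and haploid SSR genotype
tables for:

- **Sequence diversity** — polymorphic-site calling (SNPs, atomic
  indels), functional classification (synonymous / non-synonymous with
  polarity classes, in-frame indels), nucleotide diversity (π, whole
  fragment and exon-restricted), haplotype inventories, haplotype
  diversity with Nei's SD, Tajima's D with the beta-approximation
  p-value.
- **Selection** — counting-based dN/dS (Nei–Gojobori 1986 pathway
  counting with Jukes–Cantor correction) and a codon-bootstrap z-test of
  dN = dS.
- **Linkage disequilibrium** — pairwise r² from haplotype counts (no EM;
  phase is known), Fisher's exact significance, within-gene mean r²,
  inter-genic r².
- **LD decay** — non-linear least-squares fit of the sample-size-adjusted
  drift–recombination expectation E[r² | Γ, n], an empirical significance
  threshold from unlinked SSR loci (squared 95th percentile of √r²), and
  the extent of LD where the fitted curve crosses the threshold.
- **SSR diversity** — PIC with bootstrap CIs/SD, rarefied allelic
  richness, private alleles.
- **Structure** — DICE similarity, classical PCoA (Gower
  double-centering), two-level haploid AMOVA with permutation testing.
- **Synthetic data** — a forward-time Wright–Fisher simulator
  (recombination, migration, infinite-sites-style SNPs, atomic indels,
  drifting multiallelic SSR loci) that generates study-shaped fixtures
  with known ground truth, so the whole pipeline is testable offline.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: published-table
arithmetic, independent-oracle equivalences (brute-force π, Pearson r²,
exhaustive rarefaction, hypergeometric Fisher, hand-computed AMOVA,
Euclidean PCoA round-trip), decay-fit parameter recovery, full-pipeline
runtime/extent recovery, and neutral-simulation properties.

## CLI

```bash
# generate a synthetic study as plain-text fixtures
popfrag simulate --seed 1 --outdir fixtures/

# individual stages
popfrag call-sites --genes-dir fixtures/genes --populations fixtures/populations.csv --outdir sites/
popfrag diversity  --genes-dir fixtures/genes --populations fixtures/populations.csv --out diversity.csv
popfrag selection  --genes-dir fixtures/genes --populations fixtures/populations.csv --out selection.csv
popfrag ssr        --ssr-table fixtures/ssr.csv --out ssr_summary.csv
popfrag ld         --genes-dir fixtures/genes --populations fixtures/populations.csv --out ld_pairs.csv
popfrag decay      --pairs ld_pairs.csv --ssr-table fixtures/ssr.csv --n-lines 201 --out decay.json
popfrag structure  --ssr-table fixtures/ssr.csv --outdir struct/

# everything at once (simulate mode)
popfrag run-all --simulate --outdir out/ --seed 1
```

`run-all` writes `gene_summary.csv`, `ssr_summary.csv`,
`haplotype_freqs.csv`, `ld_pairs.csv`, `decay.json`, `amova.csv`,
`pcoa.csv`, plus `run.log` / `run_meta.json` (versions, seed, config
hash). Reruns with the same config and seed are byte-identical.

## File formats

- Gene alignments: gapped FASTA, `-` for deletion states, headers
  `>line_id pop=population`.
- Annotations: BED-like TSV per gene — `start  end  region  frame`
  (0-based half-open; region ∈ 5UTR/exon/intron/3UTR; frame on the
  first exon row).
- SSR table: CSV, `line_id,population,locus...` with integer allele
  sizes, empty = missing.
- Population table: CSV `line_id,population`.
- Simulator ground truth: JSON (`truth.json`) with emitted haplotypes,
  SNP positions, indel events, SSR allele frequencies, and the
  generating per-bp Γ.

## Method notes

- dN/dS uses NG86 counting, not a likelihood codon model; pairwise
  values aggregate as ratio of means, and significance comes from a
  codon bootstrap. For very short toy inputs where the substitution
  proportion saturates (p ≥ 3/4) the Jukes–Cantor correction falls back
  to the uncorrected proportion.
- π and S use pairwise deletion and exclude gap-containing columns;
  indel sites still enter haplotypes and LD as binary characters.
- Multiallelic r² is the frequency-weighted composite
  Σ D²ij / [(1 − Σp²)(1 − Σq²)], which reduces exactly to D²/(pA pa pB pb)
  for biallelic pairs.
- AMOVA is two-level (among / within populations) on haploid mismatch
  distances, with whole individuals permuted and the +1 p-value
  correction.
- The simulator's ground-truth Γ per bp is 2 · (number of simulated
  sequences) · (recombination per bp); with migration > 0 the demes are
  treated as one pooled population for this purpose.
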