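"""End-to-end orchestration: load or simulate inputs, run every stage,
write the report bundle (gene summary, SSR summary, haplotypes, LD pairs,
decay fit, AMOVA, PCoA) plus a run log."""

from __future__ import annotations

import glob
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from popfrag import alignment as aln_io
from popfrag import decay as decay_mod
from popfrag import diversity, ld, selection, ssr as ssr_mod, structure
from popfrag.alignment import HaplotypeAlignment, call_sites, classify_effects, filter_maf, site_genotypes
from popfrag.simulate import SimConfig, simulate_study, write_fixtures
from popfrag.ssr import SSRMatrix

logger = logging.getLogger(__name__)

REGION_ABBREV = {"5UTR": "5'UTR", "exon": "E", "intron": "I", "3UTR": "3'UTR"}


@dataclass
class PipelineConfig:
    # exactly one of (genes_dir, ...) or simulate must be provided
    genes_dir: str | None = None
    ssr_table: str | None = None
    populations_table: str | None = None
    simulate: SimConfig | None = None
    maf_threshold: float = 0.05
    rarefaction_n: int | None = None
    bootstrap_B: int = 10_000
    dnds_bootstrap_B: int = 1000
    amova_perms: int = 15_000
    percentile: float = 95.0
    d_max: float = decay_mod.DEFAULT_D_MAX
    seed: int = 0
    outdir: str = "popfrag_out"

    def validate(self) -> None:
        sim_mode = self.simulate is not None
        input_mode = self.genes_dir is not None
        if sim_mode == input_mode:
            raise ValueError("config must set exactly one of genes_dir/simulate")
        if input_mode and (self.ssr_table is None or self.populations_table is None):
            raise ValueError("input mode requires ssr_table and populations_table")
        if not 0.0 <= self.maf_threshold <= 0.5:
            raise ValueError("maf_threshold must be in [0, 0.5]")
        if not 0.0 < self.percentile < 100.0:
            raise ValueError("percentile must be in (0, 100)")
        for name in ("bootstrap_B", "dnds_bootstrap_B", "amova_perms"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("outdir")  # output location does not affect results
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_inputs(config: PipelineConfig):
    if config.simulate is not None:
        return simulate_study(config.simulate)[:2]
    alignments = []
    fastas = sorted(glob.glob(os.path.join(config.genes_dir, "*.fasta")))
    if not fastas:
        raise FileNotFoundError(f"no FASTA files under {config.genes_dir}")
    for fasta in fastas:
        bed = os.path.splitext(fasta)[0] + ".bed"
        alignments.append(aln_io.read_alignment(
            fasta, bed if os.path.exists(bed) else None,
            config.populations_table))
    ssr = SSRMatrix.from_csv(config.ssr_table)
    return alignments, ssr


def coverage_string(annotation) -> str:
    """Region composition of a fragment, e.g. 5'UTR/E/3'UTR."""
    if annotation is None:
        return ""
    parts: list[str] = []
    for _s, _e, region in annotation.intervals:
        abbrev = REGION_ABBREV[region]
        if not parts or parts[-1] != abbrev:
            parts.append(abbrev)
    return "/".join(parts)


def summarize_gene_table(records: list[dict]) -> pd.DataFrame:
    """Assemble per-gene records into the gene summary table + totals row."""
    table = pd.DataFrame(records)
    totals = {
        "gene_id": "Total",
        "length_bp": int(table["length_bp"].sum()),
        "n_snps": int(table["n_snps"].sum()),
        "n_nonsyn_snps": int(table["n_nonsyn_snps"].sum()),
        "n_indels": int(table["n_indels"].sum()),
        "n_haplotypes": int(table["n_haplotypes"].sum()),
    }
    if totals["n_snps"] > 0:
        totals["snp_per_bp"] = diversity.snp_density(
            totals["length_bp"], totals["n_snps"])
    return pd.concat([table, pd.DataFrame([totals])], ignore_index=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every analysis stage; returns {output name: path}."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    log_path = os.path.join(config.outdir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("popfrag")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    outputs: dict[str, str] = {}
    timings: dict[str, float] = {}
    try:
        return _run_stages(config, outputs, timings)
    finally:
        _write_meta(config, outputs, timings)
        root.removeHandler(handler)
        handler.close()


def _stage(name, timings):
    logger.info("stage %s", name)
    timings[name] = time.perf_counter()
    return name


def _done(name, timings):
    timings[name] = time.perf_counter() - timings[name]
    logger.info("stage %s done in %.2fs", name, timings[name])


def _run_stages(config: PipelineConfig, outputs, timings) -> dict:
    rng_seed = config.seed

    name = _stage("load", timings)
    try:
        alignments, ssr = _load_inputs(config)
    except Exception as exc:
        raise RuntimeError(f"stage load failed: {exc}") from exc
    _done(name, timings)

    # ----- per-gene sequence analyses
    name = _stage("genes", timings)
    gene_records = []
    hap_rows = []
    pair_frames = []
    pooled_scatter: list[tuple[float, float]] = []
    try:
        for aln in alignments:
            sites = call_sites(aln)
            if aln.annotation is not None and len(sites):
                sites = classify_effects(sites, aln)
            record = diversity.summarize_gene(aln, sites)
            record["coverage"] = coverage_string(aln.annotation)
            record["n_nonsyn_snps"] = int(
                ((sites["kind"] == "SNP") &
                 (sites["coding_effect"] == "non-synonymous")).sum()
            ) if len(sites) else 0

            if aln.annotation is not None:
                sel = selection.test_neutrality(
                    aln, B=config.dnds_bootstrap_B, seed=rng_seed)
                record["dn_ds"] = sel.omega
                record["dn_ds_p"] = sel.p_neutral
            else:
                record["dn_ds"] = float("nan")
                record["dn_ds_p"] = float("nan")

            haps = diversity.haplotype_table(aln, sites)
            for _, row in haps.iterrows():
                hap_rows.append({"gene_id": aln.gene_id, **row})

            kept = filter_maf(sites, config.maf_threshold)
            if len(kept) >= 2:
                geno = site_genotypes(aln, kept)
                genes_map = {c: aln.gene_id for c in geno.columns}
                pos_map = {c: float(c.split("@")[1]) for c in geno.columns}
                ldm = ld.pairwise_r2(geno, genes_map, pos_map)
                record["mean_r2"] = ld.gene_mean_r2(ldm, aln.gene_id)
                pairs = ldm.pair_table()
                pair_frames.append(pairs)
                within = pairs.dropna(subset=["distance_bp", "r2"])
                within = within[within["distance_bp"] > 0]
                pooled_scatter.extend(
                    zip(within["distance_bp"], within["r2"]))
            else:
                record["mean_r2"] = float("nan")
            gene_records.append(record)
    except Exception as exc:
        raise RuntimeError(f"stage genes failed: {exc}") from exc
    _done(name, timings)

    gene_summary = summarize_gene_table(gene_records)
    path = os.path.join(config.outdir, "gene_summary.csv")
    gene_summary.to_csv(path, index=False, na_rep="n.a.")
    outputs["gene_summary"] = path

    path = os.path.join(config.outdir, "haplotype_freqs.csv")
    pd.DataFrame(hap_rows).to_csv(path, index=False)
    outputs["haplotype_freqs"] = path

    path = os.path.join(config.outdir, "ld_pairs.csv")
    (pd.concat(pair_frames, ignore_index=True) if pair_frames
     else pd.DataFrame()).to_csv(path, index=False)
    outputs["ld_pairs"] = path

    # ----- SSR diversity
    name = _stage("ssr", timings)
    try:
        ssr_summary = ssr_mod.summarize_populations(
            ssr, rarefaction_n=config.rarefaction_n,
            B=config.bootstrap_B, seed=rng_seed)
    except Exception as exc:
        raise RuntimeError(f"stage ssr failed: {exc}") from exc
    _done(name, timings)
    path = os.path.join(config.outdir, "ssr_summary.csv")
    ssr_summary.to_csv(path)
    outputs["ssr_summary"] = path

    # ----- LD decay: pooled gene scatter + unlinked-SSR threshold
    name = _stage("decay", timings)
    try:
        poly_loci = [c for c in ssr.calls.columns
                     if ssr.calls[c].dropna().nunique() >= 2]
        ssr_geno = ssr.calls[poly_loci].astype(object).where(
            ssr.calls[poly_loci].notna())
        unlinked = [
            ld.r2_pair(ssr_geno[a], ssr_geno[b])
            for i, a in enumerate(poly_loci) for b in poly_loci[i + 1:]
        ]
        decay_payload: dict = {"n_scatter_points": len(pooled_scatter),
                               "n_unlinked_pairs": len(unlinked),
                               "threshold_r2": None}
        if unlinked:
            decay_payload["mean_unlinked_r2"] = float(np.nanmean(unlinked))
        threshold = None
        try:
            threshold = decay_mod.ld_threshold(unlinked, config.percentile)
            decay_payload["threshold_r2"] = threshold
        except ValueError as exc:
            logger.warning("no LD threshold: %s", exc)
            decay_payload["threshold_note"] = str(exc)
        if len(pooled_scatter) >= 5:
            d, r2 = zip(*pooled_scatter)
            n_lines = int(np.median([a.n_rows for a in alignments]))
            fit = decay_mod.fit_gamma(d, r2, n_lines)
            decay_payload.update(
                gamma_per_bp=fit.gamma_per_bp, n=fit.n, sse=fit.sse)
            if threshold is not None:
                fit = decay_mod.ld_extent(fit, threshold, config.d_max)
                decay_payload.update(extent_bp=fit.extent_bp,
                                     extent_status=fit.extent_status)
    except Exception as exc:
        raise RuntimeError(f"stage decay failed: {exc}") from exc
    _done(name, timings)
    path = os.path.join(config.outdir, "decay.json")
    with open(path, "w") as fh:
        json.dump(decay_payload, fh, indent=2)
    outputs["decay"] = path

    # ----- structure: AMOVA + PCoA on SSRs
    name = _stage("structure", timings)
    try:
        d2 = structure.mismatch_distances(ssr.calls)
        am = structure.amova(d2, ssr.populations.to_numpy(),
                             n_perm=config.amova_perms, seed=rng_seed)
        profiles = structure.ssr_profiles(ssr.calls)
        sim = structure.dice_matrix(profiles.to_numpy())
        coords = structure.pcoa(1.0 - sim)
    except Exception as exc:
        raise RuntimeError(f"stage structure failed: {exc}") from exc
    _done(name, timings)

    path = os.path.join(config.outdir, "amova.csv")
    am.to_frame().assign(phi_st=am.phi_st, p_perm=am.p_perm).to_csv(
        path, index=False)
    outputs["amova"] = path

    n_axes = min(4, coords.coordinates.shape[1])
    pcoa_df = pd.DataFrame(
        coords.coordinates[:, :n_axes],
        columns=[f"PCo{i + 1}" for i in range(n_axes)],
        index=ssr.calls.index)
    pcoa_df.insert(0, "population", ssr.populations)
    pcoa_df.index.name = "line_id"
    path = os.path.join(config.outdir, "pcoa.csv")
    with open(path, "w") as fh:
        pcts = ", ".join(f"PCo{i + 1}={coords.pct_variance[i]:.4f}%"
                         for i in range(n_axes))
        fh.write(f"# percent variance explained: {pcts}\n")
        pcoa_df.to_csv(fh)
    outputs["pcoa"] = path
    return outputs


def _write_meta(config: PipelineConfig, outputs, timings) -> None:
    import popfrag
    meta = {
        "popfrag_version": popfrag.__version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": {k: (asdict(v) if isinstance(v, SimConfig) else v)
                   for k, v in asdict(config).items()},
        "outputs": outputs,
        "stage_seconds": {k: v for k, v in timings.items() if v < 1e6},
    }
    os.makedirs(config.outdir, exist_ok=True)
    with open(os.path.join(config.outdir, "run_meta.json"), "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
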