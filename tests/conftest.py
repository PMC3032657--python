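import numpy as np
import pytest

from popfrag.alignment import GeneAnnotation, HaplotypeAlignment
from popfrag.simulate import SimConfig, simulate_study


def make_alignment(rows, gene_id="toy", populations=None, line_ids=None,
                   annotation=None):
    """Build a HaplotypeAlignment from a list of equal-length strings."""
    n = len(rows)
    if line_ids is None:
        line_ids = [f"L{i + 1}" for i in range(n)]
    if populations is None:
        populations = ["popA"] * n
    seqs = np.array([list(r) for r in rows], dtype="U1")
    return HaplotypeAlignment(gene_id, seqs, line_ids, populations, annotation)


@pytest.fixture
def aln_factory():
    return make_alignment


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_pops=2, pop_sizes=(12, 14), n_genes=3,
        gene_lengths=(500, 700, 400), mu=3e-5, rec_per_bp=1e-4,
        n_generations=150, migration_rate=0.05, n_ssr_loci=10,
        ssr_allele_range=(2, 8), sim_pop_size=40, seed=11)


@pytest.fixture(scope="session")
def small_study(small_config):
    """One modest simulated study shared by read-only tests."""
    return simulate_study(small_config)


@pytest.fixture
def exon_annotation():
    """Single-exon annotation covering 30 columns, frame 0."""
    return GeneAnnotation(((0, 30, "exon"),), 0)
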