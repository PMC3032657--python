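import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from popfrag.ld import (
    fisher_ld_test,
    gene_mean_r2,
    intergenic_r2,
    pairwise_r2,
    r2_pair,
)


def haplotype_columns(counts):
    """Expand {(a, b): count} into two parallel allele lists."""
    x, y = [], []
    for (a, b), c in counts.items():
        x += [a] * c
        y += [b] * c
    return x, y


def pearson_r2(x, y):
    """Oracle: squared Pearson correlation of 0/1-coded alleles."""
    xa = np.array([0 if v == sorted(set(x))[0] else 1 for v in x], float)
    ya = np.array([0 if v == sorted(set(y))[0] else 1 for v in y], float)
    return float(np.corrcoef(xa, ya)[0, 1] ** 2)


def hypergeom_fisher(table):
    """Oracle: two-sided Fisher p by full hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d

    def prob(x):
        return (comb(r1, x, exact=True) * comb(r2, c1 - x, exact=True)
                / comb(n, c1, exact=True))

    p_obs = prob(a)
    return sum(prob(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


class TestR2Pair:
    def test_complete_association(self):
        x, y = haplotype_columns({("A", "B"): 50, ("a", "b"): 50})
        assert r2_pair(x, y) == pytest.approx(1.0)

    def test_independence(self):
        x, y = haplotype_columns({("A", "B"): 25, ("A", "b"): 25,
                                  ("a", "B"): 25, ("a", "b"): 25})
        assert r2_pair(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_worked_example(self):
        x, y = haplotype_columns({("A", "B"): 40, ("A", "b"): 10,
                                  ("a", "B"): 10, ("a", "b"): 40})
        assert r2_pair(x, y) == pytest.approx(0.36)

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_squared_pearson(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        x = rng.choice(["A", "G"], n, p=[0.6, 0.4])
        y = np.where(rng.random(n) < 0.7, x == "A", rng.random(n) < 0.5)
        y = np.where(y, "C", "T")
        assert r2_pair(x, y) == pytest.approx(pearson_r2(x, y), abs=1e-12)

    def test_allele_relabeling_invariant(self):
        x, y = haplotype_columns({("A", "B"): 40, ("A", "b"): 10,
                                  ("a", "B"): 10, ("a", "b"): 40})
        x2 = ["Z" if v == "A" else "Q" for v in x]
        assert r2_pair(x2, y) == pytest.approx(r2_pair(x, y))

    def test_row_permutation_invariant(self):
        rng = np.random.default_rng(1)
        x, y = haplotype_columns({("A", "B"): 30, ("a", "b"): 20,
                                  ("A", "b"): 10})
        perm = rng.permutation(len(x))
        assert r2_pair(np.array(x)[perm], np.array(y)[perm]) == \
            pytest.approx(r2_pair(x, y))

    def test_missing_dropped_pairwise(self):
        x = ["A", "A", "a", "a", None]
        y = ["B", "B", "b", "b", "B"]
        assert r2_pair(x, y) == pytest.approx(1.0)

    def test_multiallelic_composite(self):
        # three alleles vs two; value equals the normalised sum of D_ij^2
        x = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        y = ["X"] * 4 + ["Y"] * 4 + ["X", "X", "Y", "Y"]
        n = len(x)
        joint = pd.crosstab(pd.Series(x), pd.Series(y)).to_numpy() / n
        p, q = joint.sum(1), joint.sum(0)
        D = joint - np.outer(p, q)
        expected = (D**2).sum() / ((1 - (p**2).sum()) * (1 - (q**2).sum()))
        assert r2_pair(x, y) == pytest.approx(expected, abs=1e-12)


class TestFisher:
    def test_small_table(self):
        # [[3,0],[0,3]]: 2 of the C(6,3)=20 arrangements are as extreme
        x, y = haplotype_columns({("A", "B"): 3, ("a", "b"): 3})
        assert fisher_ld_test(x, y) == pytest.approx(0.1)

    def test_balanced_table_p1(self):
        x, y = haplotype_columns({("A", "B"): 25, ("A", "b"): 25,
                                  ("a", "B"): 25, ("a", "b"): 25})
        assert fisher_ld_test(x, y) == pytest.approx(1.0)

    def test_transpose_symmetry(self):
        x, y = haplotype_columns({("A", "B"): 12, ("A", "b"): 3,
                                  ("a", "B"): 5, ("a", "b"): 9})
        assert fisher_ld_test(x, y) == pytest.approx(fisher_ld_test(y, x))

    def test_multiallelic_na(self):
        x = ["A", "B", "C", "A", "B", "C"]
        y = ["X", "Y", "X", "Y", "X", "Y"]
        assert math.isnan(fisher_ld_test(x, y))

    @pytest.mark.parametrize("table", [
        ((3, 0), (0, 3)), ((5, 2), (1, 6)), ((8, 8), (8, 8)),
        ((10, 1), (2, 9)), ((4, 7), (6, 2)),
    ])
    def test_matches_hypergeometric_enumeration(self, table):
        counts = {("A", "B"): table[0][0], ("A", "b"): table[0][1],
                  ("a", "B"): table[1][0], ("a", "b"): table[1][1]}
        counts = {k: v for k, v in counts.items() if v > 0}
        x, y = haplotype_columns(counts)
        assert fisher_ld_test(x, y) == pytest.approx(
            hypergeom_fisher(table), rel=1e-9)


class TestLDMatrix:
    def _frame(self):
        rng = np.random.default_rng(2)
        n = 40
        data = {}
        base = rng.choice(["A", "G"], n)
        data["SNP@10"] = base
        data["SNP@200"] = np.where(rng.random(n) < 0.8, base, "T")
        data["SNP@450"] = rng.choice(["C", "T"], n)
        return pd.DataFrame(data, index=[f"L{i}" for i in range(n)],
                            dtype=object)

    def test_matrix_properties(self):
        geno = self._frame()
        genes = {c: "g1" for c in geno.columns}
        pos = {c: float(c.split("@")[1]) for c in geno.columns}
        ldm = pairwise_r2(geno, genes, pos)
        assert np.allclose(np.diag(ldm.r2), 1.0)
        assert np.allclose(ldm.r2, ldm.r2.T)
        assert ldm.distance_bp[0, 1] == 190.0

    def test_monomorphic_errors(self):
        geno = self._frame()
        geno["SNP@999"] = "A"
        with pytest.raises(ValueError, match="monomorphic"):
            pairwise_r2(geno)

    def test_gene_mean_r2(self):
        geno = self._frame()
        genes = {c: "g1" for c in geno.columns}
        pos = {c: float(c.split("@")[1]) for c in geno.columns}
        ldm = pairwise_r2(geno, genes, pos)
        vals = [ldm.r2[0, 1], ldm.r2[0, 2], ldm.r2[1, 2]]
        assert gene_mean_r2(ldm, "g1") == pytest.approx(np.mean(vals))
        assert math.isnan(gene_mean_r2(ldm, "unknown"))

    def test_pair_table_matches_matrix(self):
        geno = self._frame()
        genes = {c: "g1" for c in geno.columns}
        pos = {c: float(c.split("@")[1]) for c in geno.columns}
        ldm = pairwise_r2(geno, genes, pos)
        table = ldm.pair_table()
        assert len(table) == 3
        row = table.iloc[0]
        assert row["r2"] == ldm.r2[0, 1]


class TestIntergenic:
    def test_same_gene_self_consistency(self):
        rng = np.random.default_rng(4)
        n = 30
        geno = pd.DataFrame({
            "a": rng.choice(["A", "G"], n),
            "b": rng.choice(["C", "T"], n),
        }, index=[f"L{i}" for i in range(n)], dtype=object)
        val = intergenic_r2(geno, geno)
        # cross pairs include self-pairs (r2=1) and both orders of (a, b)
        expected = np.mean([1.0, 1.0, r2_pair(geno["a"], geno["b"]),
                            r2_pair(geno["a"], geno["b"])])
        assert val == pytest.approx(expected)

    def test_independent_genes_near_null(self, small_study):
        from popfrag.alignment import call_sites, filter_maf, site_genotypes
        alignments, _, _ = small_study
        genos = []
        for aln in alignments[:2]:
            sites = filter_maf(call_sites(aln), 0.05)
            if len(sites):
                genos.append(site_genotypes(aln, sites))
        if len(genos) == 2:
            n = len(genos[0])
            val = intergenic_r2(genos[0], genos[1])
            assert val <= 2.0 / (n - 1) + 0.05

    def test_disjoint_lines_na(self):
        a = pd.DataFrame({"x": ["A", "G"]}, index=["L1", "L2"], dtype=object)
        b = pd.DataFrame({"y": ["C", "T"]}, index=["L3", "L4"], dtype=object)
        with pytest.warns(UserWarning):
            assert math.isnan(intergenic_r2(a, b))
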