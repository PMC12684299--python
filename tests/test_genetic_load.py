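"""Effect classification, relative abundance and load summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from islepop.containers import MISSING, DerivedMatrix
from islepop.genetic_load import (
    CATEGORIES,
    EX_DELETERIOUS_MAX,
    LOF_CONSEQUENCES,
    classify_effect,
    classify_sites,
    compare_groups,
    derived_homozygosity,
    fixed_homozygous_lof_genes,
    load_counts,
    load_summary,
    relative_abundance,
)


def make_dm(dc, gene_id=None, consequence=None, ex_score=None):
    dc = np.asarray(dc, dtype=np.int8)
    n_samples, n_sites = dc.shape
    sites = pd.DataFrame(
        {
            "chrom": ["chr1"] * n_sites,
            "pos": np.arange(1, n_sites + 1) * 100,
            "ref": ["A"] * n_sites,
            "alt": ["G"] * n_sites,
            "ancestral": ["A"] * n_sites,
            "derived": ["G"] * n_sites,
        }
    )
    if gene_id is not None:
        sites["gene_id"] = gene_id
    if consequence is not None:
        sites["consequence"] = consequence
        sites["ex_score"] = ex_score if ex_score is not None else np.nan
    return DerivedMatrix(
        samples=[f"s{i}" for i in range(n_samples)], sites=sites, dc=dc
    )


class TestClassifyEffect:
    @pytest.mark.parametrize("cons", sorted(LOF_CONSEQUENCES))
    def test_lof_membership(self, cons):
        assert classify_effect(cons) == "lof"

    def test_spaced_consequence_normalised(self):
        # VEP writes underscores but tables sometimes carry spaces
        assert classify_effect("splice region variant") == "lof"
        assert classify_effect("Stop Gained") == "lof"

    def test_ex_boundary_inclusive(self):
        assert classify_effect("missense_variant", EX_DELETERIOUS_MAX) == "missense_deleterious"
        assert classify_effect("missense_variant", 0.30) == "missense_tolerated"
        assert classify_effect("missense_variant", 0.01) == "missense_deleterious"

    def test_synonymous_and_excluded(self):
        assert classify_effect("synonymous_variant") == "synonymous"
        assert classify_effect("intron_variant") == "excluded"
        assert classify_effect("3_prime_UTR_variant") == "excluded"

    def test_missense_without_ex_is_error(self):
        with pytest.raises(ValueError, match="EX"):
            classify_effect("missense_variant")
        with pytest.raises(ValueError, match="EX"):
            classify_effect("missense_variant", float("nan"))

    def test_category_partition_over_table(self):
        sites = pd.DataFrame(
            {
                "consequence": [
                    "stop_gained",
                    "missense_variant",
                    "missense_variant",
                    "synonymous_variant",
                    "intergenic_variant",
                ],
                "ex_score": [np.nan, 0.1, 0.9, np.nan, np.nan],
            }
        )
        cats = classify_sites(sites)
        assert sorted(cats) == sorted(
            ["lof", "missense_deleterious", "missense_tolerated", "synonymous", "excluded"]
        )
        assert np.isin(cats, list(CATEGORIES) + ["excluded"]).all()


class TestLoadCounts:
    def test_toy_counts_and_ra(self):
        # sample s0: het at 2 sites, hom at 1, 10 category sites in total
        dc = np.zeros((2, 10), dtype=np.int8)
        dc[0, :2] = 1
        dc[0, 2] = 2
        dc[1, :] = 1  # keeps every site segregating species-wide
        dm = make_dm(dc, consequence=["synonymous_variant"] * 10)
        cats = classify_sites(dm.sites)
        n_het, n_hom, n_p = load_counts(dm, cats, "s0", "synonymous")
        assert (n_het, n_hom, n_p) == (2, 1, 10)
        assert relative_abundance(n_het, n_hom, n_p) == pytest.approx(0.2)

    def test_all_hom_derived_maximises_ra(self):
        dc = np.full((3, 6), 2, dtype=np.int8)
        dm = make_dm(dc, consequence=["synonymous_variant"] * 6)
        cats = classify_sites(dm.sites)
        n_het, n_hom, n_p = load_counts(dm, cats, "s1", "synonymous")
        assert (n_het, n_hom, n_p) == (0, 6, 6)
        assert relative_abundance(n_het, n_hom, n_p) == 1.0

    def test_no_derived_alleles(self):
        dc = np.zeros((2, 5), dtype=np.int8)
        dc[1, :] = 1
        dm = make_dm(dc, consequence=["synonymous_variant"] * 5)
        cats = classify_sites(dm.sites)
        assert load_counts(dm, cats, "s0", "synonymous") == (0, 0, 5)

    def test_np_is_species_wide_and_ignores_other_categories(self):
        # 4 synonymous sites, 3 lof sites; s0 only carries synonymous alleles
        cons = ["synonymous_variant"] * 4 + ["stop_gained"] * 3
        dc = np.zeros((2, 7), dtype=np.int8)
        dc[0, 0] = 1
        dc[1, 1:] = 2  # s1 makes every site count towards its category n_p
        dm = make_dm(dc, consequence=cons)
        cats = classify_sites(dm.sites)
        assert load_counts(dm, cats, "s0", "synonymous") == (1, 0, 4)
        assert load_counts(dm, cats, "s0", "lof") == (0, 0, 3)

    def test_missing_genotypes_excluded_from_counts_not_np(self):
        dc = np.array([[1, MISSING, 2], [0, 1, 0]], dtype=np.int8)
        dm = make_dm(dc, consequence=["synonymous_variant"] * 3)
        cats = classify_sites(dm.sites)
        assert load_counts(dm, cats, "s0", "synonymous") == (1, 1, 3)

    def test_ra_requires_sites(self):
        with pytest.raises(ValueError):
            relative_abundance(1, 1, 0)

    @given(
        n_het=st.integers(0, 50),
        n_hom=st.integers(0, 50),
        extra=st.integers(1, 10),
    )
    @settings(max_examples=60, deadline=None)
    def test_ra_monotone_in_counts(self, n_het, n_hom, extra):
        n_p = n_het + n_hom + extra
        base = relative_abundance(n_het, n_hom, n_p)
        assert relative_abundance(n_het + 1, n_hom, n_p) > base
        assert relative_abundance(n_het, n_hom + 1, n_p) > base
        assert 0.0 <= base <= 1.0


class TestDerivedHomozygosity:
    def test_cases(self):
        assert derived_homozygosity(0, 5) == 1.0
        assert derived_homozygosity(3, 1) == pytest.approx(0.25)
        assert math.isnan(derived_homozygosity(0, 0))


class TestFixedHomozygousLofGenes:
    def test_fixed_gene_found_and_het_carrier_blocks(self):
        cons = ["stop_gained", "stop_gained", "synonymous_variant"]
        genes = ["G1", "G2", "G3"]
        dc = np.array([[2, 2, 2], [2, 1, 2]], dtype=np.int8)
        dm = make_dm(dc, gene_id=genes, consequence=cons)
        cats = classify_sites(dm.sites)
        assert fixed_homozygous_lof_genes(dm, cats, ["s0", "s1"]) == {"G1"}

    def test_missing_genotypes_tolerated(self):
        dm = make_dm(
            np.array([[2], [MISSING]], dtype=np.int8),
            gene_id=["G1"],
            consequence=["stop_gained"],
        )
        cats = classify_sites(dm.sites)
        assert fixed_homozygous_lof_genes(dm, cats, ["s0", "s1"]) == {"G1"}

    def test_matches_brute_force_on_random_instance(self):
        rng = np.random.default_rng(11)
        n_sites, n_samples = 60, 6
        dc = rng.choice([0, 1, 2, MISSING], size=(n_samples, n_sites), p=[0.3, 0.2, 0.4, 0.1]).astype(np.int8)
        genes = [f"g{rng.integers(0, 8)}" for _ in range(n_sites)]
        cons = rng.choice(["stop_gained", "synonymous_variant"], size=n_sites)
        dm = make_dm(dc, gene_id=genes, consequence=list(cons))
        cats = classify_sites(dm.sites)
        pop = ["s0", "s2", "s4"]
        rows = [0, 2, 4]
        expected = set()
        for j in range(n_sites):
            if cons[j] != "stop_gained":
                continue
            calls = [dc[i, j] for i in rows if dc[i, j] != MISSING]
            if calls and all(c == 2 for c in calls):
                expected.add(genes[j])
        assert fixed_homozygous_lof_genes(dm, cats, pop) == expected


class TestCompareGroups:
    def test_small_group_not_testable(self):
        res = compare_groups([1.0, 2.0], [1.0] * 8)
        assert not res.testable
        assert "N < 3" in res.reason
        assert math.isnan(res.pvalue)

    def test_identical_groups_p_one(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        res = compare_groups(vals, vals)
        assert res.testable
        assert res.pvalue == pytest.approx(1.0)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_textbook_welch_formula(self):
        rng = np.random.default_rng(42)
        a = rng.normal(0.0, 1.0, 20)
        b = rng.normal(0.5, 2.0, 20)
        res = compare_groups(a, b)
        # independent oracle: Welch statistic and Satterthwaite df by hand
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        p = 2 * stats.t.sf(abs(t), df)
        assert res.statistic == pytest.approx(t, rel=1e-12)
        assert res.pvalue == pytest.approx(p, rel=1e-9)

    def test_nan_values_dropped_before_size_rule(self):
        res = compare_groups([1.0, 2.0, float("nan")], [3.0, 4.0, 5.0])
        assert not res.testable


class TestLoadSummary:
    def test_summary_is_consistent_with_load_counts(self):
        rng = np.random.default_rng(5)
        cons = rng.choice(
            ["stop_gained", "missense_variant", "synonymous_variant"], size=30
        )
        ex = np.where(
            cons == "missense_variant", rng.uniform(0.0, 1.0, 30), np.nan
        )
        dc = rng.choice([0, 1, 2], size=(4, 30)).astype(np.int8)
        dm = make_dm(dc, consequence=list(cons), ex_score=ex)
        cats = classify_sites(dm.sites)
        table = load_summary(dm, cats)
        assert set(table["category"]) == set(CATEGORIES)
        for _, row in table.iterrows():
            n_het, n_hom, n_p = load_counts(dm, cats, row["sample"], row["category"])
            assert (row["n_het"], row["n_hom"], row["n_p"]) == (n_het, n_hom, n_p)
            if n_p:
                assert row["ra"] == pytest.approx((n_het + 2 * n_hom) / (2 * n_p))
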