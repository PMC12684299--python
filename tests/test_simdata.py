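"""Simulator behaviour: determinism, drift, emission formats, outgroups."""

import subprocess
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from cyvcf2 import VCF

from islepop.containers import GenotypeMatrix
from islepop.simdata import (
    SimConfig,
    _Population,
    _next_generation,
    emit_outgroups,
    sample_metadata,
    simulate,
)
from islepop.variant_prep import polarize
from islepop.vcfio import emit_vcf, read_vcf


@pytest.fixture(scope="module")
def tiny_run(tiny_sim_config):
    return simulate(tiny_sim_config)


class TestConfigValidation:
    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimConfig(
                class_fractions={
                    "synonymous": 0.5,
                    "missense_tolerated": 0.5,
                    "missense_deleterious": 0.5,
                    "lof": 0.5,
                }
            )

    def test_tiny_island_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            SimConfig(n_island=1)

    def test_island_larger_than_mainland_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_island=600, n_mainland=500)

    def test_selection_outside_unit_interval_rejected(self):
        bad = {"synonymous": 0.0, "missense_tolerated": 0.0,
               "missense_deleterious": 0.0, "lof": 1.5}
        with pytest.raises(ValueError):
            SimConfig(sel_coeff=bad)


class TestSimulate:
    def test_no_mutation_means_no_sites(self):
        gm, sites, truth = simulate(
            SimConfig(
                mu=0.0,
                n_mainland=20,
                n_island=4,
                total_generations=12,
                split_generation=10,
                n_sample_mainland=3,
                n_sample_island=3,
                seed=3,
            )
        )
        assert gm.n_sites == 0
        assert len(truth.sites) == 0

    def test_identical_seed_identical_output(self, tiny_sim_config, tiny_run, tmp_path):
        gm1, sites1, truth1 = tiny_run
        gm2, sites2, truth2 = simulate(tiny_sim_config)
        assert np.array_equal(gm1.gt, gm2.gt)
        assert sites1.equals(sites2)
        assert truth1.pedigree_f.equals(truth2.pedigree_f)
        p1, p2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
        emit_vcf(gm1, sites1, p1, seed=5)
        emit_vcf(gm2, sites2, p2, seed=5)
        assert p1.read_bytes() == p2.read_bytes()

    def test_truth_has_one_record_per_emitted_site(self, tiny_run):
        gm, sites, truth = tiny_run
        assert len(truth.sites) == gm.n_sites
        assert list(truth.sites["pos"]) == list(sites["pos"])

    def test_island_bottleneck_raises_pedigree_inbreeding(self, tiny_run):
        _, _, truth = tiny_run
        f = truth.pedigree_f
        assert (
            f.loc[f.population == "island", "pedigree_f"].mean()
            > f.loc[f.population == "mainland", "pedigree_f"].mean()
        )

    def test_metadata_matches_samples(self, tiny_run):
        gm, _, truth = tiny_run
        meta = sample_metadata(truth)
        assert list(meta["sample_id"]) == gm.samples
        assert set(meta["population"]) == {"island", "mainland"}


class TestDriftCalibration:
    def test_single_locus_heterozygosity_decay(self):
        # gene diversity at a neutral locus decays as (1 - 1/(2N))^t
        rng = np.random.default_rng(2024)
        N, t, reps = 30, 20, 300
        H0 = np.zeros((2 * N, 1), dtype=np.uint8)
        H0[::2] = 1  # p0 = 0.5
        s = np.zeros(1)
        h = np.full(1, 0.5)
        bounds = (np.empty(0, dtype=int), None, 0.0, np.empty(0, dtype=int))
        div = []
        for _ in range(reps):
            pop = _Population(
                H=H0.copy(), kin=np.zeros((N, N), np.float32), f=np.zeros(N)
            )
            for _ in range(t):
                pop = _next_generation(pop, s, h, N, rng, bounds)
            p = pop.H.mean()
            div.append(2 * p * (1 - p))
        expected = 0.5 * (1 - 1 / (2 * N)) ** t
        assert np.mean(div) == pytest.approx(expected, rel=0.08)


class TestEmitVcf:
    def test_round_trip_genotypes(self, tiny_run, tmp_path):
        gm, sites, _ = tiny_run
        path = tmp_path / "sim.vcf"
        emit_vcf(gm, sites, path, mean_depth=30, seed=1)
        back = read_vcf(path)
        assert back.samples == gm.samples
        assert np.array_equal(back.gt, gm.gt)
        assert list(back.sites["ref"]) == list(sites["ref"])

    def test_het_allele_depths_sum_to_depth(self, tiny_run, tmp_path):
        gm, sites, _ = tiny_run
        path = tmp_path / "sim.vcf"
        emit_vcf(gm, sites, path, mean_depth=10, seed=2)
        checked = 0
        for v in VCF(str(path)):
            ad = v.format("AD")
            dp = v.format("DP")[:, 0]
            assert (np.clip(ad, 0, None).sum(axis=1) == dp).all()
            checked += 1
        assert checked == gm.n_sites

    def test_parses_under_external_validator(self, tiny_run, tmp_path):
        gm, sites, _ = tiny_run
        path = tmp_path / "sim.vcf"
        emit_vcf(gm, sites, path, seed=3)
        res = subprocess.run(
            ["bcftools", "view", str(path)], capture_output=True, text=True
        )
        assert res.returncode == 0, res.stderr
        n_records = sum(
            1 for line in res.stdout.splitlines() if line and not line.startswith("#")
        )
        assert n_records == gm.n_sites


class TestEmitOutgroups:
    def test_clean_outgroups_keep_every_site(self, tiny_run):
        gm, sites, _ = tiny_run
        og = emit_outgroups(sites, 0.0, 0.0, seed=1)
        dm = polarize(gm, og)
        assert dm.n_sites == gm.n_sites
        assert list(dm.sites["ancestral"]) == list(sites["ancestral"])

    def test_fully_discordant_outgroups_drop_everything(self, tiny_run):
        gm, sites, _ = tiny_run
        og = emit_outgroups(sites, 1.0, 0.0, seed=1)
        assert polarize(gm, og).n_sites == 0

    def test_retention_matches_direct_concordance_count(self):
        n = 1000
        sites = pd.DataFrame(
            {
                "chrom": ["chr1"] * n,
                "pos": np.arange(1, n + 1) * 50,
                "ref": ["A"] * n,
                "alt": ["G"] * n,
                "ancestral": ["A"] * n,
            }
        )
        og = emit_outgroups(sites, discordant_fraction=0.1, het_fraction=0.05, seed=9)
        concordant = 0
        for _, row in og.iterrows():
            gts = [row["out1"], row["out2"], row["out3"]]
            alleles = {a for g in gts for a in g.split("/")}
            if all(g.split("/")[0] == g.split("/")[1] for g in gts) and len(alleles) == 1:
                concordant += 1
        assert concordant == n - round(0.1 * n) - round(0.05 * n)
        gm = GenotypeMatrix(
            samples=["s0"],
            sites=sites.drop(columns=["ancestral"]),
            gt=np.ones((1, n), dtype=np.int8),
        )
        assert polarize(gm, og).n_sites == concordant

    def test_fraction_bounds_validated(self, tiny_run):
        _, sites, _ = tiny_run
        with pytest.raises(ValueError):
            emit_outgroups(sites, -0.1, 0.0)
        with pytest.raises(ValueError):
            emit_outgroups(sites, 0.7, 0.7)
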