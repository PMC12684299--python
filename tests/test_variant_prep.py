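"""Genotype masking rules and outgroup polarisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from islepop.containers import MISSING
from islepop.variant_prep import (
    drop_invariant,
    mask_allelic_balance,
    mask_depth,
    polarize,
)

from conftest import make_gm


def outgroup_table(n, genos, chrom=None, pos=None):
    """Outgroup table with the same (chrom, pos) keys the fixtures use."""
    return pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["chr1"] * n,
            "pos": pos if pos is not None else np.arange(1, n + 1) * 1000,
            "out1": [g[0] for g in genos],
            "out2": [g[1] for g in genos],
            "out3": [g[2] for g in genos],
        }
    )


class TestAllelicBalanceMask:
    def test_skewed_het_masked(self):
        # 2 of 10 reads on the minor allele: 0.20 < 0.25 -> missing
        gm = make_gm([[1]], dp=[[10]], minor_ad=[[2]])
        assert mask_allelic_balance(gm).gt[0, 0] == MISSING

    def test_balanced_het_kept(self):
        gm = make_gm([[1]], dp=[[10]], minor_ad=[[5]])
        assert mask_allelic_balance(gm).gt[0, 0] == 1

    def test_boundary_fraction_kept(self):
        # exactly 0.25 is not strictly below the threshold
        gm = make_gm([[1]], dp=[[20]], minor_ad=[[5]])
        assert mask_allelic_balance(gm).gt[0, 0] == 1

    def test_homozygotes_untouched(self):
        gm = make_gm([[2, 0]], dp=[[10, 10]], minor_ad=[[0, 0]])
        out = mask_allelic_balance(gm)
        assert np.array_equal(out.gt, gm.gt)

    def test_missing_ad_warns_and_leaves_unmasked(self):
        gm = make_gm([[1, 1]])
        with pytest.warns(UserWarning, match="unmasked"):
            out = mask_allelic_balance(gm)
        assert np.array_equal(out.gt, gm.gt)

    def test_threshold_validated(self):
        gm = make_gm([[1]], dp=[[10]], minor_ad=[[5]])
        with pytest.raises(ValueError):
            mask_allelic_balance(gm, 0.6)


class TestDepthMask:
    def _gm(self, depths):
        """One sample whose mean depth is 30 by construction."""
        gt = np.zeros((1, len(depths)), dtype=np.int8)
        return make_gm(gt, dp=[depths], minor_ad=[[0] * len(depths)])

    def test_below_half_mean_masked(self):
        gm = self._gm([14, 30, 46])  # mean 30
        assert mask_depth(gm).gt[0, 0] == MISSING

    def test_exactly_half_kept(self):
        gm = self._gm([15, 30, 45])  # mean 30; 15 is not < 15
        assert mask_depth(gm).gt[0, 0] == 0

    def test_above_double_masked_boundary_kept(self):
        gm = self._gm([61, 30, 28, 1])  # mean 30
        out = mask_depth(gm)
        assert out.gt[0, 0] == MISSING  # 61 > 60
        gm2 = self._gm([60, 30, 29, 1])  # mean 30; 60 is not > 60
        assert mask_depth(gm2).gt[0, 0] == 0

    def test_mean_computed_before_masking(self):
        # depth 10 drags the mean; thresholds must come from the raw mean
        depths = [10, 30, 30, 30, 50]  # mean 30 -> bounds (15, 60)
        gm = self._gm(depths)
        out = mask_depth(gm)
        assert out.gt[0, 0] == MISSING and (out.gt[0, 1:] == 0).all()

    def test_unsequenced_sample_named(self):
        gm = make_gm([[0, 0]], dp=[[0, 0]], minor_ad=[[0, 0]])
        with pytest.raises(ValueError, match="s0"):
            mask_depth(gm)


@st.composite
def noisy_matrices(draw):
    n_samples = draw(st.integers(1, 4))
    n_sites = draw(st.integers(1, 12))
    gt = draw(
        hnp.arrays(
            np.int8, (n_samples, n_sites), elements=st.sampled_from([-1, 0, 1, 2])
        )
    )
    # a sequenced hom-ref call survives every mask, keeping each sample's
    # depth mean computable in either masking order
    gt[:, 0] = 0
    dp = draw(hnp.arrays(np.int32, (n_samples, n_sites), elements=st.integers(0, 80)))
    dp[:, 0] = np.maximum(dp[:, 0], 1)
    minor = np.minimum(
        draw(hnp.arrays(np.int32, (n_samples, n_sites), elements=st.integers(0, 40))),
        dp,
    )
    return make_gm(gt, dp=dp, minor_ad=minor)


class TestMaskingProperties:
    @given(noisy_matrices())
    @settings(max_examples=60, deadline=None)
    def test_masks_only_add_missingness(self, gm):
        for masked in (mask_allelic_balance(gm), mask_depth(gm)):
            changed = masked.gt != gm.gt
            assert (masked.gt[changed] == MISSING).all()
            assert masked.n_sites == gm.n_sites and masked.n_samples == gm.n_samples

    @given(noisy_matrices())
    @settings(max_examples=60, deadline=None)
    def test_masks_idempotent_and_order_free(self, gm):
        ab_then_dp = mask_depth(mask_allelic_balance(gm))
        dp_then_ab = mask_allelic_balance(mask_depth(gm))
        assert np.array_equal(ab_then_dp.gt, dp_then_ab.gt)
        twice = mask_allelic_balance(mask_allelic_balance(gm))
        assert np.array_equal(twice.gt, mask_allelic_balance(gm).gt)


class TestPolarize:
    def test_concordant_outgroups_define_ancestral(self):
        gm = make_gm([[0, 1, 2]] * 2)
        og = outgroup_table(3, [("A/A", "A/A", "A/A")] * 3)
        dm = polarize(gm, og)
        assert dm.n_sites == 3
        assert list(dm.sites["ancestral"]) == ["A"] * 3
        assert list(dm.sites["derived"]) == ["G"] * 3
        assert np.array_equal(dm.dc, gm.gt)  # ancestral == ref: counts unchanged

    def test_ancestral_alt_flips_coding(self):
        gm = make_gm([[0, 1, 2, MISSING]])
        og = outgroup_table(4, [("G/G", "G/G", "G/G")] * 4)  # alt allele ancestral
        dm = polarize(gm, og)
        assert list(dm.sites["derived"]) == ["A"] * 4
        assert list(dm.dc[0]) == [2, 1, 0, MISSING]

    @pytest.mark.parametrize(
        "genos",
        [
            ("A/A", "A/A", "G/G"),  # discordant outgroup
            ("A/G", "A/A", "A/A"),  # heterozygous outgroup
            ("./.", "A/A", "A/A"),  # missing outgroup
            ("T/T", "T/T", "T/T"),  # consensus allele not ref or alt
        ],
    )
    def test_unusable_outgroups_drop_site(self, genos):
        gm = make_gm([[1]])
        dm = polarize(gm, outgroup_table(1, [genos]))
        assert dm.n_sites == 0

    def test_site_absent_from_outgroup_table_dropped(self):
        gm = make_gm([[1, 1]])
        og = outgroup_table(1, [("A/A", "A/A", "A/A")])  # only covers site 1
        assert polarize(gm, og).n_sites == 1


class TestDropInvariant:
    def test_examples(self):
        # 10 sites; sites 0-2 carry no derived allele, the rest do
        dc = np.zeros((2, 10), dtype=np.int8)
        dc[0, 3] = 1  # single het keeps a site
        dc[:, 4:10] = 2  # fixed derived sites are retained
        dm_sites = pd.DataFrame(
            {
                "chrom": ["chr1"] * 10,
                "pos": np.arange(1, 11),
                "ref": ["A"] * 10,
                "alt": ["G"] * 10,
                "ancestral": ["A"] * 10,
                "derived": ["G"] * 10,
            }
        )
        from islepop.containers import DerivedMatrix

        dm = DerivedMatrix(samples=["a", "b"], sites=dm_sites, dc=dc)
        out = drop_invariant(dm)
        assert out.n_sites == 7
        assert list(out.sites["pos"]) == list(range(4, 11))
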