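"""Contact-matrix normalization, domain structure, and SIMA resampling."""

import numpy as np
import pytest

from chromdyn.hic import (
    compartment_eigenvector,
    contact_concordance,
    expected_by_distance,
    ice_normalize,
    insulation_tads,
    observed_over_expected,
    shifted_control,
    sima,
)
from chromdyn.intervals import GenomicInterval, ScoredInterval
from chromdyn.io import ContactMatrix


def decay_matrix(n=100, exponent=1.0, rng=None, bin_size=10_000):
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    lam = 100.0 * (d + 1.0) ** (-exponent)
    if rng is not None:
        upper = rng.poisson(np.triu(lam))
        lam = upper + np.triu(upper, 1).T
    return ContactMatrix("chr1", bin_size, lam.astype(float))


class TestIce:
    def test_balanced_matrix_is_fixed_point(self):
        # constant matrix: every row sum equal, nothing to correct
        m = ContactMatrix("chr1", 10_000, np.full((50, 50), 7.0))
        norm = ice_normalize(m)
        np.testing.assert_allclose(norm.bias, 1.0, atol=1e-6)
        np.testing.assert_allclose(norm.counts, m.counts, rtol=1e-6)

    def test_planted_bias_recovered(self, rng):
        n = 80
        base = np.full((n, n), 10.0)  # balanced target
        b = rng.lognormal(0, 0.4, n)
        m = ContactMatrix("chr1", 10_000, base * np.outer(b, b))
        norm = ice_normalize(m)
        r = np.corrcoef(norm.bias, b)[0, 1]
        assert r >= 0.99

    def test_row_sums_equalized_and_symmetry_kept(self, rng):
        m = decay_matrix(60, rng=rng)
        norm = ice_normalize(m)
        s = norm.counts.sum(axis=1)
        mask = m.counts.sum(axis=1) > 0
        assert s[mask].std() / s[mask].mean() < 1e-3
        np.testing.assert_allclose(norm.counts, norm.counts.T, atol=1e-9)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            ice_normalize(ContactMatrix("chr1", 10_000, np.zeros((5, 5))))


class TestExpectedAndOE:
    def test_constant_diagonals_give_unit_oe(self):
        m = decay_matrix(40)
        oe = observed_over_expected(m)
        mask = np.ones((40, 40), dtype=bool)
        np.testing.assert_allclose(oe[mask], 1.0, atol=1e-9)

    def test_fitted_decay_slope(self, rng):
        m = decay_matrix(200, exponent=1.0, rng=rng)
        exp = expected_by_distance(m)
        d = np.arange(1, 80)
        slope = np.polyfit(np.log(d + 1), np.log(exp[1:80]), 1)[0]
        assert abs(slope + 1.0) < 0.1


class TestInsulation:
    def test_block_diagonal_boundaries_recovered(self):
        n, block = 120, 30
        mat = np.full((n, n), 1.0)
        for b in range(0, n, block):
            mat[b : b + block, b : b + block] = 10.0
        m = ContactMatrix("chr1", 10_000, mat)
        boundaries, tads = insulation_tads(m, window_bins=10)
        true = [block * k * 10_000 for k in range(1, n // block)]
        for t in true:
            assert min(abs(np.array(boundaries) - t)) <= 10_000
        assert sum(len(t) for t in tads) == n * 10_000

    def test_constant_matrix_has_no_boundaries(self):
        m = ContactMatrix("chr1", 10_000, np.full((60, 60), 5.0))
        boundaries, tads = insulation_tads(m)
        assert boundaries == [] and len(tads) == 1

    def test_matrix_smaller_than_window_rejected(self):
        m = ContactMatrix("chr1", 10_000, np.ones((5, 5)))
        with pytest.raises(ValueError):
            insulation_tads(m, window_bins=10)


class TestCompartments:
    def checkerboard(self, n=40):
        sign = np.array([1 if (i // 10) % 2 == 0 else -1 for i in range(n)])
        mat = 5.0 + np.outer(sign, sign)
        return ContactMatrix("chr1", 10_000, mat), sign

    def test_checkerboard_partitioned_by_sign(self):
        m, sign = self.checkerboard()
        ev = compartment_eigenvector(m)
        assert len(np.unique(np.sign(ev[sign == 1]))) == 1
        assert len(np.unique(np.sign(ev[sign == -1]))) == 1
        assert np.sign(ev[0]) != np.sign(ev[10])

    def test_orientation_flip_with_covariate(self):
        m, sign = self.checkerboard()
        cov = (sign > 0).astype(float)
        ev1 = compartment_eigenvector(m, orientation_covariate=cov)
        ev2 = compartment_eigenvector(m, orientation_covariate=1 - cov)
        np.testing.assert_allclose(ev1, -ev2, atol=1e-9)
        assert ev1[sign == 1].mean() > 0

    def test_unit_norm(self):
        m, _ = self.checkerboard()
        assert np.linalg.norm(compartment_eigenvector(m)) == pytest.approx(1.0)


class TestSima:
    def setup_inputs(self, rng, n=360, n_domains=6, per_domain=4):
        m = ice_normalize(decay_matrix(n, rng=rng))
        domains = [GenomicInterval("chr1", i * 500_000, (i + 1) * 500_000) for i in range(n_domains)]
        regions = []
        for d in domains:
            for _ in range(per_domain):
                start = int(rng.integers(d.start, d.end - 200))
                regions.append(GenomicInterval("chr1", start, start + 200))
        return m, domains, regions

    def test_random_regions_have_unit_strength(self, rng):
        m, domains, regions = self.setup_inputs(rng, per_domain=10)
        res = sima(domains, regions, {"chr1": m}, n_rand=300, seed=0)
        assert 0.7 <= res.median_strength <= 1.3
        assert res.signed_rank_p >= 0.01

    def test_translation_invariance_of_null(self, rng):
        m, domains, regions = self.setup_inputs(rng)
        shift = 500_000
        domains2 = [GenomicInterval(d.chrom, d.start + shift, d.end + shift) for d in domains]
        regions2 = [r.shift(shift) for r in regions]
        r1 = sima(domains, regions, {"chr1": m}, n_rand=200, seed=0)
        r2 = sima(domains2, regions2, {"chr1": m}, n_rand=200, seed=0)
        # same seed, same relative geometry: identical null placements
        np.testing.assert_allclose(r1.null_means, r2.null_means, rtol=0.2)

    def test_inter_mode_requires_same_class_pairs(self, rng):
        m, domains, regions = self.setup_inputs(rng)
        labels = ["a", "a", "b", "b", "a", "b"]
        res = sima(domains, regions, {"chr1": m}, mode="inter", domain_labels=labels,
                   block_span=5_000_000, n_rand=50, seed=0)
        for a, b in res.domain_ids:
            assert labels[a] == labels[b]

    def test_unknown_mode_rejected(self, rng):
        m, domains, regions = self.setup_inputs(rng)
        with pytest.raises(ValueError):
            sima(domains, regions, {"chr1": m}, mode="diagonal")


class TestShiftedControl:
    def test_zero_offset_is_identity(self):
        domains = [GenomicInterval("chr1", 0, 100_000)]
        regions = [GenomicInterval("chr1", 5_000, 5_200)]
        shifted, dropped = shifted_control(regions, domains, offset=0)
        assert shifted == regions and dropped == 0

    def test_region_shifted_across_boundary_dropped(self):
        domains = [GenomicInterval("chr1", 0, 10_000), GenomicInterval("chr1", 10_000, 20_000)]
        regions = [GenomicInterval("chr1", 9_000, 9_200), GenomicInterval("chr1", 1_000, 1_200)]
        shifted, dropped = shifted_control(regions, domains, offset=5_000)
        assert dropped == 1 and len(shifted) == 1
        assert shifted[0].start == 6_000


class TestContactConcordance:
    def test_identical_matrices_give_perfect_concordance(self, rng):
        m = ice_normalize(decay_matrix(100, rng=rng))
        elements = [GenomicInterval("chr1", i * 50_000, i * 50_000 + 30_000) for i in range(15)]
        res = contact_concordance(elements, {"chr1": m}, {"chr1": m})
        assert res["spearman_r"] == pytest.approx(1.0)
        np.testing.assert_allclose(res["log2_fold_change"], 0.0, atol=1e-12)

    def test_per_kb_scaling_arithmetic(self):
        # uniform matrix: pooled anchored contact grows linearly with element
        # length, so the per-kb value is length-invariant; doubling length at
        # fixed pooled contact would halve it by the same division
        mat = np.full((20, 20), 4.0)
        m = ContactMatrix("chr1", 10_000, mat)
        short = [GenomicInterval("chr1", 0, 10_000)]
        double = [GenomicInterval("chr1", 0, 20_000)]
        r1 = contact_concordance(short, {"chr1": m}, {"chr1": m}, anchored=True)
        r2 = contact_concordance(double, {"chr1": m}, {"chr1": m}, anchored=True)
        assert r1["ss"][0] == pytest.approx(r2["ss"][0], rel=0.01)
        assert r1["ss"][0] == pytest.approx(m.counts[0].sum() / 10.0)

    def test_sub_bin_elements_skipped(self):
        m = ContactMatrix("chr1", 10_000, np.ones((10, 10)))
        res = contact_concordance([GenomicInterval("chr1", 0, 500)], {"chr1": m}, {"chr1": m})
        assert res["element_indices"] == []
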