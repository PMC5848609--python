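"""DAR annotation, homotypic clustering, TAD-level differential analysis."""

import numpy as np
import pytest
from scipy import stats

from chromdyn.diffcount import DAR, estimate_dispersion, estimate_size_factors, merge_windows_to_dars
from chromdyn.diffcount import test_regions as nb_test
from chromdyn.domains import (
    annotate_dars,
    dar_gene_correlation_matrix,
    differential_tads,
    gene_tad_cross_tab,
    homotypic_spacing_test,
)
from chromdyn.diffcount import DiffResult
from chromdyn.intervals import GenomicInterval
from chromdyn.simulate import Gene


def make_dar(chrom, start, end, direction="gain", summit=None):
    return DAR(
        region=GenomicInterval(chrom, start, end), lfc=1.0 if direction == "gain" else -1.0,
        pvalue=1e-4, qvalue=1e-3, direction=direction, member_windows=[],
        summit=summit if summit is not None else (start + end) // 2,
    )


def make_gene(name, chrom, tss, length=10_000):
    return Gene(name, chrom, tss, "+", GenomicInterval(chrom, tss, tss + length, "+"))


class TestAnnotateDars:
    def test_promoter_priority_over_genic(self):
        gene = make_gene("g", "chr1", 10_000)
        dar = make_dar("chr1", 9_500, 12_000)
        (res,) = annotate_dars([dar], [gene])
        assert res.compartment == "promoter"

    def test_intergenic_when_nothing_overlaps(self):
        gene = make_gene("g", "chr1", 100_000)
        dar = make_dar("chr1", 0, 1_000)
        (res,) = annotate_dars([dar], [gene])
        assert res.compartment == "intergenic"

    def test_compartments_partition_dars(self, rng):
        genes = [make_gene(f"g{i}", "chr1", int(p)) for i, p in enumerate(np.sort(rng.integers(0, 900_000, 30)))]
        dars = [make_dar("chr1", int(s), int(s) + 2000) for s in rng.integers(0, 990_000, 100)]
        annotated = annotate_dars(dars, genes)
        counts = {}
        for a in annotated:
            counts[a.compartment] = counts.get(a.compartment, 0) + 1
        assert sum(counts.values()) == len(dars)
        assert set(counts) <= {"promoter", "genic", "intergenic"}


class TestHomotypicSpacing:
    def test_two_same_class_dars_distance(self):
        dars = [
            make_dar("chr1", 50, 150, "gain", summit=100),
            make_dar("chr1", 250, 350, "gain", summit=300),
        ]
        res = homotypic_spacing_test(dars, n_perm=5, seed=0)
        np.testing.assert_array_equal(res["gain"]["observed"], [200, 200])

    def test_random_labels_are_not_called_clustered(self, rng):
        positions = np.sort(rng.integers(0, 5_000_000, 200))
        dars = [
            make_dar("chr1", int(p), int(p) + 500, str(rng.choice(["gain", "loss"])), summit=int(p))
            for p in positions
        ]
        ps = [homotypic_spacing_test(dars, n_perm=30, seed=s)["gain"]["pvalue"] for s in range(10)]
        assert np.mean(np.array(ps) >= 0.01) >= 0.9

    def test_clustered_labels_detected(self):
        # gains packed tightly at the left end, losses spread to the right
        dars = [make_dar("chr1", 1000 * i, 1000 * i + 500, "gain", summit=1000 * i) for i in range(30)]
        dars += [make_dar("chr1", 200_000 * (i + 1), 200_000 * (i + 1) + 500, "loss",
                          summit=200_000 * (i + 1)) for i in range(30)]
        res = homotypic_spacing_test(dars, n_perm=100, seed=1)
        assert res["gain"]["pvalue"] < 0.01

    def test_singleton_class_skipped_with_warning(self):
        dars = [
            make_dar("chr1", 0, 100, "gain"),
            make_dar("chr1", 5000, 5100, "loss"),
            make_dar("chr1", 9000, 9100, "loss"),
        ]
        with pytest.warns(UserWarning):
            res = homotypic_spacing_test(dars, n_perm=5, seed=0)
        assert "gain" not in res


class TestDifferentialTads:
    def test_planted_tad_classes_recovered(self, small_chip):
        cfg, ann, truth, chip = small_chip
        sf = estimate_size_factors(chip)
        tds = differential_tads(ann.tads, chip, sf)
        truth_of = dict(zip(ann.tads, truth.tad_class))
        called_diff = [t for t in tds if t.tad_class != "unchanged"]
        # every confidently called TAD with a planted class matches it in
        # direction; several planted TADs are recovered
        expected = {"induced": "induced", "repressed": "repressed"}
        matched = [
            t for t in called_diff
            if truth_of[t.tad] != "neutral"
            and t.tad_class == expected[truth_of[t.tad]]
        ]
        wrong_direction = [
            t for t in called_diff
            if truth_of[t.tad] != "neutral" and t not in matched
        ]
        assert len(matched) >= 4
        assert len(wrong_direction) == 0

    def test_null_tads_rarely_called(self, rng):
        from conftest import small_config
        from chromdyn.simulate import plant_truth, simulate_annotation, simulate_chip_counts

        called = tested = 0
        for seed in range(3):
            cfg = small_config(frac_dar_gain=0, frac_dar_loss=0, seed=100 + seed)
            ann = simulate_annotation(cfg)
            truth = plant_truth(ann, cfg)
            chip = simulate_chip_counts(ann, truth, cfg)
            sf = estimate_size_factors(chip)
            tds = differential_tads(ann.tads, chip, sf)
            tested += len(tds)
            called += sum(t.tad_class != "unchanged" for t in tds)
        assert called / tested <= 0.04

    def test_empty_tads_excluded(self, small_chip):
        cfg, ann, truth, chip = small_chip
        sf = estimate_size_factors(chip)
        empty = GenomicInterval("chrX", 0, 1_000_000)
        tds = differential_tads([empty], chip, sf)
        assert tds == []


class TestGeneTadCrossTab:
    def make_inputs(self):
        from chromdyn.domains import TadDiff

        tads = [
            TadDiff(GenomicInterval("chr1", 0, 1_000_000), 1, 1, 1.0, 1e-4, 1e-3, "induced", 5),
            TadDiff(GenomicInterval("chr1", 1_000_000, 2_000_000), 1, 1, 0.0, 0.5, 0.9, "unchanged", 5),
        ]
        genes = [
            DiffResult(GenomicInterval("chr1", 100, 10_000), 2.0, 1e-5, 1e-4, "gain"),
            DiffResult(GenomicInterval("chr1", 1_500_000, 1_510_000), 0.0, 0.9, 0.95, "none"),
        ]
        tss = [("chr1", 100), ("chr1", 1_500_000)]
        return genes, tads, tss

    def test_counts_conserve(self):
        genes, tads, tss = self.make_inputs()
        res = gene_tad_cross_tab(genes, tads, tss)
        total = sum(sum(row.values()) for row in res["counts"].values())
        assert total == res["n_assigned"] == 2

    def test_concentrated_enrichment_closed_form(self):
        genes, tads, tss = self.make_inputs()
        res = gene_tad_cross_tab(genes, tads, tss)
        # all "gain" genes sit in induced TADs; baseline fraction is 1/2
        assert res["fractions"]["gain"]["induced"] == 1.0
        assert res["enrichment"]["gain"]["induced"] == pytest.approx(1 / res["baseline"]["induced"])


class TestDarGeneCorrelation:
    def test_identical_counts_give_unit_correlation(self):
        from chromdyn.domains import TadDiff

        tads = [
            TadDiff(GenomicInterval("chr1", i * 100_000, (i + 1) * 100_000), 1, 1, 1.0, 1e-4, 1e-3, "induced", 3)
            for i in range(5)
        ]
        dars, genes, tss = [], [], []
        for i, n in enumerate([1, 2, 3, 4, 5]):
            for k in range(n):
                start = i * 100_000 + 1000 * (k + 1)
                dars.append(make_dar("chr1", start, start + 500, "gain", summit=start))
                genes.append(DiffResult(GenomicInterval("chr1", start, start + 10), 1.0, 1e-5, 1e-4, "gain"))
                tss.append(("chr1", start))
        res = dar_gene_correlation_matrix(tads, dars, genes, tss)
        i, j = res["names"].index("dar_gain"), res["names"].index("gene_up")
        assert res["matrix"][i, j] == pytest.approx(1.0)

    def test_spearman_equals_rank_then_pearson(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        expected = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert stats.spearmanr(x, y).statistic == pytest.approx(expected)

    def test_too_few_differential_tads_rejected(self):
        with pytest.raises(ValueError):
            dar_gene_correlation_matrix([], [], [], [])
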