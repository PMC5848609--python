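"""Generator invariants: determinism, planted-effect recovery, layout."""

import numpy as np
import pytest

from chromdyn.simulate import (
    SyntheticConfig,
    plant_truth,
    simulate_annotation,
    simulate_chip_counts,
    simulate_hic,
    simulate_pchic,
    simulate_rna_counts,
    simulate_sequences_and_tf,
)
from conftest import small_config


class TestConfig:
    @pytest.mark.parametrize("field,value", [
        ("frac_dar_gain", 1.5), ("tad_cluster_prob", -0.1),
        ("nb_dispersion", 0.0), ("n_tads", 0),
    ])
    def test_invalid_values_rejected(self, field, value):
        with pytest.raises(ValueError):
            SyntheticConfig(**{field: value})


class TestAnnotation:
    def test_single_tad_spans_chromosome(self):
        cfg = small_config(n_tads=1, n_genes=20, n_enhancers=30)
        ann = simulate_annotation(cfg)
        (tad,) = ann.tads
        assert tad.start == 0 and tad.end == cfg.chrom_length

    def test_tads_tile_and_elements_fall_inside(self):
        cfg = small_config(seed=2)
        ann = simulate_annotation(cfg)
        pos = 0
        for t in ann.tads:
            assert t.start == pos
            pos = t.end
        assert pos == cfg.chrom_length
        starts = np.array([t.start for t in ann.tads])
        ends = np.array([t.end for t in ann.tads])
        for el in ann.elements:
            mid = el.interval.midpoint
            k = np.searchsorted(starts, mid, side="right") - 1
            assert starts[k] <= mid < ends[k]

    def test_fragments_tile_genome(self):
        cfg = small_config(seed=2)
        ann = simulate_annotation(cfg)
        pos = 0
        for f in ann.fragments:
            assert f.start == pos
            pos = f.end
        assert pos == cfg.chrom_length
        lengths = [len(f) for f in ann.fragments]
        assert 2_000 < np.mean(lengths) < 6_000

    def test_seed_determinism_and_divergence(self):
        a1 = simulate_annotation(small_config(seed=7))
        a2 = simulate_annotation(small_config(seed=7))
        a3 = simulate_annotation(small_config(seed=8))
        assert a1.tads == a2.tads and a1.enhancers == a2.enhancers
        assert a1.tads != a3.tads


class TestChipCounts:
    def test_seed_determinism(self):
        cfg = small_config(seed=5)
        ann = simulate_annotation(cfg)
        truth = plant_truth(ann, cfg)
        m1 = simulate_chip_counts(ann, truth, cfg)
        m2 = simulate_chip_counts(ann, truth, cfg)
        np.testing.assert_array_equal(m1.counts, m2.counts)

    def test_null_lfc_centred_at_zero(self):
        cfg = small_config(frac_dar_gain=0.0, frac_dar_loss=0.0, seed=6)
        ann = simulate_annotation(cfg)
        truth = plant_truth(ann, cfg)
        cm = simulate_chip_counts(ann, truth, cfg)
        sf = np.asarray(cfg.size_factors_true)
        y = cm.counts / sf
        marked = y.mean(axis=1) > 20
        lfc = np.log2(y[marked][:, 2:].mean(axis=1) + 0.5) - np.log2(y[marked][:, :2].mean(axis=1) + 0.5)
        assert abs(np.mean(lfc)) < 0.05

    def test_planted_lfc_recovered_at_high_depth(self):
        cfg = small_config(
            dar_lfc_mean=1.0, dar_lfc_sd=1e-9, depth_per_sample=1e7, seed=6,
            nb_dispersion=0.01,
        )
        ann = simulate_annotation(cfg)
        truth = plant_truth(ann, cfg)
        cm = simulate_chip_counts(ann, truth, cfg)
        sf = np.asarray(cfg.size_factors_true)
        y = cm.counts / sf
        win_index = {(w.chrom, w.start): i for i, w in enumerate(cm.regions)}
        lfcs = []
        for region in truth.dar_regions:
            mid = region.interval.midpoint
            wi = win_index.get((region.interval.chrom, (mid // 1000) * 1000))
            if wi is None:
                continue
            lfc = np.log2(y[wi, 2:].mean() + 0.5) - np.log2(y[wi, :2].mean() + 0.5)
            lfcs.append(lfc if region.label == "gain" else -lfc)
        assert abs(np.mean(lfcs) - 1.0) <= 0.1

    def test_mean_variance_consistent_with_dispersion(self):
        cfg = small_config(seed=9, frac_dar_gain=0, frac_dar_loss=0)
        ann = simulate_annotation(cfg)
        truth = plant_truth(ann, cfg)
        cm = simulate_chip_counts(ann, truth, cfg)
        y = cm.counts / np.asarray(cfg.size_factors_true)
        mu = y.mean(axis=1)
        marked = mu > 50
        s2 = y[marked].var(axis=1, ddof=1)
        alpha_hat = np.median((s2 - mu[marked]) / mu[marked] ** 2)
        assert cfg.nb_dispersion / 2 <= alpha_hat <= cfg.nb_dispersion * 2


class TestRnaCounts:
    def test_planted_gene_lfc_recovered(self):
        cfg = small_config(gene_lfc_mean=2.0, seed=10, nb_dispersion=0.01)
        ann = simulate_annotation(cfg)
        truth = plant_truth(ann, cfg)
        cm = simulate_rna_counts(ann, truth, cfg)
        y = cm.counts / np.asarray(cfg.size_factors_true)
        diff = [i for i, c in enumerate(truth.gene_class) if c != "null"]
        lfc = np.log2(y[diff, 2:].mean(axis=1) + 0.5) - np.log2(y[diff, :2].mean(axis=1) + 0.5)
        signed = np.where(np.array(truth.gene_class)[diff] == "gain", lfc, -lfc)
        planted = np.abs(truth.gene_lfc[diff])
        assert abs(np.mean(signed - planted)) <= 0.2

    def test_null_genes_centred(self):
        cfg = small_config(seed=10)
        ann = simulate_annotation(cfg)
        truth = plant_truth(ann, cfg)
        cm = simulate_rna_counts(ann, truth, cfg)
        y = cm.counts / np.asarray(cfg.size_factors_true)
        nulls = [i for i, c in enumerate(truth.gene_class) if c == "null"]
        lfc = np.log2(y[nulls, 2:].mean(axis=1) + 0.5) - np.log2(y[nulls, :2].mean(axis=1) + 0.5)
        assert abs(np.mean(lfc)) < 0.1


class TestHic:
    def test_seed_determinism(self):
        cfg = small_config(seed=11)
        ann = simulate_annotation(cfg)
        truth = plant_truth(ann, cfg)
        h1 = simulate_hic(ann, truth, cfg)
        h2 = simulate_hic(ann, truth, cfg)
        np.testing.assert_array_equal(h1["SS"]["chr1"].counts, h2["SS"]["chr1"].counts)

    def test_decay_matches_configured_exponent(self):
        cfg = small_config(tad_boost=1.0, seed=11)
        ann = simulate_annotation(cfg)
        truth = plant_truth(ann, cfg)
        mat = simulate_hic(ann, truth, cfg)["SS"]["chr1"].counts
        n = mat.shape[0]
        dists = np.arange(1, 60)
        means = np.array([np.diagonal(mat, d).mean() for d in dists])
        slope = np.polyfit(np.log(dists + 1), np.log(means), 1)[0]
        assert abs(slope + cfg.hic_decay_exponent) < 0.1

    def test_tad_boost_visible_in_oe(self):
        cfg = small_config(tad_boost=3.0, seed=11)
        ann = simulate_annotation(cfg)
        truth = plant_truth(ann, cfg)
        mat = simulate_hic(ann, truth, cfg)["SS"]["chr1"].counts
        bs = cfg.bin_size
        tad_id = np.full(mat.shape[0], -1)
        for ti, t in enumerate(ann.tads):
            tad_id[t.start // bs : t.end // bs] = ti
        d = 5  # compare intra vs inter at matched distance
        diag = np.diagonal(mat, d)
        same = tad_id[: len(diag)] == tad_id[d : d + len(diag)]
        ratio = diag[same].mean() / diag[~same].mean()
        assert 2.4 <= ratio <= 3.6


class TestPchic:
    def test_median_pir_count(self):
        cfg = small_config(n_genes=500, seed=13)
        ann = simulate_annotation(cfg)
        truth = plant_truth(ann, cfg)
        recs = simulate_pchic(ann, truth, cfg)
        per_gene = {}
        for r in recs:
            per_gene.setdefault(r.gene, set()).add((r.other_end.start, r.other_end.end))
        counts = [len(v) for v in per_gene.values()]
        assert np.median(counts) in (12, 13, 14)

    def test_score_monotone_in_frequency(self):
        cfg = small_config(score_noise=0.0, seed=13)
        ann = simulate_annotation(cfg)
        truth = plant_truth(ann, cfg)
        recs = simulate_pchic(ann, truth, cfg)
        by_gene = {}
        for r in recs:
            by_gene.setdefault(r.gene, []).append(r)
        checked = 0
        for recs_g in by_gene.values():
            if len(recs_g) < 3:
                continue
            ds = [abs(r.bait.midpoint - r.other_end.midpoint) for r in recs_g]
            order = np.argsort(ds)
            for a, b in zip(order, order[1:]):
                # compare per-kb enrichment at matched distance: the score is
                # monotone in frequency relative to the distance expectation
                if abs(ds[a] - ds[b]) >= 5_000:
                    continue
                fa, fb = recs_g[a], recs_g[b]
                ea = fa.freq_ss / len(fa.other_end)
                eb = fb.freq_ss / len(fb.other_end)
                if abs(np.log(ea / eb)) > 0.7:
                    hi, lo = (fa, fb) if ea > eb else (fb, fa)
                    assert hi.score_ss > lo.score_ss
                    checked += 1
        assert checked > 5

    def test_seed_determinism(self):
        cfg = small_config(seed=14)
        ann = simulate_annotation(cfg)
        truth = plant_truth(ann, cfg)
        assert simulate_pchic(ann, truth, cfg) == simulate_pchic(ann, truth, cfg)


class TestSequencesAndTf:
    def test_perfect_peaks_separate_classes(self):
        cfg = small_config(tf_sensitivity=1.0, tf_specificity=1.0, seed=15)
        ann = simulate_annotation(cfg)
        truth = plant_truth(ann, cfg)
        _, peaks, _ = simulate_sequences_and_tf(ann, truth, cfg)
        from chromdyn.intervals import overlap_pairs

        els = [e.interval for e in ann.elements]
        hit = np.zeros(len(els), dtype=bool)
        for i, _ in overlap_pairs(els, peaks["MYC"]):
            hit[i] = True
        classes = np.array(truth.element_class)
        assert hit[classes == "gain"].all()
        assert not hit[classes != "gain"].any()

    def test_no_embedding_means_no_class_difference(self):
        cfg = small_config(motif_embed_prob=0.0, seed=15)
        ann = simulate_annotation(cfg)
        truth = plant_truth(ann, cfg)
        seqs, _, pwms = simulate_sequences_and_tf(ann, truth, cfg)
        from chromdyn.predictor import scan_pwms

        gain = [seqs[f"element{i:04d}"] for i, c in enumerate(truth.element_class) if c == "gain"]
        loss = [seqs[f"element{i:04d}"] for i, c in enumerate(truth.element_class) if c == "loss"]
        gas = [p for p in pwms if p.name == "GAS_STAT"]
        cg, _, _ = scan_pwms(gain, gas)
        cl, _, _ = scan_pwms(loss, gas)
        # hit counts in the two classes are exchangeable background noise
        from scipy import stats as sps

        assert sps.mannwhitneyu(cg.ravel(), cl.ravel()).pvalue > 0.01

    def test_seed_determinism(self):
        cfg = small_config(seed=16)
        ann = simulate_annotation(cfg)
        truth = plant_truth(ann, cfg)
        s1, p1, _ = simulate_sequences_and_tf(ann, truth, cfg)
        s2, p2, _ = simulate_sequences_and_tf(ann, truth, cfg)
        assert s1 == s2 and p1 == p2
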