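"""Config-driven orchestration of the full analysis on synthetic data.

Stages run in dependency order: counts -> DARs -> TAD/domain analysis ->
Hi-C normalization + SIMA -> super-enhancers -> cis-regulatory units ->
predictive modelling. Each stage writes TSV outputs and contributes
headline numbers to a JSON summary; a single global seed is fanned out
into named per-stage substreams so stages are individually reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .cru import build_crus, permutation_test, pir_stats
from .diffcount import (
    call_differential_genes,
    estimate_dispersion,
    estimate_size_factors,
    merge_windows_to_dars,
    test_regions,
)
from .domains import (
    annotate_dars,
    dar_gene_correlation_matrix,
    differential_tads,
    gene_tad_cross_tab,
    homotypic_spacing_test,
)
from .hic import ice_normalize, insulation_tads, sima, sima_compare_conditions
from .intervals import ScoredInterval
from .predictor import kmer_features, tf_and_hic_features, train_eval_forest, train_eval_lasso
from .simulate import SyntheticConfig, simulate_all
from .summaries import (
    cru_significance_summary,
    dar_class_summary,
    intra_chromosomal_summary,
    se_response_summary,
)
from .superenhancers import call_super_enhancers, differential_ses, pchic_se_targets

log = logging.getLogger("chromdyn.pipeline")

_STAGE_SEEDS = {"dars": 11, "domains": 12, "hic": 13, "se": 14, "cru": 15, "predict": 16}


def _stage_seed(global_seed: int, stage: str) -> int:
    return int(np.random.SeedSequence([global_seed, _STAGE_SEEDS[stage]]).generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Validated parameters for every stage.

    ``generate`` holds SyntheticConfig overrides; the remaining blocks
    hold per-stage parameters. Unknown keys are rejected.
    """

    seed: int = 0
    generate: dict = field(default_factory=dict)
    dar: dict = field(default_factory=dict)
    tad: dict = field(default_factory=dict)
    sima: dict = field(default_factory=dict)
    se: dict = field(default_factory=dict)
    cru: dict = field(default_factory=dict)
    predict: dict = field(default_factory=dict)

    _ALLOWED = {
        "dar": {"max_gap", "fdr", "min_abundance"},
        "tad": {"fdr"},
        "sima": {"n_rand", "block_span"},
        "se": {"stitch_gap", "tss_exclusion_flank", "fdr"},
        "cru": {"n_perm", "fdr", "min_fragments", "min_score"},
        "predict": {"n_models", "n_folds", "n_boot", "test_frac"},
    }

    def __post_init__(self) -> None:
        gen_fields = {f.name for f in dataclasses.fields(SyntheticConfig)} - {"seed"}
        unknown = set(self.generate) - gen_fields
        if unknown:
            raise ValueError(f"unknown generate keys: {sorted(unknown)}")
        for block, allowed in self._ALLOWED.items():
            unknown = set(getattr(self, block)) - allowed
            if unknown:
                raise ValueError(f"unknown {block} keys: {sorted(unknown)}")
        for block in ("dar", "tad", "se", "cru"):
            fdr = getattr(self, block).get("fdr")
            if fdr is not None and not (0 < fdr < 1):
                raise ValueError(f"{block}.fdr must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _write_tsv(path: Path, header: list, rows) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage on a synthetic dataset; return the summary dict.

    Writes per-stage TSVs, ``summary.json`` and ``run.log`` to ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    summary: dict = {"version": __version__, "seed": config.seed}
    try:
        log.info("chromdyn %s, global seed %d", __version__, config.seed)

        # ------------------------------------------------------ generate
        syn = SyntheticConfig(seed=config.seed, **config.generate)
        data = simulate_all(syn)
        ann, truth = data["annotation"], data["truth"]
        chip, rna = data["chip"], data["rna"]
        log.info("generated %d windows, %d genes, %d enhancers",
                 len(chip.regions), len(ann.genes), len(ann.enhancers))

        # ----------------------------------------------------------- DARs
        sf = estimate_size_factors(chip)
        chip.size_factors = sf
        disp = estimate_dispersion(chip, sf)
        ws = test_regions(chip, sf, disp)
        dars = merge_windows_to_dars(
            ws,
            max_gap=config.dar.get("max_gap", 100),
            fdr=config.dar.get("fdr", 0.01),
            min_abundance=config.dar.get("min_abundance", 5.0),
        )
        n_gain = sum(d.direction == "gain" for d in dars)
        n_loss = sum(d.direction == "loss" for d in dars)
        summary["dars"] = dar_class_summary(n_gain, n_loss)
        _write_tsv(
            outdir / "dars.tsv",
            ["chrom", "start", "end", "direction", "lfc", "qvalue", "summit"],
            [(d.region.chrom, d.region.start, d.region.end, d.direction,
              f"{d.lfc:.4f}", f"{d.qvalue:.3e}", d.summit) for d in dars],
        )
        log.info("called %d DARs (%d gain / %d loss)", len(dars), n_gain, n_loss)

        # --------------------------------------------------------- genes
        genes_diff = call_differential_genes(rna)
        gene_tss = [(g.chrom, g.tss) for g in ann.genes]
        summary["genes"] = {
            "n_up": sum(g.direction == "gain" for g in genes_diff),
            "n_down": sum(g.direction == "loss" for g in genes_diff),
        }

        # ------------------------------------------------------- domains
        dhs_sets = {
            "promoter_dhs": ann.promoters,
            "enhancer_dhs": ann.enhancers,
        }
        annotated = annotate_dars(dars, ann.genes, dhs_sets=dhs_sets)
        comp_counts: dict[str, int] = {}
        for a in annotated:
            comp_counts[a.compartment] = comp_counts.get(a.compartment, 0) + 1
        summary["dar_annotation"] = comp_counts
        spacing = homotypic_spacing_test(dars, n_perm=50, seed=_stage_seed(config.seed, "domains"))
        summary["homotypic_spacing_p"] = {k: v["pvalue"] for k, v in spacing.items()}
        tad_diffs = differential_tads(ann.tads, chip, sf, fdr=config.tad.get("fdr", 0.01))
        summary["tads"] = {
            "n_induced": sum(t.tad_class == "induced" for t in tad_diffs),
            "n_repressed": sum(t.tad_class == "repressed" for t in tad_diffs),
            "n_tested": len(tad_diffs),
        }
        _write_tsv(
            outdir / "tads.tsv",
            ["chrom", "start", "end", "class", "lfc", "qvalue", "per_kb_ss", "per_kb_tpo"],
            [(t.tad.chrom, t.tad.start, t.tad.end, t.tad_class, f"{t.lfc:.4f}",
              f"{t.qvalue:.3e}", f"{t.signal_per_kb_ss:.3f}", f"{t.signal_per_kb_tpo:.3f}")
             for t in tad_diffs],
        )
        cross = gene_tad_cross_tab(genes_diff, tad_diffs, gene_tss)
        summary["gene_tad_enrichment"] = {
            g: {t: (None if not np.isfinite(v) else round(v, 3)) for t, v in row.items()}
            for g, row in cross["enrichment"].items()
        }
        try:
            corr = dar_gene_correlation_matrix(tad_diffs, dars, genes_diff, gene_tss)
            summary["dar_gene_spearman"] = [
                [None if not np.isfinite(x) else round(float(x), 3) for x in row]
                for row in corr["matrix"]
            ]
        except ValueError:
            summary["dar_gene_spearman"] = None

        # ---------------------------------------------------------- Hi-C
        norm = {
            cond: {c: ice_normalize(m) for c, m in mats.items()}
            for cond, mats in data["hic"].items()
        }
        boundaries = {
            c: insulation_tads(norm["SS"][c])[0] for c in ann.chrom_sizes
        }
        summary["n_insulation_boundaries"] = {c: len(b) for c, b in boundaries.items()}
        diff_tad_ivs = [t.tad for t in tad_diffs if t.tad_class != "unchanged"]
        dar_enh = [
            ScoredInterval(iv, 0.0, cls)
            for iv, cls in zip(ann.enhancers,
                               truth.element_class[len(ann.promoters):])
            if cls != "null"
        ]
        sima_seed = _stage_seed(config.seed, "hic")
        n_rand = config.sima.get("n_rand", 500)
        sima_res = {}
        for cond in ("SS", "TPO"):
            sima_res[cond] = sima(
                diff_tad_ivs, dar_enh, norm[cond], mode="intra",
                n_rand=n_rand, seed=sima_seed,
            )
        summary["sima"] = {
            cond: {
                "median_strength": round(r.median_strength, 4),
                "signed_rank_p": r.signed_rank_p,
                "n_domains": len(r.strengths),
            }
            for cond, r in sima_res.items()
        }
        summary["sima"]["between_condition_p"] = sima_compare_conditions(
            sima_res["SS"], sima_res["TPO"]
        )

        # ------------------------------------------------ super-enhancers
        norm_chip = chip.counts / sf
        cols_ss = chip.condition_columns("SS")
        win_signal_ss = norm_chip[:, cols_ss].mean(axis=1)
        from .intervals import GenomicInterval, overlap_pairs

        enh_signal = np.zeros(len(ann.enhancers))
        for ei, wi in overlap_pairs(ann.enhancers, chip.regions):
            enh_signal[ei] += win_signal_ss[wi]
        flank = config.se.get("tss_exclusion_flank", 2_500)
        tss_zones = [
            GenomicInterval(g.chrom, max(0, g.tss - flank), g.tss + flank)
            for g in ann.genes
        ]
        ses, curve = call_super_enhancers(
            ann.enhancers, enh_signal,
            stitch_gap=config.se.get("stitch_gap", 12_500),
            tss_exclusion=tss_zones,
        )
        tested_ses = differential_ses(ses, chip, sf, fdr=config.se.get("fdr", 0.01))
        n_ind = sum(s.direction == "gain" for s in tested_ses)
        n_rep = sum(s.direction == "loss" for s in tested_ses)
        summary["super_enhancers"] = se_response_summary(n_ind, n_rep, len(ses))
        se_targets = pchic_se_targets(ses, data["pchic"])
        summary["super_enhancers"]["pchic_fraction_anchored_pct"] = round(
            100 * se_targets["fraction_anchored"], 1
        )
        _write_tsv(
            outdir / "super_enhancers.tsv",
            ["chrom", "start", "end", "rank", "signal", "direction", "qvalue"],
            [(s.region.chrom, s.region.start, s.region.end, s.rank,
              f"{s.signal:.2f}", s.direction, f"{s.qvalue:.3e}") for s in ses],
        )

        # ------------------------------------------------------------ CRUs
        n_intra = sum(r.is_intra for r in data["pchic"])
        summary["interactions"] = intra_chromosomal_summary(n_intra, len(data["pchic"]))
        pstats = pir_stats(
            data["pchic"],
            diff_genes={ann.genes[i].name: genes_diff[i].direction
                        for i in range(len(ann.genes))},
        )
        summary["median_pirs"] = pstats["median_pirs"]
        # the tested units are differentially transcribed promoters
        diff_names = {
            ann.genes[i].name
            for i in range(len(ann.genes))
            if genes_diff[i].direction != "none"
        }
        cru_interactions = [r for r in data["pchic"] if r.gene in diff_names]
        crus = build_crus(
            cru_interactions, dars, chip, sf,
            min_fragments=config.cru.get("min_fragments", 5),
            min_score=config.cru.get("min_score", 5.0),
        )
        if len(crus) >= 2:
            crus, sig = permutation_test(
                crus,
                n_perm=config.cru.get("n_perm", 500),
                fdr=config.cru.get("fdr", 0.05),
                seed=_stage_seed(config.seed, "cru"),
            )
            summary["crus"] = cru_significance_summary(len(sig), len(crus))
            _write_tsv(
                outdir / "crus.tsv",
                ["gene", "n_members", "spearman_r", "pvalue", "qvalue"],
                [(c.gene, c.n_members, f"{c.spearman_r:.4f}", f"{c.pvalue:.4f}",
                  f"{c.qvalue:.4f}")
                 for c in sorted(crus, key=lambda c: -(c.spearman_r if np.isfinite(c.spearman_r) else -9))],
            )
        else:
            summary["crus"] = cru_significance_summary(0, len(crus))

        # ------------------------------------------------------- predictor
        labels_map = {"gain": 1, "loss": 0}
        dar_regions = [d.region for d in dars if d.direction in labels_map]
        elements = ann.elements
        el_ivs = [e.interval for e in elements]
        el_dir = [""] * len(elements)
        for ei, di_ in overlap_pairs(el_ivs, dar_regions):
            d = [d for d in dars if d.direction in labels_map][di_]
            el_dir[ei] = d.direction
        use = [i for i, c in enumerate(el_dir) if c in labels_map]
        y = np.array([labels_map[el_dir[i]] for i in use])
        seqs = [data["sequences"][f"element{i:04d}"] for i in use]
        regions = [el_ivs[i] for i in use]
        pred_seed = _stage_seed(config.seed, "predict")
        n_models = config.predict.get("n_models", 5)
        n_folds = config.predict.get("n_folds", 5)
        summary["predictor"] = {}
        if len(np.unique(y)) == 2 and min(np.bincount(y)) >= 30:
            kmer_X, _ = kmer_features(seqs)
            tfhic_X, tfhic_names, fams = tf_and_hic_features(
                regions, data["tf_peaks"],
                {"SS": norm["SS"], "TPO": norm["TPO"]},
            )
            fams = np.array(fams)
            tf_X = tfhic_X[:, fams == "tf_chip"]
            hic_X = tfhic_X[:, fams == "hic"]
            for name, X in (("tf", tf_X), ("hic", hic_X), ("kmer", kmer_X),
                            ("combined", np.column_stack([kmer_X, tfhic_X]))):
                res = train_eval_lasso(
                    X, y, n_models=n_models, n_folds=n_folds, seed=pred_seed
                )
                summary["predictor"][f"auc_{name}"] = round(res["auc_mean"], 4)
            forest = train_eval_forest(tf_X, y, n_models=n_models, seed=pred_seed)
            summary["predictor"]["auc_tf_forest"] = round(forest["auc_mean"], 4)
        else:
            log.warning("too few labelled elements for the predictor stage")

        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        log.info("pipeline complete")
        return summary
    finally:
        log.removeHandler(handler)
        handler.close()
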