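"""Spatial organization of differentially acetylated regions.

Covers genomic annotation of DARs, the homotypic-spacing clustering test,
TAD-level differential acetylation, and the cross-analysis of
differentially transcribed genes against differentially acetylated TADs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .diffcount import CountMatrix, estimate_dispersion, test_regions
from .intervals import GenomicInterval, overlap_pairs

__all__ = [
    "AnnotatedDAR",
    "TadDiff",
    "annotate_dars",
    "homotypic_spacing_test",
    "differential_tads",
    "gene_tad_cross_tab",
    "dar_gene_correlation_matrix",
]


@dataclass
class AnnotatedDAR:
    dar: object
    compartment: str      # promoter / genic / intergenic
    element_class: str    # promoter_dhs / enhancer_dhs / none


@dataclass
class TadDiff:
    tad: GenomicInterval
    signal_per_kb_ss: float
    signal_per_kb_tpo: float
    lfc: float
    pvalue: float
    qvalue: float
    tad_class: str        # induced / repressed / unchanged
    n_windows: int


def annotate_dars(dars, genes, promoter_flank: int = 2_000, dhs_sets: dict | None = None):
    """Assign each DAR a genomic compartment and a DHS element class.

    Compartment priority: promoter (overlaps a TSS +/- ``promoter_flank``)
    > genic (overlaps a gene body) > intergenic. ``dhs_sets`` maps
    element-class names (e.g. "promoter_dhs", "enhancer_dhs") to interval
    lists; the first class (in dict order) with an overlap wins.
    """
    regions = [d.region for d in dars]
    tss_windows = [
        GenomicInterval(g.chrom, max(0, g.tss - promoter_flank), g.tss + promoter_flank)
        for g in genes
    ]
    bodies = [g.body for g in genes]
    promoter_hits = {i for i, _ in overlap_pairs(regions, tss_windows)}
    genic_hits = {i for i, _ in overlap_pairs(regions, bodies)}
    element = ["none"] * len(dars)
    if dhs_sets:
        for cls, intervals in dhs_sets.items():
            ivs = [getattr(x, "interval", x) for x in intervals]
            for i, _ in overlap_pairs(regions, ivs):
                if element[i] == "none":
                    element[i] = cls
    out = []
    for i, d in enumerate(dars):
        if i in promoter_hits:
            comp = "promoter"
        elif i in genic_hits:
            comp = "genic"
        else:
            comp = "intergenic"
        out.append(AnnotatedDAR(d, comp, element[i]))
    return out


def homotypic_spacing_test(dars, n_perm: int = 100, seed: int = 0) -> dict:
    """Observed vs label-randomized distances between nearest homotypic DARs.

    For each class, the observed statistic is each DAR's distance (summit
    to summit) to the nearest DAR of the same class on the same
    chromosome; the null pools the same statistic over ``n_perm``
    permutations of class labels across all DAR positions. A one-sided
    Wilcoxon rank-sum tests observed < null (clustering). Classes with
    < 2 members are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    positions = np.array([d.summit for d in dars])
    chroms = np.array([d.region.chrom for d in dars])
    labels = np.array([d.direction for d in dars])

    def nearest_same(labels_arr, cls):
        dists = []
        for c in np.unique(chroms):
            sel = (chroms == c) & (labels_arr == cls)
            pos = np.sort(positions[sel])
            if len(pos) < 2:
                continue
            gaps = np.diff(pos)
            d = np.minimum(
                np.concatenate([[gaps[0]], gaps]),
                np.concatenate([gaps, [gaps[-1]]]),
            )
            dists.append(d)
        return np.concatenate(dists) if dists else np.array([])

    out = {}
    for cls in [c for c in np.unique(labels) if c not in ("none",)]:
        if (labels == cls).sum() < 2:
            warnings.warn(f"class {cls!r} has < 2 DARs; skipped")
            continue
        observed = nearest_same(labels, cls)
        null = []
        for _ in range(n_perm):
            null.append(nearest_same(rng.permutation(labels), cls))
        null = np.concatenate([x for x in null if len(x)]) if null else np.array([])
        if len(observed) and len(null):
            p = float(stats.ranksums(observed, null, alternative="less").pvalue)
        else:
            p = float("nan")
        out[cls] = {"observed": observed, "null": null, "pvalue": p}
    return out


def differential_tads(
    tads,
    window_counts: CountMatrix,
    size_factors: np.ndarray,
    fdr: float = 0.01,
    min_abundance: float = 5.0,
) -> list[TadDiff]:
    """Per-TAD differential acetylation from summed member-window counts.

    Only windows above the marked-signal abundance floor contribute (a TAD
    "contains" a window when the window midpoint falls inside it); TADs
    with no such windows are excluded. The NB test uses an offset of
    log(TAD length) so reported abundances are per-kb comparable.
    """
    y = window_counts.counts / size_factors
    marked = y.mean(axis=1) >= min_abundance
    windows = window_counts.regions
    sums = np.zeros((len(tads), window_counts.counts.shape[1]), dtype=np.int64)
    n_win = np.zeros(len(tads), dtype=int)
    tad_by_chrom: dict[str, list[int]] = {}
    for ti, t in enumerate(tads):
        tad_by_chrom.setdefault(t.chrom, []).append(ti)
    starts = {
        c: np.array([tads[i].start for i in idx]) for c, idx in tad_by_chrom.items()
    }
    for wi, w in enumerate(windows):
        if not marked[wi]:
            continue
        idx = tad_by_chrom.get(w.chrom)
        if not idx:
            continue
        pos = np.searchsorted(starts[w.chrom], w.midpoint, side="right") - 1
        if pos < 0:
            continue
        ti = idx[pos]
        if tads[ti].start <= w.midpoint < tads[ti].end:
            sums[ti] += window_counts.counts[wi]
            n_win[ti] += 1

    keep = np.flatnonzero(n_win > 0)
    if len(keep) == 0:
        return []
    cm = CountMatrix([tads[i] for i in keep], sums[keep], window_counts.samples)
    dispersions = estimate_dispersion(cm, size_factors)
    offsets = np.log([float(len(tads[i])) for i in keep])
    ws = test_regions(cm, size_factors, dispersions, offsets=offsets)
    pvals = np.array([w.pvalue for w in ws])
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    s = np.asarray(size_factors)
    out = []
    for k, (ti, w, q) in enumerate(zip(keep, ws, qvals)):
        cols_ss = cm.condition_columns("SS")
        cols_tpo = cm.condition_columns("TPO")
        norm = cm.counts / s
        kb = len(tads[ti]) / 1000.0
        if q <= fdr and w.lfc != 0:
            cls = "induced" if w.lfc > 0 else "repressed"
        else:
            cls = "unchanged"
        out.append(
            TadDiff(
                tad=tads[ti],
                signal_per_kb_ss=float(norm[k, cols_ss].mean() / kb),
                signal_per_kb_tpo=float(norm[k, cols_tpo].mean() / kb),
                lfc=w.lfc,
                pvalue=w.pvalue,
                qvalue=float(q),
                tad_class=cls,
                n_windows=int(n_win[ti]),
            )
        )
    return out


_GENE_CLASSES = ["gain", "loss", "none"]
_TAD_CLASSES = ["induced", "repressed", "unchanged"]


def gene_tad_cross_tab(diff_genes, tad_diffs, gene_tss) -> dict:
    """Cross-tabulate gene classes against the class of their host TAD.

    ``gene_tss`` gives each gene's TSS position (parallel to
    ``diff_genes``); a gene is assigned to the (at most one) TAD
    containing its TSS. Returns counts, within-gene-class fractions
    across TAD classes, and fold enrichment against the all-genes
    baseline distribution over TAD classes.
    """
    tad_class_of = []
    for tss, dg in zip(gene_tss, diff_genes):
        cls = None
        for td in tad_diffs:
            if td.tad.chrom == tss[0] and td.tad.start <= tss[1] < td.tad.end:
                cls = td.tad_class
                break
        tad_class_of.append(cls)
    counts = {g: {t: 0 for t in _TAD_CLASSES} for g in _GENE_CLASSES}
    for dg, tc in zip(diff_genes, tad_class_of):
        if tc is None:
            continue
        counts[dg.direction][tc] += 1
    total_by_tad = {t: sum(counts[g][t] for g in _GENE_CLASSES) for t in _TAD_CLASSES}
    grand = sum(total_by_tad.values())
    baseline = {t: (total_by_tad[t] / grand if grand else np.nan) for t in _TAD_CLASSES}
    fractions, enrichment = {}, {}
    for g in _GENE_CLASSES:
        row_total = sum(counts[g].values())
        fractions[g] = {
            t: (counts[g][t] / row_total if row_total else np.nan) for t in _TAD_CLASSES
        }
        enrichment[g] = {
            t: (fractions[g][t] / baseline[t] if baseline[t] else np.nan)
            for t in _TAD_CLASSES
        }
    return {"counts": counts, "fractions": fractions, "enrichment": enrichment,
            "baseline": baseline, "n_assigned": grand}


def dar_gene_correlation_matrix(tad_diffs, dars, diff_genes, gene_tss) -> dict:
    """Spearman correlations between per-TAD DAR and gene class counts.

    Over differentially acetylated TADs only, counts gain/loss DARs (by
    summit) and up-/down-regulated genes (by TSS) per TAD and correlates
    the four count vectors pairwise. Requires >= 3 differential TADs.
    Zero-variance vectors give NaN entries.
    """
    diff_tads = [t for t in tad_diffs if t.tad_class != "unchanged"]
    if len(diff_tads) < 3:
        raise ValueError("need >= 3 differentially acetylated TADs")
    names = ["dar_gain", "dar_loss", "gene_up", "gene_down"]
    vectors = {n: np.zeros(len(diff_tads)) for n in names}
    for ti, td in enumerate(diff_tads):
        for d in dars:
            if (
                d.region.chrom == td.tad.chrom
                and td.tad.start <= d.summit < td.tad.end
                and d.direction in ("gain", "loss")
            ):
                vectors[f"dar_{d.direction}"][ti] += 1
        for dg, tss in zip(diff_genes, gene_tss):
            if (
                tss[0] == td.tad.chrom
                and td.tad.start <= tss[1] < td.tad.end
                and dg.direction in ("gain", "loss")
            ):
                vectors["gene_up" if dg.direction == "gain" else "gene_down"][ti] += 1
    mat = np.full((4, 4), np.nan)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            va, vb = vectors[a], vectors[b]
            if np.ptp(va) == 0 or np.ptp(vb) == 0:
                continue
            mat[i, j] = stats.spearmanr(va, vb).statistic
    return {"names": names, "matrix": mat, "vectors": vectors, "n_tads": len(diff_tads)}
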