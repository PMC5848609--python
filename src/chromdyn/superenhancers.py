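"""ROSE-style super-enhancer calling, differential analysis and target
assignment by genomic proximity and by promoter capture Hi-C."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .diffcount import CountMatrix, estimate_dispersion, test_regions
from .intervals import GenomicInterval, ScoredInterval, nearest_k, overlap_pairs, stitch_intervals

__all__ = [
    "SuperEnhancer",
    "call_super_enhancers",
    "differential_ses",
    "nearest_gene_response",
    "pchic_se_targets",
]


@dataclass
class SuperEnhancer:
    region: GenomicInterval
    constituents: list        # member enhancer intervals
    signal: float             # control-subtracted normalized signal (basal)
    rank: int                 # 1 = highest signal
    lfc: float = float("nan")
    pvalue: float = float("nan")
    qvalue: float = float("nan")
    direction: str = "none"   # gain / loss / none after differential testing


def call_super_enhancers(
    enhancers,
    signal_ss,
    control_signal=None,
    stitch_gap: int = 12_500,
    tss_exclusion=None,
):
    """Stitch enhancers and call super-enhancers by the rank-curve elbow.

    Enhancers overlapping a TSS-exclusion zone are removed, the rest are
    stitched within ``stitch_gap``, and stitched regions are ranked by
    summed control-subtracted signal. On the rank curve with both axes
    scaled to [0, 1], the cutoff sits where the tangent slope reaches 1
    (the slope of the diagonal); regions above it are super-enhancers.

    Returns ``(ses, rank_curve)`` where ``rank_curve`` is the ascending
    (scaled_rank, scaled_signal) array for plotting.
    """
    signal_ss = np.asarray(signal_ss, dtype=float)
    control = np.zeros(len(enhancers)) if control_signal is None else np.asarray(control_signal, dtype=float)
    ivs = [getattr(e, "interval", e) for e in enhancers]
    keep = np.ones(len(ivs), dtype=bool)
    if tss_exclusion:
        excl = [getattr(e, "interval", e) for e in tss_exclusion]
        for i, _ in overlap_pairs(ivs, excl):
            keep[i] = False
    kept_idx = np.flatnonzero(keep)
    kept = [ivs[i] for i in kept_idx]
    merged, members = stitch_intervals(kept, stitch_gap)
    if len(merged) < 3:
        raise ValueError("fewer than 3 stitched regions; rank curve undefined")
    net = signal_ss - control
    region_signal = np.array([net[kept_idx[np.array(mem)]].sum() for mem in members])

    order = np.argsort(region_signal, kind="stable")  # ascending
    y = region_signal[order]
    n = len(y)
    y_scaled = (y - y.min()) / (y.max() - y.min()) if y.max() > y.min() else np.zeros(n)
    x_scaled = np.arange(n) / max(n - 1, 1)
    # the cutoff sits where a slope-1 line is tangent to the scaled curve
    # from below, i.e. at argmin(y - x); past it the curve rises faster
    # than the diagonal. A flat curve has its argmin at the last point,
    # giving zero SEs.
    tangent_idx = int(np.argmin(y_scaled - x_scaled))
    se_positions = order[tangent_idx + 1 :]

    ses = []
    desc = sorted(se_positions, key=lambda i: -region_signal[i])
    for rank, i in enumerate(desc, 1):
        ses.append(
            SuperEnhancer(
                region=merged[i],
                constituents=[kept[j] for j in members[i]],
                signal=float(region_signal[i]),
                rank=rank,
            )
        )
    return ses, np.column_stack([x_scaled, y_scaled])


def differential_ses(
    ses,
    window_counts: CountMatrix,
    size_factors: np.ndarray,
    fdr: float = 0.01,
):
    """Differential acetylation of SEs from summed member-window counts.

    SEs overlapping zero windows are excluded (returned unmodified with
    direction "none"). Tested SEs get lfc/p/q/direction filled in place;
    returns the tested subset.
    """
    windows = window_counts.regions
    pairs = overlap_pairs([s.region for s in ses], windows)
    sums = np.zeros((len(ses), window_counts.counts.shape[1]), dtype=np.int64)
    n_win = np.zeros(len(ses), dtype=int)
    for si, wi in pairs:
        sums[si] += window_counts.counts[wi]
        n_win[si] += 1
    keep = np.flatnonzero(n_win > 0)
    if len(keep) == 0:
        return []
    cm = CountMatrix([ses[i].region for i in keep], sums[keep], window_counts.samples)
    dispersions = estimate_dispersion(cm, size_factors)
    offsets = np.log([float(len(ses[i].region)) for i in keep])
    ws = test_regions(cm, size_factors, dispersions, offsets=offsets)
    pvals = np.array([w.pvalue for w in ws])
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    tested = []
    for i, w, q in zip(keep, ws, qvals):
        se = ses[i]
        se.lfc, se.pvalue, se.qvalue = w.lfc, w.pvalue, float(q)
        if q <= fdr and w.lfc != 0:
            se.direction = "gain" if w.lfc > 0 else "loss"
        else:
            se.direction = "none"
        tested.append(se)
    return tested


def nearest_gene_response(diff_ses, diff_genes, gene_tss, k: int = 4) -> dict:
    """LFC and distance of the k nearest genes to each differential SE.

    ``gene_tss`` is a list of (chrom, tss) parallel to ``diff_genes``.
    Returns per (SE class, rank) lists of gene LFCs and |distances|.
    """
    tss_ivs = [GenomicInterval(c, t, t + 1) for c, t in gene_tss]
    ses = [s for s in diff_ses if s.direction in ("gain", "loss")]
    hits = nearest_k([s.region for s in ses], tss_ivs, k)
    out: dict = {}
    for se, neigh in zip(ses, hits):
        for rank, (gi, dist) in enumerate(neigh, 1):
            cell = out.setdefault((se.direction, rank), {"lfc": [], "distance": []})
            cell["lfc"].append(diff_genes[gi].lfc)
            cell["distance"].append(abs(dist))
    return out


def pchic_se_targets(ses, interactions, min_score: float = 5.0, condition: str = "either") -> dict:
    """Link SEs to bait genes through significant capture Hi-C interactions.

    An interaction is significant when its score reaches ``min_score`` in
    the chosen condition ("ss", "tpo", or "either"); it links an SE to its
    bait gene when the other end overlaps an SE constituent. Returns the
    links, per-(SE, gene) constituent-link counts, and the fraction of all
    significant interactions anchored at SEs.
    """
    def significant(rec):
        if condition == "ss":
            return rec.score_ss >= min_score
        if condition == "tpo":
            return rec.score_tpo >= min_score
        return rec.score_ss >= min_score or rec.score_tpo >= min_score

    sig = [r for r in interactions if significant(r)]
    constituents = []
    owner = []
    for si, se in enumerate(ses):
        for c in se.constituents:
            constituents.append(c)
            owner.append(si)
    pairs = overlap_pairs([r.other_end for r in sig], constituents)
    links: dict[tuple[int, str], set] = {}
    anchored = set()
    for ri, ci in pairs:
        anchored.add(ri)
        links.setdefault((owner[ci], sig[ri].gene), set()).add(ci)
    link_counts = {key: len(v) for key, v in links.items()}
    fraction = len(anchored) / len(sig) if sig else 0.0
    return {
        "links": links,
        "constituent_link_counts": link_counts,
        "n_significant": len(sig),
        "n_anchored_at_se": len(anchored),
        "fraction_anchored": fraction,
    }
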