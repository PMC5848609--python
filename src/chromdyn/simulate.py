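"""Synthetic miniature-genome generator with planted ground truth.

Emulates every data modality the pipeline consumes — replicated NB window
counts for H3K27ac ChIP and chromatin RNA, distance-decaying Hi-C contact
matrices with TAD blocks, capture-Hi-C interaction lists with
CHiCAGO-like scores, and DHS sequences with class-correlated motifs and
TF peak sets — so every downstream stage can be exercised and its
parameter recovery measured against known truth.

Design notes
------------
* Every generator is a pure function of ``(annotation, truth, config)``;
  randomness comes from per-stage substreams of ``config.seed``.
* The two conditions ("SS" serum-starved, "TPO" stimulated) share the
  Hi-C intensity surface by default, encoding an invariant chromatin
  architecture; ``rewired_fraction > 0`` plants promoters whose looping
  changes track acetylation changes, powering the cis-regulatory-unit
  permutation test's alternative.
* Hi-C counts are Poisson (not NB): standard for binned contacts and it
  keeps the SIMA resampling null well defined.
* ChIP counts are simulated on non-overlapping 1-kb windows; overlapping
  sliding windows would double-count simulated reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .intervals import GenomicInterval, ScoredInterval
from .io import ContactMatrix, CountMatrix, InteractionRecord, SampleInfo

__all__ = [
    "SyntheticConfig",
    "Gene",
    "Annotation",
    "PlantedTruth",
    "simulate_annotation",
    "simulate_chip_counts",
    "simulate_rna_counts",
    "simulate_hic",
    "simulate_pchic",
    "simulate_sequences_and_tf",
    "simulate_all",
]

_STREAMS = {
    "annotation": 1,
    "truth": 2,
    "chip": 3,
    "hic_ss": 4,
    "hic_tpo": 5,
    "pchic": 6,
    "rna": 7,
    "seq": 8,
}


def _rng(config, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _STREAMS[stream]])


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic genome.

    Defaults give a 2 x 20 Mb genome with 40 TADs, 400 genes and 600
    enhancers: small enough for minute-scale tests, large enough for
    stable resampling statistics.
    """

    n_chroms: int = 2
    chrom_length: int = 20_000_000
    bin_size: int = 10_000           # Hi-C resolution
    chip_window: int = 1_000         # ChIP quantification window
    n_tads: int = 40
    n_genes: int = 400
    n_enhancers: int = 600
    # differential structure
    frac_dar_gain: float = 0.10      # fraction of DHS elements planted as gains
    frac_dar_loss: float = 0.20      # ... as losses (gain:loss ~ 1:2)
    dar_lfc_mean: float = 1.5        # log2 units
    dar_lfc_sd: float = 0.65         # spread of planted magnitudes
    tad_cluster_prob: float = 0.8    # planted DAR adopts its TAD's class
    tad_frac_induced: float = 0.25
    tad_frac_repressed: float = 0.25
    frac_gene_up: float = 0.15
    frac_gene_down: float = 0.08
    gene_lfc_mean: float = 2.0
    # count model
    nb_dispersion: float = 0.05
    depth_per_sample: float = 1.5e6  # expected ChIP reads per sample
    background_window_mean: float = 2.0  # diffuse non-peak signal per window
    size_factors_true: tuple = (1.0, 1.15, 0.9, 1.05)
    # Hi-C model
    hic_decay_exponent: float = 1.0
    hic_depth: float = 60.0          # expected counts at distance 0
    tad_boost: float = 2.0           # contact multiplier inside TADs
    pair_boost: float = 1.0          # planted enhancer-pair multiplier
    # PCHi-C model
    pir_mean: float = 13.0           # mean PIRs per promoter
    dar_pir_frac: float = 0.45       # fraction of PIRs drawn at DAR elements
    pir_distance_mean: float = 300_000.0
    pchic_depth: float = 100.0       # scales frequencies to read-count range
    score_noise: float = 0.5
    rewired_fraction: float = 0.0    # promoters whose looping tracks acetylation
    rewire_slope: float = 1.0
    # sequences / TF peaks
    seq_flank: int = 500
    motif_embed_prob: float = 0.8
    tf_sensitivity: float = 0.85
    tf_specificity: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "frac_dar_gain", "frac_dar_loss", "tad_cluster_prob", "tad_frac_induced",
            "tad_frac_repressed", "frac_gene_up", "frac_gene_down", "dar_pir_frac",
            "motif_embed_prob", "tf_sensitivity", "tf_specificity", "rewired_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_chroms", "chrom_length", "bin_size", "chip_window", "n_tads",
                     "n_genes", "n_enhancers"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.chrom_length % self.bin_size != 0:
            raise ValueError("bin_size must divide chrom_length")

    @property
    def chrom_sizes(self) -> dict:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}


@dataclass(frozen=True)
class Gene:
    name: str
    chrom: str
    tss: int
    strand: str
    body: GenomicInterval


@dataclass
class Annotation:
    chrom_sizes: dict
    tads: list
    genes: list
    enhancers: list          # enhancer DHS intervals
    promoters: list          # promoter DHS intervals (one per gene)
    fragments: list          # HindIII-like restriction fragments

    @property
    def elements(self) -> list:
        """All DHS elements: promoters first, then enhancers, with labels."""
        out = [ScoredInterval(iv, 0.0, "promoter") for iv in self.promoters]
        out += [ScoredInterval(iv, 0.0, "enhancer") for iv in self.enhancers]
        return out


@dataclass
class PlantedTruth:
    """Ground truth for parameter-recovery tests.

    ``element_class[i]`` / ``element_lfc[i]`` index ``annotation.elements``;
    ``dar_regions`` are the planted differential neighbourhoods (label =
    class) a caller can score recall against.
    """

    element_class: list          # gain / loss / null per DHS element
    element_lfc: np.ndarray      # true log2 fold change (0 for null)
    dar_regions: list            # ScoredInterval, label in {gain, loss}
    tad_class: list              # induced / repressed / neutral per TAD
    gene_class: list             # gain / loss / null per gene
    gene_lfc: np.ndarray
    clustered_pairs: list        # (enhancer_i, enhancer_j) same-TAD same-class
    tf_class_map: dict           # TF name -> associated class (or None)
    rewired_genes: set           # gene names with planted looping changes


# ---------------------------------------------------------------------------
# annotation + truth

def simulate_annotation(config: SyntheticConfig) -> Annotation:
    """Lay out TADs, genes, DHS elements and restriction fragments.

    TADs tile each chromosome without gaps (boundaries aligned to Hi-C
    bins), so every TSS and enhancer falls in exactly one TAD. Fragments
    tile the genome with ~4-kb mean length, emulating a HindIII digest.
    """
    rng = _rng(config, "annotation")
    sizes = config.chrom_sizes
    chroms = list(sizes)
    tads: list[GenomicInterval] = []
    per_chrom_tads = np.full(config.n_chroms, config.n_tads // config.n_chroms)
    per_chrom_tads[: config.n_tads % config.n_chroms] += 1
    n_bins = config.chrom_length // config.bin_size
    for chrom, k in zip(chroms, per_chrom_tads):
        if k == 0:
            continue
        if k > n_bins // 2:
            raise ValueError(f"{k} TADs do not fit {n_bins} bins on {chrom}")
        lengths = rng.dirichlet(np.full(k, 5.0)) * n_bins
        lengths = np.maximum(np.round(lengths).astype(int), 2)
        while lengths.sum() > n_bins:
            lengths[np.argmax(lengths)] -= 1
        while lengths.sum() < n_bins:
            lengths[np.argmin(lengths)] += 1
        bounds = np.concatenate([[0], np.cumsum(lengths)]) * config.bin_size
        for a, b in zip(bounds[:-1], bounds[1:]):
            tads.append(GenomicInterval(chrom, int(a), int(b)))

    genes: list[Gene] = []
    per_chrom_genes = np.full(config.n_chroms, config.n_genes // config.n_chroms)
    per_chrom_genes[: config.n_genes % config.n_chroms] += 1
    gi = 0
    for chrom, k in zip(chroms, per_chrom_genes):
        # enforce >= 2 kb spacing between TSSs so promoter elements and
        # their flanking peaks never bleed onto a neighbouring promoter
        tss: list[int] = []
        while len(tss) < k:
            cand = int(rng.integers(10_000, sizes[chrom] - 10_000))
            if all(abs(cand - t) >= 2_000 for t in tss):
                tss.append(cand)
        for t in sorted(tss):
            strand = "+" if rng.random() < 0.5 else "-"
            body_len = int(np.clip(rng.lognormal(np.log(20_000), 0.8), 2_000, 200_000))
            if strand == "+":
                body = GenomicInterval(chrom, int(t), min(int(t) + body_len, sizes[chrom]), "+")
            else:
                body = GenomicInterval(chrom, max(0, int(t) - body_len), int(t) + 1, "-")
            genes.append(Gene(f"gene{gi:04d}", chrom, int(t), strand, body))
            gi += 1

    promoters = [
        GenomicInterval(g.chrom, max(0, g.tss - 200), g.tss + 200) for g in genes
    ]
    enhancers: list[GenomicInterval] = []
    per_chrom_enh = np.full(config.n_chroms, config.n_enhancers // config.n_chroms)
    per_chrom_enh[: config.n_enhancers % config.n_chroms] += 1
    tss_by_chrom = {c: np.array([g.tss for g in genes if g.chrom == c]) for c in chroms}
    for chrom, k in zip(chroms, per_chrom_enh):
        placed = 0
        while placed < k:
            pos = int(rng.integers(5_000, sizes[chrom] - 5_000))
            tss = tss_by_chrom[chrom]
            if len(tss) and np.abs(tss - pos).min() < 3_000:
                continue  # keep enhancers clear of promoters
            if any(e.chrom == chrom and abs(e.midpoint - pos) < 1_000
                   for e in enhancers[-min(len(enhancers), 400):]):
                continue  # and clear of each other
            enhancers.append(GenomicInterval(chrom, pos - 100, pos + 100))
            placed += 1

    fragments: list[GenomicInterval] = []
    for chrom in chroms:
        pos = 0
        while pos < sizes[chrom]:
            frag_len = int(np.clip(rng.exponential(3_500) + 500, 500, 12_000))
            end = min(pos + frag_len, sizes[chrom])
            fragments.append(GenomicInterval(chrom, pos, end))
            pos = end

    return Annotation(sizes, tads, genes, enhancers, promoters, fragments)


def _tad_index(annotation: Annotation):
    """Map a (chrom, position) to its TAD index (TADs tile each chrom)."""
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in annotation.chrom_sizes:
        idx = [i for i, t in enumerate(annotation.tads) if t.chrom == c]
        starts = np.array([annotation.tads[i].start for i in idx])
        by_chrom[c] = (starts, np.array(idx))

    def lookup(chrom: str, pos: int) -> int:
        starts, idx = by_chrom[chrom]
        if len(idx) == 0:
            return -1
        return int(idx[np.searchsorted(starts, pos, side="right") - 1])

    return lookup


def plant_truth(annotation: Annotation, config: SyntheticConfig) -> PlantedTruth:
    """Assign TAD, element and gene classes with TAD-level clustering."""
    rng = _rng(config, "truth")
    tad_of = _tad_index(annotation)

    classes = ["induced", "repressed", "neutral"]
    probs = [config.tad_frac_induced, config.tad_frac_repressed,
             1 - config.tad_frac_induced - config.tad_frac_repressed]
    tad_class = list(rng.choice(classes, size=len(annotation.tads), p=probs))

    elements = annotation.elements
    p_dar = config.frac_dar_gain + config.frac_dar_loss
    p_gain_given_dar = config.frac_dar_gain / p_dar if p_dar > 0 else 0.5
    element_class: list[str] = []
    element_lfc = np.zeros(len(elements))
    dar_regions: list[ScoredInterval] = []
    tad_to_dir = {"induced": "gain", "repressed": "loss"}
    for i, el in enumerate(elements):
        if rng.random() >= p_dar:
            element_class.append("null")
            continue
        tcls = tad_class[tad_of(el.interval.chrom, el.interval.midpoint)]
        if tcls in tad_to_dir and rng.random() < config.tad_cluster_prob:
            cls = tad_to_dir[tcls]
        else:
            cls = "gain" if rng.random() < p_gain_given_dar else "loss"
        element_class.append(cls)
        mag = max(0.5, rng.normal(config.dar_lfc_mean, config.dar_lfc_sd))
        element_lfc[i] = mag if cls == "gain" else -mag
        mid = el.interval.midpoint
        half = int(rng.integers(1_000, 2_500))
        region = GenomicInterval(
            el.interval.chrom,
            max(0, mid - half),
            min(annotation.chrom_sizes[el.interval.chrom], mid + half),
        )
        dar_regions.append(ScoredInterval(region, float(element_lfc[i]), cls))

    p_diff = config.frac_gene_up + config.frac_gene_down
    p_up_given = config.frac_gene_up / p_diff if p_diff > 0 else 0.5
    gene_class: list[str] = []
    gene_lfc = np.zeros(len(annotation.genes))
    for i, g in enumerate(annotation.genes):
        if rng.random() >= p_diff:
            gene_class.append("null")
            continue
        tcls = tad_class[tad_of(g.chrom, g.tss)]
        if tcls in tad_to_dir and rng.random() < config.tad_cluster_prob:
            cls = tad_to_dir[tcls]
        else:
            cls = "gain" if rng.random() < p_up_given else "loss"
        gene_class.append(cls)
        mag = max(0.5, rng.normal(config.gene_lfc_mean, 0.4))
        gene_lfc[i] = mag if cls == "gain" else -mag

    # same-TAD same-class enhancer pairs (candidates for contact boosting)
    n_prom = len(annotation.promoters)
    clustered_pairs: list[tuple[int, int]] = []
    by_tad: dict[tuple[int, str], list[int]] = {}
    for j, enh in enumerate(annotation.enhancers):
        cls = element_class[n_prom + j]
        if cls == "null":
            continue
        t = tad_of(enh.chrom, enh.midpoint)
        by_tad.setdefault((t, cls), []).append(j)
    for members in by_tad.values():
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                clustered_pairs.append((members[a], members[b]))

    tf_class_map = {
        "MYC": "gain", "pSTAT1": "gain",
        "MYB": "loss", "LYL1": "loss", "uSTAT5": "loss",
        "CTCF": None,
    }
    # rewired promoters are chosen by simulate_pchic once PIR sets exist
    return PlantedTruth(
        element_class, element_lfc, dar_regions, tad_class,
        gene_class, gene_lfc, clustered_pairs, tf_class_map, set(),
    )


# ---------------------------------------------------------------------------
# counts

def _nb_draw(rng, mean, dispersion):
    """NB draw parameterised by mean and dispersion (Var = mu + a mu^2)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1e-8:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


_SAMPLES = [
    SampleInfo("SS_rep1", "SS", 1),
    SampleInfo("SS_rep2", "SS", 2),
    SampleInfo("TPO_rep1", "TPO", 1),
    SampleInfo("TPO_rep2", "TPO", 2),
]


def simulate_chip_counts(
    annotation: Annotation, truth: PlantedTruth, config: SyntheticConfig
) -> CountMatrix:
    """NB window counts, two conditions x two replicates.

    Background windows share a low mean across conditions; windows inside
    a planted differential neighbourhood split the planted LFC
    symmetrically between conditions. About half the simulated depth goes
    to DHS-marked windows.
    """
    rng = _rng(config, "chip")
    from .diffcount import tile_windows

    windows = tile_windows(annotation.chrom_sizes, config.chip_window)
    n = len(windows)
    w_index = {(w.chrom, w.start): i for i, w in enumerate(windows)}

    marked = np.zeros(n, dtype=bool)
    lfc = np.zeros(n)
    elements = annotation.elements
    for el, cls, true_lfc in zip(elements, truth.element_class, truth.element_lfc):
        mid = el.interval.midpoint
        half = 1_500 if cls == "null" else 0
        region = next(
            (r for r in truth.dar_regions
             if r.interval.chrom == el.interval.chrom
             and r.interval.start <= mid < r.interval.end and r.label == cls),
            None,
        ) if cls != "null" else None
        if region is not None:
            lo, hi = region.interval.start, region.interval.end
        else:
            lo, hi = mid - half, mid + half
        for ws in range((lo // config.chip_window) * config.chip_window, hi, config.chip_window):
            i = w_index.get((el.interval.chrom, ws))
            if i is None:
                continue
            marked[i] = True
            if cls != "null":
                lfc[i] = true_lfc

    n_marked = max(1, int(marked.sum()))
    base = np.empty(n)
    # diffuse background sits below the analysis abundance floor; the
    # remaining depth concentrates at DHS-marked windows (ChIP enrichment)
    bg_mean = config.background_window_mean
    marked_mean = max(
        5.0, (config.depth_per_sample - bg_mean * (n - n_marked)) / n_marked
    )
    base[~marked] = bg_mean * rng.lognormal(0.0, 0.25, size=int((~marked).sum()))
    base[marked] = marked_mean * rng.lognormal(0.0, 0.5, size=n_marked)

    mean_ss = base * np.exp2(-lfc / 2)
    mean_tpo = base * np.exp2(lfc / 2)
    sf = np.asarray(config.size_factors_true)
    cols = []
    for j, sample in enumerate(_SAMPLES):
        mu = (mean_ss if sample.condition == "SS" else mean_tpo) * sf[j]
        cols.append(_nb_draw(rng, mu, config.nb_dispersion))
    return CountMatrix(windows, np.column_stack(cols), list(_SAMPLES))


def simulate_rna_counts(
    annotation: Annotation, truth: PlantedTruth, config: SyntheticConfig
) -> CountMatrix:
    """Gene-level chromatin-associated RNA counts (same NB machinery)."""
    rng = _rng(config, "rna")
    n = len(annotation.genes)
    base = rng.lognormal(np.log(200.0), 1.0, size=n).clip(5, 20_000)
    lfc = truth.gene_lfc
    mean_ss = base * np.exp2(-lfc / 2)
    mean_tpo = base * np.exp2(lfc / 2)
    sf = np.asarray(config.size_factors_true)
    cols = []
    for j, sample in enumerate(_SAMPLES):
        mu = (mean_ss if sample.condition == "SS" else mean_tpo) * sf[j]
        cols.append(_nb_draw(rng, mu, config.nb_dispersion))
    regions = [g.body for g in annotation.genes]
    return CountMatrix(regions, np.column_stack(cols), list(_SAMPLES))


# ---------------------------------------------------------------------------
# Hi-C

def _hic_lambda(annotation: Annotation, truth: PlantedTruth, config: SyntheticConfig, chrom: str) -> np.ndarray:
    n = annotation.chrom_sizes[chrom] // config.bin_size
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    lam = config.hic_depth * (d + 1.0) ** (-config.hic_decay_exponent)
    tad_id = np.full(n, -1)
    for t_i, tad in enumerate(annotation.tads):
        if tad.chrom != chrom:
            continue
        tad_id[tad.start // config.bin_size : tad.end // config.bin_size] = t_i
    same = (tad_id[:, None] == tad_id[None, :]) & (tad_id[:, None] >= 0)
    lam *= np.where(same, config.tad_boost, 1.0)
    if config.pair_boost != 1.0:
        for a, b in truth.clustered_pairs:
            ea, eb = annotation.enhancers[a], annotation.enhancers[b]
            if ea.chrom != chrom or eb.chrom != chrom:
                continue
            i, j = ea.midpoint // config.bin_size, eb.midpoint // config.bin_size
            if i != j:
                lam[i, j] *= config.pair_boost
                lam[j, i] *= config.pair_boost
    return lam


def simulate_hic(
    annotation: Annotation, truth: PlantedTruth, config: SyntheticConfig
) -> dict:
    """Poisson contact matrices per chromosome for both conditions.

    Both conditions share the intensity surface (invariant architecture);
    only the Poisson noise differs between them.
    """
    out = {"SS": {}, "TPO": {}}
    for cond, stream in (("SS", "hic_ss"), ("TPO", "hic_tpo")):
        rng = _rng(config, stream)
        for chrom in annotation.chrom_sizes:
            lam = _hic_lambda(annotation, truth, config, chrom)
            upper = rng.poisson(np.triu(lam))
            mat = upper + np.triu(upper, 1).T
            out[cond][chrom] = ContactMatrix(chrom, config.bin_size, mat.astype(float))
    return out


# ---------------------------------------------------------------------------
# PCHi-C

def simulate_pchic(
    annotation: Annotation,
    truth: PlantedTruth,
    config: SyntheticConfig,
) -> list[InteractionRecord]:
    """Promoter-anchored interaction records with CHiCAGO-like scores.

    Each promoter draws a Poisson number of promoter-interacting regions
    (PIRs); per-condition frequencies follow the shared Hi-C intensity
    surface at fragment resolution, and scores are monotone in the
    observed/expected enrichment plus Gaussian noise. A configurable
    fraction of PIRs is drawn at fragments hosting planted DAR elements.
    In rewired mode, selected promoters' TPO frequencies track the
    acetylation fold change of the DAR on each PIR.
    """
    rng = _rng(config, "pchic")
    frag_by_chrom: dict[str, list[int]] = {}
    for i, f in enumerate(annotation.fragments):
        frag_by_chrom.setdefault(f.chrom, []).append(i)
    frag_starts = {
        c: np.array([annotation.fragments[i].start for i in idx])
        for c, idx in frag_by_chrom.items()
    }
    # fragments hosting a planted DAR element, per chromosome
    dar_frags: dict[str, list[tuple[int, float]]] = {c: [] for c in annotation.chrom_sizes}
    dar_lfc_of: dict[int, float] = {}
    elements = annotation.elements
    for el, cls, l in zip(elements, truth.element_class, truth.element_lfc):
        if cls == "null":
            continue
        c = el.interval.chrom
        fi = frag_by_chrom[c][int(np.searchsorted(frag_starts[c], el.interval.midpoint, side="right") - 1)]
        dar_frags[c].append((fi, float(l)))
    # a fragment overlapping planted differential regions carries the LFC
    # of the region with the largest overlap (its dominant signal)
    best_overlap: dict[int, int] = {}
    for region in truth.dar_regions:
        c = region.interval.chrom
        lo = int(np.searchsorted(frag_starts[c], region.interval.start, side="right") - 1)
        for fi in frag_by_chrom[c][max(lo, 0):]:
            frag = annotation.fragments[fi]
            if frag.start >= region.interval.end:
                break
            ov = min(frag.end, region.interval.end) - max(frag.start, region.interval.start)
            if ov > best_overlap.get(fi, 0):
                best_overlap[fi] = ov
                dar_lfc_of[fi] = region.score

    lam_cache = {c: _hic_lambda(annotation, truth, config, c) for c in annotation.chrom_sizes}
    expected = {}
    for c, lam in lam_cache.items():
        n = lam.shape[0]
        exp_d = np.array([np.mean(np.diagonal(lam, k)) for k in range(n)])
        expected[c] = exp_d

    # first pass: choose each promoter's PIR fragment set
    chosen_of: dict[int, list[int]] = {}
    for g_i, gene in enumerate(annotation.genes):
        c = gene.chrom
        bait_idx = frag_by_chrom[c][int(np.searchsorted(frag_starts[c], gene.tss, side="right") - 1)]
        n_pir = rng.poisson(config.pir_mean)
        chosen: list[int] = []
        chosen_set: set[int] = set()
        # candidate DAR fragments within capture range of this bait
        max_d = 5 * config.pir_distance_mean
        dar_pool = [
            (fi, l) for fi, l in dar_frags[c]
            if abs(annotation.fragments[fi].midpoint - gene.tss) <= max_d
        ]
        for _ in range(n_pir):
            fi = None
            want_dar = bool(dar_pool) and rng.random() < config.dar_pir_frac
            for _attempt in range(8):  # retry collisions to keep PIR counts
                if want_dar:
                    cand, _lfc = dar_pool[rng.integers(len(dar_pool))]
                else:
                    offset = rng.exponential(config.pir_distance_mean) * (1 if rng.random() < 0.5 else -1)
                    pos = int(np.clip(gene.tss + offset, 0, annotation.chrom_sizes[c] - 1))
                    cand = frag_by_chrom[c][int(np.searchsorted(frag_starts[c], pos, side="right") - 1)]
                if cand not in chosen_set and cand != bait_idx:
                    fi = cand
                    break
                want_dar = False  # fall back to a distance-based draw
            if fi is None:
                continue
            chosen.append(fi)
            chosen_set.add(fi)
        chosen_of[g_i] = chosen

    # rewired promoters: a fraction of the units the downstream analysis
    # will actually test (differentially transcribed promoters with >= 5
    # DAR-containing PIRs) get looping changes that track acetylation
    if config.rewired_fraction > 0:
        qualifying = [
            g_i for g_i, chosen in chosen_of.items()
            if truth.gene_class[g_i] != "null"
            and sum(1 for fi in chosen if fi in dar_lfc_of) >= 5
        ]
        n_rewired = int(round(config.rewired_fraction * len(qualifying)))
        picked = rng.choice(len(qualifying), size=min(n_rewired, len(qualifying)), replace=False)
        truth.rewired_genes.clear()
        truth.rewired_genes.update(annotation.genes[qualifying[i]].name for i in picked)

    records: list[InteractionRecord] = []
    for g_i, gene in enumerate(annotation.genes):
        c = gene.chrom
        bait_idx = frag_by_chrom[c][int(np.searchsorted(frag_starts[c], gene.tss, side="right") - 1)]
        bait = annotation.fragments[bait_idx]
        rewired = gene.name in truth.rewired_genes
        for fi in chosen_of[g_i]:
            # rewiring tracks acetylation at any DAR-hosting fragment
            dar_lfc = dar_lfc_of.get(fi, 0.0)
            frag = annotation.fragments[fi]
            bi = bait.midpoint // config.bin_size
            oi = frag.midpoint // config.bin_size
            frag_scale = (len(frag) / config.bin_size) * config.pchic_depth
            lam = lam_cache[c][bi, oi] * frag_scale
            freq_ss = float(lam * rng.lognormal(0.0, 0.2))
            if rewired and dar_lfc != 0.0:
                # rewired promoters: looping change tracks acetylation
                freq_tpo = float(freq_ss * np.exp2(config.rewire_slope * dar_lfc))
            else:
                freq_tpo = float(lam * rng.lognormal(0.0, 0.2))
            exp_frag = max(expected[c][abs(bi - oi)] * frag_scale, 1e-9)
            noise = rng.normal(0.0, config.score_noise, size=2) if config.score_noise > 0 else np.zeros(2)
            score_ss = max(0.0, 6.0 + np.log2((freq_ss + 1) / (exp_frag + 1)) + noise[0])
            score_tpo = max(0.0, 6.0 + np.log2((freq_tpo + 1) / (exp_frag + 1)) + noise[1])
            records.append(
                InteractionRecord(bait, frag, gene.name, score_ss, score_tpo, freq_ss, freq_tpo)
            )
    return records


# ---------------------------------------------------------------------------
# sequences, motifs, TF peaks

_CLASS_MOTIFS = {
    # class-specific consensus embedded in the matching class only
    "gain": ("GAS_STAT", "TTCCCGGAA"),
    "loss": ("EBOX_REP", "CACCTGTC"),
}
_SHARED_MOTIFS = [
    ("ETS_core", "ACAGGAAGT"),
    ("RUNX", "TGTGGTTT"),
    ("GATA", "AGATAAGA"),
]


def _consensus_pwm(name: str, consensus: str, strength: float = 0.9):
    from .predictor import PWM

    base_idx = {b: i for i, b in enumerate("ACGT")}
    mat = np.full((len(consensus), 4), (1 - strength) / 3)
    for p, b in enumerate(consensus):
        mat[p, base_idx[b]] = strength
    return PWM(name, mat)


def default_pwms() -> list:
    """The generator's PWM collection: class-specific + shared motifs."""
    pwms = [_consensus_pwm(n, c) for n, c in _CLASS_MOTIFS.values()]
    pwms += [_consensus_pwm(n, c) for n, c in _SHARED_MOTIFS]
    return pwms


def simulate_sequences_and_tf(
    annotation: Annotation, truth: PlantedTruth, config: SyntheticConfig
):
    """Per-DHS sequences, TF peak BED sets and the PWM collection.

    Background sequence is i.i.d. uniform ACGT; each class-specific motif
    consensus is embedded with probability ``motif_embed_prob`` in
    elements of the matching class (shared motifs in all classes). Each
    TF peak set covers elements of its associated class with probability
    ``tf_sensitivity`` and other elements with ``1 - tf_specificity``.

    Returns ``(sequences, peak_sets, pwms)`` where sequences maps element
    names ("element0000", indexing ``annotation.elements``) to strings
    centred on the element midpoint (summit) with ``seq_flank`` flanks.
    """
    rng = _rng(config, "seq")
    elements = annotation.elements
    L = 2 * config.seq_flank + 1
    bases = np.array(list("ACGT"))
    sequences: dict[str, str] = {}
    for i, (el, cls) in enumerate(zip(elements, truth.element_class)):
        seq = rng.integers(0, 4, size=L)
        embeds = list(_SHARED_MOTIFS)
        if cls in _CLASS_MOTIFS:
            embeds.append(_CLASS_MOTIFS[cls])
        for name, consensus in embeds:
            if rng.random() >= config.motif_embed_prob:
                continue
            # embed near the summit, random strand
            w = len(consensus)
            pos = int(rng.integers(max(0, L // 2 - 100), L // 2 + 100 - w))
            motif = consensus if rng.random() < 0.5 else _revcomp(consensus)
            seq[pos : pos + w] = [{"A": 0, "C": 1, "G": 2, "T": 3}[b] for b in motif]
        sequences[f"element{i:04d}"] = "".join(bases[seq])

    peak_sets: dict[str, list] = {}
    for tf, tf_cls in truth.tf_class_map.items():
        peaks: list[GenomicInterval] = []
        for el, cls in zip(elements, truth.element_class):
            if tf_cls is None:
                hit = rng.random() < 0.3
            elif cls == tf_cls:
                hit = rng.random() < config.tf_sensitivity
            else:
                hit = rng.random() < (1 - config.tf_specificity)
            if hit:
                iv = el.interval
                peaks.append(GenomicInterval(iv.chrom, max(0, iv.start - 100), iv.end + 100))
        peak_sets[tf] = peaks
    return sequences, peak_sets, default_pwms()


def _revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# one-call dataset

def simulate_all(config: SyntheticConfig) -> dict:
    """Generate the full synthetic dataset as an in-memory dict."""
    annotation = simulate_annotation(config)
    truth = plant_truth(annotation, config)
    out = {
        "config": config,
        "annotation": annotation,
        "truth": truth,
        "chip": simulate_chip_counts(annotation, truth, config),
        "rna": simulate_rna_counts(annotation, truth, config),
        "hic": simulate_hic(annotation, truth, config),
        "pchic": simulate_pchic(annotation, truth, config),
    }
    out["sequences"], out["tf_peaks"], out["pwms"] = simulate_sequences_and_tf(
        annotation, truth, config
    )
    return out
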