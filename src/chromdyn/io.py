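"""Readers and writers for the on-disk formats the pipeline touches.

Formats
-------
BED3/BED6
    Standard tab-separated intervals; column 4 is the class label, column 5
    the score, column 6 the strand.
chrom.sizes
    Two columns: chromosome name, length in bases.
Sparse contact text
    Header lines ``#bin_size=<int>`` and one ``#chrom_size=<name> <len>``
    per chromosome, then ``chrom<TAB>bin_i<TAB>bin_j<TAB>count`` triplets
    with ``bin_i <= bin_j`` (intra-chromosomal only).
Interaction table
    BEDPE-extended TSV with a header line naming the columns
    ``bait_chrom bait_start bait_end oe_chrom oe_start oe_end gene
    score_ss score_tpo freq_ss freq_tpo``. This dialect is this package's
    own interchange format for capture Hi-C results; upstream
    CHiCAGO-style outputs are converted into it (see README).
Count table
    TSV with a two-line header (``#samples`` names, ``#design``
    condition:replicate per sample) then ``chrom start end`` + one count
    column per sample.
PWM text
    JASPAR-like: ``>name`` then four rows ``A|C|G|T <counts...>``, with an
    optional ``#background A C G T`` line applying to subsequent records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomicInterval, ScoredInterval

__all__ = [
    "SampleInfo",
    "CountMatrix",
    "InteractionRecord",
    "ContactMatrix",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_contacts",
    "write_contacts",
    "read_interactions",
    "write_interactions",
    "read_counts",
    "write_counts",
    "read_fasta",
    "write_fasta",
    "read_pwms",
    "write_pwms",
]


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# containers

@dataclass(frozen=True)
class SampleInfo:
    name: str
    condition: str  # "SS" (serum-starved) or "TPO" (stimulated)
    replicate: int


@dataclass
class CountMatrix:
    """Integer read counts over genomic regions for a set of samples."""

    regions: list
    counts: np.ndarray  # shape (n_regions, n_samples)
    samples: list
    size_factors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.regions), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.regions)} regions x {len(self.samples)} samples"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.size_factors is not None:
            self.size_factors = np.asarray(self.size_factors, dtype=float)
            if (self.size_factors <= 0).any():
                raise ValueError("size factors must be positive")

    @property
    def conditions(self) -> np.ndarray:
        return np.array([s.condition for s in self.samples])

    def condition_columns(self, condition: str) -> np.ndarray:
        return np.flatnonzero(self.conditions == condition)

    def subset(self, region_indices) -> "CountMatrix":
        region_indices = np.asarray(region_indices)
        return CountMatrix(
            [self.regions[i] for i in region_indices],
            self.counts[region_indices],
            self.samples,
            self.size_factors,
        )


@dataclass
class InteractionRecord:
    """A bait-fragment / other-end-fragment interaction with per-condition
    confidence scores and normalized contact frequencies."""

    bait: GenomicInterval
    other_end: GenomicInterval
    gene: str
    score_ss: float
    score_tpo: float
    freq_ss: float
    freq_tpo: float

    @property
    def is_intra(self) -> bool:
        return self.bait.chrom == self.other_end.chrom

    @property
    def distance(self) -> int | None:
        """Bait-to-other-end midpoint distance (intra-chromosomal only)."""
        if not self.is_intra:
            return None
        return abs(self.bait.midpoint - self.other_end.midpoint)


@dataclass
class ContactMatrix:
    """Symmetric binned intra-chromosomal contact matrix."""

    chrom: str
    bin_size: int
    counts: np.ndarray
    normalized: bool = False
    bias: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n = self.counts.shape[0]
        if self.counts.shape != (n, n):
            raise ValueError("contact matrix must be square")
        if not np.allclose(self.counts, self.counts.T):
            raise ValueError("contact matrix must be symmetric")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def bin_of(self, position: int) -> int:
        return position // self.bin_size


# ---------------------------------------------------------------------------
# BED

def read_bed(path) -> list[ScoredInterval]:
    """Parse a BED3/BED6 file into ScoredIntervals (input order preserved)."""
    out: list[ScoredInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {ln}: expected >= 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {ln}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise ParseError(
                    f"{path}: line {ln}: invalid coordinates {start}-{end}"
                )
            label = fields[3] if len(fields) > 3 else ""
            score = 0.0
            if len(fields) > 4 and fields[4] not in ("", "."):
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            out.append(ScoredInterval(GenomicInterval(chrom, start, end, strand), score, label))
    return out


def write_bed(intervals, path) -> None:
    """Write ScoredIntervals (or bare GenomicIntervals) as BED6."""
    with open(path, "w") as fh:
        for item in intervals:
            if isinstance(item, GenomicInterval):
                item = ScoredInterval(item)
            iv = item.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{item.label}\t{float(item.score)!r}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# chrom.sizes

def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            name, length = line.split()[:2]
            sizes[name] = int(length)
    return sizes


def write_chrom_sizes(sizes: dict, path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# contacts

def read_contacts(path, bin_size: int | None = None, chrom_sizes: dict | None = None) -> dict:
    """Read sparse triplets into one dense ContactMatrix per chromosome.

    ``bin_size`` / ``chrom_sizes`` override (or supply, if absent) the
    header metadata. Missing cells are zero; the dense matrix is
    symmetrised from the upper-triangle triplets.
    """
    header_sizes: dict[str, int] = {}
    triplets: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#bin_size="):
                    bin_size = int(line.split("=", 1)[1])
                elif line.startswith("#chrom_size="):
                    name, length = line.split("=", 1)[1].split()
                    header_sizes[name] = int(length)
                continue
            chrom, i, j, c = line.split("\t")
            i, j = int(i), int(j)
            if i > j:
                raise ParseError(f"{path}: line {ln}: require bin_i <= bin_j")
            triplets.setdefault(chrom, []).append((i, j, float(c)))
    if bin_size is None:
        raise ParseError(f"{path}: bin size neither in header nor supplied")
    sizes = chrom_sizes if chrom_sizes is not None else header_sizes
    out: dict[str, ContactMatrix] = {}
    for chrom, trips in triplets.items():
        if chrom not in sizes:
            raise ParseError(f"{path}: no chromosome length for {chrom}")
        n = math.ceil(sizes[chrom] / bin_size)
        mat = np.zeros((n, n))
        for i, j, c in trips:
            if j >= n:
                raise ParseError(
                    f"{path}: bin {j} out of range for {chrom} (n_bins={n})"
                )
            mat[i, j] = c
            mat[j, i] = c
        out[chrom] = ContactMatrix(chrom, bin_size, mat)
    return out


def write_contacts(matrices: dict, path, chrom_sizes: dict | None = None) -> None:
    mats = list(matrices.values())
    with open(path, "w") as fh:
        if mats:
            fh.write(f"#bin_size={mats[0].bin_size}\n")
        for chrom, m in matrices.items():
            size = (chrom_sizes or {}).get(chrom, m.n_bins * m.bin_size)
            fh.write(f"#chrom_size={chrom} {size}\n")
        for chrom, m in matrices.items():
            ii, jj = np.nonzero(np.triu(m.counts))
            for i, j in zip(ii, jj):
                fh.write(f"{chrom}\t{i}\t{j}\t{float(m.counts[i, j])!r}\n")


# ---------------------------------------------------------------------------
# interactions

_INTERACTION_COLUMNS = [
    "bait_chrom", "bait_start", "bait_end",
    "oe_chrom", "oe_start", "oe_end",
    "gene", "score_ss", "score_tpo", "freq_ss", "freq_tpo",
]


def read_interactions(path) -> list[InteractionRecord]:
    out: list[InteractionRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").lstrip("#").split("\t")
        missing = [c for c in _INTERACTION_COLUMNS if c not in header]
        if missing:
            raise ParseError(f"{path}: missing columns {missing}")
        col = {name: header.index(name) for name in _INTERACTION_COLUMNS}
        for ln, line in enumerate(fh, 2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            out.append(
                InteractionRecord(
                    bait=GenomicInterval(f[col["bait_chrom"]], int(f[col["bait_start"]]), int(f[col["bait_end"]])),
                    other_end=GenomicInterval(f[col["oe_chrom"]], int(f[col["oe_start"]]), int(f[col["oe_end"]])),
                    gene=f[col["gene"]],
                    score_ss=float(f[col["score_ss"]]),
                    score_tpo=float(f[col["score_tpo"]]),
                    freq_ss=float(f[col["freq_ss"]]),
                    freq_tpo=float(f[col["freq_tpo"]]),
                )
            )
    return out


def write_interactions(records, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_INTERACTION_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.bait.chrom}\t{r.bait.start}\t{r.bait.end}\t"
                f"{r.other_end.chrom}\t{r.other_end.start}\t{r.other_end.end}\t"
                f"{r.gene}\t{float(r.score_ss)!r}\t{float(r.score_tpo)!r}\t{float(r.freq_ss)!r}\t{float(r.freq_tpo)!r}\n"
            )


# ---------------------------------------------------------------------------
# count tables

def read_counts(path) -> CountMatrix:
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        second = fh.readline().rstrip("\n")
        if not first.startswith("#samples") or not second.startswith("#design"):
            raise ParseError(f"{path}: expected '#samples' and '#design' header lines")
        names = first.split("\t")[1:]
        design = second.split("\t")[1:]
        samples = []
        for name, d in zip(names, design):
            condition, rep = d.split(":")
            samples.append(SampleInfo(name, condition, int(rep)))
        regions = []
        rows = []
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            regions.append(GenomicInterval(f[0], int(f[1]), int(f[2])))
            rows.append([int(x) for x in f[3:]])
    return CountMatrix(regions, np.array(rows, dtype=np.int64).reshape(len(regions), len(samples)), samples)


def write_counts(cm: CountMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("#samples\t" + "\t".join(s.name for s in cm.samples) + "\n")
        fh.write("#design\t" + "\t".join(f"{s.condition}:{s.replicate}" for s in cm.samples) + "\n")
        for iv, row in zip(cm.regions, cm.counts):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t" + "\t".join(str(int(x)) for x in row) + "\n")


# ---------------------------------------------------------------------------
# FASTA (thin wrappers over Biopython)

def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict, path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


# ---------------------------------------------------------------------------
# PWMs

def read_pwms(path) -> list:
    """Read JASPAR-like position frequency matrices into PWM objects."""
    from .predictor import PWM

    pwms = []
    background = np.full(4, 0.25)
    name = None
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        lines = list(fh) + [">"]
    for line in lines:
        line = line.strip()
        if line.startswith("#background"):
            background = np.array([float(x) for x in line.split()[1:5]])
            continue
        if line.startswith(">"):
            if name is not None:
                if set(rows) != set("ACGT"):
                    raise ParseError(f"PWM {name}: need A/C/G/T rows")
                counts = np.array([rows[b] for b in "ACGT"]).T
                # rows may be raw counts or probabilities; normalize either
                # way (zeros are tolerated by the log-odds pseudocount)
                probs = counts / counts.sum(axis=1, keepdims=True)
                pwms.append(PWM(name, probs, background=background))
            name = line[1:].split()[0] if len(line) > 1 else None
            rows = {}
            continue
        if not line:
            continue
        parts = line.replace("[", " ").replace("]", " ").split()
        rows[parts[0]] = [float(x) for x in parts[1:]]
    return pwms


def write_pwms(pwms, path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f"#background {' '.join(repr(float(x)) for x in pwm.background)}\n")
            fh.write(f">{pwm.name}\n")
            for bi, base in enumerate("ACGT"):
                vals = " ".join(repr(float(x)) for x in pwm.matrix[:, bi])
                fh.write(f"{base} [ {vals} ]\n")
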