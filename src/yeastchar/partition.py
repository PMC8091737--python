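"""Exon / intron / intergenic partition statistics of an annotated genome.

Every contig base is assigned to exactly one of three classes:

* exon — covered by at least one annotated exon of any transcript;
* intron — inside a merged gene span but not exonic;
* intergenic — outside all merged gene spans.

Overlapping gene spans are merged before the intron/intergenic split, so
inter-gene overlaps are counted once. On top of the partition the module
reports genome-level totals and percentages, length-class histograms of
the regions, and a windowed coding-density (exon fraction) track.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import gffutils
import numpy as np
import pandas as pd

from . import intervals as iv

__all__ = [
    "Transcript",
    "Gene",
    "GenomeAnnotation",
    "RegionPartition",
    "PartitionSummary",
    "LengthClassHistogram",
    "DensityTrack",
    "DEFAULT_LENGTH_EDGES",
    "load_annotation",
    "contig_lengths_from_fasta",
    "partition_genome",
    "summarize_partition",
    "length_class_histogram",
    "density_track",
    "density_track_to_bedgraph",
]

DEFAULT_LENGTH_EDGES = (0, 1_000, 10_000, 100_000, float("inf"))


@dataclass(frozen=True)
class Transcript:
    id: str
    exons: tuple[tuple[int, int], ...]  # 0-based half-open, sorted, non-overlapping


@dataclass(frozen=True)
class Gene:
    id: str
    contig: str
    start: int
    end: int
    strand: str
    transcripts: tuple[Transcript, ...]


@dataclass
class GenomeAnnotation:
    contigs: dict[str, int]  # name -> length
    genes: list[Gene]

    @property
    def n_transcripts(self) -> int:
        return sum(len(g.transcripts) for g in self.genes)


@dataclass
class RegionPartition:
    """Disjoint exon/intron/intergenic interval sets tiling each contig."""

    contigs: dict[str, int]
    exon: dict[str, np.ndarray]
    intron: dict[str, np.ndarray]
    intergenic: dict[str, np.ndarray]

    def class_intervals(self, cls: str) -> dict[str, np.ndarray]:
        return {"exon": self.exon, "intron": self.intron,
                "intergenic": self.intergenic}[cls]


@dataclass(frozen=True)
class PartitionSummary:
    genome_size_bp: int
    total_exon_bp: int
    total_intron_bp: int
    total_intergenic_bp: int
    exon_percent: float
    intron_percent: float
    intergenic_percent: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "genome_size_bp": self.genome_size_bp,
            "exon_bp": self.total_exon_bp, "exon_percent": self.exon_percent,
            "intron_bp": self.total_intron_bp, "intron_percent": self.intron_percent,
            "intergenic_bp": self.total_intergenic_bp,
            "intergenic_percent": self.intergenic_percent,
        }])


@dataclass
class LengthClassHistogram:
    edges: tuple[float, ...]
    region_counts: np.ndarray
    base_counts: np.ndarray
    base_fractions: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        labels = [f"[{int(a)}, {'inf' if np.isinf(b) else int(b)})"
                  for a, b in zip(self.edges[:-1], self.edges[1:])]
        return pd.DataFrame({"length_class": labels,
                             "n_regions": self.region_counts,
                             "n_bases": self.base_counts,
                             "base_fraction": self.base_fractions})


@dataclass
class DensityTrack:
    window: int
    # per contig: (window starts, window ends, coding fraction)
    windows: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]


def contig_lengths_from_fasta(path) -> dict[str, int]:
    from Bio import SeqIO
    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def load_annotation(gff3, contig_lengths: dict[str, int] | None = None) -> GenomeAnnotation:
    """Parse a GFF3 gene/mRNA/exon hierarchy into a :class:`GenomeAnnotation`.

    ``contig_lengths`` may be omitted when the GFF3 carries
    ``##sequence-region`` pragmas. GFF's 1-based inclusive coordinates
    are converted to 0-based half-open. Exons outside their transcript,
    transcripts outside their gene, dangling Parent references and
    features beyond the contig end are rejected.
    """
    db = gffutils.create_db(str(gff3), dbfn=":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    lengths = dict(contig_lengths or {})
    if not lengths:
        for d in db.directives:
            if d.startswith("sequence-region"):
                _, name, _one, end = d.split()
                lengths[name] = int(end)
    if not lengths:
        raise ValueError("contig lengths unavailable: pass contig_lengths or add "
                         "##sequence-region pragmas to the GFF3")

    genes: list[Gene] = []
    for g in db.features_of_type("gene"):
        if g.seqid not in lengths:
            raise ValueError(f"gene {g.id} on unknown contig {g.seqid}")
        g_iv = (g.start - 1, g.end)
        if g.end > lengths[g.seqid]:
            raise ValueError(f"gene {g.id} extends beyond contig {g.seqid}")
        transcripts = []
        for t in db.children(g, featuretype=("mRNA", "transcript"), order_by="start"):
            t_iv = (t.start - 1, t.end)
            if t_iv[0] < g_iv[0] or t_iv[1] > g_iv[1]:
                raise ValueError(f"transcript {t.id} outside gene {g.id}")
            exons = []
            for e in db.children(t, featuretype="exon", order_by="start"):
                e_iv = (e.start - 1, e.end)
                if e_iv[0] < t_iv[0] or e_iv[1] > t_iv[1]:
                    raise ValueError(f"exon at {e.seqid}:{e.start}-{e.end} outside "
                                     f"transcript {t.id}")
                exons.append(e_iv)
            exons.sort()
            for (s1, e1), (s2, _e2) in zip(exons, exons[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping exons within transcript {t.id}")
            transcripts.append(Transcript(id=t.id, exons=tuple(exons)))
        genes.append(Gene(id=g.id, contig=g.seqid, start=g_iv[0], end=g_iv[1],
                          strand=g.strand or ".", transcripts=tuple(transcripts)))
    return GenomeAnnotation(contigs=lengths, genes=genes)


def partition_genome(ann: GenomeAnnotation) -> RegionPartition:
    """Tile every contig into exon, intron and intergenic intervals."""
    exon_by, gene_by = {}, {}
    for g in ann.genes:
        gene_by.setdefault(g.contig, []).append((g.start, g.end))
        for t in g.transcripts:
            exon_by.setdefault(g.contig, []).extend(t.exons)
    exon, intron, intergenic = {}, {}, {}
    for contig, length in ann.contigs.items():
        ex = iv.merge(exon_by.get(contig, []))
        spans = iv.merge(gene_by.get(contig, []))
        exon[contig] = ex
        intron[contig] = iv.subtract(spans, ex)
        intergenic[contig] = iv.complement(spans, length)
    return RegionPartition(contigs=dict(ann.contigs), exon=exon,
                           intron=intron, intergenic=intergenic)


def _round_to_total(values, total: float = 100.0, decimals: int = 2):
    """Largest-remainder rounding so the parts sum exactly to ``total``."""
    scale = 10 ** decimals
    scaled = [v * scale for v in values]
    floors = [math.floor(v) for v in scaled]
    short = round(total * scale) - sum(floors)
    order = sorted(range(len(values)), key=lambda i: scaled[i] - floors[i],
                   reverse=True)
    for i in order[:short]:
        floors[i] += 1
    return [f / scale for f in floors]


def summarize_partition(p: RegionPartition) -> PartitionSummary:
    """Genome-wide totals; percentages (2 decimals, largest-remainder
    rounded so they sum to exactly 100) on the genome basis."""
    size = sum(p.contigs.values())
    ex = sum(iv.total_length(p.exon[c]) for c in p.contigs)
    intr = sum(iv.total_length(p.intron[c]) for c in p.contigs)
    inter = sum(iv.total_length(p.intergenic[c]) for c in p.contigs)
    pct = _round_to_total([100.0 * ex / size, 100.0 * intr / size,
                           100.0 * inter / size])
    return PartitionSummary(
        genome_size_bp=size, total_exon_bp=ex, total_intron_bp=intr,
        total_intergenic_bp=inter,
        exon_percent=pct[0], intron_percent=pct[1], intergenic_percent=pct[2],
    )


def length_class_histogram(region_intervals, edges=DEFAULT_LENGTH_EDGES) -> LengthClassHistogram:
    """Histogram of region lengths over left-closed right-open bins.

    ``region_intervals`` is a flat iterable of (start, end) intervals
    (concatenate contigs upstream); ``edges`` must be strictly increasing.
    """
    edges = tuple(float(e) for e in edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must be strictly increasing")
    lengths = np.array([e - s for s, e in region_intervals], dtype=float)
    nbins = len(edges) - 1
    counts = np.zeros(nbins, dtype=int)
    bases = np.zeros(nbins, dtype=float)
    if lengths.size:
        bin_idx = np.searchsorted(edges, lengths, side="right") - 1
        if np.any(bin_idx < 0) or np.any(bin_idx >= nbins):
            raise ValueError("region length outside the histogram edges")
        for b in range(nbins):
            sel = bin_idx == b
            counts[b] = int(sel.sum())
            bases[b] = float(lengths[sel].sum())
    total = bases.sum()
    fractions = bases / total if total > 0 else np.zeros(nbins)
    return LengthClassHistogram(edges=edges, region_counts=counts,
                                base_counts=bases.astype(np.int64),
                                base_fractions=fractions)


def density_track(p: RegionPartition, window: int = 10_000) -> DensityTrack:
    """Coding (exonic) fraction per non-overlapping window.

    The last window of a contig is truncated to the contig end and its
    fraction uses the actual window length.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    tracks = {}
    for contig, length in p.contigs.items():
        cov = np.zeros(length, dtype=bool)
        for s, e in p.exon[contig]:
            cov[s:e] = True
        starts = np.arange(0, length, window)
        ends = np.minimum(starts + window, length)
        frac = np.array([cov[s:e].mean() if e > s else 0.0
                         for s, e in zip(starts, ends)])
        tracks[contig] = (starts, ends, frac)
    return DensityTrack(window=window, windows=tracks)


def density_track_to_bedgraph(track: DensityTrack, out) -> None:
    with open(out, "w") as fh:
        fh.write("track type=bedGraph name=coding_density\n")
        for contig, (starts, ends, frac) in track.windows.items():
            for s, e, f in zip(starts, ends, frac):
                fh.write(f"{contig}\t{s}\t{e}\t{f:.6g}\n")
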