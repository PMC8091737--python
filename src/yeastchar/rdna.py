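"""In-silico rDNA ITS-D1/D2 profiling.

Yeast genomes carry the rDNA cistron in multi-copy arrays, typically
collapsed by assemblers and left at contig ends. This module locates the
~880 bp ITS-D1/D2 barcode segment by primer search (forward primer ITS1,
reverse primer NL4 by default), extracts all copies per assembly,
quantifies within-genome copy variability from a multiple alignment,
computes minimal between-strain distances, and estimates the expected
genomic copy number from the read-depth excess over the single-copy
baseline.

Coordinates are 0-based half-open internally; emitted tables are 1-based
inclusive (FASTA/GFF convention) and say so in their headers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import edlib
import numpy as np
import pandas as pd

__all__ = [
    "Primer",
    "PrimerSite",
    "AmpliconLocus",
    "AmpliconSet",
    "CopyAlignment",
    "VariabilityProfile",
    "DepthTrack",
    "CopyNumberEstimate",
    "DEFAULT_PRIMERS",
    "revcomp",
    "find_primer_sites",
    "extract_amplicons",
    "align_copies",
    "count_variable_positions",
    "min_pairwise_distance",
    "distance_matrix",
    "read_bedgraph",
    "estimate_copy_number",
    "classify_locus_positions",
]

# IUPAC nucleotide codes as 4-bit sets over (A, C, G, T)
_IUPAC_BITS = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
    "B": 14, "D": 13, "H": 11, "V": 7, "N": 15,
}
_COMPLEMENT = str.maketrans("ACGTURYSWKMBDHVN", "TGCAAYRSWMKVHDBN")

_ENCODE_LUT = np.zeros(256, dtype=np.uint8)
for _c, _b in _IUPAC_BITS.items():
    _ENCODE_LUT[ord(_c)] = _b
    _ENCODE_LUT[ord(_c.lower())] = _b


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    bits = _ENCODE_LUT[arr]
    if np.any(bits == 0):
        bad = chr(arr[int(np.argmax(bits == 0))])
        raise ValueError(f"non-IUPAC nucleotide character {bad!r}")
    return bits


@dataclass(frozen=True)
class Primer:
    """An oligonucleotide search pattern (IUPAC alphabet)."""

    name: str
    sequence: str
    max_mismatches: int = 2

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty primer sequence")
        _encode(self.sequence)  # validates the alphabet
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


# Canonical published fungal rDNA primer sequences (White et al. ITS1/ITS4;
# O'Donnell NL1/NL4). The source assemblies' segment is bounded by ITS1 and NL4.
DEFAULT_PRIMERS: dict[str, Primer] = {
    "ITS1": Primer("ITS1", "TCCGTAGGTGAACCTGCGG"),
    "ITS4": Primer("ITS4", "TCCTCCGCTTATTGATATGC"),
    "NL1": Primer("NL1", "GCATATCAATAAGCGGAGGAAAAG"),
    "NL4": Primer("NL4", "GGTCCGTGTTTCAAGACGG"),
}


@dataclass(frozen=True)
class PrimerSite:
    contig: str
    start: int
    end: int
    strand: str  # '+': primer as given; '-': its reverse complement on the forward text
    mismatches: int


@dataclass(frozen=True)
class AmpliconLocus:
    contig: str
    start: int
    end: int
    strand: str
    sequence: str  # orientation-normalized: forward primer first
    full_length: bool = True
    at_contig_end: bool = False

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError("invalid locus coordinates")
        if len(self.sequence) != self.end - self.start:
            raise ValueError("sequence length does not match coordinates")


@dataclass
class AmpliconSet:
    strain_id: str
    loci: list[AmpliconLocus] = field(default_factory=list)

    def full_length(self) -> list[AmpliconLocus]:
        return [l for l in self.loci if l.full_length]


@dataclass
class CopyAlignment:
    """Gapped rows of equal length; row order follows the input copies."""

    rows: list[str]

    def __post_init__(self):
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, i: int) -> str:
        return "".join(r[i] for r in self.rows)


@dataclass(frozen=True)
class VariabilityProfile:
    n_copies: int
    n_variable_positions: int
    runs: list[tuple[int, int]]  # (first column, run length), 0-based columns


@dataclass
class DepthTrack:
    """Per-base read depth as non-overlapping bedGraph-style intervals."""

    table: pd.DataFrame  # columns: contig, start, end, depth

    def per_base(self, contig: str, length: int | None = None) -> np.ndarray:
        sub = self.table[self.table["contig"] == contig]
        n = int(length if length is not None else (sub["end"].max() if len(sub) else 0))
        arr = np.zeros(n, dtype=float)
        for s, e, d in zip(sub["start"], sub["end"], sub["depth"]):
            arr[int(s):int(e)] = d
        return arr

    def contigs(self) -> list[str]:
        return list(dict.fromkeys(self.table["contig"]))


@dataclass(frozen=True)
class CopyNumberEstimate:
    assembled_copies: int
    depth_ratio: float
    expected_copies: float


def find_primer_sites(genome: dict[str, str], primer: Primer,
                      max_mismatches: int | None = None) -> list[PrimerSite]:
    """All IUPAC-aware matches of the primer on both strands.

    A primer position matches a genome position when their IUPAC base
    sets intersect; a site qualifies with at most ``max_mismatches``
    non-intersecting positions. Reverse-strand hits are reported in
    forward coordinates with strand ``'-'``.
    """
    mm_cap = primer.max_mismatches if max_mismatches is None else max_mismatches
    patterns = {"+": _encode(primer.sequence), "-": _encode(revcomp(primer.sequence))}
    m = len(primer.sequence)
    sites: list[PrimerSite] = []
    for contig, seq in genome.items():
        if len(seq) < m:
            continue
        enc = _encode(seq)
        win = np.lib.stride_tricks.sliding_window_view(enc, m)
        for strand, pat in patterns.items():
            mism = np.count_nonzero(win & pat == 0, axis=1)
            for pos in np.nonzero(mism <= mm_cap)[0]:
                sites.append(PrimerSite(contig, int(pos), int(pos) + m,
                                        strand, int(mism[pos])))
    sites.sort(key=lambda s: (s.contig, s.start, s.strand))
    return sites


def _pair_candidates(fwd_sites, rev_sites, contig_len, max_len):
    """Candidate amplicons on one contig: (start, end, strand, full_length).

    Plus strand: forward primer '+' upstream of reverse primer '-'.
    Minus strand: reverse primer '+' upstream of forward primer '-'.
    Each anchor primer takes the shortest valid span; an unpaired anchor
    whose partner window runs off the contig yields a partial copy.
    """
    cands = []
    f_plus = [s for s in fwd_sites if s.strand == "+"]
    f_minus = [s for s in fwd_sites if s.strand == "-"]
    r_minus = [s for s in rev_sites if s.strand == "-"]
    r_plus = [s for s in rev_sites if s.strand == "+"]

    used_rev: set[tuple[int, int, str]] = set()

    for f in f_plus:
        mates = [r for r in r_minus if r.start >= f.end and r.end - f.start <= max_len]
        if mates:
            r = min(mates, key=lambda r: r.end)
            used_rev.add((r.start, r.end, r.strand))
            cands.append((f.start, r.end, "+", True))
        elif f.start + max_len > contig_len:  # rev site would lie past the edge
            cands.append((f.start, contig_len, "+", False))
    for f in f_minus:
        mates = [r for r in r_plus if r.end <= f.start and f.end - r.start <= max_len]
        if mates:
            r = max(mates, key=lambda r: r.start)
            used_rev.add((r.start, r.end, r.strand))
            cands.append((r.start, f.end, "-", True))
        elif f.end - max_len < 0:
            cands.append((0, f.end, "-", False))
    # lone reverse-primer sites at the opposite edge -> fwd-truncated partials
    for r in r_minus:
        if (r.start, r.end, r.strand) not in used_rev and r.end - max_len < 0:
            cands.append((0, r.end, "+", False))
    for r in r_plus:
        if (r.start, r.end, r.strand) not in used_rev and r.start + max_len > contig_len:
            cands.append((r.start, contig_len, "-", False))
    return cands


def extract_amplicons(genome: dict[str, str], fwd: Primer, rev: Primer,
                      max_len: int = 2000, strain_id: str = "",
                      max_mismatches: int | None = None) -> AmpliconSet:
    """Extract all primer-bounded segments (both strands) from an assembly.

    For every same-contig, correctly oriented (forward site, reverse
    site) pair spanning at most ``max_len``, the segment inclusive of
    both primer sites is emitted with its sequence normalized so the
    forward primer comes first. Overlapping candidates are resolved
    shortest-span first; a lone primer site within ``max_len`` of a
    contig edge yields a truncated copy flagged ``full_length=False``.
    """
    if max_len <= max(len(fwd.sequence), len(rev.sequence)):
        raise ValueError("max_len must exceed the primer lengths")
    fwd_sites = find_primer_sites(genome, fwd, max_mismatches)
    rev_sites = find_primer_sites(genome, rev, max_mismatches)
    loci: list[AmpliconLocus] = []
    for contig, seq in genome.items():
        cands = _pair_candidates([s for s in fwd_sites if s.contig == contig],
                                 [s for s in rev_sites if s.contig == contig],
                                 len(seq), max_len)
        # full-length before partial, then shortest span wins on overlap
        cands.sort(key=lambda c: (not c[3], c[1] - c[0], c[0]))
        taken: list[tuple[int, int]] = []
        for start, end, strand, full in cands:
            if any(start < e and s < end for s, e in taken):
                continue
            taken.append((start, end))
            segment = seq[start:end].upper()
            if strand == "-":
                segment = revcomp(segment)
            loci.append(AmpliconLocus(contig, start, end, strand, segment, full))
    loci.sort(key=lambda l: (l.contig, l.start))
    return AmpliconSet(strain_id=strain_id, loci=loci)


def _pairwise_nice(query: str, target: str):
    res = edlib.align(query, target, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, query, target)
    return nice["query_aligned"], nice["target_aligned"]


def align_copies(copies: AmpliconSet | list[str]) -> CopyAlignment:
    """Center-star multiple alignment of the copies of one genome.

    The copy minimizing the summed unit-cost edit distance to all others
    is the center; every other copy is globally aligned to it and the
    pairwise gaps are merged into shared columns. Suited to the
    near-identical sequences of an intragenomic repeat family.
    """
    seqs = [l.sequence for l in copies.loci] if isinstance(copies, AmpliconSet) else list(copies)
    if len(seqs) < 2:
        raise ValueError("need >= 2 copies to align; skip single-copy genomes")
    n = len(seqs)
    dist = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = edlib.align(seqs[i], seqs[j], mode="NW", task="distance")["editDistance"]
            dist[i, j] = dist[j, i] = d
    center = int(np.argmin(dist.sum(axis=1)))
    c_seq = seqs[center]
    L = len(c_seq)

    # per sequence: inserted-query blocks before each center position,
    # and the query char aligned to each center position ('-' = deletion)
    blocks_all, aligned_all = [], []
    for i, s in enumerate(seqs):
        if i == center:
            blocks_all.append([""] * (L + 1))
            aligned_all.append(list(c_seq))
            continue
        q_aln, t_aln = _pairwise_nice(s, c_seq)
        blocks = [""] * (L + 1)
        aligned = []
        pos, run = 0, []
        for qc, tc in zip(q_aln, t_aln):
            if tc == "-":
                run.append(qc)
            else:
                blocks[pos] = "".join(run)
                run = []
                aligned.append(qc)
                pos += 1
        blocks[L] = "".join(run)
        blocks_all.append(blocks)
        aligned_all.append(aligned)

    ins_max = [max(len(b[i]) for b in blocks_all) for i in range(L + 1)]
    rows = []
    for blocks, aligned in zip(blocks_all, aligned_all):
        parts = []
        for i in range(L):
            parts.append(blocks[i] + "-" * (ins_max[i] - len(blocks[i])))
            parts.append(aligned[i])
        parts.append(blocks[L] + "-" * (ins_max[L] - len(blocks[L])))
        rows.append("".join(parts))
    return CopyAlignment(rows=rows)


def count_variable_positions(aln: CopyAlignment) -> VariabilityProfile:
    """Count alignment columns with >= 2 distinct symbols (gaps count as a
    symbol, so a single-base indel is one variable position), grouped
    into runs of adjacent variable columns."""
    variable = [len(set(aln.column(i))) >= 2 for i in range(aln.n_columns)]
    runs: list[tuple[int, int]] = []
    i = 0
    while i < len(variable):
        if variable[i]:
            j = i
            while j < len(variable) and variable[j]:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return VariabilityProfile(n_copies=len(aln.rows),
                              n_variable_positions=int(sum(variable)), runs=runs)


def min_pairwise_distance(a: AmpliconSet, b: AmpliconSet) -> int:
    """Minimal number of variations (mismatch + gap columns of a
    unit-cost global alignment) between any full-length copy of ``a``
    and any full-length copy of ``b``."""
    fa, fb = a.full_length(), b.full_length()
    if not fa or not fb:
        raise ValueError("both sets need at least one full-length copy")
    return min(edlib.align(x.sequence, y.sequence, mode="NW",
                           task="distance")["editDistance"]
               for x in fa for y in fb)


def distance_matrix(sets: list[AmpliconSet]) -> pd.DataFrame:
    """Symmetric matrix of minimal copy-to-copy variation counts."""
    ids = [s.strain_id for s in sets]
    mat = np.zeros((len(sets), len(sets)), dtype=int)
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            mat[i, j] = mat[j, i] = min_pairwise_distance(sets[i], sets[j])
    return pd.DataFrame(mat, index=ids, columns=ids)


def read_bedgraph(source) -> DepthTrack:
    df = pd.read_csv(source, sep="\t", header=None, comment="#",
                     names=["contig", "start", "end", "depth"])
    if (df["depth"] < 0).any():
        raise ValueError("negative depth in bedGraph")
    return DepthTrack(table=df)


def estimate_copy_number(depth: DepthTrack, loci: AmpliconSet,
                         contig_lengths: dict[str, int]) -> CopyNumberEstimate:
    """Expected genomic copy number from assembly depth.

    Collapsed repeats attract the reads of every genomic copy, so their
    assembled depth exceeds the single-copy baseline. The estimate is

        expected = assembled_copies x mean(depth over locus bases)
                                    / median(depth over non-locus bases)

    with the median baseline chosen to resist other repeat families.
    """
    if not loci.loci:
        raise ValueError("no loci given")
    locus_vals, background_vals = [], []
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for l in loci.loci:
        by_contig.setdefault(l.contig, []).append((l.start, l.end))
    for contig, length in contig_lengths.items():
        arr = depth.per_base(contig, length)
        mask = np.zeros(length, dtype=bool)
        for s, e in by_contig.get(contig, []):
            if e > length:
                raise ValueError(f"locus exceeds depth track on {contig}")
            mask[s:e] = True
        locus_vals.append(arr[mask])
        background_vals.append(arr[~mask])
    locus_depth = np.concatenate(locus_vals)
    background = np.concatenate(background_vals)
    if locus_depth.size == 0:
        raise ValueError("depth track does not cover the loci")
    baseline = float(np.median(background))
    if baseline <= 0:
        raise ValueError("zero baseline depth; cannot form a depth ratio")
    ratio = float(locus_depth.mean() / baseline)
    n = len(loci.loci)
    return CopyNumberEstimate(assembled_copies=n, depth_ratio=ratio,
                              expected_copies=n * ratio)


def classify_locus_positions(loci: AmpliconSet, contig_lengths: dict[str, int],
                             edge_window: int = 20_000) -> tuple[AmpliconSet, dict]:
    """Flag loci lying within ``edge_window`` of either contig edge.

    Returns a new set with ``at_contig_end`` set, plus a summary dict
    (counts and fraction at ends).
    """
    if edge_window <= 0:
        raise ValueError("edge_window must be positive")
    flagged = []
    for l in loci.loci:
        clen = contig_lengths[l.contig]
        at_end = l.start < edge_window or clen - l.end < edge_window
        flagged.append(replace(l, at_contig_end=at_end))
    n_end = sum(l.at_contig_end for l in flagged)
    summary = {"n_loci": len(flagged), "n_at_contig_end": n_end,
               "fraction_at_contig_end": n_end / len(flagged) if flagged else float("nan")}
    return AmpliconSet(strain_id=loci.strain_id, loci=flagged), summary
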