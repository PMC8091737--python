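"""Seeded synthetic-data generators with planted ground truth.

Each generator emulates the statistical structure one analysis stage
assumes — bimodal well-score distributions, primer-flanked rDNA repeat
arrays near contig ends, collapsed-repeat depth elevation, nested
gene/transcript/exon annotations, core/clade-specific/singleton protein
families — and returns, next to the input object, a :class:`TruthBundle`
that is sufficient to compute the expected downstream result without
re-running the generator. The same seed reproduces outputs bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .orthologs import ProteinEntry, ProteinSet
from .pm import WELL_IDS, PlateSeries, WellMeasurement
from .rdna import DEFAULT_PRIMERS, AmpliconLocus, AmpliconSet, DepthTrack, Primer, revcomp

__all__ = [
    "TruthBundle",
    "VariantEdit",
    "CopySpec",
    "gen_pm_plate",
    "plates_to_csv",
    "gen_rdna_genome",
    "random_copy_plan",
    "write_fasta",
    "gen_depth_track",
    "write_bedgraph",
    "gen_annotation",
    "gen_protein_families",
    "write_protein_fastas",
]

_BASES = np.array(list("ACGT"))
_AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class TruthBundle:
    """Planted parameters and per-item labels of one generator run."""

    generator: str
    seed: int
    params: dict
    data: dict


# ---------------------------------------------------------------- PM plates

def gen_pm_plate(frac_positive: float = 30 / 96, timepoints=(24.0, 48.0),
                 neg_mean: float = 3.0, pos_mean: float = 60.0,
                 neg_sd: float = 1.0, pos_sd: float = 10.0,
                 n_wells: int = 96, seed: int = 0, strain_id: str = "SYN",
                 plate_type: str = "PM1") -> tuple[PlateSeries, TruthBundle]:
    """Synthesize one plate with a planted positive/negative well split.

    Exactly ``round(frac_positive * n_wells)`` wells are positive, placed
    at random, with A1 forced negative as the no-substrate control. Each
    well's corrected signal is drawn once from its class distribution
    (on a 0-100 raw-score scale, clipped at 0, stored as absorbance/100)
    and decomposed per timepoint into ``a590 = signal + baseline`` and
    ``a750 = baseline``, so the corrected mean recovers the signal
    exactly.
    """
    if not 0.0 <= frac_positive <= 1.0:
        raise ValueError("frac_positive must lie in [0, 1]")
    if not pos_mean > neg_mean >= 0.0:
        raise ValueError("need pos_mean > neg_mean >= 0")
    rng = np.random.default_rng(seed)
    wells = list(WELL_IDS[:n_wells])
    n_pos = int(round(frac_positive * n_wells))
    eligible = [w for w in wells if w != "A1"]
    if n_pos > len(eligible):
        raise ValueError("frac_positive leaves no room for the A1 control")
    positive = set(rng.choice(eligible, size=n_pos, replace=False)) if n_pos else set()

    measurements = []
    signals = {}
    for w in wells:
        mean, sd = (pos_mean, pos_sd) if w in positive else (neg_mean, neg_sd)
        raw = max(0.0, float(rng.normal(mean, sd)))
        signals[w] = raw
        for t in timepoints:
            baseline = float(rng.uniform(0.05, 0.15))
            measurements.append(WellMeasurement(w, float(t),
                                                a590=raw / 100.0 + baseline,
                                                a750=baseline))
    series = PlateSeries(strain_id=strain_id, plate_type=plate_type,
                         measurements=measurements,
                         substrate_map={w: w for w in wells})
    truth = TruthBundle(
        generator="pm_plate", seed=seed,
        params=dict(frac_positive=frac_positive, n_wells=n_wells,
                    neg_mean=neg_mean, pos_mean=pos_mean,
                    neg_sd=neg_sd, pos_sd=pos_sd, timepoints=tuple(timepoints)),
        data=dict(positive_wells={w: (w in positive) for w in wells},
                  n_positive=n_pos, signals=signals))
    return series, truth


def plates_to_csv(plates: list[PlateSeries], path=None) -> str:
    """Serialize plates to the long-format CSV schema (deterministic)."""
    rows = []
    for p in plates:
        for m in p.measurements:
            for wl, val in ((590, m.a590), (750, m.a750)):
                rows.append((p.strain_id, p.plate_type, p.replicate, m.well_id,
                             m.timepoint, wl, val))
    df = pd.DataFrame(rows, columns=["strain_id", "plate_type", "replicate",
                                     "well_id", "timepoint_h", "wavelength_nm",
                                     "absorbance"])
    text = df.to_csv(index=False, float_format="%.6f")
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------- rDNA genomes

@dataclass(frozen=True)
class VariantEdit:
    """A single-position edit relative to the master copy."""

    pos: int            # master coordinate
    kind: str           # 'sub' | 'ins' | 'del'
    base: str = ""      # 'ins' needs a base; for 'sub', "" = any non-master base

    def __post_init__(self):
        if self.kind not in ("sub", "ins", "del"):
            raise ValueError(f"unknown edit kind {self.kind!r}")
        if self.kind == "ins" and self.base not in "ACGT":
            raise ValueError("insertions need a concrete base")
        if self.kind == "sub" and self.base not in ("", "A", "C", "G", "T"):
            raise ValueError("substitution base must be A/C/G/T or empty for auto")


@dataclass(frozen=True)
class CopySpec:
    contig: str
    position: int       # start of the copy on the forward strand
    strand: str = "+"
    edits: tuple[VariantEdit, ...] = ()
    fwd_primer_mismatches: int = 0
    rev_primer_mismatches: int = 0


def _random_seq(rng, length: int, gc: float) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=probs))


def _apply_edits(master: str, edits) -> str:
    seq = list(master)
    for e in sorted(edits, key=lambda e: e.pos, reverse=True):
        if not 0 <= e.pos < len(master):
            raise ValueError("edit outside the segment")
        if e.kind == "sub":
            if e.base == master[e.pos]:
                raise ValueError("substitution must change the base")
            if e.base:
                seq[e.pos] = e.base
            else:  # auto: deterministic non-master base
                seq[e.pos] = "ACGT"[("ACGT".index(master[e.pos]) + 1) % 4]
        elif e.kind == "del":
            del seq[e.pos]
        else:
            seq.insert(e.pos, e.base)
    return "".join(seq)


def random_copy_plan(contig_lengths: dict[str, int], n_copies: int,
                     n_variants: int = 0, segment_length: int = 880,
                     fwd: Primer = DEFAULT_PRIMERS["ITS1"],
                     rev: Primer = DEFAULT_PRIMERS["NL4"],
                     seed: int = 0, edge_offset: int = 300,
                     spacing: int = 400, indel_fraction: float = 0.2,
                     min_separation: int = 5) -> list[CopySpec]:
    """Lay out ``n_copies`` rDNA copies near contig ends and distribute
    ``n_variants`` single-position edits (SNPs plus a fraction of
    single-base indels) over them at distinct, well-separated master
    positions outside the primer regions — so the downstream variable-
    position count equals ``n_variants`` exactly.
    """
    if n_copies < 1:
        raise ValueError("need at least one copy")
    if n_variants and n_copies < 2:
        raise ValueError("variants need >= 2 copies to be variable")
    rng = np.random.default_rng(seed)
    slot = segment_length + spacing
    ends = []  # (contig, end_side)
    for contig in contig_lengths:
        ends.extend([(contig, "left"), (contig, "right")])
    per_end: dict[tuple, int] = {}
    placements = []
    for k in range(n_copies):
        contig, side = ends[k % len(ends)]
        i = per_end.get((contig, side), 0)
        per_end[(contig, side)] = i + 1
        L = contig_lengths[contig]
        pos = (edge_offset + i * slot if side == "left"
               else L - edge_offset - (i + 1) * slot)
        if pos < 0 or pos + segment_length + 10 > L:
            raise ValueError("contigs too short for the requested copy layout")
        strand = "+" if (k % 2 == 0) else "-"
        placements.append((contig, pos, strand))

    lo = len(fwd.sequence) + 10
    hi = segment_length - len(rev.sequence) - 10
    usable = np.arange(lo, hi)
    positions: list[int] = []
    rng.shuffle(usable)
    for p in usable:
        if len(positions) == n_variants:
            break
        if all(abs(p - q) >= min_separation for q in positions):
            positions.append(int(p))
    if len(positions) < n_variants:
        raise ValueError("segment too short for that many separated variants")
    edits_per_copy: dict[int, list[VariantEdit]] = {k: [] for k in range(n_copies)}
    for j, p in enumerate(sorted(positions)):
        copy_idx = int(rng.integers(0, n_copies))
        if indel_fraction > 0 and j % max(1, round(1 / indel_fraction)) == 0:
            kind = "del" if j % 2 else "ins"
            base = str(rng.choice(_BASES)) if kind == "ins" else ""
        else:
            kind, base = "sub", ""  # resolved to a non-master base at build time
        edits_per_copy[copy_idx].append(VariantEdit(p, kind, base))
    return [CopySpec(contig=c, position=p, strand=s,
                     edits=tuple(edits_per_copy[k]))
            for k, (c, p, s) in enumerate(placements)]


def gen_rdna_genome(contig_lengths: dict[str, int], copy_plan: list[CopySpec],
                    segment_length: int = 880, gc: float = 0.49, seed: int = 0,
                    fwd: Primer = DEFAULT_PRIMERS["ITS1"],
                    rev: Primer = DEFAULT_PRIMERS["NL4"],
                    strain_id: str = "SYN") -> tuple[dict[str, str], TruthBundle]:
    """Random background genome with planted primer-flanked rDNA copies.

    The master copy is ``fwd + core + revcomp(rev)`` of total length
    ``segment_length``; each planted copy applies its spec's edits (and
    optional primer-site mismatches) to the master and overwrites the
    background at its position (reverse-complemented for strand '-').
    Truth records exact coordinates, strands, oriented sequences, edits
    and the expected variable-position count.
    """
    rng = np.random.default_rng(seed)
    core_len = segment_length - len(fwd.sequence) - len(rev.sequence)
    if core_len <= 0:
        raise ValueError("segment_length must exceed the combined primer length")
    master = fwd.sequence + _random_seq(rng, core_len, gc) + revcomp(rev.sequence)
    genome = {c: list(_random_seq(rng, L, gc)) for c, L in contig_lengths.items()}

    # one edit position may be used by only one copy, else the planted
    # variable-position count would not equal the column count
    seen_pos: set[int] = set()
    for spec in copy_plan:
        for e in spec.edits:
            if e.pos in seen_pos:
                raise ValueError(f"edit position {e.pos} reused across copies")
            seen_pos.add(e.pos)

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in contig_lengths}
    loci, copy_truth = [], []
    for spec in copy_plan:
        seq = _apply_edits(master, spec.edits)
        seq = list(seq)
        for n_mm, lo, hi in ((spec.fwd_primer_mismatches, 0, len(fwd.sequence)),
                             (spec.rev_primer_mismatches,
                              len(seq) - len(rev.sequence), len(seq))):
            if n_mm:
                sites = rng.choice(np.arange(lo, hi), size=n_mm, replace=False)
                for s in sites:
                    alt = [b for b in "ACGT" if b != seq[s]]
                    seq[s] = str(rng.choice(alt))
        seq = "".join(seq)
        start, end = spec.position, spec.position + len(seq)
        if end > contig_lengths[spec.contig]:
            raise ValueError(f"copy runs past the end of {spec.contig}")
        if any(start < e and s < end for s, e in occupied[spec.contig]):
            raise ValueError(f"planted copies overlap on {spec.contig}")
        occupied[spec.contig].append((start, end))
        inserted = seq if spec.strand == "+" else revcomp(seq)
        genome[spec.contig][start:end] = list(inserted)
        loci.append(AmpliconLocus(spec.contig, start, end, spec.strand, seq))
        copy_truth.append(dict(contig=spec.contig, start=start, end=end,
                               strand=spec.strand, sequence=seq,
                               edits=spec.edits,
                               fwd_primer_mismatches=spec.fwd_primer_mismatches,
                               rev_primer_mismatches=spec.rev_primer_mismatches))
    genome_str = {c: "".join(s) for c, s in genome.items()}
    truth = TruthBundle(
        generator="rdna_genome", seed=seed,
        params=dict(contig_lengths=dict(contig_lengths), gc=gc,
                    segment_length=segment_length,
                    fwd=fwd.name, rev=rev.name),
        data=dict(master=master, loci=AmpliconSet(strain_id, loci),
                  copies=copy_truth,
                  n_variable_positions=len(seen_pos)))
    return genome_str, truth


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


# ---------------------------------------------------------------- depth tracks

def gen_depth_track(contig_lengths: dict[str, int], loci,
                    collapse_factor: float = 1.57, baseline: float = 50.0,
                    noise_cv: float = 0.0, seed: int = 0
                    ) -> tuple[DepthTrack, TruthBundle]:
    """Per-base depth with multiplicative log-normal noise; the given
    loci (an :class:`AmpliconSet` or (contig, start, end) triples) are
    elevated by ``collapse_factor``, mimicking a collapsed repeat."""
    if collapse_factor < 0:
        raise ValueError("collapse_factor must be >= 0")
    rng = np.random.default_rng(seed)
    if isinstance(loci, AmpliconSet):
        triples = [(l.contig, l.start, l.end) for l in loci.loci]
    else:
        triples = [(c, int(s), int(e)) for c, s, e in loci]
    if noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(noise_cv ** 2)))
        mu = -0.5 * sigma ** 2  # mean-one multiplicative noise
    rows = []
    for contig, length in contig_lengths.items():
        depth = np.full(length, float(baseline))
        if noise_cv > 0:
            depth *= rng.lognormal(mean=mu, sigma=sigma, size=length)
        for c, s, e in triples:
            if c == contig:
                depth[s:e] *= collapse_factor
        depth = np.round(depth, 3)
        # run-length encode equal neighbours
        change = np.flatnonzero(np.diff(depth)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [length]))
        for s, e in zip(starts, ends):
            rows.append((contig, int(s), int(e), float(depth[s])))
    table = pd.DataFrame(rows, columns=["contig", "start", "end", "depth"])
    truth = TruthBundle(
        generator="depth_track", seed=seed,
        params=dict(collapse_factor=collapse_factor, baseline=baseline,
                    noise_cv=noise_cv),
        data=dict(n_loci=len(triples),
                  expected_copies=len(triples) * collapse_factor))
    return DepthTrack(table=table), truth


def write_bedgraph(track: DepthTrack, path) -> None:
    track.table.to_csv(path, sep="\t", header=False, index=False,
                       float_format="%.3f")


# ---------------------------------------------------------------- annotations

def gen_annotation(contig_lengths: dict[str, int], n_genes: int = 20,
                   exons_per_gene=(1, 4), exon_len=(200, 1500),
                   intron_len=(50, 500), gap_len=(200, 3000),
                   seed: int = 0, plan=None) -> tuple[str, TruthBundle]:
    """Emit a GFF3 gene/mRNA/exon hierarchy with known exact totals.

    In random mode genes are packed contig by contig with random
    intergenic gaps and exon/intron geometry; ``plan`` overrides it with
    an explicit layout: a list of ``(contig, [exon (start, end), ...])``
    with absolute, sorted, non-overlapping exon coordinates per gene.
    Truth records the exact planted exon/intron/intergenic base totals.
    """
    rng = np.random.default_rng(seed)
    genes: list[tuple[str, list[tuple[int, int]]]] = []
    if plan is not None:
        genes = [(c, [tuple(map(int, e)) for e in exons]) for c, exons in plan]
    else:
        contigs = list(contig_lengths)
        cursors = {c: 0 for c in contigs}
        ci = 0
        for _ in range(n_genes):
            placed = False
            for _try in range(len(contigs)):
                contig = contigs[ci % len(contigs)]
                ci += 1
                L = contig_lengths[contig]
                gap = int(rng.integers(*gap_len))
                k = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
                ex_lens = rng.integers(*exon_len, size=k)
                in_lens = rng.integers(*intron_len, size=max(0, k - 1))
                start = cursors[contig] + gap
                exons, pos = [], start
                for j, el in enumerate(ex_lens):
                    exons.append((pos, pos + int(el)))
                    pos += int(el) + (int(in_lens[j]) if j < len(in_lens) else 0)
                if exons[-1][1] + 1 > L:
                    continue
                cursors[contig] = exons[-1][1]
                genes.append((contig, exons))
                placed = True
                break
            if not placed:
                raise ValueError("infeasible packing: contigs too small for n_genes")

    lines = ["##gff-version 3"]
    for c, L in contig_lengths.items():
        lines.append(f"##sequence-region {c} 1 {L}")
    exon_bp = intron_bp = 0
    gene_spans: dict[str, list[tuple[int, int]]] = {c: [] for c in contig_lengths}
    for i, (contig, exons) in enumerate(genes, start=1):
        gid, tid = f"gene{i:04d}", f"mRNA{i:04d}"
        gs, ge = exons[0][0], exons[-1][1]
        gene_spans[contig].append((gs, ge))
        exon_bp += sum(e - s for s, e in exons)
        intron_bp += (ge - gs) - sum(e - s for s, e in exons)
        strand = "+" if i % 2 else "-"
        lines.append(f"{contig}\tsynth\tgene\t{gs + 1}\t{ge}\t.\t{strand}\t.\tID={gid}")
        lines.append(f"{contig}\tsynth\tmRNA\t{gs + 1}\t{ge}\t.\t{strand}\t.\t"
                     f"ID={tid};Parent={gid}")
        for j, (s, e) in enumerate(exons, start=1):
            lines.append(f"{contig}\tsynth\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                         f"ID={tid}.exon{j};Parent={tid}")
    genome_size = sum(contig_lengths.values())
    gene_bp = sum(e - s for spans in gene_spans.values() for s, e in spans)
    truth = TruthBundle(
        generator="annotation", seed=seed,
        params=dict(contig_lengths=dict(contig_lengths), n_genes=len(genes)),
        data=dict(exon_bp=exon_bp, intron_bp=intron_bp,
                  intergenic_bp=genome_size - gene_bp,
                  genome_size_bp=genome_size, genes=genes))
    return "\n".join(lines) + "\n", truth


# ---------------------------------------------------------------- protein sets

def _mutate(rng, seq: str, rate: float) -> str:
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        alt = _AA20[_AA20 != out[i]]
        out[i] = str(rng.choice(alt))
    return "".join(out)


def gen_protein_families(n_genomes: int = 5, n_core: int = 50,
                         clades=((0, 1), (2, 3, 4)), n_clade_specific=(10, 10),
                         n_singletons: int = 2, mutation_rate: float = 0.05,
                         length: int = 150, seed: int = 0
                         ) -> tuple[list[ProteinSet], TruthBundle]:
    """Protein sets with a planted core / clade-specific / singleton
    architecture.

    Each family has one random master sequence, copied into its member
    genomes with independent per-residue substitutions at
    ``mutation_rate``; singletons are fresh random sequences private to
    one genome. Truth records every family's genome pattern and the
    expected UpSet-style pattern counts (singletons included as
    genome-exclusive groups).
    """
    if not 0.0 <= mutation_rate <= 1.0:
        raise ValueError("mutation_rate must lie in [0, 1]")
    if any(i >= n_genomes for clade in clades for i in clade):
        raise ValueError("clade index out of range")
    rng = np.random.default_rng(seed)
    genome_ids = [f"G{i + 1}" for i in range(n_genomes)]
    families = [(f"core{k:04d}", tuple(range(n_genomes))) for k in range(n_core)]
    for ci, (clade, n_spec) in enumerate(zip(clades, n_clade_specific)):
        families += [(f"clade{ci}_{k:04d}", tuple(clade)) for k in range(n_spec)]

    entries: dict[str, list[ProteinEntry]] = {g: [] for g in genome_ids}
    fam_truth = {}
    for fam_id, member_idx in families:
        master = "".join(rng.choice(_AA20, size=length))
        pattern = frozenset(genome_ids[i] for i in member_idx)
        fam_truth[fam_id] = pattern
        for i in member_idx:
            seq = _mutate(rng, master, mutation_rate)
            entries[genome_ids[i]].append(
                ProteinEntry(gene_id=fam_id, transcript_id=f"{fam_id}.t1.{i}",
                             sequence=seq))
    singleton_ids = []
    for i, g in enumerate(genome_ids):
        for k in range(n_singletons):
            gid = f"sing_{g}_{k:02d}"
            entries[g].append(ProteinEntry(
                gene_id=gid, transcript_id=f"{gid}.t1",
                sequence="".join(rng.choice(_AA20, size=length))))
            singleton_ids.append((g, gid))

    expected_counts: dict[frozenset, int] = {}
    for pattern in fam_truth.values():
        expected_counts[pattern] = expected_counts.get(pattern, 0) + 1
    for g, _gid in singleton_ids:
        p = frozenset({g})
        expected_counts[p] = expected_counts.get(p, 0) + 1

    psets = [ProteinSet(genome_id=g, entries=entries[g]) for g in genome_ids]
    truth = TruthBundle(
        generator="protein_families", seed=seed,
        params=dict(n_genomes=n_genomes, n_core=n_core, clades=clades,
                    n_clade_specific=tuple(n_clade_specific),
                    n_singletons=n_singletons, mutation_rate=mutation_rate,
                    length=length),
        data=dict(family_patterns=fam_truth, singletons=singleton_ids,
                  expected_pattern_counts=expected_counts))
    return psets, truth


def write_protein_fastas(psets: list[ProteinSet], outdir) -> list[str]:
    import os
    paths = []
    for p in psets:
        path = os.path.join(str(outdir), f"{p.genome_id}.faa")
        with open(path, "w") as fh:
            for e in p.entries:
                fh.write(f">{e.gene_id}|{e.transcript_id}\n{e.sequence}\n")
        paths.append(path)
    return paths
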