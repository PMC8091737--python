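"""Reciprocal-best-hit (RBH) gene classification across genomes.

Genes are compared by in-process Smith-Waterman local alignment
(BLOSUM62, affine gaps: a gap of length L costs 11 + L, the BLAST
default cost model). For every ordered genome pair each query's best
subject is recorded; a pair of genes is orthologous when each is the
other's best hit and both scores pass a score-ratio filter relative to
the query's self-alignment score. RBH pairs are grouped transitively
(single linkage) into ortholog groups whose genome membership patterns
yield core / subset-specific / strain-exclusive counts. Singletons are
stricter than pattern-exclusive genes: a singleton has no hit at all
above the score-ratio cutoff in any other genome.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

__all__ = [
    "ProteinEntry",
    "ProteinSet",
    "Hit",
    "HitTable",
    "OrthologGroup",
    "OrthologSets",
    "Singleton",
    "read_protein_fasta",
    "make_aligner",
    "select_representative",
    "score_pairs",
    "reciprocal_best_hits",
    "membership_patterns",
    "find_singletons",
    "classify",
]

_AA = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class ProteinEntry:
    gene_id: str
    transcript_id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.gene_id}")
        bad = set(self.sequence.upper()) - _AA
        if bad:
            raise ValueError(f"non-amino-acid letters {sorted(bad)} in {self.gene_id}")


@dataclass
class ProteinSet:
    """One genome's proteins, one representative transcript per gene."""

    genome_id: str
    entries: list[ProteinEntry]

    def __post_init__(self):
        tids = [e.transcript_id for e in self.entries]
        if len(tids) != len(set(tids)):
            raise ValueError("duplicate transcript ids")

    def gene_ids(self) -> list[str]:
        return [e.gene_id for e in self.entries]


@dataclass(frozen=True)
class Hit:
    query: str
    subject: str
    score: float
    is_best: bool


@dataclass
class HitTable:
    """Directed all-vs-all scores for one ordered genome pair."""

    query_genome: str
    subject_genome: str
    hits: list[Hit]
    query_self_scores: dict[str, float]

    def best(self) -> dict[str, tuple[str, float]]:
        return {h.query: (h.subject, h.score) for h in self.hits if h.is_best}


@dataclass(frozen=True)
class OrthologGroup:
    members: tuple[tuple[str, str], ...]  # (genome_id, gene_id)
    pattern: frozenset[str]
    inparalog_collision: bool


@dataclass
class OrthologSets:
    genome_ids: list[str]
    groups: list[OrthologGroup]

    def pattern_counts(self) -> dict[frozenset, int]:
        """Number of ortholog groups per genome-membership pattern."""
        out: dict[frozenset, int] = {}
        for g in self.groups:
            out[g.pattern] = out.get(g.pattern, 0) + 1
        return out

    def gene_counts_per_genome(self) -> dict[str, int]:
        out = {g: 0 for g in self.genome_ids}
        for grp in self.groups:
            for genome, _gene in grp.members:
                out[genome] += 1
        return out

    @property
    def core_pattern(self) -> frozenset:
        return frozenset(self.genome_ids)


@dataclass(frozen=True)
class Singleton:
    genome_id: str
    gene_id: str
    best_cross_ratio: float
    note: str = ""


def read_protein_fasta(path, genome_id: str) -> ProteinSet:
    """Read a protein FASTA with ``gene_id|transcript_id`` headers."""
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene, _, tid = rec.id.partition("|")
        entries.append(ProteinEntry(gene_id=gene, transcript_id=tid or rec.id,
                                    sequence=str(rec.seq).upper()))
    return ProteinSet(genome_id=genome_id, entries=entries)


def make_aligner(gap_open: int = 11, gap_extend: int = 1,
                 matrix: str = "BLOSUM62") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # Biopython's open score applies to a gap's first residue, so BLAST's
    # "11/1" (gap of length L costs 11 + L) maps to open -(11+1), extend -1.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def select_representative(transcripts, support) -> tuple[str, str]:
    """Pick one transcript per gene: maximal cross-genome homolog
    support, ties broken by longest sequence, then lexicographic id.

    ``transcripts`` is an iterable of (transcript_id, sequence);
    ``support`` maps transcript_id to the number of genomes containing a
    qualifying homolog of it.
    """
    transcripts = list(transcripts)
    if not transcripts:
        raise ValueError("gene has no transcripts")
    return min(transcripts,
               key=lambda ts: (-support.get(ts[0], 0), -len(ts[1]), ts[0]))


def _self_scores(pset: ProteinSet, aligner) -> dict[str, float]:
    return {e.gene_id: float(aligner.score(e.sequence, e.sequence))
            for e in pset.entries}


def score_pairs(a: ProteinSet, b: ProteinSet,
                aligner: Align.PairwiseAligner | None = None) -> HitTable:
    """Local-alignment scores of every gene of ``a`` against every gene
    of ``b``; each query's best subject is flagged (ties broken by
    lexicographically smallest subject id; no flag when the best score
    is not positive)."""
    if not a.entries or not b.entries:
        raise ValueError("empty protein set")
    aligner = aligner or make_aligner()
    hits: list[Hit] = []
    for qa in a.entries:
        scores = [(float(aligner.score(qa.sequence, sb.sequence)), sb.gene_id)
                  for sb in b.entries]
        best_score = max(s for s, _ in scores)
        best_subject = min(g for s, g in scores if s == best_score)
        for s, g in scores:
            hits.append(Hit(query=qa.gene_id, subject=g, score=s,
                            is_best=(best_score > 0 and g == best_subject
                                     and s == best_score)))
    return HitTable(query_genome=a.genome_id, subject_genome=b.genome_id,
                    hits=hits, query_self_scores=_self_scores(a, aligner))


def reciprocal_best_hits(ab: HitTable, ba: HitTable, min_ratio: float = 0.3):
    """Ortholog pairs for one genome pair.

    (x, y) qualifies when y is x's best subject, x is y's best subject,
    and each direction's score is at least ``min_ratio`` times the
    query's self-alignment score.

    Returns tuples ``((genome_a, x), (genome_b, y), score_ab, score_ba)``.
    """
    if ab.query_genome != ba.subject_genome or ab.subject_genome != ba.query_genome:
        raise ValueError("hit tables are not the two directions of one genome pair")
    best_ab, best_ba = ab.best(), ba.best()
    pairs = []
    for x, (y, s_xy) in sorted(best_ab.items()):
        back = best_ba.get(y)
        if back is None or back[0] != x:
            continue
        s_yx = back[1]
        if s_xy < min_ratio * ab.query_self_scores[x]:
            continue
        if s_yx < min_ratio * ba.query_self_scores[y]:
            continue
        pairs.append(((ab.query_genome, x), (ab.subject_genome, y), s_xy, s_yx))
    return pairs


class _UnionFind:
    def __init__(self):
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def membership_patterns(genomes: list[ProteinSet], pairs) -> OrthologSets:
    """Group genes transitively linked by RBH pairs (single linkage) and
    tally genome-membership patterns, UpSet-style.

    Every gene of every genome appears in exactly one group; unlinked
    genes form their own genome-exclusive group. A group holding two
    genes of one genome is kept and flagged as an inparalog collision.
    """
    uf = _UnionFind()
    for pset in genomes:
        for gene in pset.gene_ids():
            uf.find((pset.genome_id, gene))
    for (na, nb, *_rest) in pairs:
        uf.union(na, nb)
    members_by_root: dict = {}
    for pset in genomes:
        for gene in pset.gene_ids():
            node = (pset.genome_id, gene)
            members_by_root.setdefault(uf.find(node), []).append(node)
    groups = []
    for root in sorted(members_by_root):
        members = tuple(sorted(members_by_root[root]))
        pattern = frozenset(g for g, _ in members)
        groups.append(OrthologGroup(members=members, pattern=pattern,
                                    inparalog_collision=len(pattern) < len(members)))
    return OrthologSets(genome_ids=[p.genome_id for p in genomes], groups=groups)


def find_singletons(genomes: list[ProteinSet], hit_tables: dict,
                    singleton_cutoff: float = 0.3) -> list[Singleton]:
    """Genes with no qualifying similarity hit in any other genome.

    A gene is a singleton iff, for every other genome, its best
    cross-genome score divided by its self-score stays below
    ``singleton_cutoff``. This is stricter than having no RBH: a gene
    whose partner was disrupted (e.g. a frameshift splitting the ORF)
    still scores a strong partial hit and is therefore not a singleton.

    ``hit_tables`` maps (query_genome, subject_genome) to the
    :class:`HitTable` of that direction.
    """
    singles: list[Singleton] = []
    ids = [p.genome_id for p in genomes]
    for pset in genomes:
        others = [g for g in ids if g != pset.genome_id]
        best_by_query: dict[str, float] = {}
        self_scores: dict[str, float] = {}
        for other in others:
            table = hit_tables[(pset.genome_id, other)]
            self_scores.update(table.query_self_scores)
            per_query: dict[str, float] = {}
            for h in table.hits:
                per_query[h.query] = max(per_query.get(h.query, 0.0), h.score)
            for q, s in per_query.items():
                best_by_query[q] = max(best_by_query.get(q, 0.0), s)
        for gene in pset.gene_ids():
            ratio = best_by_query.get(gene, 0.0) / self_scores[gene]
            if ratio < singleton_cutoff:
                singles.append(Singleton(genome_id=pset.genome_id, gene_id=gene,
                                         best_cross_ratio=float(ratio)))
    return singles


def classify(genomes: list[ProteinSet], min_ratio: float = 0.3,
             singleton_cutoff: float = 0.3,
             aligner: Align.PairwiseAligner | None = None):
    """End-to-end classification of a set of proteomes.

    Returns ``(OrthologSets, singletons, hit_tables)``.
    """
    aligner = aligner or make_aligner()
    hit_tables: dict[tuple[str, str], HitTable] = {}
    all_pairs = []
    for i, a in enumerate(genomes):
        for b in genomes[i + 1:]:
            ab = score_pairs(a, b, aligner)
            ba = score_pairs(b, a, aligner)
            hit_tables[(a.genome_id, b.genome_id)] = ab
            hit_tables[(b.genome_id, a.genome_id)] = ba
            all_pairs.extend(reciprocal_best_hits(ab, ba, min_ratio))
    sets = membership_patterns(genomes, all_pairs)
    singles = find_singletons(genomes, hit_tables, singleton_cutoff)
    return sets, singles, hit_tables
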