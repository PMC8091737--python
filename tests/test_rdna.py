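"""Primer search, amplicon extraction, copy variability and depth tests."""

import dataclasses

import numpy as np
import pytest

from yeastchar import rdna, synth
from yeastchar.rdna import DEFAULT_PRIMERS, Primer, revcomp

ITS1, NL4 = DEFAULT_PRIMERS["ITS1"], DEFAULT_PRIMERS["NL4"]


def _brute_force_sites(genome, primer, max_mm):
    """Independent O(n*m) scan oracle, IUPAC-aware on the primer side."""
    iupac = {"A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT",
             "S": "CG", "W": "AT", "K": "GT", "M": "AC", "B": "CGT",
             "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT"}
    out = []
    for strand, pat in (("+", primer.sequence), ("-", revcomp(primer.sequence))):
        for contig, seq in genome.items():
            for i in range(len(seq) - len(pat) + 1):
                mm = sum(seq[i + j] not in iupac[p] for j, p in enumerate(pat))
                if mm <= max_mm:
                    out.append((contig, i, i + len(pat), strand, mm))
    return sorted(out)


class TestFindPrimerSites:
    def test_planted_exact_forward_site(self):
        genome = {"c": "T" * 50 + ITS1.sequence + "A" * 50}
        sites = rdna.find_primer_sites(genome, ITS1, max_mismatches=0)
        assert [(s.start, s.end, s.strand, s.mismatches) for s in sites] == \
            [(50, 50 + len(ITS1.sequence), "+", 0)]

    def test_reverse_complement_site(self):
        genome = {"c": "T" * 30 + revcomp(ITS1.sequence) + "A" * 30}
        (site,) = rdna.find_primer_sites(genome, ITS1, max_mismatches=0)
        assert site.strand == "-" and site.start == 30

    def test_mismatch_budget(self):
        seq = list(ITS1.sequence)
        seq[5] = {"A": "C"}.get(seq[5], "A")  # one planted mismatch
        genome = {"c": "T" * 40 + "".join(seq) + "G" * 40}
        assert len(rdna.find_primer_sites(genome, ITS1, max_mismatches=2)) == 1
        assert len(rdna.find_primer_sites(genome, ITS1, max_mismatches=0)) == 0

    def test_iupac_degeneracy_matches_base_set(self):
        p = Primer("deg", "ACGTN" + "R")
        genome = {"c": "TTACGTCGTT"}  # ACGTCG: N matches C, R matches G
        sites = rdna.find_primer_sites(genome, p, max_mismatches=0)
        assert any(s.start == 2 and s.strand == "+" for s in sites)

    def test_primer_longer_than_contig(self):
        assert rdna.find_primer_sites({"c": "ACGT"}, ITS1) == []

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        genome = {"c1": "".join(rng.choice(list("ACGT"), 400))}
        # embed a noisy primer copy
        s = list(genome["c1"])
        s[100:100 + len(ITS1.sequence)] = ITS1.sequence
        s[103] = "A" if s[103] != "A" else "C"
        genome["c1"] = "".join(s)
        for mm in (0, 1, 2):
            got = sorted((x.contig, x.start, x.end, x.strand, x.mismatches)
                         for x in rdna.find_primer_sites(genome, ITS1, mm))
            assert got == _brute_force_sites(genome, ITS1, mm)


class TestExtractAmplicons:
    def test_planted_copies_recovered_exactly(self, planted_rdna):
        genome, truth, _ = planted_rdna
        amps = rdna.extract_amplicons(genome, ITS1, NL4, strain_id="S")
        got = {(l.contig, l.start, l.end, l.strand, l.sequence) for l in amps.loci}
        exp = {(l.contig, l.start, l.end, l.strand, l.sequence)
               for l in truth.data["loci"].loci}
        assert got == exp
        assert all(l.full_length for l in amps.loci)

    def test_reverse_strand_copy_orientation_normalized(self):
        lengths = {"c": 5000}
        plan = [synth.CopySpec("c", 1000, "-")]
        genome, truth = synth.gen_rdna_genome(lengths, plan, seed=1)
        (locus,) = rdna.extract_amplicons(genome, ITS1, NL4).loci
        assert locus.strand == "-"
        assert locus.sequence == truth.data["master"]
        assert locus.sequence.startswith(ITS1.sequence)

    def test_partial_copy_at_contig_end(self):
        lengths = {"c": 5000}
        plan = [synth.CopySpec("c", 1000, "+")]
        genome, truth = synth.gen_rdna_genome(lengths, plan, seed=2)
        # truncate the contig inside the planted copy, past the fwd primer
        cut = 1000 + 400
        truncated = {"c": genome["c"][:cut]}
        (locus,) = rdna.extract_amplicons(truncated, ITS1, NL4).loci
        assert not locus.full_length
        assert locus.start == 1000 and locus.end == cut

    def test_loci_do_not_overlap(self, planted_rdna):
        genome, _, _ = planted_rdna
        loci = rdna.extract_amplicons(genome, ITS1, NL4).loci
        by_contig = {}
        for l in loci:
            by_contig.setdefault(l.contig, []).append((l.start, l.end))
        for spans in by_contig.values():
            spans.sort()
            assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))

    def test_extraction_with_primer_site_mismatches(self):
        lengths = {"c1": 6000, "c2": 6000}
        plan = [synth.CopySpec("c1", 500, "+", (), 2, 1),
                synth.CopySpec("c2", 500, "-", (), 1, 2)]
        genome, truth = synth.gen_rdna_genome(lengths, plan, seed=3)
        amps = rdna.extract_amplicons(genome, ITS1, NL4, max_mismatches=2)
        got = {(l.contig, l.start, l.end, l.strand) for l in amps.loci}
        assert got == {("c1", 500, 500 + 880, "+"), ("c2", 500, 500 + 880, "-")}
        assert rdna.extract_amplicons(genome, ITS1, NL4, max_mismatches=0).loci == []

    def test_recall_precision_over_seeded_genomes(self):
        lengths = {"cA": 9000, "cB": 9000}
        for seed in range(50):
            plan = synth.random_copy_plan(lengths, n_copies=4, n_variants=5,
                                          seed=seed)
            plan = [dataclasses.replace(s, fwd_primer_mismatches=seed % 3,
                                        rev_primer_mismatches=(seed + 1) % 3)
                    for s in plan]
            genome, truth = synth.gen_rdna_genome(lengths, plan, seed=seed)
            amps = rdna.extract_amplicons(genome, ITS1, NL4, max_mismatches=2)
            got = {(l.contig, l.start, l.end, l.strand) for l in amps.loci}
            exp = {(l.contig, l.start, l.end, l.strand)
                   for l in truth.data["loci"].loci}
            assert got == exp, f"seed {seed}"


class TestAlignAndVariability:
    def test_identical_copies_no_gaps(self):
        aln = rdna.align_copies(["ACGTACGT", "ACGTACGT", "ACGTACGT"])
        assert all("-" not in r for r in aln.rows)
        assert rdna.count_variable_positions(aln).n_variable_positions == 0

    def test_single_deletion_single_gap_column(self):
        aln = rdna.align_copies(["ACGTTTACGT", "ACGTTACGT"])
        gap_cols = [i for i in range(aln.n_columns) if "-" in aln.column(i)]
        assert len(gap_cols) == 1
        prof = rdna.count_variable_positions(aln)
        assert prof.n_variable_positions == 1
        assert prof.runs == [(gap_cols[0], 1)]

    def test_ungapping_round_trip(self, planted_rdna):
        genome, _, _ = planted_rdna
        amps = rdna.extract_amplicons(genome, ITS1, NL4)
        aln = rdna.align_copies(amps)
        for row, locus in zip(aln.rows, amps.loci):
            assert row.replace("-", "") == locus.sequence

    def test_single_copy_errors(self):
        with pytest.raises(ValueError, match="single-copy"):
            rdna.align_copies(["ACGT"])

    def test_planted_snps_and_indel_counted(self):
        base = "ACGTACGTACGTACGTACGTACGTACGT"
        copies = [base,
                  base[:5] + "T" + base[6:],              # SNP at 5 (C->T)
                  base[:12] + "C" + base[13:],            # SNP at 12 (A->C)
                  base[:20] + base[21:]]                  # 1-base deletion at 20
        prof = rdna.count_variable_positions(rdna.align_copies(copies))
        assert prof.n_variable_positions == 3
        assert all(length == 1 for _, length in prof.runs)

    def test_counts_match_column_scan_oracle(self, planted_rdna):
        genome, truth, _ = planted_rdna
        aln = rdna.align_copies(rdna.extract_amplicons(genome, ITS1, NL4))
        oracle = sum(len(set(col)) >= 2 for col in zip(*aln.rows))
        prof = rdna.count_variable_positions(aln)
        assert prof.n_variable_positions == oracle == truth.data["n_variable_positions"]
        assert prof.n_variable_positions == sum(l for _, l in prof.runs)


def _copy_set(strain, seqs):
    loci = [rdna.AmpliconLocus("c", 1000 * i, 1000 * i + len(s), "+", s)
            for i, s in enumerate(seqs)]
    return rdna.AmpliconSet(strain, loci)


class TestMinPairwiseDistance:
    def _master(self, seed=4):
        rng = np.random.default_rng(seed)
        return "".join(rng.choice(list("ACGT"), 300))

    def test_shared_identical_copy_gives_zero(self):
        m = self._master()
        a = _copy_set("A", [m, m[:100] + "T" + m[101:]])
        b = _copy_set("B", [m])
        assert rdna.min_pairwise_distance(a, b) == 0

    @pytest.mark.parametrize("k", [1, 5, 20])
    def test_planted_substitution_count(self, k):
        m = self._master()
        rng = np.random.default_rng(k)
        pos = rng.choice(len(m), size=k, replace=False)
        other = list(m)
        for p in pos:
            other[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[p]]
        assert rdna.min_pairwise_distance(_copy_set("A", [m]),
                                          _copy_set("B", ["".join(other)])) == k

    def test_symmetry(self):
        m = self._master()
        a = _copy_set("A", [m])
        b = _copy_set("B", [m[:50] + m[60:]])
        assert rdna.min_pairwise_distance(a, b) == rdna.min_pairwise_distance(b, a)

    def test_requires_full_length_copies(self):
        a = _copy_set("A", ["ACGTACGT"])
        partial = rdna.AmpliconSet("B", [dataclasses.replace(
            a.loci[0], full_length=False)])
        with pytest.raises(ValueError, match="full-length"):
            rdna.min_pairwise_distance(a, partial)

    def test_distance_matrix_symmetric_zero_diagonal(self):
        m = self._master()
        sets = [_copy_set("A", [m]), _copy_set("B", [m[:150] + "A" + m[150:]]),
                _copy_set("C", [m])]
        mat = rdna.distance_matrix(sets)
        assert (mat.values == mat.values.T).all()
        assert (np.diag(mat.values) == 0).all()
        assert mat.loc["A", "C"] == 0


class TestCopyNumber:
    def _setup(self, collapse, noise_cv, seed=0, n_copies=3):
        lengths = {"c1": 9000, "c2": 9000}
        plan = synth.random_copy_plan(lengths, n_copies, 0, seed=seed)
        genome, truth = synth.gen_rdna_genome(lengths, plan, seed=seed)
        track, _ = synth.gen_depth_track(lengths, truth.data["loci"],
                                         collapse_factor=collapse,
                                         noise_cv=noise_cv, seed=seed)
        return track, truth.data["loci"], lengths

    def test_uniform_depth_ratio_one(self):
        track, loci, lengths = self._setup(1.0, 0.0)
        est = rdna.estimate_copy_number(track, loci, lengths)
        assert est.expected_copies == pytest.approx(3.0)

    def test_double_depth_doubles_copies(self):
        track, loci, lengths = self._setup(2.0, 0.0)
        assert rdna.estimate_copy_number(track, loci, lengths).expected_copies \
            == pytest.approx(6.0)

    def test_collapse_factor_mirroring_depth_excess(self):
        track, loci, lengths = self._setup(1.57, 0.0)
        est = rdna.estimate_copy_number(track, loci, lengths)
        assert est.expected_copies == pytest.approx(4.71, abs=0.01)

    def test_noisy_depth_within_5_percent(self):
        for seed in range(50):
            track, loci, lengths = self._setup(1.57, 0.1, seed=seed)
            est = rdna.estimate_copy_number(track, loci, lengths)
            assert est.expected_copies == pytest.approx(3 * 1.57, rel=0.05)

    def test_zero_baseline_errors(self):
        track, loci, lengths = self._setup(1.57, 0.0)
        zero = rdna.DepthTrack(track.table.assign(depth=0.0))
        with pytest.raises(ValueError, match="baseline"):
            rdna.estimate_copy_number(zero, loci, lengths)


class TestLocusPositions:
    def test_edge_flags(self):
        loci = rdna.AmpliconSet("S", [
            rdna.AmpliconLocus("c", 0, 880, "+", "A" * 880),
            rdna.AmpliconLocus("c", 499_000, 499_880, "+", "A" * 880),
            rdna.AmpliconLocus("c", 999_000, 999_880, "+", "A" * 880),
        ])
        flagged, summary = rdna.classify_locus_positions(loci, {"c": 1_000_000},
                                                         edge_window=20_000)
        assert [l.at_contig_end for l in flagged.loci] == [True, False, True]
        assert summary["n_at_contig_end"] == 2

    def test_tandem_array_near_end_all_flagged(self):
        lengths = {"c": 8000}
        plan = [synth.CopySpec("c", p, "+") for p in (4000, 5000, 6000)]
        genome, truth = synth.gen_rdna_genome(lengths, plan, seed=6)
        flagged, summary = rdna.classify_locus_positions(
            truth.data["loci"], lengths, edge_window=5000)
        assert summary["fraction_at_contig_end"] == 1.0
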